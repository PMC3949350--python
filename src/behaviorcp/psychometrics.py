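"""Psychometric functions: logistic fits of P(long | stimulus duration).

A psychometric function maps stimulus duration I to the probability of a
"long" categorization via a two-parameter logistic,

    P(long | I) = logistic(intercept + slope * f(I)),

with f the stimulus transform (log duration by default, since the interval
set is near-geometric; linear duration optional).  The bias point is the
duration judged long 50% of the time, f^{-1}(-intercept / slope); the
slope measures sensitivity.  Fits are per session; subjects are summarized
by averaging fitted parameters across their converged session fits.
"""

from __future__ import annotations

import math
import warnings
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.base import BaseEstimator

from ._utils import sigmoid
from .exceptions import DegenerateDesignError, InputError, SummaryError

_TRANSFORMS = ("log_duration", "linear_duration")


class PsychometricRegression(BaseEstimator):
    """Maximum-likelihood logistic psychometric fit.

    Parameters
    ----------
    transform : {"log_duration", "linear_duration"}
        Stimulus predictor scale.

    Attributes
    ----------
    intercept_ : float
        Fitted intercept, log-odds.
    slope_ : float
        Fitted slope, log-odds per unit of transformed stimulus.
    bias_point_ : float
        Stimulus (seconds) at which P(long) = 0.5; NaN when slope = 0.
    converged_ : bool
        False when the optimizer failed or the data were separable.
    n_trials_ : int
    """

    def __init__(self, transform: str = "log_duration"):
        self.transform = transform

    def _check_transform(self):
        if self.transform not in _TRANSFORMS:
            raise InputError(f"unknown stimulus transform {self.transform!r}")

    def _f(self, stimulus):
        self._check_transform()
        stimulus = np.asarray(stimulus, dtype=float)
        if self.transform == "log_duration":
            if np.any(stimulus <= 0):
                raise InputError("log transform requires positive stimuli")
            return np.log(stimulus)
        return stimulus

    def fit(self, X, y):
        """Fit P(choice = long) against stimulus duration.

        Parameters
        ----------
        X : array-like, shape (n,) or (n, 1)
            Stimulus durations in seconds.
        y : array-like of bool
            True for "long" choices.
        """
        stimulus = np.asarray(X, dtype=float).reshape(-1)
        y = np.asarray(y, dtype=float).reshape(-1)
        if stimulus.shape != y.shape:
            raise InputError("X and y lengths differ")
        if np.unique(stimulus).size < 2:
            raise DegenerateDesignError(
                "psychometric fit needs at least 2 distinct stimulus values"
            )
        exog = sm.add_constant(self._f(stimulus), has_constant="add")
        converged = True
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                res = sm.Logit(y, exog).fit(disp=0, maxiter=200)
                converged = bool(res.mle_retvals.get("converged", False))
            except Exception:
                # Newton fails under (quasi-)separation; fall back to a
                # capped BFGS fit and flag non-convergence.
                res = sm.Logit(y, exog).fit(disp=0, method="bfgs", maxiter=500)
                converged = False
        params = np.asarray(res.params, dtype=float)
        # extreme estimates indicate separation even when the optimizer
        # reports success
        if np.max(np.abs(params)) > 1e3:
            converged = False
        self._set_fitted(params[0], params[1], converged, y.size)
        return self

    def _set_fitted(self, intercept, slope, converged=True, n_trials=0):
        self._check_transform()
        self.intercept_ = float(intercept)
        self.slope_ = float(slope)
        self.converged_ = bool(converged)
        self.n_trials_ = int(n_trials)
        if slope == 0 or not np.isfinite(slope):
            self.bias_point_ = float("nan")
        else:
            raw = -intercept / slope
            self.bias_point_ = (
                math.exp(raw) if self.transform == "log_duration" else float(raw)
            )
        return self

    def predict_p_long(self, stimulus):
        """P(long | stimulus) from the fitted curve."""
        return sigmoid(self.intercept_ + self.slope_ * self._f(stimulus))

    def predict_proba(self, X):
        p = np.atleast_1d(self.predict_p_long(np.asarray(X).reshape(-1)))
        return np.column_stack([1 - p, p])

    def to_dict(self) -> dict:
        return {
            "intercept": self.intercept_,
            "slope": self.slope_,
            "stimulus_transform": self.transform,
            "bias_point": self.bias_point_,
            "n_trials": self.n_trials_,
            "converged": self.converged_,
        }


def fit_psychometric(
    trials: pd.DataFrame,
    transform: str = "log_duration",
    exclude_premature: bool = True,
) -> PsychometricRegression:
    """Fit one session's (or any trial subset's) psychometric function.

    Premature trials are excluded by default: their early pokes are not
    interval categorizations.
    """
    if exclude_premature and "premature" in trials:
        trials = trials.loc[~trials["premature"].astype(bool)]
    if len(trials) == 0:
        raise InputError("no trials to fit")
    model = PsychometricRegression(transform=transform)
    return model.fit(trials["stimulus_s"], trials["choice"] == "long")


def predict_p_long(fit: PsychometricRegression, stimulus) -> float:
    """P(long | stimulus) under a fitted psychometric function."""
    return fit.predict_p_long(stimulus)


def summarize_subject(
    fits: Sequence[PsychometricRegression],
) -> PsychometricRegression:
    """Subject summary: parameter-wise mean over converged session fits."""
    fits = list(fits)
    if not fits:
        raise SummaryError("no fits to summarize")
    good = [f for f in fits if f.converged_]
    if not good:
        raise SummaryError("no converged fits to summarize")
    transforms = {f.transform for f in good}
    if len(transforms) > 1:
        raise InputError("cannot average fits with different transforms")
    summary = PsychometricRegression(transform=good[0].transform)
    summary._set_fitted(
        np.mean([f.intercept_ for f in good]),
        np.mean([f.slope_ for f in good]),
        converged=True,
        n_trials=sum(f.n_trials_ for f in good),
    )
    return summary


def fit_sessions(
    trials: pd.DataFrame, transform: str = "log_duration"
) -> pd.DataFrame:
    """Fit every (subject, session) and return a tidy parameter table."""
    records = []
    for (subject, session), group in trials.groupby(["subject", "session"], sort=True):
        try:
            fit = fit_psychometric(group, transform=transform)
            rec = fit.to_dict()
        except (DegenerateDesignError, InputError):
            rec = {
                "intercept": np.nan, "slope": np.nan,
                "stimulus_transform": transform, "bias_point": np.nan,
                "n_trials": len(group), "converged": False,
            }
        rec.update({"subject": subject, "session": session})
        records.append(rec)
    return pd.DataFrame.from_records(records)


def filter_sessions_by_performance(
    trials: pd.DataFrame,
    config,
    min_easy_accuracy: float = 0.9,
) -> pd.DataFrame:
    """Keep sessions whose easiest-stimulus accuracy meets a floor.

    Mirrors performance-based session screening: a session passes when the
    fraction of correct categorizations of the extreme (easiest) stimuli
    is at least ``min_easy_accuracy``.  Premature trials are excluded from
    the accuracy computation.
    """
    stim = np.asarray(config.stimulus_set, dtype=float)
    easiest = {stim.min(), stim.max()}
    keep = []
    for key, group in trials.groupby(["subject", "session"], sort=False):
        g = group.loc[~group["premature"].astype(bool)]
        g = g.loc[g["stimulus_s"].isin(easiest)]
        if len(g) == 0:
            continue
        correct = (
            ((g["choice"] == "long") & (g["stimulus_s"] > config.boundary))
            | ((g["choice"] == "short") & (g["stimulus_s"] < config.boundary))
        )
        if correct.mean() >= min_easy_accuracy:
            keep.append(key)
    if not keep:
        return trials.iloc[0:0]
    index = pd.MultiIndex.from_tuples(keep, names=["subject", "session"])
    mask = pd.MultiIndex.from_frame(trials[["subject", "session"]]).isin(index)
    return trials.loc[mask]
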