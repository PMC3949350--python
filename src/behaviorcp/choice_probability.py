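"""Choice probability from ongoing behavior.

Two complementary estimators of how predictive head position is of the
upcoming binary categorization ("long" vs "short"):

* **Instantaneous CP** — at each timepoint, the area under the ROC curve
  comparing head-position distributions on long- vs short-choice trials,
  rectified about 0.5 (``max(A, 1 - A)``), with a one-sided 95% null band
  from recomputing the statistic on label-shuffled data (default 100
  shuffles, 95th percentile).  Applied separately per subject and
  stimulus interval.

* **Trajectory CP** — trajectory vectors **H** (head positions in a 1 s
  window centered on interval onset, 120 samples at 120 fps) are fitted
  with per-choice-class Gaussian mixture likelihoods P(**H**|C) by
  weighted maximum likelihood, each trial weighted by the binomial choice
  variance n·p̂·(1−p̂) of its (session, stimulus) cell — concentrating
  influence on ambiguous stimuli, where choice variability is not already
  explained by the stimulus.  Bayes' theorem then yields per-trial
  posteriors P(C|**H**) = P(**H**|C)·P(C) / P(**H**).  Trials are grouped
  into equal-count CP bins (default 6) and a psychometric function is fit
  per bin.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy.linalg import solve_triangular
from scipy.special import logsumexp
from scipy.stats import rankdata
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

from .exceptions import DegenerateDesignError, InputError
from .psychometrics import PsychometricRegression, fit_psychometric
from .trajectories import TrajectoryMatrix

logger = logging.getLogger(__name__)

#: The 1 s trajectory window centered on interval onset (half-open, seconds).
DEFAULT_FEATURE_WINDOW = (-0.5, 0.5)

#: Common sampling rate trajectories are brought to before vector analyses.
COMMON_FRAME_RATE = 120.0


# -- choice variance -------------------------------------------------------


def choice_variance(n_long: int, n_total: int) -> float:
    """Binomial variance of the choice count: n·p̂·(1−p̂), p̂ = n_long/n_total."""
    if n_total < 1:
        raise InputError("n_total must be >= 1")
    if not (0 <= n_long <= n_total):
        raise InputError("need 0 <= n_long <= n_total")
    p = n_long / n_total
    return float(n_total * p * (1.0 - p))


def choice_variance_table(
    trials: pd.DataFrame, exclude_premature: bool = True
) -> pd.DataFrame:
    """Per (subject, session, stimulus) cell: n, fraction long, σ²_choice."""
    t = trials
    if exclude_premature and "premature" in t:
        t = t.loc[~t["premature"].astype(bool)]
    if len(t) == 0:
        raise InputError("no trials")
    rows = []
    for (subject, session, stim), g in t.groupby(
        ["subject", "session", "stimulus_s"], sort=True
    ):
        n = len(g)
        n_long = int((g["choice"] == "long").sum())
        rows.append(
            {
                "subject": subject, "session": session, "stimulus_s": stim,
                "n": n, "p_long": n_long / n,
                "variance": choice_variance(n_long, n),
            }
        )
    return pd.DataFrame(rows)


def trial_weights(trials: pd.DataFrame, exclude_premature: bool = True) -> np.ndarray:
    """Per-trial weight = its (subject, session, stimulus) cell's σ²_choice.

    Returns one weight per row of ``trials`` (0 for excluded premature
    trials, and for unanimous cells by the definition of the variance).
    """
    table = choice_variance_table(trials, exclude_premature=exclude_premature)
    key = ["subject", "session", "stimulus_s"]
    lookup = table.set_index(key)["variance"]
    idx = pd.MultiIndex.from_frame(trials[key])
    w = lookup.reindex(idx).to_numpy(dtype=float)
    w = np.where(np.isfinite(w), w, 0.0)
    if exclude_premature and "premature" in trials:
        w = np.where(trials["premature"].astype(bool).to_numpy(), 0.0, w)
    return w


def select_highest_variance_stimulus(trials: pd.DataFrame) -> dict:
    """Per subject, the stimulus whose choice variance, summed across
    sessions, is highest (the pooled selection rule)."""
    table = choice_variance_table(trials)
    out = {}
    for subject, g in table.groupby("subject", sort=True):
        pooled = g.groupby("stimulus_s")["variance"].sum()
        out[subject] = float(pooled.idxmax())
    return out


# -- instantaneous (ROC) choice probability --------------------------------


def auroc(pos_class: np.ndarray, neg_class: np.ndarray) -> float:
    """P(random pos sample > random neg sample), ties counted half.

    Computed via the rank-sum identity: with average ranks R over the
    pooled sample, A = (sum R_pos - n_pos(n_pos+1)/2) / (n_pos * n_neg).
    """
    pos = np.asarray(pos_class, dtype=float)
    neg = np.asarray(neg_class, dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise InputError("both classes must be non-empty")
    ranks = rankdata(np.concatenate([pos, neg]))
    r_pos = ranks[: pos.size].sum()
    return float((r_pos - pos.size * (pos.size + 1) / 2.0) / (pos.size * neg.size))


def instantaneous_cp(pos_long, pos_short) -> float:
    """Rectified auROC between long- and short-choice position samples."""
    a = auroc(pos_long, pos_short)
    return max(a, 1.0 - a)


@dataclass
class CPSeries:
    """Time-resolved choice probability with its shuffle-null band."""

    time_axis: np.ndarray
    cp: np.ndarray            # rectified auROC per timepoint, in [0.5, 1]
    null_upper: np.ndarray    # 95th percentile of the shuffle distribution
    significant: np.ndarray   # cp > null_upper
    usable: bool = True
    n_long: int = 0
    n_short: int = 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_s": self.time_axis, "cp": self.cp,
                "null_upper": self.null_upper, "significant": self.significant,
            }
        )


def cp_timecourse(
    trajs: TrajectoryMatrix,
    choices,
    window: Optional[tuple[float, float]] = None,
    n_shuffles: int = 100,
    seed: int = 0,
    percentile: float = 95.0,
) -> CPSeries:
    """Per-timepoint rectified auROC with a label-shuffle null band.

    ``choices`` is boolean (True = long) or "long"/"short" labels, one per
    trajectory row.  The null band is the ``percentile``-th percentile of
    the rectified statistic recomputed over ``n_shuffles`` random label
    permutations (one-sided, as a band around chance).  Callers slice the
    data per subject and stimulus before calling.  A class with fewer
    than 2 trials yields an unusable (all-NaN) series.
    """
    long_mask = _as_long_mask(choices)
    pos = trajs.window(*window).positions if window is not None else trajs.positions
    taxis = trajs.window(*window).time_axis if window is not None else trajs.time_axis
    if long_mask.size != pos.shape[0]:
        raise InputError("choices length must match trajectory rows")
    n_long = int(long_mask.sum())
    n_short = int(long_mask.size - n_long)
    n_time = pos.shape[1]
    if n_long < 2 or n_short < 2:
        nan = np.full(n_time, np.nan)
        return CPSeries(taxis, nan, nan.copy(),
                        np.zeros(n_time, bool), False, n_long, n_short)

    ranks = rankdata(pos, axis=0)  # (n_trials, n_time), per-timepoint ranks
    offset = n_long * (n_long + 1) / 2.0
    denom = n_long * n_short

    def rectify(a):
        return np.maximum(a, 1.0 - a)

    cp = rectify((ranks[long_mask].sum(axis=0) - offset) / denom)

    rng = np.random.default_rng(seed)
    n = long_mask.size
    perms = np.empty((n_shuffles, n), dtype=bool)
    for s in range(n_shuffles):
        perms[s] = long_mask[rng.permutation(n)]
    # shuffle rank sums in one matrix product: (n_shuffles, n) @ (n, n_time)
    a_null = rectify((perms.astype(float) @ ranks - offset) / denom)
    null_upper = np.percentile(a_null, percentile, axis=0)
    significant = cp > null_upper
    return CPSeries(taxis, cp, null_upper, significant, True, n_long, n_short)


def cp_timecourse_by_cell(
    trials: pd.DataFrame,
    trajs: TrajectoryMatrix,
    window: tuple[float, float] = (-0.5, 2.5),
    n_shuffles: int = 100,
    seed: int = 0,
    stimulus_rule: str = "highest_variance",
) -> dict:
    """Instantaneous CP per subject at its highest-choice-variance stimulus.

    Applies :func:`cp_timecourse` separately per subject, pooling that
    subject's sessions at the single stimulus selected by the pooled
    highest-choice-variance rule.  Returns ``{subject: CPSeries}``.
    """
    if stimulus_rule != "highest_variance":
        raise InputError("only the highest_variance rule is implemented")
    selection = select_highest_variance_stimulus(trials)
    out = {}
    for i, (subject, stim) in enumerate(sorted(selection.items())):
        mask = (
            (trials["subject"] == subject)
            & np.isclose(trials["stimulus_s"].to_numpy(dtype=float), stim)
        ).to_numpy()
        if "premature" in trials:
            mask &= ~trials["premature"].astype(bool).to_numpy()
        sub = trials.loc[mask]
        out[subject] = cp_timecourse(
            trajs.select(mask), (sub["choice"] == "long").to_numpy(),
            window=window, n_shuffles=n_shuffles, seed=seed + i,
        )
    return out


def _as_long_mask(choices) -> np.ndarray:
    choices = np.asarray(choices)
    if choices.dtype == bool:
        return choices
    return choices == "long"


# -- trajectory choice probability (weighted GMM + Bayes) ------------------


class TrajectoryChoiceModel(BaseEstimator, ClassifierMixin):
    """Bayes classifier over trajectory vectors with weighted GMM likelihoods.

    Per choice class C, the class-conditional density P(**H**|C) is a
    Gaussian mixture fitted by weighted maximum likelihood (EM in which
    each trial's weight enters as a multiplicity in the responsibilities
    and sufficient statistics).  Class priors P(C) are the weighted class
    frequencies.  Posteriors are computed in the log domain, so extreme
    trajectories never produce NaN.

    Parameters
    ----------
    n_components : int
        Mixture components per class (full covariances).
    reg_covar : float
        Ridge added to covariance diagonals.
    pca_guard : bool
        Full-covariance density estimation needs on the order of tens of
        samples per dimension; below that, in-sample Bayes posteriors
        degenerate into memorizing the training labels.  When the
        weighted effective trial count of a class falls below
        ``samples_per_dim * n_components * n_features``, the model is
        fitted in the top-k PCA subspace retaining ``pca_min_variance``
        of pooled variance.
    samples_per_dim : float
        Effective-samples-per-dimension threshold of the guard.
    random_state : int
        Seeds k-means initialization.

    Attributes
    ----------
    classes_ : ndarray
        Sorted class labels.
    priors_ : ndarray
        P(C) per class (weighted frequencies; sum to 1).
    mixtures_ : dict
        Per class: dict with "weights", "means", "covariances".
    pca_ : fitted PCA or None
        Present only when the dimensionality guard was triggered.
    """

    def __init__(
        self,
        n_components: int = 2,
        reg_covar: float = 1e-6,
        max_iter: int = 200,
        tol: float = 1e-6,
        pca_guard: bool = True,
        pca_min_variance: float = 0.9,
        samples_per_dim: float = 30.0,
        random_state: int = 0,
    ):
        self.n_components = n_components
        self.reg_covar = reg_covar
        self.max_iter = max_iter
        self.tol = tol
        self.pca_guard = pca_guard
        self.pca_min_variance = pca_min_variance
        self.samples_per_dim = samples_per_dim
        self.random_state = random_state

    def fit(self, X, y, sample_weight=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise InputError("X must be 2-D (trials x features)")
        y = np.asarray(y)
        if y.shape[0] != X.shape[0]:
            raise InputError("X and y lengths differ")
        self.classes_ = np.unique(y)
        if self.classes_.size != 2:
            raise InputError("exactly two choice classes are required")
        if sample_weight is None:
            w = np.ones(X.shape[0])
        else:
            w = np.asarray(sample_weight, dtype=float)
            if w.shape[0] != X.shape[0] or np.any(w < 0) or not np.all(np.isfinite(w)):
                raise InputError("sample_weight must be non-negative and aligned")
        if w.sum() == 0:
            raise InputError("all sample weights are zero")

        self.n_features_in_ = X.shape[1]
        # class priors from the same trial weights
        totals = np.array([w[y == c].sum() for c in self.classes_])
        if np.any(totals == 0):
            raise InputError("each class needs positive total weight")
        self.priors_ = totals / totals.sum()

        # dimensionality guard: effective (Kish) sample size per class
        n_eff = np.array(
            [
                (w[y == c].sum() ** 2) / np.sum(w[y == c] ** 2)
                if np.any(w[y == c] > 0) else 0.0
                for c in self.classes_
            ]
        )
        self.pca_ = None
        Xf = X
        guard_floor = self.samples_per_dim * self.n_components * X.shape[1]
        if self.pca_guard and X.shape[1] > 1 and n_eff.min() < guard_floor:
            pca = PCA(random_state=self.random_state).fit(X)
            k = int(
                np.searchsorted(
                    np.cumsum(pca.explained_variance_ratio_), self.pca_min_variance
                )
                + 1
            )
            k = max(1, min(k, X.shape[1]))
            self.pca_ = PCA(n_components=k, random_state=self.random_state).fit(X)
            Xf = self.pca_.transform(X)
            logger.warning(
                "dimensionality guard: fitting in %d-D PCA subspace "
                "(min effective n=%.1f < %.0f)",
                k, n_eff.min(), guard_floor,
            )

        self.mixtures_ = {}
        for c in self.classes_:
            mask = (y == c) & (w > 0)
            self.mixtures_[c] = _weighted_gmm_fit(
                Xf[mask], w[mask], self.n_components, self.reg_covar,
                self.max_iter, self.tol, self.random_state,
            )
        return self

    def _features(self, X):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.n_features_in_:
            raise InputError(
                f"expected {self.n_features_in_} features, got {X.shape[1]}"
            )
        return self.pca_.transform(X) if self.pca_ is not None else X

    def log_likelihood(self, X) -> np.ndarray:
        """log P(**H**|C) per class, shape (n, n_classes)."""
        Xf = self._features(X)
        cols = [
            _gmm_logpdf(Xf, self.mixtures_[c]) for c in self.classes_
        ]
        return np.column_stack(cols)

    def predict_proba(self, X) -> np.ndarray:
        """Bayes posteriors P(C|**H**), columns ordered as ``classes_``."""
        log_like = self.log_likelihood(X)
        log_joint = log_like + np.log(self.priors_)[None, :]
        return np.exp(log_joint - logsumexp(log_joint, axis=1, keepdims=True))

    def predict(self, X) -> np.ndarray:
        return self.classes_[np.argmax(self.predict_proba(X), axis=1)]

    def posterior_long(self, X) -> np.ndarray:
        """P(long | **H**) per trial."""
        proba = self.predict_proba(X)
        idx = _long_class_index(self.classes_)
        return proba[:, idx]


def _long_class_index(classes: np.ndarray) -> int:
    for i, c in enumerate(classes):
        if c == "long" or c is True or (isinstance(c, (bool, np.bool_)) and c):
            return i
    return int(np.argmax(classes))


def _weighted_gmm_fit(X, w, n_components, reg_covar, max_iter, tol, random_state):
    """Weighted-EM fit of a full-covariance Gaussian mixture.

    Weights enter as multiplicities: the weighted log-likelihood
    sum_n w_n log p(x_n) is maximized, with responsibilities scaled by
    w_n in every sufficient statistic.  Weights are normalized to mean 1
    for optimizer stability (the MLE is invariant to that scale).
    """
    n, d = X.shape
    if n < n_components:
        raise InputError("fewer weighted trials than mixture components")
    w = w / w.mean()

    km = KMeans(n_clusters=n_components, random_state=random_state, n_init=10)
    labels = km.fit_predict(X)
    resp = np.zeros((n, n_components))
    resp[np.arange(n), labels] = 1.0

    ll_old = -np.inf
    params = None
    for _ in range(max_iter):
        params = _gmm_m_step(X, w, resp, reg_covar)
        log_prob = _component_log_prob(X, params)  # (n, K) incl. log mixing
        ll = float(np.sum(w * logsumexp(log_prob, axis=1)))
        resp = np.exp(log_prob - logsumexp(log_prob, axis=1, keepdims=True))
        if abs(ll - ll_old) <= tol * (1.0 + abs(ll)):
            break
        ll_old = ll
    params["log_likelihood"] = ll
    return params


def _gmm_m_step(X, w, resp, reg_covar):
    n, d = X.shape
    wr = w[:, None] * resp                     # weighted responsibilities
    nk = wr.sum(axis=0) + 1e-12
    means = (wr.T @ X) / nk[:, None]
    covs = np.empty((resp.shape[1], d, d))
    for k in range(resp.shape[1]):
        diff = X - means[k]
        covs[k] = (wr[:, k][:, None] * diff).T @ diff / nk[k]
        covs[k].flat[:: d + 1] += reg_covar
    return {"weights": nk / nk.sum(), "means": means, "covariances": covs}


def _component_log_prob(X, params):
    """log(pi_k) + log N(x | mu_k, Sigma_k) for every sample/component."""
    K = params["means"].shape[0]
    out = np.empty((X.shape[0], K))
    for k in range(K):
        out[:, k] = np.log(params["weights"][k] + 1e-300) + _mvn_logpdf(
            X, params["means"][k], params["covariances"][k]
        )
    return out


def _mvn_logpdf(X, mean, cov):
    d = mean.size
    try:
        chol = np.linalg.cholesky(cov)
    except np.linalg.LinAlgError:
        cov = cov + 1e-6 * np.eye(d)
        chol = np.linalg.cholesky(cov)
    diff = X - mean
    z = solve_triangular(chol, diff.T, lower=True)
    logdet = 2.0 * np.sum(np.log(np.diag(chol)))
    return -0.5 * (d * np.log(2 * np.pi) + logdet + np.sum(z**2, axis=0))


def _gmm_logpdf(X, params) -> np.ndarray:
    return logsumexp(_component_log_prob(X, params), axis=1)


def fit_trajectory_choice_model(
    X, choices, weights=None, n_components: int = 2, seed: int = 0, **kwargs
) -> TrajectoryChoiceModel:
    """Fit the per-class mixture likelihoods + priors on windowed vectors."""
    model = TrajectoryChoiceModel(
        n_components=n_components, random_state=seed, **kwargs
    )
    return model.fit(X, np.asarray(choices), sample_weight=weights)


def posterior_choice_probability(model: TrajectoryChoiceModel, traj) -> np.ndarray:
    """P(long | **H**) for one or more trajectory vectors."""
    return model.posterior_long(traj)


# -- CP binning and per-bin psychometrics ----------------------------------


@dataclass
class CPBinning:
    """Equal-count (quantile) binning of per-trial choice probabilities."""

    assignments: np.ndarray    # bin index per trial, 0-based
    n_bins: int
    counts: np.ndarray
    bin_edges: np.ndarray      # CP values at bin boundaries (n_bins + 1)


def bin_trials_by_cp(cps, n_bins: int = 6) -> CPBinning:
    """Quantile binning: counts equal to within 1, ties broken by trial order.

    Trials are stably sorted by CP and split into ``n_bins`` contiguous
    groups, so identical CPs are assigned in original trial order.
    """
    cps = np.asarray(cps, dtype=float)
    if n_bins < 2:
        raise InputError("n_bins must be >= 2")
    if cps.size < n_bins:
        raise InputError("fewer trials than bins")
    order = np.argsort(cps, kind="stable")
    chunks = np.array_split(order, n_bins)
    assignments = np.empty(cps.size, dtype=int)
    for i, chunk in enumerate(chunks):
        assignments[chunk] = i
    counts = np.array([chunk.size for chunk in chunks])
    sorted_cps = cps[order]
    edges = [sorted_cps[0]]
    start = 0
    for chunk in chunks:
        start += chunk.size
        edges.append(sorted_cps[min(start, cps.size) - 1])
    return CPBinning(assignments, n_bins, counts, np.asarray(edges))


def per_bin_psychometrics(
    trials: pd.DataFrame,
    binning: CPBinning,
    transform: str = "log_duration",
) -> list[Optional[PsychometricRegression]]:
    """Fit a psychometric function to the trials of each CP bin.

    Bins with a degenerate design (fewer than 2 distinct stimuli) yield
    ``None`` in the returned list.
    """
    if len(trials) != binning.assignments.size:
        raise InputError("binning does not align with trials")
    fits: list[Optional[PsychometricRegression]] = []
    for b in range(binning.n_bins):
        sub = trials.iloc[np.flatnonzero(binning.assignments == b)]
        try:
            fits.append(fit_psychometric(sub, transform=transform,
                                         exclude_premature=False))
        except (DegenerateDesignError, InputError):
            fits.append(None)
    return fits


@dataclass
class TrajectoryCPResult:
    """Per-subject trajectory-CP analysis outputs."""

    posteriors: pd.Series                 # P(long | H) per analyzed trial
    models: dict                          # subject -> TrajectoryChoiceModel
    binnings: dict                        # subject -> CPBinning
    bin_fits: dict                        # subject -> list of fits (or None)
    analyzed_index: pd.Index              # rows of `trials` analyzed


def trajectory_cp_analysis(
    trials: pd.DataFrame,
    trajs: TrajectoryMatrix,
    feature_window: tuple[float, float] = DEFAULT_FEATURE_WINDOW,
    n_components: int = 2,
    n_bins: int = 6,
    seed: int = 0,
    exclude_premature: bool = True,
    flat_weights: bool = False,
    transform: str = "log_duration",
    **model_kwargs,
) -> TrajectoryCPResult:
    """Full trajectory-CP pipeline, applied separately per subject.

    Resamples trajectories to the common 120 samples/s grid, extracts the
    1 s window centered on interval onset, fits the choice-variance-
    weighted mixture model per subject, computes Bayes posteriors for
    every analyzed trial, bins trials into ``n_bins`` equal-count CP bins,
    and fits a psychometric function per bin.  ``flat_weights=True``
    replaces the choice-variance weights with uniform ones (for the
    robustness comparison).
    """
    common = trajs.resample(COMMON_FRAME_RATE)
    windowed = common.window(*feature_window)
    weights_all = (
        np.ones(len(trials))
        if flat_weights
        else trial_weights(trials, exclude_premature=exclude_premature)
    )
    keep = weights_all >= 0
    if exclude_premature and "premature" in trials:
        keep &= ~trials["premature"].astype(bool).to_numpy()

    posteriors = pd.Series(np.nan, index=trials.index, name="cp_long")
    models, binnings, bin_fits = {}, {}, {}
    analyzed = []
    for subject in sorted(trials["subject"].unique()):
        mask = (trials["subject"] == subject).to_numpy() & keep
        sub = trials.loc[mask]
        X = windowed.positions[mask]
        w = weights_all[mask]
        if w.sum() <= 0:
            continue
        model = fit_trajectory_choice_model(
            X, (sub["choice"] == "long").to_numpy(), weights=w,
            n_components=n_components, seed=seed, **model_kwargs,
        )
        post = model.posterior_long(X)
        posteriors.loc[sub.index] = post
        binning = bin_trials_by_cp(post, n_bins=n_bins)
        models[subject] = model
        binnings[subject] = binning
        bin_fits[subject] = per_bin_psychometrics(sub, binning, transform=transform)
        analyzed.extend(sub.index.tolist())
    return TrajectoryCPResult(
        posteriors=posteriors, models=models, binnings=binnings,
        bin_fits=bin_fits, analyzed_index=pd.Index(analyzed),
    )
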