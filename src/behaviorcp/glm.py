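"""Logistic choice-model ladder with trajectory and trial-history predictors.

Four nested logistic regressions predict the binary choice (long = 1):

* model 1: subject (categorical) + current interval I
* model 2: model 1 + trajectory principal-component scores T_PC1, T_PC2
* model 3: model 1 + trial history — previous reward R_{t-1} (coded +1 for
  reward after a long choice, 0 for no reward, -1 for reward after a short
  choice), previous difficulty d(I_{t-1}) = |I_{t-1} - boundary|, and
  previous interval I_{t-1}
* model 4: all of the above

Trajectory scores come from a PCA pooled over the whole dataset's 1 s
windows (120 dims).  Premature trials and their immediate successors are
excluded, as is each session's first trial (no history).  Models are
compared by prediction success, deviance (-2 log-likelihood), AIC and
BIC (computed from the identities aic = dev + 2k, bic = dev + k ln n),
and likelihood-ratio tests between nested pairs; initial specifications
can be refined by a greedy stepwise search over single-term removals and
pairwise interactions that minimizes BIC.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.base import BaseEstimator
from sklearn.decomposition import PCA

from .exceptions import DegenerateDesignError, InputError
from .trajectories import TrajectoryMatrix

#: Canonical ordering of main-effect terms.
MAIN_TERMS = (
    "subject", "interval", "traj_pc1", "traj_pc2",
    "prev_reward", "prev_difficulty", "prev_interval",
)


@dataclass(frozen=True)
class DesignSpec:
    """A set of predictor terms (main effects and pairwise interactions)."""

    terms: tuple
    model_id: Optional[int] = None

    def __post_init__(self):
        object.__setattr__(self, "terms", tuple(self.terms))
        for term in self.terms:
            for part in term.split(":"):
                if part not in MAIN_TERMS:
                    raise InputError(f"unknown term {term!r}")

    @property
    def main_effects(self) -> tuple:
        return tuple(t for t in self.terms if ":" not in t)

    @property
    def interactions(self) -> tuple:
        return tuple(t for t in self.terms if ":" in t)

    def with_terms(self, terms) -> "DesignSpec":
        return DesignSpec(tuple(terms), self.model_id)

    def is_nested_in(self, other: "DesignSpec") -> bool:
        return set(self.terms) <= set(other.terms)


#: Initial (all-linear, no-interaction) specifications of the four models.
MODEL_SPECS = {
    1: DesignSpec(("subject", "interval"), model_id=1),
    2: DesignSpec(("subject", "interval", "traj_pc1", "traj_pc2"), model_id=2),
    3: DesignSpec(
        ("subject", "interval", "prev_reward", "prev_difficulty", "prev_interval"),
        model_id=3,
    ),
    4: DesignSpec(
        ("subject", "interval", "traj_pc1", "traj_pc2",
         "prev_reward", "prev_difficulty", "prev_interval"),
        model_id=4,
    ),
}

#: Nested model pairs declared on the initial specifications.
DEFAULT_NESTING = ((1, 2), (1, 3), (2, 4), (3, 4))


@dataclass
class TrajectoryFeatures:
    """First two PC scores of the pooled windowed trajectories."""

    pc_scores: np.ndarray                # (n_trials, 2)
    explained_variance_fraction: np.ndarray
    loadings: np.ndarray                 # (2, n_window_samples)


def trajectory_pca(trajs, n_components: int = 2) -> TrajectoryFeatures:
    """Mean-centered PCA over all trials of all subjects pooled.

    ``trajs`` is the windowed trajectory matrix (trials x window samples);
    pass the common 1 s window so scores are comparable across subjects.
    """
    X = trajs.positions if isinstance(trajs, TrajectoryMatrix) else np.asarray(trajs, float)
    if X.ndim != 2 or X.shape[0] < max(3, n_components + 1):
        raise InputError("need at least 3 trials for trajectory PCA")
    pca = PCA(n_components=n_components)
    scores = pca.fit_transform(X)
    return TrajectoryFeatures(
        pc_scores=scores,
        explained_variance_fraction=pca.explained_variance_ratio_.copy(),
        loadings=pca.components_.copy(),
    )


def glm_row_mask(trials: pd.DataFrame) -> np.ndarray:
    """Rows admissible for the choice GLM.

    Drops premature trials, their immediate successors within the same
    session, and each session's first trial (which has no history).
    """
    n = len(trials)
    mask = np.ones(n, dtype=bool)
    premature = trials["premature"].astype(bool).to_numpy()
    mask &= ~premature
    session_key = pd.MultiIndex.from_frame(trials[["subject", "session"]])
    same_session_as_prev = np.zeros(n, dtype=bool)
    same_session_as_prev[1:] = session_key[1:] == session_key[:-1]
    mask &= same_session_as_prev                    # drops first trial per session
    prev_premature = np.zeros(n, dtype=bool)
    prev_premature[1:] = premature[:-1]
    mask &= ~(prev_premature & same_session_as_prev)
    return mask


def build_design_matrix(
    trials: pd.DataFrame,
    features: Optional[TrajectoryFeatures],
    spec: DesignSpec,
) -> tuple[pd.DataFrame, pd.Series]:
    """Build the (X, y) pair for a design specification.

    Subjects become indicator columns (first level as reference, absorbed
    by the intercept); interval and history predictors are continuous;
    interaction terms are element-wise products of their parts' columns.
    ``features`` must align row-for-row with ``trials`` (it may be None
    when the spec uses no trajectory terms).
    """
    needs_traj = any("traj" in t for t in spec.terms)
    if needs_traj:
        if features is None:
            raise InputError("spec uses trajectory terms but features is None")
        if features.pc_scores.shape[0] != len(trials):
            raise InputError("features misaligned with trials")

    mask = glm_row_mask(trials)
    sub = trials.loc[mask]
    base: dict[str, pd.Series | pd.DataFrame] = {}
    subjects = sorted(trials["subject"].unique())
    dummies = pd.DataFrame(
        {
            f"subject[{s}]": (sub["subject"] == s).astype(float)
            for s in subjects[1:]
        },
        index=sub.index,
    )
    base["subject"] = dummies
    base["interval"] = sub["stimulus_s"].astype(float)
    if needs_traj:
        base["traj_pc1"] = pd.Series(
            features.pc_scores[mask, 0], index=sub.index)
        base["traj_pc2"] = pd.Series(
            features.pc_scores[mask, 1], index=sub.index)
    base["prev_reward"] = sub["prev_reward_code"].astype(float)
    base["prev_difficulty"] = sub["prev_difficulty_s"].astype(float)
    base["prev_interval"] = sub["prev_stimulus_s"].astype(float)

    def columns_for(term: str) -> pd.DataFrame:
        parts = term.split(":")
        frames = []
        for part in parts:
            block = base[part]
            if isinstance(block, pd.Series):
                block = block.to_frame(part)
            frames.append(block)
        out = frames[0]
        for nxt in frames[1:]:
            prod = {}
            for a in out.columns:
                for b in nxt.columns:
                    prod[f"{a}:{b}"] = out[a] * nxt[b]
            out = pd.DataFrame(prod, index=out.index)
        return out

    blocks = [columns_for(t) for t in spec.terms]
    X = pd.concat(blocks, axis=1) if blocks else pd.DataFrame(index=sub.index)
    X.insert(0, "const", 1.0)
    y = (sub["choice"] == "long").rename("choice_long")
    return X, y


@dataclass
class GLMResult:
    """One fitted logistic choice model and its comparison statistics."""

    spec: DesignSpec
    params: pd.Series
    deviance: float            # -2 log-likelihood
    aic: float                 # deviance + 2 k
    bic: float                 # deviance + k ln n
    prediction_success: float  # % trials with (p >= 0.5) matching choice
    n_params: int
    n_trials: int
    converged: bool
    separation_flagged: bool = False


class ChoiceGLM(BaseEstimator):
    """sklearn-style wrapper around the maximum-likelihood logistic fit.

    ``fit`` takes an already-built design matrix (including the constant
    column) and the boolean response.  Perfect separation is flagged and
    handled by an L1-penalized refit with a tiny penalty.
    """

    def __init__(self, spec: Optional[DesignSpec] = None):
        self.spec = spec

    def fit(self, X: pd.DataFrame, y):
        y = np.asarray(y, dtype=float).reshape(-1)
        if X.shape[1] < 1:
            raise InputError("need at least one predictor column")
        if y.min() == y.max():
            raise DegenerateDesignError("both response classes must be present")
        Xv = np.asarray(X, dtype=float)
        if not np.all(np.isfinite(Xv)):
            raise InputError("design matrix contains non-finite values")
        separation = False
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                res = sm.Logit(y, Xv).fit(disp=0, maxiter=200)
                converged = bool(res.mle_retvals.get("converged", False))
            except Exception:
                separation = True
                res = sm.Logit(y, Xv).fit_regularized(
                    method="l1", alpha=1e-4, disp=0, maxiter=500
                )
                converged = False
        params = np.asarray(res.params, dtype=float)
        if np.max(np.abs(params)) > 1e3 and not separation:
            separation = True
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = sm.Logit(y, Xv).fit_regularized(
                    method="l1", alpha=1e-4, disp=0, maxiter=500
                )
            params = np.asarray(res.params, dtype=float)
            converged = False

        self.coef_ = pd.Series(params, index=list(X.columns))
        self.llf_ = float(res.llf)
        self.deviance_ = -2.0 * self.llf_
        self.n_params_ = int(X.shape[1])
        self.n_trials_ = int(y.size)
        self.aic_ = self.deviance_ + 2.0 * self.n_params_
        self.bic_ = self.deviance_ + self.n_params_ * math.log(self.n_trials_)
        p = self.predict_proba(X)[:, 1]
        self.prediction_success_ = float(100.0 * np.mean((p >= 0.5) == (y == 1.0)))
        self.converged_ = converged
        self.separation_flagged_ = separation
        return self

    def predict_proba(self, X) -> np.ndarray:
        z = np.asarray(X, dtype=float) @ self.coef_.to_numpy()
        p = 1.0 / (1.0 + np.exp(-np.clip(z, -700, 700)))
        return np.column_stack([1 - p, p])

    def result(self) -> GLMResult:
        return GLMResult(
            spec=self.spec if self.spec is not None else DesignSpec(()),
            params=self.coef_,
            deviance=self.deviance_,
            aic=self.aic_,
            bic=self.bic_,
            prediction_success=self.prediction_success_,
            n_params=self.n_params_,
            n_trials=self.n_trials_,
            converged=self.converged_,
            separation_flagged=self.separation_flagged_,
        )


def fit_choice_glm(X: pd.DataFrame, y, spec: Optional[DesignSpec] = None) -> GLMResult:
    """Maximum-likelihood logistic fit of a built design; see GLMResult."""
    return ChoiceGLM(spec=spec).fit(X, y).result()


def fit_model(
    trials: pd.DataFrame,
    features: Optional[TrajectoryFeatures],
    spec: DesignSpec,
) -> GLMResult:
    """Build the design for ``spec`` and fit it."""
    X, y = build_design_matrix(trials, features, spec)
    return fit_choice_glm(X, y, spec=spec)


def stepwise_select(
    initial: DesignSpec,
    trials: pd.DataFrame,
    features: Optional[TrajectoryFeatures],
    max_steps: int = 50,
) -> DesignSpec:
    """Greedy BIC-minimizing refinement of a specification.

    At each step, every single-term removal (keeping hierarchy: a main
    effect stays while any of its interactions is present) and every
    admissible pairwise interaction between current main effects is
    evaluated; the move with the lowest BIC is accepted; the search stops
    when no move improves BIC.  Deterministic given the data.
    """
    current = initial
    best_bic = fit_model(trials, features, current).bic
    for _ in range(max_steps):
        candidates = []
        mains = current.main_effects
        inters = current.interactions
        for term in current.terms:
            if ":" not in term and any(term in it.split(":") for it in inters):
                continue  # hierarchy: main kept while its interaction exists
            remaining = tuple(t for t in current.terms if t != term)
            if remaining:
                candidates.append(remaining)
        for a, b in itertools.combinations(mains, 2):
            inter = f"{a}:{b}"
            if inter not in current.terms:
                candidates.append(current.terms + (inter,))
        best_move, best_move_bic = None, best_bic
        for terms in candidates:
            try:
                bic = fit_model(trials, features, current.with_terms(terms)).bic
            except (InputError, DegenerateDesignError):
                continue
            if bic < best_move_bic - 1e-9:
                best_move, best_move_bic = terms, bic
        if best_move is None:
            break
        current = current.with_terms(best_move)
        best_bic = best_move_bic
    return current


def compare_models(
    results: dict[int, GLMResult],
    nesting: Sequence[tuple[int, int]] = DEFAULT_NESTING,
    check_nesting: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Comparison table plus likelihood-ratio tests between nested pairs.

    The LR statistic is the deviance difference, with degrees of freedom
    the parameter-count difference; p-values come from the chi-squared
    distribution.  A pair whose specs are not nested raises InputError.
    """
    table = pd.DataFrame(
        [
            {
                "model": mid,
                "prediction_success": r.prediction_success,
                "deviance": r.deviance,
                "bic": r.bic,
                "aic": r.aic,
                "n_params": r.n_params,
                "n_trials": r.n_trials,
            }
            for mid, r in sorted(results.items())
        ]
    ).set_index("model")
    lr_rows = []
    for small, big in nesting:
        if small not in results or big not in results:
            continue
        rs, rb = results[small], results[big]
        if check_nesting and not rs.spec.is_nested_in(rb.spec):
            raise InputError(
                f"model {small} is not nested in model {big}; LR test refused"
            )
        chi2 = max(rs.deviance - rb.deviance, 0.0)
        df = rb.n_params - rs.n_params
        p = float(stats.chi2.sf(chi2, df)) if df > 0 else (1.0 if chi2 == 0 else 0.0)
        lr_rows.append(
            {"reduced": small, "full": big, "chi2": chi2, "df": df, "p": p}
        )
    return table, pd.DataFrame(lr_rows)


def run_model_ladder(
    trials: pd.DataFrame,
    trajs: TrajectoryMatrix,
    feature_window: tuple[float, float] = (-0.5, 0.5),
    stepwise: bool = False,
) -> tuple[dict[int, GLMResult], pd.DataFrame, pd.DataFrame]:
    """Fit the four-model ladder end to end.

    Computes pooled trajectory PCA on the 1 s window, fits models 1–4
    (initial specs, optionally stepwise-refined), and returns
    ``(results, comparison_table, lr_tests)``.
    """
    from .choice_probability import COMMON_FRAME_RATE

    windowed = trajs.resample(COMMON_FRAME_RATE).window(*feature_window)
    features = trajectory_pca(windowed)
    results = {}
    for mid, spec in MODEL_SPECS.items():
        use = stepwise_select(spec, trials, features) if stepwise else spec
        results[mid] = fit_model(trials, features, use)
    # after stepwise refinement the final specs need not nest; the declared
    # nesting holds on the initial specifications
    table, lr = compare_models(results, check_nesting=not stepwise)
    return results, table, lr
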