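"""Trajectory reproducibility and idiosyncrasy analysis.

Quantifies how reproducible head trajectories are within and between
subjects: the full pairwise Pearson correlation matrix over trials,
partition of the upper-triangle coefficients into same-session /
same-subject-different-session / different-subject groups, and two-sample
Kolmogorov–Smirnov comparisons between the groups' coefficient
distributions.  By default the analysis is restricted to presentations of
the longest interval, where behavioral sequences can unfold for the
longest time before the interval-offset go signal.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import InputError
from .trajectories import TrajectoryMatrix

#: Default correlation window (seconds): onset to the longest interval's offset.
DEFAULT_WINDOW = (0.0, 2.4)


def pairwise_trajectory_correlations(trajs) -> np.ndarray:
    """Pearson correlation between every pair of trial trajectories.

    Returns a symmetric matrix with unit diagonal.  Rows with zero
    variance (flat trajectories) have undefined correlations, returned as
    NaN (diagonal included).
    """
    positions = trajs.positions if isinstance(trajs, TrajectoryMatrix) else np.asarray(trajs, float)
    if positions.ndim != 2 or positions.shape[0] < 2:
        raise InputError("need at least 2 equal-length trajectories")
    flat = np.std(positions, axis=1) == 0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        corr = np.corrcoef(positions)
    corr[flat, :] = np.nan
    corr[:, flat] = np.nan
    valid = ~flat
    corr[np.ix_(valid, valid)] = np.clip(corr[np.ix_(valid, valid)], -1.0, 1.0)
    corr[np.diag_indices_from(corr)] = np.where(flat, np.nan, 1.0)
    return corr


@dataclass
class CorrelationPartition:
    """Upper-triangle correlation coefficients routed into three groups."""

    same_session: np.ndarray
    same_subject_diff_session: np.ndarray
    diff_subject: np.ndarray
    n_undefined: int = 0

    @property
    def n_pairs(self) -> int:
        return (
            self.same_session.size
            + self.same_subject_diff_session.size
            + self.diff_subject.size
            + self.n_undefined
        )

    def summary(self) -> dict:
        """Medians and interquartile ranges per group."""
        out = {}
        for name in ("same_session", "same_subject_diff_session", "diff_subject"):
            vals = getattr(self, name)
            if vals.size:
                q1, med, q3 = np.percentile(vals, [25, 50, 75])
            else:
                q1 = med = q3 = float("nan")
            out[name] = {
                "n": int(vals.size), "median": float(med),
                "iqr": [float(q1), float(q3)],
            }
        out["n_undefined"] = int(self.n_undefined)
        return out


def partition_correlations(
    matrix: np.ndarray, subject_labels, session_labels
) -> CorrelationPartition:
    """Route each upper-triangle coefficient to exactly one group.

    Pairs from the same subject are split by whether they share a session;
    pairs of different subjects form the third group.  Undefined (NaN)
    coefficients are excluded and counted.
    """
    matrix = np.asarray(matrix, dtype=float)
    n = matrix.shape[0]
    subjects = np.asarray(subject_labels)
    sessions = np.asarray(session_labels)
    if subjects.shape[0] != n or sessions.shape[0] != n:
        raise InputError("label lengths must match the matrix size")
    iu, ju = np.triu_indices(n, k=1)
    vals = matrix[iu, ju]
    same_subj = subjects[iu] == subjects[ju]
    same_sess = same_subj & (sessions[iu] == sessions[ju])
    defined = np.isfinite(vals)
    return CorrelationPartition(
        same_session=vals[defined & same_sess],
        same_subject_diff_session=vals[defined & same_subj & ~same_sess],
        diff_subject=vals[defined & ~same_subj],
        n_undefined=int(np.sum(~defined)),
    )


def compare_distributions_ks(a, b) -> tuple[float, float]:
    """Two-sample Kolmogorov–Smirnov test (asymptotic p-value).

    Returns ``(D, p)`` with D = sup |ECDF_a - ECDF_b|.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise InputError("both samples must be non-empty")
    res = stats.ks_2samp(a, b, method="asymp")
    return float(res.statistic), float(res.pvalue)


def mean_trajectory(trajs, group) -> np.ndarray:
    """Pointwise mean trajectory over the selected trials."""
    positions = trajs.positions if isinstance(trajs, TrajectoryMatrix) else np.asarray(trajs, float)
    group = np.asarray(group)
    if group.size == 0:
        raise InputError("group must be non-empty")
    return positions[group].mean(axis=0)


def longest_interval_analysis(
    trials: pd.DataFrame,
    trajs: TrajectoryMatrix,
    config,
    window: tuple[float, float] = DEFAULT_WINDOW,
) -> tuple[np.ndarray, CorrelationPartition, dict]:
    """Figure-style reproducibility analysis on longest-interval trials.

    Restricts to trials presenting the longest stimulus, correlates their
    trajectories over ``window`` (half-open, default onset to the longest
    interval's offset), partitions the coefficients by subject/session,
    and KS-compares the three groups.

    Returns ``(correlation_matrix, partition, ks_tests)`` where
    ``ks_tests`` maps comparison names to ``{"D": ..., "p": ...}``.
    """
    longest = float(np.max(np.asarray(config.stimulus_set, dtype=float)))
    mask = np.isclose(trials["stimulus_s"].to_numpy(dtype=float), longest)
    if mask.sum() < 2:
        raise InputError("need at least 2 longest-interval trials")
    sub = trials.loc[mask]
    windowed = trajs.select(mask).window(*window)
    corr = pairwise_trajectory_correlations(windowed)
    part = partition_correlations(
        corr, sub["subject"].to_numpy(), sub["session"].to_numpy()
    )
    ks_tests = {}
    pairs = [
        ("same_session_vs_diff_session",
         part.same_session, part.same_subject_diff_session),
        ("same_session_vs_diff_subject", part.same_session, part.diff_subject),
        ("diff_session_vs_diff_subject",
         part.same_subject_diff_session, part.diff_subject),
    ]
    for name, x, y in pairs:
        if x.size and y.size:
            d, p = compare_distributions_ks(x, y)
            ks_tests[name] = {"D": d, "p": p}
    return corr, part, ks_tests
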