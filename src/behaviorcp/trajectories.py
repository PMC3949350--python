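"""Per-trial head-trajectory container and its on-disk format.

A :class:`TrajectoryMatrix` holds one head-position time series per trial,
expressed in pixels along the port axis (the axis on which the three nose
ports are aligned), on a uniform time grid aligned to stimulus-interval
onset (t = 0 at trial initiation).  Windows are half-open ``[t0, t1)`` and
frame ``k`` covers ``[k/fps, (k+1)/fps)``, so a 1 s window at 120 frames/s
has exactly 120 columns.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .exceptions import InputError

_TIME_EPS = 1e-9


@dataclass
class TrajectoryMatrix:
    """Trials x timepoints matrix of 1-D head positions.

    Parameters
    ----------
    positions : ndarray, shape (n_trials, n_timepoints)
        Head position along the port axis, in pixels.
    time_axis : ndarray, shape (n_timepoints,)
        Time of each sample in seconds relative to interval onset;
        strictly increasing, uniformly spaced at ``1 / frame_rate``.
    frame_rate : float
        Sampling rate in frames per second.
    alignment : str
        Alignment event; only ``"interval_onset"`` is defined.
    """

    positions: np.ndarray
    time_axis: np.ndarray
    frame_rate: float
    alignment: str = "interval_onset"

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float)
        self.time_axis = np.asarray(self.time_axis, dtype=float)
        if self.positions.ndim != 2:
            raise InputError("positions must be a 2-D (trials x time) array")
        if self.time_axis.ndim != 1 or self.time_axis.size != self.positions.shape[1]:
            raise InputError("time_axis length must match positions columns")
        if self.frame_rate <= 0:
            raise InputError("frame_rate must be positive")
        if self.time_axis.size > 1:
            dt = np.diff(self.time_axis)
            if np.any(dt <= 0):
                raise InputError("time_axis must be strictly increasing")
            if not np.allclose(dt, 1.0 / self.frame_rate, rtol=0, atol=1e-6):
                raise InputError("time_axis spacing must equal 1/frame_rate")
        if self.alignment != "interval_onset":
            raise InputError(f"unknown alignment {self.alignment!r}")

    @property
    def n_trials(self) -> int:
        return self.positions.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.positions.shape[1]

    def window(self, t0: float, t1: float) -> "TrajectoryMatrix":
        """Return the half-open time window ``[t0, t1)`` as a new matrix."""
        if t1 <= t0:
            raise InputError("window requires t0 < t1")
        mask = (self.time_axis >= t0 - _TIME_EPS) & (self.time_axis < t1 - _TIME_EPS)
        if not mask.any():
            raise InputError(f"window [{t0}, {t1}) is outside the trajectory support")
        return TrajectoryMatrix(
            self.positions[:, mask], self.time_axis[mask], self.frame_rate,
            self.alignment,
        )

    def resample(self, target_rate: float) -> "TrajectoryMatrix":
        """Linearly resample onto a uniform grid at ``target_rate`` fps.

        The new grid starts at the same first sample time and covers the
        same half-open span ``[t_start, t_start + n/fps)``, so a 90 fps
        mouse recording resampled to 120 fps yields the same 1 s windows
        with 120 columns as rat recordings.
        """
        if target_rate <= 0:
            raise InputError("target_rate must be positive")
        if np.isclose(target_rate, self.frame_rate):
            return self
        span = self.n_timepoints / self.frame_rate
        n_new = int(round(span * target_rate))
        new_axis = self.time_axis[0] + np.arange(n_new) / target_rate
        new_pos = np.empty((self.n_trials, n_new))
        for i in range(self.n_trials):
            new_pos[i] = np.interp(new_axis, self.time_axis, self.positions[i])
        return TrajectoryMatrix(new_pos, new_axis, target_rate, self.alignment)

    def select(self, indices) -> "TrajectoryMatrix":
        """Row-subset the matrix (boolean mask or integer indices)."""
        return TrajectoryMatrix(
            self.positions[np.asarray(indices)], self.time_axis, self.frame_rate,
            self.alignment,
        )

    # -- on-disk format: dense CSV matrix + JSON sidecar ------------------

    def save(self, path) -> None:
        """Write positions as a dense CSV plus a ``.json`` sidecar."""
        path = Path(path)
        np.savetxt(path, self.positions, delimiter=",")
        sidecar = {
            "frame_rate": self.frame_rate,
            "alignment": self.alignment,
            "time0": float(self.time_axis[0]),
            "n_timepoints": int(self.n_timepoints),
        }
        path.with_suffix(path.suffix + ".json").write_text(
            json.dumps(sidecar, indent=2)
        )

    @classmethod
    def load(cls, path) -> "TrajectoryMatrix":
        path = Path(path)
        sidecar = json.loads(path.with_suffix(path.suffix + ".json").read_text())
        positions = np.loadtxt(path, delimiter=",", ndmin=2)
        time_axis = sidecar["time0"] + np.arange(positions.shape[1]) / sidecar["frame_rate"]
        return cls(positions, time_axis, sidecar["frame_rate"], sidecar["alignment"])


def time_grid(frame_rate: float, t_start: float = -0.5, t_stop: float = 2.5) -> np.ndarray:
    """Uniform sample times covering ``[t_start, t_stop)`` at ``frame_rate``."""
    n = int(round((t_stop - t_start) * frame_rate))
    return t_start + np.arange(n) / frame_rate
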