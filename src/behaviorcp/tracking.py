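"""Head tracking from grayscale frame stacks.

The tracking pipeline mirrors the standard blob-tracking recipe for
overhead rodent video: per-pixel background estimation, background
subtraction and thresholding, retention of the largest connected
component, location of the blob's principal (largest) axis from its
second-order moments, and extraction of the axis tip corresponding to the
animal's head.  Only motion along the port axis (the axis on which the
nose ports are aligned) is analyzed; the orthogonal component is
discarded by projection.

Positions are reported as ``(x, y)`` pixel coordinates (x = column,
y = row).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np

from .exceptions import ConfigurationError, InputError, MissingDetectionError
from .synthetic import FrameStack
from .trajectories import TrajectoryMatrix


@dataclass(frozen=True)
class TrackerConfig:
    """Tracking parameters.

    threshold : absolute background-difference threshold (intensity units).
    min_blob_area : smallest accepted connected component, pixels.
    background_method : per-pixel "median" (robust to the animal's transit)
        or "mean" over frames.
    tip_disambiguation : "nearest_previous" picks the principal-axis
        endpoint closest to the previous head estimate; "marker" picks the
        endpoint with the brighter local intensity (for fixtures rendered
        with a head marker).
    max_gap : longest run of missing detections filled by linear
        interpolation; longer gaps flag the trajectory unusable.
    """

    threshold: float = 25.0
    min_blob_area: int = 20
    background_method: str = "median"
    tip_disambiguation: str = "nearest_previous"
    max_gap: int = 5

    def __post_init__(self):
        if not (0 <= self.threshold <= 255):
            raise ConfigurationError("threshold must be within intensity range")
        if self.min_blob_area < 1:
            raise ConfigurationError("min_blob_area must be >= 1")
        if self.background_method not in ("median", "mean"):
            raise ConfigurationError("background_method must be median or mean")
        if self.tip_disambiguation not in ("nearest_previous", "marker"):
            raise ConfigurationError(
                "tip_disambiguation must be nearest_previous or marker"
            )


@dataclass
class HeadEstimate:
    """One frame's head position and whether the axis was degenerate."""

    position: np.ndarray  # (x, y)
    degenerate: bool = False


def estimate_background(frames: np.ndarray, method: str = "median") -> np.ndarray:
    """Per-pixel median (default) or mean over frames.

    The median is robust to the animal transiting each pixel in a minority
    of frames, so on typical stacks it recovers the empty scene.
    """
    frames = np.asarray(frames)
    if frames.ndim != 3 or frames.shape[0] < 1:
        raise InputError("need a non-empty (n_frames, h, w) stack")
    if method == "median":
        bg = np.median(frames, axis=0)
    elif method == "mean":
        bg = np.mean(frames, axis=0)
    else:
        raise ConfigurationError(f"unknown background method {method!r}")
    if np.issubdtype(frames.dtype, np.integer):
        bg = np.round(bg).astype(frames.dtype)
    return bg


def segment_animal(
    frame: np.ndarray, background: np.ndarray, config: TrackerConfig = TrackerConfig()
) -> np.ndarray:
    """Largest connected component of |frame - background| > threshold.

    Components smaller than ``min_blob_area`` are discarded; an all-False
    mask is returned when nothing qualifies.
    """
    from skimage.measure import label

    frame = np.asarray(frame)
    background = np.asarray(background)
    if frame.shape != background.shape:
        raise InputError("frame and background shapes differ")
    diff = np.abs(frame.astype(float) - background.astype(float))
    binary = diff > config.threshold
    labels = label(binary, connectivity=2)
    if labels.max() == 0:
        return np.zeros_like(binary)
    counts = np.bincount(labels.ravel())
    counts[0] = 0
    best = int(np.argmax(counts))
    if counts[best] < config.min_blob_area:
        return np.zeros_like(binary)
    return labels == best


def extract_head_position(
    mask: np.ndarray,
    prev_head: Optional[np.ndarray] = None,
    config: TrackerConfig = TrackerConfig(),
    intensity: Optional[np.ndarray] = None,
) -> HeadEstimate:
    """Head = tip of the mask's principal axis.

    The principal axis is the leading eigenvector of the mask's
    second-order central moments; the two candidate tips are the extreme
    mask pixels along that axis.  The returned tip is the one nearest to
    ``prev_head`` (default rule) or, in "marker" mode, the one whose local
    neighborhood in ``intensity`` is brighter.  A near-isotropic mask
    (axis ratio < 1.2) is flagged degenerate; the extreme point is still
    returned.
    """
    mask = np.asarray(mask, dtype=bool)
    ys, xs = np.nonzero(mask)
    if xs.size == 0:
        raise MissingDetectionError("empty mask: no blob detected")
    pts = np.column_stack([xs, ys]).astype(float)  # (n, 2) as (x, y)
    centroid = pts.mean(axis=0)
    centered = pts - centroid
    cov = centered.T @ centered / pts.shape[0]
    evals, evecs = np.linalg.eigh(cov)  # ascending
    axis = evecs[:, -1]
    ratio = np.sqrt(max(evals[-1], 1e-12) / max(evals[0], 1e-12))
    degenerate = ratio < 1.2

    proj = centered @ axis
    # sub-pixel tips: centroid of the pixels within 1 px of the extreme
    # projection (robust to rasterization of the blob boundary)
    tip_lo = pts[proj <= proj.min() + 1.0].mean(axis=0)
    tip_hi = pts[proj >= proj.max() - 1.0].mean(axis=0)

    if config.tip_disambiguation == "marker":
        if intensity is None:
            raise InputError("marker disambiguation requires an intensity image")
        tip = max(
            (tip_lo, tip_hi), key=lambda p: _local_intensity(intensity, p)
        )
    elif prev_head is not None:
        prev = np.asarray(prev_head, dtype=float)
        tip = min((tip_lo, tip_hi), key=lambda p: np.linalg.norm(p - prev))
    else:
        tip = tip_hi  # deterministic fallback; callers should supply a hint
    return HeadEstimate(np.asarray(tip, dtype=float), bool(degenerate))


def _local_intensity(image: np.ndarray, point: np.ndarray, radius: int = 3) -> float:
    h, w = image.shape
    x, y = int(round(point[0])), int(round(point[1]))
    y0, y1 = max(0, y - radius), min(h, y + radius + 1)
    x0, x1 = max(0, x - radius), min(w, x + radius + 1)
    return float(np.mean(image[y0:y1, x0:x1]))


def project_to_port_axis(positions: np.ndarray, port_axis: np.ndarray) -> np.ndarray:
    """Project (x, y) positions onto the port axis, discarding the rest."""
    positions = np.atleast_2d(np.asarray(positions, dtype=float))
    axis = np.asarray(port_axis, dtype=float)
    norm = np.linalg.norm(axis)
    if norm == 0:
        raise InputError("port_axis must be a non-zero vector")
    axis = axis / norm
    return positions @ axis


@dataclass
class TrackResult:
    """Output of frame-by-frame tracking for one trial's stack."""

    positions: np.ndarray   # (n_frames, 2) (x, y); interpolated where missing
    missing: np.ndarray     # bool per frame: detection failed there
    degenerate: np.ndarray  # bool per frame: principal axis ill-defined
    usable: bool            # False when a gap exceeded config.max_gap


class HeadTracker:
    """Frame-stack to 1-D port-axis trajectory tracker."""

    def __init__(self, config: TrackerConfig = TrackerConfig()):
        self.config = config

    def track(
        self,
        frames: np.ndarray,
        initial_hint: Optional[np.ndarray] = None,
        background: Optional[np.ndarray] = None,
    ) -> TrackResult:
        """Track the head through a stack, chaining tip disambiguation.

        Missing detections (no blob) are linearly interpolated when the
        gap is at most ``max_gap`` consecutive frames; longer or edge gaps
        mark the result unusable.
        """
        frames = np.asarray(frames)
        if background is None:
            background = estimate_background(frames, self.config.background_method)
        n = frames.shape[0]
        positions = np.full((n, 2), np.nan)
        missing = np.zeros(n, dtype=bool)
        degenerate = np.zeros(n, dtype=bool)
        prev = None if initial_hint is None else np.asarray(initial_hint, float)
        for t in range(n):
            mask = segment_animal(frames[t], background, self.config)
            try:
                est = extract_head_position(
                    mask, prev_head=prev, config=self.config, intensity=frames[t]
                )
            except MissingDetectionError:
                missing[t] = True
                continue
            positions[t] = est.position
            degenerate[t] = est.degenerate
            prev = est.position
        positions, usable = _fill_gaps(positions, missing, self.config.max_gap)
        return TrackResult(positions, missing, degenerate, usable)

    def track_stack(self, stack: FrameStack, initial_hint=None) -> np.ndarray:
        """Track a :class:`FrameStack` and project onto its port axis."""
        if initial_hint is None:
            initial_hint = stack.ground_truth_head[0]
        result = self.track(stack.frames, initial_hint=initial_hint)
        return project_to_port_axis(result.positions, stack.port_axis)


def _fill_gaps(positions: np.ndarray, missing: np.ndarray, max_gap: int):
    """Linear interpolation over interior gaps of at most ``max_gap`` frames."""
    n = positions.shape[0]
    valid = ~missing
    if valid.all():
        return positions, True
    if not valid.any():
        return positions, False
    usable = True
    idx = np.flatnonzero(valid)
    # edge gaps: hold nearest valid value, unusable if longer than max_gap
    first, last = idx[0], idx[-1]
    if first > 0:
        positions[:first] = positions[first]
        usable &= first <= max_gap
    if last < n - 1:
        positions[last + 1:] = positions[last]
        usable &= (n - 1 - last) <= max_gap
    # interior gaps
    for a, b in zip(idx[:-1], idx[1:]):
        gap = b - a - 1
        if gap == 0:
            continue
        if gap > max_gap:
            usable = False
        frac = np.arange(1, gap + 1) / (gap + 1)
        positions[a + 1:b] = (
            positions[a][None, :] * (1 - frac[:, None])
            + positions[b][None, :] * frac[:, None]
        )
    return positions, usable


# -- frame-stack I/O -------------------------------------------------------


def load_frames(path) -> np.ndarray:
    """Load a stack from a multi-page TIFF file or a directory of PNGs."""
    path = Path(path)
    if path.is_dir():
        import imageio.v3 as iio

        files = sorted(path.glob("*.png"))
        if not files:
            raise InputError(f"no PNG frames in {path}")
        return np.stack([iio.imread(f) for f in files])
    import tifffile

    return tifffile.imread(path)


def save_frames(frames: np.ndarray, path) -> None:
    """Save a stack as a multi-page TIFF."""
    import tifffile

    tifffile.imwrite(path, np.asarray(frames))


def track_frames_to_trajectory(
    stacks: list[FrameStack],
    config: TrackerConfig = TrackerConfig(),
    frame_rate: float = 120.0,
    t_start: float = -0.5,
) -> TrajectoryMatrix:
    """Track a list of per-trial stacks into a trajectory matrix."""
    tracker = HeadTracker(config)
    rows = [tracker.track_stack(stack) for stack in stacks]
    n_time = min(len(r) for r in rows)
    positions = np.vstack([r[:n_time] for r in rows])
    time_axis = t_start + np.arange(n_time) / frame_rate
    return TrajectoryMatrix(positions, time_axis, frame_rate)
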