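"""Synthetic duration-categorization sessions with known ground truth.

This module generates behavioral sessions with the statistical structure the
analysis pipeline assumes: stimuli drawn from the eight-interval set used in
the duration-categorization task (symmetric around the 1.5 s boundary),
logistic choice behavior on log duration, a slowly drifting latent bias that
couples head trajectories to choices, a previous-reward history effect,
premature responses whose interrupted stimuli repeat on the next trial, and
idiosyncratic per-subject trajectory templates sampled at 120 (rat) or 90
(mouse) frames/s.  It also renders synthetic grayscale frame stacks so the
video-tracking stage can be exercised against planted ground truth.

Generative model per trial t (within a session)::

    z_t   = latent_ar_coeff * z_{t-1} + eps_t,   eps_t ~ N(0, latent_noise_sd^2)
    logit = psycho_slope * (ln I_t - ln boundary) + psycho_bias
            + z_t + history_reward_weight * R_{t-1}
    P(choice = long) = logistic(logit)
    trajectory_t(.)  = template(.) + traj_coupling_gain * z_t * mode(.) + noise

where ``mode`` is a fixed unit-norm half-cosine ramp over time, so the
latent bias is expressed in the trajectory from before interval onset —
with ``traj_coupling_gain = 0`` trajectories carry no choice information
by construction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd

from ._utils import derive_seed, sigmoid, stable_hash
from .exceptions import ConfigurationError, InputError, ParameterError
from .trajectories import TrajectoryMatrix, time_grid

#: The eight stimulus intervals (seconds) of the duration-categorization task.
DEFAULT_STIMULUS_SET = (0.6, 1.05, 1.26, 1.38, 1.62, 1.74, 1.95, 2.4)

#: Canonical subject names used by the default multi-subject simulator.
DEFAULT_SUBJECTS = ("Edgar", "Fernando", "Gabriel")

TRIAL_COLUMNS = [
    "subject", "session", "trial", "stimulus_s", "choice", "rewarded",
    "premature", "prev_stimulus_s", "prev_reward_code", "prev_difficulty_s",
]


@dataclass(frozen=True)
class TaskConfig:
    """Static parameters of the duration-categorization task.

    Defaults reproduce the rat task: eight intervals symmetric around the
    1.5 s categorical boundary, long judged at the left port, 11 s error
    timeout, 9 s inter-trial spacing, 150 ms / 7 kHz tones, 120 fps video.
    """

    stimulus_set: tuple = DEFAULT_STIMULUS_SET
    boundary: float = 1.5
    long_reward_side: str = "left"
    timeout_error: float = 11.0
    timeout_trial_spacing: float = 9.0
    tone_duration: float = 0.150
    tone_freq: float = 7000.0
    frame_rate: float = 120.0

    def __post_init__(self):
        if len(self.stimulus_set) == 0:
            raise ConfigurationError("stimulus_set must be non-empty")
        stim = np.asarray(self.stimulus_set, dtype=float)
        if not (stim.min() < self.boundary < stim.max()):
            raise ConfigurationError(
                "boundary must lie strictly inside the stimulus range"
            )
        for s in stim:
            mirror = 2.0 * self.boundary - s
            if not np.any(np.isclose(stim, mirror, atol=1e-9)):
                raise ConfigurationError(
                    f"stimulus {s} has no mirror {mirror} in the set"
                )
        if self.frame_rate <= 0:
            raise ConfigurationError("frame_rate must be positive")


def make_subject_template(
    subject: str,
    slot: Optional[int] = None,
    n_slots: int = 8,
    amplitude_sd: float = 50.0,
    n_harmonics: int = 4,
    period: float = 3.0,
) -> Callable[[np.ndarray], np.ndarray]:
    """Build a deterministic, idiosyncratic trajectory template for a subject.

    The template is a sum of cosine harmonics of the analysis window
    (period 3 s, covering [-0.5, 2.5) s).  Each subject draws its harmonics
    from a disjoint frequency slot, so templates of different subjects are
    mutually near-orthogonal — cross-subject trajectory correlations are
    close to zero by construction, while within-subject trajectories stay
    highly correlated.  Amplitudes and phases are seeded from a stable hash
    of the subject name, so the template is reproducible across processes.

    Parameters
    ----------
    slot : int, optional
        Frequency-slot index in ``range(n_slots)``.  When omitted it is
        derived from the subject name; :func:`make_subject_templates`
        assigns disjoint slots explicitly.
    amplitude_sd : float
        Target standard deviation of the template over time, in pixels.
    """
    if slot is None:
        slot = stable_hash(subject) % n_slots
    rng = np.random.default_rng(stable_hash("template:" + subject) % 2**31)
    # harmonic indices m -> frequency m / period; disjoint across slots
    ms = slot + 1 + n_slots * np.arange(n_harmonics)
    amps = rng.normal(size=n_harmonics) / (1.0 + np.arange(n_harmonics))
    phases = rng.uniform(0, 2 * np.pi, size=n_harmonics)
    # cos terms with these amplitudes have time-variance sum(a^2)/2
    scale = amplitude_sd / math.sqrt(float(np.sum(amps**2)) / 2.0)
    amps = amps * scale
    # subjects occupy distinct baseline positions along the port axis
    offset = (slot - (n_slots - 1) / 2.0) * 60.0

    def template(t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        out = np.full_like(t, offset)
        for a, m, ph in zip(amps, ms, phases):
            out += a * np.cos(2 * np.pi * m * (t + 0.5) / period + ph)
        return out

    return template


def make_subject_templates(
    subjects: Sequence[str], **kwargs
) -> dict[str, Callable]:
    """Templates for a cohort, with disjoint frequency slots by position."""
    n_slots = max(len(subjects), 8)
    return {
        name: make_subject_template(name, slot=i, n_slots=n_slots, **kwargs)
        for i, name in enumerate(subjects)
    }


def coupling_mode(time_axis: np.ndarray) -> np.ndarray:
    """Fixed unit-norm temporal mode through which the latent bias couples.

    A half-cosine ramp rising from 0 at t = -0.5 s to a plateau at
    t = +0.5 s, unit-normalized over the time grid.  The latent bias is
    thus expressed as a sustained head-position displacement along the
    port axis — leaning toward the long-choice port predicts a long
    report — with the same sign for every subject, since all subjects
    share the port geometry.  The coupling is time-extended and already
    present before interval onset, so choice information appears early
    in the trial.
    """
    t = np.asarray(time_axis, dtype=float)
    raw = np.where(
        t < -0.5, 0.0,
        np.where(t < 0.5, 0.5 * (1.0 - np.cos(np.pi * (t + 0.5))), 1.0),
    )
    norm = np.linalg.norm(raw)
    return raw / norm if norm > 0 else raw


@dataclass
class GenerativeParams:
    """Parameters of the synthetic session generator.

    Attributes
    ----------
    psycho_slope : float
        Logistic sensitivity in 1/log-seconds.  The default (10.0),
        together with the latent-bias and history noise, puts accuracy
        near 99% on the easiest intervals and ~68% on the hardest — the
        well-trained regime in which psychometric curves asymptote at 0
        and 1 on the easiest stimuli.
    psycho_bias : float
        Additive bias in log-odds (0 = indifference at the boundary).
    latent_ar_coeff : float
        AR(1) coefficient of the slowly drifting latent bias z_t, in [0, 1).
    latent_noise_sd : float
        Innovation SD of z_t (stationary SD = sd / sqrt(1 - coeff^2)).
    traj_coupling_gain : float
        Pixels of trajectory displacement, along the unit coupling mode,
        per unit of latent bias; 0 decouples trajectories from choice.
        The default (300, with the mode's per-sample plateau of ~0.06)
        produces sustained port-axis displacements of order ten pixels
        per unit bias — the visible-by-eye separation of choice-split
        mean trajectories in overhead rodent video.
    history_reward_weight : float
        Log-odds weight of the signed previous-reward code R_{t-1}.
    premature_rate_base : float
        Mean premature-response probability over the stimulus set; per
        trial the probability scales with stimulus/boundary (longer waits
        are harder to withhold).
    traj_template : callable or None
        time -> pixels baseline trajectory; ``None`` uses the subject's
        idiosyncratic default template.
    traj_noise_sd : float
        SD of the smooth (temporally correlated) trial-to-trial motion
        noise, pixels.  Body motion varies smoothly, so this component is
        a Gaussian process with correlation time ``traj_noise_timescale``
        rather than white noise.
    traj_noise_timescale : float
        Correlation time of the smooth motion noise, seconds.
    measurement_noise_sd : float
        Per-sample i.i.d. tracking jitter, pixels.
    seed : int
        Seed for all randomness of the session.
    """

    psycho_slope: float = 10.0
    psycho_bias: float = 0.0
    latent_ar_coeff: float = 0.9
    latent_noise_sd: float = 0.3
    traj_coupling_gain: float = 300.0
    history_reward_weight: float = 0.5
    premature_rate_base: float = 0.067
    traj_template: Optional[Callable] = None
    traj_noise_sd: float = 10.0
    traj_noise_timescale: float = 0.15
    measurement_noise_sd: float = 1.0
    seed: int = 0

    def validate(self):
        numeric = [
            self.psycho_slope, self.psycho_bias, self.latent_ar_coeff,
            self.latent_noise_sd, self.traj_coupling_gain,
            self.history_reward_weight, self.premature_rate_base,
            self.traj_noise_sd, self.traj_noise_timescale,
            self.measurement_noise_sd,
        ]
        if not all(np.isfinite(v) for v in numeric):
            raise ParameterError("generative parameters must be finite")
        if not (0 <= self.latent_ar_coeff < 1):
            raise ParameterError("latent_ar_coeff must be in [0, 1)")
        if not (0 <= self.premature_rate_base <= 1):
            raise ParameterError("premature_rate_base must be a probability")
        if min(self.latent_noise_sd, self.traj_noise_sd,
               self.traj_noise_timescale, self.measurement_noise_sd) < 0:
            raise ParameterError("noise SDs and timescales must be non-negative")


def _smooth_noise(rng, shape, sd, timescale, frame_rate):
    """Temporally smooth Gaussian noise (squared-exponential-like).

    White noise convolved with a Gaussian kernel of width ``timescale``
    seconds, rescaled so every sample has marginal SD ``sd``.  Emulates
    smooth trial-to-trial body-motion variability; white jitter is added
    separately as measurement noise.
    """
    if sd == 0:
        return np.zeros(shape)
    white = rng.normal(size=shape)
    sigma = timescale * frame_rate
    if sigma <= 0:
        return sd * white
    from scipy.ndimage import gaussian_filter1d

    smooth = gaussian_filter1d(white, sigma=sigma, axis=-1, mode="nearest")
    scale = smooth.std()
    if scale == 0:
        return np.zeros(shape)
    return sd * smooth / scale


def sample_stimulus_sequence(
    config: TaskConfig,
    n_trials: int,
    premature_flags: Sequence[bool],
    seed: int,
) -> np.ndarray:
    """Draw a stimulus sequence with premature-trial repetition.

    Stimuli are sampled uniformly from the task's stimulus set, except that
    a stimulus interrupted by a premature response is repeated on the next
    trial (the subject cannot skip long intervals by responding early).
    """
    if n_trials < 1:
        raise InputError("n_trials must be >= 1")
    premature_flags = np.asarray(premature_flags, dtype=bool)
    if premature_flags.shape != (n_trials,):
        raise InputError("premature_flags length must equal n_trials")
    if len(config.stimulus_set) == 0:
        raise ConfigurationError("stimulus_set must be non-empty")
    rng = np.random.default_rng(seed)
    stim_set = np.asarray(config.stimulus_set, dtype=float)
    out = np.empty(n_trials)
    for t in range(n_trials):
        if t > 0 and premature_flags[t - 1]:
            out[t] = out[t - 1]
        else:
            out[t] = rng.choice(stim_set)
    return out


def simulate_session(
    config: TaskConfig,
    params: GenerativeParams,
    n_trials: int,
    subject: str = "Edgar",
    session: str = "s01",
    seed: Optional[int] = None,
    t_start: float = -0.5,
    t_stop: float = 2.5,
    return_latent: bool = False,
):
    """Simulate one session: trial records plus the trajectory matrix.

    Returns a trial table with columns ``subject, session, trial,
    stimulus_s, choice, rewarded, premature, prev_stimulus_s,
    prev_reward_code, prev_difficulty_s`` and a :class:`TrajectoryMatrix`
    on the grid ``[t_start, t_stop)`` at ``config.frame_rate``.

    Rewards obey the task rule (long choices rewarded above the boundary,
    short below; premature trials never rewarded), and stimuli interrupted
    by premature responses repeat on the following trial.
    """
    if n_trials < 1:
        raise InputError("n_trials must be >= 1")
    params.validate()
    rng = np.random.default_rng(params.seed if seed is None else seed)

    template = params.traj_template or make_subject_template(subject)
    taxis = time_grid(config.frame_rate, t_start, t_stop)
    base = template(taxis)
    mode = coupling_mode(taxis)

    log_b = math.log(config.boundary)
    stat_sd = params.latent_noise_sd / math.sqrt(1.0 - params.latent_ar_coeff**2)
    stim_set = np.asarray(config.stimulus_set, dtype=float)

    rows = []
    z = rng.normal(0.0, stat_sd) if stat_sd > 0 else 0.0
    z_trace = np.empty(n_trials)
    prev_premature = False
    prev_stimulus = np.nan
    prev_reward_code = 0
    stimulus = np.nan
    for t in range(n_trials):
        if t > 0 and prev_premature:
            pass  # stimulus repeats
        else:
            stimulus = float(rng.choice(stim_set))
        if t > 0:
            z = params.latent_ar_coeff * z + rng.normal(0.0, params.latent_noise_sd)
        z_trace[t] = z
        logit = (
            params.psycho_slope * (math.log(stimulus) - log_b)
            + params.psycho_bias
            + z
            + params.history_reward_weight * prev_reward_code
        )
        choice_long = rng.random() < sigmoid(logit)
        p_premature = min(
            1.0, params.premature_rate_base * stimulus / config.boundary
        )
        premature = rng.random() < p_premature
        correct = (choice_long and stimulus > config.boundary) or (
            not choice_long and stimulus < config.boundary
        )
        rewarded = bool(correct and not premature)
        rows.append(
            {
                "subject": subject,
                "session": session,
                "trial": t + 1,
                "stimulus_s": stimulus,
                "choice": "long" if choice_long else "short",
                "rewarded": rewarded,
                "premature": bool(premature),
                "prev_stimulus_s": prev_stimulus,
                "prev_reward_code": int(prev_reward_code),
                "prev_difficulty_s": (
                    abs(prev_stimulus - config.boundary)
                    if np.isfinite(prev_stimulus)
                    else np.nan
                ),
            }
        )
        prev_stimulus = stimulus
        prev_premature = premature
        if rewarded:
            prev_reward_code = 1 if choice_long else -1
        else:
            prev_reward_code = 0

    positions = (
        base[None, :]
        + params.traj_coupling_gain * z_trace[:, None] * mode[None, :]
        + _smooth_noise(
            rng, (n_trials, taxis.size), params.traj_noise_sd,
            params.traj_noise_timescale, config.frame_rate,
        )
        + rng.normal(0.0, params.measurement_noise_sd,
                     size=(n_trials, taxis.size))
    )
    trials = pd.DataFrame(rows, columns=TRIAL_COLUMNS)
    trajs = TrajectoryMatrix(positions, taxis, config.frame_rate)
    if return_latent:
        return trials, trajs, z_trace
    return trials, trajs


def simulate_dataset(
    config: TaskConfig = TaskConfig(),
    params: GenerativeParams = None,
    subjects: Sequence[str] = DEFAULT_SUBJECTS,
    n_sessions: int = 2,
    n_trials: int = 450,
    seed: int = 0,
    **session_kwargs,
) -> tuple[pd.DataFrame, TrajectoryMatrix]:
    """Simulate a multi-subject, multi-session dataset.

    Each subject receives an idiosyncratic template from a disjoint
    frequency slot; per-session seeds are derived from ``seed`` by stable
    hashing so individual sessions can be regenerated independently.
    """
    if params is None:
        params = GenerativeParams()
    templates = make_subject_templates(subjects)
    all_trials, all_pos = [], []
    taxis = None
    for subject in subjects:
        sub_params = replace(params, traj_template=templates[subject])
        for k in range(n_sessions):
            session = f"s{k + 1:02d}"
            child = derive_seed(seed, f"{subject}:{session}")
            trials, trajs = simulate_session(
                config, sub_params, n_trials, subject=subject, session=session,
                seed=child, **session_kwargs,
            )
            all_trials.append(trials)
            all_pos.append(trajs.positions)
            taxis = trajs.time_axis
    trials = pd.concat(all_trials, ignore_index=True)
    trajs = TrajectoryMatrix(np.vstack(all_pos), taxis, config.frame_rate)
    return trials, trajs


# -- synthetic video frames for the tracking stage ------------------------


@dataclass
class FrameStack:
    """Time-ordered grayscale frames plus planted tracking ground truth."""

    frames: np.ndarray          # (n_frames, height, width) uint8
    ground_truth_head: np.ndarray  # (n_frames, 2) as (x, y) pixels
    port_axis: np.ndarray       # unit 2-vector (x, y)

    def __post_init__(self):
        self.frames = np.asarray(self.frames)
        self.ground_truth_head = np.asarray(self.ground_truth_head, dtype=float)
        self.port_axis = np.asarray(self.port_axis, dtype=float)
        if self.frames.ndim != 3:
            raise InputError("frames must be (n_frames, height, width)")
        n, h, w = self.frames.shape
        x, y = self.ground_truth_head[:, 0], self.ground_truth_head[:, 1]
        if np.any((x < 0) | (x >= w) | (y < 0) | (y >= h)):
            raise InputError("ground_truth_head must lie inside image bounds")


def _default_background(image_size: tuple[int, int], seed: int) -> np.ndarray:
    """A static, smoothly varying grayscale background."""
    h, w = image_size
    yy, xx = np.mgrid[0:h, 0:w]
    rng = np.random.default_rng(derive_seed(seed, "background"))
    phase = rng.uniform(0, 2 * np.pi, size=2)
    img = (
        55
        + 25 * np.sin(2 * np.pi * xx / max(w, 1) + phase[0])
        + 15 * np.cos(2 * np.pi * yy / max(h, 1) + phase[1])
    )
    return np.clip(img, 0, 255).astype(np.uint8)


def render_synthetic_frames(
    head_path: np.ndarray,
    image_size: tuple[int, int] = (120, 160),
    blob_axes: tuple[float, float] = (18.0, 9.0),
    blob_angle: float = 0.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    background: Optional[np.ndarray] = None,
    port_axis: tuple[float, float] = (1.0, 0.0),
    blob_intensity: int = 200,
    head_marker: bool = False,
    draw_blob: bool = True,
) -> FrameStack:
    """Render frames of an ellipse "animal" whose major-axis tip follows a path.

    Each frame is the static background plus an ellipse of half-axes
    ``blob_axes = (a, b)`` (a = major) rotated by ``blob_angle`` (radians,
    measured from the +x axis), positioned so that the tip of its major
    axis sits at ``head_path[t]`` (given as (x, y) pixel coordinates).
    Optionally a small bright marker disk is drawn at the head for the
    marker-based tip-disambiguation mode, and Gaussian intensity noise of
    SD ``noise_sd`` is added.
    """
    from skimage.draw import disk, ellipse

    head_path = np.atleast_2d(np.asarray(head_path, dtype=float))
    h, w = image_size
    a, b = blob_axes
    if a <= 0 or b <= 0:
        raise ConfigurationError("blob axes must be positive")
    if 2 * max(a, b) >= min(h, w):
        raise ConfigurationError("blob larger than image")
    x, y = head_path[:, 0], head_path[:, 1]
    if np.any((x < 0) | (x >= w) | (y < 0) | (y >= h)):
        raise InputError("head_path must lie within image bounds")

    if background is None:
        background = _default_background(image_size, seed)
    background = np.asarray(background, dtype=np.uint8)
    if background.shape != (h, w):
        raise InputError("background shape must match image_size")

    u = np.array([math.cos(blob_angle), math.sin(blob_angle)])  # (x, y)
    rng = np.random.default_rng(derive_seed(seed, "frame-noise"))
    frames = np.empty((head_path.shape[0], h, w), dtype=np.uint8)
    for t, head in enumerate(head_path):
        img = background.astype(float).copy()
        if draw_blob:
            center = head - a * u  # tip of major axis at the head
            # skimage.draw.ellipse works in (row, col); rotation is the
            # angle of the r_radius axis, so pass the major axis as
            # c_radius with rotation measuring x->y (row = y, col = x).
            rr, cc = ellipse(
                center[1], center[0], b, a, shape=(h, w), rotation=-blob_angle
            )
            img[rr, cc] = blob_intensity
            if head_marker:
                rr, cc = disk((head[1], head[0]), 2.5, shape=(h, w))
                img[rr, cc] = 255
        if noise_sd > 0:
            img = img + rng.normal(0.0, noise_sd, size=img.shape)
        frames[t] = np.clip(np.round(img), 0, 255).astype(np.uint8)

    axis = np.asarray(port_axis, dtype=float)
    norm = np.linalg.norm(axis)
    if norm == 0:
        raise InputError("port_axis must be non-zero")
    return FrameStack(frames, head_path, axis / norm)


# -- session table I/O -----------------------------------------------------


def save_session_table(trials: pd.DataFrame, path) -> None:
    """Write the trial table as CSV with the canonical header."""
    trials.to_csv(path, index=False)


def load_session_table(path) -> pd.DataFrame:
    trials = pd.read_csv(path, comment="#")
    missing = set(TRIAL_COLUMNS[:7]) - set(trials.columns)
    if missing:
        raise InputError(f"session table missing columns: {sorted(missing)}")
    return trials
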