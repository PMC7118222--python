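"""Temporal preprocessing of resting-state BOLD runs.

The chain mirrors the standard single-subject temporal pipeline used in
network-homogeneity studies: drop initial volumes, motion quality control,
linear detrend, band-pass filtering (0.01-0.08 Hz), nuisance regression
(Friston-24 motion expansion plus white-matter/CSF signals, no global
signal), framewise-displacement (FD) computation, and scrubbing of
high-motion frames.  Spatial steps (realignment estimation, normalisation)
are out of scope: runs are assumed to live on a common grid already.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "BOLDRun",
    "MotionSeries",
    "ConfoundMatrix",
    "UnusableRunError",
    "drop_initial_volumes",
    "exclude_by_motion",
    "compute_fd",
    "detrend_linear",
    "bandpass",
    "build_friston24",
    "regress_confounds",
    "scrub",
    "preprocess_run",
]

#: minimum number of retained frames for a run to stay analysable
MIN_USABLE_FRAMES = 20


class UnusableRunError(ValueError):
    """Raised when an operation would leave too few frames to analyse."""


@dataclass
class BOLDRun:
    """One subject/timepoint 4D BOLD series on a voxel grid.

    ``data`` is (x, y, z, t); ``affine`` maps grid indices to mm.
    ``nuisance`` optionally carries tissue signals (keys ``wm``, ``csf``)
    aligned with the time axis.  ``usable`` is cleared when scrubbing
    leaves fewer than :data:`MIN_USABLE_FRAMES` frames.
    """

    data: np.ndarray
    tr_s: float
    subject_id: str
    timepoint: str  # "baseline" | "week8"
    affine: np.ndarray
    nuisance: dict = field(default_factory=dict)
    usable: bool = True

    @property
    def n_frames(self) -> int:
        return self.data.shape[-1]

    def __post_init__(self) -> None:
        if self.data.ndim != 4:
            raise ValueError(f"BOLD data must be 4D, got {self.data.ndim}D")
        if self.tr_s <= 0:
            raise ValueError("tr_s must be positive")


@dataclass
class MotionSeries:
    """Rigid-body motion parameters: t x 6 (tx, ty, tz in mm; rx, ry, rz in rad).

    ``fd`` is Power-style framewise displacement derived from the
    parameters; ``mean_fd`` is its average and is the motion covariate
    used in group analyses.
    """

    params: np.ndarray
    head_radius_mm: float = 50.0
    fd: np.ndarray = field(init=False)
    mean_fd: float = field(init=False)

    def __post_init__(self) -> None:
        self.params = np.asarray(self.params, dtype=float)
        if self.params.ndim != 2 or self.params.shape[1] != 6:
            raise ValueError("motion params must be t x 6")
        self.fd = compute_fd(self.params, self.head_radius_mm)
        self.mean_fd = float(self.fd.mean())

    @property
    def n_frames(self) -> int:
        return self.params.shape[0]


@dataclass
class ConfoundMatrix:
    """Nuisance design: t x k columns with labels (friston24 x24, wm, csf)."""

    columns: np.ndarray
    labels: list

    def __post_init__(self) -> None:
        self.columns = np.asarray(self.columns, dtype=float)
        if self.columns.shape[1] != len(self.labels):
            raise ValueError("column count must match labels")


def drop_initial_volumes(run: BOLDRun, motion: MotionSeries | None = None, k: int = 10):
    """Remove the first ``k`` frames of a run (signal-equilibration dummies).

    Any aligned motion series is trimmed in sync.  Returns the trimmed run,
    or a ``(run, motion)`` pair when a motion series is given.
    """
    if k < 0:
        raise ValueError("k must be >= 0")
    if run.n_frames <= k:
        raise ValueError(f"cannot drop {k} of {run.n_frames} frames")
    out = replace(run, data=run.data[..., k:],
                  nuisance={key: v[k:] for key, v in run.nuisance.items()})
    if motion is None:
        return out
    if motion.n_frames != run.n_frames + 0 and motion.n_frames < run.n_frames:
        raise ValueError("motion series shorter than run")
    return out, MotionSeries(motion.params[k:], motion.head_radius_mm)


def exclude_by_motion(motion: MotionSeries, max_trans_mm: float = 2.0,
                      max_rot_deg: float = 2.0) -> bool:
    """Motion QC: True (exclude subject) iff any frame exceeds the translation
    or rotation limit on any single axis (rotations compared in degrees)."""
    if motion.n_frames == 0:
        raise ValueError("empty motion series")
    trans = np.abs(motion.params[:, :3])
    rot_deg = np.degrees(np.abs(motion.params[:, 3:]))
    return bool(trans.max() > max_trans_mm or rot_deg.max() > max_rot_deg)


def compute_fd(params: np.ndarray, head_radius_mm: float = 50.0) -> np.ndarray:
    """Power-style framewise displacement.

    fd[0] = 0; fd[i] = sum of absolute frame-to-frame differences of the six
    parameters, with rotations converted to arc length on a sphere of
    ``head_radius_mm``.
    """
    params = np.asarray(params, dtype=float)
    if params.ndim != 2 or params.shape[1] != 6:
        raise ValueError("params must be t x 6")
    if not np.all(np.isfinite(params)):
        raise ValueError("non-finite motion parameters")
    d = np.diff(params, axis=0)
    d[:, 3:] *= head_radius_mm
    fd = np.zeros(params.shape[0])
    fd[1:] = np.abs(d).sum(axis=1)
    return fd


def detrend_linear(series: np.ndarray) -> np.ndarray:
    """Remove the least-squares linear trend along the last axis."""
    series = np.asarray(series, dtype=float)
    t = series.shape[-1]
    if t < 3:
        raise ValueError("need at least 3 frames to detrend")
    x = np.arange(t, dtype=float)
    x = (x - x.mean()) / x.std()
    flat = series.reshape(-1, t)
    slope = flat @ x / t  # x has unit population variance, zero mean
    resid = flat - flat.mean(axis=-1, keepdims=True) - np.outer(slope, x)
    return resid.reshape(series.shape)


def _bandpass_response(freqs: np.ndarray, low_hz: float, high_hz: float) -> np.ndarray:
    """Near-ideal band-pass response with 10% raised-cosine roll-off at each edge."""
    h = np.zeros_like(freqs)
    lo0, lo1 = 0.9 * low_hz, 1.1 * low_hz
    hi0, hi1 = 0.9 * high_hz, 1.1 * high_hz
    h[(freqs >= lo1) & (freqs <= hi0)] = 1.0
    rise = (freqs > lo0) & (freqs < lo1)
    h[rise] = 0.5 * (1 - np.cos(np.pi * (freqs[rise] - lo0) / (lo1 - lo0)))
    fall = (freqs > hi0) & (freqs < hi1)
    h[fall] = 0.5 * (1 + np.cos(np.pi * (freqs[fall] - hi0) / (hi1 - hi0)))
    return h


def bandpass(series: np.ndarray, tr_s: float, low_hz: float = 0.01,
             high_hz: float = 0.08) -> np.ndarray:
    """Frequency-domain band-pass along the last axis.

    The response is 1 in the pass band with a raised-cosine transition of
    width 10% of each cutoff; DC is always removed when ``low_hz > 0``.
    """
    nyquist = 0.5 / tr_s
    if not (0 <= low_hz < high_hz):
        raise ValueError("need 0 <= low < high")
    if high_hz >= nyquist:
        raise ValueError(f"high cutoff {high_hz} >= Nyquist {nyquist}")
    series = np.asarray(series, dtype=float)
    t = series.shape[-1]
    spec = np.fft.rfft(series, axis=-1)
    freqs = np.fft.rfftfreq(t, d=tr_s)
    return np.fft.irfft(spec * _bandpass_response(freqs, low_hz, high_hz), n=t, axis=-1)


def build_friston24(params: np.ndarray) -> np.ndarray:
    """Friston-24 motion expansion: [p, p^2, p(t-1), p(t-1)^2] per parameter.

    Lagged rows at frame 0 are filled with 0 (any constant is absorbed by
    the regression intercept).
    """
    params = np.asarray(params, dtype=float)
    if params.ndim != 2 or params.shape[1] != 6:
        raise ValueError("params must be t x 6")
    if params.shape[0] < 2:
        raise ValueError("need at least 2 frames")
    lag = np.zeros_like(params)
    lag[1:] = params[:-1]
    return np.hstack([params, params**2, lag, lag**2])


def make_confounds(motion: MotionSeries, run: BOLDRun) -> ConfoundMatrix:
    """Assemble the default 26-column nuisance design (Friston-24 + wm + csf)."""
    cols = [build_friston24(motion.params)]
    labels = [f"friston24_{i}" for i in range(24)]
    for key in ("wm", "csf"):
        if key in run.nuisance:
            cols.append(np.asarray(run.nuisance[key], dtype=float)[:, None])
            labels.append(key)
    return ConfoundMatrix(np.hstack(cols), labels)


def regress_confounds(run: BOLDRun, confounds: ConfoundMatrix) -> BOLDRun:
    """Per-voxel least-squares removal of the confound columns (plus intercept).

    Rank-deficient designs are handled by the pseudoinverse solution of
    ``lstsq`` rather than producing NaN.
    """
    t = run.n_frames
    if confounds.columns.shape[0] != t:
        raise ValueError("confound rows must match run length")
    design = np.column_stack([np.ones(t), confounds.columns])
    flat = run.data.reshape(-1, t).T  # t x V
    beta = np.linalg.pinv(design) @ flat  # pseudoinverse: rank-deficiency safe
    resid = flat - design @ beta
    return replace(run, data=resid.T.reshape(run.data.shape))


def scrub(run: BOLDRun, fd: np.ndarray, threshold_mm: float = 0.2):
    """Censor frames with FD above threshold; returns (run, kept_mask).

    If fewer than :data:`MIN_USABLE_FRAMES` frames remain, the returned run
    is flagged ``usable=False`` (downstream NH refuses such runs).
    """
    fd = np.asarray(fd, dtype=float)
    if fd.shape[0] != run.n_frames:
        raise ValueError("fd not aligned with run")
    kept = fd <= threshold_mm
    out = replace(run, data=run.data[..., kept],
                  nuisance={k: v[kept] for k, v in run.nuisance.items()},
                  usable=bool(kept.sum() >= MIN_USABLE_FRAMES))
    return out, kept


def preprocess_run(run: BOLDRun, motion: MotionSeries, n_drop: int = 10,
                   low_hz: float = 0.01, high_hz: float = 0.08,
                   fd_threshold_mm: float = 0.2):
    """Full temporal chain: drop -> detrend -> band-pass -> nuisance regression -> scrub.

    Returns ``(run, motion, kept_mask)`` with the trimmed motion series.
    Motion QC (:func:`exclude_by_motion`) is a cohort-level decision and is
    applied by the pipeline before calling this.
    """
    run, motion = drop_initial_volumes(run, motion, k=n_drop)
    run = replace(run, data=detrend_linear(run.data))
    run = replace(run, data=bandpass(run.data, run.tr_s, low_hz, high_hz))
    run = regress_confounds(run, make_confounds(motion, run))
    run, kept = scrub(run, motion.fd, fd_threshold_mm)
    return run, motion, kept
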