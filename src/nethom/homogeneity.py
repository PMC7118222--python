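"""Per-voxel network homogeneity (NH).

For a voxel *i* inside a network mask of N voxels, NH(i) is the mean
Pearson correlation between its time series and the series of the other
N-1 in-network voxels.  The production path uses the O(N*t) identity

    sum_j corr(i, j) = z_i . (sum_j z_j) / t,

where z_v is the population-z-scored series of voxel v, so

    NH(i) = (z_i . s / t - 1) / (N - 1),      s = sum of all z_v,

which equals the brute-force pairwise average exactly.  Zero-variance
voxels contribute (and receive) correlations of 0 by convention; the event
is logged rather than propagating NaN.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np

from .preprocess import BOLDRun

__all__ = ["NHMap", "compute_nh", "compute_nh_brute", "standardize_map"]

log = logging.getLogger(__name__)

MIN_FRAMES = 20


@dataclass
class NHMap:
    """NH values on the mask voxels of one run.

    ``values`` is 1-D in the C-order of ``np.argwhere(mask)``; use
    :meth:`to_volume` for the 3-D view (NaN outside the mask).
    """

    values: np.ndarray
    mask: np.ndarray
    subject_id: str
    timepoint: str
    affine: np.ndarray
    standardized: bool = False

    def to_volume(self) -> np.ndarray:
        vol = np.full(self.mask.shape, np.nan)
        vol[self.mask] = self.values
        return vol


def _masked_series(run: BOLDRun, mask: np.ndarray) -> np.ndarray:
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != run.data.shape[:3]:
        raise ValueError("mask dims do not match run grid")
    if mask.sum() < 2:
        raise ValueError("mask must contain at least 2 voxels")
    if run.n_frames < MIN_FRAMES:
        raise ValueError(f"need >= {MIN_FRAMES} frames, got {run.n_frames}")
    if not run.usable:
        raise ValueError(f"run {run.subject_id}/{run.timepoint} flagged unusable")
    return run.data[mask].astype(float)  # N x t


def _zscore_rows(x: np.ndarray):
    """Population z-score per row; zero-variance rows become all-zero."""
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, keepdims=True)
    dead = sd[:, 0] == 0
    if dead.any():
        log.warning("NH: %d zero-variance voxel(s); correlations set to 0", dead.sum())
    sd[dead] = 1.0
    z = (x - mu) / sd
    z[dead] = 0.0
    return z, dead


def compute_nh(run: BOLDRun, mask: np.ndarray, subject_id: str | None = None,
               timepoint: str | None = None) -> NHMap:
    """NH map via the O(N*t) reformulation (production path)."""
    x = _masked_series(run, mask)
    n, t = x.shape
    z, dead = _zscore_rows(x)
    s = z.sum(axis=0)
    vals = (z @ s / t - 1.0) / (n - 1)
    vals[dead] = 0.0
    return NHMap(vals, np.asarray(mask, dtype=bool),
                 subject_id or run.subject_id, timepoint or run.timepoint, run.affine)


def compute_nh_brute(run: BOLDRun, mask: np.ndarray) -> NHMap:
    """Reference path: explicit pairwise correlation average (test oracle)."""
    x = _masked_series(run, mask)
    n, t = x.shape
    z, dead = _zscore_rows(x)
    corr = z @ z.T / t
    corr[dead, :] = 0.0
    corr[:, dead] = 0.0
    np.fill_diagonal(corr, 0.0)
    vals = corr.sum(axis=1) / (n - 1)
    return NHMap(vals, np.asarray(mask, dtype=bool),
                 run.subject_id, run.timepoint, run.affine)


def standardize_map(nh: NHMap) -> NHMap:
    """In-mask z-scoring of an NH map (mean 0, SD 1 within the mask)."""
    sd = nh.values.std()
    if sd == 0:
        raise ValueError("cannot standardize a constant NH map")
    return replace(nh, values=(nh.values - nh.values.mean()) / sd, standardized=True)
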