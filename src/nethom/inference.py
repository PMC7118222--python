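"""Voxel-wise group inference on NH maps with GRF cluster correction.

The group model is an ordinary least-squares GLM per mask voxel (group /
time / arm indicators plus mean-centred age and mean-FD covariates).
Cluster-level multiple-comparison correction follows Gaussian random field
theory: residual smoothness is estimated from the variance of spatial
derivatives of the normalised residuals (Kiebel/Worsley estimator), resel
counts are computed from the mask geometry, the statistic map is
thresholded voxel-wise (p < 0.001 per tail by default), 26-connected
clusters are labelled, and each cluster receives a corrected p from the
expected-cluster-count approximation.  A subject-permutation null of the
maximum cluster size is provided as an independent calibration oracle.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, stats

__all__ = [
    "StatMap", "SmoothnessEstimate",
    "stack_maps", "make_design", "fit_voxelwise_glm", "interaction_f",
    "estimate_smoothness", "resel_counts", "grf_cluster_correct",
    "grf_critical_cluster_size", "label_clusters", "permutation_cluster_null",
    "extract_cluster_means", "pearson_corr", "chi_square_contingency",
]

CONNECTIVITY = np.ones((3, 3, 3), dtype=bool)  # 26-neighbour clusters
FOUR_LN2 = 4.0 * np.log(2.0)


@dataclass
class StatMap:
    """Voxel statistic on mask voxels (1-D, argwhere order); kind 'T' or 'F'."""

    values: np.ndarray
    mask: np.ndarray
    kind: str
    dof: float

    def to_volume(self) -> np.ndarray:
        vol = np.zeros(self.mask.shape)
        vol[self.mask] = self.values
        return vol


@dataclass
class SmoothnessEstimate:
    fwhm_voxels: np.ndarray  # per-axis FWHM in voxel units
    fwhm_mm: np.ndarray
    resels: float  # volume resel count V / prod(FWHM_vox)


def stack_maps(maps: list) -> np.ndarray:
    """Stack NHMap values into an n_maps x V matrix (shared mask assumed)."""
    ref = maps[0].mask
    for m in maps:
        if m.mask.shape != ref.shape or not np.array_equal(m.mask, ref):
            raise ValueError("maps must share one mask")
    return np.vstack([m.values for m in maps])


def make_design(frame: pd.DataFrame, factor: str, covariates: tuple = ("age", "mean_fd")):
    """Two-level design: intercept, indicator of the second factor level, and
    mean-centred covariates.  Returns (X, contrast, level_order)."""
    levels = list(pd.unique(frame[factor]))
    if len(levels) != 2:
        raise ValueError(f"factor {factor} must have exactly 2 levels, got {levels}")
    cols = [np.ones(len(frame)), (frame[factor] == levels[1]).to_numpy(float)]
    for cov in covariates:
        v = frame[cov].to_numpy(float)
        cols.append(v - v.mean())
    x = np.column_stack(cols)
    contrast = np.zeros(x.shape[1])
    contrast[1] = 1.0
    return x, contrast, levels


def fit_voxelwise_glm(y: np.ndarray, design: np.ndarray, contrast: np.ndarray):
    """OLS per voxel; returns (StatMap-like T values, residuals, dof).

    ``y`` is n x V; T = c'b / se(c'b).  Rank-deficient designs fall back to
    the pseudoinverse solution.  Within-subject (paired) contrasts are
    handled upstream by differencing maps before the fit.
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(design, dtype=float)
    c = np.asarray(contrast, dtype=float)
    if y.shape[0] != x.shape[0]:
        raise ValueError("design rows must match number of maps")
    rank = np.linalg.matrix_rank(x)
    dof = y.shape[0] - rank
    if dof < 1:
        raise ValueError("no residual degrees of freedom")
    pinv = np.linalg.pinv(x)
    beta = pinv @ y
    resid = y - x @ beta
    sigma2 = (resid**2).sum(axis=0) / dof
    cvar = float(c @ np.linalg.pinv(x.T @ x) @ c)
    se = np.sqrt(np.maximum(sigma2 * cvar, 1e-300))
    return (beta.T @ c) / se, resid, dof


def interaction_f(diff_maps: np.ndarray, design: np.ndarray, contrast: np.ndarray):
    """Group x time interaction as a two-sample comparison of within-subject
    difference maps; returns (F values, T values, resid, dof) with F = T^2."""
    t, resid, dof = fit_voxelwise_glm(diff_maps, design, contrast)
    return t**2, t, resid, dof


# --- smoothness and resels -------------------------------------------------

def estimate_smoothness(residuals: np.ndarray, mask: np.ndarray,
                        voxel_size_mm: float = 3.0) -> SmoothnessEstimate:
    """Per-axis FWHM from spatial derivatives of normalised residuals.

    Residual maps are scaled voxel-wise to unit sum of squares across maps;
    the per-axis derivative variance Lambda_aa then gives
    FWHM_a = sqrt(4 ln 2 / Lambda_aa) voxels.  A floor of half a voxel is
    applied (and logged through the returned value) as a sanity bound.
    """
    mask = np.asarray(mask, bool)
    if mask.sum() < 30:
        raise ValueError("mask too small for smoothness estimation")
    r = np.asarray(residuals, float)
    if r.ndim != 2 or r.shape[0] < 10:
        raise ValueError("need >= 10 residual maps (n x V)")
    norm = np.sqrt((r**2).sum(axis=0))
    norm[norm == 0] = 1.0
    u = r / norm
    vols = np.zeros((r.shape[0],) + mask.shape)
    vols[:, mask] = u
    inmask = np.zeros(mask.shape, bool)
    inmask[mask] = True
    lam = np.empty(3)
    for ax in range(3):
        sl_a = [slice(None)] * 3
        sl_b = [slice(None)] * 3
        sl_a[ax] = slice(1, None)
        sl_b[ax] = slice(None, -1)
        pair = inmask[tuple(sl_a)] & inmask[tuple(sl_b)]
        if pair.sum() == 0:
            lam[ax] = 2.0  # no pairs along this axis: assume white
            continue
        d = vols[(slice(None),) + tuple(sl_a)] - vols[(slice(None),) + tuple(sl_b)]
        lam[ax] = (d[:, pair] ** 2).sum(axis=0).mean()
    fwhm_vox = np.sqrt(FOUR_LN2 / lam)
    fwhm_vox = np.maximum(fwhm_vox, 0.5)
    resels = mask.sum() / np.prod(fwhm_vox)
    return SmoothnessEstimate(fwhm_vox, fwhm_vox * voxel_size_mm, float(resels))


def resel_counts(mask: np.ndarray, fwhm_voxels: np.ndarray) -> np.ndarray:
    """Resel counts R0..R3 of a voxelised region (SPM counting scheme):
    voxels, in-mask edge pairs, 2x2 faces and 2x2x2 cubes per axis plane,
    scaled by the per-axis FWHM."""
    m = np.asarray(mask, bool)
    rx, ry, rz = np.asarray(fwhm_voxels, float)
    p = m.sum()
    ex = (m[1:, :, :] & m[:-1, :, :]).sum()
    ey = (m[:, 1:, :] & m[:, :-1, :]).sum()
    ez = (m[:, :, 1:] & m[:, :, :-1]).sum()
    fxy = (m[1:, 1:, :] & m[:-1, 1:, :] & m[1:, :-1, :] & m[:-1, :-1, :]).sum()
    fxz = (m[1:, :, 1:] & m[:-1, :, 1:] & m[1:, :, :-1] & m[:-1, :, :-1]).sum()
    fyz = (m[:, 1:, 1:] & m[:, :-1, 1:] & m[:, 1:, :-1] & m[:, :-1, :-1]).sum()
    c = (m[1:, 1:, 1:] & m[:-1, 1:, 1:] & m[1:, :-1, 1:] & m[1:, 1:, :-1]
         & m[:-1, :-1, 1:] & m[:-1, 1:, :-1] & m[1:, :-1, :-1]
         & m[:-1, :-1, :-1]).sum()
    r0 = p - (ex + ey + ez) + (fxy + fxz + fyz) - c
    r1 = (ex - fxy - fxz + c) / rx + (ey - fxy - fyz + c) / ry + (ez - fxz - fyz + c) / rz
    r2 = (fxy - c) / (rx * ry) + (fxz - c) / (rx * rz) + (fyz - c) / (ry * rz)
    r3 = c / (rx * ry * rz)
    return np.array([r0, r1, r2, r3], dtype=float)


def _ec_densities(u: float) -> np.ndarray:
    """Gaussian-field Euler characteristic densities rho_0..rho_3 at height u."""
    e = np.exp(-u * u / 2.0)
    return np.array([
        stats.norm.sf(u),
        np.sqrt(FOUR_LN2) / (2 * np.pi) * e,
        FOUR_LN2 / (2 * np.pi) ** 1.5 * u * e,
        FOUR_LN2**1.5 / (2 * np.pi) ** 2 * (u * u - 1) * e,
    ])


def _expected_clusters(mask, smoothness, u) -> float:
    r = resel_counts(mask, smoothness.fwhm_voxels)
    return float(max(r @ _ec_densities(u), 1e-12))


def _cluster_p(k: int, em: float, en: float, tails: int) -> float:
    """Corrected cluster p for size k voxels (expected-cluster-count form,
    D=3), Bonferroni-multiplied by the number of tails tested."""
    # beta = [Gamma(D/2 + 1) * E[clusters] / E[suprathreshold voxels]]^(2/D), D=3
    beta = ((3 * np.sqrt(np.pi) / 4) * em / en) ** (2 / 3)
    p_unc = np.exp(-beta * k ** (2 / 3))
    return float(min(tails * (1.0 - np.exp(-em * p_unc)), 1.0))


def label_clusters(binary: np.ndarray):
    """26-connected component labelling; returns (labels, n)."""
    return ndimage.label(binary, structure=CONNECTIVITY)


def grf_cluster_correct(stat: StatMap, smoothness: SmoothnessEstimate,
                        voxel_p: float = 0.001, cluster_p: float = 0.05,
                        affine: np.ndarray | None = None,
                        two_sided: bool = True):
    """Threshold a T map voxel-wise and keep clusters surviving GRF correction.

    Each tail is thresholded at ``voxel_p``; corrected cluster p-values are
    doubled under two-sided testing so the combined procedure controls the
    family-wise error at ``cluster_p``.  Returns (ClusterTable DataFrame,
    label volume); surviving clusters get labels 1..n.
    """
    if stat.kind != "T":
        raise ValueError("grf_cluster_correct expects a T map")
    if smoothness.resels <= 0:
        raise ValueError("resels must be positive")
    mask = stat.mask
    t_thr = stats.t.isf(voxel_p, stat.dof)
    u = stats.norm.isf(voxel_p)
    em = _expected_clusters(mask, smoothness, u)
    en = float(max(mask.sum() * stats.norm.sf(u), 1e-12))
    tails = 2 if two_sided else 1
    vol = stat.to_volume()
    rows, keep_vol = [], np.zeros(mask.shape, dtype=int)
    signs = (1, -1) if two_sided else (1,)
    for sign in signs:
        supra = (sign * vol > t_thr) & mask
        labels, n = label_clusters(supra)
        for cid in range(1, n + 1):
            cmask = labels == cid
            k = int(cmask.sum())
            pcorr = _cluster_p(k, em, en, tails)
            vals = vol[cmask]
            peak_flat = np.argmax(sign * vals)
            peak_ijk = np.argwhere(cmask)[peak_flat]
            row = {"size_voxels": k, "peak_stat": float(vals[peak_flat]),
                   "sign": sign, "corrected_p": pcorr,
                   "peak_i": int(peak_ijk[0]), "peak_j": int(peak_ijk[1]),
                   "peak_k": int(peak_ijk[2])}
            if affine is not None:
                mm = affine @ np.append(peak_ijk, 1.0)
                row.update(peak_x_mm=mm[0], peak_y_mm=mm[1], peak_z_mm=mm[2])
            if pcorr < cluster_p:
                row["_mask"] = cmask
                rows.append(row)
    rows.sort(key=lambda r: r["corrected_p"])
    for i, row in enumerate(rows, start=1):
        keep_vol[row.pop("_mask")] = i
        row["cluster_id"] = i
    table = pd.DataFrame(rows, columns=["cluster_id", "peak_i", "peak_j", "peak_k",
                                        "peak_x_mm", "peak_y_mm", "peak_z_mm",
                                        "size_voxels", "peak_stat", "sign",
                                        "corrected_p"]
                         if affine is not None else
                         ["cluster_id", "peak_i", "peak_j", "peak_k",
                          "size_voxels", "peak_stat", "sign", "corrected_p"])
    return table, keep_vol


def grf_critical_cluster_size(stat_mask: np.ndarray, smoothness: SmoothnessEstimate,
                              dof: float, voxel_p: float = 0.001,
                              cluster_p: float = 0.05, two_sided: bool = True) -> int:
    """Smallest cluster size (voxels) that survives GRF correction."""
    u = stats.norm.isf(voxel_p)
    em = _expected_clusters(stat_mask, smoothness, u)
    en = float(max(np.asarray(stat_mask, bool).sum() * stats.norm.sf(u), 1e-12))
    tails = 2 if two_sided else 1
    for k in range(1, int(np.asarray(stat_mask).sum()) + 1):
        if _cluster_p(k, em, en, tails) < cluster_p:
            return k
    return int(np.asarray(stat_mask).sum())


def permutation_cluster_null(y: np.ndarray, design: np.ndarray, contrast: np.ndarray,
                             mask: np.ndarray, voxel_p: float = 0.001,
                             n_perm: int = 500, seed: int = 0,
                             exchange_col: int = 1, two_sided: bool = True):
    """Max-cluster-size null by permuting the exchange column of the design
    (group relabelling) across subjects; independent oracle for the GRF
    critical cluster size.  Returns (sizes array, 95th percentile)."""
    import logging
    if n_perm < 100:
        logging.getLogger(__name__).warning("permutation null with n_perm=%d < 100", n_perm)
    rng = np.random.default_rng(seed)
    mask = np.asarray(mask, bool)
    sizes = np.zeros(n_perm)
    x = np.asarray(design, float).copy()
    for p in range(n_perm):
        xp = x.copy()
        xp[:, exchange_col] = x[rng.permutation(x.shape[0]), exchange_col]
        t, _, dof = fit_voxelwise_glm(y, xp, contrast)
        thr = stats.t.isf(voxel_p, dof)
        vol = np.zeros(mask.shape)
        vol[mask] = t
        best = 0
        tails = ((vol > thr), (-vol > thr)) if two_sided else ((vol > thr),)
        for supra in tails:
            labels, n = label_clusters(supra & mask)
            if n:
                best = max(best, int(np.bincount(labels.ravel())[1:].max()))
        sizes[p] = best
    return sizes, float(np.percentile(sizes, 95))


def extract_cluster_means(maps: list, label_volume: np.ndarray) -> pd.DataFrame:
    """Mean NH per subject/timepoint/cluster (long format).

    ``label_volume`` assigns voxels to clusters 1..n (0 = background)."""
    ids = np.unique(label_volume)
    ids = ids[ids > 0]
    if ids.size == 0:
        raise ValueError("no clusters in label volume")
    rows = []
    for m in maps:
        vol = m.to_volume()
        for cid in ids:
            sel = label_volume == cid
            vals = vol[sel]
            vals = vals[np.isfinite(vals)]
            if vals.size == 0:
                raise ValueError(f"cluster {cid} empty within map mask")
            rows.append({"subject_id": m.subject_id, "timepoint": m.timepoint,
                         "cluster_id": int(cid), "mean_nh": float(vals.mean())})
    return pd.DataFrame(rows)


def pearson_corr(x: np.ndarray, y: np.ndarray):
    """Sample Pearson r with the two-sided p from the t-transform (n-2 dof)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 3:
        raise ValueError("x and y must be equal-length vectors, n >= 3")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("non-finite values")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero-variance input")
    r = float(np.corrcoef(x, y)[0, 1])
    n = x.size
    r_ = np.clip(r, -1 + 1e-15, 1 - 1e-15)
    t = r_ * np.sqrt((n - 2) / (1 - r_**2))
    return r, float(2 * stats.t.sf(abs(t), n - 2))


def chi_square_contingency(table: np.ndarray):
    """Pearson chi-square on a contingency table (no continuity correction)."""
    table = np.asarray(table, float)
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("zero marginal in contingency table")
    res = stats.chi2_contingency(table, correction=False)
    if (res.expected_freq <= 0).any():
        raise ValueError("expected cell count of zero")
    return float(res.statistic), int(res.dof), float(res.pvalue)
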