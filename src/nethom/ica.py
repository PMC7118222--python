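"""Network-of-interest mask by group ICA and template matching.

Preprocessed runs are temporally concatenated, reduced by two-stage PCA
(per-subject in time, then across the concatenated group), and decomposed
by spatial FastICA.  The component whose |map| best matches a spatial
template (here: a network indicator, in practice the generator's ground
truth or any prior network atlas) is selected, sign-aligned and
thresholded into a boolean mask used by the NH stage.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.decomposition import PCA, FastICA

from .preprocess import BOLDRun

__all__ = ["SpatialComponent", "NetworkMask", "group_ica",
           "select_network_component", "threshold_to_mask", "dice"]

MIN_MASK_VOXELS = 30


@dataclass
class SpatialComponent:
    """One spatial ICA component: a z-scored loading map plus its group
    time course and its index in the decomposition."""

    map: np.ndarray  # 3D z-scored loadings
    timecourse: np.ndarray
    index: int


@dataclass
class NetworkMask:
    mask: np.ndarray
    source_component: int
    z_threshold: float

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.n_voxels < MIN_MASK_VOXELS:
            raise ValueError(f"network mask has {self.n_voxels} voxels "
                             f"(< {MIN_MASK_VOXELS})")


def group_ica(runs: list, n_components: int, seed: int,
              subject_dim: int = 30, group_dim: int = 20) -> list:
    """Temporal-concatenation group spatial ICA.

    Each run's time dimension is reduced to ``subject_dim`` principal
    components, the concatenated stack to ``group_dim``, and FastICA
    unmixes the reduced group matrix into spatial maps.  Maps are z-scored
    over the grid.  Deterministic for a fixed seed.
    """
    if len(runs) < 2:
        raise ValueError("group ICA needs at least 2 runs")
    dims = runs[0].data.shape[:3]
    reduced = []
    for run in runs:
        x = run.data.reshape(-1, run.n_frames).T.astype(float)  # t x V
        if np.allclose(x.std(axis=0), 0):
            raise ValueError(f"degenerate (constant) run {run.subject_id}")
        x = x - x.mean(axis=0)
        k = min(subject_dim, x.shape[0] - 1)
        reduced.append(PCA(n_components=k, random_state=seed).fit_transform(x.T).T)
    stack = np.vstack(reduced)  # (n_runs * k) x V
    g = min(group_dim, stack.shape[0] - 1)
    if not n_components < g + 1:
        raise ValueError(f"n_components={n_components} exceeds reduced dimension {g}")
    group = PCA(n_components=g, random_state=seed).fit_transform(stack.T).T  # g x V
    ica = FastICA(n_components=n_components, random_state=seed,
                  whiten="unit-variance", max_iter=1000, tol=1e-5)
    sources = ica.fit_transform(group.T)  # V x n_components
    comps = []
    for i in range(n_components):
        m = sources[:, i]
        m = (m - m.mean()) / m.std()
        comps.append(SpatialComponent(m.reshape(dims), ica.mixing_[:, i].copy(), i))
    return comps


def select_network_component(components: list, template: np.ndarray):
    """Pick the component whose |map| correlates best with the template
    indicator; returns (index, score)."""
    if not components:
        raise ValueError("empty component list")
    template = np.asarray(template, dtype=float).ravel()
    if template.std() == 0:
        raise ValueError("degenerate (constant) template")
    scores = []
    for c in components:
        m = np.abs(c.map).ravel()
        scores.append(np.corrcoef(m, template)[0, 1] if m.std() > 0 else -np.inf)
    best = int(np.argmax(scores))
    return best, float(scores[best])


def threshold_to_mask(component: SpatialComponent, z_threshold: float = 1.96,
                      template: np.ndarray | None = None) -> NetworkMask:
    """Binarize the positively-loading side of a component at |z| >= threshold.

    ICA signs are arbitrary: the map is flipped so that its correlation
    with the template (when given), else its suprathreshold mass, is
    positive before taking the positive tail.
    """
    m = component.map
    if template is not None:
        flip = np.corrcoef(m.ravel(), np.asarray(template, float).ravel())[0, 1] < 0
    else:
        flip = np.sum(m[m >= z_threshold]) < -np.sum(m[m <= -z_threshold])
    if flip:
        m = -m
    mask = m >= z_threshold
    return NetworkMask(mask, component.index, z_threshold)


def dice(a: np.ndarray, b: np.ndarray) -> float:
    """Dice overlap of two boolean masks."""
    a, b = np.asarray(a, bool), np.asarray(b, bool)
    denom = a.sum() + b.sum()
    return 2.0 * np.logical_and(a, b).sum() / denom if denom else 0.0
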