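"""Seeded synthetic resting-state cohorts with known network structure.

The generator emulates the data layout of a two-arm longitudinal treatment
study: ~20 subjects per group (healthy controls scanned at baseline only;
patients in a drug-plus-psychotherapy [DPP] arm and a drug-therapy-only
[DT] arm scanned at baseline and week 8), 240-volume runs at TR = 2 s on a
common 3 mm voxel grid.

Signal model, per run:

* a shared network signal ``g(t)`` (unit-variance white noise) loads onto
  every in-network voxel with a loading in [0, 1];
* planted clusters override the loading per group/arm/timepoint, so that a
  lower loading yields a lower expected network homogeneity (NH) there —
  this is how group deficits and a treatment-arm restoration are planted;
* every voxel adds an independent local AR(1) fluctuation and AR(1) noise,
  a small linear drift, and a weak contribution from generator-provided
  white-matter/CSF nuisance series;
* out-of-network voxels carry no shared signal.

Clinical scores: patients receive PANSS subscale scores at baseline
(totals > 75, the inclusion rule) and at week 8; the week-8 scores are
back-computed from planted reduction ratios (RR) that are linearly coupled
to the subject's realized baseline NH in one planted region, so that
prediction of treatment response from baseline NH is testable against a
known coupling strength.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .preprocess import BOLDRun, MotionSeries

__all__ = [
    "SimConfig",
    "PlantedEffect",
    "ClinicalCoupling",
    "GroundTruth",
    "default_config",
    "generate_cohort",
    "generate_run",
    "generate_motion",
    "generate_clinical",
    "subject_table",
]

GROUPS = ("control", "patient_dpp", "patient_dt")

#: baseline PANSS subscale (mean, sd) used for patient score generation
PANSS_BASELINE = {"positive": (24.0, 4.5), "negative": (27.3, 5.3), "general": (52.8, 5.1)}

#: cognitive battery (mean, sd) at baseline and mean gain at week 8
COGNITIVE_TESTS = {
    "TMT-A": (52.0, 20.0, -19.0), "BACS-SC": (38.0, 9.0, 9.0),
    "HVLT-R": (16.4, 4.0, 6.0), "BVMT-R": (17.7, 6.6, 9.3),
    "CPT-IP": (1.08, 0.7, 0.8), "WMS-SS": (11.6, 2.4, 4.1),
    "NAB-M": (9.0, 5.2, 7.0), "MSCEIT": (77.9, 9.1, 11.8),
    "CF-ANF": (13.4, 3.3, 5.2),
}


@dataclass
class PlantedEffect:
    """A cluster of in-network voxels whose shared-signal loading differs by
    group/arm/timepoint.  Lower loading => lower expected NH (monotone)."""

    cluster_voxels: np.ndarray  # (k, 3) int grid coordinates
    baseline_loading_patient: float
    baseline_loading_control: float
    followup_loading_dpp: float
    followup_loading_dt: float

    def __post_init__(self) -> None:
        self.cluster_voxels = np.atleast_2d(np.asarray(self.cluster_voxels, dtype=int))
        for name in ("baseline_loading_patient", "baseline_loading_control",
                     "followup_loading_dpp", "followup_loading_dt"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")

    def loading(self, group: str, timepoint: str) -> float:
        if group == "control":
            return self.baseline_loading_control
        if timepoint == "baseline":
            return self.baseline_loading_patient
        return self.followup_loading_dpp if group == "patient_dpp" else self.followup_loading_dt


@dataclass
class ClinicalCoupling:
    """Linear coupling RR = intercept + slope * z(baseline region NH) + noise.

    With ``standardize=True`` (default) the slope applies to the z-scored
    region NH across patients, so the planted population correlation is
    slope / sqrt(slope^2 + noise_sd^2) regardless of the NH scale; the
    defaults plant r = 0.9.  Generated RR values are clamped to [0, 1].
    """

    slope: float = 0.1
    intercept: float = 0.55
    noise_sd: float = 0.1 * np.sqrt(1 / 0.81 - 1)  # => population r = 0.9
    coupled_region_index: int = 1
    standardize: bool = True

    @property
    def population_r(self) -> float:
        denom = np.hypot(self.slope, self.noise_sd)
        return 0.0 if denom == 0 else float(self.slope / denom)


@dataclass
class SimConfig:
    seed: int = 0
    grid_dims: tuple = (20, 24, 20)
    voxel_size_mm: float = 3.0
    n_timepoints: int = 240
    tr_s: float = 2.0
    n_per_group: dict = field(default_factory=lambda: {g: 20 for g in GROUPS})
    network_fraction: float = 0.10
    planted_clusters: list = None
    ar1_coef: float = 0.3
    noise_sd: float = 1.0
    local_signal_sd: float = 0.2
    background_loading: float = 0.7
    nuisance_weight: float = 0.1
    drift_sd: float = 0.5
    motion_walk_step_mm: float = 0.02
    motion_walk_step_rad: float = 4e-4
    motion_spike_prob: float = 0.02
    motion_spike_amp_mm: tuple = (0.3, 0.6)
    clinical_coupling: ClinicalCoupling = field(default_factory=ClinicalCoupling)

    def __post_init__(self) -> None:
        dims = tuple(int(d) for d in self.grid_dims)
        if any(d <= 0 for d in dims):
            raise ValueError(f"grid dims must be positive, got {dims}")
        self.grid_dims = dims
        if int(np.prod(dims)) < 500:
            raise ValueError("grid volume must be >= 500 voxels")
        if self.n_timepoints < 50:
            raise ValueError("n_timepoints must be >= 50")
        if not 0 < self.network_fraction < 1:
            raise ValueError("network_fraction must be in (0, 1)")
        if not 0 <= self.ar1_coef < 1:
            raise ValueError("ar1_coef must be in [0, 1)")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if not 0 <= self.motion_spike_prob <= 1:
            raise ValueError("motion_spike_prob must be in [0, 1]")
        if any(int(n) <= 0 for n in self.n_per_group.values()):
            raise ValueError("group sizes must be positive")
        if self.planted_clusters is None:
            self.planted_clusters = _default_planted_clusters(self.grid_dims)
        mask = network_mask_for(self)
        for eff in self.planted_clusters:
            vox = eff.cluster_voxels
            if np.any(vox < 0) or np.any(vox >= np.array(self.grid_dims)):
                raise ValueError("planted cluster outside grid")
            if not mask[tuple(vox.T)].all():
                raise ValueError("planted cluster must lie inside the true network")

    @property
    def affine(self) -> np.ndarray:
        aff = np.diag([self.voxel_size_mm] * 3 + [1.0])
        aff[:3, 3] = -np.array(self.grid_dims) / 2.0 * self.voxel_size_mm
        return aff

    @property
    def subjects(self) -> list:
        """Stable (subject_id, group) ordering: controls, DPP, DT."""
        out = []
        tags = {"control": "con", "patient_dpp": "dpp", "patient_dt": "dt"}
        for g in GROUPS:
            out += [(f"{tags[g]}{i + 1:02d}", g) for i in range(int(self.n_per_group[g]))]
        return out


@dataclass
class GroundTruth:
    true_network_mask: np.ndarray
    planted_cluster_masks: list
    per_subject_loadings: pd.DataFrame
    true_rr: pd.Series | None = None


# --- network geometry ------------------------------------------------------

_SPHERE_CENTRES = [(0.50, 0.78, 0.42), (0.50, 0.22, 0.45),
                   (0.28, 0.30, 0.72), (0.72, 0.62, 0.70)]


def _sphere(dims, centre_frac, radius) -> np.ndarray:
    grids = np.indices(dims)
    c = [f * (d - 1) for f, d in zip(centre_frac, dims)]
    d2 = sum((g - ci) ** 2 for g, ci in zip(grids, c))
    return d2 <= radius**2


def network_mask_for(config: SimConfig) -> np.ndarray:
    """True in-network indicator: union of spheres sized to hit the target
    fraction of grid voxels (approximately; the geometry is deterministic)."""
    dims = config.grid_dims
    target = config.network_fraction * np.prod(dims)
    radius = (target / len(_SPHERE_CENTRES) / (4 / 3 * np.pi)) ** (1 / 3)
    mask = np.zeros(dims, dtype=bool)
    for c in _SPHERE_CENTRES:
        mask |= _sphere(dims, c, radius)
    return mask


def _default_planted_clusters(dims) -> list:
    """Two ~30-voxel clusters: a posterior-midline-like deficit that the DPP
    arm recovers at week 8, and an anterior-midline-like NH excess that is
    stable over time and carries the clinical coupling."""
    def ball(centre, radius=1.95):
        return np.argwhere(_sphere(dims, centre, radius))
    deficit = PlantedEffect(ball(_SPHERE_CENTRES[1]), 0.3, 0.9, 0.9, 0.3)
    excess = PlantedEffect(ball(_SPHERE_CENTRES[0]), 1.0, 0.6, 1.0, 1.0)
    return [deficit, excess]


def ground_truth_for(config: SimConfig) -> GroundTruth:
    mask = network_mask_for(config)
    cluster_masks = []
    for eff in config.planted_clusters:
        m = np.zeros(config.grid_dims, dtype=bool)
        m[tuple(eff.cluster_voxels.T)] = True
        cluster_masks.append(m)
    rows = []
    for sid, group in config.subjects:
        tps = ("baseline",) if group == "control" else ("baseline", "week8")
        for tp in tps:
            row = {"subject_id": sid, "group": group, "timepoint": tp}
            for j, eff in enumerate(config.planted_clusters):
                row[f"loading_cluster{j}"] = eff.loading(group, tp)
            rows.append(row)
    return GroundTruth(mask, cluster_masks, pd.DataFrame(rows))


# --- time-series generation ------------------------------------------------

def _ar1(rng, shape, coef, sd):
    """AR(1) noise with the stated marginal standard deviation."""
    innov_sd = sd * np.sqrt(1 - coef**2)
    white = rng.standard_normal(shape) * innov_sd
    if coef == 0:
        return white
    return lfilter([1.0], [1.0, -coef], white, axis=-1)


def _subject_index(config: SimConfig, subject_id: str) -> int:
    for i, (sid, _) in enumerate(config.subjects):
        if sid == subject_id:
            return i
    raise KeyError(subject_id)


def _voxel_block(rng, loadings, g, wm, csf, config):
    """Voxel time series for one block of voxels with the given loadings.

    The local AR(1) fluctuation and the AR(1) noise share the coefficient,
    so their sum is drawn as a single AR(1) process with the combined
    variance; the per-voxel linear drift comes from the same stream.
    """
    n = loadings.size
    t = config.n_timepoints
    data = _ar1(rng, (n, t), config.ar1_coef,
                float(np.hypot(config.noise_sd, config.local_signal_sd)))
    data += loadings[:, None] * g
    data += config.nuisance_weight * (wm + csf)
    tt = np.linspace(-0.5, 0.5, t)
    data += rng.normal(0, config.drift_sd, n)[:, None] * tt
    return data


def _run_streams(config: SimConfig, subject_id: str, timepoint: str):
    idx = _subject_index(config, subject_id)
    group = dict(config.subjects)[subject_id]
    if group == "control" and timepoint != "baseline":
        raise ValueError("controls are scanned at baseline only")
    tp_code = {"baseline": 0, "week8": 1}[timepoint]
    key = [int(config.seed), 1, idx, tp_code]
    return group, (np.random.default_rng(key + [0]),   # shared signals
                   np.random.default_rng(key + [1]),   # in-network voxels
                   np.random.default_rng(key + [2]))   # out-of-network voxels


def generate_run(config: SimConfig, subject_id: str, timepoint: str,
                 scope: str = "full") -> BOLDRun:
    """Deterministically generate one subject/timepoint run (float32).

    ``scope='full'`` returns the 4D grid; ``scope='network'`` returns only
    the in-network voxel series as an (N, 1, 1, t) run (N = network voxels
    in C order of the mask), bit-identical to the network part of the full
    run — shared signals, in-network noise and out-of-network noise come
    from separate substreams, so skipping the out-of-network draw does not
    perturb the rest.
    """
    group, (rng_common, rng_net, rng_out) = _run_streams(config, subject_id, timepoint)
    dims, t = config.grid_dims, config.n_timepoints
    net = network_mask_for(config)
    loadings = np.where(net, config.background_loading, 0.0)
    for eff in config.planted_clusters:
        loadings[tuple(eff.cluster_voxels.T)] = eff.loading(group, timepoint)

    g = rng_common.standard_normal(t)  # shared network signal, unit variance
    wm = _ar1(rng_common, t, config.ar1_coef, 1.0)
    csf = _ar1(rng_common, t, config.ar1_coef, 1.0)

    net_data = _voxel_block(rng_net, loadings[net], g, wm, csf, config)
    if scope == "network":
        data = net_data[:, None, None, :]
    elif scope == "full":
        flat = np.empty((int(np.prod(dims)), t))
        nf = net.ravel()
        flat[nf] = net_data
        flat[~nf] = _voxel_block(rng_out, np.zeros(int((~nf).sum())),
                                 g, wm, csf, config)
        data = flat.reshape(dims + (t,))
    else:
        raise ValueError("scope must be 'full' or 'network'")
    return BOLDRun(data.astype(np.float32), config.tr_s,
                   subject_id, timepoint, config.affine,
                   nuisance={"wm": wm, "csf": csf})


def generate_motion(config: SimConfig, seed_offset: int) -> MotionSeries:
    """Bounded random-walk motion with occasional displacement spikes.

    Spikes are single-frame pulses of 0.3-0.6 mm (alternating sign) on one
    translation axis, guaranteeing FD > 0.2 mm at the spiked frame.
    """
    t = config.n_timepoints
    if t < 2:
        raise ValueError("need at least 2 frames")
    rng = np.random.default_rng([int(config.seed), 2, int(seed_offset)])
    steps = np.hstack([
        rng.normal(0, config.motion_walk_step_mm, (t, 3)),
        rng.normal(0, config.motion_walk_step_rad, (t, 3)),
    ])
    steps[0] = 0.0
    params = np.cumsum(steps, axis=0)
    params[:, :3] = np.clip(params[:, :3], -1.0, 1.0)
    params[:, 3:] = np.clip(params[:, 3:], -0.01, 0.01)

    spiked = rng.random(t) < config.motion_spike_prob
    spiked[0] = False
    lo, hi = config.motion_spike_amp_mm
    amps = rng.uniform(lo, hi, t)
    axes = rng.integers(0, 3, t)
    sign = 1.0
    for f in np.flatnonzero(spiked):
        params[f, axes[f]] += sign * amps[f]
        sign = -sign
    return MotionSeries(params)


def subject_table(config: SimConfig) -> pd.DataFrame:
    """Demographics, baseline PANSS (patients; totals forced > 75) and
    cognitive battery scores at both timepoints."""
    rng = np.random.default_rng([int(config.seed), 3])
    rows = []
    for sid, group in config.subjects:
        patient = group != "control"
        row = {
            "subject_id": sid, "group": "patient" if patient else "control",
            "arm": {"patient_dpp": "DPP", "patient_dt": "DT"}.get(group, "none"),
            "age": float(np.clip(rng.normal(24.5, 5.0), 18, 50)),
            "sex": "male" if rng.random() < 0.66 else "female",
        }
        if patient:
            while True:
                subs = {k: float(max(rng.normal(m, s), 1.0))
                        for k, (m, s) in PANSS_BASELINE.items()}
                if sum(subs.values()) > 75:
                    break
            for k, v in subs.items():
                row[f"panss_{k}_1"] = v
            row["panss_total_1"] = sum(subs.values())
        for test, (m, s, gain) in COGNITIVE_TESTS.items():
            base = float(rng.normal(m, s))
            row[f"{test}_1"] = base
            row[f"{test}_2"] = base + float(rng.normal(gain, abs(gain) * 0.4 + 0.1))
        rows.append(row)
    return pd.DataFrame(rows)


def generate_clinical(subjects: pd.DataFrame, baseline_region_nh: pd.Series,
                      coupling: ClinicalCoupling, seed: int) -> pd.DataFrame:
    """Plant reduction ratios coupled to baseline NH and back-compute week-8
    PANSS scores, then re-derive the stored RR columns from the scores.

    ``baseline_region_nh`` maps patient subject_id -> mean baseline NH of the
    coupled planted region.  Each subscale RR is drawn around the planted
    value; week-8 subscale scores are baseline * (1 - RR), the week-8 total
    is their sum, and the rr_* columns come from the RR formula applied to
    the stored scores (so they stay internally consistent).
    """
    out = subjects.copy()
    patients = out[out["group"] == "patient"]["subject_id"]
    missing = [s for s in patients if s not in baseline_region_nh.index]
    if missing:
        raise ValueError(f"missing baseline NH for {missing}")
    rng = np.random.default_rng([int(seed), 4])
    x = baseline_region_nh.loc[patients].to_numpy(dtype=float)
    if coupling.standardize:
        sd = x.std()
        x = (x - x.mean()) / sd if sd > 0 else np.zeros_like(x)
    rr = coupling.intercept + coupling.slope * x
    rr = rr + rng.normal(0, coupling.noise_sd, rr.shape)
    rr = np.clip(rr, 0.0, 1.0)
    sub_jitter = min(0.03, float(coupling.noise_sd))  # noiseless coupling stays exact
    for sid, rr_i in zip(patients, rr):
        sel = out["subject_id"] == sid
        bases, weeks = [], []
        for sub in PANSS_BASELINE:
            rr_sub = float(np.clip(rr_i + rng.normal(0, sub_jitter), 0.0, 1.0))
            bases.append(float(out.loc[sel, f"panss_{sub}_1"].iloc[0]))
            weeks.append(bases[-1] * (1 - rr_sub))
        # rescale the subscales so the total reduction equals the planted RR
        # exactly (the subscale ratios keep their scatter around it)
        target_total2 = sum(bases) * (1 - rr_i)
        scale = target_total2 / sum(weeks) if sum(weeks) > 0 else 0.0
        for sub, wk in zip(PANSS_BASELINE, weeks):
            out.loc[sel, f"panss_{sub}_2"] = wk * scale
        out.loc[sel, "panss_total_2"] = target_total2
    from .ml import reduction_ratio
    for sub in list(PANSS_BASELINE) + ["total"]:
        b, w = out.get(f"panss_{sub}_1"), out.get(f"panss_{sub}_2")
        out[f"rr_{sub}"] = [
            reduction_ratio(bi, wi) if np.isfinite(bi) and np.isfinite(wi) else np.nan
            for bi, wi in zip(b, w)]
    return out


def generate_cohort(config: SimConfig):
    """Generate the full cohort: one run per subject per timepoint (controls at
    baseline only), per-run motion, the subject table and the ground truth.

    Identical configs (same seed) produce bit-identical output.  For large
    cohorts prefer streaming :func:`generate_run` per subject to bound memory.
    """
    truth = ground_truth_for(config)
    runs, motions = [], []
    offset = itertools.count()
    for sid, group in config.subjects:
        tps = ("baseline",) if group == "control" else ("baseline", "week8")
        for tp in tps:
            runs.append(generate_run(config, sid, tp))
            motions.append(generate_motion(config, next(offset)))
    return runs, motions, subject_table(config), truth


def default_config(seed: int = 0, **overrides) -> SimConfig:
    """The study-condition defaults; keyword overrides for desk-scale tests."""
    return SimConfig(seed=seed, **overrides)
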