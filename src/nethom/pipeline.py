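"""Stage orchestration: simulate -> preprocess -> mask -> nh -> infer -> ml -> report.

Each stage reads its predecessor's files from the output directory and
writes its own, recording input/output SHA-256 checksums in a run manifest
(``manifest.json``).  Re-running with an unchanged config skips stages
whose recorded inputs and outputs still verify; corrupting an intermediate
file invalidates exactly the stages downstream of it.

All study constants (10 dropped volumes, 0.01-0.08 Hz band, FD > 0.2 mm
scrubbing, 2 mm / 2 degree exclusion, voxel p < 0.001, cluster p < 0.05,
alpha/16 Bonferroni) are named config fields, never literals in stage code.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import homogeneity, ica, inference, ml, preprocess, simulate
from .io import (load_motion_tsv, load_nifti, save_json, save_motion_tsv,
                 save_nifti, sha256_file)

log = logging.getLogger("nethom.pipeline")

STAGES = ["simulate", "preprocess", "mask", "nh", "infer", "ml", "report"]


@dataclass
class PipelineConfig:
    """Single config for all stages; ``sim`` holds SimConfig overrides."""

    seed: int = 0
    sim: dict = field(default_factory=dict)
    n_drop: int = 10
    low_hz: float = 0.01
    high_hz: float = 0.08
    fd_threshold_mm: float = 0.2
    max_trans_mm: float = 2.0
    max_rot_deg: float = 2.0
    n_ica_components: int = 5
    ica_z_threshold: float = 1.96
    standardize_nh: bool = True
    voxel_p: float = 0.001
    cluster_p: float = 0.05
    svm_grid_step: int = 4
    svm_mode: str = "nested"
    alpha: float = 0.05
    bonferroni_m: int = 16

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        raw = json.loads(Path(path).read_text())
        known = {f.name for f in dataclasses.fields(cls)}
        bad = set(raw) - known
        if bad:
            raise ValueError(f"unknown config keys: {sorted(bad)}")
        return cls(**raw)

    def sim_config(self) -> simulate.SimConfig:
        return simulate.SimConfig(seed=self.seed, **self.sim)

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def demo_config(seed: int = 0) -> PipelineConfig:
    """Desk-scale demo: small grid / cohort so run-all finishes in seconds."""
    return PipelineConfig(seed=seed, svm_grid_step=8, sim={
        "grid_dims": (14, 16, 14), "n_timepoints": 120,
        "n_per_group": {"control": 10, "patient_dpp": 10, "patient_dt": 10},
        "network_fraction": 0.14,
    })


class Manifest:
    """Checksummed stage registry enabling skip/rerun decisions."""

    def __init__(self, outdir: Path, config: PipelineConfig):
        self.path = Path(outdir) / "manifest.json"
        self.outdir = Path(outdir)
        fresh = {"config_hash": config.config_hash(), "version": __version__,
                 "seed": config.seed, "stages": {}}
        if self.path.exists():
            old = json.loads(self.path.read_text())
            if old.get("config_hash") == fresh["config_hash"]:
                fresh["stages"] = old.get("stages", {})
        self.data = fresh

    def _verify(self, record: dict) -> bool:
        for path, digest in {**record.get("inputs", {}),
                             **record.get("outputs", {})}.items():
            p = self.outdir / path
            if not p.exists() or sha256_file(p) != digest:
                return False
        return True

    def _rel(self, p) -> str:
        p = Path(p)
        return str(p.relative_to(self.outdir)) if p.is_absolute() else str(p)

    def up_to_date(self, stage: str, inputs: list) -> bool:
        rec = self.data["stages"].get(stage)
        if rec is None:
            return False
        if set(rec.get("inputs", {})) != {self._rel(p) for p in inputs}:
            return False
        return self._verify(rec)

    def record(self, stage: str, inputs: list, outputs: list) -> None:
        self.data["stages"][stage] = {
            "inputs": {self._rel(p): sha256_file(self.outdir / self._rel(p))
                       for p in inputs},
            "outputs": {self._rel(p): sha256_file(self.outdir / self._rel(p))
                        for p in outputs},
        }
        save_json(self.data, self.path)


def _run_paths(outdir: Path, cfg: simulate.SimConfig):
    out = []
    for sid, group in cfg.subjects:
        tps = ("baseline",) if group == "control" else ("baseline", "week8")
        for tp in tps:
            out.append((sid, group, tp,
                        outdir / "runs" / f"{sid}_{tp}.nii.gz",
                        outdir / "motion" / f"{sid}_{tp}.tsv"))
    return out


def run_pipeline(config: PipelineConfig, outdir, stages=None,
                 force: bool = False) -> dict:
    """Execute the requested stages (default: all) and return the manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = Manifest(outdir, config)
    scfg = config.sim_config()
    for stage in stages or STAGES:
        if stage not in STAGES:
            raise ValueError(f"unknown stage {stage}")
        fn = globals()[f"_stage_{stage}"]
        fn(config, scfg, outdir, manifest, force)
    return manifest.data


def _execute(manifest, stage, inputs, force, builder):
    if not force and manifest.up_to_date(stage, inputs):
        log.info("stage %s up to date; skipped", stage)
        return
    log.info("stage %s: running", stage)
    outputs = builder()
    manifest.record(stage, inputs, outputs)


def _stage_simulate(config, scfg, outdir, manifest, force):
    def build():
        truth = simulate.ground_truth_for(scfg)
        outputs = [save_nifti(truth.true_network_mask.astype(np.float32),
                              scfg.affine, outdir / "truth_network.nii.gz")]
        for j, m in enumerate(truth.planted_cluster_masks):
            outputs.append(save_nifti(m.astype(np.float32), scfg.affine,
                                      outdir / f"truth_cluster{j}.nii.gz"))
        offset = 0
        for sid, group, tp, rpath, mpath in _run_paths(outdir, scfg):
            run = simulate.generate_run(scfg, sid, tp)
            motion = simulate.generate_motion(scfg, offset)
            offset += 1
            outputs += [save_nifti(run.data, run.affine, rpath),
                        save_motion_tsv(motion.params, mpath)]
            nuis = pd.DataFrame(run.nuisance)
            nuis.to_csv(outdir / "motion" / f"{sid}_{tp}_nuisance.tsv",
                        sep="\t", index=False)
            outputs.append(outdir / "motion" / f"{sid}_{tp}_nuisance.tsv")
        subjects = simulate.subject_table(scfg)
        subjects.to_csv(outdir / "subjects.csv", index=False)
        save_json({"seed": scfg.seed, "grid_dims": scfg.grid_dims,
                   "n_timepoints": scfg.n_timepoints, "tr_s": scfg.tr_s},
                  outdir / "sim_config.json")
        return outputs + [outdir / "subjects.csv", outdir / "sim_config.json"]
    _execute(manifest, "simulate", [], force, build)


def _stage_preprocess(config, scfg, outdir, manifest, force):
    paths = _run_paths(outdir, scfg)
    inputs = [p for _, _, _, r, m in paths for p in (r, m)]

    def build():
        outputs, qc = [], {"excluded": [], "mean_fd": {}, "kept_frames": {}}
        for sid, group, tp, rpath, mpath in paths:
            data, affine = load_nifti(rpath)
            nuis = pd.read_csv(outdir / "motion" / f"{sid}_{tp}_nuisance.tsv", sep="\t")
            run = preprocess.BOLDRun(np.asarray(data, float), scfg.tr_s, sid, tp, affine,
                                     nuisance={k: nuis[k].to_numpy() for k in nuis})
            motion = preprocess.MotionSeries(load_motion_tsv(mpath))
            if preprocess.exclude_by_motion(motion, config.max_trans_mm,
                                            config.max_rot_deg):
                if sid not in qc["excluded"]:
                    qc["excluded"].append(sid)
                continue
            run, motion, kept = preprocess.preprocess_run(
                run, motion, config.n_drop, config.low_hz, config.high_hz,
                config.fd_threshold_mm)
            key = f"{sid}_{tp}"
            qc["mean_fd"][key] = motion.mean_fd
            qc["kept_frames"][key] = int(kept.sum())
            outputs.append(save_nifti(run.data, run.affine,
                                      outdir / "preproc" / f"{key}.nii.gz"))
        outputs.append(save_json(qc, outdir / "qc.json"))
        return outputs
    _execute(manifest, "preprocess", inputs, force, build)


def _load_preproc(config, scfg, outdir):
    qc = json.loads((outdir / "qc.json").read_text())
    runs = {}
    for sid, group, tp, *_ in _run_paths(outdir, scfg):
        key = f"{sid}_{tp}"
        p = outdir / "preproc" / f"{key}.nii.gz"
        if not p.exists():
            continue
        data, affine = load_nifti(p)
        runs[key] = (preprocess.BOLDRun(np.asarray(data, float), scfg.tr_s,
                                        sid, tp, affine), group)
    return runs, qc


def _stage_mask(config, scfg, outdir, manifest, force):
    inputs = sorted((outdir / "preproc").glob("*.nii.gz")) + [outdir / "qc.json"]

    def build():
        runs, _ = _load_preproc(config, scfg, outdir)
        baseline = [r for (r, g) in runs.values() if r.timepoint == "baseline"]
        comps = ica.group_ica(baseline, config.n_ica_components, seed=config.seed)
        template, _ = load_nifti(outdir / "truth_network.nii.gz")
        idx, score = ica.select_network_component(comps, template > 0.5)
        mask = ica.threshold_to_mask(comps[idx], config.ica_z_threshold,
                                     template=template > 0.5)
        outputs = [save_nifti(mask.mask.astype(np.float32), scfg.affine,
                              outdir / "network_mask.nii.gz")]
        for c in comps:
            outputs.append(save_nifti(c.map, scfg.affine,
                                      outdir / f"component{c.index}.nii.gz"))
        n_cc = int(inference.label_clusters(mask.mask)[1])
        outputs.append(save_json(
            {"selected": idx, "score": score, "n_voxels": mask.n_voxels,
             "connected_components": n_cc,
             "dice_truth": ica.dice(mask.mask, template > 0.5)},
            outdir / "mask_selection.json"))
        return outputs
    _execute(manifest, "mask", inputs, force, build)


def _stage_nh(config, scfg, outdir, manifest, force):
    inputs = sorted((outdir / "preproc").glob("*.nii.gz")) + \
        [outdir / "network_mask.nii.gz", outdir / "subjects.csv", outdir / "qc.json"]

    def build():
        runs, _ = _load_preproc(config, scfg, outdir)
        maskvol, _ = load_nifti(outdir / "network_mask.nii.gz")
        mask = maskvol > 0.5
        outputs, rows = [], []
        region_nh = {}
        coupled, _ = load_nifti(
            outdir / f"truth_cluster{scfg.clinical_coupling.coupled_region_index}.nii.gz")
        coupled = (coupled > 0.5) & mask
        for key, (run, group) in runs.items():
            nh = homogeneity.compute_nh(run, mask)
            outputs.append(save_nifti(nh.to_volume(), run.affine,
                                      outdir / "nh" / f"{key}_raw.nii.gz"))
            std = homogeneity.standardize_map(nh) if config.standardize_nh else nh
            outputs.append(save_nifti(std.to_volume(), run.affine,
                                      outdir / "nh" / f"{key}.nii.gz"))
            if run.timepoint == "baseline" and coupled.any():
                region_nh[run.subject_id] = float(nh.to_volume()[coupled].mean())
            for vi, v in enumerate(std.values):
                rows.append((run.subject_id, run.timepoint, vi, v))
        pd.DataFrame(rows, columns=["subject_id", "timepoint", "voxel", "nh"]).to_csv(
            outdir / "nh_long.csv", index=False)
        subjects = pd.read_csv(outdir / "subjects.csv")
        present = subjects["subject_id"].isin(
            {r.subject_id for r, _ in runs.values()})
        clinical = simulate.generate_clinical(
            subjects[present].reset_index(drop=True),
            pd.Series(region_nh), scfg.clinical_coupling, scfg.seed)
        clinical.to_csv(outdir / "subjects_clinical.csv", index=False)
        return outputs + [outdir / "nh_long.csv", outdir / "subjects_clinical.csv"]
    _execute(manifest, "nh", inputs, force, build)


def _nh_frame(config, scfg, outdir):
    """NH maps + per-run covariates, keyed by (subject, timepoint)."""
    qc = json.loads((outdir / "qc.json").read_text())
    maskvol, _ = load_nifti(outdir / "network_mask.nii.gz")
    mask = maskvol > 0.5
    clinical = pd.read_csv(outdir / "subjects_clinical.csv").set_index("subject_id")
    maps = {}
    for p in sorted((outdir / "nh").glob("*.nii.gz")):
        if p.name.endswith("_raw.nii.gz"):
            continue
        sid, tp = p.name[:-len(".nii.gz")].rsplit("_", 1)
        vol, affine = load_nifti(p)
        maps[(sid, tp)] = homogeneity.NHMap(vol[mask], mask, sid, tp, affine,
                                            standardized=config.standardize_nh)
    meta = []
    for (sid, tp) in maps:
        meta.append({"subject_id": sid, "timepoint": tp,
                     "group": clinical.loc[sid, "group"],
                     "arm": clinical.loc[sid, "arm"],
                     "age": clinical.loc[sid, "age"],
                     "mean_fd": qc["mean_fd"][f"{sid}_{tp}"]})
    return maps, pd.DataFrame(meta), mask, clinical.reset_index()


CONTRASTS = ["dpp_baseline_vs_control", "dt_baseline_vs_control",
             "dpp_week8_vs_baseline", "dt_week8_vs_baseline",
             "interaction_arm_time", "dpp_vs_dt_week8"]


def _stage_infer(config, scfg, outdir, manifest, force):
    inputs = sorted((outdir / "nh").glob("*.nii.gz")) + \
        [outdir / "network_mask.nii.gz", outdir / "subjects_clinical.csv",
         outdir / "qc.json"]

    def build():
        maps, meta, mask, clinical = _nh_frame(config, scfg, outdir)
        affine = next(iter(maps.values())).affine
        outputs, report = [], {}
        features = []

        def run_contrast(name, frame, y, factor):
            x, c, levels = inference.make_design(frame, factor)
            t, resid, dof = inference.fit_voxelwise_glm(y, x, c)
            sm = inference.estimate_smoothness(resid, mask, scfg.voxel_size_mm)
            stat = inference.StatMap(t, mask, "T", dof)
            table, labels = inference.grf_cluster_correct(
                stat, sm, config.voxel_p, config.cluster_p, affine)
            table.to_csv(outdir / f"clusters_{name}.csv", index=False)
            outputs.append(outdir / f"clusters_{name}.csv")
            outputs.append(save_nifti(labels.astype(np.float32), affine,
                                      outdir / f"clusters_{name}.nii.gz"))
            report[name] = {"dof": dof, "fwhm_mm": sm.fwhm_mm,
                            "resels": sm.resels, "levels": levels,
                            "n_clusters": int(len(table))}
            return table, labels

        for arm in ("DPP", "DT"):
            sel = meta[(meta.timepoint == "baseline")
                       & ((meta.group == "control") | (meta.arm == arm))].copy()
            sel["is_patient"] = (sel.group == "patient").astype(int)
            y = np.vstack([maps[(r.subject_id, "baseline")].values
                           for r in sel.itertuples()])
            table, labels = run_contrast(f"{arm.lower()}_baseline_vs_control",
                                         sel, y, "is_patient")
            if len(table):
                all_baseline = meta[meta.timepoint == "baseline"]
                nh_maps = [maps[(r.subject_id, "baseline")]
                           for r in all_baseline.itertuples()]
                feats = inference.extract_cluster_means(nh_maps, labels)
                feats["contrast"] = f"{arm.lower()}_baseline_vs_control"
                features.append(feats)

        # within-arm week8 vs baseline and arm x time interaction on diff maps
        diff_frames = {}
        for arm in ("DPP", "DT"):
            sel = meta[(meta.arm == arm) & (meta.timepoint == "baseline")].copy()
            sel = sel[[(s, "week8") in maps for s in sel.subject_id]]
            diff = np.vstack([maps[(r.subject_id, "week8")].values
                              - maps[(r.subject_id, "baseline")].values
                              for r in sel.itertuples()])
            diff_frames[arm] = (sel, diff)
            sel = sel.assign(dummy=0)
            x = np.column_stack([np.ones(len(sel)),
                                 sel.age - sel.age.mean(),
                                 sel.mean_fd - sel.mean_fd.mean()])
            c = np.array([1.0, 0.0, 0.0])
            t, resid, dof = inference.fit_voxelwise_glm(diff, x, c)
            sm = inference.estimate_smoothness(resid, mask, scfg.voxel_size_mm)
            table, labels = inference.grf_cluster_correct(
                inference.StatMap(t, mask, "T", dof), sm,
                config.voxel_p, config.cluster_p, affine)
            name = f"{arm.lower()}_week8_vs_baseline"
            table.to_csv(outdir / f"clusters_{name}.csv", index=False)
            outputs += [outdir / f"clusters_{name}.csv",
                        save_nifti(labels.astype(np.float32), affine,
                                   outdir / f"clusters_{name}.nii.gz")]
            report[name] = {"dof": dof, "fwhm_mm": sm.fwhm_mm, "resels": sm.resels,
                            "n_clusters": int(len(table))}

        inter = pd.concat([diff_frames["DPP"][0], diff_frames["DT"][0]])
        ydiff = np.vstack([diff_frames["DPP"][1], diff_frames["DT"][1]])
        run_contrast("interaction_arm_time", inter, ydiff, "arm")

        wk = meta[(meta.timepoint == "week8")].copy()
        ywk = np.vstack([maps[(r.subject_id, "week8")].values for r in wk.itertuples()])
        run_contrast("dpp_vs_dt_week8", wk, ywk, "arm")

        if features:
            pd.concat(features).to_csv(outdir / "features.csv", index=False)
            outputs.append(outdir / "features.csv")
        outputs.append(save_json(
            {"voxel_p": config.voxel_p, "cluster_p": config.cluster_p, **report},
            outdir / "inference_report.json"))
        return outputs
    _execute(manifest, "infer", inputs, force, build)


def _stage_ml(config, scfg, outdir, manifest, force):
    inputs = [outdir / "subjects_clinical.csv", outdir / "inference_report.json"]
    if (outdir / "features.csv").exists():
        inputs.append(outdir / "features.csv")

    def build():
        clinical = pd.read_csv(outdir / "subjects_clinical.csv")
        grid = ml.default_grid(config.svm_grid_step)
        svm_rows, svr_rows = [], []
        if (outdir / "features.csv").exists():
            feats = pd.read_csv(outdir / "features.csv")
            base = feats.merge(clinical, on="subject_id")
            for (contrast, cid), sub in base[base.timepoint == "baseline"].groupby(
                    ["contrast", "cluster_id"]):
                arm = contrast.split("_")[0].upper()
                sub = sub[(sub.group == "control") | (sub.arm == arm)]
                y = (sub.group == "patient").astype(int).to_numpy()
                if y.min() == y.max():
                    continue
                rep = ml.loo_svm_classify(sub.mean_nh.to_numpy()[:, None], y,
                                          grid=grid, seed=config.seed,
                                          mode=config.svm_mode)
                svm_rows.append({"contrast": contrast, "cluster_id": cid,
                                 "accuracy": rep.accuracy,
                                 "sensitivity": rep.sensitivity,
                                 "specificity": rep.specificity,
                                 "tp": rep.tp, "fn": rep.fn,
                                 "tn": rep.tn, "fp": rep.fp})
                pats = sub[sub.group == "patient"]
                for domain in ("total", "positive", "negative", "general"):
                    rr = pats[f"rr_{domain}"].to_numpy(float)
                    if len(rr) < 6 or rr.std() == 0:
                        continue
                    srep = ml.loo_svr_predict(
                        pats.mean_nh.to_numpy()[:, None], rr, grid=grid,
                        seed=config.seed, mode=config.svm_mode,
                        alpha=config.alpha, m_tests=config.bonferroni_m)
                    svr_rows.append({"contrast": contrast, "cluster_id": cid,
                                     "domain": domain, "r": srep.r, "p": srep.p,
                                     "threshold": srep.bonferroni_alpha,
                                     "significant": srep.significant})
        pd.DataFrame(svm_rows).to_csv(outdir / "svm_report.csv", index=False)
        pd.DataFrame(svr_rows).to_csv(outdir / "svr_report.csv", index=False)
        return [outdir / "svm_report.csv", outdir / "svr_report.csv"]
    _execute(manifest, "ml", inputs, force, build)


def _stage_report(config, scfg, outdir, manifest, force):
    inputs = [outdir / "svm_report.csv", outdir / "svr_report.csv",
              outdir / "inference_report.json"] + \
        sorted(outdir.glob("clusters_*.csv"))

    def build():
        # cluster-table summary, one block per contrast ("No cluster" when empty)
        blocks = []
        for name in CONTRASTS:
            p = outdir / f"clusters_{name}.csv"
            if not p.exists():
                continue
            t = pd.read_csv(p)
            if len(t) == 0:
                blocks.append(pd.DataFrame([{"contrast": name,
                                             "cluster": "No cluster"}]))
            else:
                t = t.assign(contrast=name, cluster=t.cluster_id)
                blocks.append(t[["contrast", "cluster", "peak_x_mm", "peak_y_mm",
                                 "peak_z_mm", "size_voxels", "peak_stat"]])
        pd.concat(blocks).to_csv(outdir / "report_clusters.csv", index=False)

        overlap = []
        truth_files = sorted(outdir.glob("truth_cluster*.nii.gz"))
        for name in CONTRASTS:
            p = outdir / f"clusters_{name}.nii.gz"
            if not p.exists():
                continue
            labels, _ = load_nifti(p)
            for j, tf in enumerate(truth_files):
                tvol, _ = load_nifti(tf)
                overlap.append({"contrast": name, "planted_cluster": j,
                                "dice": ica.dice(labels > 0.5, tvol > 0.5)})
        pd.DataFrame(overlap).to_csv(outdir / "report_overlap.csv", index=False)
        return [outdir / "report_clusters.csv", outdir / "report_overlap.csv"]
    _execute(manifest, "report", inputs, force, build)
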