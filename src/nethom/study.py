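"""In-memory study harness: streamed cohort -> preprocessed NH maps.

Convenience layer over :mod:`simulate`, :mod:`preprocess` and
:mod:`homogeneity` for Monte-Carlo work: runs are generated one at a time
with ``scope='network'`` (bit-identical to the network part of the full
grid) and reduced immediately to an NH map, so memory stays bounded by a
single run.  The file-based pipeline in :mod:`pipeline` produces the same
maps from on-disk artefacts.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import homogeneity, preprocess, simulate

__all__ = ["nh_cohort", "baseline_region_nh", "clinical_table"]


def nh_cohort(config: simulate.SimConfig, groups=None, timepoints=("baseline",),
              standardize: bool = True, apply_motion_qc: bool = True):
    """Generate, preprocess and reduce a cohort to NH maps.

    Returns ``(maps, meta)``: ``maps`` keys are ``(subject_id, timepoint)``
    and values are :class:`~nethom.homogeneity.NHMap` objects on the true
    network mask (3-D); ``meta`` carries group/arm/age/mean FD per run.
    Subjects failing the 2 mm / 2 degree motion rule are dropped (logged in
    ``meta`` via absence).
    """
    groups = groups or simulate.GROUPS
    net = simulate.network_mask_for(config)
    flat_mask = np.ones((int(net.sum()), 1, 1), dtype=bool)
    subjects = simulate.subject_table(config).set_index("subject_id")
    maps, rows = {}, []
    offset = 0
    for sid, group in config.subjects:
        tps = ("baseline",) if group == "control" else ("baseline", "week8")
        wanted = [tp for tp in tps if tp in timepoints]
        for tp in tps:
            my_offset = offset
            offset += 1
            if group not in groups or tp not in wanted:
                continue
            motion = simulate.generate_motion(config, my_offset)
            if apply_motion_qc and preprocess.exclude_by_motion(motion):
                continue
            run = simulate.generate_run(config, sid, tp, scope="network")
            run, motion, _ = preprocess.preprocess_run(run, motion)
            if not run.usable:
                continue
            nh = homogeneity.compute_nh(run, flat_mask)
            if standardize:
                nh = homogeneity.standardize_map(nh)
            # re-home the flat map onto the 3-D network mask
            maps[(sid, tp)] = homogeneity.NHMap(
                nh.values, net, sid, tp, config.affine, nh.standardized)
            rows.append({"subject_id": sid, "timepoint": tp,
                         "group": "patient" if group != "control" else "control",
                         "arm": {"patient_dpp": "DPP", "patient_dt": "DT"}.get(group, "none"),
                         "age": subjects.loc[sid, "age"],
                         "mean_fd": motion.mean_fd})
    return maps, pd.DataFrame(rows)


def baseline_region_nh(config: simulate.SimConfig, maps: dict,
                       region_index: int | None = None) -> pd.Series:
    """Per-patient mean baseline NH of a planted region.

    Averages on whatever scale the maps carry; the clinical coupling
    z-scores the values across patients, so raw and standardised maps give
    the same planted correlation.
    """
    if region_index is None:
        region_index = config.clinical_coupling.coupled_region_index
    truth = simulate.ground_truth_for(config)
    region = truth.planted_cluster_masks[region_index]
    vals = {}
    for (sid, tp), m in maps.items():
        if tp != "baseline" or not sid.startswith(("dpp", "dt")):
            continue
        vol = m.to_volume()
        sel = region & m.mask
        vals[sid] = float(vol[sel].mean())
    return pd.Series(vals).sort_index()


def clinical_table(config: simulate.SimConfig, maps: dict) -> pd.DataFrame:
    """Subject table with planted clinical outcomes coupled to baseline NH."""
    region = baseline_region_nh(config, maps)
    present = {sid for sid, _ in maps}
    table = simulate.subject_table(config)
    table = table[table.subject_id.isin(present)].reset_index(drop=True)
    return simulate.generate_clinical(table, region,
                                      config.clinical_coupling, config.seed)
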