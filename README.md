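# nethom

Network-homogeneity (NH) analysis of longitudinal resting-state fMRI for
two-arm treatment studies — with a fully synthetic, seeded cohort
generator so that every stage of the analysis is testable end to end
without any imaging data.

## The scientific problem

Psychotherapy add-ons (such as metacognitive training) may act on the
brain's default-mode network (DMN). A typical study design scans patients
at baseline and after 8 weeks of treatment in two arms — drug plus
psychotherapy (DPP) and drug therapy alone (DT) — plus once-scanned
healthy controls, and asks:

1. **Where is network homogeneity abnormal?** For a voxel *i* inside a
   network mask of *N* voxels,

   NH(*i*) = (1/(N−1)) · Σ_{j≠i} corr(x_i, x_j),

   the mean Pearson correlation of its time series with every other
   in-network voxel. Voxel-wise group inference with age and mean
   framewise displacement (FD) as covariates, corrected by Gaussian
   random field (GRF) cluster statistics (voxel p < 0.001, cluster
   p < 0.05), localises group and treatment effects.
2. **Is abnormal NH diagnostic?** Leave-one-out SVM on cluster-mean NH
   separates patients from controls (accuracy / sensitivity / specificity).
3. **Does baseline NH predict treatment response?** Leave-one-out SVR
   predicts the PANSS reduction ratio RR = (score₁ − score₂)/score₁,
   scored by the correlation between held-out predictions and actual RR
   against a Bonferroni threshold (0.05/16).

`nethom` implements the full chain: temporal preprocessing (drop 10
volumes, 2 mm / 2° motion exclusion, linear detrend, 0.01–0.08 Hz
band-pass, Friston-24 + WM/CSF nuisance regression without global-signal
removal, scrubbing at FD > 0.2 mm), group-ICA network-mask construction,
fast per-voxel NH, GRF-corrected inference with a permutation oracle, and
the SVM/SVR evaluation. A seeded generator emulates the study conditions
(240 volumes at TR = 2 s on a 3 mm grid, ~20 subjects/group, planted NH
deficits, a DPP-only week-8 restoration, and clinical scores coupled to
baseline NH) so every claim is checked against known ground truth.

## Worked example

```bash
python examples/predict_response.py
```

```
LOO-SVM: accuracy 100.0%, sensitivity 100.0%, specificity 100.0%  (tp=19 fn=0 tn=20 fp=0)
baseline NH vs RR: sample r = 0.885 (planted population 0.9)
LOO-SVR predicted-vs-actual r = 0.870, p = 1.32e-06, Bonferroni 0.05/16 = 0.003125: significant
```

The cluster-mean NH of the planted deficit separates the 19 DPP patients
from 20 controls perfectly (the planted loading gap, 0.3 vs 0.9, is a
strong effect by design), and leave-one-out SVR recovers the planted
r = 0.9 coupling between baseline NH and the total-score reduction ratio
as a held-out prediction correlation of 0.87 — significant at the
Bonferroni-corrected threshold.

`examples/group_inference.py` shows the inference half: the corrected
cluster table contains exactly the two planted effects (negative-T
deficit, positive-T excess) with Dice ≥ 0.98 against ground truth.
The other examples cover the generator, the NH identities and the
file-based pipeline (`nethom run-all --outdir ...`), which writes NIfTI /
TSV / CSV artefacts with a checksum manifest and skips up-to-date stages.

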