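# rwradiomics

Rectal-wall subimage radiomics from planning CT and daily MVCT images,
for predicting grade >= 1 late rectal bleeding after prostate
radiotherapy and for choosing the week at which adaptive re-planning
decisions are as well informed as they will get.

## Who this is for

Radiotherapy imaging researchers who have (or want to simulate) serial
per-fraction CT-like images with rectum contours and a binary late-
toxicity endpoint, and who want a tested, seeded, end-to-end
implementation of the wall-subimage radiomics workflow: ROI
construction, IBSI-style feature extraction, weekly aggregation,
penalised modelling and time-point comparison.

## The method in brief

For each slice the rectum contour is rasterised and expanded inwards by
2 pixels (two 3x3 erosions) to form the wall ring; 8x8 subimages are
tiled along the ring at 1-pixel intervals, spanning the 2-pixel band
plus 3 pixels on either side of the local normal.  Each subimage yields
118 features — first-order statistics plus the GLCM, GLRLM, GLSZM,
GLDZM, NGTDM and NGLDM texture families — averaged over all subimages
and slices of a scan, then over treatment weeks (74 Gy / 37 fractions:
CT, W1..W7; 60 Gy / 20 fractions: CT, W1..W4).

Per regimen, patients are split 75:25 stratified by the endpoint.
Features are z-scored with training parameters, screened with
Mann-Whitney U tests, pruned at |Spearman rho| >= 0.8 (keeping the more
significant member), and fed to an elastic-net logistic regression
(L1 ratio 0.5, C tuned over 500 log-spaced values in [1e-4, 1e3] by
5-fold cross-validated AUC, with a chance-level guard that collapses to
the intercept when no C beats chance).  AUCs carry 95 % CIs from 100
stratified bootstrap resamples; sensitivity and specificity are read at
the Youden threshold.  Time points are compared by one-sided rank tests
on the bootstrap AUC samples, separately for per-week models
("separate") and for models accumulating all previously selected
features ("cumulative"); the optimal re-planning week is the earliest
time point no later week significantly beats.

Because no public imaging dataset accompanies this design, the package
includes a first-class synthetic phantom cohort: an annular rectum
whose wall carries a spatially correlated Gaussian texture whose
variance (and correlation length) drifts upward from a configurable
onset week in endpoint-positive patients, with noisier daily images
than the planning image.  `docs/methods.md` documents every convention,
parameter and limitation.

## Worked example

```python
from rwradiomics import RunConfig, run_pipeline

cfg = RunConfig(
    out_dir="runs/demo", seed=3000,
    simulate=dict(n_patients=120, n_slices=1, regimen_mix=(0.0, 1.0),
                  radius_range=(5.0, 7.0), delta=1.0),
)
res = run_pipeline(cfg)
rr = res.regimens["60Gy_20F"]
for mode, sweep in rr.sweeps.items():
    aucs = " ".join(f"{tp}:{sweep.models[tp].train_auc:.3f}"
                    for tp in sweep.time_points)
    print(f"{mode}: {aucs} -> optimal {rr.optimal[mode].time_point}")
```

prints

```
separate: CT:0.500 W1:0.904 W2:0.979 W3:0.992 W4:0.993 -> optimal W3
cumulative: CT:0.500 W1:0.957 W2:1.000 W3:0.999 W4:0.996 -> optimal W2
```

Read: the planning CT alone carries no signal (the guarded model
collapses to chance); training AUC rises steeply from week 1, where the
injected effect switches on at half strength, and saturates at week 2 —
so the cumulative analysis picks W2 as the earliest week after which no
later week significantly improves, matching the phantom's ground truth
(effect onset week 1, saturation week 2).  The run directory contains
the cohort and feature tables, per-mode report CSVs with AUC/CI/
sensitivity/specificity per time point, the non-zero coefficients of
the best models with refit p-values, AUC-vs-week plots and a manifest
with the config hash and seeds.

The same pipeline runs from the shell:

```bash
rwradiomics simulate --n-patients 120 --seed 7 --out cohort/
rwradiomics run-all --seed 7 --out-dir runs/demo
```

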