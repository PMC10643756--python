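# ooplasm

Non-invasive image analysis of human metaphase-II oocytes for competence
assessment. The package turns Hoffman-modulation-contrast micrographs into
calibrated optical-density (OD) and texture measurements of the ooplasm,
models laboratory and clinical outcomes (fertilisation, blastulation,
implantation) from those measurements, and ranks oocytes with a two-tier
OD + gradient scoring tool. It is aimed at embryology and reproductive-
biology groups who want a reproducible, scriptable version of this analysis,
and ships synthetic-data generators so the whole pipeline can be exercised
and validated without any clinical images.

## What it computes

**Calibration.** Each imaging session includes frames of a 10-step neutral-
density filter (0.1–4.0 OD) plus clear glass (0.0 OD). The mean grey of each
frame and its known OD define a monotone piecewise-linear map from 8-bit
grey value to OD, applied pixelwise to oocyte images
(`ooplasm.calibration`).

**OD features.** Over the ooplasm ROI (mask centroid, equivalent-area radius
R = √(area/π)), the package reports the mean OD, the mean OD of four
concentric rings C1–C4 at quarter-radius steps, and the radial gradient

```
GRAD = 100 · (mean(OD_C1, OD_C2) − mean(OD_C3, OD_C4)) / OD     [%]
```

positive when the centre is optically denser than the periphery
(`ooplasm.features`).

**Texture.** Directed grey-level co-occurrence matrices (GLCM) at
orientations 0°/90°/180°/270° and distances 1–3 px, restricted to pixel
pairs inside the mask, summarised by the Haralick features ASM, CON, CORR,
IDM and ENT and averaged over the 12 combinations (`ooplasm.texture`).

**Outcome models.** Each feature is recoded into quartiles Q1–Q4 over all
inseminated oocytes; the two quartiles with the highest outcome rate form
the feature's *optimal range*. Binary logistic regression of each outcome on
the in-range indicators yields odds ratios with Wald 95% CIs, ROC AUC
(Mann–Whitney identity, Hanley–McNeil CI) and 0.5-threshold confusion
metrics (`ooplasm.model`).

**Ranking tool.** A two-tier rule — OD in/out of its optimal range first,
GRAD second — scores each oocyte 1 (both in range, highest competence)
through 4 (both out) (`ooplasm.rank`).

Supporting modules: `ooplasm.stats` (Mann–Whitney with exact enumeration at
small n, Wilcoxon signed-rank, Kruskal–Wallis, repeatability and focal-plane
checks, confusion metrics) and `ooplasm.synth` (calibration stacks, textured
disk images with analytic ground truth, cohorts with planted odds ratios).

## Worked example

Simulate a clinical-size cohort (n = 957) with planted effects, fit the
fertilisation model and rank the oocytes:

```python
from ooplasm import (clinical_cohort_spec, simulate_cohort,
                     fit_outcome_model, score_cohort)

cohort = simulate_cohort(clinical_cohort_spec(n_oocytes=957, seed=7))
om = fit_outcome_model(cohort, cohort["fertilised"], ("od", "grad", "idm"),
                       outcome_name="fertilised")
print(om.model.report.round(3).to_string(index=False))
print(f"AUC {om.auc.auc:.3f}")

scored = score_cohort(cohort, om.ranges["od"], om.ranges["grad"])
merged = cohort.merge(scored[["oocyte_id", "score"]], on="oocyte_id")
print(merged.groupby("score")["fertilised"].agg(["size", "mean"]).round(3))
```

Output:

```
    predictor  coef    se    or  ci_low  ci_high
  od_in_range 1.292 0.166 3.640   2.629    5.040
grad_in_range 0.901 0.161 2.461   1.794    3.377
 idm_in_range 0.535 0.159 1.708   1.252    2.331
AUC 0.706
       size   mean
score
1       223  0.897
2       255  0.812
3       255  0.745
4       224  0.527
```

The odds ratios are the fitted effect of lying inside each feature's optimal
range (here the cohort was generated with planted ORs of 4.71, 2.31 and 2.01;
one refit at n = 957 lands near them with the expected sampling noise and
indicator-estimation attenuation). The score table shows the ranking tool's
monotone competence: oocytes scored 1 fertilise at 89.7% versus 52.7% for
score 4.

The same pipeline runs from the shell on generated images:

```sh
ooplasm demo --outdir demo_run --seed 1
```

which renders calibration and oocyte images, fits the calibration curve,
extracts features, and writes quartile tables, model reports, scores and a
cohort summary under `demo_run/`.

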