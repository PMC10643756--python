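# Methods

This note records the measurement model, the statistical conventions, the
design choices made where more than one convention was defensible, and what
the synthetic data do and do not establish.

## Optical-density calibration

Transmission imaging is calibrated per session against a variable
neutral-density filter (10 steps, 0.1–4.0 OD) plus a clear-glass frame
anchoring 0.0 OD. The mean grey value of each step frame — over the full
frame, since filter steps are spatially uniform — and its known OD form the
knots of the grey → OD map.

* **Interpolation family.** Monotone piecewise-linear through the knots. A
  parametric (e.g. Rodbard-style sigmoid) fit would be equally plausible,
  but linear interpolation is exactly reproducible, passes through every
  knot, and preserves monotonicity by construction.
* **Extrapolation.** Greys outside the measured range are clamped to the
  boundary OD (0.0 above clear glass, the maximum calibrated OD below the
  densest step): OD beyond the measured range is not physically calibrated,
  and clamping is explicit about that.
* **Validation.** Mean greys must strictly decrease with OD; a violation is
  treated as a calibration failure (unstable illumination), not reordered.

## ROI, rings and the gradient statistic

The ooplasm ROI is a non-empty, single-connected boolean mask. Its centre is
the pixel centroid and its radius the equivalent-area radius R = √(area/π),
making the decomposition deterministic for hand-drawn, not-quite-circular
ROIs. Normalized pixel-centre distance r/R is binned at quarter-radius
half-open edges into rings C1–C4; mask pixels with r/R ≥ 1 join C4 so the
rings always partition the mask exactly (a count-weighted mean of the ring
ODs therefore reproduces the overall OD to machine precision, which the
tests assert). Coordinates are row-major, origin top-left, 0-based.

Ring OD is the mean calibrated OD over the annulus pixel set — identical to
the integrated-density difference between the outer and inner circle divided
by their area difference. The radial gradient is

GRAD = 100 · (mean(OD_C1, OD_C2) − mean(OD_C3, OD_C4)) / OD  [%].

The inner-pair/outer-pair contrast could be normalized by the inner OD, the
outer OD or the overall OD; the overall OD was chosen because it is
symmetric in the two halves, dimensionless and reduces to an intuitive
percent difference. OD features are computed on the calibrated OD image;
texture is computed on the raw 8-bit greys.

## Texture (GLCM) conventions

* 256 grey levels, no requantization.
* Directed (non-symmetrized) matrices, one per orientation 0°, 90°, 180°,
  270°, at distances 1, 2, 3 px; features are the flat mean over the 12
  combinations, with the per-combination table retained for QC.
* Pairs are counted only when both endpoints are inside the mask, so
  background and the zona region never contaminate the statistics.
* Features: ASM = Σp², CON = Σ(i−j)²p, IDM = Σp/(1+(i−j)²),
  ENT = −Σp·log₂p with 0·log 0 ≡ 0 (log base configurable, 2 by default),
  CORR = Σ(i−μᵢ)(j−μⱼ)p/(σᵢσⱼ), reported as NaN when a marginal variance is
  zero (e.g. constant images) rather than silently 0.
* Because all five features are transpose-invariant and opposite
  orientations give transposed matrices, 0°/180° and 90°/270° features are
  mathematically identical (numerically to ~1e-12, from summation order).
  This is why orientation-dependence tests on these features are expected
  non-significant.

## Statistical conventions

* All p-values are two-sided; significance is descriptive at 5%.
* **Mann–Whitney U**: exact enumeration of all C(n, n₁) group assignments
  (tie-safe, both tails) when the combined n ≤ 12; otherwise the
  tie-corrected normal approximation with a 0.5 continuity correction,
  which keeps the approximation within ±0.02 of the exact p at the
  switchover size.
* **Wilcoxon signed-rank**: zero differences dropped, midranks for tied
  absolute differences, tie-corrected normal approximation; z is signed so
  that z > 0 means the second measurement tends to exceed the first.
* **Kruskal–Wallis**: tie-corrected H, chi-square reference; the degenerate
  all-identical case returns H = 0, p = 1 by contract.
* **Shapiro–Wilk / Brown–Forsythe** are exposed as descriptive gates only;
  they never alter downstream computation.
* **Confusion metrics** are percentages; any metric with a zero denominator
  is NaN, never 0.

## Quartile models and ranking

* Sample quantiles use the linear-interpolation definition (configurable);
  labels come from half-open bins (−∞,q25], (q25,q50], (q50,q75], (q75,∞),
  so a value exactly on a cut point goes to the lower quartile. Labels
  depend only on ranks, hence are invariant under monotone transforms of
  the feature.
* The optimal range is the quartile pair with the highest summed outcome
  rate; rate ties prefer a contiguous pair, then lower quartile indices.
  Non-contiguous selections are supported and flagged; range membership is
  always evaluated through the quartile labels, which reproduces the
  training selection exactly.
* Logistic regression is maximum likelihood (Newton), convergence at
  parameter change < 1e-8 within 100 iterations, Wald SEs from the inverse
  information; OR = exp(coef), 95% CI = exp(coef ± 1.96·SE). Predictors are
  entered jointly (one model per outcome); complete or quasi-complete
  separation raises an explicit error — plausible for transfer-size
  subcohorts (n ≈ 114) — rather than returning a silently penalized fit.
  The pipeline orchestrator logs and skips a separated outcome; the library
  never does.
* Classification threshold is 0.5 on the predicted probability.
* AUC uses the Mann–Whitney identity (ties count ½) and the Hanley–McNeil
  standard error.
* The ranking tool tests OD first (it carries the largest OR in every
  outcome model), GRAD second: (in,in)→1, (in,out)→2, (out,in)→3,
  (out,out)→4; the mixed-case order and the score→binary rule for
  performance metrics ({1,2} predict success) are configurable.
* Reported percentages are one-decimal, round-half-away-from-zero; a
  truncation mode exists because published one-decimal figures are
  occasionally truncated rather than rounded (e.g. 957/1126 = 84.99% can
  print as 84.9 or 85.0), and concordance checks use a ±0.1 tolerance.

## Synthetic data: what it emulates, and what it does not

The generators define the study conditions for every test:

* **Calibration stacks** — constant frames per ND step plus i.i.d. Gaussian
  noise (default grey design: transmission-shaped with a dark offset,
  strictly decreasing after 8-bit rounding). They emulate step-filter
  frames, not shading or vignetting.
* **Oocyte images** — a disk on a bright background; grey is linear in
  normalized radius (the simplest profile with a nonzero GRAD ground
  truth; positive slope = darker centre) plus Gaussian-blurred white noise
  rescaled to amplitude `texture_sigma`, correlation length
  `texture_corr_len` (longer → higher IDM, lower ENT). Ground truth is
  evaluated on the noise-free unquantized profile, so extraction agrees
  with it up to one grey level propagated through the calibration slope.
  No zona pellucida, polar body, spindle or photorealism: passing tests
  show the *measurement chain* is correct, not that real ooplasm looks
  like this.
* **Cohorts** — features are independent normals by default (an optional
  correlation matrix exists; no joint distribution is established for real
  cohorts), with in-range indicators over stated continuous bounds and
  Bernoulli outcomes from a logistic model with planted log odds ratios.
  The defaults plant the published point estimates (fertilisation OR 4.71
  for OD, 2.31 for GRAD, 2.01 for IDM; analogous sets for blastulation and
  implantation) with each optimal range the central 50% of its feature, so
  every indicator is Bernoulli(1/2). Intercepts are solved by bracketing so
  the marginal rates hit 73.0% fertilisation, 67.9% blastulation among
  cultured and 50.9% implantation; the solve is hierarchical because
  conditioning on the previous outcome re-weights the indicator cells.
  The hierarchy (blastulation only for fertilised oocytes selected for
  culture, implantation only for a transferred subset of blastocysts) is
  enforced in generation and validated in tabulation.
* All generators take explicit seeds; no global random state is touched,
  and identical specs plus seeds are bit-identical.

Clinical-scale headline metrics (AUC ≈ 0.77–0.89, accuracies 67–81%) were
estimated on real images that are not available; the package treats them as
qualitative patterns (moderate AUC, high sensitivity, limited specificity,
monotone competence across scores) that the planted simulations reproduce,
not as numeric targets.

## Problem sizes and numerical choices

The test suite and the acceptance script run entirely on generated data:
96×96-px disks, 64×64 calibration frames, cohorts of 957 oocytes (the
clinical cohort size) and 200 replicates for odds-ratio recovery, which
completes in seconds. Degenerate inputs are contracts, not crashes:
identical pooled values give p = 1, empty rings and separated fits raise,
undefined CORR and zero-denominator metrics are NaN. Ties at quartile cut
points go to the lower quartile; Wilcoxon drops zero differences; the
Mann–Whitney exact/approximate switch is at combined n = 12.

## Known limitations

* No automatic segmentation: the ROI mask is an input.
* The calibration function of the original ImageJ workflow, its GLCM
  plugin's symmetrization and log base, and the exact GRAD normalization
  are not documented anywhere authoritative; the conventions above are
  declared defaults, and the entropy base, quantile definition, tier order
  and rounding mode are configurable where it matters.
* Feature independence in the default cohort generator understates the
  collinearity real imaging features likely have; odds-ratio recovery under
  correlated features can be exercised through the optional correlation
  matrix but is not part of the default conditions.
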