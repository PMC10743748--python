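# Methods

## The asymmetry statistic and its sign convention

For one eye and one layer, the asymmetry of corresponding cell pair
(*r.c*, *(9−r).c*), *r* ≤ 4, is the signed difference

d = T(inferior cell) − T(superior cell)   [µm].

The convention is *inferior minus superior*, fixed package-wide and stated in
every output header: the RNFL, thicker inferiorly in healthy adults, therefore
shows positive asymmetries. Signed (not absolute) differences feed the
normative ranges, because superior thinning and inferior thinning move d in
opposite directions and the two percentile bounds encode exactly that
information.

Cohort inference per pair is the two-sided paired Student *t*-test on the
per-eye d values, t = d̄ / (s_d/√n) with the sample SD (n−1 denominator) and
df = n−1. Significance is α = 0.05, two-sided. No multiplicity correction is
applied by default across the 32 pairs × 10 layers (matching reference
practice for this analysis); optional Holm or Benjamini–Hochberg adjustment is
available (`adjust={"holm","bh"}`) and changes only the significance flag,
never the estimates.

Hemisphere summaries pool all eyes × 32 cells: the pooled mean equals the mean
of per-eye hemisphere means (equal weights), and the pooled SD deliberately
mixes between-subject with across-cell spatial variation. Normality screening
uses the one-sample Kolmogorov–Smirnov test with plug-in mean/SD; without a
Lilliefors correction this is anticonservative (p-values biased upward), which
is acceptable because the result is advisory only — the pipeline never
switches tests on its outcome.

## Normative ranges and classification

Per (layer, pair), the reference range is the empirical 2.5th–97.5th
percentile of d over the reference cohort, computed by linear interpolation
between closest order statistics at rank 1 + q(n−1) (numpy's "linear" method;
1..100 → 3.475 / 97.525). Classification is inclusive at both bounds: a value
exactly at P2.5 or P97.5 is within normal limits, since those values are
attained by healthy eyes. Classification is monotone in the observed value
(below → within → above).

Self-classification of the reference cohort flags slightly more than 5% per
entry: with n = 300, the interpolated bounds leave 8 observations strictly
below and 8 strictly above, i.e. 16/300 ≈ 5.3%. This is a property of the
estimator, not a defect.

The database persists as JSON (`schema_version`, provenance, 320 entries with
range, n, mean, SD); mean/SD are stored for audit, classification reads only
the range. Loading validates required fields, the schema version, hemisphere
membership of the key cell, and duplicate keys; an empty database loads with a
warning. Validation is plain field checking, not a schema engine.

## Maps

The cohort heatmap plots, for each significant pair, half the mean difference:
+d̄/2 at the inferior cell and −d̄/2 at the superior cell, so each hemisphere
shows its own excess relative to the pair midpoint and the map sums to exactly
zero over every pair (the placement convention for the halved difference was a
genuinely open choice; the symmetric attribution is consistent with
red-thickening / blue-thinning semantics per cell). Non-significant pairs are
black; the midline is green; the diverging colour scale is symmetric about
zero. The per-eye device-style map shows |d| per pair on a linear grayscale
ramp clamped at 30 µm — the ceiling the instrument's own asymmetry display
represents; only the ceiling is documented, hence the linear ramp.

Laterality is a rendering concern only. The grid nomenclature is specular
between eyes, so identically addressed cells are already anatomically
homologous; "right-eye format" for left eyes is a display-time column mirror
and no stored data or statistic is ever remapped.

## Synthetic cohort generator

The generator emulates a healthy adult reference cohort of 300 eyes (51%
right / 49% left by rounding; the defaults reproduce the reference study's
conditions). Cell thickness is

T(e, l, a) = m_l(hemisphere(a)) + g_l(a) + b_{e,l} + ε_{e,l,a}

- m_l: fixed superior/inferior hemisphere means per layer, transcribed from
  the published 300-eye healthy reference (RNFL 38.76/46.33, GCL 33.05/32.89,
  IPL 27.79/26.77, INL 31.61/31.43, OPL 26.20/27.14, ONL 55.54/51.98,
  RPE 13.03/12.57, INNER 215.92/216.62, OUTER 78.61/77.00,
  RETINA 294.53/293.61 µm).
- b ~ N(0, subject_sd²): per-eye, per-layer random effect (between-subject
  variability; identical in both hemispheres, so it cancels from every pair
  difference).
- ε ~ N(0, cell_sd² + noise_sd²): independent cell-level noise
  (within-hemisphere spatial texture plus measurement error; `noise_sd`
  defaults to 0).
- g_l: optional deterministic temporal–nasal tilt (low-order polynomial in the
  column, amplitude cell_sd/2) with zero mean within each hemisphere, so
  hemisphere calibration is unaffected; default profile is flat.

**Variance components.** The reference publication reports hemisphere
mean ± SD but does not decompose variance, so the SD components here are the
package's own settings, sized from the observable consequences rather than the
printed SDs: cell_sd = 0.35 and subject_sd = 0.25 of the layer's printed SD
scale (mean of the two hemisphere SDs). The cell-level share fixes the
per-pair asymmetry SD at √2·cell_sd, which reproduces the reported normative
ranges qualitatively — GCL ranges near ±10 µm and never beyond 30 µm, some
peripheral RNFL bounds beyond 30 µm — while the subject-level share keeps
whole-eye excursions physiologically plausible. Consequently the simulated
pooled SDs are smaller than the printed SDs; the hemisphere *means* are the
calibrated quantities. The generator cannot reproduce per-cell spatial
structure (no per-cell reference means are available), between-eye hemisphere
asymmetry variance (the subject effect cancels in pairs, so hemisphere-level
t-tests are anticonservative relative to real data, e.g. INL reaches
significance here but not in the reference), or segmentation artefacts —
passing tests therefore validate the pipeline's statistics, not device
physics.

Draws are truncated at 0 µm (thickness cannot be negative). Under the default
calibration the truncation probability is < 10⁻³ per draw in the worst layer
(superior RNFL), biasing its mean by far less than one standard error of the
pooled mean, so "expected pooled mean = calibration mean" holds to well within
every tolerance used.

**Standard error of the pooled hemisphere mean.** Because the subject effect
does not average out over an eye's 32 cells,
SE = √(subject_sd²/n + (cell_sd² + noise_sd²)/(32n)); recovery tests use 3·SE.
With the default calibration and n = 300 this is ≈ 0.41 µm for RNFL and
smaller for thinner layers.

**Determinism.** One `SeedSequence` drives everything; lesion assignment uses
a spawned substream, so toggling lesions leaves base thickness values
byte-identical. Identical config + seed ⇒ byte-identical cohorts.

**Lesions.** A `LesionSpec` adds `delta` µm to chosen cells of one layer in
`round(affected_fraction · n)` eyes sampled without replacement, floored at
0 µm (a −40 µm lesion on a ~33 µm GCL cell zeroes it, as total focal loss
would), and returns a per-(eye, cell) ground-truth table.

## Numerical and degenerate-input policy

- Grids must be complete (64 cells, finite, ≥ 0); no imputation — artefactual
  scans are excluded, not repaired. Validation returns a report naming every
  offending cell.
- Paired t-test: all-equal zero differences → t = 0, p = 1 (a tie, not an
  error); all-equal nonzero differences → rejected as degenerate (no sampling
  variability); n < 2 → rejected.
- KS screen: needs n ≥ 5 and a non-constant sample.
- Percentiles: n ≥ 2; constant samples give a degenerate [c, c] range.
- Thickness is stored as float µm (device exports are integers, but cohort
  averaging must not round).
- Map rendering is deterministic: identical inputs give byte-identical RGBA
  arrays before encoding.

## Problem sizes

Tests and the acceptance script run full-size 300-eye, ten-layer cohorts
(generation takes well under a second). The null-calibration type-I study uses
1000 replicate cohorts of 12 eyes through the complete per-pair pipeline,
plus 1000 replicates of n = 300 null difference vectors at the test level;
both pool exchangeable, independent units to estimate the per-pair rejection
rate against binomial 99% bounds around α.
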