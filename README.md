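# ppasym

Superior–inferior macular thickness asymmetry analysis for the Spectralis-style
8×8 posterior pole grid.

## The problem

Glaucoma and several retinal and neuro-ophthalmic diseases thin the macular
layers *asymmetrically* about the horizontal midline. Spectral-domain OCT
posterior pole protocols map each of ten segmented macular layers — RNFL, GCL,
IPL, INL, OPL, ONL, RPE, plus the composite INNER, OUTER and complete RETINA —
onto an 8×8 grid of 3°×3° cells aligned to the fovea–disk axis. Cell *r.c* is
numbered from inferior to superior (rows 1–8) and temporal to nasal (columns
1–8), identically in both eyes (specular nomenclature), so cell *r.c* pairs
anatomically with its mirror cell *(9−r).c* across the midline.

Healthy eyes are **not** symmetric, however, so a raw asymmetry map cannot
separate physiology from early disease. `ppasym` implements the reference
pipeline that makes this separation quantitative:

1. **Per-pair statistics.** For each of the 32 corresponding cell pairs of a
   layer, the signed per-eye asymmetry d = T(inferior) − T(superior) (µm) is
   aggregated over a cohort: mean ± SD, two-sided paired Student *t*-test
   (t = d̄ / (s_d/√n), df = n−1), and hemisphere-level summaries (the mean of
   the 32 inferior vs. the 32 superior cells).
2. **Normative database.** The empirical central 95% range — the 2.5th and
   97.5th percentiles of d, by linear rank interpolation — per (layer, pair),
   10 × 32 = 320 entries, persisted as JSON.
3. **Classification.** A new eye's asymmetries are flagged `below_p2_5` /
   `within_normal` / `above_p97_5` against the database (bounds inclusive);
   out-of-range values are likely pathological.
4. **Maps.** The significance-masked half-difference heatmap (±d/2 at the two
   pair members, black where non-significant, green midline, red = thickening,
   blue = thinning) and a per-eye device-style grayscale map of |d| saturating
   at 30 µm. Left eyes are rendered in right-eye format.
5. **Synthetic cohorts.** A calibrated simulator generates healthy cohorts
   (default: 300 eyes, 51% right) whose per-layer hemisphere means equal a
   published healthy-adult reference (e.g. RNFL 38.76 µm superior / 46.33 µm
   inferior), with subject-level random effects, cell-level noise, and optional
   focal lesions with ground-truth labels for classifier evaluation.

## Worked example

```python
import ppasym as pp
from ppasym.simulate import CohortConfig, LesionSpec, generate_cohort, inject_lesions

cohort = generate_cohort(CohortConfig(seed=42))          # 300 healthy eyes
inf, sup = pp.hemisphere_summary(cohort, "RNFL")
print(f"RNFL superior: {sup.pooled_mean:.2f} +/- {sup.pooled_sd:.2f} um")
print(f"RNFL inferior: {inf.pooled_mean:.2f} +/- {inf.pooled_sd:.2f} um")

summaries = pp.pairwise_summary_table(cohort, "RNFL")
s = summaries[0]                                          # pair 1.1 / 8.1
print(f"pair {s.inferior_cell}/{s.superior_cell}: diff {s.mean_diff:+.2f} um, "
      f"p={s.test.p_value:.2e}, normal range [{s.range.p2_5:.2f}, {s.range.p97_5:.2f}]")

model = pp.NormativeAsymmetryModel().fit(cohort)          # 320 reference ranges

patient = generate_cohort(CohortConfig(n_eyes=1, seed=1000))
lesioned, truth = inject_lesions(
    patient, [LesionSpec("GCL", ((5, 4), (5, 5), (6, 4), (6, 5)), -40.0, 1.0)], seed=3
)
for c in model.predict(lesioned.eyes[0]):
    if c.out_of_range and c.layer == "GCL":
        print(f"GCL pair {c.inferior_cell}: {c.observed_diff:+.1f} um -> {c.verdict}")
```

prints

```
RNFL superior: 39.47 +/- 11.51 um
RNFL inferior: 46.78 +/- 11.56 um
pair 1.1/8.1: diff +8.03 um, p=2.23e-20, normal range [-19.80, 34.90]
GCL pair 3.4: observed +41.5 um -> above_p97_5
GCL pair 3.5: observed +27.5 um -> above_p97_5
GCL pair 3.7: observed -13.0 um -> below_p2_5
GCL pair 4.3: observed -10.2 um -> below_p2_5
GCL pair 4.4: observed +30.4 um -> above_p97_5
GCL pair 4.5: observed +36.7 um -> above_p97_5
```

The recovered RNFL hemisphere means sit within sampling error of the 38.76 /
46.33 µm calibration, and every pair of this layer shows the expected
inferior-dominant asymmetry (+8 µm at pair 1.1/8.1, *p* ≪ 0.05). The
40 µm superior GCL thinning at cells 5.4–6.5 drives exactly the four lesioned
pairs (3.4, 3.5, 4.4, 4.5) above the 97.5th percentile; the two `below_p2_5`
flags are the ~5% background rate any central-95% range produces by
construction (32 GCL pairs × 5% ≈ 1.6 expected chance flags per eye).

The same workflow is available from a shell:

```bash
ppasym simulate --n-eyes 300 --seed 42 --out cohort/
ppasym analyze cohort/manifest.csv --out analysis/          # CSVs + heatmaps
ppasym build-norms cohort/manifest.csv --out norms.json
ppasym classify patient_grids.csv --db norms.json --out report/
ppasym render patient_grids.csv --layer RNFL --out maps/    # device-style maps
```

Grid files are plain long-format CSV
(`subject_id,laterality,layer,row,col,thickness_um`); see `ppasym.io`.

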