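# femurmetrics

3D landmark morphometry of the proximal femur. The package measures, from a
named set of landmarks per femur:

* **FNSAO** — the femur neck–shaft axis offset: the common-perpendicular
  (minimal) distance between the neck axis and the proximal shaft axis,
  which are skew lines, with the neck axis passing anterior to the shaft;
* the distance along the shaft axis from the greater-trochanter tip to the
  neck/shaft point of closest approach (GT → sLSNI);
* the neck axis length (lateral cortical entry to head apex);
* the neck-shaft angle under three shaft-axis definitions (proximal
  segment fit, entry → bow apex, entry → distal intercondylar notch), as a
  full 3D angle, i.e. inherently anteversion-corrected;
* signed femoral anteversion versus the posterior condylar axis, measured
  in the plane perpendicular to the proximal shaft axis;
* the intramedullary radius of curvature: the circle through the proximal
  canal point, the canal's point of maximal deviation from the
  entry → notch chord, and the distal canal point.

It also ships a parametric synthetic-femur generator (bowed tubular shaft,
spherical head on a skew neck axis, cohort sampling from configurable
truncated-normal truth distributions with sex strata and left/right
mirroring), a cephalomedullary-nail catalog with per-femur compatibility
reports, and a cohort statistics stage (descriptives with t-based 95% CIs,
Shapiro-gated Welch / Mann-Whitney subgroup comparisons, Pearson/Spearman
correlation screens).

## Conventions

Specimens live in a right-handed canonical frame: for a right femur
+X = medial, +Y = anterior, +Z = proximal; left femurs are stored
x-mirrored so every scalar measure is side-invariant. Lengths are in mm
(radius of curvature alone is reported in meters), angles in degrees.
Specimen files are JSON (`schema_version: 1`, landmark groups as arrays of
`[x, y, z]`); tables are plain CSV.

## CLI

```sh
femurmetrics generate  --config cohort.json --out cohort/ --seed 17
femurmetrics measure   --in cohort/ --out measurements.csv
femurmetrics compare   --measurements measurements.csv --out report.csv
femurmetrics summarize --measurements measurements.csv --out tables/
```

`generate` writes one specimen JSON per femur plus `truth.csv` with the
encoded ground truth. `measure` recomputes all eight measures from the
landmarks alone. `compare` scores every specimen against every implant in
the catalog (bundled by default, `--catalog` to override); because no nail
design exposes a neck–shaft axis offset parameter, every report carries an
unconditional `FNSAO_UNCOMPENSATED` flag. `summarize` writes
`descriptives.csv` (one row per measure: n, mean, SD, 95% CI, median, IQR,
normality flag), `subgroups.csv` (per measure × {sex, side} comparison with
the test used, statistic, and p-value), and `correlations.csv` (age vs
each measure plus all measure pairs). All commands accept `--log-level`.

A cohort config JSON may set `n`, `sex_counts`, `side_counts`,
`noise_sd_mm`, `seed`, `stratify_by_sex`, and per-measure
`distributions` overrides (`{"fnsao_mm": {"mean": 6.1, "sd": 1.7}}`, with
optional explicit `low`/`high` truncation bounds).

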