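# File formats

All files are UTF-8, comma-delimited, `.` decimal separator, `NA` for
missing values.

## Spectral table (wide format)

One row per sample. Four metadata columns precede the spectral block:

| column | type | notes |
|---|---|---|
| `sample_id` | string | unique |
| `phase` | int | extraction phase, 1, 2 or 3 |
| `time_min` | float | sampling time within the phase |
| `temperature_c` | float or `NA` | optional process temperature |

Every remaining column header is a wavelength in nm. The header must be
strictly increasing and uniformly spaced; the grid is inferred from it
under the half-open convention `[start, stop)` (so 800–2200 nm at 0.5 nm
is 2800 columns, `800.0 ... 2199.5`). Absorbance values are written at 12
significant digits; write → read round-trips at that precision.

Readers reject ragged rows, non-monotone or non-uniform wavelength
headers, and phase labels outside {1, 2, 3}, naming the offending
row/column.

## Reference table (long format)

One row per (sample, analyte) pair:

| column | type |
|---|---|
| `sample_id` | string |
| `analyte` | one of `glycyrrhizic_acid`, `liquiritin`, `isoliquiritin`, `total_flavonoids` (free-form for synthetic data) |
| `concentration_mg_per_ml` | float ≥ 0, or `NA` where the reference assay failed |

`sample_id`s must be a subset of the companion spectral table's ids.
Samples with `NA` for the modelled analyte are dropped before splitting
and excluded from phase means.

## Split table

Two columns, `sample_id` and `role` (`calibration` | `validation`),
persisting a Kennard–Stone partition so downstream runs are reproducible.

## Model artifact (JSON)

Centering vectors, NIPALS weights/loadings, regression vector, the
variable mask (indices into the full grid) and the full-grid width.
Reloading predicts identically.

## Run config (YAML)

Keys mirror `nirpls.pipeline.RunConfig`; flags given on the CLI override
the file. See `examples/run_config.yaml`.

## Run report (JSON)

`report.json` holds, per analyte: the pretreatment-ladder metric table
(RMSEC/RMSECV/RMSEP + R² per candidate), the selected pretreatment, the
moving-window verdict, the best interval combination with nm ranges, the
final masked-model metrics, the per-phase relative-error assessment
(full precision plus 2-decimal round-half-up display values), the
regression F test and the detection-limit estimate (mg/mL and ppm under
the stated 1 g/mL density convention). Reports regenerate byte-identically
for identical config + seed.
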