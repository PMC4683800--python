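# nirpls

Chemometric calibration toolkit for online NIR monitoring of multi-phase
herbal extraction. Implements the complete workflow for quantifying
several ingredients simultaneously from 800–2200 nm absorbance spectra:

- **Sample-set partitioning** — Kennard–Stone max–min-distance split
  (e.g. 93 samples → 62 calibration / 31 validation at fraction 2/3).
- **Pretreatment ladder** — raw, Savitzky–Golay smoothing (9/11-point)
  and 1st/2nd derivatives, SNV, MSC, orthogonal signal correction (Wold's
  iterative variant), wavelet denoising (built-in periodized orthogonal
  DWT with soft universal thresholding), unit-norm normalization; all as
  composable fit/apply transforms with strict train/test hygiene.
- **PLS core** — NIPALS PLS1 with mean centering, leave-one-out
  cross-validation, PRESS-based latent-factor selection, and the
  RMSEC/RMSECV/RMSEP + R² metric suite.
- **Variable selection** — moving-window PLS scanning (window sizes
  13–41) with an accept/"inappropriate" verdict against the full-spectrum
  benchmark, and exhaustive synergy-interval search over all C(20, 3) =
  1140 combinations of equidistant subintervals ranked by RMSECV.
- **Assessment** — per-phase relative errors with round-half-up 2-decimal
  display, regression F test at df (1, n−2), and a pseudounivariate
  multivariate detection limit (reported in mg/mL and ppm).
- **Synthetic data** — a Beer–Lambert extraction-process generator
  (Gaussian pure-component bands, first-order kinetics with diminishing
  yield over three phases, dominant water band near 1950 nm, elevated
  noise in 2000–2200 nm, scatter/baseline artifacts), fully reproducible
  from one seed. Pre-generated 20- and 93-sample datasets ship under
  `fixtures/`.

The wavelength grid uses a half-open convention `[start, stop)` so that
800–2200 nm at 0.5 nm yields exactly 2800 variables, and the 20-way
equidistant split yields 70 nm subintervals (1010–1080 nm is interval 4,
etc.). See `docs/file_formats.md` for all file schemas.

## CLI

```sh
# generate a synthetic extraction run
nirpls simulate --out-spectra spectra.csv --out-references refs.csv --seed 1

# Kennard-Stone partition
nirpls split spectra.csv --out split.csv --fraction 0.6667

# full pipeline: split -> pretreatment ladder -> MWPLS -> SiPLS -> assessment
nirpls run --config examples/run_config.yaml --seed 1 --out-dir runs/demo
nirpls report runs/demo
```

Every artifact (split, per-analyte model JSON, interval ranking CSV,
`report.json`) lands in the run directory; reruns with the same config
and seed are byte-identical.

Library use mirrors the CLI:

```python
import nirpls as nl

dataset, refs = nl.simulate_dataset(nl.default_config(seed=1))
X, c, ids, dropped = nl.align(dataset, refs, "glycyrrhizic_acid")
split = nl.ks_split(X, 2 / 3, ids)
cal = [ids.index(s) for s in split.calibration_ids]
curve = nl.loo_cv(X[cal], c[cal], A_max=10)          # PRESS-based factor choice
result = nl.sipls_search(X[cal], c[cal], dataset.grid, 20, 3, A_max=10)
model = nl.build_final_model(X[cal], c[cal], result.best["intervals"],
                             result.best["n_factors"],
                             grid=dataset.grid, n_intervals=20)
```

## Notes

- The exhaustive searches are O(combinations × LOO folds); use the
  `thin` config (averaging adjacent grid points) for fast exploratory
  runs, as the tests do.
- A published per-sample relative-error benchmark table ships in
  `src/nirpls/data/` and validates the phase-mean arithmetic; one of its
  printed second-phase averages (4.42) disagrees with the mean of its own
  printed column (4.43) — the code reproduces the arithmetic, not the
  misprint.
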