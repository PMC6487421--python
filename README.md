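# irspec-calib

Multivariate calibration of ATR-IR spectra against reference-method
concentrations, built as a reusable chemometrics pipeline:

1. **SNV preprocessing** — per-spectrum standard normal variate transform
   (removes additive baseline offsets and multiplicative scatter exactly).
2. **Kennard-Stone splitting** — deterministic greedy max-min Euclidean
   selection of a representative calibration set (default 158 of 198).
3. **Hybrid PLS / LS-SVM regression** — single-response NIPALS partial least
   squares extracts latent variables; a least-squares support vector machine
   with a Gaussian RBF kernel, `K(u,v) = exp(-||u-v||² / 2σ²)`, regresses the
   response on the scores. Training solves one linear saddle-point system.
4. **Validation** — PRESS/r²/Q² metrics, leave-one-out and leave-many-out
   (20%) cross-validation, PRESS-based latent-variable selection, external
   test-set validation, and a y-permutation (y-randomization) test.
5. **Synthetic data** — a generator of ATR-IR-like spectra (overlapping
   Gaussian bands, per-sample baseline/scatter corruption, interferents, a
   constant aqueous-matrix background, additive noise) plus a linear
   reference-method absorbance simulator, so the whole pipeline is testable
   end to end without laboratory data.

## CLI

Each stage is a subcommand; `run` chains them from one YAML config.

```bash
# full pipeline (generates synthetic data, writes artifacts + report)
irspec-calib run --config pipeline.yaml

# stage by stage
irspec-calib generate   --config synth.yaml --out spectra.csv --truth truth.csv --aas aas.csv
irspec-calib preprocess --in spectra.csv --out spectra_snv.csv
irspec-calib split      --in spectra_snv.csv --n-cal 158 --out split.json
irspec-calib fit        --spectra spectra_snv.csv --response aas.csv \
                        --split split.json --n-lv 3 --out model.json
irspec-calib validate   --model model.json --spectra spectra_snv.csv \
                        --response aas.csv --split split.json \
                        --permutations 100 --seed 1 --out report.json
```

A minimal `pipeline.yaml`:

```yaml
synthetic:
  n_samples: 198
  conc_range: [0.5, 25.0]
  seed: 1
n_cal: 158
lv_range: [1, 2, 3, 4, 5, 6, 7, 8, 9, 10]
n_permutations: 100
seed: 1
output_dir: runs/demo
```

Omit `synthetic:` and set `spectra_path:` / `response_path:` to run on CSV
inputs instead (first row wavenumbers, first column sample ids). Single
spectra in plain-numeric JCAMP-DX are also readable
(`irspec_calib.read_jcampdx`).

All randomness flows from the single `seed`; re-running an identical config
byte-reproduces every artifact (spectra, split, model and report JSON).

## Report schema

`report.json` contains `per_lv` (per latent-variable count: `prediction`,
`loo`, `lmo`, each with `r_squared`, `press`, `rmse`, `n`), `chosen_lv`,
`external` (same metric fields), `permutation` (observed r², permuted
r²/Q²_LOO/Q²_LMO distributions, exceedance) and `hyperparameters` (γ, σ²
per LV, split sizes, seed). `report.txt` renders the per-LV table as
aligned text.
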