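# lungdot

Adhesion pulmonary-nodule detection for 2D lung-CT slices.

Nodules appear as bright, roughly circular blobs; vessels as bright lines.
A multiscale Hessian-eigenvalue *dot filter* enhances blob-like structures
and suppresses lines — but vessel ends and crossings are blob-like too and
come out as false positives. `lungdot` separates them by extracting the
vessel centerline (two-subiteration thinning with spur pruning) and
measuring, for each suspect region, the perpendicular distance `d1` from
its center of mass to the locally fitted centerline and the minimum
distance `d2` to any centerline pixel:

| rule (threshold t = 1.5 mm) | label |
| --- | --- |
| `d1 > t` | `attached_nodule` |
| `d1 <= t`, `d2 > t` | `vessel_end` |
| `d1 <= t`, `d2 <= t` | `vessel_intersection_or_end` |

All test inputs are synthetic: a phantom generator renders Gaussian
dot/line fields, single/Y/X vessel models, and attached-nodule scenes with
known ground truth, so no CT data is required.

## Package layout

- `lungdot.phantoms` — Gaussian dot/line renderers, the five-dot/three-line
  panel, vessel models (`single`, `Y`, `X`), attached-nodule scenes.
- `lungdot.preprocess` — gray-threshold soft-tissue extraction (default
  threshold 130 on the 8-bit scale) and Gaussian pre-smoothing.
- `lungdot.dotfilter` — Hessian fields, the blob response
  `w_d = λ2²/|λ1|` (both eigenvalues negative, |λ1| ≥ |λ2|), the geometric
  scale ladder `σ_k = r^k · r0/3` with `r = (r1/r0)^(1/(N−1))`, multiscale
  maximum with σ² normalization, and suspect-region extraction.
- `lungdot.centerline` — `N(p1)`/`T(p1)` neighborhood operators,
  two-subiteration thinning, endpoint (burr) pruning with long-branch
  protection, gap bridging across removed suspect regions, total-least-squares
  local line fits and their replicate deviations.
- `lungdot.classify` — `d1`/`d2` measurement, the decision rules, and the
  full pipeline (`run_pipeline`).
- `lungdot.cli` / `lungdot.io` / `lungdot.config` — command line, PNG/TIFF
  (and optional DICOM) I/O, JSON/CSV reports, YAML/JSON configuration.

Coordinates are `(row, col)`, 0-based, pixel centers on integers. Lines
`αx + βy + γ = 0` use `x` = column, `y` = row. Physical pixel spacing
defaults to 0.6 mm/px (isotropic).

## CLI

```sh
# render phantoms
lungdot phantom --kind attached --size 160 --offset-px 5 \
    --out attached.png --truth truth.json
lungdot phantom --kind X --out crossing.png

# full detection pipeline -> JSON (and optional CSV) report
lungdot detect --input attached.png --r1-mm 9 --out report.json \
    --csv report.csv --save-intermediates artifacts/

# thin a 0/255 mask to its pruned skeleton
lungdot skeletonize --input crossing.png --prune 8 --out skeleton.png
```

`detect` accepts a YAML/JSON config file (`--config`) overridable by flags;
unknown config keys are rejected by name. Exit codes: 0 success, 2 bad
arguments/config, 3 I/O failure.

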