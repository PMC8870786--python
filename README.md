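# trabkit

2D trabecular-bone microarchitecture quantification for µCT-like and
ultra-high-field-MRI-like grayscale slices:

- **Segmentation** — automatic local (sliding-window Otsu) bone/marrow
  binarization robust to shading gradients, plus three-phase
  bone/marrow/air labelling for CT-like images and air-bubble volumetry.
- **Aperture-map histomorphometry** — per-pixel maximal-inclusion-disk
  diameters (local thickness) with sub-pixel radii, yielding BVF, Tb.Th,
  Tb.Sp and Tb.N = BVF/Tb.Th.
- **Orientation analysis** — multi-scale Hessian (σ = 1–5 px,
  γ-normalized max-response scale selection) per-pixel strut orientation,
  the pooled orientation distribution over bone pixels, a
  two-Gaussian-plus-linear-baseline model fit, and the metrics Tb.OrP,
  Tb.OrS (ND when no secondary mode is detected) and Tb.Int — the SD of
  the whole orientation distribution about the principal orientation.
- **Resolution degradation** — integer block-merging (factor 2/3) that
  models partial-volume averaging and scales the pixel spacing.
- **Registration** — slice-to-stack matching and 2D affine registration
  (Pearson correlation or mutual information for multimodal pairs) with
  per-slice correlation scoring.
- **Agreement statistics** — Kruskal–Wallis, OLS R², Bland–Altman bias
  and limits, ICC (two-way absolute agreement, single measurement) with
  low/good/excellent bands, and per-sample maximum percentage
  differences.
- **Phantom generator** — synthetic strut networks with exact,
  generator-bookkept ground truth (BVF, nominal thickness/spacing,
  per-pixel orientation, bubble volume), used throughout the test suite
  in place of unavailable cadaveric data.

Supported raster formats: TIFF (spacing from resolution tags), NIfTI-1
and MetaImage (`.mhd`/`.raw`). All lengths are millimetres, all angles
degrees; images are row-major with angles measured counter-clockwise
from the +x (column) axis.

## Tests

```sh
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance criteria: reference
worked values, the exhaustive aperture-map oracle comparison,
phantom parameter-recovery batteries, the degradation monotonicity
property, registration translation recovery, and the Kruskal–Wallis
type-I-error calibration.

## Command line

```sh
trabkit phantom  --spec spec.json --out phantom.tif --truth truth.json
trabkit segment  --in slice.tif --out mask.tif --modality CT_LIKE [--three-phase]
trabkit morpho   --in mask.tif --out report.csv
trabkit orient   --in slice.tif --mask mask.tif --out orientation.json
trabkit degrade  --in slice.tif --out degraded.tif --factor 2
trabkit register --moving mr.tif --stack uct_stack.tif --out reg.json --metric mi
trabkit stats    --in metrics_long.csv --out agreement.csv
```

Every flag can also come from a JSON config (`--config cfg.json`,
flat keys matching the flag names); explicit flags win. Reports write ND
for an undetected secondary orientation.

## Conventions worth knowing

- Aperture map: disk centres live on the half-pixel lattice and the
  maximal radius is the distance to the out-of-phase region with pixels
  modelled as unit squares; a width-w bar therefore measures exactly
  w·spacing for even and odd w. Outside the frame the phase is
  continued; `periodic=True` treats the mask as one tile of a periodic
  pattern.
- Orientation histograms exclude a margin of 3× the largest Hessian
  scale along the frame (smoothing kernels see fabricated content
  there); disable with `exclude_border=False`.
- The orientation model is fitted with free component amplitudes by
  default (`free_amplitudes=False` recovers the strict unit-area form).
  Tb.OrS is reported both as the raw secondary mean and as the
  difference from the principal orientation.
- Air-bubble volumes are mm³ when a slice thickness is available,
  otherwise in-plane mm² flagged as an area.
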