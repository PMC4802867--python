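# discgabor

Unsupervised localization and segmentation of intervertebral discs (IVDs) in
mid-sagittal T2-weighted spine MRI, driven entirely by a 2-D Gabor filter
bank — no training data required.

The pipeline:

1. **Gabor filter bank** — 16 directions x 5 scales of complex Gabor kernels
   (31x31, upper frequency pi/2, frequency spacing 2^(1/4), anisotropic
   Gaussian envelope with sigma_y = 2 sigma_x), applied with same-size FFT
   convolution and reflective padding.
2. **Spinal curve detection** — a direction-contrast feature image
   (near-vertical minus near-horizontal response means, clipped at zero)
   highlights the spinal column edges; a banded cumulative profile locates
   the column, and a row-by-row ridge tracker traces the left/right edges.
3. **Disc localization** — the disc-direction feature image is median
   filtered with a 44/17 elliptical template; row/column profiles restricted
   to the spinal band yield candidate centers, filtered by anatomical priors
   (25–60 px vertical spacing, common vertical line), boxed by profile
   minima/zeros, and refined by feature-map centroids.
4. **Disc segmentation** — per disc, a candidate region is built from
   quadratic curves fitted to the binarized maximum direction-mean feature
   map; a local grayscale threshold is found by area-constrained bisection
   from an Otsu initialization (≤ 30 iterations), followed by morphological
   cleanup (hole fill, open, 8-neighbor majority rule, largest component).
5. **Metrics** — localization accuracy, Dice/sensitivity/specificity, and
   Euclidean center-distance statistics (px and mm).

Because the original patient data are private, the package ships a
**phantom generator** (`discgabor.phantom`) that renders sagittal spine
phantoms — a bright, optionally curved spinal column band, stacked
elliptical discs with endplate shells, darker vertebrae, noise and bias
field — with exact ground truth (masks, centers, angles, band edges). All
evaluation and acceptance testing runs against these phantoms.

## CLI

```bash
# generate a phantom with ground truth
discgabor phantom --seed 3 --noise 0.05 --out ph/

# run the pipeline on a slice (PNG/TIFF/NIfTI/DICOM)
discgabor run ph/phantom.png --out results/
# -> centers.csv, labels.png (16-bit label mask), overlay.png

# compare two label masks
discgabor evaluate results/labels.png ph/truth_labels.png

# phantom evaluation suite (deterministic for a given seed)
discgabor suite --n 20 --seed 1 --compare-box
```

Every stage parameter can be overridden with a flat `key = value` config
file passed as `--config` (see `discgabor.pipeline.PipelineConfig` for the
keys; defaults reproduce the reference settings).

## Library

```python
from discgabor import (GaborBankParams, build_bank, apply_bank,
                       detect_spine, localize_discs, segment_disc)
from discgabor.phantom import PhantomSpec, generate
from discgabor.pipeline import run_on_array

truth = generate(PhantomSpec(seed=0))
result = run_on_array(truth.image)
for det, seg in zip(result.detections, result.segmentations):
    print(det.center, det.angle, seg.mask.sum())
```

Coordinate convention: `(row, col)`, 0-based, rows increase superior →
inferior. Kernel direction `theta_mu = mu*pi/S` is the orientation of the
sinusoidal axis, so `theta ≈ 0` responds to vertical structures and
`theta ≈ pi/2` to horizontal ones (disc long axes). Positive disc angles
tilt the disc's right end inferiorly.

## Tests and acceptance

```bash
python -m pytest -q            # full suite (~2 min single core)
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

`tests/test_acceptance.py` implements the acceptance criteria (kernel
formula oracle, brute-force convolution oracle, exhaustive Otsu oracle,
profile monotonicity, 20-phantom localization/segmentation recovery, the
feature-restriction ablation, threshold termination, metric identities).
The acceptance script reruns the 20-phantom suites (noise-free and at 5%
noise) and prints the aggregate metrics; since the reference clinical
evaluation was conducted on a private patient dataset, there are no numeric
acceptance targets and the emitted JSON object is empty.
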