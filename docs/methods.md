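# Methods

This note records the models the package implements, the defaults and the
reasoning behind the open design choices, and what the synthetic fixtures
do and do not demonstrate.

## Outcomes and conservation

Every pathway reports the same record: %-G in [0, 100] and GV/FV/TV in
mL with GV + FV = TV. Wherever a total is decomposed by a percentage the
fat volume is computed as `FV = TV − GV` rather than `TV·(1 − %-G/100)`;
the two are identical in exact arithmetic, but the subtraction form keeps
the conservation identity exact in floating point (the invariant is
enforced at construction with 1e-9 relative tolerance).

## Metadata ingestion

The eleven acquisition parameters of the linear model are read from a
DICOM header through a name→tag map. Standard tags are used where DICOM
defines one (kVp, body-part thickness, compression force, filter and
anode material, sensitivity); the vendor-specific remainder defaults to a
private-group dialect and every entry is overridable from JSON, because
the tags genuinely differ between scanner models. Physical units for the
dose, mean-intensity, "thresh" and sensitivity headers are not defined by
the model; they are opaque raw values passed through unchanged.
Thicknesses are standardized to mm on read; a sidecar may declare a cm
dialect, which is converted and logged. The pixel-area→mL factor (9.96
for the original imager geometry) absorbs all remaining unit conversion
and is configuration, with the convention that it multiplies pixel count
× thickness-in-mm directly.

Synthetic fixtures use a raster (`.npy`/PNG/TIFF) plus JSON sidecar
carrying the same fields; a minimal generated DICOM exercises the DICOM
path in tests.

## HSM segmentation

* ROI: largest connected component above a background level, with an
  optional chest-wall column margin (no pectoral-muscle model).
* Threshold: the historical workflow is analyst-interactive and
  irreproducible by construction, so the default programmatic stand-in is
  Otsu's criterion computed directly on the (value, count) histogram:
  between-class variance `w0·w1·(μ0−μ1)²` evaluated at every cut, lowest
  maximizer on ties. A `fixed:<value>` strategy is available. Integer
  images use exact integer bins; float images use 256 uniform bins with
  bin centers as representative values.
* Polarity and ties: glandular is the bright class on raw mammograms and
  pixels exactly at the threshold are glandular (closed lower bound);
  a flag handles inverted dialects.

## Linear %-G model

The twelve coefficients are frozen defaults matching the published fit
and live in a versioned JSON schema because they are specific to the
scanner family that produced the training images. The raw linear score
can leave [0, 100]; clamping to the percent range is on by default (with
a logged warning), and volume decomposition deliberately rejects
out-of-range inputs so silent repair cannot happen downstream. The model
is evaluated as a plain ordered sum; agreement with a compensated
(`math.fsum`) oracle to 1e-12 relative is part of the acceptance surface.

## MRI two-Gaussian decomposition

The fit target is the binned histogram (curve fitting), not per-voxel EM:
it is deterministic for fixed bins and matches how such histograms are
analysed with peak-fitting software. Defaults: 256 bins spanning the
masked intensity range; auto-initialization with means at the weighted
25th/75th percentiles, σ = range/8, amplitudes from local histogram
height; bounded trust-region least squares (amplitudes ≥ 0, widths > 0,
means within one range-width of the data) with up to 5 seeded jittered
restarts. No baseline/offset term — the two-compartment assumption is
taken literally, and lack of fit shows up in the reported RSS.
Non-convergence is reported honestly (`converged=False`), never raised
from the optimizer loop; composition refuses unconverged fits.

A fit is flagged *degenerate* (warning, not error) when one peak carries
under 1% of the total area or the two means are closer than the larger
width — both signatures of a single-compartment histogram split
arbitrarily. Gland-peak assignment is a polarity rule (3DGRE: low mean;
STIR: high mean) with an explicit override that logs.

Recovery accuracy: with peak separation ≥ 3σ the mean absolute
gland-fraction error over seeded 100k-voxel histograms is well under
0.02. Below ~2σ separation the two-peak decomposition becomes poorly
identified and the fraction estimate degrades smoothly; this regime is
documented, not asserted.

Breast-mask generation from raw MRI is out of scope (vendor workstation
territory); masks are inputs. Multi-acquisition averaging (e.g. repeated
STIR runs) is left to the caller, which accepts one volume.

## Concordance statistics

Paired-*t* mean differences per method pair with Benjamini–Hochberg FDR
across the family replace a Tukey-style range test: the same subjects
underlie every method column, so paired contrasts are the defensible
error model, and FDR is applied to the pair family either way. With zero
within-pair variance the CI degenerates to the constant difference and p
is 0 or 1 by the sign of the difference. Correlations are
pairwise-complete Pearson with a 3-pair minimum; cells below it are NaN,
never imputed. Statistics require ≥ 3 complete rows.

## Synthetic fixtures

The generators emulate the structure the estimators assume: an elliptical
(2D) or ellipsoidal (3D) two-compartment region with Gaussian intensity
noise per class, class membership planted by **exact count** so the true
fraction is exact at pixel/voxel resolution (this is what makes
segmentation tests sharp), and protocol-correct intensity ordering for
MRI. Mammogram phantoms also emit self-consistent acquisition metadata:
the anatomical-mean-intensity header is solved from the default
coefficients so the linear pathway tracks the planted fraction (emulating
a unit whose exposure settings encode density), the Raddose field is the
truth plus ~1.5-point noise, and the pixel→mL factor is calibrated so the
phantom breast totals 800 mL — a realistic premenopausal breast volume.
Default conditions: 256×256 phantoms (48×64×64 MRI), gland/fat means
800/400 (protocol-ordered 400/1000 and 900/200 for MRI), class SD 40,
52 mm compression, 1 mm isotropic voxels.

Measure tables draw each outcome from an equicorrelated multivariate
normal across methods (default ρ = 0.9) with per-method offsets, around
population-plausible scales (%-G 35 ± 8, TV 800 ± 150 mL).

What the phantoms do **not** contain: anatomical texture, projection
physics, bias fields, and Rician MRI noise (Gaussian per class is used;
there is no principled parameterization to copy for this design, and at
the SNRs emulated the difference is second-order). Passing recovery tests
therefore bounds *algorithmic* error under the two-compartment model, not
error on clinical images.

## Problem sizes and determinism

Validation runs use 128×128 mammogram phantoms (≈9,100-pixel ROI), 100k
sampled voxels per MRI histogram, 50-histogram recovery batches, and
200-replicate coverage simulations — sizes at which the discreteness of
a single pixel (~0.01 percentage points) is visible in the error floor.
Every generator and fit is a pure function of an explicit seed; the CLI
threads one seed through a run and the whole
synth → estimate → concordance chain is byte-deterministic, which the
test suite asserts by comparing output files across runs.

## Known limitations

* The linear model is evaluated, never refitted; its coefficients do not
  transfer across scanner brands without recalibration.
* The 2D pathways inherit mammography's projection bias (differential
  compressibility of fat vs gland); nothing corrects for peripheral
  breast thickness.
* The two MRI protocols are treated independently; no cross-protocol
  fusion.
* The Otsu stand-in for analyst thresholding is a different estimator
  than a human reader; on well-separated phantoms they agree, on clinical
  images they need not.
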