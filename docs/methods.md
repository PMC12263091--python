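# Methods

## The problem

Point-scanning microscopes (confocal, scanning electron) trade
resolution, signal-to-noise, speed and sample preservation against one
another: acquiring at 4x finer pixel size costs roughly 16x the dwell
time and dose. Deep learning-based restoration sidesteps the trade-off
by training a network to map cheap low-resolution (LR), noisy
acquisitions to high-resolution (HR) targets. The practical obstacle is
training data: perfectly aligned real HR/LR pairs are hard to acquire,
so the LR half is synthesized from real HR images by a configurable
degradation operator, colloquially a *crappifier*.

## Crappification model

A crappifier is `noise(downsample(HR, s), theta)`:

- **Downsampling** is block averaging over `s x s` pixel blocks (area
  interpolation), the physically sensible model of acquiring the same
  field with `s`-times larger pixels. Sides not divisible by `s` are
  cropped bottom/right with a logged warning, keeping HR/LR geometry
  exact.
- **Noise is injected after downsampling.** The order is load-bearing:
  i.i.d. noise added before block averaging is suppressed by a factor of
  `s^2` in variance (the mean of `s^2` i.i.d. values), so noise-first
  degradation produces unrealistically clean LR training inputs. The
  package keeps the noise-first operator (`crappify_legacy_order`) only
  so the variance law is testable: on a constant image the pixel-variance
  ratio between the two orders converges to `s^2` (16 at `s = 4`), and
  the acceptance checks assert it lands in [12, 20] over 200 Monte-Carlo
  repetitions.
- **Per-image intensity.** Each training image draws its own noise
  intensity uniformly from `[intensity_low, intensity_high]`, so one
  trained model covers a range of acquisition qualities. Uniform is the
  minimal-assumption choice for an interval constraint.

Two noise families are built in; user families can be registered at run
time (the zero-intensity-identity contract is checked at registration).

- `additive_gaussian`: `x + N(0, sigma^2)` on the [0, 1] scale.
- `poisson`: intensity `I >= 0` acts as an inverse photon budget. Pixel
  `x` maps to `Poisson(x * G / I) * I / G` with photon gain `G = 255` by
  default. The draw is mean-preserving with variance `x * I / G`, so
  noise grows with both signal level (the shot-noise signature of
  point-scanning detectors) and intensity, and `I -> 0` is the
  deterministic limit. The gain pins "one photon" to one 8-bit grey
  level; any positive value works, it simply rescales the intensity
  axis.

Clipping to [0, 1] after noise injection is on by default (detectors
saturate). All pixel math in the package happens on float64 values
normalized to [0, 1]; integer bit depths exist only at the TIFF
boundary, which removes bit-depth ambiguity from losses and metrics.

## Datasets, tiles and leakage

Large mosaics are decomposed into a row-major grid of square tiles
(anchors at multiples of the stride; remainder pixels beyond the last
full tile are dropped with a logged count). Non-spatial axes (time,
depth, channel) unroll into *frames* of the same tile. Train/validation
splits operate on tile keys, never on frames: frames of one tile can be
nearly identical, and splitting them apart would leak training content
into validation. `ceil(val_fraction * n_tiles)` tiles go to validation.

Training samples are crappified **at access time**: every epoch the same
HR tile yields a fresh LR input (new intensity, new noise realization),
which multiplies the effective dataset size and reduces overfitting.
Validation samples instead pin the intensity to the interval midpoint
and reuse one fixed noise realization each epoch, so the validation loss
is comparable across epochs (a policy choice; random validation
degradation would add variance to checkpoint selection). Benchmark
datasets load real HR/LR pairs matched by identical basename across two
directories; no crappifier ever runs on that path.

## Noise-profile calibration

Given real pairs, the crappifier intensity is estimated rather than
guessed. The HR image is block-averaged into a "noiseless" LR and
subtracted from the true LR; the signed residual array is the *noise
profile*. Calibration minimizes the mean (over pairs) 1-D Wasserstein
distance between the residual-value distribution of the real LR and that
of a semi-synthetic LR generated at a candidate intensity. Only value
distributions are compared — the model assumes spatially independent
noise, so residual arrangement carries no information for this fit. The
Wasserstein distance is well defined for continuous values without
binning artifacts and varies smoothly with the parameter; a 64-bin
histogram L1 distance is available as an alternative.

Minimization is Bayesian optimization under a Matern-5/2 Gaussian
process with expected-improvement acquisition: 10 initial probes (the
two bound endpoints, which also guarantees the fit is never worse than
either endpoint, plus 8 seeded uniform draws), then sequential
acquisition to a default budget of 50 objective evaluations. The
acquisition candidate pool mixes global uniform draws with perturbations
around the incumbent so the minimum is localized finely. Every candidate
evaluation re-crappifies the pairs with the same fit-level seed (common
random numbers), making the objective a deterministic, smooth function
of the parameter; a per-candidate seed would leave realization jitter
between neighbouring candidates that degrades both the GP fit and the
final localization. Degenerate bounds (`lo == hi`) return that point
after a single evaluation.

At the sizes used in the tests (8 pairs, 256x256 LR = 524k residuals),
ground-truth parameters are recovered to well under 1% for both
families, comfortably inside the 15%/20% tolerances asserted, and the
optimizer's best objective matches or beats a 200-point grid search over
the same bounds.

## Architecture

`ResUNet` is an encoder/decoder with residual blocks
(conv-BN-ReLU-conv-BN plus identity shortcut), average-pool downsampling
with 1x1 channel widening between levels, nearest-neighbour upsampling
with 3x3 convolution and skip-connection concatenation on the way up,
and a sub-pixel (pixel-shuffle) head realizing the super-resolution
factor. `scale = 1` configures the same network for denoising. Defaults
(4 levels, blocks (3, 4, 6, 3), 64 base channels) give a ResNet-depth
encoder; the desk-scale runs in the tests use 2 levels and 8 channels.

Two choices matter for short training schedules:

- the head convolution is initialized near zero and the output is added
  to a bilinear upscale of the input, so an untrained model *is* the
  bilinear control and training learns a residual correction;
- the bilinear skip and the benchmark control share one interpolation
  routine (half-pixel centers), so no alignment-convention difference
  can masquerade as restoration quality.

The network and its training loss run on a small reverse-mode autograd
engine over numpy float64 (`scopesr.nn`): convolution via im2col,
batch normalization composed from differentiable primitives, Adam. All
operations are deterministic, so seeded training histories are
bit-reproducible on one machine. The engine is sized for desk-scale
experiments, not GPU-scale production training.

`count_trainable_layers` reports the number of parameter-bearing
convolution layers (one per weight tensor of rank >= 2; normalization
scale/shift vectors are not layers) as a depth-class diagnostic.

## Loss and metrics

Training minimizes `alpha * (1 - MS-SSIM) + (1 - alpha) * L1_G` with
`alpha = 0.84`, where `L1_G` is the mean Gaussian-window-filtered
absolute error (11x11 window, sigma 1.5 — the same window as SSIM) and
MS-SSIM uses the canonical 5-scale weights (0.0448, 0.2856, 0.3001,
0.2363, 0.1333), `K1 = 0.01`, `K2 = 0.03`. Images too small for five
dyadic scales reduce the pyramid depth automatically (weights
renormalized, logged); odd intermediate sizes drop the last row/column
before pooling. Inputs smaller than the 11-pixel window are rejected.

Benchmarking computes per-image PSNR (`10 log10(range^2 / MSE)`,
`data_range = 1`, identical images report +infinity) and single-scale
SSIM for both the model and the bilinear control, then mean uplifts and
two-sided paired t-tests. All-zero paired differences degenerate to
`t = 0, p = 1` with a warning, keeping reports totally ordered.
`relative_uplift` compares two methods' uplifts as a fraction of the
baseline and refuses a zero baseline (report the absolute difference
instead). Adam with learning rate 1e-3 is the training default; the
desk-scale runs use 2e-3, chosen for the 5-epoch schedule.

## Synthetic fixtures

The fixture generator emulates the geometry of paired electron
microscopy sets (e.g. 512x512 HR at 2 nm against 128x128 LR at 8 nm,
scale 4): flat background (default 0.15) plus non-overlapping bright
disks, dark-lumen rings (vesicle-like) and thin filaments
(membrane-like), rasterized at 2x supersampling and block-averaged so
edges are anti-aliased rather than degenerately sharp. Structure
contrast is at least 0.3 above background so restoration uplifts are
measurable by small models. LR partners come from the crappifier
(default Poisson, intensity uniform on [5, 15] — shot noise being the
realistic family for point-scanning data) and every per-image intensity
is recorded in a manifest, closing the loop for calibration-recovery
tests.

What the fixtures do *not* emulate: real EM texture, point-spread
blurring, spatially correlated or fixed-pattern noise, registration
error between the pair halves. Passing tests therefore demonstrate that
the machinery is correct under the package's own noise model, not that a
desk-scale model generalizes to real micrographs.

## Problem sizes and numerical choices

The test suite and the acceptance script run everything at desk scale,
chosen as the smallest sizes at which each property is statistically
unambiguous: 200 Monte-Carlo repetitions for the variance-order law on a
512x512 constant image; 8 pairs of 1024x1024 HR for calibration
recovery; 64 training + 16 held-out fixture pairs (HR 128, scale 4) with
a 2-level, 8-channel network trained 5 epochs (batch 4) for the
end-to-end benchmark; 100 seeds for the split-leakage property. Under
these conditions the trained model beats the bilinear control by about
+1 dB PSNR and +0.2 SSIM with paired-t p-values far below 0.05.

Ties and degenerate inputs: empty images, degenerate value ranges,
val_fraction outside [0, 1), non-positive scales, color TIFFs, unpaired
basenames and geometry mismatches all raise with messages naming the
offending quantity. Stitching requires full coverage and averages
overlaps per pixel.

## Known limitations

- The autograd engine is single-threaded numpy; wall-clock scaling
  beyond desk-scale images calls for a GPU framework.
- Only single-parameter noise families are calibrated; joint fitting of
  mixed families is out of scope.
- Spatially structured noise is explicitly not modelled.
- TIFF is the only container format; vendor formats need conversion.
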