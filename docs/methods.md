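# Methods

## Problem and approach

The target structure is the TMJ articular disc on sagittal proton
density-weighted MR slices: a biconcave, low-signal band between the
mandibular condyle and the temporal fossa, often displaced anteriorly in
temporomandibular disorders. Segmentation is posed as per-pixel binary
classification. Three convolutional encoder-decoder families are built
and compared under identical training conditions; the package's job is
to make that comparison reproducible, from data generation through the
statistical test.

## Network families

All three map a grayscale patch to a same-sized foreground-probability
map through a 1-channel 1x1 convolution + sigmoid head, and are built
from one spec (`family`, `input_size`, `depth`, `base_filters`,
`kernel_size`, `dropout_rate`, `seed`). Input sides must be divisible by
`2^depth` so pooled sizes stay integral.

* **3DiscNet** (asymmetric encoder-decoder). Encoder: `depth` stages of
  conv/ReLU with dropout behind both the convolution and the 2x2 max
  pooling; filters double per stage. Decoder: `depth - 1` learned
  upsampling stages (2x2 stride-2 transposed convolution + conv/ReLU)
  and one final *non-learned* 2x nearest-neighbour upsampling + conv.
  The published description fixes the asymmetry, the dropout placement
  and rate (0.3), and the sigmoid head, but the exact stage/filter
  schedule is given only in a figure we could not transcribe; the
  schedule above is therefore a documented reconstruction, and the
  builder is config-driven so any other reading is expressible.
* **U-Net.** Symmetric; two conv/ReLU per stage; transposed-convolution
  upsampling; each decoder stage concatenates the mirrored encoder
  feature map (doubling its channel count); one dropout at the
  bottleneck, matching the original's contracting-path placement.
* **SegNet-Basic.** Constant filter width; encoder stages are
  conv/ReLU/pool where each pooling records the argmax position of every
  2x2 window; the decoder upsamples *only* by scattering values back
  through those indices, then convolves. No skips, no learned
  upsampling, and — following the original design — no dropout; the
  sigmoid head replaces the original soft-max. Pooling ties break to the
  first occurrence in row-major order, which makes stored indices (and
  therefore whole runs) reproducible.

Weights are Glorot-uniform from the spec seed; biases start at zero.
Batch normalization is deliberately absent (not part of the reference
descriptions used). Checkpoints are `.npz` weights plus a JSON spec, so
they are self-describing.

The layers live in `discseg.nn`: NumPy forward/backward for same-padded
convolution (sum of shifted matrix products), 2x2 stride-2 transposed
convolution, max-pool-with-indices / max-unpool, nearest upsampling,
inverted dropout, ReLU, sigmoid; Adam; BCE and soft-Dice losses. Each
backward is verified as the exact adjoint of its forward map in float64.
One caution for anyone extending the engine: finite-difference checks
through ReLU report spurious error where pre-activations are exactly
zero (common right after unpooling, whose outputs are mostly zeros);
the analytic subgradient uses ReLU'(0) = 0, the usual convention.

## Training

Adam, learning rate 1.0e-3, applied identically to all three families
so the comparison is not confounded by per-model tuning; the nominal
epoch budget is 2000, reducible. The loss is mean per-pixel binary
cross-entropy (probabilities clipped at 1e-7), the canonical pairing
with a sigmoid pixel head; soft Dice is available via config but is not
the default, so the Dice *metric* stays independent of the objective.
Batch size defaults to 8. Shuffling, dropout, and initialization all
derive from explicit seeds, so identical configs give bit-identical
loss curves. The test split never influences training; validation loss
is logged only if a separate validation set is passed.

## Phantom cohort

The generator emulates the *statistical skeleton* of a clinical TMJ
dataset: 10 "patient" (displaced) and 10 "control" (normal) subjects,
4–7 slices each (both jaw states and sides), yielding ~110 slices per
cohort. Per slice it renders, at 512x512 by default (geometry scales
linearly with image size):

* a dark biconcave disc — an outer ellipse minus two symmetric
  elliptical "bites" above and below its long axis — at intensity ~55
  against a ~150 background, rotated per subject;
* a bright condyle-like ellipse (~205) below the disc that translates
  forward/down in the open-jaw state, and a brighter fossa band above;
* degradation: low-order polynomial bias field (8% of range), Gaussian
  blur (sigma 1.2 px), additive Gaussian noise (SD 6 on 0–255), then
  clipping to [0, 255].

The mask is the exact pixel support of the disc before degradation,
written as an RGB PNG with foreground exactly (255,255,255) — the
white-fill convention used by expert annotations made in image editors.
Displaced subjects shift the disc 30 px (at 512 scale) anteriorly;
alternate patients are flagged "with reduction" and return the disc to
the normal position when the jaw opens. Disc appearance statistics
(size, contrast, noise) are free parameters documented here, not claims
about clinical data: real discs have far fuzzier borders, neighbouring
structures of similar intensity, and scanner-dependent contrast, so a
network's success on phantoms shows the pipeline learns and evaluates
correctly — not that it would reach the same accuracy clinically.

## Preprocessing conventions

* Grayscale reading: PNG/JPEG via Pillow (RGB converted by ITU-R 601
  luminance); single-frame DICOM via pydicom with per-slice min–max
  scaling to 0–255 (no windowing information is assumed).
* Mask decoding: foreground iff all three channels >= 128. The
  threshold is deliberately far from 255 so masks that passed through
  JPEG recompression still decode to within ~2% of the original fill.
* ROI: a fixed 161x184 box (for 512x512 input; scaled proportionally
  otherwise), placed at the image center by default. Automatic disc
  localization is out of scope; the box is configuration.
* Patches: ROI crops resized to 224x256 by default — bilinear for
  images (then scaled to [0,1]), nearest-neighbour for masks so labels
  stay strictly binary. Coordinates are 0-based, row-major, half-open.
* Splits: `floor(0.8 n)` training samples under a seeded uniform
  permutation, per stratum (normal / displaced / both-as-one-pool);
  with the cohort sizes 111, 106 and 217 this floor rule yields 88/23,
  84/22 and 173/44.

## Evaluation and statistics

Metrics are exact integer pixel-set arithmetic per test image at
network resolution, then aggregated: Dice, sensitivity, PPV; Dice
equals the harmonic mean of the other two whenever both are defined.
Probability maps binarize at 0.5 with a `>=` convention. An empty
prediction makes PPV the undefined 0/0 form; it is recorded as 0 with
an explicit flag so group means remain computable — a conservative
choice that penalizes the model. An empty *ground-truth* mask is an
error by construction (only slices with a visible disc are annotated).
Summaries use the sample (n-1) SD; box-plot statistics use quartiles
with 1.5xIQR whiskers and outliers beyond them.

Model comparison: classical one-way ANOVA (implemented directly,
cross-checked against an independent reference in tests) and Tukey HSD
via statsmodels' Tukey–Kramer implementation (valid for unequal test
sets), alpha 0.05 by default. Letter groups come from the
insert-and-absorb compact-letter-display algorithm, lettered in order
of descending group mean. Per-image values are treated as independent
observations; slices from the same subject are in fact correlated, a
limitation noted, not corrected.

## Desk-scale sizes

The full-scale defaults (512x512 slices, 224x256 patches, depth-4
networks, 2000 epochs) are impractical for routine verification, so
tests and `scripts/acceptance.py` run a reduced preset chosen once:
128x128 slices, 64x64 patches, depth 2, 8 base filters, 150 epochs,
~113-slice cohort. Under these conditions the reduced 3DiscNet and
SegNet-Basic reach mean test Dice >= 0.8 and training loss decreases
and converges for all three families. No qualitative ranking between
the families is asserted on phantoms: which architecture wins is a
property of the data, and phantom discs are far easier than clinical
ones (U-Net, with the most capacity, tends to win here).

## Known limitations

* The phantom is a geometric emulation, not an MRI simulation (no
  Rician noise, no partial-volume effects, no 3D consistency).
* 3DiscNet's concrete layer schedule is a reconstruction (see above).
* Metrics are computed at network resolution, not mapped back to the
  original 512x512 grid; the comparison is internally consistent.
* The statistics treat slices as independent; a mixed-effects model
  with subject as a random effect would be the stricter analysis.
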