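# Methods

## Scope and engine

`cervnet` implements the shuffle-style inverted residual network family with
optional SE/SK channel attention, an analytic convolution cost model, a
reproducible data pipeline and a multiclass evaluation suite.  The neural
network layer (`cervnet.nn`) is a self-contained NumPy engine: each layer is a
module with an explicit forward and backward pass, composed manually inside the
residual units.  There is no tape autograd; correctness of every layer and every
composite block is pinned by central-difference gradient tests (absolute
tolerance 5e-6, observed errors ~1e-8).  Activations and weights are float64.

## Architecture

Stem: 3×3 conv, stride 2, BN, ReLU; 3×3 max pool, stride 2, padding 1.  Three
stages, each one stride-2 downsample unit followed by (repeat−1) stride-1 split
units.  Head: 1×1 conv + BN + ReLU, global average pool, optional dropout
(default 0), linear classifier.

* Stride-1 unit: split C channels into ⌊C/2⌋ identity channels and the rest;
  transform the second half by 1×1 conv/BN/ReLU → k×k depthwise conv/BN →
  [attention] → 1×1 conv/BN/ReLU; concatenate; channel shuffle with G=2.
  Output shape equals input shape; the unit requires even C.
* Stride-2 unit: no split; branch A = depthwise stride-2 conv/BN → 1×1
  conv/BN/ReLU, branch B = 1×1 conv/BN/ReLU → depthwise stride-2 conv/BN →
  [attention] → 1×1 conv/BN/ReLU; concatenate to `channels_out`; shuffle G=2.
  The stride-2 unit is not depicted in the source description of the stride-1
  unit; it follows the same design family, which is the only staged completion
  consistent with the split unit.
* Channel shuffle: output channel i·G+g = input channel g·n+i (n = C/G); a pure
  permutation, inverted by shuffling with n groups.

Default backbone: stem 24, stage repeats (4, 8, 4), stage channels
(116, 232, 464), final 1024, 5 classes — the canonical 1.0× schedule for this
unit family (1.26 M parameters, ~144 M multiplications at 224×224).  All widths
are configurable through `ModelConfig`.

### Attention

Attention is applied to the depthwise-convolution output inside each unit (both
unit types), matching the stated placement "inserted into the depth-separable
convolution".

* SE: squeeze = global average pool (exact per-channel spatial mean); excite =
  sigmoid(W₂·relu(W₁·z)) with bottleneck width ⌈C/r⌉.  The excitation pair
  (ReLU then sigmoid, two linear maps) is the canonical completion of
  "activation function and linear mapping"; it is configuration, not an
  assertion about the source's exact choice.
* SK: branch 1 = depthwise-separable 3×3 conv at dilation 1, branch 2 at
  dilation 2 (receptive field 5, padding 2), each stage followed by BN; fused
  sum feeds a shared bottleneck (width ⌈C/r⌉, ReLU) and two per-branch scoring
  heads.  Branch weights are normalised per channel by softmax across the two
  branches (default; weights are convex, w₁+w₂=1).  An independent-sigmoid mode
  is provided because the phrase "computed similar to the SE channel attention"
  also admits that literal reading.  The dilated branch requires spatial dims
  ≥ 2; smaller maps raise a shape error.
* Reduction ratio r defaults to 16 and is exposed in `AttentionConfig`; the
  source never states r.

Both attention modules expose a diagnostic override (`gate_override`,
`weight_override`) that pins gates/weights to constants; this is used by tests
to verify the identity and single-branch limits and is never active in
training.

## Cost model

Multiplications only (no additions, no bias), the convention under which the
separable/dense ratio collapses to 1/C_out + 1/N²: dense N×N conv on an output
grid W×H costs W·H·C_in·C_out·N², the separable factorisation
W·H·C_in·N² + W·H·C_in·C_out.  Strided convs use the output grid for W, H.
`reduction_ratio` returns an exact `Fraction`.  `model_complexity` runs one
recorded forward pass so counts reflect true activation shapes at every layer
(branching, strides, pooling); BN layers contribute parameters (2C) but no
multiplications.  Serialized size is total_params × 4 bytes (single precision,
configurable) — a parameter-file size, not peak memory.

## Data pipeline

Image-folder layout `root/<label-int>/*.jpg|png` with labels 0–4 (normal, LSIL,
HSIL, cervical cancer, cervical neoplasm).  The clinical reference inventory
(2352/780/2532/408/924 images; 6,996 total from 1,189 patients) is recorded as
`TABLE1_COUNTS` and reproducible at any scale by the generator.

* Split: stratified 90/10 by default.  Per class, train counts are
  round-half-up(count·0.9), then nudged ±1 in largest-remainder order so the
  global train count matches round-half-up(total·0.9) within one record, with
  ≥1 record per class in each subset.  A group-aware mode assigns whole
  patient groups to one subset because image-level splitting of multi-image
  patients leaks identity; the default follows the stated image-level
  procedure.
* Training augmentation, in order: resize shorter side to 256 (for a 224 crop;
  generally 8/7 of the crop — chosen so any input admits a valid crop), random
  224×224 crop, horizontal flip p=0.5, vertical flip p=0.5, per-channel
  standardization (x−mean)/sd on [0, 1] pixels.  Statistics are computed from
  the training split by default; published constants may be passed instead.
  Eval uses the deterministic resize → center crop → standardization
  counterpart.  Augmentation is applied on the fly, not as offline dataset
  inflation, since the inventory counts are pre-augmentation.
* All randomness flows from explicit `numpy.random.Generator` objects.

### Synthetic generator

Per class: a base hue (monotone increasing over class index:
0.02/0.18/0.38/0.60/0.82), a count of brighter elliptical blobs (2–6) and a
sinusoidal value texture (2–8 cycles), rendered in HSV and converted to RGB,
plus Gaussian pixel noise of sd `noise_sd` (default 0.05 on [0, 1] pixels — mild
sensor-like noise; 0 makes the task exactly separable).  Consecutive images of
a class share a synthetic patient id (6 frames per patient, mirroring the
clinical ratio of ≈5.9 images/patient).  At noise 0 the class-conditional mean
colors are distinct by construction, so a nearest-mean-color classifier is
perfect — passing learning tests therefore demonstrates that the optimisation
and architecture work, **not** that the networks would reach clinical accuracy
on real colposcopy frames, whose anatomy, illumination variability and
inter-grade subtlety the generator does not emulate.

## Training and evaluation

SGD with Nesterov momentum 0.9, weight decay 1e-4, batch size 32, 100 epochs,
initial learning rate 0.05 (the study recipe).  The schedule defaults to linear
decay lr·(1 − epoch/epochs) because only the initial rate is stated; constant
and cosine schedules are available.  Loss is cross-entropy on logits.  Per
epoch the mean train loss and validation accuracy are recorded; the
best-validation weights are restored at the end.  Non-finite loss raises a
divergence error naming the epoch and step.

Evaluation: K×K confusion matrix (rows true, columns predicted); per-class
one-vs-rest marginals TP/FP/FN/TN; percent precision, recall, F1 and overall
accuracy = trace/total·100.  Macro averaging (unweighted over classes) is the
headline aggregation — with micro also reported — because the binary-form
metric definitions only extend to multiclass through an explicit average, and
macro is the convention consistent with the published baseline numbers.
Division by zero (empty predicted or true class) yields 0 with a warning.  The
row-normalised confusion matrix has per-class recall/100 on its diagonal; empty
rows are flagged.  AUC is the one-vs-rest rank statistic with midranks
(equivalent to trapezoidal ROC integration); macro, micro and single-class
variants are available since the aggregation behind a single published AUC
value is not stated.  Repeated-run summaries report mean ± sample sd (ddof=1;
sd absent for a single run); the default repeat count is 3.

## Problem sizes used in tests and the acceptance script

Chosen so the full suite runs in minutes on one CPU:

* Learning checks: 50 images/class at 64×64, noise 0, stratified 90/10,
  10 epochs at batch 32, on a reduced backbone (stem 16, repeats (2, 2),
  channels (32, 64), final 128, r=8).  Every variant reaches ≥95% (observed
  100%) validation accuracy.
* Single-batch overfit: the full default backbone at 32×32 input memorises 8
  synthetic images within 200 steps (observed ≈7) at lr 0.05.
* Cost-model oracle grid: W, H ≤ 4, C_in, C_out ≤ 8, N ∈ {1, 3, 5}, exhaustive.

## Numerical choices and degenerate inputs

* Same padding everywhere (total pad = dilation·(N−1), split low/high); stride-s
  output dims are ceil(dim/s).
* BN: momentum 0.1, eps 1e-5, biased variance for both normalisation and
  running stats; eval mode uses running statistics.
* Weight init: Kaiming-normal for convs (fan-in of the filter group), uniform
  ±1/√fan_in for linear layers, BN scale 1 / shift 0; all from one seeded
  generator, so identical seeds give identical models.
* Channel split uses the floor rule on odd counts; the units themselves require
  even widths (the default schedule only produces even widths).
* Ties: argmax prediction breaks ties toward the lowest class index; max-pool
  distributes gradient equally over tied maxima; AUC handles score ties by
  midrank.
* Softmax and sigmoid are computed in shifted/branched form to avoid overflow.

## Known limitations

* CPU-only float64 NumPy: fine at test scale, not suited to 100-epoch training
  on thousands of 224×224 images.
* The generator's classes are far easier than clinical colposcopy; results on
  it say nothing quantitative about clinical accuracy.
* No pretrained weights, no transfer learning, no grouped 1×1 convolutions, no
  attention kinds beyond SE/SK, no hardware latency or memory-access modelling.
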