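# Methods

This note documents the models, the synthetic data, the numerical choices
and the known limitations of `tailmix`. It states no empirical result that
the test suite does not itself compute.

## The two-phase framework

### Problem setting

Training data is long-tailed: with `n` classes and `D` training images, the
mean class size is `m = D/n`. Classes with more than `m` images are *heads*,
classes with at most `m` are *tails* (a class sitting exactly at `m` is
treated as tail; it needs no resampling either way, so the tie rule only
affects bookkeeping). Test sets are class-balanced, and head/tail accuracies
are macro averages (mean of per-class accuracies); on a balanced test set
micro and macro coincide, and overall accuracy equals the class-count
weighted mean of the head and tail figures — asserted exactly in the tests.

### Phase I

Standard cross-entropy training of the backbone on all images. The fitted
model F₁ is then frozen and reused three ways: lower-layer feature extractor
for herding, penultimate-feature index for donor retrieval, and softened
teacher for distillation.

### Head undersampling (herding)

Each head class is cut to `⌊m⌋` samples by ranking its members by Euclidean
distance to the class mean feature vector and keeping the closest
(`nearest-mean`, the default); the classic greedy exemplar loop
(`greedy-herding`, iteratively adding the sample that moves the running mean
of picks closest to the class mean) is also provided. Ties break by sample
id, making selection order-invariant.

Two feature-space choices matter:

- **Layer.** Herding ranks in the globally averaged activation of the
  *first* convolution layer by default (`herding_layer=0`). Lower-layer
  embeddings measure appearance typicality; ranking in the penultimate
  (classifier-collapsed) space instead measures classification margin, which
  systematically discards boundary samples and erodes the head/tail decision
  boundary. Any layer, or the penultimate embedding (`herding_layer=None`),
  can be selected.
- **Normalization.** Feature vectors are unit-normalized before herding by
  default; this stabilizes the class mean and makes dot products cosine
  similarities for the retrieval step. A flag disables it.

The selected/removed partition (`Ds`/`Dr`) serializes to CSV.

### Knowledge distillation

During phase II the student F₂ minimizes, in addition to cross-entropy, the
cross-entropy of its temperature-softened outputs under the frozen teacher's
softened outputs, by default on the herding-selected head samples only
(`kd_scope="selected-head-only"`; `"all-samples"` is available). Defaults:
temperature `T = 0.5` (sharpens the teacher for efficient transfer), weight
`λ = 1.0` (the combination weight is not otherwise determined; it is
configurable). Natural logarithms are used throughout. The per-batch loss is

    (1/B) · Σᵢ [ CE(xᵢ) + λ·1{xᵢ ∈ Ds}·KD(xᵢ) ]

— the KD term is normalized by the batch size `B`, not by the number of
KD-scope samples in the batch, so its per-sample gradient stays on the CE
scale no matter how few head samples a batch contains (normalizing by the
masked count makes sparse batches take disproportionate steps and destabilizes
training). An optional `T²` factor on the KD term (a common gradient-scale
convention) is off by default. Teacher logits are computed once in inference
mode; no gradient reaches the teacher.

### Tail oversampling (visual-aware CutMix)

Each tail class is lifted to `⌊m⌋` effective samples. For every needed
synthetic sample the generator cycles through the class's originals, draws a
fresh donor batch `Br` uniformly from the removed pool `Dr` (batch size 32,
matching the training batch — the donor batch plays the role of the
per-batch pairing pool), retrieves the top-`k` donors by cosine similarity
between penultimate features (descending, ties by id; `policy="random"`
instead draws donors uniformly from `Br`, isolating the retrieval axis), and
composes sequentially:

    running ← (1 − Mᵢ) ⊙ donorᵢ + Mᵢ ⊙ running,   i = 1..k

where mask `Mᵢ` holds 1 inside a `⌊sW⌋×⌊sH⌋` rectangle placed uniformly at
random, `s ~ U(low, high)` (default `(0, 1)`), redrawn until the rectangle
covers at least one pixel. Mask value 1 keeps the (running) tail composite;
0 pastes the donor. A literal summation over the k donor terms would push
pixel intensities out of range, so multi-image mixing is implemented as this
sequential re-composition, which reduces exactly to the single-donor formula
at `k = 1`; each step draws a fresh mask and fresh `s`. Defaults: `k = 1`.

Pixel ownership is tracked per composite (owner index per pixel), giving the
expected tail-owned area `E[s²] = 1/3` per step under the default mixing law
— verified against 10⁴ Monte-Carlo draws in the tests — and a tail-owned
fraction that strictly decreases as `k` grows.

**Composite labels.** The label of a composite is the original tail label
(`label_policy="tail-only"`, the default). The area-proportional alternative
(`"area-mix"`, the convention of generic CutMix training) is implemented and
selectable, but it is not the default for a structural reason: under the
mixing law above a composite is on average two-thirds donor by area, so
area labels assign the majority of the label mass to the donor class. When
donors are retrieved by visual similarity the composite is, by construction,
similar to the tail class's own appearance — majority-donor labels on
tail-like inputs then actively suppress the tail logit exactly where the
tail must be recognized, and the more similar the donors, the worse the
suppression. With tail-only labels the similarity-retrieved context instead
reinforces the tail in its own visual context, while random donors dilute
the tail's template with foreign context; this reproduces the framework's
intended ordering (visual ≥ random donors, both above plain training),
which the acceptance suite checks.

Recipes (tail id, donor ids, rectangles, `s` values, label) serialize as
JSON-lines and are regenerated every epoch by default (`recipes_per_epoch`),
giving fresh augmentation randomness per epoch; a pre-generate mode reuses
one recipe set for reproducibility studies.

### Phase-II training

The student warm-starts from the teacher's weights (a cold-start flag
exists; warm start is the default since the framework is one continuous
two-phase procedure). One cosine learning-rate schedule spans both phases:
phase II continues the decay at epoch `e₁` of `e₁+e₂` rather than restarting
at the full step size — restarting erases the warm-started knowledge in the
first few epochs. Cross-entropy is computed against soft target rows (with
one-hot rows it reduces to standard CE), so both label policies train
correctly.

## Backbones

Two numpy backbones share one SGD trainer (mini-batch SGD, momentum 0.9,
cosine or constant schedule, optional weight decay, seeded shuffling):

- `CompactConvClassifier` (default): three stride-2 3×3 convolution layers
  (8, 16, 32 channels), global average pooling, linear softmax head. GAP
  makes class evidence additive over image regions — the credit assignment
  CutMix-style composites rely on and the head design of standard residual
  networks — while the deepest layer's ~15-pixel receptive fields let
  surrounding context modulate how a pasted patch is encoded. Penultimate
  features are the pooled last-layer activations; any conv layer's pooled
  activation is available via `layer_embedding`.
- `SmallImageClassifier`: a single-hidden-layer perceptron on raw pixels.
  Cheaper, but its global features lack the locality that patch-composed
  training assumes; it serves as a crude reference backbone.

Inputs live in `[0, 1]` and are centered by subtracting 0.5. Weights use
He-scaled Gaussian initialization. Gradients of both backbones are verified
against finite differences in the tests. At full scale the framework the
package emulates uses a standard 18-layer residual network; that is out of
reach for a pure-numpy desk-scale package, and the backbone interface is
deliberately pluggable.

## The synthetic benchmark

`tailmix.benchmark` fixes the desk-scale study conditions: 10 classes on a
geometric profile from 600 down to 6 training images (imbalance ratio 100,
1,489 images), 32×32 RGB, 25 test images per class, compact convolutional
backbone, 10 + 20 epochs, three seeds. A full five-strategy comparison runs
in a few minutes on one CPU.

What the generator emulates, and why:

- **Inter-class similarity**: classes partition into three round-robin
  similarity groups; group members share a background hue band (what makes
  them look alike to a feature extractor) while foreground hue offsets and
  polygon vertex counts separate classes within a group. Round-robin
  assignment puts head and tail classes in every group, so similarity-aware
  donor retrieval has same-group head donors available for each tail.
- **Intra-class diversity**: per-image jitter in hue, polygon position,
  scale, rotation and pixel noise.
- **Foreground dominance**: the polygon fills most of the frame, as the food
  fills most of a food photograph; random crop rectangles therefore usually
  carry class-discriminative content.
- **Training-set noise**: 10% of training images are outliers. The default
  style (`corrupt`) keeps the class render but rotates the palette to an
  arbitrary hue and adds occluding blobs — the "intense colors" failure mode
  documented for the uncleaned training split of the classic 101-class food
  benchmark. `junk` (structureless clutter) and `mislabel` (another class's
  appearance under this label) styles are also available.
- **Curated test split**: test images are always clean and rendered with
  half the appearance spread, emulating the manually reviewed test sets of
  the real benchmarks.

What it does **not** emulate: natural-image statistics, texture-level
within-class variation, object occlusion and scale hierarchies, label
ambiguity between genuinely overlapping foods, or ImageNet-pretrained
representations. Passing the benchmark's qualitative ordering checks shows
the pipeline's machinery behaves as designed under controlled conditions; it
is not evidence about accuracy on real food images.

## Numerical and design choices

- Softmax and its temperature-scaled variants use a numerically stable
  log-sum-exp shift; softened distributions are strictly positive and sum to
  1 to 1e-9.
- `s` rounding in frequency plans: round half away from zero, then floor at
  1, so the rarest foods keep at least one image and the most-consumed food
  keeps all of its images.
- `⌊m⌋` is the per-class integer target everywhere (`m` itself is real).
- All randomness flows through explicit seeds: image rendering derives a
  generator per (seed, class, split, index), so datasets are bit-identical
  across runs and machines; subsampling, donor batches, masks and batch
  shuffling consume seeded generators. Identical seeds give identical
  manifests, partitions, recipe logs and training losses (asserted to
  rtol 1e-9 in the tests).
- Geometric profiles pin both endpoints exactly after rounding; the
  Pareto-sampled variant rescales affinely to the requested endpoints and
  enforces monotonicity after rounding.
- Empty donor pools raise a configuration error only when composites are
  actually needed; already-balanced data trains without oversampling.

## Known limitations

- The numpy backbones are orders of magnitude smaller than production
  networks; absolute accuracies on the synthetic benchmark say nothing about
  real datasets, and only qualitative orderings are asserted.
- `nearest-mean` herding keeps a prototypical core; on data whose test
  distribution is as broad as the training distribution this can cost head
  accuracy relative to random selection. The lower-layer feature default
  mitigates but does not eliminate this.
- Strategy comparisons on the benchmark have seed-to-seed variability of a
  few points; the acceptance checks average over three seeds, as many as the
  desk-scale budget allows.
- The donor pool is the removed-head set `Dr`; when herding concentrates
  noisy images there, similarity retrieval can select them. Larger donor
  pools (more heads per similarity group) dilute the effect.
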