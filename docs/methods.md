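# Methods

## The architecture

MobileNet-MFS is MobileNet v3-Large with two modifications: a multi-scale
convolutional front end ahead of the stem, and the FSCA attention block at
every site where the published v3-Large layer table places SE.  Everything
else — the 15-bottleneck chain, kernel sizes, strides, the ReLU/hard-swish
assignment, the 960→1280 head and the classifier — is the published layout.
The baseline-recovery identity (front end off, FSCA mapped back to SE equals
the v3-Large baseline in parameter count and per-tensor shapes) is enforced
by a test.

### FSCA

The block chains two gates.

**Directional stage.**  For input `x ∈ R^{H×W×C}`, average-pool along width
to an H-profile and along height to a W-profile, concatenate to a
`1×(H+W)×C` strip, pass it through a shared 1×1 reduce convolution to
`max(C/r, m)` channels with batch normalization and hard-swish, then through
two per-direction 1×1 expand convolutions back to `C`.  The sigmoid of each
result gates rows and columns multiplicatively:
`y[i,j,c] = x[i,j,c]·σ(r[i,c])·σ(s[j,c])`.

**Cross-channel stage.**  Per location, the channel max and channel mean are
stacked into an `H×W×2` map, fused by a k×k convolution with one output
channel (bias, no normalization) and squashed by a sigmoid into one weight
per location: `z[i,j,c] = y[i,j,c]·σ(w[i,j])`.

The two stages run directional-first; the order is a config switch
(`AttentionConfig.spatial_first`) because nothing forces it structurally.
Naming note: although the second stage is described as "channel attention"
in the source narrative, it pools *across* channels and emits one weight per
spatial location — in CBAM's terminology that construction is a spatial
gate.  We implement the construction as described and keep the name FSCA for
the composite.

Defaults and why:

| parameter | default | rationale |
|---|---|---|
| `reduction_ratio` r | 32 | the published coordinate-attention convention the directional stage follows |
| `min_reduced_channels` m | 8 | floor so narrow maps keep a usable bottleneck |
| `spatial_kernel` k | 7 | the published CBAM spatial-gate convention |
| reduce-conv sharing | shared reduce, split expands | coordinate-attention convention |
| nonlinearity in the strip | hard-swish | consistency with the backbone's activation family |
| biases | none where normalization follows; bias on the fuse conv | parameter parity with the published blocks |

A consequence worth stating plainly: FSCA at r=32 is far cheaper than SE, so
MobileNet-MFS at these defaults counts **3,001,523** trainable scalars versus
the baseline's 4,213,561.  Published totals for this architecture family
(4.96 M parameters / 251.94 MFLOPs) imply wider attention internals or a
wider front end than these defaults; those widths are not recoverable, so
the published totals are documented as reference points, not reproduction
targets.

### Multi-scale front end

Branches of kernel 1/3/5/7, each 3 → 8 channels at stride 1 with "same"
padding, concatenated (32 channels) and fused by a 1×1 convolution to 16
channels that replace the raw image as the stem's input.  Branch widths are
a design choice (nothing published fixes them); each branch is
convolution + batch normalization + hard-swish, and a concat-only mode is
exposed for ablation.  Because batch normalization is per-channel, the four
per-branch norms are implemented as one norm over the concatenated channels
— mathematically identical, one kernel pass instead of four.  At run time
the four branches execute as a single shared-im2col convolution with the
smaller kernels embedded centered in a 7×7 frame; the per-branch path is
used when the complexity tally is active so MAC accounting sees true kernel
sizes.  The front end replaces the raw image as stem input (rather than
being concatenated with it); that is the reading most consistent with a
front end "ahead of the network".

### Complexity accounting

`count_params` counts trainable scalars (convolution/linear weights and
biases, two affine scalars per normalized channel).  `count_macs` counts
`out_H·out_W·out_C·in_C·k²/groups` per convolution plus fully connected
products, one MAC per multiply-accumulate, elementwise/normalization/
activation ops excluded — the dominant convention.  Under it, v3-Large with
a 9-way head measures 215.3 MFLOPs at 224²; published figures for this
architecture family vary by a few percent with the counting convention,
which is why the accounting is compared to references with a 15% band
rather than exactly.

## The engine

All learnable computation runs on a small reverse-mode autodiff engine over
NumPy float32 arrays (NCHW): a tape of parent links with one backward
closure per operation.  Dense convolutions are im2col plus one GEMM;
depthwise convolutions are a shift-accumulate loop over kernel offsets;
both adjoints are hand-written and verified against central finite
differences and SciPy's `correlate2d` in the test suite.  Batch
normalization uses batch statistics in training and exponential-moving-
average buffers (momentum 0.1, eps 1e-3) in evaluation.  Gradients are
retained on intermediate tensors after `backward()`, which is exactly what
Grad-CAM consumes.  Model builds and every stochastic step (initialization,
batch order, dropout, augmentation draws) are driven by explicitly seeded
`numpy.random.Generator` instances, so runs are bit-reproducible on a given
platform.

## Data handling

The stratified split assigns `test = floor(n/5)` per class — the rule that
reproduces, class by class, the published per-class figures of the reference
apple-leaf collection (train 12204 / test 3046 / total 15250).  Splitting
happens before augmentation, and augmented copies derive only from training
originals, so no augmented twin of a test image can leak into training.
Augmentation appends `factor−1` transformed copies per training original
(default ladder: horizontal flip, then rotations uniform in ±25°); only the
×3 multiplicity is anchored to the reference table — the transform choice is
ours.  Normalization uses the standard natural-image channel means/sds and
is configurable.

## The synthetic generator

The generator exists so that the full pipeline — data loading, training,
evaluation, explanation — is exercisable and testable without any external
image collection.  Each image is a vein-textured green leaf with an
illumination gradient and pixel noise, plus class-conditional lesions:

- **Rust**: many small red-orange pustules (highest red channel);
- **Grey spot**: more numerous small neutral-grey spots;
- **Frogeye**: mid-size tan spots with a darker ring;
- **Alternaria**: few large dark-brown spots;
- **Scab**: dark olive multi-lobe blotches;
- **Brown spot**: one large chlorotic (yellowed) region plus brown patches;
- **Mosaic**: angular yellow mottling patches;
- **Powdery mildew**: whitened venation plus pale speckles;
- **Health**: no lesions.

Counts are Poisson with per-class means and floors, radii and colors are
Gaussian around per-class centers; generation is a pure function of
`(spec, seed)` and byte-reproducible.  Two statistical guarantees are
tested: lesion-mask mean red intensity of rust exceeds grey spot by at
least 30/255 at defaults, and a nearest class-mean classifier on eight
color/texture summaries reaches ≥ 80% held-out accuracy — i.e. the classes
are genuinely learnable, so a CNN scoring far higher is meaningful and a
broken model cannot pass by chance.

What the generator does **not** emulate: real lesion morphology and
texture, leaf shape and background clutter, illumination extremes,
inter-class ambiguity (real rust and scab genuinely overlap; the synthetic
classes are near-separable by design), and class imbalance.  Passing the
synthetic end-to-end check therefore demonstrates that the architecture,
optimizer, metrics and explanation stack are wired correctly and can fit a
vision task of this shape — it says nothing about accuracy on real
orchard imagery.

## Training and evaluation

Cross-entropy with Adam (lr 1e-3, batch 32) by default; momentum SGD and a
cosine schedule are available.  The published epoch horizon for this task
family is ~80 epochs; desk-scale runs here use far fewer (below).  Transfer
learning is supported by tensor-name/shape matching from a checkpoint:
matching tensors load, fresh modules (front end, FSCA, classifier) stay
randomly initialized, and loaded tensors can be frozen for a configurable
number of epochs.

Evaluation builds the K×K confusion matrix (rows true, columns predicted)
and derives per-class one-vs-rest precision, recall and F1.  Conventions:
0/0 is reported as 0 with a warning and excluded from macro averages;
headline averages are support-weighted with macro alongside (on an
imbalanced test set weighted averaging is what makes the three headline
numbers nearly coincide); multiclass AUC is the unweighted mean of
per-class one-vs-rest AUCs.  ROC curves sweep the distinct score values
with ties grouped; AUC is the trapezoidal area, which equals the normalized
Mann-Whitney U statistic (tested).  Note the canonical accuracy
`(TP+TN)/(TP+FP+TN+FN)` is implemented; a variant rendering sometimes seen
with TP+FN in the numerator is a typesetting artifact, not a different
estimator.

## Grad-CAM

Channel weights are the spatial mean of the target-class score's gradient
at the chosen layer; the map is the rectified weighted sum of activations,
normalized by its maximum (a zero map stays zero — max-division rather than
min-max, preserving the zero baseline), bilinearly upsampled to the input
size and renormalized after interpolation.  The default layer is the last
bottleneck's output, the deepest spatial map, per common practice.  The map
is invariant to positive rescaling of the logits (tested).

## Problem sizes

Desk-scale defaults, chosen once as realistic for a CPU-only NumPy stack:
the end-to-end benchmark trains on 9 × 200 synthetic images at 96×96
(4:1 split) for 15 epochs with seed-driven determinism and must reach
≥ 0.90 test accuracy; in practice it converges to ≈ 0.99 by epoch 3.  The
benchmark model is a compact preset of the same family (multi-scale front
end with 4-channel branches, five FSCA-gated bottlenecks, 160-channel
head, ~74 k parameters): the full 3 M-parameter network trains identically
but several times slower, which buys nothing for a correctness benchmark.
Unit tests use smaller sets (9 × 6–20 images at 32–64 px).

## Known limitations

- Single-process CPU execution; no data-parallel or GPU path.
- The engine implements exactly the operations this model family needs;
  grouped convolutions other than depthwise are not supported.
- ECA's channel convolution is realized as shifted weighted slices, which
  is exact but not the fastest possible form.
- The 4.96 M / 251.94 MFLOPs configuration of the original MobileNet-MFS is
  not recoverable (see above) and is documented as a reference point only.
- Real-data performance claims (98%+ accuracy on apple-leaf collections)
  require the multi-source real dataset and GPU-scale training, both out of
  scope here.
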