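# Methods

This note documents the models, the procedural data generator, the numerical
choices, and the limits of what the test suite demonstrates.

## Problem setting

Root cross-section images (laser-ablation tomography, LAT) show concentric
tissues — epidermis, sclerenchyma, cortex with aerenchyma lacunae,
endodermis, and a stele containing stele tissue, vascular bundles and
metaxylem vessels. Anatomical traits derived from these tissues (root and
stele diameter, cortex width, vessel geometry) feed drought-tolerance
phenotyping. Dense pixel annotation is the bottleneck: a segmentation model
that transfers across species and imaging protocols, and that turns
annotation into region labelling rather than boundary tracing, is the goal.

## Two-stage decomposition

Stage 1 answers the species-agnostic question *is this pixel plant tissue?*
(2 classes); stage 2 answers *which tissue?* (9 classes). Both stages are
the same U-Net, differing only in output channels. The decomposition buys
two things: the binary model transfers across species unchanged, and its
output is the starting point both for stage-2 inputs and for the annotation
workflow.

## Robust input channels

Both stages consume a 3-channel stack on the 0–255 scale instead of RGB:

- **B_adp** — inverse-binary adaptive threshold. The grayscale image
  (BT.601 luminance) is blurred with a 15×15 Gaussian; a pixel becomes 255
  when its blurred value is strictly below the Gaussian-weighted mean of its
  35×35 neighbourhood plus an offset C = 1. Cell lumens and flat background
  are foreground; bright walls are 0. A constant image is all-255 by
  construction.
- **θ_f³ and θ_f⁷** — Sobel gradient orientation at kernel sizes 3 and 7,
  computed on the *raw* grayscale (not the blurred copy), folded modulo π
  into [−π/2, π/2) (edge orientation is direction-less), mapped linearly to
  (θ+π/2)/π·255, and kept only where the gradient magnitude strictly
  exceeds the 75th percentile of magnitudes over the whole image.

Stage 1 uses (B_adp, θ_f³, θ_f⁷); stage 2 replaces the first channel with
the stage-1 binary output B_out (a hard {0,255} mask from the argmax of the
stage-1 probabilities). Because thresholding is local and the magnitude
gate is a per-image percentile, all three channels are invariant to
positive affine intensity changes, which is the mechanism behind
cross-protocol and cross-species robustness.

Numerical conventions (all overridable through `PreprocParams` and shared
by the slow per-pixel reference implementations in the test suite):

- Gaussian σ from kernel size: σ = 0.3·((k−1)·0.5 − 1) + 0.8, the de-facto
  default of mainstream adaptive-threshold implementations.
- Sobel kernels built from binomial rows: smoothing = binomial(k−1),
  derivative = binomial(k−3) ∗ [−1, 0, 1]; k=3 gives the classic matrices,
  k=7 gives smooth [1,6,15,20,15,6,1] and derivative [−1,−4,−5,0,5,4,1].
  Filters are applied by correlation; the orientation fold makes the
  correlation/convolution sign irrelevant.
- Borders: symmetric reflection for blur, local mean and Sobel.
- Percentile: linear interpolation over all pixels; strict `>` comparison.
- Preprocessing runs at native resolution; geometric augmentation and
  resizing are applied to the stacked channels afterwards (masks with
  nearest-neighbour), so the pixel-denominated constants keep their
  meaning.

## Network and loss

The U-Net is a small encoder–decoder with skip connections: widths
(8, 16, 32, 64), three 2×2 max-poolings, conv→group-norm→ReLU blocks,
nearest-neighbour upsampling and a 1×1 head. The ~105 px receptive field
is sized so that stele-interior pixels of a 256-px root section (stele
radius ≈ 35 px) see the endodermis boundary as context — with a shallower
net the stele interior must be classified from texture alone, which is
unreliable. Group normalisation (batch-size independent) plays the role
batch-norm plays in standard pretrained backbones. The engine is
implemented directly on numpy (channels-last im2col convolutions with
explicit backprop and Adam); the `tiny` encoder is the default and the
only one available in this build — a pretrained ResNet-34 encoder is
rejected with an explanatory error. Training and inference are
deterministic for a fixed seed on a fixed thread configuration.

The objective is `L = λ·L_CE + L_Dice` with λ = 0.1. L_CE is per-pixel mean
cross-entropy (natural log). L_Dice is soft Dice on probabilities averaged
over classes, smoothed as (2·Σyp + ε)/(Σy + Σp + ε) with ε = 1e-6 in
numerator and denominator, so a class absent from both prediction and truth
contributes a perfect term instead of 0/0 and the loss is exactly 0 at a
one-hot match. The analytic gradient (softmax chain rule for both terms) is
verified against finite differences to 1e-4.

## Training protocol

Two presets of the same protocol:

| setting | paper preset | desk preset (default) |
|---|---|---|
| optimizer | Adam, lr 1e-4, wd 1e-3 | Adam, lr 2e-3, wd 1e-3 |
| λ | 0.1 | 0.1 |
| epochs / batch | 500 / 8 | 30 / 4 |
| augment | hflip, scale jitter, 768² crop | hflip, scale jitter 0.75–1.25, 192² crop |
| evaluation | resize to 1024² | resize to 256² |
| model selection | final epoch | final epoch |

The desk preset is sized for CPU training on 256-px synthetic data: the
crop/eval ratios track the paper preset (192/768 = 0.25, 256/1024 = 0.25),
the learning rate is raised ×20 (stable under group normalisation) to compensate for the ~16× shorter
schedule, and the "random resizing to S then random S-crop" step — which is
contradictory as printed — is implemented as scale jitter in 0.75–1.25
followed by a fixed-size crop (reflect-padded when short). No early
stopping: the final-epoch model is evaluated.

Stage-2 training feeds the ground-truth binary mask as B_out; inference
feeds the stage-1 prediction. On synthetic data the substitution changes
mean Dice by < 0.01 because stage-1 Dice is ≈ 0.99. Masks are scored at
native resolution (predictions are resized back with nearest-neighbour).

## Synthetic data

The generator draws a root as an ellipse (radius, ellipticity, orientation,
centre jitter sampled per image), splits it into concentric bands
(epidermis / sclerenchyma / cortex / endodermis / stele by radial
fractions), and textures each tissue with bright cell walls over dark
lumens: jittered-grid Voronoi cells for cortex, stele and sclerenchyma
(distinct cell sizes are what make tissues separable from orientation
texture alone), radial-spoke cells for epidermis and endodermis, bright
rings for metaxylem vessel walls and interface boundaries, solid bright
discs for vascular bundles, wedge-shaped wall-free cavities for
aerenchyma. Intensity is then modulated by a linear illumination gradient,
colourised with a per-family hue (jittered per image), and degraded with
Gaussian noise. The 9-class mask records the generating geometry exactly,
and the analytic root/stele diameters and cortex width are stored as
ground-truth traits before any noise.

Families A and B stand in for two species: B has a smaller root
(mean radius offset ≈ 18 px at 256²), a larger stele fraction
(0.46–0.55 vs 0.36–0.44), smaller cortex cells, fewer lacunae, and a
different colour cast and background level. Raw-RGB models therefore break
on the family shift while the structural channels do not, which is what
the transfer tests measure.

What the generator does **not** emulate: section tearing and debris,
out-of-plane blur, stain variability beyond a hue rotation, cell-scale
biological irregularity, or the instrument's native 4096×3000 resolution
(default is 256²; all pixel-denominated constants remain meaningful at
that scale). Passing tests therefore demonstrate the pipeline's mechanics
and its invariance claims on idealised anatomy, not field performance on
real LAT data.

## Metrics

Exact integer confusion counts per class; IoU = TP/(TP+FP+FN),
Dice = 2TP/(2TP+FP+FN); means are over all classes *including background*.
A class absent from both masks of an image is excluded from that image's
mean (an empty class carries no information; 0-or-1 conventions distort
averages). Dataset numbers are macro averages over images.

## Traits

Centroid of the non-background pixels defines the centre; chords are
measured along 0°, 45°, 90°, 135° as the distance between the outermost
region hits on each line (0.25-px sampling), the way a ruler-tool
measurement ignores interior gaps. Root diameter and stele diameter are
the 4-chord means; the stele region is the union of stele tissue,
metaxylem and vascular bundle (everything interior to the endodermis);
cortex width is half the diameter difference, robust to aerenchyma. If no
stele class is present the stele fields are reported absent, not zero.
Agreement between trait tables is OLS R², mean bias and RMSE per trait.

## Annotation workflow

`export_template` decomposes a binary mask into regions: plain 8-connected
components by default (sub-threshold regions, default 30 px at 256², merge
into their closest neighbour), or — given a cell-structure channel — a
nearest-seed tiling of the foreground seeded by the lumen components, so
regions follow visible cell walls and tile the foreground exactly.  For
seeding, the adaptive threshold is best run at cell scale (blur 3, window
9, minimum region ~4 px) rather than with the network channel's heavy
15×15 blur, which exists for noise robustness and merges adjacent lumens. Experts fill a one-row-per-region CSV with class names;
`merge_labels` rebuilds a 9-class training mask (unassigned regions →
background). `rank_candidates` orders unlabelled images by mean per-pixel
predictive entropy of the stage-2 probabilities — a proxy for the
"high classification error" selection that needs no ground truth on a new
species.

## Problem sizes used by the test suite and acceptance script

Desk-scale end-to-end checks train on 48 of 60 family-A 256² samples for
30 epochs per stage. Transfer, fine-tuning and
ordering properties run on a 96-px harness (16 training samples per
family; 12–100 epochs depending on the check) where only orderings and
improvements are asserted, never absolute quality. Trait-recovery and
annotation round-trip checks are training-free.

## Known limitations

- Behaviour on *rootless* frames is unspecified. The magnitude gate of the
  orientation channels is a per-image percentile, so on a featureless
  noisy frame a quarter of pure-noise pixels are promoted to "edges" — a
  stimulus the model never sees in training; and on a perfectly blank
  frame the group-norm blocks normalise zero-variance features into
  arbitrary bias-driven output. Screen empty frames upstream (e.g. by the
  variance of the raw image) before running the pipeline.

- The numpy engine is single-device and unbatched beyond the configured
  batch size; full published-scale runs (500 epochs, 768² crops, ResNet-34 encoder)
  are out of reach by design.
- Thin-ring classes (endodermis) are the weakest stage-2 classes at desk
  scale (per-class Dice ≈ 0.7 vs ≥ 0.85 for large tissues), and the short
  30-epoch schedule is seed-sensitive: in occasional training runs a rare
  compact class (vascular bundle, metaxylem) fails to lift off within the
  schedule. The published 500-epoch schedule has no such constraint.
- The B_out channel for stage-2 training comes from ground truth; with a
  much weaker stage-1 model than observed here the train/inference input
  mismatch could matter.
- Chord-based traits assume a star-convex root around its centroid;
  strongly concave outlines would need a different protocol.
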