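# Methods

`vesseltopo` implements topology-aware, domain-generalized segmentation of
tubular vessel trees from 3D TOF-MRA-like volumes.  This note records the
model, the choices that were genuinely open, and what the synthetic
phantom studies do and do not demonstrate.

## Problem and model

Cerebrovascular segmentation from time-of-flight MR angiography faces two
coupled difficulties.  First, overlap scores such as Dice are dominated by
large vessels: a prediction that drops a thin branch can score the same as
one that traces the whole tree with a small offset, although the latter is
clinically preferable.  Second, volumes acquired at different sites carry
systematic intensity differences ("domain shift") that a convolutional
encoder happily absorbs, hurting generalization to unseen scanners.

The package addresses both with a multi-task 3D encoder–decoder:

* **Main task** — voxel-wise vessel probability `L̂`, trained with the soft
  Dice loss
  `θ3 = 1 − (2 Σ L·L̂ + ε) / (Σ L + Σ L̂ + ε)`.
* **Auxiliary task T1** — regression of the surface distance transform
  `D(v) = min_{s∈S} ‖v − s‖₂` over vessel voxels `V`, where `S` is the set
  of foreground voxels with a background 6-neighbour.  Loss:
  `θ1 = Σ_{v∈V} smooth_L1(D(v) − Ĵ1(v))` with
  `smooth_L1(z) = 0.5 z²/β` for `|z| < β`, else `|z| − 0.5 β`.
* **Auxiliary task T2** — prediction of the vessel centerline `Ĵ2`,
  coupled to the main task through the topological-coincidence loss
  `θ2 = 1 − (Σ Ĵ2·δ_L + Σ δ_{L̂}·φ_L + ε) / (Σ Ĵ2 + Σ φ_L + ε)`,
  where `φ_L` is the homotopic skeleton of the ground truth, `δ_L` its
  cube dilation, and `δ_{L̂}` a differentiable 3×3×3 max-filter dilation of
  the predicted probability map.
* **Domain regularization** — a small head (global average pooling of the
  bottleneck, two fully connected layers, softmax over `n` sites) produces
  a domain probability vector `P`; the decorrelation loss is the Pearson
  correlation between `P` and the one-hot site label `D`.  Driving the
  correlation to zero removes site identity from the shared encoder.

The evaluation counterpart of `θ2` is the topological-coincidence score
`TC = (Σ φ_P·δ_L + Σ δ_P·φ_L + ε) / (Σ φ_P + Σ φ_L + ε)`, which is 1 when
each mask's centerline lies inside a one-voxel tolerance band around the
other mask, and ≈ 0 for an empty prediction.  TC separates the
"equal-Dice" pair above: the test suite constructs a trunk-plus-thin-branch
ground truth with two predictions whose Dice agree within 0.01 while their
TC differ by ≈ 0.5 in favour of the topology-preserving one.

## Architecture

Encoder: `levels` blocks (default 4), each two 3×3×3 convolutions with
ReLU and a residual add (1×1×1 projection when the channel count changes),
followed by a 2×2×2 max-intensity-projection (MIP) pooling that records
per-window argmax indices.  Channels start at `base_channels` (default 16)
and double per level.  Main decoder: `levels` blocks, each an index-driven
reverse-projection (RIP) unpooling with the matching encoder indices, a
concatenation skip from the matching encoder stage, and two conv+ReLU with
residual add; each block's output width matches the encoder stage whose
indices the next unpooling consumes (unpooling is per-channel).  The first
`shared_decoder_levels` (default 2) decoder blocks are shared by all three
tasks; T1 and T2 then branch into exclusive stacks of the same structure
without encoder skips.  Heads: 1×1×1 convolutions with sigmoid (`L̂`, `Ĵ2`)
and softplus (`Ĵ1`, to keep predicted distances non-negative).  Window-max
ties break toward the lowest linear index for bit-reproducibility.

The whole network, its losses and Adam run on a small tape-based
reverse-mode autodiff engine over numpy arrays (`vesseltopo.autodiff`);
convolutions are evaluated as im2col matrix products, and every gradient
is verified against central finite differences in the test suite.

## Topology operators

Skeletonization is sequential thinning that deletes only (26, 6)-simple
points — the Malandain–Bertrand characterisation via one 26-component of
foreground in the punctured 3³ neighbourhood and one face-adjacent
6-component of background in the 18-neighbourhood — visited in six
directional sub-iterations in lexicographic order, with curve endpoints
(≤ 1 foreground 26-neighbour) preserved.  This preserves 26-connected
foreground components, 6-connected background components (counted with the
outside-is-background convention) and the Euler characteristic exactly;
the tests verify all three on tubes, Y-junctions, tori and random masks
against a cubical-complex oracle.  The inner predicate is numba-compiled.

Voxels outside the image are background for every neighbourhood operation,
so border foreground counts as surface.  The distance transform is the
exact Euclidean distance to the nearest *surface* voxel (zero on
background and on the surface itself), computed with
`scipy.ndimage.distance_transform_edt` on the surface complement and
verified exactly against an `O(|V|·|S|)` brute-force oracle.  Distances and
ASD default to voxel units (making oracle tests exact); millimetre units
via the voxel spacing are available.

## Domain unlearning

Minimising the raw Pearson correlation has its optimum at
anti-correlation, which still encodes the site; the training objective
therefore penalises the *squared* per-sample correlation
(`total = θ3 + w1·θ1 + w2·θ2 + wd·DcL²`), whose optimum is exactly zero
correlation.  `decorrelation_loss` itself returns the signed value in
[−1, 1]; the alternative denominator form `√(Σ(p−p̄)²(d−d̄)²)` is available
as `dcl_form="printed"`.

Getting the decorrelation gradient to genuinely strip the encoder requires
scheme-level choices, each motivated by an observed failure mode of the
naive coupling:

1. **The head is kept an honest domain predictor** by a cross-entropy term
   evaluated on a *detached* copy of the latent, so domain supervision
   never reaches the encoder.  Without it the head drifts to a constant
   output and the decorrelation term carries no information.
2. **The decorrelation path uses frozen head weights**, so its gradient
   reaches only the encoder.  When both terms shape the head it settles at
   an uninformative equilibrium and the encoder never unlearns.  The head
   input is standardized with running latent statistics to keep its
   softmax out of saturation, the head trains faster than the body
   (`head_lr_multiplier`), and it is periodically re-initialized
   (`head_reset_every`) so successive phases probe different residual
   domain-informative directions.
3. **A latent-level decorrelation step runs once per epoch**: an
   encoder-only pass over a dedicated patch cohort minimizes the
   variance-normalized discrepancy of per-domain latent means *and
   variances* (`domain_mean_discrepancy`).  Zero feature–domain Pearson
   correlation is equivalent to equal per-feature domain means, which is
   precisely what defeats a linear site probe; the variance term removes
   the second statistic such a probe exploits.  The step has its own
   optimizer (mixing its gradient into the main Adam's moment estimates
   dilutes both objectives), and the cohort spans many volumes with few
   patches each, because the erasure generalizes only as well as the
   cohort's between-volume diversity.  A single minibatch cannot serve
   here: a correlation estimated from 4 samples has a noise floor of
   roughly 1/3 and its gradient is dominated by sampling noise.

This remains a single training phase — there is no alternating adversarial
loop; every step sums its terms into one objective.

The unlearning diagnostic is a fresh logistic probe on encoder latents
whose train/test split is **by volume**: a patch-level split lets the
probe score by memorizing volume identity (which is confounded with the
site in small cohorts) rather than by reading genuine site features.

## Synthetic phantoms

The generator grows random vascular trees (perturbed random-walk polylines
with probabilistic branching and radius decay, minimum radius 0.9 voxel so
the rounded centerline always lies inside the swept tube), rasterizes them
as sphere-swept tubes with a voxelized 26-connected centerline, optionally
attaches spherical aneurysms (recorded as a separate pathology mask, fully
contained in the vessel label by construction), and renders intensities:
vessel and background voxels from two normal distributions (vessels
hyperintense), a smooth multiplicative bias field (cubic-upsampled 4³
noise), and additive Gaussian noise.

Three default synthetic sites share background 0.2 and differ in vessel
mean (0.7 / 0.8 / 0.9) and noise (σ = 0.02 / 0.05 / 0.08), mimicking the
per-site histogram shifts of multi-center MRA at reduced scale.  The
differences survive per-volume z-scoring (contrast-to-noise varies), so a
real domain signal remains for the unlearning experiments — a linear
classifier on per-volume histograms separates the sites with accuracy
> 0.9.  Gaussian (not Rician) noise is used; the phantoms make no claim to
anatomical realism (no circle-of-Willis geometry, no MR physics, no flow
artifacts).  Passing phantom studies therefore demonstrates the
correctness and learnability of the pipeline, not clinical performance.

## Training and inference

Patches are sampled on the ground-truth centerline with uniform jitter up
to a quarter of the patch extent per axis (with replacement), guaranteeing
at least one skeleton voxel per patch; crops beyond the border are
zero-padded.  Inference tiles the volume into non-overlapping patches
(zero-padding each axis to the next multiple of the patch extent), runs
the forward pass per tile, stitches exactly, and thresholds at 0.5.

Defaults: β = 1, ε = 1e−6, task weights (w1, w2, wd) = (1, 1, 0.1),
dilation radius 1 ("slight tracing differences" ≈ a one-voxel tolerance),
Adam with learning rate 1e−4.  The trainer defaults to per-vessel-voxel
*mean* reduction for θ1 so the four terms stay on comparable scales (the
summed form is available and is the printed definition).  For the
desk-scale phantom studies the recipe uses learning rate 1e−3, batch 4 and
short schedules, appropriate for tiny models on small cohorts.

## Study sizes

The standard studies (`vesseltopo.experiments`) are sized for a single CPU
core: the segmentation benchmark trains a 3-level, 8-channel model on
8×64×64 patches (3 per volume, 2 training volumes per site, 3 sites) for
15 epochs and evaluates one held-out volume per site.  The unlearning
comparison trains paired 8×32×32-patch models for 25 epochs (decorrelation
completes after the main task converges) with the head re-initialized
every 5 epochs and a decorrelation cohort of 33 volumes × 2 patches; the
probe reads 600 latents from 10 independent volumes per site, split by
volume and averaged over five splits.  At this scale the probe typically
drops from roughly twenty points above chance to the low teens — the
erasure is estimation-limited, since per-domain latent statistics can only
be equalized up to sampling error of order σ/√V over the V cohort
volumes, and a probe with hundreds of training latents detects the
residual.  Full suppression to near-chance is expected to need cohort and
schedule sizes closer to a full multi-site study than to this desk-scale
one.  The patch-extraction census generates 227 single-tree phantoms and
extracts 100 centerline-based patches from each.

## Degenerate cases and conventions

Dice of two empty masks is 1; precision of an empty prediction and ASD of
an empty mask are undefined and reported as missing (NaN), never coerced
to 0; TC of an empty prediction against a non-empty reference is ≈ ε.  The
two TC numerator terms are implemented exactly as defined (they are not
perfectly symmetric).  The decorrelation loss returns 0 when either vector
is numerically constant (e.g. a uniform prediction).  Axis order is
(depth, width, height) with 0-based indices everywhere.

## Known limitations

Training is CPU-bound and deliberately small; no GPU path, no mixed
precision, no overlapping-window inference with blending.  The domain head
observes only globally pooled bottleneck features; domain cues that vanish
under global pooling would be invisible to it (and to the probe).  The
phantom intensity model is two-class normal with a smooth bias field —
real TOF-MRA noise is Rician and vessels have partial-volume profiles.
Skeletonization of very thick, blob-like shapes yields a small central
cluster rather than a meaningful curve skeleton (any homotopy-preserving
thinning does).
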