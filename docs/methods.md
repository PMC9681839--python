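# Methods

This note documents the models, conventions and design choices behind
`pics-wbc`, in the order the pipeline runs them.

## Phase reconstruction (`pics.slim_recon`)

Phase-shifting interferometry on a phase-contrast microscope records four
intensity frames with the incident/scattered phase delay stepped by π/2:

    I_k = |U_i|² + |U_s|² + 2|U_i||U_s| cos(Δφ + kπ/2),  k = 0..3.

The four-bucket inversion is closed-form:

    Δφ = atan2(I₃ − I₁, I₀ − I₂)
    G  = ¼√((I₀−I₂)² + (I₃−I₁)²) = |U_i||U_s|
    S  = ¼(I₀+I₁+I₂+I₃)          = |U_i|² + |U_s|²

`|U_i|²` and `|U_s|²` are the roots of x² − Sx + G² = 0; we assign the larger
root to the incident field (the brightfield-like configuration), giving
β = |U_s|/|U_i| ≤ 1 and the full-field argument
φ = atan2(β sin Δφ, 1 + β cos Δφ). Conventions and edge cases:

* **Two phases.** Both Δφ (scattered-vs-incident difference) and φ (argument
  of the total field) are exposed — `AmplitudeFields.delta_phi` and
  `PhaseMap.phi` — because downstream uses differ in which they mean.
  The simulator's ground-truth phase is Δφ.
* **Degenerate pixels.** Where modulation G < 10⁻¹² S the fringe carries no
  phase information; Δφ = φ = 0 and β = 0 by convention (avoids atan2(0,0)).
* **Equal-root case.** At β → 1 the discriminant S² − 4G² cancels to
  rounding noise; it is clamped at zero, never raised, and β loses half the
  mantissa (≈10⁻⁸ accuracy) there.
* **Principal branch.** φ ∈ (−π, π]; no unwrapping — blood smears are thin
  and well inside the branch.
* **Color stacks.** Each channel is inverted independently and the phase maps
  averaged (`per_channel_mean`, default — reduces uncorrelated noise), or the
  frames are collapsed to Rec.-709 luminance first (`luminance`). On
  noiseless data with identical channels both agree to machine precision.
* **Halo.** The acquisition geometry leaves the phase-contrast halo in all
  four frames, so it is *not* corrected; the simulator injects it instead
  (below), and the round-trip tests run halo-free.

## Smear simulator (`pics.smear_sim`)

The simulator emulates the study conditions of a Wright-stained smear survey
so the full pipeline can be exercised without clinical data.

* **Population.** Four WBC classes with priors at the midpoints of the
  normal differential ranges — neutrophils 40–60 %, lymphocytes 20–40 %,
  monocytes 2–8 %, eosinophils 1–4 % — renormalized over the four classes
  (≈ 0.571 / 0.343 / 0.057 / 0.029). Basophils are not simulated. Per-field
  WBC counts are Poisson (mean 2) truncated at ≥ 1, matching fields selected
  to contain leukocytes; the mean is a documented guess, as no per-field
  count distribution is published.
* **Morphology.** Neutrophil: 3–5 nuclear lobes; eosinophil: bilobed nucleus
  with red granular cytoplasm; lymphocyte: large round nucleus, thin rim;
  monocyte: kidney-shaped nucleus, largest body. Diameters follow hematology
  convention (lymphocyte 8–10 µm, neutrophil/eosinophil 10–14 µm, monocyte
  14–18 µm); RBCs are anucleate biconcave discs (6.5–8 µm) drawn underneath.
  All shape constants are module-level and configurable.
* **Rendering.** Brightfield colors map components directly to a Wright
  palette (purple nuclei, red granules, pale pink RBCs) — a learnable
  phase↔color correspondence, not a physical staining model. The phase map
  assigns nucleus > cytoplasm > background optical pathlength and is lightly
  smoothed; labels stay crisp.
* **Placement.** WBC bounding squares may not overlap (rejection sampling
  with a systematic grid fallback, whole-field resampling, then a
  `GenerationError`); this makes ground-truth boxes disjoint so every
  foreground component lies in exactly one box. WBC–RBC overlap is allowed.
* **Interferograms.** I_k = T·(1 + β² + 2β cos(φ_eff + kπ/2)) + ε, with T
  the per-channel stain transmission, ε ~ N(0, σ²) clipped to I ≥ 0, and
  φ_eff = φ − h·lowpass(φ) injecting the high-pass halo character
  (h ∈ [0,1], Gaussian low-pass width 8 px by default; defaults h = 0.25,
  σ = 0.01, β = 0.3).
* **What it does not model:** optical diffraction and partial coherence,
  stain chemistry variation, touching/overlapping leukocytes, platelets and
  debris, uneven illumination. Passing tests on this simulator therefore
  demonstrate the pipeline's mechanics (losses, harnesses, fusion, metrics)
  and achievable separability under clean conditions — not clinical-image
  performance.
* **Splits.** A fixed test set is held out first; the remainder is split
  train:val at 8:1, five times, with val = ⌊remaining/9⌋ (504 images with 50
  test → 404 train / 50 val). Rounding is the floor rule; the source
  protocol does not state one.

## Networks (`pics._nn`, `translation`, `detection`, `segmentation`)

No autodiff framework is used: layers (im2col convolutions, batch-norm,
pooling, nearest-neighbour upsampling, dropout) carry hand-written backward
passes verified against finite differences in the test suite, and Adam is
implemented directly. Networks are deliberately compact so the pipeline
trains on one CPU; all widths/depths are configurable and the reproducible
substance is the objectives and training contracts, not backbone scale.

* **Translator** — pix2pix-style conditional GAN. Objective
  L_cGAN = E[log D(x,y)] + E[log(1 − D(x,G(x,z)))]; D ascends it, G descends
  the second term plus λ‖G(x) − y‖₁ with λ = 100 (the pix2pix convention;
  the weight is not published). The noise z is realized as train-time
  dropout in the decoder. Probabilities are clamped at ε = 10⁻⁷ inside
  logs. Generator: depth-3 encoder–decoder with skips, tanh output in
  [−1, 1]; discriminator: two-level patch classifier on the (input, image)
  pair. Training: Adam, generator lr 2·10⁻⁴ (the discriminator mirrors it;
  its rate is not published), batch 2; the snapshot with the lowest
  validation loss is kept. Inputs are phase maps rescaled to [0,1] by the
  dataset's 1st–99th percentiles (normalization is a package choice).
* **Detector** — single-scale anchor head (stride 8, anchor sizes 16/24/34 px,
  aspect 1) on a three-level backbone. Compound loss: focal classification
  (α = 0.25, γ = 1.5, per-class sigmoids, normalized by positive-anchor
  count) + smooth-L1 on center/size offsets of positive anchors
  (IoU ≥ 0.5 positive, < 0.4 negative, in-between ignored, best anchor per
  GT forced positive). Class biases start at σ⁻¹(0.01) so focal loss is
  stable from epoch 1. Early stopping: validation mAP not increasing for 10
  consecutive epochs; the highest-mAP snapshot is returned. Inference:
  per-class score threshold 0.5 and class-wise NMS at IoU 0.5 (both
  conventions, both configurable). A full-scale pretrained detector can be
  substituted — anything with `forward/state/load_state` and the same head
  layout satisfies the contract.
* **Segmenter** — compact U-Net: five convolution blocks on the contracting
  side of which four pool (the fifth is the bottleneck, so inputs need only
  be divisible by 2⁴ = 16), four up-sampling blocks with skip connections,
  channel doubling per level, sigmoid head. The published block description
  assigns pooling to the expansion path; standard U-Net semantics require it
  on the contracting side and we read the two lists as swapped. Blocks use
  2 (configurable: 1) 3×3 conv+BN+ReLU stages. Loss: per-pixel MSE against
  {0,1} masks; Adam, lr 3·10⁻⁵, batch 2; stop after 5 epochs without
  validation-loss decrease, lowest-loss snapshot kept. Binarization at 0.5
  with ties to foreground.

The published learning rates above are the config defaults. The scaled-down
runs in this package use larger rates (2·10⁻³ detector, 10⁻³ segmenter):
the compact numpy networks are far smaller than the published backbones and
under-train badly at rates tuned for them; this is a deliberate scaled-run
setting, documented here once.

## Fusion and voting (`pics.fusion`)

Per pixel: mask 0 → background; mask 1 inside exactly one box → that box's
class; inside several boxes → the covering box with the highest confidence;
inside none → background. Box membership is half-open
(x_min ≤ x < x_max) in 0-based raster coordinates. Two tie rules are package
choices (none are published): exact confidence ties and majority-vote ties
both resolve to the smallest label — background-favoring, the conservative
direction for screening. Majority voting is the per-pixel mode across the
ensemble's maps; it is permutation-invariant and idempotent on unanimous
input.

## Metrics (`pics.metrics`)

* **AP/mAP.** Greedy confidence-descending matching, one detection per
  ground truth, IoU threshold 0.5 (the classical convention; the published
  protocol is unstated). AP integrates the all-point interpolated PR
  envelope (an 11-point variant is provided for comparison); mAP is the
  equal-weight mean over classes, with classes absent from both predictions
  and ground truth excluded as undefined.
* **Pixel scores.** Per-class precision/recall/F1 over pooled test-set
  pixels; macro averages include the background class (five classes), which
  is required to reproduce the published voting-table averages. Classes
  absent from both maps score 1 with support 0.
* **Aggregation.** Repeated-split columns are arithmetic mean ± population
  (divide-by-n) standard deviation — the convention that exactly reproduces
  the bundled reference rows (`pics.benchmarks`; one row is internally
  inconsistent at the 2·10⁻⁴ level and is documented there).

## Pipeline (`pics.pipeline`, `pics.protocols`)

Each repeat trains its stages on that repeat's split, always evaluating on
the one fixed test set; in SLIM mode the single-channel phase map is
replicated to three channels (channel handling for phase input is a package
choice). All stage artifacts are persisted and the report is compiled from
disk, so regeneration is idempotent; every stage seed derives from the
single run seed through named (stage, repeat) substreams.

`pics.protocols.scaled_study` fixes this package's CPU-scale study: 80×80 px
fields at 0.55 µm/px, 245 images (200 train / 25 val per repeat, 20 test),
five repeats, detector ≤ 40 epochs and segmenter ≤ 20. The sizes were chosen
once so several monocytes can coexist in a field and a five-repeat study
completes on one CPU core in minutes; its scores are sanity bars for the
mechanics, not reproductions of clinical-scale results.

## Known limitations

* The synthetic classes are more separable than real leukocytes; absolute
  mAP/F1 on the simulator exceed what the same pipeline could achieve on
  clinical smears.
* The detector is single-scale; heavily varying magnifications would need
  the pluggable-backbone route.
* No instance separation: touching WBCs of one class fuse into one
  component (the simulator forbids WBC–WBC overlap for exactly this reason).
* Phase unwrapping, halo removal and slide-level mosaicking are out of
  scope.
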