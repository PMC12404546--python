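# Methods

`ihcprior` classifies immunohistochemistry (IHC) patches into four
expression grades — negative, weak positive, positive, strong positive —
by combining a conventional CNN view of the patch with a *stain-chemistry
prior*: a color-deconvolution estimate of where, and how strongly, the DAB
chromogen has deposited.  This note documents the model, the synthetic data
the package trains and validates on, and the numerical and design choices a
maintainer would want to know about.

## Stain separation (the CD prior)

Brightfield stains obey the Lambert–Beer law: transmitted intensity in
channel c is `I_c = I_0 * 10^(-OD_c)`, and the optical density `OD_c =
-log10(I_c / I_0)` is *linear* in stain concentration.  Each dye is a unit
3-vector of per-channel optical densities; for hematoxylin–eosin–DAB we use
the classical published matrix

```
M̂ = [0.65 0.70 0.29]   (hematoxylin)
    [0.07 0.99 0.11]   (eosin)
    [0.27 0.57 0.78]   (DAB)
```

A pixel's OD vector y mixes the per-stain concentrations C as `y = C·M̂`
(row convention), so unmixing is a 3×3 inversion.  We store the
deconvolution matrix in the column-vector layout `D = inv(M̂ᵀ)` — the
orientation in which this matrix is conventionally printed (entry (1,1) ≈
1.88) — and compute `C = od @ D.T`.  Note the published M̂ and D derive
from unrounded source measurements: M̂ is *not* exactly the row
normalization of the usual 2-decimal raw matrix (the eosin row differs by
up to 0.03), so the package stores each published matrix verbatim rather
than recomputing one from another.

Numerical choices:

- Incident intensity `I_0 = 255` per channel (8-bit white).
- Transmitted intensities are clamped at one grey level before the log, so
  OD is finite and bounded by `log10(255) ≈ 2.41`.
- CD34 slides carry only hematoxylin and DAB; the 2×3 stain matrix is
  completed to 3×3 with the unit cross product of the two rows
  (unclamped — the residual is an algebraic complement, not a dye, and
  orthogonality is what makes it absorb only out-of-span color; this
  matches skimage's H-DAB matrices).
- Matrices with condition number above 1e8 are rejected rather than
  inverted.
- The **anomaly map** is the DAB concentration channel clipped to
  `[0, saturation_od]` and divided by `saturation_od` (default 1.0, a
  typical strong-DAB OD).  Negative unmixed concentrations are clipped to
  zero in the map but preserved in the `ConcentrationMap`, since clipping
  is a feature choice, not algebra.  The map is single-channel; an RGB
  re-rendering of the DAB channel is available for visualization only.

## Synthetic patches

The generator renders labeled patches through the same Lambert–Beer
forward model, so the whole pipeline is testable without any slide
archive.  A scene is: hematoxylin "nuclei" (overlapping disks,
max-composited, per-nucleus OD uniform in 0.35–0.7, total coverage ≈ 22%
of the patch at any scale) plus DAB-positive structures (disks, or
ribbon-shaped random walks as a crude vessel analogue) with a flat
concentration `dab_mean_od` over a mask grown to the target
`dab_area_fraction`.  Concentrations map to OD through the unit-norm
hematoxylin/DAB vectors, to RGB through `I = 255·10^(-OD)`, plus Gaussian
pixel noise (sd 2 grey levels) and per-patch stain-vector jitter (sd 0.02
before renormalization) to emulate slide-to-slide staining variation.
With jitter and noise disabled and quantization off, unmixing recovers the
generating concentrations to machine precision — the generator and the
deconvolution module are exact inverses by construction.

Labels follow the semi-quantitative scoring convention: staining intensity
scored 0–3 (OD bin edges 0.15 / 0.4 / 0.8) plus positive-area proportion
scored 0–4 (edges 0.01 / 0.1 / 0.33 / 0.66); the total maps to classes as
0 → negative, 1–3 → weak, 4–5 → positive, 6–7 → strong.  The scoring
convention does not fix its cut points; these defaults produce four
well-populated classes and are fully configurable.  Every record's label is
computed from its *achieved* ground truth (the rendered mask fraction), so
label consistency holds by construction; per-class sampling ranges keep a
0.05 OD margin to the bin edges so area overshoot cannot flip a class.

What the generator does **not** emulate: real nuclear texture and chromatin
patterns, membranous vs. cytoplasmic DAB localization, stain bleed-through
beyond the linear model, focus/compression artifacts, and the long-tailed
morphology of real vasculature.  Passing tests therefore demonstrate that
the method's machinery is correct and that the prior helps when DAB
intensity/area carry the class signal — not that any particular accuracy
transfers to clinical slides.

Dataset plumbing follows standard whole-slide practice: non-overlapping
patchify (a tile is kept when ≥ 10% of its pixels have mean OD > 0.15 —
the screening statistic is a package choice, screening itself is standard),
stratified 7:3 train/validation split with floor-on-the-training-side
rounding (2,437 → 1,705/732), and label-preserving augmentation (quarter
rotations; crop-and-resize; per-channel gain jitter bounded at ±4.5% so the
induced OD shift < 0.02 stays inside the scoring margin).

## The classifier

Two branches share one backbone architecture:

- **IHC branch** — backbone on the RGB patch → features `F ∈ R^{16×16×c}`,
  re-weighted by a feature-importance attention: the patch's grayscale
  image (ITU-R 601 luminance, area-average downsampled to the 16×16 grid)
  multiplies each min–max-normalized feature channel to form a mask stack;
  a small shared scorer (the FWB: two 3×3 convs, hidden width 4 → global
  average pool → linear) maps each mask to an importance score `S_c`; the
  class activation map is `CAM = ReLU(Σ_c S_c F_c)`, max-normalized per
  sample to [0, 1], and the attended features are `(1 + CAM) ⊗ F` — the
  bounded attention-residual form, so the re-weighting is between 1× and
  2× regardless of the channel count or the score scale.  (Unbounded, the
  CAM magnitude grows with c and the attended branch drowns the CD branch
  out of the fused LayerNorm.)  The FWB applies identical weights to every
  channel, which makes it channel-permutation-equivariant and keeps its
  parameter count independent of c.
- **CD branch** — the same backbone (1-channel stem) on the DAB anomaly
  map.

Both branches are globally average-pooled to c-vectors, concatenated,
LayerNorm-ed over the flattened 2c features, and mapped by a single linear
layer to the logits.  Cross-entropy is the loss.  Either branch
modification can be ablated (`use_prior`, `use_attention`).

Design choices where the design was genuinely open:

- *FWB internals*: the smallest head matching the mask-stack-in /
  score-vector-out contract, kept swappable behind `fwb_scores`.  The score
  head's bias starts at +0.5: post-ReLU feature magnitude concentrates on
  tissue, so a uniformly positive initial score vector makes the CAM start
  as feature-magnitude saliency and the `ReLU` in the CAM meaningful;
  training then differentiates the channels around that operating point.
  (With a zero-centered start the learned scores stay near zero and the
  attention map degenerates into sign noise that does not highlight the
  stained structures.)
- *Attention gradients*: the loss gradient flows through the CAM into the
  FWB parameters and into the backbone features (both through the direct
  `(1+CAM)⊗F` product and the `Σ S_c F_c` term); the min–max-normalized
  mask stack entering the FWB and the CAM's per-sample peak are treated as
  stop-gradient, because min/max subgradients are sparse and make those
  paths noisy without adding signal.
- *Constant feature channels* min–max-normalize to all-zeros.
- *LayerNorm axis*: the flattened 2c vector.
- *Head initialization*: classifier weights scaled by 0.01 so an untrained
  model is near-uniform over classes (initial loss ≈ ln 4).
- *Backbones*: `resnet18` (standard BasicBlock [2,2,2,2]; last stage at
  stride 1 so 256 px inputs give the 16×16 grid; 11.18M parameters with a
  2-class head) and `small_cnn` (stem + log2(input/16) stride-2 conv/BN
  stages + head conv).  No pretraining; random init by default, with the
  constructor seed as the only source of weight randomness.
- The engine itself is numpy (channels-last, float32, im2col convolutions,
  momentum SGD with L2 decay) with analytic backprop verified against
  central finite differences in the test suite.

## Training and evaluation

Two named presets ship as YAML:

- `fullscale`: the reference full-scale recipe — SGD, 300 epochs, lr 1e-5 dropped 10×
  at 50% and 75% of the epochs, weight decay 1e-4, 256 px patches,
  ResNet-18.
- `desk`: the CPU-scale study used by the test suite — 30 epochs, lr 1e-3
  (same schedule shape), `small_cnn` with c = 32 on 32 px patches, batch
  32, rotation augmentation.  Problem sizes (400 train / 160 validation
  patches; 2 models × 3 seeds) were chosen so the complete study runs in
  minutes on one core while leaving the class structure non-trivial.

Checkpoint selection is by best validation macro-F1 (the literature this
follows does not state a selection rule).  Metrics are per-class
precision/recall/F1 from the confusion matrix (rows = true class), with
macro *and* support-weighted averages both reported since published tables
rarely say which they use; zero-support classes are excluded from the macro
average with a warning.  Training is a pure function of (weights seed,
shuffling seed) on one device, which the tests assert bit-exactly.

The desk-scale experiment (`compare_prior`) trains the prior-guided model
and the no-prior ablation on the identical split across seeds and reports
mean ± sd per metric plus the macro-F1 delta.  The accompanying
localization check verifies that the trained CAM averages higher inside the
generator's true DAB masks than outside on strong-positive validation
patches — the attention looks at the stained structures, not the
background.

## Known limitations

- Fixed published stain vectors only; no Macenko/Vahadane-style stain
  estimation, no whole-slide stain normalization, and no real WSI container
  formats (SVS/NDPI) — slides enter as plain RGB arrays.
- The numpy engine is single-device and eager; the `fullscale`
  preset is faithful to the reference recipe but slow without substituting a GPU framework behind
  the same module surface.
- The desk-scale accuracy figures characterize the synthetic task only
  (see the generator's non-goals above).
- Reported batch-size conventions for this kind of training vary widely
  (256/200 and 32/32 both appear); both presets expose batch size
  explicitly rather than privileging one.
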