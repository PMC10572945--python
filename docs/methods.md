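# Methods

`sonomass` implements a complete classification pipeline for grayscale
ultrasound images of adnexal (pelvic) masses: geometric augmentation,
segmentation by Tsallis-entropy multilevel thresholding of a 3D local-statistics
histogram, texture description by the wrapping fast discrete curvelet transform,
and a three-class classifier (benign / borderline / malignant) trained by a
gravitational population search with a gradient polish, plus a nomadic-people
metaheuristic used for threshold search and hyperparameter tuning.  Because no
public corpus of labeled pelvic-mass ultrasound exists, the package ships a
synthetic phantom generator that makes every stage testable end to end.

## Synthetic phantoms

Each phantom is a hypoechoic (darker-than-background) mass on a speckled
background.  The mass boundary is an ellipse whose radius is perturbed by a
sum of 7 sinusoidal harmonics (orders 2–8) with random phases; the composite
bump is normalized to unit peak so that the `irregularity` parameter is
exactly the peak radial deviation as a fraction of the local radius.  Class
difficulty is controlled by this single scalar: benign 0.02, borderline 0.12,
malignant 0.30, mirroring the clinical association between irregular margins
and malignant potential.

Defaults (chosen once as a realistic display-domain regime, then frozen):

| parameter | default | rationale |
|---|---|---|
| frame | 128 × 128 px, 8-bit | the working size of the curvelet stage |
| ellipse semi-axes | (36, 24) px, ±20% per-item jitter | a zoomed clinical still: the mass fills roughly half the frame, so a 12% boundary lobe spans ~4 px and is resolvable on the raster |
| background / contrast | 170 / −80 gray levels | clearly visible hypoechoic lesion |
| point-spread blur | Gaussian σ = 1.5 px | soft edges as after beamforming |
| speckle | gamma-multiplicative, shape 100 (≈10% relative sd), mean 1 | residual speckle contrast of *log-compressed display* B-mode; raw-envelope speckle (~35–50%) is not what an 8-bit clinical still contains |

What the phantoms do **not** emulate: depth-dependent attenuation and focus,
acoustic shadowing/enhancement, internal echotexture differences (septations,
papillary projections, solid components), Doppler signal, and operator
variability.  Passing the end-to-end tests therefore demonstrates that the
pipeline can recover a *boundary-shape* class signal through segmentation and
curvelet texture under speckle — not clinical performance.

## Segmentation

Every pixel contributes a triple (intensity, 3×3 rounded local mean, 3×3
local median); borders replicate.  The joint histogram of these triples
(quantized to `k_q = 32` bins per axis for tractability; tests use 8) is
partitioned by per-axis ascending thresholds into ML+1 diagonal boxes
(default ML = 2).  The objective is the pseudo-additive Tsallis composition

    S_z = (1 − Σ_box (p/P_z)^λ) / (λ − 1),   score = Σ S_z + (1−λ) Π S_z,

with empty boxes contributing 0.  Off-diagonal mass (speckled pixels whose
three statistics disagree) belongs to no box; reported class probabilities are
renormalized over in-box mass, and a pixel with an off-diagonal triple is
assigned the median of its three per-axis bin indices.

**Entropic index.** λ = 1.5 by default.  With λ < 1 the criterion emphasizes
rare triples and on speckled phantoms it frequently "optimizes" by slicing the
sparse dark tail without separating the mass mode from the background mode;
λ > 1 weights dominant modes and reliably places a cut inside the
edge-gradient band (on a 20-phantom probe: zero foreground-collapse failures
at λ = 1.5 versus several at λ = 0.8).  λ is configurable and the λ→1 limit
reproduces Shannon entropy (tested).

**Threshold search.** Exhaustive enumeration (global optimum, lexicographic
tie-break) when the candidate count permits; otherwise the nomadic-people
optimizer over the continuous relaxation, rounded to the lattice with a
deterministic collision repair (default budget 1500 evaluations).

**ROI extraction.** The foreground class is the one whose box contains the
darker (configurable: brighter) histogram mode.  The mode is located on the
local-mean histogram — the denoised intensity — below 0.75× (above 1.25×) the
dominant mode, assuming the mass level differs from background by ≥ ~25%; the
mode triple is then classified by the same median-of-bins vote as a pixel.
Classes beyond the mass class toward the polarity extreme are folded in
because an edge-gradient class can split the mass mode across boxes.  The ROI
is the largest connected component, hole-filled.

**Boundary refinement** (`refine_roi`, on by default in `segment_image`): the
optimal Tsallis cut level varies within the edge-gradient band from image to
image, which shifts and roughens the recovered boundary by 1–2 px — exactly
the scale of the class-defining lobes.  The boundary is therefore re-anchored
at the half-contrast level of the local-mean map (mass and background levels
estimated from the initial mask), and the mask is smoothed at the speckle
scale (Gaussian σ = 2 on the binary mask, re-threshold at 0.5).  On phantoms
this halves the boundary error (symmetric-difference fraction 0.12 → 0.04,
Dice ≥ 0.97 typical).

## Curvelet features

The wrapping fast discrete curvelet transform partitions the FFT plane with
Meyer-type radial windows (concentric max-norm coronae) and cos–Meyer angular
wedges whose squared sum is normalized to exactly 1, making the frame tight:
Parseval holds to machine precision and the adjoint is the exact inverse.
Each windowed wedge is wrapped — re-indexed modulo its frequency bounding
box, a bijection on the support — and inverse-transformed into a small
complex matrix.  Scale count follows `floor(log2(min(nc,ns))) − 3` (4 scales
at 128×128); orientations per scale are 1 (isotropic coarsest), then 16
doubling every other scale, i.e. (1, 16, 16, 32) = 65 matrices.

Eleven statistics are computed per coefficient-magnitude matrix: weighted
marginal means and standard deviations on both axes, third-central-moment
skewness, and GLCM-style contrast, energy, homogeneity, entropy
(Σ M ln M with 0·ln 0 := 0), correlation (guarded to 0 when a marginal sd
vanishes), and dissimilarity — 715 named features per image.  The marginal
moments use the weighted-marginal convention (divide by ΣM) so correlation
lies in [−1, 1].  At extraction the matrices may be normalized to unit sum
(probability convention) or left raw; the classification pipeline uses raw
magnitudes because absolute per-wedge energies carry the cross-scale energy
signature that distinguishes boundary roughness.

The pipeline feeds the *binary ROI rendering* (mask × 255) to the transform
by default — on phantoms the class signal is purely boundary shape —
switchable to the ROI-masked image or the raw image for data where interior
echotexture matters.

## Classifier

A neocognitron-style network: S-layer (32 linear feature detectors +
rectification), C-layer (max-pooling over groups of 2 → 16 position-tolerant
units), and a 3-unit output read through either independent logistic units
(model default) or a softmax (selected by the pipeline configuration, which
measurably improves three-class boundaries on the phantom features).
Features are z-scored with train-set statistics.

Training has two phases:

1. **Gravitational population search.** Agents are weight vectors in the unit
   box (decoded to signed, fan-in-scaled weights).  Masses derive from the
   full-training-set loss (best agent mass 1, worst 0, normalized to sum 1);
   pairwise forces C(a)·Q_q·Q_i/(L^b + ρ) act along unit vectors with
   per-dimension uniform jitter; acceleration divides by the agent's own mass
   (floored), velocity carries stochastic inertia, positions are clipped.
   C(a) = C0·exp(−β·a/a_max), C0 = 100, β = 20.  The elitist best is
   monotone by construction.
2. **Gradient polish.** The top-5 distinct agents are refined independently
   by mini-batch SGD (batch 12, learning rate 1.32×10⁻³ decayed ×0.1 every
   10 epochs, 30 epochs, gradients summed over the batch and classes so that
   step size is effective, optional weight decay).  Their class scores are
   averaged at prediction time — an elite ensemble that suppresses the
   considerable run-to-run variance of a single SGD trajectory.

A note on the population phase: mutual gravitational attraction averages
weight vectors, which is informative in compact search spaces but is washed
out by hidden-unit permutation symmetry in wide layers; accordingly the
"population search beats random search at equal budget" property is
demonstrated on a compact topology (4 S-units, exploration-heavy
C0 = 300, β = 10), while at the default width the polish phase does most of
the work and the population supplies diverse, elitist initializations.

## Nomadic-people optimizer

Clans of families around leaders on a bounded box: leaders initialize
uniformly; families disperse semicircularly (additive form
Y = υ + R_clan·RD·cosθ; the literal multiplicative form is available behind a
flag but collapses toward the origin when leader coordinates are near zero);
leadership transfers when a family beats its leader; a clan stagnant for 3
generations sends families on Mantegna Lévy flights (stability 1.5) toward
and past its leader.  Defaults 5 clans × 10 families, elitist best-so-far,
fully seeded.  `tune_egnnn` wraps it for hyperparameter search over
(C0, β, population, S-width), scoring candidates by validation loss of a
short training run with a fixed inner seed; integer dimensions decode by
rounding (S-width to a multiple of the pool size).

## Pipeline protocol

Stage order: simulate → segment → extract → augment → train → evaluate.  Two
deliberate deviations from the source protocol, for statistical hygiene at
desk scale:

- **Split before augmenting.**  Corpus-level augmentation followed by a
  random 3:2 split would place augmented copies of one source image on both
  sides of the split and inflate test accuracy.  Here the split is over
  source images; only training sources contribute augmented variants, and the
  test side uses the unaugmented rendering.
- **Dihedral orbit, applied to the ROI rendering.**  The joint 3D histogram
  is invariant under the square's 8 symmetries, so segmenting a rotated image
  yields the rotated ROI; the pipeline applies the full dihedral orbit
  (rotations, flips, and the two diagonal transpositions that the five named
  operations omit) directly to the segmented rendering.  The 63× expansion
  with small-angle rotations remains available in the augmentation module for
  image-domain use; it is not the desk-scale default because nearest-neighbor
  small-angle rotation corrupts binary masks.

One pipeline seed determines every artifact: phantom draws, the (shared)
threshold-search seed, the split, and training.  Default problem sizes keep a
full run at roughly a minute on one CPU: 150 phantoms (50 per class), 8
variants of each of the 90 training sources (720 training rows), a population
of 20 for 30 iterations, and a 5-member polish ensemble.

## Evaluation

3:2 train/test split with half-up rounding (39,942 items → 23,965 / 15,977),
five-fold rotation of the training part, and a report containing the 3×3
confusion matrix (rows actual), one-vs-rest per-class accuracy, precision,
specificity, sensitivity and F1 (0/0 := 0), overall accuracy, and per-class
trapezoidal one-vs-rest AUC with a macro average.

## Numerical notes and limitations

- All integer statistics (local mean rounding, medians, histogram counts) use
  exact integer arithmetic; thresholds map between quantized and full scales
  at bin boundaries.
- Curvelet windows are precomputed and cached per image shape; forward +
  inverse on 128×128 runs in tens of milliseconds.
- Ties: threshold search prefers the lexicographically smallest triple;
  prediction argmax resolves ties to the lowest class index.
- The mode-based foreground rule assumes a mass/background contrast of at
  least ~25% of the background level; lower-contrast lesions need the
  polarity/threshold configuration adjusted.
- Exact reconstruction is guaranteed for the window systems constructed here
  (supports are contiguous in the centered grid); extremely anisotropic
  images (aspect beyond ~4:1) have not been exercised.
- The boundary-shape class signal of the phantoms is a deliberate
  simplification; on clinical data the feature input should be switched to
  the masked image so interior echotexture contributes.
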