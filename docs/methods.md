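# Methods

## Problem and pipeline

Small-animal CT studies of radiation-induced lung fibrosis need per-animal
lung masks on scans that contain four to six mice per bed, acquired at
clinical CT resolution (~0.35–0.6 mm) or micro-CT resolution (~0.1–0.2 mm).
`murineseg` implements the full automatic pipeline: an HU-window reference
segmentation (the "semiautomatic" standard, with curation automated), data
preparation into normalized per-mouse axial slices, a 2D U-Net trained in
k-fold cross-validation, median fusion of the per-fold probability maps,
Otsu or hard binarization, overlap/surface-distance evaluation,
template-space mismatch mapping, and encoder-frozen transfer learning
across resolutions.

## Containers and geometry

Volumes are `(z, y, x)` arrays with per-axis spacing and origin in mm;
world position of voxel `(k, j, i)` is `origin + (k, j, i)·spacing` (voxel
centres, 0-based).  NRRD and NIfTI I/O goes through SimpleITK; NRRD files
must carry an explicit `space directions`/`spacings` field rather than
falling back to unit spacing.  Isotropic resampling chooses the output size
`round(shape·spacing/target)`, which preserves physical extent to within
half a voxel per axis; intensities interpolate linearly, masks
nearest-neighbour (binarity is an invariant, not a hope).

## Reference segmentation

`threshold_lung` selects voxels in the closed interval [−900, −100] HU (the
inclusive reading of "between"; an open-interval flag exists).  The window
also captures the trachea and primary bronchi.  The published protocol
removed those by hand; `clean_mask` is an **automated surrogate**, not a
reproduction of human curation: morphological opening with a ball of
physical radius `airway_radius_mm` (default 0.9 mm) followed by
reconstruction — whole 26-connected components that survive the opening are
restored, thin tube-like components vanish entirely — then retention of the
`keep_components` (default 2) largest components.  The operation never adds
voxels and is idempotent.  Connectivity, component count and airway radius
are configurable because no published values exist for them.

## Phantoms

`generate_mouse` builds a thorax from ellipsoids: a soft-tissue body
(+20 HU) on air background (−1000 HU), two lung lobes (−750 HU, inside the
−900…−100 HU window by construction), a heart that indents the medial lung
surfaces (so mismatch analysis has a realistic hot-spot site), and a thin
airway at lung-like HU that is *excluded* from the ground truth — giving
the HU-window segmentation exactly the kind of surplus the cleanup must
remove.  Per-animal anatomical variability is mild and seeded (~3%
semi-axis jitter, sub-2-voxel positional shifts).  Fibrotic lesions are
spheres grown from random in-lung seeds (radius 2–4.5 voxels) until exactly
`round(fibrosis_fraction·|lung|)` voxels are raised to −300 HU; the final
blob is trimmed nearest-first so the achieved fraction is exact to one
voxel.  Gaussian noise (default sd 20 HU, a typical low-dose small-animal
noise magnitude) is added last; HU are kept as floats with no integer
rounding so determinism by seed holds across platforms.  An emphysema
variant (patches below −900 HU) exists behind a flag, default off.

`generate_bed` tiles 1–6 mice on a 1×n or 2×n grid, one animal per tile,
so bodies and masks are disjoint by construction; bed-level noise is added
once.

What the phantoms do **not** model: reconstruction texture and streaks,
beam hardening, partial-volume blur at interfaces, respiratory motion,
genuine anatomical shape variation beyond affine-like jitter, and real
fibrosis texture (the lesion model is an invention controlled by one
severity knob).  Phantom results therefore demonstrate that the pipeline's
machinery is correct and well-calibrated, not that the network reaches any
particular accuracy on real animals.

## Data preparation

Cropping uses the tightest reference-mask bounding box expanded by
`margin_voxels` (default 10) and clamped to the grid, with origins shifted
so world coordinates are preserved.  The margin matters: with too little
surrounding context the network has no evidence to reject exterior
air/tissue interfaces near the crop border, and small false-positive islands
appear there.  Crops are resampled isotropically (0.35 mm standard,
0.2 mm micro-CT), then min–max normalized **per volume** to [0, 1] (per
volume, not per slice, keeps inter-slice contrast consistent; a fixed-window
alternative is available).  Axial sections are zero-padded symmetrically to
a multiple of `pad_multiple` (default 16 = 2⁴ pooling levels); the padding
is recorded and slice extraction/restacking inverts exactly.

## Network and training

The U-Net has `depth` pooling levels (default 4) with `base_filters`
channels at the top (default 32), doubling per level: per block two 3×3
convolutions + ReLU; 2×2 max pooling down, 2×2 transposed convolutions up,
skip concatenation, 1×1 sigmoid head.  The published architecture figure is
not reproduced in the available text, so these are the canonical U-Net
defaults, all configurable.  Forward and backward passes are written in
numpy (im2col convolutions); analytic gradients are verified against
central finite differences in the test suite, with a second-difference
guard that skips parameters whose ±ε window straddles a ReLU/max-pool kink.

Training follows the published recipe: Adam at learning rate 10⁻⁴, binary
cross-entropy loss, Dice monitored on the validation fold, batch 50, 30
epochs, 5 folds at 80/20.  Fold splits are at scan (subject) level — all
slices of one animal stay on one side of each fold — and each subject
appears in exactly one validation set.  Per fold the best-validation-Dice
epoch's weights are kept (`keep="last"` restores the alternative, since the
published text does not say which was used).  No data augmentation and no
class weighting, as none are described.

The **scaled profile** used by the CPU-scale studies and CI keeps the
recipe's shape but shrinks it: 64×64 slices, base 8 filters, depth 3, 2
folds, 5 epochs.  At 5 epochs the step budget is small, so the profile uses
batch 3 with learning rate 2·10⁻³ (tuned for convergence within that
budget on the phantom task), and `train_fold` initializes the head bias to
the logit of the foreground prevalence so unlearned regions default to
"not lung" rather than probability 0.5 — standard practice for imbalanced
segmentation that also keeps uncertain background away from the
binarization threshold.

Transfer learning freezes everything up to and including the bottleneck
("encoder"); frozen parameters are never touched by the optimizer, so they
are bitwise identical after retraining — an invariant asserted in tests,
not an approximation.

## Inference and binarization

Each axial section passes through each fold model; maps are restacked and
un-padded onto the input grid, and fused voxelwise by the median (for even
fold counts, the mean of the central pair — median fusion is permutation-
invariant and idempotent by construction).  Binarization is `p ≥ t` with
`t` either hard 0.5 or the Otsu threshold computed once per volume over a
256-bin histogram of [0, 1], maximizing the between-class variance
`w₀w₁(μ₀−μ₁)²` with ties broken toward the lower edge.  One consequence of
that tie rule worth knowing: for a cleanly bimodal map the variance is
constant across the empty gap between modes, so the threshold sits at the
gap's *lower* boundary (scikit-image's Otsu does the same); this changes
nothing about which voxels are selected.  No post-processing follows
binarization by default (largest-component filtering is available behind a
flag).

## Evaluation

DSC is the standard overlap ratio; two empty masks score 1.0 with a warning
(the all-negative case is agreement).  HD95 takes surface voxels (mask
voxels with a face-adjacent background neighbour, grid boundary counting as
background), computes nearest-surface distances between voxel centres in
world coordinates in both directions, pools them, and returns the 95th
percentile with linear (type-7) interpolation; `max_directed` gives the
alternative convention.  Cohort summaries report median and IQR.  The
fibrosis index is a **surrogate** — the fraction of in-mask voxels above a
cutoff (default −500 HU) — monotone in lesion burden on phantoms but *not*
the published fibrosis-index formula, which lives in the fibrosis
literature this package does not reimplement.

## Mismatch mapping

Subjects are registered to an iterative mean template: rigid alignment to
the first volume and averaging (iteration 0), then rounds of registration
to the current mean.  The default stack is multi-resolution affine followed
by a coarse B-spline refinement, mean-squares similarity (same-modality CT;
mutual information available), full metric sampling for the affine stage
and a seeded 25% regular sample for the B-spline stage.  Signed differences
(reference − network, in {−1, 0, +1}; positive = network under-segments)
are warped per subject to template space, and each voxel gets
`z = mean/sd` across subjects, with the population sd by default
(`ddof=1` behind a flag — the published normalization is not specified).
Zero-variance voxels are flagged invalid and set to 0 rather than infinity.

## Study recipes (`experiments`)

`run_scaled_study` trains the scaled 2-fold ensemble on 20 phantoms whose
fibrosis severity cycles through {0, 0.1, 0.2, 0.3} — a cohort spanning
healthy to markedly fibrotic lungs — and evaluates 5 held-out phantoms
under both binarization modes.  `run_transfer_study` trains a base model at
0.35 mm and adapts the decoder to a cohort generated at 0.2 mm where
anatomy spans 1.5× as many voxels.  `run_interchangeability_study` trains
the same scaled ensemble for 10 epochs (lesion capture keeps improving past
the 5-epoch accuracy benchmark) and compares fibrosis indices and in-lung
HU histograms between network and reference masks on noiseless phantoms at
the severest cohort level.  Problem sizes (20/5 subjects, 8–12 transfer
subjects, 8-subject mismatch cohorts) are chosen so each study completes in
minutes on one CPU while keeping enough subjects for median/IQR summaries.

## Known limitations

- 2D slice-wise segmentation has no through-plane context; systematic
  errors concentrate at interfaces (heart/lung, air/tissue), which is
  exactly what the mismatch analysis is for.
- Under the scaled profile this shows up concretely: on some cohort seeds
  one of the two training folds under-converges on exterior-air
  suppression near the crop border, and because a two-member "median" is a
  mean, the fused probability there can straddle the data-adaptive Otsu
  threshold — visible as held-out HD95 outliers of a few mm while DSC
  stays above 0.96.  The full 5-fold, 30-epoch recipe is far less exposed:
  a true median ignores one bad fold.
- The airway cleanup and the fibrosis index are documented surrogates for
  steps that were manual or externally defined in the original protocol.
- Phantom cohorts share one generative anatomy family; template
  registration on them is much easier than on real animals, so the
  registration defaults should be revisited for real data.
- The numpy engine is single-threaded BLAS-bound; it trains the scaled
  profile in minutes but is not meant for full-resolution 30-epoch runs.
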