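# Methods

This note records the models, conventions and numerical choices behind
`pzseg`, including every place where the design was genuinely open and the
package had to commit to one reading.

## Segmentation model

Each ensemble member is a U-shaped residual encoder–decoder with a shared
down-sampling path and two decoder paths: `up-pg` (whole gland) and `up-pz`
(peripheral zone).  Structure, per member:

- Down path: `n_blocks` residual blocks, each followed by 2×2 max-pooling;
  a spatial-dropout layer precedes every residual block except the first.
- One middle residual block joins the paths (the "U" bottom).
- Each decoder: `n_blocks` stages of spatial dropout → 2× nearest-neighbour
  up-sampling → concatenation with the matching encoder features → residual
  block.  Filters start at `base_filters`, double per level down, and mirror
  on the way up.
- The final `up-pz` features are concatenated into the gland head, so zonal
  evidence conditions the gland boundary.  Both heads are kernel-size-1
  convolutions with sigmoid activations.
- A residual block is 3 × [zero-padded convolution → batch normalisation →
  activation] plus an additive shortcut, with a 1×1 projection when the
  channel counts differ.

Open points the package decided:

- **Lateral skips.** "U-shape" does not by itself fix whether encoder
  features are concatenated into the decoders; lateral skips are the U-Net
  convention and are on by default here.
- **3D pooling.** A 23-slice (or 8-slice) volume cannot be halved
  `n_blocks` times through-plane; pooling and up-sampling act in-plane only
  (2×2×1), preserving the slice count at every scale.
- **Shortcut placement.** The shortcut is added after the third
  conv–norm–activation stage (post-activation residual).
- **Decoder branching.** Both decoders branch from the middle residual
  block.
- **Up-sampling operator.** Nearest-neighbour up-sampling followed by the
  block's convolutions (not transposed convolution).
- **Initialisation.** He-uniform, seeded; fully reproducible.

The 12-component hyperparameter vector is 7 architecture components
(`n_blocks`, `base_filters`, activation ∈ {relu, elu, leaky_relu}, the three
kernel sizes used by every residual block, spatial-dropout probability ∈
[0, 0.5]) plus 5 augmentation magnitudes (rotation degrees, width shift,
height shift, zoom — all fractions of the in-plane size — and a horizontal
flip switch).  All residual blocks share the same kernel triple, dropout
rate and activation, which is what keeps the search 12-dimensional.

### Autodiff core

No GPU framework is assumed: `pzseg.autodiff` is a compact reverse-mode
tensor engine (stride-1 same-padded N-D convolution via sliding windows,
batch normalisation with running statistics, in-plane pooling/up-sampling,
channel concatenation, spatial dropout, sigmoid, Adam).  Gradients were
verified against central finite differences to ~1e-8 relative error.  It is
written for the small problem sizes this package targets; it is not a
general-purpose deep-learning library.

## Losses and metrics

- **Training loss** (differentiable, squared denominators):
  `1 − 2Σp·y/(Σp² + Σy² + ε)` per structure, combined as
  `loss(gland) + α·loss(pz)` with α = 0.1 and ε = 1e-6 for stability.  When
  a case has no PZ reference the PZ term is skipped.
- **Evaluation Dice** uses set cardinalities, `2|y∩ŷ|/(|y|+|ŷ|)`.  The two
  forms coexist deliberately; they coincide for binary predictions at ε = 0.
  Both masks empty is defined as Dice 1.
- **Hausdorff distance** is the full symmetric maximum (not a percentile
  variant) between boundary-voxel centres in physical millimetres; boundary
  voxels are mask voxels with ≥ 1 face neighbour outside.  An empty mask is
  an error, recorded as missing — never as 0.
- **Cohort discrepancies** compare pooled voxel-intensity histograms (100
  uniform bins on [0, 1], all voxels pooled, background included): KL with
  1e-12 smoothing of the reference-free argument, 1-D Wasserstein as the
  CDF-difference integral on the bin grid (so the value is on the intensity
  scale), and the Jensen–Shannon *distance* (base-2, bounded by [0, 1]).
  Whether pooled or per-case-averaged histograms (and which bin count)
  underlie published discrepancy tables is generally unstated; pooled with
  100 bins is this package's documented choice.

## Bayesian hyperparameter search

Sequential model-based optimisation of λ against the validation loss of
partially trained networks (`partial_epochs` per candidate; partial training
is what makes the search affordable, at the known risk of favouring
fast-learning architectures).  Choices:

- Surrogate: Gaussian process, Matérn-5/2 ARD kernel on features encoded to
  [0, 1] (integers and reals min–max scaled, categoricals one-hot), length
  scales bounded to [1e-2, 10], observation jitter 1e-6, 3 restart fits.
- Acquisition: expected improvement (ξ = 0.01) maximised over a 1,000-point
  random candidate pool; already-evaluated points are filtered from the pool
  (the objective is deterministic given the seed), which also guarantees
  that a discrete space is enumerated rather than resampled.
- Warm-up: `n_init = 5` uniform random trials.
- Default space: depth {2, 3, 4}, base filters {8, 16, 32}, three
  activations, kernels {3, 5}, dropout [0, 0.5], rotation [0°, 30°], shifts
  [0, 0.2], zoom [0, 0.3], flip {off, on}.
- The 2D and 3D searches run independently and share the space definition.
- Divergent candidates (non-finite loss) are recorded at the worst possible
  loss (1 + α) with a warning, and the search continues.

## Preprocessing

Fixed order: resample → standardise shape → normalise intensity.

- Resampling to the target spacing (default 0.5 × 0.5 × 3 mm) uses cubic
  B-spline interpolation for images and nearest-neighbour for masks (so they
  stay binary); the physical centre is preserved, hence the extent matches
  within one voxel.
- "Resizing" to the reference grid (default 256 × 256 × 23) is a symmetric
  centre crop/pad **at fixed spacing** — anisotropic stretching would
  silently change the standard resolution.  Pad value: image minimum for
  images, 0 for masks.  The signed offsets are recorded so predictions map
  back to the native grid (nearest-neighbour resampling on the way back).
- Intensity normalisation is per axial slice: clip to mean ± 3 sd of that
  slice, then min–max rescale to [0, 1].  The slice-wise reading governs
  both the clip statistics and the rescale.  Constant slices map to zeros
  (avoids division by zero).

## RT-contour handling

Planar polygons (patient millimetres) convert to voxel masks via a
deterministic even–odd rule on voxel centres: a centre exactly on an edge
counts as inside when the edge is on the lower-index side (half-open rule),
which makes adjacent tilings non-overlapping.  Polygon planes snap to the
nearest slice within half the through-plane spacing; farther contours are an
error naming the offending plane.  Multiple polygons on a slice combine by
parity, which supports holes.  The inverse (`masks_to_contours`) traces
pixel-boundary loops with vertices on half-integer indices, so no voxel
centre can lie on an edge and re-rasterization is voxel-exact; the point-in-
polygon convention is this package's, since annotation tools rarely state
one.  Direction matrices must be orthonormal (oblique allowed, shear not).

## Phantom generator

The generator emulates the *cohort-level properties* that matter to this
pipeline, not MR physics:

- **Gland**: an ellipsoid (default axis ratios 1 : 1.15 : 0.85) with a
  band-limited radial perturbation (Gaussian-filtered noise field, amplitude
  0.06) for organic boundaries.  A global scale is bisected until the voxel
  count matches the requested volume, so realised volumes are
  discretisation-exact; infeasible requests fail naming the maximum feasible
  volume.  Largest connected component kept.
- **PZ**: the shell between an inner confocal level set and the gland
  surface, clipped to the posterior half — a crescent in axial slices.  The
  inner level is bisected to hit the target PZ fraction (default 0.27 of
  gland volume, matching the observed PZ-to-gland ratio of ~16/60 cm³).
  Quantitative PZ shape statistics are not available in the literature this
  emulates; only the volume fractions are calibrated.
- **Intensities**: Gaussian per region (background / central gland / PZ,
  with PZ brightest, as on T2).  The "bimodal heavy-tail" profile adds a
  log-normal bright subpopulation (4 % of voxels) to produce the heavy right
  tail typical of 3T training cohorts; "unimodal low-contrast" concentrates
  density below ~0.2 after normalisation, emulating domain-shifted cohorts.
  Additive Gaussian noise, sd 0.04 by default; Rician noise and coil-bias
  fields are out of scope.
- **Cohorts**: per-case seeds spawn deterministically from a master seed;
  the default sampler draws gland volumes from N(55, 12²) cm³ truncated to
  the grid-feasible range, spanning roughly 25–70 cm³ as observed across
  multi-centre prostate cohorts.  `shift_cohort_intensity` re-renders a
  cohort's intensities under another profile with identical geometry/masks
  (same per-case seed), so a self-remap is exactly the identity — the tool
  for manufacturing domain-shift experiments.

What passing on phantoms does **not** show: robustness to real anatomy
(bladder/rectum context, lesions), scanner artefacts, reader variability, or
inter-protocol geometry differences.  The phantoms exercise the code paths
and the statistical machinery, not clinical performance.

## Ensemble and inference

- Folds: "5 folds, 80 %/20 % randomly assigned" is read as disjoint 5-fold
  cross-validation (each case validates exactly once, sizes balanced within
  one); the alternative reading — five independent random splits — is
  available via `mode="random"`.
- Fusion order: within a pair, average the 2D and 3D probability maps
  (inside the 3D crop; outside it the 2D probability stands alone, since
  averaging against an undefined 3D value would bias toward background),
  threshold at 0.5, then majority-vote across the five pairs.
  Averaging-then-thresholding across pairs is available via
  `vote="probability"`.
- The 3D crop is centred (default 128 × 128 × 23 of the 256 × 256 × 23
  grid); gland-centred cropping was considered and rejected as it would leak
  reference information at inference time.
- No post-processing (largest-component filtering, hole filling) by
  default: reported failure modes of such networks include discontinuous
  contours, and silently cleaning them would hide exactly that behaviour.
- Full-scale schedule defaults: 3,000 epochs (2D), 2,000 epochs (3D), Adam
  with β₁ = 0.9, β₂ = 0.999, ε = 1e-8, learning rate 1e-5, best-validation
  checkpointing, real-time augmentation with the searched magnitudes.

## Statistics

- 95 % CIs are normal-theory t intervals (mean ± t₀.₉₇₅,ₙ₋₁·sd/√n); the
  construction is swappable but bootstrap is not the default.
- Quartile stratification ranks cases by reference gland volume (ties broken
  by case id) and partitions into four contiguous groups differing by at
  most one case — the empirical 25/50/75 split with a deterministic
  tie-break.
- Cohort volume comparisons use Welch's unpooled two-sample t-test
  (two-sided); model comparisons use a one-tailed paired t-test in the
  direction of the larger sample mean, winner declared at p < 0.05,
  all-zero differences a declared tie (p = 0.5).  No multiple-comparison
  correction is applied.

## Scaled-down study conditions

The full-scale recipe is a GPU-sized workload, so the package's end-to-end
study (`pzseg.studies.run_small_study`, also driven by
`scripts/acceptance.py`) shrinks the geometry while keeping every code path
identical:

- Grid 16 × 16 × 8 at 5 × 5 × 6 mm (extent 80 × 80 × 48 mm); flattened
  gland axis ratios (1 : 1.2 : 0.6) so volumes near 30 cm³ fit 8 thick
  slices; cohort volumes N(30, 6²) cm³.
- 40 training phantoms, 20 held-out phantoms, 5 folds.
- Fixed member vector: 1 residual level, 4 base filters, relu, 3/3/3
  kernels, dropout 0.05, mild augmentation (5°, 2 % shifts, 5 % zoom, no
  flip).
- 50 epochs per member, Adam at 3e-3 (the full-scale 1e-5 is matched to
  thousands of epochs; 50-epoch training needs a proportionally larger
  step), batch 16; 3D members train on central 8 × 8 × 8 crops.

Under these conditions the five-fold ensemble reaches held-out gland Dice
≈ 0.99 with Hausdorff of one-to-two voxel pitches, the majority vote sits at
or above the mean member performance, and the domain-shifted (unimodal)
cohort shows strictly larger KL/JS discrepancy than the self-comparison —
the qualitative orderings the statistics machinery is built to detect.

## Known limitations

- The autodiff core is single-threaded numpy; full-scale 256 × 256 × 23
  training is out of its intended range.
- Phantom realism is deliberately limited (no neighbouring organs, lesions,
  bias fields, Rician noise).
- RT-STRUCT support reads the contour/geometry tags only and does not write
  clinical-grade DICOM.
- Batch-norm running statistics make evaluation-mode outputs depend mildly
  on the training history; inference is deterministic for a fixed trained
  model.
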