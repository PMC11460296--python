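# pzseg

Automatic segmentation of the whole prostate gland and its peripheral zone
(PZ) from T2-weighted MR volumes, for researchers studying zonal anatomy,
gland volumetry and the domain-shift behaviour of segmentation networks.

Most prostate tumours arise in the peripheral zone, so a usable model must
delineate both the gland boundary and the zonal boundary.  `pzseg` implements
a **dual-decoder 2D/3D convolutional network ensemble**:

- **Network family.** Each member is a U-shaped residual encoder–decoder with
  *two* decoder paths: `up-pg` predicts the whole gland, `up-pz` the
  peripheral zone; the last `up-pz` feature block is concatenated into the
  gland head so zonal evidence informs the gland boundary.  Every residual
  block is three `conv → batch-norm → activation` stages with an additive
  shortcut; both heads are 1×1 convolutions with sigmoid outputs.
- **Hyperparameter search.** A 12-component vector λ (7 architecture
  components: block depth, base filter count, activation, three kernel sizes,
  spatial-dropout rate; 5 augmentation magnitudes: rotation, width/height
  shift, zoom, horizontal flip) is optimised by sequential Bayesian
  optimisation: a Gaussian-process surrogate (Matérn-5/2) with
  expected-improvement acquisition minimises the validation Dice loss of
  partially trained candidates over the space Ω = Ω₁ × … × Ω₁₂.
- **Training loss.** The two-structure Dice loss with squared denominators,

  `L = 1 − 2Σŷᵖyᵖ/(Σ(ŷᵖ)² + Σ(yᵖ)²) + α·(1 − 2Σŷᵖᶻyᵖᶻ/(Σ(ŷᵖᶻ)² + Σ(yᵖᶻ)²))`,
  α = 0.1,

  optimised with Adam (β₁ = 0.9, β₂ = 0.999, ε = 1e-8), keeping the weights
  with the smallest validation loss.
- **Ensemble.** The training cohort is split into five folds (80 % train /
  20 % validation); each fold trains one (2D slice-wise, 3D volumetric)
  member pair.  A pair's probability maps are averaged, thresholded at 0.5,
  and the five pair predictions are fused by per-voxel majority voting.
- **Evaluation.** Cardinality Dice `DS = 2|y∩ŷ|/(|y|+|ŷ|)`, symmetric
  Hausdorff distance in millimetres, gland/PZ volumes with t-based 95 % CIs,
  gland-volume quartile stratification, Welch and one-tailed paired t
  comparisons, and cohort intensity-histogram discrepancies (KL, 1-D
  Wasserstein, Jensen–Shannon).

The package also ships DICOM RT-STRUCT planar-contour ↔ voxel-mask conversion
(even–odd voxel-centre rasterization, voxel-exact mask→contour→mask round
trips), the preprocessing chain (B-spline resampling to 0.5 × 0.5 × 3 mm,
centre crop/pad to 256 × 256 × 23, slice-wise 3-σ clip + min–max
normalisation), and a **synthetic phantom generator** so the entire pipeline
is testable without clinical data: deformed-ellipsoid glands in the
clinically observed volume range with a posterior-crescent PZ, and two cohort
intensity archetypes (bimodal heavy-tailed vs unimodal low-contrast) to
manufacture domain-shifted test cohorts.

The network core runs on a small numpy reverse-mode autodiff engine included
in the package (`pzseg.autodiff`), so everything trains on a plain CPU.

## Worked example

```python
import numpy as np
from scipy import ndimage
from pzseg import (PhantomSpec, generate_phantom, HyperparamVector,
                   build_network, dice_score, hausdorff_mm, mask_volume_cm3)

# a synthetic prostate volume with gland + peripheral-zone ground truth
sample, truth = generate_phantom(PhantomSpec(gland_volume_cm3=55.0, seed=7))
print("gland volume:", round(mask_volume_cm3(truth.gland, sample.spacing_mm), 1), "cm^3")
print("PZ / gland fraction:", round(truth.pz.sum() / truth.gland.sum(), 3))

# a dual-decoder 2D member built from a hyperparameter vector
hp = HyperparamVector(n_blocks=2, base_filters=8, activation="relu",
                      kernel_1=3, kernel_2=3, kernel_3=3, dropout_p=0.1)
net, spec = build_network(hp, mode="2d", input_shape=(256, 256))
print("trainable parameters:", spec.parameter_count)

# evaluation metrics against a perturbed copy of the reference
eroded = ndimage.binary_erosion(truth.gland, iterations=2).astype(np.uint8)
print("Dice:", round(dice_score(truth.gland, eroded), 3))
print("Hausdorff:", round(hausdorff_mm(truth.gland, eroded, sample.spacing_mm), 2), "mm")
```

prints

```
gland volume: 55.0 cm^3
PZ / gland fraction: 0.27
trainable parameters: 62458
Dice: 0.722
Hausdorff: 6.0 mm
```

The phantom realises the requested 55 cm³ gland with a PZ near the typical
quarter of the gland volume; eroding the reference by two voxels costs ~0.28
Dice and leaves a 6 mm boundary excursion — the kind of sensitivity the
evaluation metrics are there to expose.

A command-line interface covers the same pipeline
(`pzseg generate / preprocess / search / train / predict / analyze`); see
`pzseg --help`.

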