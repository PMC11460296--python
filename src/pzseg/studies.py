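"""Pre-configured phantom studies exercising the full pipeline at small scale.

The full-scale recipe (256 x 256 x 23 grids, thousands of epochs) is a
GPU-sized workload; these studies shrink the grid to 16 x 16 x 8 voxels with
coarse spacing so the identical code path -- phantom cohort, preprocessing,
five-fold 2D-3D member training, fusion, majority voting, evaluation,
discrepancy and cohort statistics -- runs on one CPU in minutes.  The phantom
volumes stay in the clinically observed range (tens of cm^3); only the voxel
grid is coarse.

All randomness derives from a single seed, so a study is reproducible
end to end.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np

from .analysis import mask_volume_cm3, summarize_cohort
from .ensemble import EnsembleSegmenter, fuse_pair, majority_vote
from .metrics import (EvalRecord, EmptyMaskError, cohort_histogram,
                      dice_score, discrepancy, hausdorff_mm)
from .network import HyperparamVector
from .phantom import PhantomSpec, cohort_spec_sampler, generate_cohort, \
    shift_cohort_intensity
from .preprocess import PreprocessConfig
from .training import TrainSchedule

__all__ = ["SmallStudyConfig", "small_phantom_base", "small_sampler",
           "run_small_study"]


def small_phantom_base() -> PhantomSpec:
    """Base phantom for the small grid: a flattened gland (large axial
    footprint, modest through-plane extent) so realistic volumes fit 8 thick
    slices."""
    return PhantomSpec(grid_shape=(16, 16, 8), spacing_mm=(5.0, 5.0, 6.0),
                       gland_volume_cm3=30.0, gland_axis_ratios=(1.0, 1.2, 0.6),
                       deformation_amplitude=0.05, noise_sd=0.03)


def small_sampler(mean_volume_cm3: float = 30.0, sd_volume_cm3: float = 6.0):
    return cohort_spec_sampler(mean_volume_cm3=mean_volume_cm3,
                               sd_volume_cm3=sd_volume_cm3,
                               base_spec=small_phantom_base(),
                               min_volume_cm3=15.0)


@dataclass(frozen=True)
class SmallStudyConfig:
    """The small-scale study conditions: 40 training phantoms, 20 held-out
    phantoms, five folds, a fixed tiny member architecture, 50 epochs per
    member with Adam at 3e-3."""

    n_train: int = 40
    n_test: int = 20
    k: int = 5
    epochs: int = 50
    member_hp: HyperparamVector = field(default_factory=lambda: HyperparamVector(
        n_blocks=1, base_filters=4, activation="relu",
        kernel_1=3, kernel_2=3, kernel_3=3, dropout_p=0.05,
        aug_rotation_deg=5.0, aug_width_shift=0.02, aug_height_shift=0.02,
        aug_zoom=0.05, aug_hflip=False))
    preprocess: PreprocessConfig = field(default_factory=lambda: PreprocessConfig(
        target_spacing_mm=(5.0, 5.0, 6.0), target_shape=(16, 16, 8),
        crop3d_shape=(8, 8, 8)))
    schedule: TrainSchedule = field(default_factory=lambda: TrainSchedule(
        learning_rate=3e-3, batch_size=16))


def _pair_dice(ensemble: EnsembleSegmenter, probs, truth_std_gland) -> List[float]:
    """Per-member-pair gland Dice on the standardized grid."""
    out = []
    for pg, _ in probs:
        out.append(dice_score(truth_std_gland, pg >= ensemble.threshold))
    return out


def run_small_study(seed: int, cfg: Optional[SmallStudyConfig] = None) -> dict:
    """Train the small five-fold 2D-3D ensemble and evaluate it end to end.

    Returns a dict with the fitted ensemble, per-case evaluation records,
    member-vs-ensemble Dice, training histories and cohort discrepancy
    measurements (training profile vs a domain-shifted unimodal re-rendering
    of the held-out cohort).
    """
    cfg = cfg if cfg is not None else SmallStudyConfig()
    rng_seed = int(seed) % (2**31)
    train = generate_cohort(cfg.n_train, small_sampler(), seed=rng_seed)
    test = generate_cohort(cfg.n_test, small_sampler(), seed=rng_seed + 7919)

    ensemble = EnsembleSegmenter(
        hp_2d=cfg.member_hp, hp_3d=cfg.member_hp, preprocess=cfg.preprocess,
        schedule=cfg.schedule, k=cfg.k, seed=rng_seed,
        epochs_2d=cfg.epochs, epochs_3d=cfg.epochs)
    ensemble.fit(train)

    records: List[EvalRecord] = []
    member_dice: List[List[float]] = []
    ensemble_dice: List[float] = []
    for i, (sample, truth) in enumerate(test):
        pred, probs = ensemble.predict(sample, return_probability=True)
        spacing = truth.geometry.spacing_mm
        d_gl = dice_score(truth.gland, pred.gland)
        try:
            hd_gl = hausdorff_mm(truth.gland, pred.gland, spacing)
        except EmptyMaskError:
            hd_gl = None
        records.append(EvalRecord(
            case_id=f"case{i:03d}", structure="gland", dice=d_gl,
            hausdorff_mm=hd_gl,
            reference_volume_cm3=mask_volume_cm3(truth.gland, spacing),
            predicted_volume_cm3=mask_volume_cm3(pred.gland, spacing)))
        if truth.pz is not None:
            d_pz = dice_score(truth.pz, pred.pz)
            try:
                hd_pz = hausdorff_mm(truth.pz, pred.pz, spacing)
            except EmptyMaskError:
                hd_pz = None
            records.append(EvalRecord(
                case_id=f"case{i:03d}", structure="pz", dice=d_pz,
                hausdorff_mm=hd_pz,
                reference_volume_cm3=mask_volume_cm3(truth.pz, spacing),
                predicted_volume_cm3=mask_volume_cm3(pred.pz, spacing)))
        # member-vs-ensemble comparison on the standardized grid
        st_sample, st_truth, _ = ensemble.preprocessor_.transform(sample, truth)
        member_dice.append(_pair_dice(ensemble, probs, st_truth.gland))
        vote = majority_vote([(p[0] >= ensemble.threshold) for p in probs])
        ensemble_dice.append(dice_score(st_truth.gland, vote))

    # cohort discrepancy: self vs domain-shifted (unimodal) re-rendering
    shifted = shift_cohort_intensity(test, "unimodal_low_contrast")
    pre = ensemble.preprocessor_
    h_train = cohort_histogram([pre.transform(s, None)[0] for s, _ in test])
    h_self = cohort_histogram([pre.transform(s, None)[0] for s, _ in test])
    h_shift = cohort_histogram([pre.transform(s, None)[0] for s, _ in shifted])
    disc = {name: {"self": discrepancy(h_train, h_self, name),
                   "shifted": discrepancy(h_train, h_shift, name)}
            for name in ("kl", "js", "wasserstein")}

    return {
        "ensemble": ensemble,
        "records": records,
        "summary": summarize_cohort(records),
        "member_dice": np.asarray(member_dice),
        "ensemble_dice": np.asarray(ensemble_dice),
        "histories": ensemble.histories_,
        "discrepancy": disc,
        "train_cohort": train,
        "test_cohort": test,
    }
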