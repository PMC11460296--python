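"""Five-fold 2D-3D ensemble: fold construction, member training, probability
fusion, majority voting, and the deployable predictor.

Each of the five folds trains one (2D member, 3D member) pair.  At inference
a pair's prediction is the average of the 2D slice-stack probability map and
the 3D central-crop probability map (outside the crop the 2D probability
stands alone), thresholded at 0.5; the final segmentation sets a voxel when
more than half of the five pairs set it.  Predicted masks are mapped back to
the input volume's native geometry through the recorded preprocessing
offsets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .geometry import Geometry, StructureMaskSet, VolumeSample
from .metrics import LossConfig
from .network import DualDecoderNet, HyperparamVector, build_network
from .preprocess import (GeometryRecord, PreprocessConfig, VolumePreprocessor,
                         crop_3d, map_mask_to_geometry, paste_3d)
from .training import TrainSchedule, fit_network
# re-exported here because augmentation is part of the training pipeline surface
from .training import augment_batch  # noqa: F401

__all__ = ["FoldSplit", "TrainSchedule", "EnsembleSegmenter", "make_folds",
           "augment_batch", "train_member", "fuse_pair", "majority_vote"]


@dataclass
class FoldSplit:
    """k disjoint validation folds covering the cohort (default reading of a
    5-fold 80/20 split); ``mode='random'`` gives k independent random splits
    instead."""

    k: int
    folds: List[Tuple[List, List]]  # (train_ids, valid_ids) per fold
    seed: int
    mode: str = "cv"


def make_folds(cohort_ids: Sequence, k: int = 5, seed: int = 0,
               mode: str = "cv") -> FoldSplit:
    """Split case ids into k folds of ~80% train / 20% validation.

    With ``mode='cv'`` the validation sets are pairwise disjoint and cover the
    cohort (each case validates exactly once); fold sizes are balanced within
    one.  ``mode='random'`` draws k independent 80/20 splits.
    """
    ids = list(cohort_ids)
    if k > len(ids):
        raise ValueError(f"k={k} exceeds cohort size {len(ids)}")
    rng = np.random.default_rng(seed)
    folds = []
    if mode == "cv":
        perm = [ids[i] for i in rng.permutation(len(ids))]
        chunks = np.array_split(np.arange(len(perm)), k)
        for ch in chunks:
            valid = [perm[i] for i in ch]
            train = [c for c in perm if c not in set(valid)]
            folds.append((train, valid))
    elif mode == "random":
        n_valid = max(1, round(0.2 * len(ids)))
        for _ in range(k):
            perm = [ids[i] for i in rng.permutation(len(ids))]
            folds.append((perm[n_valid:], perm[:n_valid]))
    else:
        raise ValueError("mode must be 'cv' or 'random'")
    return FoldSplit(k=k, folds=folds, seed=seed, mode=mode)


def train_member(hp: HyperparamVector, mode: str, train_data, valid_data,
                 schedule: TrainSchedule, seed: int,
                 epochs: Optional[int] = None):
    """Train one ensemble member; returns (network, history).

    The returned network carries the checkpoint with the smallest validation
    loss.  ``epochs`` overrides the schedule's per-mode default.
    """
    if train_data[0].shape[0] == 0 or valid_data[0].shape[0] == 0:
        raise ValueError("fold must contain training and validation cases")
    input_shape = train_data[0].shape[1:]
    net, _ = build_network(hp, mode, input_shape, seed=seed)
    n_epochs = epochs if epochs is not None else schedule.epochs_for(mode)
    _, history = fit_network(net, train_data, valid_data, schedule,
                             epochs=n_epochs, seed=seed, keep_best=True)
    return net, history


def fuse_pair(prob_2d_stack: np.ndarray, prob_3d_crop: np.ndarray,
              crop_offsets) -> np.ndarray:
    """Average the 2D and 3D probability maps inside the 3D crop region.

    Outside the crop the 2D probability stands alone (averaging with an
    undefined 3D value would bias toward background).
    """
    full = np.asarray(prob_2d_stack, dtype=np.float64)
    crop = np.asarray(prob_3d_crop, dtype=np.float64)
    for o, c, s in zip(crop_offsets, crop.shape, full.shape):
        if o < 0 or o + c > s:
            raise ValueError(f"crop offsets {crop_offsets} out of bounds for "
                             f"{crop.shape} in {full.shape}")
    fused = full.copy()
    sl = tuple(slice(o, o + c) for o, c in zip(crop_offsets, crop.shape))
    fused[sl] = 0.5 * (full[sl] + crop)
    return fused


def majority_vote(binary_masks: Sequence[np.ndarray]) -> np.ndarray:
    """Voxelwise majority over an odd number of binary masks."""
    k = len(binary_masks)
    if k % 2 == 0:
        raise ValueError("majority voting needs an odd member count")
    stack = np.stack([np.asarray(m).astype(np.uint8) for m in binary_masks])
    if any(m.shape != stack[0].shape for m in stack):
        raise ValueError("masks must share one shape")
    return (stack.sum(axis=0) > k / 2).astype(np.uint8)


def _volume_to_2d_batch(values: np.ndarray) -> np.ndarray:
    # (H, W, S) -> (S, H, W)
    return np.moveaxis(values, 2, 0)


def _batch_to_volume(batch: np.ndarray) -> np.ndarray:
    return np.moveaxis(batch, 0, 2)


class EnsembleSegmenter:
    """The deployable predictor: five trained (2D, 3D) member pairs.

    sklearn-style estimator: ``fit(cohort)`` takes a list of
    ``(VolumeSample, StructureMaskSet)`` pairs, preprocesses them, builds the
    fold split and trains all members; ``predict(sample)`` returns a
    :class:`StructureMaskSet` on the input volume's native grid.

    Parameters
    ----------
    hp_2d, hp_3d : HyperparamVector
        Architecture/augmentation vectors of the 2D and 3D members (typically
        the winners of the two Bayesian searches).
    preprocess : PreprocessConfig
        Geometry/intensity standardisation targets.
    schedule : TrainSchedule
        Optimiser constants and epoch budgets.
    k : int
        Number of folds / member pairs (odd).
    vote : {'binary', 'probability'}
        Majority-vote on thresholded member masks (default) or threshold the
        across-pair mean probability instead.
    """

    def __init__(self, hp_2d: Optional[HyperparamVector] = None,
                 hp_3d: Optional[HyperparamVector] = None,
                 preprocess: Optional[PreprocessConfig] = None,
                 schedule: Optional[TrainSchedule] = None,
                 k: int = 5, threshold: float = 0.5, vote: str = "binary",
                 split_mode: str = "cv", seed: int = 0,
                 epochs_2d: Optional[int] = None,
                 epochs_3d: Optional[int] = None):
        self.hp_2d = hp_2d
        self.hp_3d = hp_3d
        self.preprocess = preprocess
        self.schedule = schedule
        self.k = k
        self.threshold = threshold
        self.vote = vote
        self.split_mode = split_mode
        self.seed = seed
        self.epochs_2d = epochs_2d
        self.epochs_3d = epochs_3d

    def get_params(self, deep=True):
        return {k: getattr(self, k) for k in
                ("hp_2d", "hp_3d", "preprocess", "schedule", "k", "threshold",
                 "vote", "split_mode", "seed", "epochs_2d", "epochs_3d")}

    def set_params(self, **params):
        for k, v in params.items():
            setattr(self, k, v)
        return self

    # -- fitting -----------------------------------------------------------
    def _materialise(self):
        hp2 = self.hp_2d if self.hp_2d is not None else HyperparamVector()
        hp3 = self.hp_3d if self.hp_3d is not None else HyperparamVector()
        pre = self.preprocess if self.preprocess is not None else PreprocessConfig()
        sch = self.schedule if self.schedule is not None else TrainSchedule()
        return hp2, hp3, pre, sch

    def _prepare_case(self, sample: VolumeSample, masks: Optional[StructureMaskSet]):
        pre = self.preprocessor_
        st_sample, st_masks, record = pre.transform(sample, masks)
        crop_sample, crop_masks, offsets = crop_3d(st_sample, st_masks, pre.config)
        return st_sample, st_masks, crop_sample, crop_masks, offsets, record

    @staticmethod
    def _dataset_2d(cases):
        imgs, gl, pz, has_pz = [], [], [], True
        for st_sample, st_masks in cases:
            imgs.append(_volume_to_2d_batch(st_sample.values))
            gl.append(_volume_to_2d_batch(st_masks.gland))
            if st_masks.pz is None:
                has_pz = False
            else:
                pz.append(_volume_to_2d_batch(st_masks.pz))
        return (np.concatenate(imgs), np.concatenate(gl),
                np.concatenate(pz) if has_pz else None)

    @staticmethod
    def _dataset_3d(cases):
        imgs = np.stack([c.values for c, _ in cases])
        gl = np.stack([m.gland for _, m in cases])
        has_pz = all(m.pz is not None for _, m in cases)
        pz = np.stack([m.pz for _, m in cases]) if has_pz else None
        return imgs, gl, pz

    def fit(self, cohort: Sequence[Tuple[VolumeSample, StructureMaskSet]],
            case_ids: Optional[Sequence] = None):
        """Preprocess the cohort, split into folds and train all member pairs."""
        hp2, hp3, pre_cfg, sch = self._materialise()
        self.preprocessor_ = VolumePreprocessor(pre_cfg)
        ids = list(range(len(cohort))) if case_ids is None else list(case_ids)
        prepared = {}
        for cid, (sample, masks) in zip(ids, cohort):
            st_s, st_m, cr_s, cr_m, offsets, _ = self._prepare_case(sample, masks)
            prepared[cid] = dict(std=(st_s, st_m), crop=(cr_s, cr_m),
                                 offsets=offsets)
        self.crop_offsets_ = next(iter(prepared.values()))["offsets"]
        self.folds_ = make_folds(ids, k=self.k, seed=self.seed,
                                 mode=self.split_mode)
        self.members_ = []
        self.histories_ = []
        for f, (train_ids, valid_ids) in enumerate(self.folds_.folds):
            tr2 = self._dataset_2d([prepared[i]["std"] for i in train_ids])
            va2 = self._dataset_2d([prepared[i]["std"] for i in valid_ids])
            tr3 = self._dataset_3d([prepared[i]["crop"] for i in train_ids])
            va3 = self._dataset_3d([prepared[i]["crop"] for i in valid_ids])
            m2d, h2d = train_member(hp2, "2d", tr2, va2, sch,
                                    seed=self.seed + 101 * f,
                                    epochs=self.epochs_2d)
            m3d, h3d = train_member(hp3, "3d", tr3, va3, sch,
                                    seed=self.seed + 101 * f + 50,
                                    epochs=self.epochs_3d)
            self.members_.append((m2d, m3d))
            self.histories_.append({"2d": h2d, "3d": h3d})
        return self

    # -- inference ---------------------------------------------------------
    def _pair_probs(self, pair, st_values: np.ndarray, crop_values: np.ndarray):
        m2d, m3d = pair
        batch = _volume_to_2d_batch(st_values)
        pg2, pz2 = m2d.forward(batch, training=False)
        pg2 = _batch_to_volume(pg2.data[:, 0])
        pz2 = _batch_to_volume(pz2.data[:, 0])
        pg3_t, pz3_t = m3d.forward(crop_values[None], training=False)
        pg3, pz3 = pg3_t.data[0, 0], pz3_t.data[0, 0]
        fused_pg = fuse_pair(pg2, pg3, self.crop_offsets_)
        fused_pz = fuse_pair(pz2, pz3, self.crop_offsets_)
        return fused_pg, fused_pz

    def predict_proba(self, sample: VolumeSample):
        """Per-pair fused probability maps on the standardized grid."""
        self._check_fitted()
        st_sample, _, record = self.preprocessor_.transform(sample, None)
        crop_sample, _, offsets = crop_3d(st_sample, None,
                                          self.preprocessor_.config)
        probs = [self._pair_probs(pair, st_sample.values, crop_sample.values)
                 for pair in self.members_]
        return probs, record

    def predict(self, sample: VolumeSample,
                return_probability: bool = False):
        """Segment one volume; masks are returned on its native geometry."""
        probs, record = self.predict_proba(sample)
        if self.vote == "binary":
            pg_masks = [(p[0] >= self.threshold) for p in probs]
            pz_masks = [(p[1] >= self.threshold) for p in probs]
            pg_std = majority_vote(pg_masks)
            pz_std = majority_vote(pz_masks)
        elif self.vote == "probability":
            pg_std = (np.mean([p[0] for p in probs], axis=0)
                      >= self.threshold).astype(np.uint8)
            pz_std = (np.mean([p[1] for p in probs], axis=0)
                      >= self.threshold).astype(np.uint8)
        else:
            raise ValueError("vote must be 'binary' or 'probability'")
        gland = map_mask_to_geometry(pg_std, record)
        pz = map_mask_to_geometry(pz_std, record)
        out = StructureMaskSet(gland=gland, pz=pz, geometry=record.original)
        if return_probability:
            return out, probs
        return out

    def _check_fitted(self):
        if not hasattr(self, "members_"):
            raise RuntimeError("EnsembleSegmenter is not fitted")
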