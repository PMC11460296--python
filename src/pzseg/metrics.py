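"""Losses and evaluation quantities.

Two distinct Dice forms coexist deliberately: the training loss uses squared
denominator terms, ``1 - 2 sum(p*y) / (sum(p^2) + sum(y^2) + eps)``, which is
differentiable in the predicted probabilities; the evaluation score uses set
cardinalities, ``2|y & p| / (|y| + |p|)``.  For binary predictions and eps=0
the two coincide (squares of 0/1 values equal the values).

The combined two-structure training loss is
``dice_loss(gland) + alpha * dice_loss(pz)`` with ``alpha = 0.1`` by default.

The Hausdorff distance is the full symmetric maximum over the two directed
max-min boundary distances, measured in physical millimetres between
boundary-voxel centres (boundary = mask voxels with at least one face
neighbour outside).

Cohort discrepancy metrics (KL divergence, 1D Wasserstein distance,
Jensen-Shannon distance) compare pooled voxel-intensity histograms.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import cKDTree
from scipy.spatial.distance import jensenshannon

__all__ = [
    "LossConfig", "EvalRecord", "EmptyMaskError",
    "dice_loss", "dice_loss_grad", "combined_loss", "combined_loss_grads",
    "dice_score", "hausdorff_mm", "cohort_histogram", "discrepancy",
    "records_to_frame",
]


class EmptyMaskError(ValueError):
    """Hausdorff distance is undefined for an empty mask."""


@dataclass(frozen=True)
class LossConfig:
    """alpha weights the PZ term of the combined loss; smooth_eps stabilises
    the Dice-loss denominator during training."""

    alpha: float = 0.1
    smooth_eps: float = 1e-6

    def __post_init__(self):
        if self.alpha < 0 or self.smooth_eps < 0:
            raise ValueError("alpha and smooth_eps must be >= 0")


@dataclass
class EvalRecord:
    """One evaluation row: a (case, structure) pair."""

    case_id: str
    structure: str
    dice: float
    hausdorff_mm: Optional[float] = None
    reference_volume_cm3: float = 0.0
    predicted_volume_cm3: float = 0.0

    def __post_init__(self):
        if not (0.0 <= self.dice <= 1.0):
            raise ValueError("dice must lie in [0, 1]")
        if self.hausdorff_mm is not None and self.hausdorff_mm < 0:
            raise ValueError("hausdorff_mm must be >= 0")


def records_to_frame(records: Sequence[EvalRecord]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in records])


def _check_shapes(a, b):
    if np.shape(a) != np.shape(b):
        raise ValueError(f"shape mismatch: {np.shape(a)} vs {np.shape(b)}")


def dice_loss(pred_prob: np.ndarray, truth: np.ndarray, eps: float = 1e-6) -> float:
    """Squared-denominator Dice loss of a probability map against a binary truth."""
    _check_shapes(pred_prob, truth)
    p = np.asarray(pred_prob, dtype=np.float64)
    y = np.asarray(truth, dtype=np.float64)
    num = 2.0 * float((p * y).sum())
    den = float((p * p).sum() + (y * y).sum()) + eps
    return 1.0 - num / den if den > 0 else 1.0


def dice_loss_grad(pred_prob: np.ndarray, truth: np.ndarray,
                   eps: float = 1e-6) -> Tuple[float, np.ndarray]:
    """Dice loss and its gradient with respect to the predicted probabilities."""
    _check_shapes(pred_prob, truth)
    p = np.asarray(pred_prob, dtype=np.float64)
    y = np.asarray(truth, dtype=np.float64)
    s_xy = float((p * y).sum())
    den = float((p * p).sum() + (y * y).sum()) + eps
    loss = 1.0 - 2.0 * s_xy / den
    grad = -2.0 * (y * den - s_xy * 2.0 * p) / (den * den)
    return loss, grad


def combined_loss(pred_pg, pred_pz, truth_pg, truth_pz,
                  cfg: LossConfig = LossConfig()) -> float:
    """Two-structure training loss: gland Dice loss + alpha * PZ Dice loss.

    When the PZ reference is absent (None), the PZ term is skipped.
    """
    loss = dice_loss(pred_pg, truth_pg, cfg.smooth_eps)
    if truth_pz is not None:
        loss += cfg.alpha * dice_loss(pred_pz, truth_pz, cfg.smooth_eps)
    return loss


def combined_loss_grads(pred_pg, pred_pz, truth_pg, truth_pz,
                        cfg: LossConfig = LossConfig()):
    """Loss plus gradients for both heads (PZ gradient zero if no reference)."""
    loss, g_pg = dice_loss_grad(pred_pg, truth_pg, cfg.smooth_eps)
    if truth_pz is not None:
        l_pz, g_pz = dice_loss_grad(pred_pz, truth_pz, cfg.smooth_eps)
        loss += cfg.alpha * l_pz
        g_pz = cfg.alpha * g_pz
    else:
        g_pz = np.zeros_like(np.asarray(pred_pz, dtype=np.float64))
    return loss, g_pg, g_pz


def dice_score(truth: np.ndarray, pred: np.ndarray) -> float:
    """Cardinality Dice score between two binary masks; both empty -> 1."""
    _check_shapes(truth, pred)
    y = np.asarray(truth).astype(bool)
    p = np.asarray(pred).astype(bool)
    denom = int(y.sum()) + int(p.sum())
    if denom == 0:
        return 1.0
    return 2.0 * int((y & p).sum()) / denom


def _boundary_points_mm(mask: np.ndarray, spacing) -> np.ndarray:
    """Centres (mm) of mask voxels with at least one face neighbour outside."""
    m = np.asarray(mask).astype(bool)
    structure = ndimage.generate_binary_structure(m.ndim, 1)  # face connectivity
    interior = ndimage.binary_erosion(m, structure=structure, border_value=0)
    boundary = m & ~interior
    idx = np.argwhere(boundary).astype(np.float64)
    return idx * np.asarray(spacing, dtype=np.float64)


def hausdorff_mm(truth: np.ndarray, pred: np.ndarray, spacing) -> float:
    """Symmetric Hausdorff distance between mask boundaries, in millimetres."""
    _check_shapes(truth, pred)
    if not np.any(truth) or not np.any(pred):
        raise EmptyMaskError("Hausdorff distance undefined for an empty mask")
    a = _boundary_points_mm(truth, spacing)
    b = _boundary_points_mm(pred, spacing)
    ta, tb = cKDTree(a), cKDTree(b)
    h_ab = float(tb.query(a)[0].max())
    h_ba = float(ta.query(b)[0].max())
    return max(h_ab, h_ba)


def cohort_histogram(cohort: Sequence, n_bins: int = 100) -> np.ndarray:
    """Pooled voxel-intensity histogram on [0, 1], normalised to sum 1.

    ``cohort`` is a sequence of VolumeSample or raw arrays of normalised
    intensities; all voxels are pooled without exclusion.
    """
    if len(cohort) == 0:
        raise ValueError("cohort must be nonempty")
    vals = []
    for item in cohort:
        arr = getattr(item, "values", item)
        vals.append(np.asarray(arr, dtype=np.float64).ravel())
    pooled = np.concatenate(vals)
    hist, _ = np.histogram(pooled, bins=n_bins, range=(0.0, 1.0))
    total = hist.sum()
    if total == 0:
        raise ValueError("cohort intensities fall outside [0, 1]")
    return hist / total


def discrepancy(p: np.ndarray, q: np.ndarray, metric: str,
                bin_centers: Optional[np.ndarray] = None,
                kl_eps: float = 1e-12) -> float:
    """Histogram discrepancy: 'kl', 'wasserstein' or 'js'.

    Both inputs must be nonnegative and sum to 1 on the same support.  The
    Wasserstein distance is the 1D earth-mover computed from CDF differences
    on the bin grid (default: uniform bin centres on [0, 1], so the value is
    on the intensity scale); the Jensen-Shannon distance uses base-2 logs and
    is bounded by [0, 1].
    """
    p = np.asarray(p, dtype=np.float64)
    q = np.asarray(q, dtype=np.float64)
    if p.shape != q.shape:
        raise ValueError("histograms must share their support")
    if (p < 0).any() or (q < 0).any():
        raise ValueError("histogram masses must be nonnegative")
    if abs(p.sum() - 1.0) > 1e-8 or abs(q.sum() - 1.0) > 1e-8:
        raise ValueError("histograms must each sum to 1")

    if metric == "kl":
        qs = q + kl_eps
        qs = qs / qs.sum()
        pos = p > 0
        return float((p[pos] * np.log(p[pos] / qs[pos])).sum())
    if metric == "wasserstein":
        if bin_centers is None:
            n = len(p)
            bin_centers = (np.arange(n) + 0.5) / n
        centers = np.asarray(bin_centers, dtype=np.float64)
        cdf_diff = np.abs(np.cumsum(p) - np.cumsum(q))[:-1]
        return float((cdf_diff * np.diff(centers)).sum())
    if metric == "js":
        return float(jensenshannon(p, q, base=2))
    raise ValueError(f"unknown discrepancy metric {metric!r}")
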