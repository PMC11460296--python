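"""Shared training loop: real-time augmentation, Adam, best-checkpoint rule.

Used by both the Bayesian search (partial training) and the ensemble pipeline
(full training).  A training dataset is a triple of arrays
``(images, gland, pz)`` with leading sample axis -- ``(N, H, W)`` for the 2D
member, ``(N, H, W, D)`` for the 3D member; ``pz`` may be None when no PZ
reference exists, in which case the PZ loss term is skipped.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np
from scipy import ndimage

from . import autodiff as ad
from .metrics import LossConfig, combined_loss, combined_loss_grads
from .network import DualDecoderNet, HyperparamVector

__all__ = ["TrainSchedule", "TrainingDivergedError", "augment_batch",
           "fit_network", "evaluate_loss"]


class TrainingDivergedError(RuntimeError):
    """Training produced a non-finite loss."""


@dataclass(frozen=True)
class TrainSchedule:
    """Optimisation schedule; defaults follow the full-scale training recipe
    (3,000 epochs for the 2D member, 2,000 for the 3D member, Adam with
    beta1=0.9, beta2=0.999, eps=1e-8, learning rate 1e-5, and the weights
    with the smallest validation loss kept for testing)."""

    epochs_2d: int = 3000
    epochs_3d: int = 2000
    learning_rate: float = 1e-5
    beta1: float = 0.9
    beta2: float = 0.999
    epsilon: float = 1e-8
    batch_size: int = 16
    loss: LossConfig = field(default_factory=LossConfig)

    def __post_init__(self):
        if self.epochs_2d < 1 or self.epochs_3d < 1:
            raise ValueError("epochs must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")

    def epochs_for(self, mode: str) -> int:
        return self.epochs_2d if mode == "2d" else self.epochs_3d


def _affine_params(hp: HyperparamVector, rng: np.random.Generator):
    theta = np.deg2rad(rng.uniform(-hp.aug_rotation_deg, hp.aug_rotation_deg))
    zoom = 1.0 + rng.uniform(-hp.aug_zoom, hp.aug_zoom)
    dr = rng.uniform(-hp.aug_height_shift, hp.aug_height_shift)
    dc = rng.uniform(-hp.aug_width_shift, hp.aug_width_shift)
    flip = bool(hp.aug_hflip and rng.random() < 0.5)
    return theta, zoom, dr, dc, flip


def _apply_affine_2d(img: np.ndarray, theta, zoom, dr, dc, flip, order):
    """In-plane rotate/zoom/shift (about the image centre) + optional h-flip."""
    h, w = img.shape[:2]
    if flip:
        img = img[:, ::-1, ...]
    c, s = np.cos(theta), np.sin(theta)
    rot = np.array([[c, -s], [s, c]]) / zoom  # output->input mapping
    centre = np.array([(h - 1) / 2.0, (w - 1) / 2.0])
    shift = np.array([dr * h, dc * w])
    offset = centre - rot @ (centre + shift)
    if img.ndim == 3:  # volume: same transform on every slice
        m = np.eye(3)
        m[:2, :2] = rot
        off = np.array([offset[0], offset[1], 0.0])
        return ndimage.affine_transform(img, m, offset=off, order=order,
                                        mode="constant", cval=0.0)
    return ndimage.affine_transform(img, rot, offset=offset, order=order,
                                    mode="constant", cval=0.0)


def augment_batch(images: np.ndarray, gland: np.ndarray,
                  pz: Optional[np.ndarray], hp: HyperparamVector,
                  rng: np.random.Generator):
    """Randomly rotate/shift/zoom/flip each sample; masks move identically.

    Images are interpolated linearly, masks nearest-neighbour (stay binary).
    With all magnitudes zero and flip off this is the identity.
    """
    if (hp.aug_rotation_deg == 0 and hp.aug_width_shift == 0
            and hp.aug_height_shift == 0 and hp.aug_zoom == 0
            and not hp.aug_hflip):
        return images, gland, pz
    out_i = np.empty_like(images)
    out_g = np.empty_like(gland)
    out_p = np.empty_like(pz) if pz is not None else None
    for i in range(images.shape[0]):
        par = _affine_params(hp, rng)
        out_i[i] = _apply_affine_2d(images[i], *par, order=1)
        out_g[i] = (_apply_affine_2d(gland[i].astype(np.float64), *par, order=0)
                    > 0.5).astype(gland.dtype)
        if pz is not None:
            out_p[i] = (_apply_affine_2d(pz[i].astype(np.float64), *par, order=0)
                        > 0.5).astype(pz.dtype)
    return out_i, out_g, out_p


def evaluate_loss(net: DualDecoderNet, data, cfg: LossConfig,
                  batch_size: int = 32) -> float:
    """Combined loss over a dataset in evaluation mode (dropout off)."""
    images, gland, pz = data
    losses, weights = [], []
    for start in range(0, images.shape[0], batch_size):
        sl = slice(start, start + batch_size)
        pg, pzp = net.forward(images[sl], training=False)
        losses.append(combined_loss(pg.data[:, 0], pzp.data[:, 0], gland[sl],
                                    None if pz is None else pz[sl], cfg))
        weights.append(images[sl].shape[0])
    return float(np.average(losses, weights=weights))


def fit_network(net: DualDecoderNet, train_data, valid_data,
                schedule: TrainSchedule, epochs: int, seed: int,
                keep_best: bool = True):
    """Train with real-time augmentation; return (best_weights, history).

    ``history`` is a dict of per-epoch train/valid loss lists.  The checkpoint
    rule keeps the weights with the smallest validation loss.  A non-finite
    training loss raises :class:`TrainingDivergedError`.
    """
    images, gland, pz = train_data
    rng = np.random.default_rng(seed)
    opt = ad.Adam(net.parameters(), lr=schedule.learning_rate,
                  beta1=schedule.beta1, beta2=schedule.beta2,
                  eps=schedule.epsilon)
    hp = net.hp
    cfg = schedule.loss
    n = images.shape[0]
    bs = min(schedule.batch_size, n)
    history = {"train_loss": [], "valid_loss": []}
    best_loss, best_weights = np.inf, None

    for epoch in range(epochs):
        order = rng.permutation(n)
        ai, ag, ap = augment_batch(images[order], gland[order],
                                   None if pz is None else pz[order], hp, rng)
        epoch_losses = []
        for start in range(0, n, bs):
            sl = slice(start, start + bs)
            pg_t, pz_t = net.forward(ai[sl], training=True, rng=rng)
            loss, g_pg, g_pz = combined_loss_grads(
                pg_t.data[:, 0], pz_t.data[:, 0], ag[sl],
                None if ap is None else ap[sl], cfg)
            if not np.isfinite(loss):
                raise TrainingDivergedError(
                    f"non-finite training loss at epoch {epoch}")
            opt.zero_grad()
            ad.backward([pg_t, pz_t], [g_pg[:, None], g_pz[:, None]])
            opt.step()
            epoch_losses.append(loss)
        history["train_loss"].append(float(np.mean(epoch_losses)))
        vloss = evaluate_loss(net, valid_data, cfg)
        history["valid_loss"].append(vloss)
        if keep_best and vloss < best_loss:
            best_loss = vloss
            best_weights = net.get_weights()

    if keep_best and best_weights is not None:
        net.set_weights(best_weights)
    return net.get_weights(), history
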