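"""Dual-decoder residual encoder--decoder network family (2D and 3D).

A concrete network is built from a 12-component hyperparameter vector: 7
architecture components (residual-block depth, base filter count, activation,
the 3 kernel sizes used by every residual block, spatial-dropout probability)
and 5 augmentation magnitudes (rotation, width/height shift, zoom, horizontal
flip) that are consumed at training time, not by the graph itself.

Structure: a down-sampling path of ``n_blocks`` residual blocks with 2x2
in-plane max-pooling, one middle residual block (U-shape), and two up-sampling
decoder paths -- up-pg for the whole gland, up-pz for the peripheral zone.
A spatial-dropout layer precedes every residual block except the first.
The features of the last up-pz block are concatenated into the up-pg head so
PZ evidence informs the gland prediction; both heads are kernel-size-1
convolutions with sigmoid outputs.  Filters double at each deeper level and
mirror on the way up.  Pooling and up-sampling act in-plane only, so 3D
inputs keep their slice count at every scale.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Dict, List, Optional, Tuple

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor

__all__ = ["HyperparamVector", "ArchitectureSpec", "DualDecoderNet",
           "build_network", "forward"]

_ACTIVATIONS = ("relu", "elu", "leaky_relu")


@dataclass(frozen=True)
class HyperparamVector:
    """The 12-component search vector: 7 architecture + 5 augmentation."""

    n_blocks: int = 2
    base_filters: int = 8
    activation: str = "relu"
    kernel_1: int = 3
    kernel_2: int = 3
    kernel_3: int = 3
    dropout_p: float = 0.1
    aug_rotation_deg: float = 10.0
    aug_width_shift: float = 0.05
    aug_height_shift: float = 0.05
    aug_zoom: float = 0.1
    aug_hflip: bool = False

    ARCH_COMPONENTS = ("n_blocks", "base_filters", "activation",
                       "kernel_1", "kernel_2", "kernel_3", "dropout_p")
    AUG_COMPONENTS = ("aug_rotation_deg", "aug_width_shift", "aug_height_shift",
                      "aug_zoom", "aug_hflip")

    def __post_init__(self):
        if self.n_blocks < 1:
            raise ValueError("n_blocks must be >= 1")
        if self.base_filters < 1:
            raise ValueError("base_filters must be >= 1")
        if self.activation not in _ACTIVATIONS:
            raise ValueError(f"activation must be one of {_ACTIVATIONS}")
        for k in (self.kernel_1, self.kernel_2, self.kernel_3):
            if k < 1 or k % 2 == 0:
                raise ValueError("kernel sizes must be odd and >= 1")
        if not (0.0 <= self.dropout_p <= 0.5):
            raise ValueError("dropout_p must lie in [0, 0.5]")
        for name in ("aug_width_shift", "aug_height_shift", "aug_zoom"):
            v = getattr(self, name)
            if not (0.0 <= v <= 0.5):
                raise ValueError(f"{name} must lie in [0, 0.5]")
        if self.aug_rotation_deg < 0:
            raise ValueError("aug_rotation_deg must be >= 0")

    @property
    def kernels(self) -> Tuple[int, int, int]:
        return (self.kernel_1, self.kernel_2, self.kernel_3)

    def as_dict(self) -> dict:
        return asdict(self)


@dataclass
class ArchitectureSpec:
    """Emitted description of a built network: mode, layers, parameter count."""

    mode: str
    input_shape: Tuple[int, ...]
    layers: List[dict] = field(default_factory=list)
    parameter_count: int = 0

    def count(self, layer_type: str) -> int:
        return sum(1 for l in self.layers if l["type"] == layer_type)

    def to_json(self) -> str:
        return json.dumps({"mode": self.mode, "input_shape": list(self.input_shape),
                           "parameter_count": self.parameter_count,
                           "layers": self.layers}, indent=2)


class _Conv:
    def __init__(self, in_ch, out_ch, kernel, ndim, rng):
        shape = (out_ch, in_ch) + (kernel,) * ndim
        fan_in = in_ch * kernel ** ndim
        limit = np.sqrt(6.0 / fan_in)  # He-uniform
        self.w = Tensor(rng.uniform(-limit, limit, size=shape), requires_grad=True)
        self.b = Tensor(np.zeros(out_ch), requires_grad=True)

    def __call__(self, x):
        return ad.conv_nd(x, self.w, self.b)

    def params(self):
        return [self.w, self.b]

    def n_params(self):
        return int(self.w.data.size + self.b.data.size)


class _BatchNorm:
    def __init__(self, ch):
        self.gamma = Tensor(np.ones(ch), requires_grad=True)
        self.beta = Tensor(np.zeros(ch), requires_grad=True)
        self.state = ad.BatchNormState(ch)

    def __call__(self, x, training):
        return ad.batch_norm(x, self.gamma, self.beta, self.state, training)

    def params(self):
        return [self.gamma, self.beta]

    def n_params(self):
        return int(self.gamma.data.size + self.beta.data.size)


class _ResidualBlock:
    """3 x [zero-padded conv -> batch norm -> activation] + identity shortcut.

    When input and output channel counts differ, the shortcut is a
    kernel-size-1 projection convolution.
    """

    def __init__(self, in_ch, out_ch, kernels, activation, ndim, rng):
        self.activation = activation
        chans = [in_ch, out_ch, out_ch, out_ch]
        self.convs = [_Conv(chans[i], chans[i + 1], kernels[i], ndim, rng)
                      for i in range(3)]
        self.bns = [_BatchNorm(out_ch) for _ in range(3)]
        self.proj = _Conv(in_ch, out_ch, 1, ndim, rng) if in_ch != out_ch else None

    def __call__(self, x, training):
        h = x
        for conv, bn in zip(self.convs, self.bns):
            h = ad.activation(bn(conv(h), training), self.activation)
        s = self.proj(x) if self.proj is not None else x
        return ad.add(h, s)

    def params(self):
        out = []
        for c in self.convs:
            out += c.params()
        for b in self.bns:
            out += b.params()
        if self.proj is not None:
            out += self.proj.params()
        return out


class DualDecoderNet:
    """One member network of the 2D/3D family; built by :func:`build_network`."""

    def __init__(self, hp: HyperparamVector, mode: str,
                 input_shape: Tuple[int, ...], seed: int = 0):
        if mode not in ("2d", "3d"):
            raise ValueError("mode must be '2d' or '3d'")
        ndim = 2 if mode == "2d" else 3
        if len(input_shape) != ndim:
            raise ValueError(f"input_shape must have {ndim} dims for mode {mode}")
        div = 2 ** hp.n_blocks
        for ax in (0, 1):  # only the in-plane axes are pooled
            if input_shape[ax] % div:
                raise ValueError(
                    f"in-plane input size {input_shape[ax]} not divisible by "
                    f"2^n_blocks = {div}")
        self.hp = hp
        self.mode = mode
        self.ndim = ndim
        self.input_shape = tuple(input_shape)
        rng = np.random.default_rng(seed)

        n, base = hp.n_blocks, hp.base_filters
        self.enc: List[_ResidualBlock] = []
        in_ch = 1
        for lvl in range(n):
            out_ch = base * 2 ** lvl
            self.enc.append(_ResidualBlock(in_ch, out_ch, hp.kernels,
                                           hp.activation, ndim, rng))
            in_ch = out_ch
        self.middle = _ResidualBlock(in_ch, base * 2 ** n, hp.kernels,
                                     hp.activation, ndim, rng)

        def make_decoder():
            blocks = []
            ch_below = base * 2 ** n
            for lvl in reversed(range(n)):
                out_ch = base * 2 ** lvl
                in_c = ch_below + out_ch  # upsampled + lateral skip
                blocks.append(_ResidualBlock(in_c, out_ch, hp.kernels,
                                             hp.activation, ndim, rng))
                ch_below = out_ch
            return blocks

        self.dec_pz = make_decoder()
        self.dec_pg = make_decoder()
        self.head_pz = _Conv(base, 1, 1, ndim, rng)
        self.head_pg = _Conv(2 * base, 1, 1, ndim, rng)  # pg features + pz features
        self._drop_rng = np.random.default_rng(seed + 1)

    # -- forward -----------------------------------------------------------
    def forward(self, batch: np.ndarray, training: bool = False,
                rng: Optional[np.random.Generator] = None):
        """Run a batch ``(N, *input_shape)`` through both heads.

        Returns ``(prob_pg, prob_pz)`` tensors with the input's spatial shape.
        Deterministic in evaluation mode (dropout off, running batch-norm
        statistics).
        """
        batch = np.asarray(batch, dtype=np.float64)
        if batch.shape[1:] != self.input_shape:
            raise ValueError(
                f"batch spatial shape {batch.shape[1:]} != {self.input_shape}")
        rng = rng if rng is not None else self._drop_rng
        p = self.hp.dropout_p
        x = Tensor(batch[:, None])  # add channel axis

        skips = []
        for lvl, block in enumerate(self.enc):
            if lvl > 0:
                x = ad.spatial_dropout(x, p, rng, training)
            x = block(x, training)
            skips.append(x)
            x = ad.max_pool(x)
        x = ad.spatial_dropout(x, p, rng, training)
        mid = self.middle(x, training)

        def run_decoder(blocks):
            h = mid
            for i, block in enumerate(blocks):
                lvl = self.hp.n_blocks - 1 - i
                h = ad.spatial_dropout(h, p, rng, training)
                h = ad.upsample(h)
                h = ad.concat([h, skips[lvl]])
                h = block(h, training)
            return h

        f_pz = run_decoder(self.dec_pz)
        f_pg = run_decoder(self.dec_pg)
        prob_pz = ad.sigmoid(self.head_pz(f_pz))
        prob_pg = ad.sigmoid(self.head_pg(ad.concat([f_pg, f_pz])))
        return prob_pg, prob_pz

    def __call__(self, batch, training=False, rng=None):
        return self.forward(batch, training, rng)

    # -- parameters --------------------------------------------------------
    def parameters(self) -> List[Tensor]:
        out = []
        for block in self.enc + [self.middle] + self.dec_pz + self.dec_pg:
            out += block.params()
        out += self.head_pz.params() + self.head_pg.params()
        return out

    def get_weights(self) -> List[np.ndarray]:
        return [p.data.copy() for p in self.parameters()]

    def set_weights(self, weights: List[np.ndarray]) -> None:
        for p, w in zip(self.parameters(), weights):
            p.data = w.copy()

    def set_eval_stats_from_batch(self, batch: np.ndarray) -> None:
        """Prime batch-norm running statistics with one training-mode pass."""
        self.forward(batch, training=True, rng=np.random.default_rng(0))

    # -- emitted spec ------------------------------------------------------
    def spec(self) -> ArchitectureSpec:
        hp = self.hp
        spec = ArchitectureSpec(mode=self.mode, input_shape=self.input_shape)
        ndim = self.ndim

        def conv_entry(where, in_ch, out_ch, k):
            return {"type": "conv", "where": where, "in": in_ch, "out": out_ch,
                    "kernel": k, "params": out_ch * in_ch * k ** ndim + out_ch}

        def bn_entry(where, ch):
            return {"type": "batch_norm", "where": where, "channels": ch,
                    "params": 2 * ch}

        def block_entries(where, in_ch, out_ch):
            entries = []
            chans = [in_ch, out_ch, out_ch, out_ch]
            for i in range(3):
                entries.append(conv_entry(where, chans[i], chans[i + 1],
                                          hp.kernels[i]))
                entries.append(bn_entry(where, out_ch))
            if in_ch != out_ch:
                entries.append(conv_entry(where + "/proj", in_ch, out_ch, 1))
            entries.append({"type": "residual_block", "where": where,
                            "in": in_ch, "out": out_ch, "params": 0})
            return entries

        n, base = hp.n_blocks, hp.base_filters
        in_ch = 1
        for lvl in range(n):
            if lvl > 0:
                spec.layers.append({"type": "spatial_dropout",
                                    "where": f"down/{lvl}", "params": 0})
            out_ch = base * 2 ** lvl
            spec.layers += block_entries(f"down/{lvl}", in_ch, out_ch)
            spec.layers.append({"type": "max_pool", "where": f"down/{lvl}",
                                "params": 0})
            in_ch = out_ch
        spec.layers.append({"type": "spatial_dropout", "where": "middle",
                            "params": 0})
        spec.layers += block_entries("middle", in_ch, base * 2 ** n)

        for path in ("up_pz", "up_pg"):
            ch_below = base * 2 ** n
            for i, lvl in enumerate(reversed(range(n))):
                where = f"{path}/{i}"
                spec.layers.append({"type": "spatial_dropout", "where": where,
                                    "params": 0})
                spec.layers.append({"type": "upsample", "where": where,
                                    "params": 0})
                out_ch = base * 2 ** lvl
                spec.layers.append({"type": "concat", "where": where, "params": 0})
                spec.layers += block_entries(where, ch_below + out_ch, out_ch)
                ch_below = out_ch
        spec.layers.append({"type": "concat", "where": "head_pg", "params": 0})
        spec.layers.append(conv_entry("head_pz", base, 1, 1))
        spec.layers.append(conv_entry("head_pg", 2 * base, 1, 1))
        spec.parameter_count = sum(l["params"] for l in spec.layers)
        return spec


def build_network(hp: HyperparamVector, mode: str, input_shape,
                  seed: int = 0) -> Tuple[DualDecoderNet, ArchitectureSpec]:
    """Build a concrete network from a hyperparameter vector.

    Raises a configuration error when the in-plane input size is not divisible
    by ``2 ** n_blocks``.
    """
    net = DualDecoderNet(hp, mode, tuple(input_shape), seed=seed)
    spec = net.spec()
    actual = sum(p.data.size for p in net.parameters())
    assert spec.parameter_count == actual, (spec.parameter_count, actual)
    return net, spec


def forward(net: DualDecoderNet, batch: np.ndarray):
    """Evaluation-mode forward pass returning (prob_pg, prob_pz) arrays."""
    pg, pz = net.forward(batch, training=False)
    return pg.data[:, 0], pz.data[:, 0]
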