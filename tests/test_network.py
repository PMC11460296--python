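"""Network family: structural contracts, parameter counting, gradient flow."""

import numpy as np
import pytest

from pzseg import autodiff as ad
from pzseg.metrics import combined_loss_grads
from pzseg.network import (ArchitectureSpec, DualDecoderNet, HyperparamVector,
                           build_network, forward)


def _recount_parameters(spec: ArchitectureSpec) -> int:
    """Independent closed-form recount of weights + biases + norm parameters."""
    ndim = 2 if spec.mode == "2d" else 3
    total = 0
    for layer in spec.layers:
        if layer["type"] == "conv":
            k = layer["kernel"]
            total += layer["out"] * layer["in"] * k ** ndim + layer["out"]
        elif layer["type"] == "batch_norm":
            total += 2 * layer["channels"]
    return total


def _random_hp(rng, max_blocks=2):
    return HyperparamVector(
        n_blocks=int(rng.integers(1, max_blocks + 1)),
        base_filters=int(rng.choice([2, 4, 8])),
        activation=str(rng.choice(["relu", "elu", "leaky_relu"])),
        kernel_1=int(rng.choice([1, 3, 5])),
        kernel_2=int(rng.choice([1, 3])),
        kernel_3=int(rng.choice([1, 3])),
        dropout_p=float(rng.uniform(0, 0.5)))


class TestHyperparamVector:
    def test_has_twelve_components_arch_first(self):
        assert len(HyperparamVector.ARCH_COMPONENTS) == 7
        assert len(HyperparamVector.AUG_COMPONENTS) == 5
        hp = HyperparamVector()
        for name in (HyperparamVector.ARCH_COMPONENTS
                     + HyperparamVector.AUG_COMPONENTS):
            assert hasattr(hp, name)

    @pytest.mark.parametrize("bad", [
        dict(n_blocks=0), dict(kernel_1=2), dict(kernel_2=4),
        dict(dropout_p=0.6), dict(activation="tanh"), dict(aug_zoom=0.7),
    ])
    def test_invalid_vectors_rejected(self, bad):
        with pytest.raises(ValueError):
            HyperparamVector(**bad)


class TestBuildNetwork:
    def test_outputs_match_input_shape_and_sigmoid_range(self):
        hp = HyperparamVector(n_blocks=2, base_filters=4)
        net, _ = build_network(hp, "2d", (64, 64), seed=0)
        pg, pz = forward(net, np.random.default_rng(0).random((2, 64, 64)))
        assert pg.shape == pz.shape == (2, 64, 64)
        assert 0 < pg.min() and pg.max() < 1
        assert 0 < pz.min() and pz.max() < 1

    def test_3d_through_plane_depth_preserved(self):
        # 23-slice-style depths are not halvable; pooling is in-plane only
        hp = HyperparamVector(n_blocks=2, base_filters=2)
        net, _ = build_network(hp, "3d", (16, 16, 5), seed=0)
        pg, pz = forward(net, np.random.default_rng(1).random((1, 16, 16, 5)))
        assert pg.shape == (1, 16, 16, 5) and pz.shape == (1, 16, 16, 5)

    def test_indivisible_input_rejected(self):
        hp = HyperparamVector(n_blocks=3)
        with pytest.raises(ValueError, match="divisible"):
            build_network(hp, "2d", (20, 20))

    @pytest.mark.parametrize("mode,shape", [("2d", (16, 16)), ("3d", (8, 8, 5))])
    def test_parameter_count_matches_independent_recount(self, mode, shape):
        rng = np.random.default_rng(42)
        for _ in range(10):
            hp = _random_hp(rng)
            net, spec = build_network(hp, mode, shape, seed=1)
            assert spec.parameter_count == _recount_parameters(spec)
            assert spec.parameter_count == sum(p.data.size
                                               for p in net.parameters())

    def test_structure_counts_follow_placement_rule(self):
        for n_blocks in (1, 2, 3):
            hp = HyperparamVector(n_blocks=n_blocks, base_filters=2)
            _, spec = build_network(hp, "2d", (32, 32), seed=0)
            # dropout precedes every residual block except the first
            assert spec.count("spatial_dropout") == 3 * n_blocks
            # down path + middle + two decoders
            assert spec.count("residual_block") == 3 * n_blocks + 1
            assert spec.count("max_pool") == n_blocks
            assert spec.count("upsample") == 2 * n_blocks

    def test_parameter_count_monotone_in_capacity(self):
        base = build_network(HyperparamVector(n_blocks=2, base_filters=4),
                             "2d", (32, 32))[1].parameter_count
        wider = build_network(HyperparamVector(n_blocks=2, base_filters=8),
                              "2d", (32, 32))[1].parameter_count
        deeper = build_network(HyperparamVector(n_blocks=3, base_filters=4),
                               "2d", (32, 32))[1].parameter_count
        assert wider > base and deeper > base


class TestForward:
    def test_eval_mode_deterministic(self):
        hp = HyperparamVector(n_blocks=1, base_filters=4, dropout_p=0.3)
        net, _ = build_network(hp, "2d", (16, 16), seed=0)
        x = np.zeros((2, 16, 16))
        pg1, _ = forward(net, x)
        pg2, _ = forward(net, x)
        np.testing.assert_array_equal(pg1, pg2)

    def test_shape_mismatch_rejected(self):
        net, _ = build_network(HyperparamVector(n_blocks=1), "2d", (16, 16))
        with pytest.raises(ValueError, match="spatial shape"):
            net.forward(np.zeros((1, 8, 8)))

    def test_single_adam_step_decreases_loss(self):
        hp = HyperparamVector(n_blocks=1, base_filters=4, dropout_p=0.0)
        net, _ = build_network(hp, "2d", (16, 16), seed=3)
        rng = np.random.default_rng(5)
        x = rng.random((4, 16, 16))
        y_pg = (rng.random((4, 16, 16)) > 0.7).astype(float)
        y_pz = (rng.random((4, 16, 16)) > 0.9).astype(float)
        opt = ad.Adam(net.parameters(), lr=1e-2)

        def step():
            pg, pz = net.forward(x, training=True,
                                 rng=np.random.default_rng(0))
            loss, g_pg, g_pz = combined_loss_grads(pg.data[:, 0], pz.data[:, 0],
                                                   y_pg, y_pz)
            opt.zero_grad()
            ad.backward([pg, pz], [g_pg[:, None], g_pz[:, None]])
            opt.step()
            return loss

        l0 = step()
        l1 = step()
        assert l1 < l0
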