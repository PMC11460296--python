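"""Losses, Dice score, Hausdorff distance and histogram discrepancies
against hand computations and brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pzseg.metrics import (EmptyMaskError, LossConfig, cohort_histogram,
                           combined_loss, dice_loss, dice_score, discrepancy,
                           hausdorff_mm)


def _random_mask(rng, shape=(8, 8, 4), p=0.3):
    return (rng.random(shape) < p).astype(np.uint8)


class TestDiceLoss:
    def test_perfect_overlap_zero(self, rng):
        y = _random_mask(rng)
        assert dice_loss(y.astype(float), y, eps=0.0) == 0.0

    def test_disjoint_nonempty_one(self):
        y = np.zeros((4, 4)); y[0, 0] = 1
        p = np.zeros((4, 4)); p[3, 3] = 1.0
        assert dice_loss(p, y, eps=0.0) == 1.0

    def test_half_probability_hand_value(self):
        # y has 4 ones; p = 0.5 on those voxels: 1 - 2*2/(1+4) = 0.2
        y = np.zeros((4, 4)); y[:2, :2] = 1
        p = 0.5 * y.astype(float)
        assert dice_loss(p, y, eps=0.0) == pytest.approx(0.2)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="shape"):
            dice_loss(np.zeros((2, 2)), np.zeros((3, 3)))

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_binary_prediction_identity_with_dice_score(self, seed):
        # squared terms equal cardinalities on 0/1 values
        rng = np.random.default_rng(seed)
        y, p = _random_mask(rng), _random_mask(rng)
        assert dice_loss(p.astype(float), y, eps=0.0) == pytest.approx(
            1.0 - dice_score(y, p))


class TestCombinedLoss:
    def test_both_perfect_zero(self, rng):
        y_pg, y_pz = _random_mask(rng), _random_mask(rng)
        assert combined_loss(y_pg.astype(float), y_pz.astype(float),
                             y_pg, y_pz, LossConfig(smooth_eps=0.0)) == 0.0

    def test_pz_weight_literal(self):
        # gland perfect, PZ completely missed, alpha 0.1 -> loss 0.1
        y_pg = np.zeros((4, 4)); y_pg[1, 1] = 1
        y_pz = np.zeros((4, 4)); y_pz[2, 2] = 1
        p_pz = np.zeros((4, 4)); p_pz[0, 0] = 1.0
        loss = combined_loss(y_pg.astype(float), p_pz, y_pg, y_pz,
                             LossConfig(alpha=0.1, smooth_eps=0.0))
        assert loss == pytest.approx(0.1)

    def test_alpha_zero_reduces_to_gland_term(self, rng):
        y_pg, y_pz = _random_mask(rng), _random_mask(rng)
        p_pg = rng.random(y_pg.shape)
        p_pz = rng.random(y_pz.shape)
        cfg = LossConfig(alpha=0.0, smooth_eps=0.0)
        assert combined_loss(p_pg, p_pz, y_pg, y_pz, cfg) == pytest.approx(
            dice_loss(p_pg, y_pg, eps=0.0))

    def test_absent_pz_reference_skips_term(self, rng):
        y_pg = _random_mask(rng)
        p = rng.random(y_pg.shape)
        assert combined_loss(p, p, y_pg, None, LossConfig(smooth_eps=0.0)) \
            == pytest.approx(dice_loss(p, y_pg, eps=0.0))


class TestDiceScore:
    def test_identical_masks_one(self, rng):
        y = _random_mask(rng)
        assert dice_score(y, y) == 1.0

    def test_cardinality_hand_value(self):
        y = np.zeros((4, 4), np.uint8); y[0, :4] = 1           # |y| = 4
        p = np.zeros((4, 4), np.uint8); p[0, :2] = 1           # |p| = 2, overlap 2
        assert dice_score(y, p) == pytest.approx(2 * 2 / 6)

    def test_both_empty_defined_as_one(self):
        assert dice_score(np.zeros((3, 3)), np.zeros((3, 3))) == 1.0

    def test_erosion_strictly_degrades(self, one_phantom):
        from scipy import ndimage
        _, masks = one_phantom
        y = masks.gland
        prev = 1.0
        pred = y.copy()
        for _ in range(2):
            pred = ndimage.binary_erosion(pred).astype(np.uint8)
            d = dice_score(y, pred)
            assert d < prev
            prev = d


class TestHausdorff:
    def test_identical_masks_zero(self, rng):
        y = _random_mask(rng, p=0.4)
        if y.sum() == 0:
            y[0, 0, 0] = 1
        assert hausdorff_mm(y, y, (1, 1, 1)) == 0.0

    def test_single_voxel_pair_through_plane(self):
        a = np.zeros((4, 4, 8), np.uint8); a[1, 1, 1] = 1
        b = np.zeros((4, 4, 8), np.uint8); b[1, 1, 6] = 1
        assert hausdorff_mm(a, b, (0.5, 0.5, 3.0)) == pytest.approx(15.0)

    def test_empty_mask_is_an_error_not_zero(self):
        y = np.zeros((4, 4, 2), np.uint8)
        p = np.ones((4, 4, 2), np.uint8)
        with pytest.raises(EmptyMaskError):
            hausdorff_mm(y, p, (1, 1, 1))

    def test_matches_brute_force_max_min(self):
        from scipy import ndimage
        rng = np.random.default_rng(9)
        spacing = np.array([0.7, 1.1, 2.9])
        for _ in range(20):
            a = _random_mask(rng, (6, 6, 4), p=0.3)
            b = _random_mask(rng, (6, 6, 4), p=0.3)
            if a.sum() == 0 or b.sum() == 0:
                continue

            def boundary_pts(m):
                er = ndimage.binary_erosion(
                    m, structure=ndimage.generate_binary_structure(3, 1),
                    border_value=0)
                return np.argwhere(m.astype(bool) & ~er) * spacing

            pa, pb = boundary_pts(a), boundary_pts(b)
            d = np.linalg.norm(pa[:, None, :] - pb[None, :, :], axis=2)
            brute = max(d.min(axis=1).max(), d.min(axis=0).max())
            assert hausdorff_mm(a, b, spacing) == pytest.approx(brute)

    def test_symmetry(self, rng):
        a, b = _random_mask(rng), _random_mask(rng)
        a[0, 0, 0] = b[1, 1, 1] = 1
        sp = (1.0, 1.0, 2.0)
        assert hausdorff_mm(a, b, sp) == hausdorff_mm(b, a, sp)


class TestHistograms:
    def test_histogram_sums_to_one_and_duplication_invariant(self, rng):
        vols = [rng.random((8, 8, 4)) for _ in range(3)]
        h = cohort_histogram(vols)
        assert h.sum() == pytest.approx(1.0)
        np.testing.assert_allclose(cohort_histogram(vols + vols), h)

    def test_constant_zero_cohort_unit_mass_first_bin(self):
        h = cohort_histogram([np.zeros((4, 4, 2))])
        assert h[0] == 1.0 and h[1:].sum() == 0.0

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError):
            cohort_histogram([])


class TestDiscrepancy:
    def test_identical_distributions_vanish(self, rng):
        p = rng.random(100); p /= p.sum()
        for metric in ("kl", "wasserstein", "js"):
            assert discrepancy(p, p, metric) == pytest.approx(0.0, abs=1e-9)

    def test_two_point_closed_form(self):
        p, q = np.array([1.0, 0.0]), np.array([0.0, 1.0])
        centers = np.array([0.0, 1.0])
        assert discrepancy(p, q, "wasserstein", bin_centers=centers) == \
            pytest.approx(1.0)
        assert discrepancy(p, q, "js") == pytest.approx(1.0)

    def test_js_symmetric_kl_not(self, rng):
        p = rng.random(50); p /= p.sum()
        q = rng.random(50); q /= q.sum()
        assert discrepancy(p, q, "js") == pytest.approx(discrepancy(q, p, "js"))
        assert discrepancy(p, q, "kl") != pytest.approx(discrepancy(q, p, "kl"))

    def test_invalid_inputs_rejected(self):
        p = np.array([0.5, 0.5])
        with pytest.raises(ValueError):
            discrepancy(p, np.array([0.7, 0.7]), "kl")
        with pytest.raises(ValueError):
            discrepancy(p, p, "total_variation")
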