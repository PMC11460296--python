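"""Contour <-> mask conversion: parsing, affine round trips, even-odd
rasterization against brute-force oracles, voxel-exact mask round trips."""

import numpy as np
import pytest
from scipy import ndimage

from pzseg.geometry import Geometry, StructureMaskSet
from pzseg.rtstruct import (ContourSet, OrphanContourError, RTStructFormatError,
                            masks_to_contours, rasterize, read_rtstruct)


def _make_rtstruct_dataset(structures):
    """Build an in-memory structure-set record {name: [(n,3) arrays]}."""
    from pydicom.dataset import Dataset
    from pydicom.sequence import Sequence

    ds = Dataset()
    ds.StructureSetROISequence = Sequence()
    ds.ROIContourSequence = Sequence()
    for num, (name, polys) in enumerate(structures.items(), start=1):
        roi = Dataset()
        roi.ROINumber = num
        roi.ROIName = name
        ds.StructureSetROISequence.append(roi)
        rc = Dataset()
        rc.ReferencedROINumber = num
        rc.ContourSequence = Sequence()
        for poly in polys:
            c = Dataset()
            c.ContourGeometricType = "CLOSED_PLANAR"
            c.ContourData = [float(v) for v in np.asarray(poly).ravel()]
            rc.ContourSequence.append(c)
        ds.ROIContourSequence.append(rc)
    return ds


SQUARE = np.array([[2.0, 2.0, 0.0], [2.0, 12.0, 0.0],
                   [12.0, 12.0, 0.0], [12.0, 2.0, 0.0]])


class TestReadRTStruct:
    def test_square_contour_parsed_faithfully(self):
        ds = _make_rtstruct_dataset({"prostate": [SQUARE]})
        cs = read_rtstruct(ds)
        assert cs.names() == ["prostate"]
        assert len(cs.structures["prostate"]) == 1
        np.testing.assert_array_equal(cs.structures["prostate"][0], SQUARE)

    def test_two_structures_exposed(self):
        ds = _make_rtstruct_dataset({"prostate": [SQUARE], "pz": [SQUARE + 1.0]})
        assert set(read_rtstruct(ds).names()) == {"prostate", "pz"}

    def test_empty_contour_sequence_warns_not_errors(self):
        ds = _make_rtstruct_dataset({"prostate": []})
        with pytest.warns(UserWarning, match="empty contour"):
            cs = read_rtstruct(ds)
        assert cs.structures["prostate"] == []

    def test_point_count_not_divisible_by_three_rejected(self):
        ds = _make_rtstruct_dataset({"prostate": [SQUARE]})
        ds.ROIContourSequence[0].ContourSequence[0].ContourData = [1.0, 2.0]
        with pytest.raises(RTStructFormatError, match="divisible by 3"):
            read_rtstruct(ds)

    def test_missing_contour_data_rejected(self):
        ds = _make_rtstruct_dataset({"prostate": [SQUARE]})
        del ds.ROIContourSequence[0].ContourSequence[0].ContourData
        with pytest.raises(RTStructFormatError, match="Contour Data"):
            read_rtstruct(ds)


class TestPatientIndexAffine:
    def test_origin_maps_to_zero_index(self):
        g = Geometry(shape=(8, 8, 4), spacing_mm=(0.5, 0.7, 3.0),
                     origin_mm=(10.0, -4.0, 2.0))
        np.testing.assert_allclose(g.patient_to_index(np.array(g.origin_mm)),
                                   np.zeros(3), atol=1e-12)

    def test_axis_aligned_step(self):
        g = Geometry(shape=(8, 8, 4), spacing_mm=(0.5, 0.7, 3.0))
        p = np.asarray(g.origin_mm) + 2 * 0.5 * g.row_dir
        np.testing.assert_allclose(g.patient_to_index(p), [2, 0, 0], atol=1e-12)

    def test_random_oblique_round_trip(self):
        from scipy.stats import special_ortho_group
        R = special_ortho_group.rvs(3, random_state=7)
        g = Geometry(shape=(8, 8, 4), spacing_mm=(0.5, 0.7, 3.0),
                     origin_mm=(5.0, -3.0, 2.0),
                     direction=(tuple(R[:, 0]), tuple(R[:, 1])))
        pts = np.random.default_rng(1).uniform(-50, 50, (100, 3))
        back = g.index_to_patient(g.patient_to_index(pts))
        assert np.abs(back - pts).max() < 1e-9


def _brute_force_even_odd(polys_rc, shape):
    """Crossing-number parity per pixel centre, half-open rule (oracle)."""
    mask = np.zeros(shape, dtype=bool)
    for r in range(shape[0]):
        for c in range(shape[1]):
            parity = 0
            for poly in polys_rc:
                p = np.asarray(poly, dtype=float)
                n = len(p)
                for i in range(n):
                    r1, c1 = p[i]
                    r2, c2 = p[(i + 1) % n]
                    if (r1 <= r < r2) or (r2 <= r < r1):
                        x = c1 + (r - r1) / (r2 - r1) * (c2 - c1)
                        if c >= x:  # crossing at or left of the centre
                            parity ^= 1
            mask[r, c] ^= bool(parity)
    return mask


class TestRasterize:
    GEOM = Geometry(shape=(20, 20, 3), spacing_mm=(1.0, 1.0, 3.0))

    def test_square_matches_brute_force_center_rule(self):
        cs = ContourSet(structures={"prostate": [SQUARE]})
        masks = rasterize(cs, self.GEOM)
        oracle = _brute_force_even_odd([SQUARE[:, :2]], (20, 20))
        np.testing.assert_array_equal(masks.gland[:, :, 0], oracle)
        assert masks.gland.sum() == oracle.sum() == 100  # half-open 10x10

    def test_concentric_squares_give_ring(self):
        inner = np.array([[5.0, 5.0, 0.0], [5.0, 9.0, 0.0],
                          [9.0, 9.0, 0.0], [9.0, 5.0, 0.0]])
        cs = ContourSet(structures={"prostate": [SQUARE, inner]})
        masks = rasterize(cs, self.GEOM)
        oracle = _brute_force_even_odd([SQUARE[:, :2], inner[:, :2]], (20, 20))
        np.testing.assert_array_equal(masks.gland[:, :, 0], oracle)
        assert masks.gland[6, 6, 0] == 0 and masks.gland[3, 3, 0] == 1

    def test_random_polygons_match_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(5):
            n = rng.integers(3, 8)
            poly = np.column_stack([rng.uniform(1, 18, n), rng.uniform(1, 18, n),
                                    np.zeros(n)])
            cs = ContourSet(structures={"gland": [poly]})
            masks = rasterize(cs, self.GEOM)
            oracle = _brute_force_even_odd([poly[:, :2]], (20, 20))
            np.testing.assert_array_equal(masks.gland[:, :, 0], oracle)

    def test_degenerate_collinear_triangle_empty_with_warning(self):
        tri = np.array([[1.0, 1.0, 0.0], [1.0, 5.0, 0.0], [1.0, 9.0, 0.0]])
        with pytest.warns(UserWarning, match="zero-area"):
            masks = rasterize(ContourSet(structures={"gland": [tri]}), self.GEOM)
        assert masks.gland.sum() == 0

    def test_orphan_contour_plane_rejected(self):
        poly = SQUARE.copy()
        poly[:, 2] = 100.0  # far from all 3 slices (spacing 3 mm)
        with pytest.raises(OrphanContourError):
            rasterize(ContourSet(structures={"gland": [poly]}), self.GEOM)

    def test_disc_area_converges_to_pi_r_squared(self):
        geom = Geometry(shape=(64, 64, 1), spacing_mm=(1.0, 1.0, 1.0))
        r = 20.0
        th = np.linspace(0, 2 * np.pi, 720, endpoint=False)
        circ = np.column_stack([31.5 + r * np.cos(th), 31.5 + r * np.sin(th),
                                np.zeros_like(th)])
        masks = rasterize(ContourSet(structures={"gland": [circ]}), geom)
        assert abs(masks.gland.sum() - np.pi * r * r) / (np.pi * r * r) < 0.02


class TestMaskContourRoundTrip:
    GEOM = Geometry(shape=(16, 16, 3), spacing_mm=(0.7, 0.9, 2.5))

    def _random_blob_masks(self, n=50):
        rng = np.random.default_rng(0)
        for _ in range(n):
            blob = ndimage.gaussian_filter(
                rng.standard_normal(self.GEOM.shape), 2) > 0
            yield StructureMaskSet(gland=blob.astype(np.uint8),
                                   geometry=self.GEOM)

    def test_round_trip_voxel_exact_on_random_blobs(self):
        for masks in self._random_blob_masks(50):
            back = rasterize(masks_to_contours(masks), self.GEOM)
            np.testing.assert_array_equal(back.gland, masks.gland)

    def test_second_cycle_is_identity(self):
        masks = next(iter(self._random_blob_masks(1)))
        once = rasterize(masks_to_contours(masks), self.GEOM)
        twice = rasterize(masks_to_contours(once), self.GEOM)
        np.testing.assert_array_equal(once.gland, twice.gland)

    def test_empty_mask_gives_empty_contours(self):
        masks = StructureMaskSet(gland=np.zeros(self.GEOM.shape, np.uint8),
                                 geometry=self.GEOM)
        assert masks_to_contours(masks).structures["gland"] == []

    def test_single_voxel_gives_four_vertex_polygon(self):
        m = np.zeros(self.GEOM.shape, np.uint8)
        m[5, 7, 1] = 1
        masks = StructureMaskSet(gland=m, geometry=self.GEOM)
        cs = masks_to_contours(masks)
        (poly,) = cs.structures["gland"]
        assert poly.shape == (4, 3)
        back = rasterize(cs, self.GEOM)
        np.testing.assert_array_equal(back.gland, m)
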