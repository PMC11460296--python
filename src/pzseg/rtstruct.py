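"""Planar contour-polygon annotations (DICOM RT-STRUCT dialect) <-> voxel masks.

Annotations arrive as per-slice planar polygons whose vertices live in patient
millimetres (Contour Data tag (3006,0050)); the voxel grid's placement in
patient space comes from the Image Orientation (0020,0037) and Image Position
(0020,0032) convention, with the slice direction given by the vector cross
product of the row and column directions.

Rasterization convention (fixed here, deterministic): a voxel is inside iff
its centre is inside the polygon under the even-odd rule; centre points lying
exactly on an edge count as inside when the edge is on the lower-index side
(half-open rule).  Multiple polygons on one slice combine by even-odd parity,
which supports holes.  ``masks_to_contours`` traces voxel-boundary polygons
whose vertices sit on half-integer indices, so re-rasterization reproduces the
mask voxel-exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Sequence

import numpy as np

from .geometry import Geometry, GeometryError, StructureMaskSet

__all__ = [
    "ContourSet",
    "RTStructFormatError",
    "OrphanContourError",
    "read_rtstruct",
    "patient_to_index",
    "index_to_patient",
    "rasterize",
    "rasterize_named",
    "masks_to_contours",
]

#: structure-name aliases mapped onto the two segmentation targets
_GLAND_NAMES = {"gland", "prostate", "whole prostate", "wp", "prostate gland"}
_PZ_NAMES = {"pz", "peripheral zone", "peripheral_zone"}


class RTStructFormatError(ValueError):
    """Malformed structure-set record."""


class OrphanContourError(ValueError):
    """A contour's plane lies farther than half the slice spacing from any slice."""


@dataclass
class ContourSet:
    """Per structure, a list of planar polygons in patient millimetres.

    Each polygon is an ``(n, 3)`` array of ordered vertices (n >= 3) sharing
    one slice plane.
    """

    structures: Dict[str, List[np.ndarray]] = field(default_factory=dict)

    def names(self):
        return list(self.structures)

    def __len__(self):
        return len(self.structures)


def patient_to_index(point_mm, geometry: Geometry):
    """Map patient-mm points to continuous voxel indices (affine inverse)."""
    return geometry.patient_to_index(point_mm)


def index_to_patient(index, geometry: Geometry):
    return geometry.index_to_patient(index)


def read_rtstruct(source) -> ContourSet:
    """Read planar contours from an RT-STRUCT record (path or pydicom Dataset).

    Only the fields the pipeline needs are consumed: structure names and the
    Contour Data point triplets.  Point order is preserved; units are patient
    millimetres.
    """
    import pydicom
    from pydicom.dataset import Dataset

    ds = source if isinstance(source, Dataset) else pydicom.dcmread(str(source), force=True)

    names = {}
    for roi in getattr(ds, "StructureSetROISequence", []):
        names[int(roi.ROINumber)] = str(roi.ROIName)

    if not hasattr(ds, "ROIContourSequence"):
        raise RTStructFormatError("record has no ROIContourSequence")

    out: Dict[str, List[np.ndarray]] = {}
    for rc in ds.ROIContourSequence:
        number = int(getattr(rc, "ReferencedROINumber", -1))
        name = names.get(number, f"roi_{number}")
        polys: List[np.ndarray] = []
        contour_seq = getattr(rc, "ContourSequence", [])
        if len(contour_seq) == 0:
            warnings.warn(f"structure {name!r} has an empty contour sequence")
        for c in contour_seq:
            if "ContourData" not in c:
                raise RTStructFormatError(
                    f"contour of structure {name!r} is missing Contour Data (3006,0050)"
                )
            data = np.asarray([float(v) for v in c.ContourData])
            if data.size % 3 != 0:
                raise RTStructFormatError(
                    f"Contour Data length {data.size} of {name!r} is not divisible by 3"
                )
            pts = data.reshape(-1, 3)
            if len(pts) >= 3:
                polys.append(pts)
            else:
                warnings.warn(f"skipping degenerate contour (<3 points) in {name!r}")
        if polys or len(contour_seq) == 0:
            out[name] = polys
    return ContourSet(structures=out)


def _fill_polygons_2d(polys_rc: Sequence[np.ndarray], shape) -> np.ndarray:
    """Even-odd scanline fill over integer pixel centres, half-open rule.

    ``polys_rc``: polygons as (n, 2) arrays in continuous (row, col) index
    coordinates.  Parity is accumulated across polygons (XOR), so holes work.
    """
    mask = np.zeros(shape, dtype=bool)
    for poly in polys_rc:
        p = np.asarray(poly, dtype=float)
        r1, c1 = p[:, 0], p[:, 1]
        r2, c2 = np.roll(r1, -1), np.roll(c1, -1)
        for y in range(shape[0]):
            # half-open crossing rule: r1 <= y < r2 or r2 <= y < r1
            hit = ((r1 <= y) & (y < r2)) | ((r2 <= y) & (y < r1))
            if not hit.any():
                continue
            t = (y - r1[hit]) / (r2[hit] - r1[hit])
            xs = np.sort(c1[hit] + t * (c2[hit] - c1[hit]))
            for x0, x1 in zip(xs[0::2], xs[1::2]):
                lo = int(np.ceil(x0))
                hi = int(np.ceil(x1))  # exclusive: centre must satisfy c < x1
                lo, hi = max(lo, 0), min(hi, shape[1])
                if hi > lo:
                    mask[y, lo:hi] ^= True
    return mask


def _canonical_name(name: str) -> str:
    n = name.strip().lower().replace("-", " ")
    if n in _GLAND_NAMES:
        return "gland"
    if n in _PZ_NAMES:
        return "pz"
    return name


def rasterize_named(contours: ContourSet, geometry: Geometry) -> Dict[str, np.ndarray]:
    """Rasterize every structure onto the geometry's grid, keyed by raw name."""
    out: Dict[str, np.ndarray] = {}
    n_slices = geometry.shape[2]
    for name, polys in contours.structures.items():
        vol = np.zeros(geometry.shape, dtype=bool)
        for poly in polys:
            idx = geometry.patient_to_index(poly)
            s = float(np.mean(idx[:, 2]))
            k = int(round(s))
            if k < 0 or k >= n_slices or abs(s - k) > 0.5 + 1e-9:
                raise OrphanContourError(
                    f"contour of {name!r} at slice index {s:.3f} is farther than half "
                    f"the slice spacing from any of the {n_slices} grid slices"
                )
            area2 = np.abs(np.dot(idx[:, 0], np.roll(idx[:, 1], -1))
                           - np.dot(idx[:, 1], np.roll(idx[:, 0], -1)))
            if area2 < 1e-12:
                warnings.warn(f"zero-area contour in {name!r} at slice {k}; rasterizes empty")
            vol[:, :, k] ^= _fill_polygons_2d([idx[:, :2]], geometry.shape[:2])
        out[name] = vol.astype(np.uint8)
    return out


def rasterize(contours: ContourSet, geometry: Geometry) -> StructureMaskSet:
    """Rasterize a ContourSet into a StructureMaskSet on the given grid.

    Structure names are mapped case-insensitively onto the gland / PZ targets;
    unrecognised names are kept under ``other``.  A missing gland structure
    yields an empty gland mask.
    """
    named = rasterize_named(contours, geometry)
    gland = np.zeros(geometry.shape, dtype=np.uint8)
    pz = None
    other = {}
    for name, mask in named.items():
        canon = _canonical_name(name)
        if canon == "gland":
            gland = mask
        elif canon == "pz":
            pz = mask
        else:
            other[name] = mask
    return StructureMaskSet(gland=gland, pz=pz, geometry=geometry, other=other)


def _trace_boundary_loops(mask2d: np.ndarray) -> List[np.ndarray]:
    """Trace the pixel-boundary of a binary image into closed polygons.

    Vertices lie on half-integer (row, col) coordinates (pixel corners), so no
    pixel centre can fall on a polygon edge and even-odd re-rasterization is
    exact.  Each directed boundary edge keeps the inside on its left; edges
    are chained into loops.
    """
    rows, cols = np.nonzero(mask2d)
    edges: Dict[tuple, List[tuple]] = {}

    def add(a, b):
        edges.setdefault(a, []).append(b)

    m = mask2d.astype(bool)
    H, W = m.shape
    for r, c in zip(rows, cols):
        if r == 0 or not m[r - 1, c]:      # top side
            add((r - 0.5, c + 0.5), (r - 0.5, c - 0.5))
        if r == H - 1 or not m[r + 1, c]:  # bottom side
            add((r + 0.5, c - 0.5), (r + 0.5, c + 0.5))
        if c == 0 or not m[r, c - 1]:      # left side
            add((r - 0.5, c - 0.5), (r + 0.5, c - 0.5))
        if c == W - 1 or not m[r, c + 1]:  # right side
            add((r + 0.5, c + 0.5), (r - 0.5, c + 0.5))

    loops = []
    while edges:
        start = next(iter(edges))
        loop = [start]
        cur = start
        while True:
            nxts = edges[cur]
            nxt = nxts.pop()
            if not nxts:
                del edges[cur]
            if nxt == start:
                break
            loop.append(nxt)
            cur = nxt
        # drop collinear intermediate vertices for compact polygons
        out = []
        n = len(loop)
        for i in range(n):
            a, b, c = loop[i - 1], loop[i], loop[(i + 1) % n]
            if (b[0] - a[0]) * (c[1] - b[1]) != (b[1] - a[1]) * (c[0] - b[0]):
                out.append(b)
        loops.append(np.asarray(out if len(out) >= 3 else loop, dtype=float))
    return loops


def masks_to_contours(masks: StructureMaskSet) -> ContourSet:
    """Convert voxel masks to per-slice boundary polygons in patient mm.

    Inverse of :func:`rasterize` on the same grid: re-rasterizing the result
    reproduces the input masks voxel-exactly.  An empty mask yields an empty
    polygon list for that structure.
    """
    geom = masks.geometry
    out: Dict[str, List[np.ndarray]] = {}
    for name, mask in masks.structures().items():
        polys: List[np.ndarray] = []
        for k in range(geom.shape[2]):
            sl = mask[:, :, k]
            if not sl.any():
                continue
            for loop in _trace_boundary_loops(sl):
                idx = np.column_stack([loop, np.full(len(loop), float(k))])
                polys.append(geom.index_to_patient(idx))
        out[name] = polys
    return ContourSet(structures=out)
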