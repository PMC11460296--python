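"""Core containers: image volumes, mask sets, and the index<->patient affine.

All volumes are rank-3 arrays indexed ``(row, col, slice)``.  Geometry follows
the DICOM patient-coordinate convention: a voxel index maps to patient
millimetres through ``origin + M @ index`` where the columns of ``M`` are the
row/column/slice direction vectors scaled by the spacing, and the slice
direction is the cross product of the row and column directions.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

__all__ = [
    "Geometry",
    "VolumeSample",
    "StructureMaskSet",
    "GeometryError",
]


class GeometryError(ValueError):
    """Raised for invalid spacing/direction metadata."""


def _as_unit(v: np.ndarray) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    n = np.linalg.norm(v)
    if n == 0:
        raise GeometryError("direction vector has zero length")
    return v / n


@dataclass(frozen=True)
class Geometry:
    """Grid geometry shared by a volume and its masks.

    Parameters
    ----------
    shape : tuple of int
        Voxel counts ``(rows, cols, slices)``.
    spacing_mm : tuple of float
        Positive spacing along (row, col, slice) in millimetres.
    origin_mm : tuple of float
        Patient coordinates (mm) of the centre of voxel ``(0, 0, 0)``.
    direction : 2x3 array
        Row direction and column direction unit vectors; the slice
        direction is their cross product.
    """

    shape: tuple
    spacing_mm: tuple
    origin_mm: tuple = (0.0, 0.0, 0.0)
    direction: tuple = ((1.0, 0.0, 0.0), (0.0, 1.0, 0.0))

    def __post_init__(self):
        if len(self.shape) != 3 or any(int(s) < 1 for s in self.shape):
            raise GeometryError(f"invalid grid shape {self.shape}")
        if any(s <= 0 for s in self.spacing_mm):
            raise GeometryError(f"spacing must be positive, got {self.spacing_mm}")
        d = np.asarray(self.direction, dtype=float)
        if d.shape != (2, 3):
            raise GeometryError("direction must hold two 3-vectors (row, col)")
        r, c = _as_unit(d[0]), _as_unit(d[1])
        if abs(float(r @ c)) > 1e-6:
            raise GeometryError("direction vectors are not orthonormal")
        object.__setattr__(self, "shape", tuple(int(s) for s in self.shape))
        object.__setattr__(self, "spacing_mm", tuple(float(s) for s in self.spacing_mm))
        object.__setattr__(self, "origin_mm", tuple(float(s) for s in self.origin_mm))
        object.__setattr__(self, "direction", (tuple(r), tuple(c)))

    @property
    def row_dir(self) -> np.ndarray:
        return np.asarray(self.direction[0])

    @property
    def col_dir(self) -> np.ndarray:
        return np.asarray(self.direction[1])

    @property
    def slice_dir(self) -> np.ndarray:
        return np.cross(self.row_dir, self.col_dir)

    @property
    def matrix(self) -> np.ndarray:
        """Columns are direction vectors scaled by spacing (index -> mm)."""
        return np.column_stack(
            [
                self.row_dir * self.spacing_mm[0],
                self.col_dir * self.spacing_mm[1],
                self.slice_dir * self.spacing_mm[2],
            ]
        )

    def index_to_patient(self, index) -> np.ndarray:
        """Map continuous voxel indices to patient millimetres."""
        idx = np.atleast_2d(np.asarray(index, dtype=float))
        pts = idx @ self.matrix.T + np.asarray(self.origin_mm)
        return pts[0] if np.ndim(index) == 1 else pts

    def patient_to_index(self, point_mm) -> np.ndarray:
        """Inverse of :meth:`index_to_patient` (continuous indices)."""
        m = self.matrix
        if abs(np.linalg.det(m)) < 1e-12:
            raise GeometryError("singular direction matrix")
        pts = np.atleast_2d(np.asarray(point_mm, dtype=float)) - np.asarray(self.origin_mm)
        idx = pts @ np.linalg.inv(m).T
        return idx[0] if np.ndim(point_mm) == 1 else idx

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing_mm))


@dataclass
class VolumeSample:
    """A rank-3 intensity grid with its geometry; the unit of all image I/O."""

    values: np.ndarray
    geometry: Geometry
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 3:
            raise ValueError("values must be rank-3 (row, col, slice)")
        if self.values.shape != self.geometry.shape:
            raise ValueError(
                f"values shape {self.values.shape} != geometry shape {self.geometry.shape}"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("volume intensities must be finite")

    @property
    def spacing_mm(self):
        return self.geometry.spacing_mm

    @property
    def shape(self):
        return self.values.shape


def _check_mask(mask: np.ndarray, geometry: Geometry) -> np.ndarray:
    mask = np.asarray(mask)
    if mask.shape != geometry.shape:
        raise ValueError(f"mask shape {mask.shape} != geometry shape {geometry.shape}")
    u = np.unique(mask)
    if not np.all(np.isin(u, (0, 1))):
        raise ValueError("mask values must be binary {0,1}")
    return mask.astype(np.uint8)


@dataclass
class StructureMaskSet:
    """Co-registered binary masks for the whole gland and the peripheral zone.

    ``pz`` may be absent (some cohorts ship gland-only references).
    """

    gland: np.ndarray
    geometry: Geometry
    pz: Optional[np.ndarray] = None
    other: dict = field(default_factory=dict)

    def __post_init__(self):
        self.gland = _check_mask(self.gland, self.geometry)
        if self.pz is not None:
            self.pz = _check_mask(self.pz, self.geometry)
        self.other = {k: _check_mask(v, self.geometry) for k, v in self.other.items()}

    def structures(self) -> dict:
        out = {"gland": self.gland}
        if self.pz is not None:
            out["pz"] = self.pz
        out.update(self.other)
        return out


def copy_with(sample: VolumeSample, **kw) -> VolumeSample:
    """Shallow-copy helper mirroring dataclasses.replace for VolumeSample."""
    base = dict(values=sample.values, geometry=sample.geometry, meta=dict(sample.meta))
    base.update(kw)
    return VolumeSample(**base)
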