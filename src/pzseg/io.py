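"""NIfTI volume and mask I/O.

The affine stored with each image is exactly the package's index->patient map:
columns are the row/col/slice direction vectors scaled by spacing, translation
is the centre of voxel (0,0,0) in patient mm.  Masks may be written either as
a single uint8 label map {0 background, 1 gland, 2 PZ-within-gland} or as one
binary file per structure.
"""

from __future__ import annotations

import os
from typing import Optional, Tuple

import nibabel as nib
import numpy as np

from .geometry import Geometry, GeometryError, StructureMaskSet, VolumeSample

__all__ = ["read_volume", "write_volume", "write_mask_set", "read_mask_set"]


def _affine(geom: Geometry) -> np.ndarray:
    a = np.eye(4)
    a[:3, :3] = geom.matrix
    a[:3, 3] = geom.origin_mm
    return a


def _geometry_from_affine(affine: np.ndarray, shape) -> Geometry:
    m = affine[:3, :3]
    spacing = np.linalg.norm(m, axis=0)
    if np.any(spacing <= 0):
        raise GeometryError("affine encodes non-positive spacing")
    d = m / spacing
    if not np.allclose(np.cross(d[:, 0], d[:, 1]), d[:, 2], atol=1e-4):
        raise GeometryError("affine is not orthonormal (sheared grids unsupported)")
    return Geometry(shape=tuple(shape), spacing_mm=tuple(spacing),
                    origin_mm=tuple(affine[:3, 3]),
                    direction=(tuple(d[:, 0]), tuple(d[:, 1])))


def read_volume(path) -> VolumeSample:
    """Read a NIfTI volume into a VolumeSample (values + geometry)."""
    path = str(path)
    if not os.path.exists(path):
        raise IOError(f"volume file not found: {path}")
    img = nib.load(path)
    data = np.asarray(img.get_fdata(), dtype=np.float64)
    if data.ndim != 3:
        raise IOError(f"{path}: expected a rank-3 volume, got shape {data.shape}")
    geom = _geometry_from_affine(img.affine, data.shape)
    return VolumeSample(values=data, geometry=geom)


def write_volume(sample: VolumeSample, path) -> None:
    """Write a VolumeSample as NIfTI; round-trips values and geometry."""
    img = nib.Nifti1Image(sample.values.astype(np.float32), _affine(sample.geometry))
    nib.save(img, str(path))


def write_mask_set(masks: StructureMaskSet, path, labels: bool = True) -> None:
    """Write masks as a label map (default) or as per-structure binary files.

    With ``labels=False``, ``path`` is treated as a prefix and one file per
    structure is written (``<prefix>_gland.nii.gz`` etc.).
    """
    aff = _affine(masks.geometry)
    if labels:
        lab = masks.gland.astype(np.uint8).copy()
        if masks.pz is not None:
            lab[masks.pz.astype(bool)] = 2
        nib.save(nib.Nifti1Image(lab, aff), str(path))
    else:
        prefix = str(path)
        for name, mask in masks.structures().items():
            nib.save(nib.Nifti1Image(mask.astype(np.uint8), aff),
                     f"{prefix}_{name}.nii.gz")


def read_mask_set(path) -> StructureMaskSet:
    """Read a label-map mask file written by :func:`write_mask_set`."""
    path = str(path)
    if not os.path.exists(path):
        raise IOError(f"mask file not found: {path}")
    img = nib.load(path)
    lab = np.rint(np.asarray(img.get_fdata())).astype(np.uint8)
    geom = _geometry_from_affine(img.affine, lab.shape)
    gland = (lab >= 1).astype(np.uint8)
    pz = (lab == 2).astype(np.uint8) if (lab == 2).any() else None
    return StructureMaskSet(gland=gland, pz=pz, geometry=geom)
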