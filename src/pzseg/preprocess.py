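"""Geometry and intensity standardisation for network input.

Pipeline order is fixed: resample -> standardize_shape -> normalize_intensity.
Images are resampled to a common spacing with cubic B-spline interpolation
(masks nearest-neighbour so they stay binary), centre-cropped/padded to a
standard reference grid at that spacing, then intensity-normalised per axial
slice (clip to mean +/- 3 sd, min-max rescale to [0,1]).

"Resizing" to the reference grid is a centre crop/pad at fixed spacing, not an
anisotropic stretch: stretching would silently change the standard spacing.
The applied offsets are recorded so predictions can be mapped back onto the
original geometry.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np
import SimpleITK as sitk

from .geometry import Geometry, GeometryError, StructureMaskSet, VolumeSample

__all__ = [
    "PreprocessConfig",
    "GeometryRecord",
    "resample",
    "standardize_shape",
    "normalize_intensity",
    "extract_2d_slices",
    "crop_3d",
    "paste_3d",
    "map_mask_to_geometry",
    "VolumePreprocessor",
]


@dataclass(frozen=True)
class PreprocessConfig:
    """Standardisation targets; defaults follow the 0.5 x 0.5 x 3 mm,
    256 x 256 x 23 reference grid with 128 x 128 x 23 central 3D crops."""

    target_spacing_mm: Tuple[float, float, float] = (0.5, 0.5, 3.0)
    target_shape: Tuple[int, int, int] = (256, 256, 23)
    crop3d_shape: Tuple[int, int, int] = (128, 128, 23)
    clip_sd: float = 3.0

    def __post_init__(self):
        if any(s <= 0 for s in self.target_spacing_mm) or self.clip_sd <= 0:
            raise ValueError("spacing and clip_sd must be positive")
        if any(int(s) < 1 for s in self.target_shape + self.crop3d_shape):
            raise ValueError("shapes must be positive")
        if any(c > t for c, t in zip(self.crop3d_shape, self.target_shape)):
            raise ValueError("crop3d_shape must not exceed target_shape")


@dataclass
class GeometryRecord:
    """Bookkeeping needed to map standardized-space predictions back."""

    original: Geometry
    resampled: Geometry
    offsets: Tuple[int, int, int]  # signed: >0 crop start, <0 pad amount (before)


def _to_sitk(values: np.ndarray, geom: Geometry) -> sitk.Image:
    # sitk arrays are indexed [k, j, i]; our arrays are (row=i, col=j, slice=k)
    img = sitk.GetImageFromArray(np.ascontiguousarray(values.transpose(2, 1, 0)))
    img.SetSpacing(tuple(geom.spacing_mm))
    img.SetOrigin(tuple(geom.origin_mm))
    d = np.column_stack([geom.row_dir, geom.col_dir, geom.slice_dir])
    img.SetDirection(tuple(d.flatten()))
    return img


def _from_sitk(img: sitk.Image) -> Tuple[np.ndarray, Geometry]:
    arr = sitk.GetArrayFromImage(img).transpose(2, 1, 0)
    d = np.asarray(img.GetDirection()).reshape(3, 3)
    geom = Geometry(shape=arr.shape, spacing_mm=img.GetSpacing(),
                    origin_mm=img.GetOrigin(),
                    direction=(tuple(d[:, 0]), tuple(d[:, 1])))
    return arr, geom


def resample(sample: VolumeSample, masks: Optional[StructureMaskSet],
             cfg: PreprocessConfig):
    """Resample to the target spacing (B-spline image, nearest masks).

    The physical centre of the volume is preserved, so the extent matches the
    input within one voxel.
    """
    geom = sample.geometry
    if any(s <= 0 for s in geom.spacing_mm):
        raise GeometryError("non-positive input spacing")
    old_size = np.asarray(geom.shape, dtype=float)
    old_sp = np.asarray(geom.spacing_mm)
    new_sp = np.asarray(cfg.target_spacing_mm)
    new_size = np.maximum(1, np.round(old_size * old_sp / new_sp)).astype(int)

    centre = geom.index_to_patient((old_size - 1) / 2.0)
    m = np.column_stack([geom.row_dir, geom.col_dir, geom.slice_dir])
    new_origin = centre - m @ (new_sp * (new_size - 1) / 2.0)

    ref = sitk.Image(*(int(s) for s in new_size), sitk.sitkFloat64)
    ref.SetSpacing(tuple(float(s) for s in new_sp))
    ref.SetOrigin(tuple(float(v) for v in new_origin))
    ref.SetDirection(tuple(m.flatten()))

    img = sitk.Resample(_to_sitk(sample.values, geom), ref, sitk.Transform(),
                        sitk.sitkBSpline, 0.0, sitk.sitkFloat64)
    vals, new_geom = _from_sitk(img)
    out_sample = VolumeSample(values=vals, geometry=new_geom, meta=dict(sample.meta))

    out_masks = None
    if masks is not None:
        def _res(mask):
            mimg = sitk.Resample(_to_sitk(mask.astype(np.float64), geom), ref,
                                 sitk.Transform(), sitk.sitkNearestNeighbor,
                                 0.0, sitk.sitkFloat64)
            return sitk.GetArrayFromImage(mimg).transpose(2, 1, 0).astype(np.uint8)

        out_masks = StructureMaskSet(
            gland=_res(masks.gland), geometry=new_geom,
            pz=None if masks.pz is None else _res(masks.pz),
            other={k: _res(v) for k, v in masks.other.items()})
    return out_sample, out_masks


def _crop_pad(arr: np.ndarray, target, pad_value) -> Tuple[np.ndarray, Tuple[int, ...]]:
    """Symmetric centre crop/pad; returns signed per-axis offsets."""
    offsets = []
    out = arr
    for ax, t in enumerate(target):
        n = out.shape[ax]
        off = (n - t) // 2
        offsets.append(off)
        if off > 0:
            sl = [slice(None)] * out.ndim
            sl[ax] = slice(off, off + t)
            out = out[tuple(sl)]
        elif off < 0:
            before = -off
            after = t - n - before
            pad = [(0, 0)] * out.ndim
            pad[ax] = (before, after)
            out = np.pad(out, pad, mode="constant", constant_values=pad_value)
    return out, tuple(offsets)


def standardize_shape(sample: VolumeSample, masks: Optional[StructureMaskSet],
                      cfg: PreprocessConfig):
    """Centre crop/pad to the reference shape at fixed spacing.

    Pad value is the image minimum (so padding does not perturb the slice-wise
    normalisation floor) and 0 for masks.  Returns the signed offsets applied.
    """
    geom = sample.geometry
    vals, offsets = _crop_pad(sample.values, cfg.target_shape,
                              float(sample.values.min()))
    # new origin: index offset maps through the affine
    new_origin = geom.index_to_patient(np.asarray(offsets, dtype=float))
    new_geom = Geometry(shape=cfg.target_shape, spacing_mm=geom.spacing_mm,
                        origin_mm=tuple(new_origin), direction=geom.direction)
    out_sample = VolumeSample(values=vals, geometry=new_geom, meta=dict(sample.meta))
    out_masks = None
    if masks is not None:
        def _cp(mask):
            return _crop_pad(mask, cfg.target_shape, 0)[0]

        out_masks = StructureMaskSet(
            gland=_cp(masks.gland), geometry=new_geom,
            pz=None if masks.pz is None else _cp(masks.pz),
            other={k: _cp(v) for k, v in masks.other.items()})
    return out_sample, out_masks, offsets


def normalize_intensity(sample: VolumeSample, cfg: PreprocessConfig) -> VolumeSample:
    """Slice-wise clip to mean +/- clip_sd * sd, then min-max rescale to [0,1].

    Both the clipping statistics and the rescale are computed per axial slice.
    Constant slices map to all-zero.
    """
    vals = sample.values.copy()
    for k in range(vals.shape[2]):
        sl = vals[:, :, k]
        mu, sd = float(sl.mean()), float(sl.std())
        clipped = np.clip(sl, mu - cfg.clip_sd * sd, mu + cfg.clip_sd * sd)
        lo, hi = float(clipped.min()), float(clipped.max())
        if hi - lo < 1e-12:
            vals[:, :, k] = 0.0
        else:
            vals[:, :, k] = (clipped - lo) / (hi - lo)
    return VolumeSample(values=vals, geometry=sample.geometry, meta=dict(sample.meta))


def extract_2d_slices(sample: VolumeSample, masks: Optional[StructureMaskSet] = None):
    """Split a standardized volume into per-axial-slice (image, masks) pairs."""
    out = []
    for k in range(sample.values.shape[2]):
        entry = {"image": sample.values[:, :, k]}
        if masks is not None:
            entry["gland"] = masks.gland[:, :, k]
            entry["pz"] = None if masks.pz is None else masks.pz[:, :, k]
        out.append(entry)
    return out


def crop_3d(sample: VolumeSample, masks: Optional[StructureMaskSet],
            cfg: PreprocessConfig):
    """Centred spatial crop to ``crop3d_shape``; offsets returned for paste-back."""
    if any(c > s for c, s in zip(cfg.crop3d_shape, sample.values.shape)):
        raise ValueError(
            f"crop {cfg.crop3d_shape} larger than volume {sample.values.shape}")
    offsets = tuple((s - c) // 2 for s, c in zip(sample.values.shape, cfg.crop3d_shape))
    sl = tuple(slice(o, o + c) for o, c in zip(offsets, cfg.crop3d_shape))
    geom = sample.geometry
    new_origin = geom.index_to_patient(np.asarray(offsets, dtype=float))
    new_geom = Geometry(shape=cfg.crop3d_shape, spacing_mm=geom.spacing_mm,
                        origin_mm=tuple(new_origin), direction=geom.direction)
    out_sample = VolumeSample(values=sample.values[sl], geometry=new_geom,
                              meta=dict(sample.meta))
    out_masks = None
    if masks is not None:
        out_masks = StructureMaskSet(
            gland=masks.gland[sl], geometry=new_geom,
            pz=None if masks.pz is None else masks.pz[sl],
            other={k: v[sl] for k, v in masks.other.items()})
    return out_sample, out_masks, offsets


def paste_3d(crop: np.ndarray, full_shape, offsets) -> np.ndarray:
    """Paste a 3D crop back into a zero volume of the standardized shape."""
    out = np.zeros(full_shape, dtype=crop.dtype)
    sl = tuple(slice(o, o + c) for o, c in zip(offsets, crop.shape))
    out[sl] = crop
    return out


def _uncrop_pad(arr: np.ndarray, orig_shape, offsets, fill=0) -> np.ndarray:
    """Invert :func:`_crop_pad`: restore the resampled-grid shape."""
    out = arr
    for ax, (n, off) in enumerate(zip(orig_shape, offsets)):
        t = out.shape[ax]
        if off > 0:  # was cropped: pad back
            after = n - t - off
            pad = [(0, 0)] * out.ndim
            pad[ax] = (off, after)
            out = np.pad(out, pad, mode="constant", constant_values=fill)
        elif off < 0:  # was padded: crop back
            sl = [slice(None)] * out.ndim
            sl[ax] = slice(-off, -off + n)
            out = out[tuple(sl)]
    return out


def map_mask_to_geometry(mask: np.ndarray, record: GeometryRecord) -> np.ndarray:
    """Map a standardized-space binary mask back to the original geometry."""
    on_resampled = _uncrop_pad(mask, record.resampled.shape, record.offsets)
    img = _to_sitk(on_resampled.astype(np.float64), record.resampled)
    ref = sitk.Image(*(int(s) for s in record.original.shape), sitk.sitkFloat64)
    ref.SetSpacing(tuple(record.original.spacing_mm))
    ref.SetOrigin(tuple(record.original.origin_mm))
    m = np.column_stack([record.original.row_dir, record.original.col_dir,
                         record.original.slice_dir])
    ref.SetDirection(tuple(m.flatten()))
    res = sitk.Resample(img, ref, sitk.Transform(), sitk.sitkNearestNeighbor,
                        0.0, sitk.sitkFloat64)
    return sitk.GetArrayFromImage(res).transpose(2, 1, 0).astype(np.uint8)


class VolumePreprocessor:
    """sklearn-style transformer composing the fixed standardisation pipeline.

    ``transform`` maps one (volume, masks) pair through
    resample -> standardize_shape -> normalize_intensity and returns the
    standardized pair plus a :class:`GeometryRecord` for mapping predictions
    back to the native grid.
    """

    def __init__(self, config: Optional[PreprocessConfig] = None):
        self.config = config if config is not None else PreprocessConfig()

    def get_params(self, deep=True):
        return {"config": self.config}

    def set_params(self, **params):
        for k, v in params.items():
            setattr(self, k, v)
        return self

    def fit(self, X=None, y=None):
        return self  # stateless

    def transform(self, sample: VolumeSample,
                  masks: Optional[StructureMaskSet] = None):
        cfg = self.config
        original = sample.geometry
        rs_sample, rs_masks = resample(sample, masks, cfg)
        resampled_geom = rs_sample.geometry
        st_sample, st_masks, offsets = standardize_shape(rs_sample, rs_masks, cfg)
        st_sample = normalize_intensity(st_sample, cfg)
        record = GeometryRecord(original=original, resampled=resampled_geom,
                                offsets=offsets)
        return st_sample, st_masks, record
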