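"""Synthetic prostate phantoms with ground-truth gland and peripheral-zone masks.

The phantom is a deformed ellipsoid gland with a posterior crescent PZ: the PZ
occupies the outer shell between two confocal level sets of the gland's
implicit function, clipped to the posterior half, which produces the familiar
crescent in axial slices.  Intensities are drawn per anatomical region
(background / central gland / PZ) from one of two named profiles that emulate
the cohort-level intensity behaviour of multi-centre T2-weighted prostate MR:
a bimodal distribution with a heavy right tail (typical 3T training cohorts)
and a unimodal low-contrast distribution (domain-shifted cohorts whose density
concentrates below ~0.2 after normalisation).

Volumes are specified in cm^3 externally; internally everything is voxel
counts, with the voxel volume in mm^3 / 1000 as the conversion factor.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, replace
from typing import Callable, List, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage

from .geometry import Geometry, StructureMaskSet, VolumeSample

__all__ = [
    "PhantomSpec",
    "PhantomSizingError",
    "INTENSITY_PROFILES",
    "generate_phantom",
    "generate_cohort",
    "shift_cohort_intensity",
    "cohort_spec_sampler",
]


class PhantomSizingError(ValueError):
    """Requested gland volume cannot be realised on the grid."""


#: Per-region (mean, sd) intensity parameters for the two cohort archetypes.
#: ``tail_fraction``/``tail_scale`` drive a log-normal bright subpopulation
#: that produces the heavy right tail of the bimodal profile.
INTENSITY_PROFILES = {
    "bimodal_heavy_tail": {
        "background": (0.13, 0.05),
        "gland": (0.38, 0.06),
        "pz": (0.68, 0.08),
        "tail_fraction": 0.04,
        "tail_scale": 0.35,
    },
    "unimodal_low_contrast": {
        "background": (0.10, 0.035),
        "gland": (0.16, 0.04),
        "pz": (0.20, 0.04),
        "tail_fraction": 0.0,
        "tail_scale": 0.0,
    },
}


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one synthetic prostate volume.

    Defaults emulate the training-cohort regime: gland volumes in the tens of
    cm^3, PZ roughly a quarter of the gland, anisotropic voxels with thick
    slices, and the bimodal heavy-tailed intensity profile.
    """

    grid_shape: Tuple[int, int, int] = (112, 112, 20)
    spacing_mm: Tuple[float, float, float] = (0.65, 0.65, 3.0)
    gland_volume_cm3: float = 55.0
    pz_fraction: float = 0.27
    gland_axis_ratios: Tuple[float, float, float] = (1.0, 1.15, 0.85)
    deformation_amplitude: float = 0.06
    intensity_profile: str = "bimodal_heavy_tail"
    intensity_params: Optional[dict] = None
    noise_sd: float = 0.04
    seed: int = 0

    def __post_init__(self):
        if not (0.0 < self.pz_fraction < 1.0):
            raise ValueError("pz_fraction must lie strictly in (0, 1)")
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError("all spacing components must be positive")
        if any(int(n) < 8 for n in self.grid_shape):
            raise ValueError("all grid dimensions must be >= 8")
        if self.gland_volume_cm3 <= 0:
            raise ValueError("gland_volume_cm3 must be positive")
        if any(r <= 0 for r in self.gland_axis_ratios):
            raise ValueError("gland_axis_ratios must be positive")
        if self.deformation_amplitude < 0 or self.noise_sd < 0:
            raise ValueError("deformation_amplitude and noise_sd must be >= 0")
        if self.intensity_params is None and self.intensity_profile not in INTENSITY_PROFILES:
            raise ValueError(
                f"unknown intensity_profile {self.intensity_profile!r}; "
                f"known: {sorted(INTENSITY_PROFILES)}"
            )

    def profile_params(self) -> dict:
        if self.intensity_params is not None:
            return self.intensity_params
        return INTENSITY_PROFILES[self.intensity_profile]


def _physical_coords(spec: PhantomSpec):
    """Centered physical coordinates (mm) of every voxel, per axis."""
    axes = []
    for n, sp in zip(spec.grid_shape, spec.spacing_mm):
        axes.append((np.arange(n) - (n - 1) / 2.0) * sp)
    return np.meshgrid(*axes, indexing="ij", sparse=True)


def _semi_axes(spec: PhantomSpec) -> np.ndarray:
    """Ellipsoid semi-axes (mm) realising the requested volume at the given ratios."""
    ar = np.asarray(spec.gland_axis_ratios, dtype=float)
    target_mm3 = spec.gland_volume_cm3 * 1000.0
    s = (target_mm3 / (4.0 / 3.0 * np.pi * np.prod(ar))) ** (1.0 / 3.0)
    return ar * s


def _max_feasible_volume_cm3(spec: PhantomSpec) -> float:
    """Largest gland volume whose base ellipsoid fits the grid with a 1-voxel margin."""
    ar = np.asarray(spec.gland_axis_ratios, dtype=float)
    half_extent = np.array(
        [(n - 3) / 2.0 * sp for n, sp in zip(spec.grid_shape, spec.spacing_mm)]
    )
    s_max = float(np.min(half_extent / ar))
    if s_max <= 0:
        return 0.0
    return 4.0 / 3.0 * np.pi * float(np.prod(ar * s_max)) / 1000.0


def _smooth_field(shape, rng, sigma_frac=0.15):
    """Band-limited unit-variance random field for boundary deformation."""
    raw = rng.standard_normal(shape)
    sigma = [max(1.0, s * sigma_frac) for s in shape]
    sm = ndimage.gaussian_filter(raw, sigma=sigma, mode="nearest")
    sd = sm.std()
    return sm / sd if sd > 0 else sm


def _largest_component(mask: np.ndarray) -> np.ndarray:
    lab, n = ndimage.label(mask)
    if n <= 1:
        return mask
    sizes = ndimage.sum_labels(mask, lab, index=np.arange(1, n + 1))
    return (lab == (1 + int(np.argmax(sizes)))).astype(np.uint8)


def _bisect_count(make_mask: Callable[[float], np.ndarray], target: int,
                  lo: float, hi: float, iters: int = 40) -> np.ndarray:
    """Bisect a monotone scale parameter until the mask voxel count hits target."""
    for _ in range(iters):
        mid = 0.5 * (lo + hi)
        m = make_mask(mid)
        c = int(m.sum())
        if c == target:
            return m
        if c < target:
            lo = mid
        else:
            hi = mid
    return make_mask(0.5 * (lo + hi))


def render_intensity(masks: StructureMaskSet, profile_params: dict,
                     noise_sd: float, rng: np.random.Generator) -> np.ndarray:
    """Draw voxel intensities for the given anatomy under a named profile."""
    shape = masks.geometry.shape
    pz = masks.pz if masks.pz is not None else np.zeros(shape, dtype=np.uint8)
    central = masks.gland.astype(bool) & ~pz.astype(bool)
    bg = ~masks.gland.astype(bool)

    vals = np.empty(shape, dtype=np.float64)
    for region, sel in (("background", bg), ("gland", central), ("pz", pz.astype(bool))):
        mu, sd = profile_params[region]
        vals[sel] = rng.normal(mu, sd, size=int(sel.sum()))

    frac = float(profile_params.get("tail_fraction", 0.0))
    if frac > 0:
        hot = rng.random(shape) < frac
        vals[hot] += rng.lognormal(mean=np.log(profile_params["tail_scale"]),
                                   sigma=0.5, size=int(hot.sum()))
    if noise_sd > 0:
        vals += rng.normal(0.0, noise_sd, size=shape)
    return np.clip(vals, 0.0, None)


def generate_phantom(spec: PhantomSpec) -> Tuple[VolumeSample, StructureMaskSet]:
    """Generate one phantom volume with its gland and PZ ground truth.

    The realised gland voxel count is matched to ``gland_volume_cm3`` by
    bisecting a global scale of the deformed implicit surface, so the volume
    error is limited by voxel discretisation only.  Identical spec (including
    seed) yields bit-identical output.
    """
    rng = np.random.default_rng(spec.seed)
    vmax = _max_feasible_volume_cm3(spec)
    if spec.gland_volume_cm3 > vmax:
        raise PhantomSizingError(
            f"gland volume {spec.gland_volume_cm3:g} cm^3 does not fit the grid; "
            f"maximum feasible is {vmax:.1f} cm^3"
        )

    coords = _physical_coords(spec)
    axes = _semi_axes(spec)
    # Normalised squared radius of the base ellipsoid.
    f = sum((c / a) ** 2 for c, a in zip(coords, axes))
    deform = spec.deformation_amplitude * _smooth_field(spec.grid_shape, rng)
    bound = np.maximum(1.0 + deform, 0.2) ** 2

    voxel_cm3 = np.prod(spec.spacing_mm) / 1000.0
    target_gland = max(1, int(round(spec.gland_volume_cm3 / voxel_cm3)))

    def gland_at(t):
        return (f <= t * t * bound).astype(np.uint8)

    gland = _bisect_count(gland_at, target_gland, lo=0.2, hi=3.0)
    gland = _largest_component(gland)

    # PZ: outer shell (f above an inner level set) clipped to the posterior half.
    posterior = coords[0] > 0  # +row direction is posterior
    target_pz = max(1, int(round(spec.pz_fraction * gland.sum())))

    def pz_at(s_in):
        return ((f > s_in * s_in * bound) & gland.astype(bool)
                & np.broadcast_to(posterior, gland.shape)).astype(np.uint8)

    # growing s_in shrinks the shell, so bisect with the decreasing orientation
    lo, hi = 0.0, 3.0
    pz = pz_at(0.0)
    for _ in range(50):
        mid = 0.5 * (lo + hi)
        cand = pz_at(mid)
        c = int(cand.sum())
        if c >= target_pz:
            lo, pz = mid, cand
        else:
            hi = mid
        if c == target_pz:
            break
    pz = (pz.astype(bool) & gland.astype(bool)).astype(np.uint8)

    geom = Geometry(shape=spec.grid_shape, spacing_mm=spec.spacing_mm)
    masks = StructureMaskSet(gland=gland, pz=pz, geometry=geom)
    vals = render_intensity(masks, spec.profile_params(), spec.noise_sd, rng)
    sample = VolumeSample(values=vals, geometry=geom,
                          meta={"phantom_spec": spec, "seed": spec.seed})
    return sample, masks


def _case_seeds(master_seed: int, n: int) -> List[int]:
    ss = np.random.SeedSequence(master_seed)
    return [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n)]


def generate_cohort(n: int, spec_sampler: Callable[[np.random.Generator], PhantomSpec],
                    seed: int) -> List[Tuple[VolumeSample, StructureMaskSet]]:
    """Generate ``n`` independent phantoms from a spec sampler.

    Per-case seeds are derived deterministically from the master seed, so the
    cohort is reproducible and cases are independent.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    seeds = _case_seeds(seed, n)
    sampler_rng = np.random.default_rng(np.random.SeedSequence((seed, 0x5eed)))
    out = []
    for case_seed in seeds:
        spec = spec_sampler(sampler_rng)
        spec = replace(spec, seed=case_seed)
        out.append(generate_phantom(spec))
    return out


def cohort_spec_sampler(mean_volume_cm3: float = 55.0, sd_volume_cm3: float = 12.0,
                        base_spec: Optional[PhantomSpec] = None,
                        min_volume_cm3: float = 15.0) -> Callable:
    """Sampler over PhantomSpec with normally distributed gland volumes.

    The default mean/sd spans roughly 25-70 cm^3, the range observed across
    multi-centre prostate cohorts; draws are truncated below at
    ``min_volume_cm3`` and at the grid's feasible maximum.
    """
    base = base_spec if base_spec is not None else PhantomSpec()

    def sample(rng: np.random.Generator) -> PhantomSpec:
        ratios = tuple(float(np.clip(rng.normal(r, 0.05), 0.4, 1.6))
                       for r in base.gland_axis_ratios)
        vmax = _max_feasible_volume_cm3(replace(base, gland_axis_ratios=ratios))
        v = float(np.clip(rng.normal(mean_volume_cm3, sd_volume_cm3),
                          min(min_volume_cm3, 0.9 * vmax), 0.9 * vmax))
        pzf = float(np.clip(rng.normal(base.pz_fraction, 0.04), 0.12, 0.45))
        return replace(base, gland_volume_cm3=v, gland_axis_ratios=ratios,
                       pz_fraction=pzf)

    return sample


def shift_cohort_intensity(cohort: Sequence[Tuple[VolumeSample, StructureMaskSet]],
                           profile: str) -> List[Tuple[VolumeSample, StructureMaskSet]]:
    """Re-render a cohort's intensities under a different named profile.

    Geometry and masks are untouched; each case re-uses its own seed, so
    remapping a cohort to its own profile reproduces it exactly.  Used to
    manufacture domain-shifted test cohorts.
    """
    if len(cohort) == 0:
        raise ValueError("cohort must be nonempty")
    if profile not in INTENSITY_PROFILES:
        raise ValueError(
            f"unknown intensity profile {profile!r}; known: {sorted(INTENSITY_PROFILES)}"
        )
    out = []
    for sample, masks in cohort:
        spec: PhantomSpec = sample.meta.get("phantom_spec")
        if spec is None:
            raise ValueError("cohort volumes lack phantom provenance metadata")
        new_spec = replace(spec, intensity_profile=profile, intensity_params=None)
        shifted, _ = generate_phantom(new_spec)
        # re-use the original mask object; geometry identical by construction
        out.append((shifted, masks))
    return out
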