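"""Synthetic CT phantoms with exactly known fat content.

The study data this package targets — ECG-gated thoracic CT stacks plus a
single abdominal slice, with expert-quality heart segmentations — is not
publicly available, so every image-domain operation here is exercised on
geometric phantoms whose ground truth is known *exactly* (by voxel
enumeration on the painted labels, not analytically).

Two phantom families are provided:

* a **cardiac** phantom: concentric ellipsoids on an anisotropic grid
  (1 x 1 mm in-plane, 1.5 mm slice increment), with lung background at
  -800 HU, a blood-pool "chambers" core at +40 HU, an epicardial fat shell
  at -70 HU (plus Gaussian noise), and a chest-wall ring at +30 HU.  The
  default shell holds ~104 ml of fat, the EATV scale of a middle-aged adult.
* an **abdominal** phantom: a single 5 mm slice with a visceral fat disc,
  a closed lean-tissue (muscle-wall) ring at +40 HU and a subcutaneous fat
  annulus, painted at -88 / -106 HU respectively — visceral fat reads
  brighter than subcutaneous fat on CT.

The HU palette deliberately straddles the adipose window [-190, -30] on both
sides so that window-boundary behaviour is testable.

:func:`inject_segmentation_failure` corrupts a mask in one of three
parameterised ways (a detached blob, a deleted wedge, a leak towards the
chest wall), emulating the conspicuous 3-D shape errors that motivate the
segmentation quality check.  The corruption size is honoured to within one
voxel by construction: the injected/removed region is the exact number of
voxels closest to the target site.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidGeometryError, ParameterError, PlacementError
from .grids import VoxelVolume, as_bool_mask, physical_coordinates, validate_spacing

# HU palette (invented; straddles the fat window on both sides)
LUNG_HU = -800.0
BLOOD_HU = 40.0
FAT_HU = -70.0
CHEST_WALL_HU = 30.0
AIR_HU = -1000.0
MUSCLE_HU = 40.0
VAT_HU = -88.0
SAT_HU = -106.0
HU_CLIP = (-1000.0, 1000.0)


@dataclass(frozen=True)
class CardiacShapeParams:
    """Geometry of the cardiac phantom (all lengths in mm).

    The defaults give a fat shell of ~104 ml between the pericardium and
    chamber ellipsoids, on a 128 x 128 x 96 grid at 1 x 1 x 1.5 mm.
    """

    shape: tuple[int, int, int] = (128, 128, 96)
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.5)
    pericardium_axes_mm: tuple[float, float, float] = (45.0, 40.0, 34.0)
    chamber_axes_mm: tuple[float, float, float] = (40.0, 35.0, 26.0)
    center_mm: tuple[float, float, float] | None = None  # grid centre if None
    chest_wall: bool = True


@dataclass
class PhantomTruth:
    """Ground truth shipped with a cardiac phantom."""

    pericardium_mask: np.ndarray
    chamber_mask: np.ndarray
    true_eatv_ml: float
    true_eata_hu: float
    fat_center_hu: float
    noise_sd_hu: float


@dataclass(frozen=True)
class FailureSpec:
    """One parameterised segmentation corruption.

    ``offset_mm`` is the displacement of added material beyond the mask
    surface (``add_blob``) or the length of the leaking finger
    (``leak_to_chest_wall``); it is ignored by ``delete_wedge``.
    ``direction`` optionally fixes the unit direction of the corruption;
    by default it is drawn from ``seed``.
    """

    mode: str
    magnitude_ml: float
    offset_mm: float = 0.0
    seed: int = 0
    direction: tuple[float, float, float] | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("add_blob", "delete_wedge", "leak_to_chest_wall"):
            raise ParameterError(f"unknown failure mode {self.mode!r}")
        if self.magnitude_ml <= 0:
            raise ParameterError("magnitude_ml must be > 0")
        if self.offset_mm < 0:
            raise ParameterError("offset_mm must be >= 0")


def _ellipsoid_mask(shape, spacing, center_mm, axes_mm) -> np.ndarray:
    coords = physical_coordinates(shape, spacing)
    grids = np.meshgrid(*coords, indexing="ij", sparse=True)
    q = np.zeros(shape, dtype=np.float64)
    for g, c, a in zip(grids, center_mm, axes_mm):
        if a <= 0:
            return np.zeros(shape, dtype=bool)
        q = q + ((g - c) / a) ** 2
    return q <= 1.0


def generate_cardiac_phantom(
    params: CardiacShapeParams | None = None,
    fat_center_hu: float = FAT_HU,
    noise_sd_hu: float = 10.0,
    seed: int = 0,
) -> tuple[VoxelVolume, PhantomTruth]:
    """Build a thoracic phantom volume and its exact ground truth.

    The pericardium interior is the outer ellipsoid, the chambers the inner
    one; every voxel between them is epicardial fat.  ``true_eatv_ml`` is an
    exhaustive count of fat-labelled voxels times the voxel volume, and
    ``true_eata_hu`` is the median of their painted (noisy) HU values, so
    both are exact for the generated grid.
    """
    params = params or CardiacShapeParams()
    spacing = validate_spacing(params.spacing)
    extent = tuple(n * s for n, s in zip(params.shape, spacing))
    center = params.center_mm or tuple(e / 2.0 for e in extent)
    if any(a <= 0 for a in params.pericardium_axes_mm):
        raise InvalidGeometryError("pericardium semi-axes must be positive")
    if any(ca >= pa for ca, pa in zip(params.chamber_axes_mm, params.pericardium_axes_mm)):
        raise InvalidGeometryError("chamber ellipsoid must be strictly inside the pericardium")
    for c, a, e in zip(center, params.pericardium_axes_mm, extent):
        if c - a < 0 or c + a > e:
            raise InvalidGeometryError(
                f"pericardium ellipsoid (semi-axis {a} mm at {c} mm) exceeds grid extent {e} mm"
            )

    pericardium = _ellipsoid_mask(params.shape, spacing, center, params.pericardium_axes_mm)
    chambers = _ellipsoid_mask(params.shape, spacing, center, params.chamber_axes_mm)
    fat = pericardium & ~chambers

    data = np.full(params.shape, LUNG_HU, dtype=np.float32)
    if params.chest_wall:
        # hollow elliptical cylinder hugging the in-plane grid boundary
        x, y = np.meshgrid(
            *physical_coordinates(params.shape[:2], spacing[:2]), indexing="ij", sparse=True
        )
        rho = np.sqrt(
            ((x - extent[0] / 2) / (0.49 * extent[0])) ** 2
            + ((y - extent[1] / 2) / (0.49 * extent[1])) ** 2
        )
        wall2d = (rho >= 0.88) & (rho <= 1.0)
        data[wall2d, :] = CHEST_WALL_HU
    data[chambers] = BLOOD_HU
    data[fat] = fat_center_hu

    if noise_sd_hu > 0:
        rng = np.random.default_rng(seed)
        data = data + rng.normal(0.0, noise_sd_hu, size=params.shape).astype(np.float32)
    data = np.clip(data, *HU_CLIP)

    volume = VoxelVolume(data=data, spacing=spacing)
    true_eatv_ml = float(int(fat.sum()) * np.prod(spacing) / 1000.0)
    true_eata_hu = float(np.median(data[fat])) if fat.any() else float("nan")
    truth = PhantomTruth(
        pericardium_mask=pericardium,
        chamber_mask=chambers,
        true_eatv_ml=true_eatv_ml,
        true_eata_hu=true_eata_hu,
        fat_center_hu=float(fat_center_hu),
        noise_sd_hu=float(noise_sd_hu),
    )
    return volume, truth


# ---------------------------------------------------------------------------
# failure injection
# ---------------------------------------------------------------------------

def _unit_direction(spec: FailureSpec, ndim: int) -> np.ndarray:
    if spec.direction is not None:
        u = np.asarray(spec.direction, dtype=np.float64)
    else:
        rng = np.random.default_rng(spec.seed)
        u = rng.normal(size=ndim)
    norm = np.linalg.norm(u)
    if norm == 0:
        raise ParameterError("direction must be a nonzero vector")
    return u / norm


def _surface_point(mask: np.ndarray, spacing, u: np.ndarray) -> np.ndarray:
    """Last point along the ray centroid + t*u that is still inside the mask."""
    idx = np.argwhere(mask)
    centroid = idx.mean(axis=0) * np.asarray(spacing)
    step = min(spacing) / 2.0
    t_max = float(np.linalg.norm(np.asarray(mask.shape) * np.asarray(spacing)))
    last_inside = centroid.copy()
    t = 0.0
    while t <= t_max:
        p = centroid + t * u
        i = np.round(p / np.asarray(spacing)).astype(int)
        if np.any(i < 0) or np.any(i >= np.asarray(mask.shape)):
            break
        if mask[tuple(i)]:
            last_inside = p
        t += step
    return last_inside


def _nearest_voxels(shape, spacing, point, n_voxels, candidate_mask=None):
    """Indices of the ``n_voxels`` grid voxels closest (physically) to ``point``.

    Ties are broken by flattened array order, so the selection is
    deterministic.  A bounding box around ``point`` keeps the search cheap.
    """
    spacing = np.asarray(spacing)
    vox_mm3 = float(np.prod(spacing))
    # generous physical search radius: 1.8x the equivalent-sphere radius
    r_eq = (3.0 * n_voxels * vox_mm3 / (4.0 * np.pi)) ** (1.0 / 3.0)
    radius = 1.8 * r_eq + 2.0 * float(spacing.max())
    lo = np.maximum(np.floor((point - radius) / spacing).astype(int), 0)
    hi = np.minimum(np.ceil((point + radius) / spacing).astype(int) + 1, np.asarray(shape))
    if np.any(lo >= hi):
        raise PlacementError("corruption site lies entirely outside the grid")
    sub_coords = [np.arange(l, h) * s for l, h, s in zip(lo, hi, spacing)]
    grids = np.meshgrid(*sub_coords, indexing="ij", sparse=True)
    d2 = sum((g - p) ** 2 for g, p in zip(grids, point))
    d2 = np.broadcast_to(d2, tuple(h - l for l, h in zip(lo, hi))).reshape(-1)
    if candidate_mask is not None:
        sub_ok = candidate_mask[tuple(slice(l, h) for l, h in zip(lo, hi))].reshape(-1)
        d2 = np.where(sub_ok, d2, np.inf)
    order = np.argsort(d2, kind="stable")[:n_voxels]
    if not np.all(np.isfinite(d2[order])):
        raise PlacementError("not enough candidate voxels near the corruption site")
    sub_shape = tuple(h - l for l, h in zip(lo, hi))
    multi = np.unravel_index(order, sub_shape)
    return tuple(m + l for m, l in zip(multi, lo))


def inject_segmentation_failure(
    mask: np.ndarray, spec: FailureSpec, spacing
) -> np.ndarray:
    """Return a corrupted copy of ``mask``; the input is left untouched.

    ``add_blob`` unions in a compact blob of exactly
    ``round(magnitude_ml / voxel_volume)`` voxels centred ``offset_mm``
    beyond the mask surface along the corruption direction.
    ``delete_wedge`` removes that many mask voxels nearest to a surface
    point.  ``leak_to_chest_wall`` attaches a finger of outside voxels
    hugging a segment that runs ``offset_mm`` outward from the surface.
    """
    mask = as_bool_mask(mask)
    spacing = validate_spacing(spacing)
    if not mask.any():
        raise ParameterError("cannot corrupt an empty mask")
    vox_mm3 = float(np.prod(spacing))
    n_voxels = max(1, int(round(spec.magnitude_ml * 1000.0 / vox_mm3)))
    u = _unit_direction(spec, mask.ndim)
    surface = _surface_point(mask, spacing, u)
    extent = np.asarray(mask.shape) * np.asarray(spacing)
    out = mask.copy()

    if spec.mode == "add_blob":
        center = surface + spec.offset_mm * u
        r_eq = (3.0 * spec.magnitude_ml * 1000.0 / (4.0 * np.pi)) ** (1.0 / 3.0)
        if np.any(center - r_eq < 0) or np.any(center + r_eq > extent):
            raise PlacementError(
                f"blob of radius {r_eq:.1f} mm at {np.round(center, 1)} mm "
                f"exceeds grid extent {np.round(extent, 1)} mm"
            )
        out[_nearest_voxels(mask.shape, spacing, center, n_voxels)] = True
    elif spec.mode == "delete_wedge":
        if n_voxels >= int(mask.sum()):
            raise ParameterError(
                "delete_wedge magnitude is at least the whole mask volume"
            )
        out[_nearest_voxels(mask.shape, spacing, surface, n_voxels, candidate_mask=mask)] = False
    else:  # leak_to_chest_wall
        length = max(spec.offset_mm, 1.0)
        tip = surface + length * u
        if np.any(tip < 0) or np.any(tip > extent):
            raise PlacementError("leak extends outside the grid")
        # score voxels by distance to the surface->tip segment, pick the
        # n_voxels best ones outside the mask: a connected finger
        steps = np.linspace(0.0, 1.0, max(8, int(length)))
        samples = surface[None, :] + steps[:, None] * (tip - surface)[None, :]
        pad = (3.0 * spec.magnitude_ml * 1000.0 / (4.0 * np.pi)) ** (1.0 / 3.0) + 2.0 * max(spacing)
        lo = np.maximum(np.floor((samples.min(0) - pad) / spacing).astype(int), 0)
        hi = np.minimum(
            np.ceil((samples.max(0) + pad) / spacing).astype(int) + 1, np.asarray(mask.shape)
        )
        sub_coords = [np.arange(l, h) * s for l, h, s in zip(lo, hi, spacing)]
        grids = np.meshgrid(*sub_coords, indexing="ij")
        pts = np.stack([g.reshape(-1) for g in grids], axis=1)
        d2 = np.full(pts.shape[0], np.inf)
        for s in samples:
            d2 = np.minimum(d2, ((pts - s[None, :]) ** 2).sum(axis=1))
        sub_slice = tuple(slice(l, h) for l, h in zip(lo, hi))
        outside = ~mask[sub_slice].reshape(-1)
        d2 = np.where(outside, d2, np.inf)
        order = np.argsort(d2, kind="stable")[:n_voxels]
        if not np.all(np.isfinite(d2[order])):
            raise PlacementError("not enough outside voxels for the requested leak")
        multi = np.unravel_index(order, tuple(h - l for l, h in zip(lo, hi)))
        out[tuple(m + l for m, l in zip(multi, lo))] = True
    return out


# ---------------------------------------------------------------------------
# abdominal phantom
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AbdominalShapeParams:
    """Geometry of the single-slice abdominal phantom (lengths in mm).

    Concentric ellipses: a visceral fat disc, a lean muscle-wall ring of
    ``wall_thickness_mm``, and a subcutaneous fat annulus out to
    ``sat_outer_axes_mm``.  The defaults give ~138 cm^2 of VAT, the NGT
    median scale.  ``wall_gap_deg`` > 0 carves an angular gap into the wall
    (only valid when no VAT is enclosed — an open ring cannot define an
    inside).
    """

    shape: tuple[int, int] = (224, 224)
    spacing: tuple[float, float] = (1.0, 1.0)
    slice_thickness_mm: float = 5.0
    vat_axes_mm: tuple[float, float] = (70.0, 63.0)
    wall_thickness_mm: float = 8.0
    sat_outer_axes_mm: tuple[float, float] = (100.0, 92.0)
    wall_gap_deg: float = 0.0


@dataclass
class AbdominalPhantomTruth:
    """Ground truth shipped with an abdominal phantom slice."""

    fat_mask: np.ndarray
    lean_wall_mask: np.ndarray
    true_vat_cm2: float
    true_sat_cm2: float
    true_vat_hu: float | None
    true_sat_hu: float | None


def generate_abdominal_phantom(
    params: AbdominalShapeParams | None = None,
    noise_sd_hu: float = 5.0,
    seed: int = 0,
) -> tuple[VoxelVolume, AbdominalPhantomTruth]:
    """Build a 2-D abdominal slice and its exact ground truth.

    Areas are exhaustive pixel counts times pixel area; attenuations are
    medians of the painted (noisy) pixel values.
    """
    params = params or AbdominalShapeParams()
    spacing = validate_spacing(params.spacing)
    extent = tuple(n * s for n, s in zip(params.shape, spacing))
    center = tuple(e / 2.0 for e in extent)
    wall_outer = tuple(a + params.wall_thickness_mm for a in params.vat_axes_mm)
    if params.wall_thickness_mm <= 0:
        raise InvalidGeometryError("wall thickness must be positive")
    if any(s < w for s, w in zip(params.sat_outer_axes_mm, wall_outer)):
        raise InvalidGeometryError("SAT outer ellipse must contain the lean wall")
    for c, a, e in zip(center, params.sat_outer_axes_mm, extent):
        if c - a < 0 or c + a > e:
            raise InvalidGeometryError("outer ellipse exceeds the grid")
    has_vat = all(a > 0 for a in params.vat_axes_mm)
    if params.wall_gap_deg > 0 and has_vat:
        raise InvalidGeometryError(
            "an open lean ring cannot enclose a VAT region; "
            "set vat_axes_mm to zero or close the wall"
        )

    vat_px = _ellipsoid_mask(params.shape, spacing, center, params.vat_axes_mm)
    wall_px = _ellipsoid_mask(params.shape, spacing, center, wall_outer) & ~vat_px
    sat_px = _ellipsoid_mask(params.shape, spacing, center, params.sat_outer_axes_mm) & ~(
        vat_px | wall_px
    )
    if params.wall_gap_deg > 0:
        x, y = np.meshgrid(*physical_coordinates(params.shape, spacing), indexing="ij")
        ang = np.degrees(np.arctan2(y - center[1], x - center[0]))
        wall_px &= ~(np.abs(ang) <= params.wall_gap_deg / 2.0)

    data = np.full(params.shape, AIR_HU, dtype=np.float32)
    data[sat_px] = SAT_HU
    data[wall_px] = MUSCLE_HU
    data[vat_px] = VAT_HU
    if noise_sd_hu > 0:
        rng = np.random.default_rng(seed)
        data = data + rng.normal(0.0, noise_sd_hu, size=params.shape).astype(np.float32)
    data = np.clip(data, *HU_CLIP)

    volume = VoxelVolume(data=data, spacing=spacing)
    truth = AbdominalPhantomTruth(
        fat_mask=vat_px | sat_px,
        lean_wall_mask=wall_px,
        true_vat_cm2=float(int(vat_px.sum()) * np.prod(spacing) / 100.0),
        true_sat_cm2=float(int(sat_px.sum()) * np.prod(spacing) / 100.0),
        true_vat_hu=float(np.median(data[vat_px])) if vat_px.any() else None,
        true_sat_hu=float(np.median(data[sat_px])) if sat_px.any() else None,
    )
    return volume, truth
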