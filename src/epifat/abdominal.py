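"""Visceral / subcutaneous fat separation on a single abdominal CT slice.

Abdominal fat is segmented by HU thresholding (same closed adipose window as
the cardiac pipeline, [-190, -30] by default), then split into visceral
(VAT) and subcutaneous (SAT) depots with an *inside lean-tissue filter*: the
abdominal muscular wall is lean tissue forming a closed ring around the
visceral compartment, so fat enclosed by lean tissue is VAT and everything
else is SAT.

"Inside lean tissue" is operationalised as border-connected background
exclusion: the lean mask is morphologically closed (metric closing, default
5 mm radius, to seal small anatomical gaps in the wall), its holes are
filled from the image border, and the filled-minus-wall region is the
visceral interior.  An open wall that the closing cannot seal yields no
interior — all fat is then subcutaneous — rather than an error.

Areas are reported in cm^2 for the single slice; this protocol acquires one
5 mm slice at the L4 level, so no volumetric abdominal measure exists.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .eat import FatWindow, median_attenuation
from .errors import ParameterError
from .grids import VoxelVolume, as_bool_mask, require_aligned, validate_spacing
from .qc import dilate_mm, erode_mm

#: Default lean-tissue window (HU); floor abuts the adipose ceiling.
DEFAULT_LEAN_WINDOW = (-29.0, 150.0)


@dataclass(frozen=True)
class AbdominalMeasurement:
    """Areas (cm^2) and median attenuations (HU) of the two abdominal depots.

    A median is ``None`` when the corresponding depot is empty.
    """

    vat_area_cm2: float
    sat_area_cm2: float
    vat_median_hu: float | None
    sat_median_hu: float | None


def segment_fat_2d(slice_volume: VoxelVolume, window: FatWindow | None = None) -> np.ndarray:
    """Threshold a 2-D slice with the closed adipose HU window."""
    if slice_volume.ndim != 2:
        raise ParameterError(f"expected a 2-D slice, got {slice_volume.ndim}-D data")
    window = window or FatWindow()
    return window.contains(slice_volume.data)


def lean_mask_from_hu(
    slice_volume: VoxelVolume,
    lo_hu: float = DEFAULT_LEAN_WINDOW[0],
    hi_hu: float = DEFAULT_LEAN_WINDOW[1],
) -> np.ndarray:
    """Threshold lean (muscle-range) tissue on a 2-D slice."""
    if slice_volume.ndim != 2:
        raise ParameterError(f"expected a 2-D slice, got {slice_volume.ndim}-D data")
    return FatWindow(lo_hu, hi_hu).contains(slice_volume.data)


def separate_vat_sat(
    fat_mask: np.ndarray,
    lean_mask: np.ndarray,
    spacing,
    closing_mm: float = 5.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Split fat pixels into (VAT, SAT) using the inside-lean-tissue filter.

    The two returned masks partition ``fat_mask`` exactly: their union is the
    fat mask and their intersection is empty.  Without any lean tissue (or
    with a wall too open for the closing to seal) the interior is empty and
    every fat pixel is SAT.
    """
    fat_mask = as_bool_mask(fat_mask)
    lean_mask = as_bool_mask(lean_mask)
    require_aligned(fat_mask.shape, lean_mask)
    spacing = validate_spacing(spacing)
    if closing_mm < 0:
        raise ParameterError("closing_mm must be >= 0")
    if lean_mask.any() and closing_mm > 0:
        closed = erode_mm(dilate_mm(lean_mask, spacing, closing_mm), spacing, closing_mm)
        closed |= lean_mask  # discrete closing must never drop wall pixels
    else:
        closed = lean_mask
    # strict interior: holes of the closed wall; then reattach pixels the
    # closing added (gap bridges, swallowed boundary pixels) when they touch
    # the interior, so an annulus partitions exactly and an open wall that
    # the closing cannot seal yields no interior at all
    strict = ndimage.binary_fill_holes(closed) & ~closed
    reclaim = closed & ~lean_mask
    interior = ndimage.binary_propagation(
        strict, mask=strict | reclaim, structure=np.ones((3,) * fat_mask.ndim, bool)
    )
    vat = fat_mask & interior
    sat = fat_mask & ~interior
    return vat, sat


def area_cm2(mask: np.ndarray, spacing) -> float:
    """Pixel count times pixel area, in cm^2."""
    mask = as_bool_mask(mask)
    spacing = validate_spacing(spacing)
    if len(spacing) != mask.ndim:
        raise ParameterError("spacing dimensionality does not match the mask")
    return float(int(mask.sum()) * np.prod(spacing) / 100.0)


def quantify_abdominal(
    slice_volume: VoxelVolume,
    window: FatWindow | None = None,
    lean_mask: np.ndarray | None = None,
    closing_mm: float = 5.0,
) -> AbdominalMeasurement:
    """Full single-slice abdominal measurement.

    When no lean mask is supplied one is derived from the slice itself with
    the default lean HU window.
    """
    fat = segment_fat_2d(slice_volume, window)
    if lean_mask is None:
        lean_mask = lean_mask_from_hu(slice_volume)
    vat, sat = separate_vat_sat(fat, lean_mask, slice_volume.spacing, closing_mm)
    return AbdominalMeasurement(
        vat_area_cm2=area_cm2(vat, slice_volume.spacing),
        sat_area_cm2=area_cm2(sat, slice_volume.spacing),
        vat_median_hu=median_attenuation(slice_volume, vat) if vat.any() else None,
        sat_median_hu=median_attenuation(slice_volume, sat) if sat.any() else None,
    )
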