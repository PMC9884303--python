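"""Voxel grids with physical spacing.

A :class:`VoxelVolume` couples a 2-D or 3-D array of CT attenuation values
(Hounsfield units) with the physical size of a voxel in millimetres.  All
distances, volumes and areas in this package are computed in physical units,
so anisotropic grids (e.g. 1x1 mm in-plane, 1.5 mm between slices) behave
correctly everywhere.

For cardiac acquisitions reconstructed with overlapping slices, the axial
component of ``spacing`` is the *slice increment* (centre-to-centre distance
between consecutive slices), not the slice thickness.  With 3 mm slices at
50 % overlap the increment is 1.5 mm, and volume integration must use it:
summing thicknesses would count overlapping tissue twice.

Binary masks are plain boolean numpy arrays aligned voxel-for-voxel with a
volume; a handful of helpers validate them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import AlignmentError, MaskValueError, ParameterError

#: Slice increment (mm) of the cardiac protocol: 3 mm slices at 50 % overlap.
CARDIAC_SLICE_INCREMENT_MM = 1.5


@dataclass
class VoxelVolume:
    """A scalar attenuation grid with per-axis physical spacing.

    Parameters
    ----------
    data:
        2-D or 3-D array of HU values.  Stored as float32.
    spacing:
        Physical size of one voxel per axis, in mm, same length as
        ``data.ndim``.  For overlapping-slice cardiac stacks the axial entry
        is the slice increment (1.5 mm for 3 mm slices at 50 % overlap).
    origin:
        Physical offset of voxel (0, 0[, 0]) in mm.  Informational only.
    """

    data: np.ndarray
    spacing: tuple[float, ...]
    origin: tuple[float, ...] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float32)
        if self.data.ndim not in (2, 3):
            raise ParameterError(f"expected 2-D or 3-D data, got {self.data.ndim}-D")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != self.data.ndim:
            raise ParameterError(
                f"spacing has {len(self.spacing)} entries for {self.data.ndim}-D data"
            )
        if any(s <= 0 for s in self.spacing):
            raise ParameterError(f"spacing must be positive, got {self.spacing}")
        if not np.all(np.isfinite(self.data)):
            raise ParameterError("volume contains non-finite values")
        if self.origin is None:
            self.origin = (0.0,) * self.data.ndim
        else:
            self.origin = tuple(float(o) for o in self.origin)

    @property
    def ndim(self) -> int:
        return self.data.ndim

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def voxel_volume_mm3(self) -> float:
        """Volume (3-D) or area (2-D) of a single voxel, in mm^3 or mm^2."""
        return float(np.prod(self.spacing))


def validate_spacing(spacing) -> tuple[float, ...]:
    spacing = tuple(float(s) for s in spacing)
    if any(s <= 0 for s in spacing):
        raise ParameterError(f"spacing must be positive, got {spacing}")
    return spacing


def as_bool_mask(mask) -> np.ndarray:
    """Coerce an array to boolean, rejecting values other than 0/1."""
    arr = np.asarray(mask)
    if arr.dtype != bool:
        labels = np.unique(arr)
        bad = [v for v in labels.tolist() if v not in (0, 1)]
        if bad:
            raise MaskValueError(f"mask contains non-binary values: {bad}")
        arr = arr.astype(bool)
    return arr


def require_aligned(volume_shape: tuple[int, ...], *masks: np.ndarray) -> None:
    """Raise :class:`AlignmentError` unless every mask matches the shape."""
    for m in masks:
        if m.shape != tuple(volume_shape):
            raise AlignmentError(
                f"mask shape {m.shape} does not match volume shape {tuple(volume_shape)}"
            )


def physical_coordinates(shape, spacing):
    """Per-axis physical coordinates (mm) of voxel centres, origin at 0."""
    spacing = validate_spacing(spacing)
    return [np.arange(n, dtype=np.float64) * s for n, s in zip(shape, spacing)]
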