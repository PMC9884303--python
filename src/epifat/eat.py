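"""Epicardial adipose tissue (EAT) quantification.

EAT is the fat contained inside the pericardial sac but outside the heart
chambers.  On non-contrast CT it is identified purely by attenuation: a voxel
counts as adipose tissue when its HU value falls inside a fixed window,
-190 to -30 HU by default, endpoints included.  The two summary statistics
are

* **EATV** — the depot volume in ml, voxel count x voxel volume, where the
  axial voxel extent is the slice *increment* (1.5 mm for 3 mm slices at
  50 % overlap), and
* **EATA** — the median attenuation (HU) of the selected voxels.

Voxels are all-or-nothing; no partial-volume weighting is applied.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ParameterError, UndefinedStatisticError
from .grids import VoxelVolume, as_bool_mask, require_aligned, validate_spacing

#: Default adipose-tissue attenuation window (HU), endpoints inclusive.
DEFAULT_FAT_WINDOW = (-190.0, -30.0)


@dataclass(frozen=True)
class FatWindow:
    """Closed HU interval defining adipose tissue."""

    lo_hu: float = DEFAULT_FAT_WINDOW[0]
    hi_hu: float = DEFAULT_FAT_WINDOW[1]

    def __post_init__(self) -> None:
        if not self.lo_hu < self.hi_hu:
            raise ParameterError(
                f"fat window requires lo < hi, got [{self.lo_hu}, {self.hi_hu}]"
            )

    def contains(self, hu: np.ndarray) -> np.ndarray:
        """Boolean mask of values inside the closed window."""
        hu = np.asarray(hu)
        return (hu >= self.lo_hu) & (hu <= self.hi_hu)


@dataclass(frozen=True)
class FatMeasurement:
    """Volume (or area) plus median attenuation of one fat depot.

    ``median_hu`` is ``None`` when no voxel was selected; a numeric sentinel
    is never used.
    """

    volume_ml: float
    median_hu: float | None
    voxel_count: int

    def __post_init__(self) -> None:
        if (self.voxel_count == 0) != (self.volume_ml == 0.0):
            raise ParameterError("volume_ml must be 0 exactly when voxel_count is 0")
        if self.voxel_count == 0 and self.median_hu is not None:
            raise ParameterError("median_hu must be None for an empty depot")


def select_eat_voxels(
    volume: VoxelVolume,
    pericardium: np.ndarray,
    chambers: np.ndarray,
    window: FatWindow | None = None,
) -> np.ndarray:
    """Voxels inside the pericardium, outside the chambers, in the fat window.

    The chamber mask is intersected with the pericardium before subtraction,
    so chamber voxels outside the sac are irrelevant.  Window endpoints are
    inclusive on both sides.
    """
    window = window or FatWindow()
    pericardium = as_bool_mask(pericardium)
    chambers = as_bool_mask(chambers)
    require_aligned(volume.shape, pericardium, chambers)
    return pericardium & ~(chambers & pericardium) & window.contains(volume.data)


def compute_volume_ml(mask: np.ndarray, spacing) -> float:
    """Mask volume in ml: voxel count x dx x dy x dz_increment / 1000.

    ``spacing`` carries the axial slice increment, not the slice thickness;
    with overlapping slices, using the thickness would double-count tissue.
    """
    mask = as_bool_mask(mask)
    spacing = validate_spacing(spacing)
    if len(spacing) != mask.ndim:
        raise ParameterError(
            f"spacing has {len(spacing)} entries for a {mask.ndim}-D mask"
        )
    return float(int(mask.sum()) * np.prod(spacing) / 1000.0)


def median_attenuation(volume: VoxelVolume, mask: np.ndarray) -> float:
    """Exact sample median HU over the masked voxels.

    Even counts take the midpoint of the two central values.  An empty mask
    has no median; :class:`UndefinedStatisticError` is raised rather than
    returning a sentinel.
    """
    mask = as_bool_mask(mask)
    require_aligned(volume.shape, mask)
    if not mask.any():
        raise UndefinedStatisticError("median attenuation of an empty mask is undefined")
    return float(np.median(volume.data[mask]))


def quantify_eat(
    volume: VoxelVolume,
    pericardium: np.ndarray,
    chambers: np.ndarray,
    window: FatWindow | None = None,
) -> FatMeasurement:
    """EATV (ml) and EATA (median HU) from a volume plus the two masks."""
    eat = select_eat_voxels(volume, pericardium, chambers, window)
    count = int(eat.sum())
    volume_ml = compute_volume_ml(eat, volume.spacing)
    median_hu = median_attenuation(volume, eat) if count else None
    return FatMeasurement(volume_ml=volume_ml, median_hu=median_hu, voxel_count=count)
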