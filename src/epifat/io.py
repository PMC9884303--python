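"""Reading and writing volumes, masks and measurement records.

NIfTI (via nibabel) is the canonical on-disk image format; a directory path
is treated as a DICOM series and read through SimpleITK.  Voxel spacing is
taken from the file header in mm and must be positive; masks must contain
only 0 and 1.  Measurements are emitted as JSON objects and flat CSV rows.
"""

from __future__ import annotations

import dataclasses
import json
import os

import nibabel as nib
import numpy as np

from .errors import MaskValueError, ParameterError
from .grids import VoxelVolume, as_bool_mask


def read_volume(path, squeeze: bool = True) -> VoxelVolume:
    """Load a NIfTI file (or DICOM series directory) as a VoxelVolume.

    ``squeeze`` drops trailing singleton axes, so a single-slice NIfTI
    becomes a 2-D volume with 2-D spacing.
    """
    if os.path.isdir(path):
        data, spacing = _read_dicom_series(path)
    else:
        img = nib.load(str(path))
        data = np.asanyarray(img.dataobj).astype(np.float32)
        spacing = tuple(float(z) for z in img.header.get_zooms()[: data.ndim])
    if any(z <= 0 for z in spacing):
        raise ParameterError(f"non-positive voxel spacing in header: {spacing}")
    while squeeze and data.ndim > 2 and data.shape[-1] == 1:
        data = data[..., 0]
        spacing = spacing[:-1]
    return VoxelVolume(data=data, spacing=spacing)


def _read_dicom_series(path):
    import SimpleITK as sitk

    reader = sitk.ImageSeriesReader()
    files = reader.GetGDCMSeriesFileNames(str(path))
    if not files:
        raise ParameterError(f"no DICOM series found under {path}")
    reader.SetFileNames(files)
    img = reader.Execute()
    # SimpleITK arrays come back (z, y, x); transpose to (x, y, z)
    data = sitk.GetArrayFromImage(img).astype(np.float32).transpose(2, 1, 0)
    return data, tuple(float(s) for s in img.GetSpacing())


def read_mask(path, squeeze: bool = True) -> tuple[np.ndarray, tuple[float, ...]]:
    """Load a binary mask; returns ``(bool array, spacing)``.

    Any value other than 0 or 1 is a validation error listing the offending
    labels.
    """
    vol = read_volume(path, squeeze=squeeze)
    values = np.unique(vol.data)
    bad = [float(v) for v in values.tolist() if v not in (0.0, 1.0)]
    if bad:
        raise MaskValueError(f"mask contains non-binary values: {bad}")
    return vol.data.astype(bool), vol.spacing


def _affine(spacing, origin) -> np.ndarray:
    aff = np.eye(4)
    for i, s in enumerate(spacing[:3]):
        aff[i, i] = s
    for i, o in enumerate(origin[:3]):
        aff[i, 3] = o
    return aff


def write_volume(volume: VoxelVolume, path) -> None:
    """Write a VoxelVolume as NIfTI, spacing carried in the affine/zooms."""
    data = volume.data
    spacing = volume.spacing
    origin = volume.origin
    if data.ndim == 2:  # single-slice volumes are stored with a unit 3rd axis
        data = data[..., None]
        spacing = (*spacing, 1.0)
        origin = (*origin, 0.0)
    img = nib.Nifti1Image(np.asarray(data, dtype=np.float32), _affine(spacing, origin))
    img.header.set_zooms(spacing)
    nib.save(img, str(path))


def write_mask(mask: np.ndarray, spacing, path) -> None:
    mask = as_bool_mask(mask)
    vol = VoxelVolume(data=mask.astype(np.float32), spacing=spacing)
    write_volume(vol, path)


def _jsonable(value):
    if dataclasses.is_dataclass(value) and not isinstance(value, type):
        return {
            k: _jsonable(v)
            for k, v in dataclasses.asdict(value).items()
            if not isinstance(v, np.ndarray)
        }
    if isinstance(value, (np.floating, np.integer)):
        return value.item()
    if isinstance(value, np.bool_):
        return bool(value)
    if isinstance(value, dict):
        return {k: _jsonable(v) for k, v in value.items()}
    if isinstance(value, (list, tuple)):
        return [_jsonable(v) for v in value]
    return value


def write_json(record, path) -> None:
    """Serialise a dataclass or dict to JSON (numpy scalars unwrapped)."""
    with open(path, "w") as fh:
        json.dump(_jsonable(record), fh, indent=2, sort_keys=True)
        fh.write("\n")


def measurement_csv_row(subject_id, measurement) -> dict:
    """Flatten a FatMeasurement into a CSV-ready row."""
    return {
        "subject_id": subject_id,
        "eatv_ml": measurement.volume_ml,
        "eata_hu": measurement.median_hu,
        "voxel_count": measurement.voxel_count,
    }
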