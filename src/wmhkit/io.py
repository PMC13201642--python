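"""NIfTI reading and writing with spacing preserved through every stage."""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np

from wmhkit.types import LabelMap, Volume, WMHKitError


class FormatError(WMHKitError):
    """Malformed or unsupported image file."""


def read_volume(path) -> Volume:
    """Load a 3-D NIfTI-1 volume; spacing comes from the header zooms."""
    path = Path(path)
    try:
        img = nib.load(str(path))
    except Exception as exc:  # malformed header, truncated file
        raise FormatError(f"cannot read NIfTI file {path}: {exc}") from exc
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise FormatError(f"{path}: expected a 3-D payload, got ndim={data.ndim}")
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return Volume(data=np.asarray(data, dtype=np.float64), spacing=spacing, affine=img.affine)


def write_volume(volume: Volume, path) -> None:
    """Write a Volume as NIfTI; the affine encodes the spacing if absent."""
    affine = volume.affine if volume.affine is not None else np.diag([*volume.spacing, 1.0])
    img = nib.Nifti1Image(np.asarray(volume.data, dtype=np.float64), affine)
    img.header.set_zooms(volume.spacing)
    nib.save(img, str(path))


def write_mask(mask: np.ndarray, spacing, path, affine=None) -> None:
    """Masks are stored as uint8 NIfTI with the source affine."""
    if affine is None:
        affine = np.diag([*spacing, 1.0])
    img = nib.Nifti1Image(np.asarray(mask, dtype=np.uint8), affine)
    img.header.set_zooms(tuple(spacing))
    nib.save(img, str(path))


def read_mask(path) -> np.ndarray:
    return read_volume(path).data.astype(bool)


def read_labels(path) -> LabelMap:
    vol = read_volume(path)
    return LabelMap(
        data=np.rint(vol.data).astype(np.int16), spacing=vol.spacing, affine=vol.affine
    )
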