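"""Reading and writing CT volumes and masks (NIfTI, NRRD, DICOM series).

NIfTI goes through nibabel, NRRD through SimpleITK, and DICOM series are
read-only through SimpleITK's series reader (rescale slope/intercept are
applied by the reader, so voxels arrive in HU).  Arrays are kept in
``[x, y, z]`` index order; SimpleITK's native ``[z, y, x]`` order is
transposed at the boundary.
"""

from __future__ import annotations

import os
from pathlib import Path

import nibabel as nib
import numpy as np
import SimpleITK as sitk

from .grid import CTVolume, VoxelMask

__all__ = ["read_volume", "write_volume", "read_mask", "write_mask"]


def _format_of(path: str | Path, fmt: str | None) -> str:
    if fmt is not None:
        return fmt.lower()
    p = str(path)
    if os.path.isdir(p):
        return "dicom"
    if p.endswith((".nii", ".nii.gz")):
        return "nifti"
    if p.endswith((".nrrd", ".nhdr")):
        return "nrrd"
    raise ValueError(f"cannot infer format of {path!r}; pass format explicitly")


def _from_sitk(img: sitk.Image) -> CTVolume:
    arr = sitk.GetArrayFromImage(img)  # (z, y, x)
    data = np.ascontiguousarray(arr.transpose(2, 1, 0)).astype(np.float32)
    return CTVolume(data, spacing=tuple(img.GetSpacing()), origin=tuple(img.GetOrigin()))


def read_volume(path: str | Path, format: str | None = None) -> CTVolume:
    """Read a CT volume from NIfTI, NRRD, or a DICOM-series directory.

    Raises
    ------
    FileNotFoundError
        If the path does not exist.
    ValueError
        For an unreadable file, an empty or non-uniformly spaced DICOM
        series, or an unknown format.
    """
    fmt = _format_of(path, format)
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    if fmt == "nifti":
        img = nib.load(str(path))
        data = np.asanyarray(img.dataobj).astype(np.float32)
        spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
        origin = tuple(float(v) for v in img.affine[:3, 3])
        return CTVolume(data, spacing=spacing, origin=origin)
    if fmt == "nrrd":
        return _from_sitk(sitk.ReadImage(str(path)))
    if fmt == "dicom":
        reader = sitk.ImageSeriesReader()
        files = reader.GetGDCMSeriesFileNames(str(path))
        if not files:
            raise ValueError(f"no DICOM series found under {path}")
        positions = []
        for f in files:
            fr = sitk.ImageFileReader()
            fr.SetFileName(f)
            fr.ReadImageInformation()
            positions.append(float(fr.GetMetaData("0020|0032").split("\\")[-1])
                             if fr.HasMetaDataKey("0020|0032") else None)
        if all(p is not None for p in positions) and len(positions) > 2:
            gaps = np.diff(sorted(positions))
            if gaps.size and (gaps.max() - gaps.min()) > 1e-3:
                raise ValueError(
                    "non-uniform DICOM slice spacing: gaps range "
                    f"{gaps.min():.4f}-{gaps.max():.4f} mm"
                )
        reader.SetFileNames(files)
        return _from_sitk(reader.Execute())
    raise ValueError(f"unknown format {fmt!r}")


def write_volume(volume: CTVolume, path: str | Path, format: str | None = None) -> None:
    """Write a volume as NIfTI (via nibabel) or NRRD (via SimpleITK)."""
    fmt = _format_of(path, format)
    if fmt == "nifti":
        affine = np.diag(list(volume.spacing) + [1.0])
        affine[:3, 3] = volume.origin
        nib.save(nib.Nifti1Image(volume.data.astype(np.float32), affine), str(path))
        return
    if fmt == "nrrd":
        img = sitk.GetImageFromArray(volume.data.transpose(2, 1, 0))
        img.SetSpacing(volume.spacing)
        img.SetOrigin(volume.origin)
        sitk.WriteImage(img, str(path))
        return
    raise ValueError(f"cannot write format {fmt!r}")


def read_mask(path: str | Path) -> VoxelMask:
    vol = read_volume(path)
    return VoxelMask(vol.data > 0.5, spacing=vol.spacing, origin=vol.origin)


def write_mask(mask: VoxelMask, path: str | Path) -> None:
    """Masks are written as unsigned-8-bit NIfTI label images."""
    affine = np.diag(list(mask.spacing) + [1.0])
    affine[:3, 3] = mask.origin
    nib.save(nib.Nifti1Image(mask.data.astype(np.uint8), affine), str(path))
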