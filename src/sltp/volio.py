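"""Volume I/O with orientation canonicalization.

All in-memory volumes use canonical LPI axes:

* axis 0 — right → left (x)
* axis 1 — anterior → posterior (y)
* axis 2 — superior → inferior (z); slice index 0 is the lung apex.

Distances are physical millimetres taken from the header spacing.
NIfTI is handled through nibabel, MetaImage through SimpleITK.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import nibabel as nib
import numpy as np
import SimpleITK as sitk

from .exceptions import HeaderError, VolumeFormatError

CANONICAL_AXCODES = ("L", "P", "I")

_NIFTI_EXT = (".nii", ".nii.gz")
_META_EXT = (".mha", ".mhd")


@dataclass
class Volume:
    """A 3D scalar grid (HU for CT, integer codes for masks / label maps).

    ``voxels`` is indexed ``[x, y, z]`` on the canonical LPI axes and
    ``spacing`` is the (dx, dy, dz) voxel size in mm.
    """

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    orientation: str = "LPI"

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise VolumeFormatError(f"expected a 3D grid, got shape {self.voxels.shape}")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise HeaderError(f"spacing must be strictly positive on all axes, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    def copy(self) -> "Volume":
        return Volume(self.voxels.copy(), self.spacing, self.orientation)


def _ext(path: str) -> str:
    lower = str(path).lower()
    for e in _NIFTI_EXT + _META_EXT:
        if lower.endswith(e):
            return e
    return os.path.splitext(lower)[1]


def _canonicalize_nifti(img: nib.spatialimages.SpatialImage) -> Volume:
    ornt_src = nib.orientations.io_orientation(img.affine)
    if np.any(np.isnan(ornt_src)):
        raise HeaderError("affine does not define a per-axis orientation")
    ornt_dst = nib.orientations.axcodes2ornt(CANONICAL_AXCODES)
    transform = nib.orientations.ornt_transform(ornt_src, ornt_dst)
    data = nib.orientations.apply_orientation(np.asanyarray(img.dataobj), transform)
    zooms = img.header.get_zooms()[:3]
    if any(z == 0 for z in zooms):
        raise HeaderError(f"header spacing is degenerate: {zooms}")
    perm = transform[:, 0].astype(int)
    spacing = tuple(float(zooms[p]) for p in perm)
    return Volume(np.ascontiguousarray(data), spacing)


def _canonicalize_meta(img: sitk.Image) -> Volume:
    img = sitk.DICOMOrient(img, "".join(CANONICAL_AXCODES))
    data = sitk.GetArrayFromImage(img).transpose(2, 1, 0)
    spacing = tuple(float(s) for s in img.GetSpacing())
    return Volume(np.ascontiguousarray(data), spacing)


def read_volume(path: str) -> Volume:
    """Read a NIfTI (.nii/.nii.gz) or MetaImage (.mha/.mhd) volume.

    The returned :class:`Volume` is canonicalized to LPI axes with spacing
    taken from the header.  Canonicalization is a normal form: re-reading a
    written canonical volume is the identity.
    """
    if not os.path.exists(path):
        raise VolumeFormatError(f"no such file: {path}")
    ext = _ext(path)
    try:
        if ext in _NIFTI_EXT:
            return _canonicalize_nifti(nib.load(path))
        if ext in _META_EXT:
            return _canonicalize_meta(sitk.ReadImage(str(path)))
    except (HeaderError, VolumeFormatError):
        raise
    except Exception as exc:  # unreadable / truncated / wrong magic
        raise VolumeFormatError(f"cannot read {path!r} as a volume: {exc}") from exc
    raise VolumeFormatError(f"unsupported volume format: {path!r} (use .nii/.nii.gz/.mha/.mhd)")


def _lpi_affine(spacing: tuple[float, float, float]) -> np.ndarray:
    # LPI axes expressed in the RAS world of NIfTI: all three axes are flipped.
    return np.diag([-spacing[0], -spacing[1], -spacing[2], 1.0])


def write_volume(volume: Volume, path: str) -> str:
    """Write a canonical volume; :func:`read_volume` inverts it."""
    ext = _ext(path)
    if ext in _NIFTI_EXT:
        img = nib.Nifti1Image(volume.voxels, _lpi_affine(volume.spacing))
        img.header.set_zooms(volume.spacing)
        nib.save(img, path)
    elif ext in _META_EXT:
        img = sitk.GetImageFromArray(np.ascontiguousarray(volume.voxels.transpose(2, 1, 0)))
        img.SetSpacing(volume.spacing)
        img.SetDirection((1.0, 0, 0, 0, 1.0, 0, 0, 0, -1.0))  # axis 2 points inferior
        sitk.WriteImage(img, str(path))
    else:
        raise VolumeFormatError(f"unsupported volume format: {path!r}")
    return str(path)


def write_label_map(labels: Volume, path: str) -> str:
    """Losslessly store an integer label map (−1 outside lung, 0 no-emphysema).

    Raises ``TypeError`` for non-integer data.
    """
    if not np.issubdtype(labels.voxels.dtype, np.integer):
        raise TypeError(f"label maps must be integer typed, got dtype {labels.voxels.dtype}")
    vol = Volume(labels.voxels.astype(np.int16), labels.spacing)
    return write_volume(vol, path)
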