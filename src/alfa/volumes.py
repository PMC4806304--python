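"""Core image data model, NIfTI I/O, resampling and intensity standardization.

The two containers defined here — :class:`Volume` for scalar 3-D images and
:class:`BinaryMask` for brain/non-brain labellings — carry their voxel spacing
(mm) and the NIfTI voxel-to-world affine, and are the currency passed between
every other module of the package.

Intensity standardization follows the histogram-landmark approach of Nyul and
Udupa: percentile landmarks of the image foreground are mapped
piecewise-linearly onto a set of reference landmarks learnt from a training
population, making intensities comparable across scans before atlas selection
and label fusion.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Sequence

import nibabel as nib
import numpy as np
import SimpleITK as sitk

__all__ = [
    "Volume",
    "BinaryMask",
    "DegenerateImageError",
    "read_volume",
    "read_mask",
    "write_volume",
    "resample_isotropic",
    "normalize_intensities",
    "train_landmarks",
    "DEFAULT_LANDMARK_PERCENTILES",
]

#: Percentiles used as histogram landmarks: clipped min/max plus deciles.
DEFAULT_LANDMARK_PERCENTILES = (1.0, 10.0, 20.0, 30.0, 40.0, 50.0,
                                60.0, 70.0, 80.0, 90.0, 99.0)


class DegenerateImageError(ValueError):
    """Raised when an image has no usable intensity structure (e.g. constant)."""


def _validate_grid(data: np.ndarray, spacing, affine: np.ndarray) -> None:
    if data.ndim != 3:
        raise ValueError(f"expected a 3-D array, got {data.ndim}-D")
    if any(s < 1 for s in data.shape):
        raise ValueError(f"each dimension must be >= 1, got shape {data.shape}")
    sp = np.asarray(spacing, dtype=float)
    if sp.shape != (3,) or not np.all(np.isfinite(sp)) or np.any(sp <= 0):
        raise ValueError(f"spacing must be 3 finite positive values, got {spacing}")
    aff = np.asarray(affine, dtype=float)
    if aff.shape != (4, 4) or abs(np.linalg.det(aff[:3, :3])) < 1e-12:
        raise ValueError("affine must be an invertible 4x4 matrix")


@dataclass
class Volume:
    """A 3-D scalar image with voxel spacing (mm) and voxel-to-world affine."""

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))
    id: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        self.affine = np.asarray(self.affine, dtype=float)
        self.spacing = tuple(float(s) for s in np.asarray(self.spacing).ravel())
        _validate_grid(self.data, self.spacing, self.affine)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def with_data(self, data: np.ndarray, id: str | None = None) -> "Volume":
        return Volume(data=data, spacing=self.spacing, affine=self.affine.copy(),
                      id=self.id if id is None else id)


@dataclass
class BinaryMask:
    """A boolean brain/non-brain labelling of a volume's grid."""

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))
    id: str = ""

    def __post_init__(self) -> None:
        arr = np.asarray(self.data)
        if arr.dtype != bool:
            uniq = np.unique(arr)
            if not np.all(np.isin(uniq, (0, 1))):
                raise ValueError(f"mask values must be binary, found {uniq[:5]}")
            arr = arr.astype(bool)
        self.data = arr
        self.affine = np.asarray(self.affine, dtype=float)
        self.spacing = tuple(float(s) for s in np.asarray(self.spacing).ravel())
        _validate_grid(self.data, self.spacing, self.affine)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def with_data(self, data: np.ndarray, id: str | None = None) -> "BinaryMask":
        return BinaryMask(data=data, spacing=self.spacing, affine=self.affine.copy(),
                          id=self.id if id is None else id)


# ---------------------------------------------------------------------------
# NIfTI I/O
# ---------------------------------------------------------------------------

def _load_nifti(path: str | os.PathLike):
    if not os.path.exists(path):
        raise FileNotFoundError(f"no such file: {path}")
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    # tolerate a trailing singleton 4th dimension
    while data.ndim > 3 and data.shape[-1] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3-D image, got shape {data.shape}")
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return data, spacing, np.asarray(img.affine, dtype=float)


def read_volume(path: str | os.PathLike) -> Volume:
    """Read a NIfTI-1 scalar image as a :class:`Volume` (float intensities)."""
    data, spacing, affine = _load_nifti(path)
    name = os.path.basename(str(path)).replace(".nii.gz", "").replace(".nii", "")
    return Volume(data=data.astype(np.float64), spacing=spacing, affine=affine, id=name)


def read_mask(path: str | os.PathLike) -> BinaryMask:
    """Read a NIfTI-1 binary mask; any nonzero voxel is treated as foreground."""
    data, spacing, affine = _load_nifti(path)
    name = os.path.basename(str(path)).replace(".nii.gz", "").replace(".nii", "")
    return BinaryMask(data=data > 0.5, spacing=spacing, affine=affine, id=name)


def write_volume(vol: Volume | BinaryMask, path: str | os.PathLike) -> None:
    """Write a volume or mask to NIfTI-1; masks are stored as uint8 {0, 1}."""
    parent = os.path.dirname(os.path.abspath(str(path)))
    os.makedirs(parent, exist_ok=True)
    if isinstance(vol, BinaryMask):
        data = vol.data.astype(np.uint8)
    else:
        data = vol.data.astype(np.float32)
    img = nib.Nifti1Image(data, vol.affine)
    img.header.set_zooms(vol.spacing)
    nib.save(img, str(path))


# ---------------------------------------------------------------------------
# Resampling
# ---------------------------------------------------------------------------

def _affine_to_sitk_geometry(vol: Volume | BinaryMask):
    """Split a voxel-to-world affine into (origin, spacing, direction) for ITK."""
    A = vol.affine[:3, :3]
    spacing = np.asarray(vol.spacing, dtype=float)
    direction = A / spacing[np.newaxis, :]
    origin = vol.affine[:3, 3]
    return tuple(origin), tuple(spacing), tuple(direction.ravel())


def to_sitk(vol: Volume | BinaryMask) -> sitk.Image:
    """Convert to a SimpleITK image (array axes are reversed, geometry kept)."""
    arr = vol.data.astype(np.uint8) if isinstance(vol, BinaryMask) else vol.data
    img = sitk.GetImageFromArray(np.ascontiguousarray(arr.T))
    origin, spacing, direction = _affine_to_sitk_geometry(vol)
    img.SetOrigin(origin)
    img.SetSpacing(spacing)
    img.SetDirection(direction)
    return img


def from_sitk(img: sitk.Image, id: str = "", as_mask: bool = False) -> Volume | BinaryMask:
    arr = sitk.GetArrayFromImage(img).T
    spacing = np.asarray(img.GetSpacing())
    direction = np.asarray(img.GetDirection()).reshape(3, 3)
    affine = np.eye(4)
    affine[:3, :3] = direction * spacing[np.newaxis, :]
    affine[:3, 3] = img.GetOrigin()
    if as_mask:
        return BinaryMask(data=arr > 0.5, spacing=tuple(spacing), affine=affine, id=id)
    return Volume(data=arr.astype(np.float64), spacing=tuple(spacing), affine=affine, id=id)


def resample_isotropic(vol: Volume | BinaryMask, target_spacing_mm: float) -> Volume | BinaryMask:
    """Resample to an isotropic grid of ``target_spacing_mm``.

    Intensities are interpolated with a Lanczos windowed-sinc kernel; masks use
    nearest-neighbour so labels stay strictly two-valued.  The world extent of
    the field of view is preserved to within one output voxel per axis.
    """
    t = float(target_spacing_mm)
    if t <= 0:
        raise ValueError("target_spacing_mm must be > 0")
    img = to_sitk(vol)
    old_size = np.asarray(img.GetSize(), dtype=float)
    old_spacing = np.asarray(img.GetSpacing(), dtype=float)
    new_size = np.maximum(1, np.round(old_size * old_spacing / t)).astype(int)
    is_mask = isinstance(vol, BinaryMask)
    interp = sitk.sitkNearestNeighbor if is_mask else sitk.sitkLanczosWindowedSinc
    fill = 0.0 if is_mask else float(np.min(vol.data))

    def _resample(image, interpolator, default):
        return sitk.Resample(image, [int(n) for n in new_size], sitk.Transform(),
                             interpolator, img.GetOrigin(), (t, t, t),
                             img.GetDirection(), default, sitk.sitkFloat64)

    if is_mask:
        out = _resample(img, interp, fill)
        return from_sitk(out, id=vol.id, as_mask=True)
    # the truncated sinc kernel's weights do not sum exactly to one, which
    # would shift even a constant image; renormalise by a resampled ones-image
    out = _resample(sitk.Cast(img, sitk.sitkFloat64), interp, fill)
    ones = sitk.Image(img.GetSize(), sitk.sitkFloat64)
    ones.CopyInformation(img)
    ones += 1.0
    weight = _resample(ones, interp, 1.0)
    out = out / weight
    return from_sitk(out, id=vol.id, as_mask=False)


# ---------------------------------------------------------------------------
# Histogram-landmark intensity standardization
# ---------------------------------------------------------------------------

def _image_landmarks(vol: Volume,
                     percentiles: Sequence[float] = DEFAULT_LANDMARK_PERCENTILES) -> np.ndarray:
    """Percentile landmarks of the image foreground.

    Foreground is defined as intensities above the image mean, which discards
    the air background that dominates head MR field-of-views.
    """
    data = vol.data
    if np.ptp(data) == 0:
        raise DegenerateImageError(f"image {vol.id!r} is constant")
    fg = data[data > data.mean()]
    if fg.size < 2:
        raise DegenerateImageError(f"image {vol.id!r} has no usable foreground")
    return np.percentile(fg, percentiles)


def train_landmarks(images: Sequence[Volume],
                    percentiles: Sequence[float] = DEFAULT_LANDMARK_PERCENTILES) -> np.ndarray:
    """Average foreground percentile landmarks over a training population."""
    if len(images) == 0:
        raise ValueError("need at least one training image")
    marks = np.stack([_image_landmarks(v, percentiles) for v in images])
    return marks.mean(axis=0)


def normalize_intensities(vol: Volume,
                          reference_landmarks: Sequence[float],
                          percentiles: Sequence[float] = DEFAULT_LANDMARK_PERCENTILES) -> Volume:
    """Map the volume's histogram landmarks piecewise-linearly onto a reference.

    The mapping is monotone non-decreasing and the output is clipped to the
    [first, last] reference landmark.  Raises :class:`DegenerateImageError` for
    a constant image.
    """
    ref = np.asarray(reference_landmarks, dtype=float)
    if ref.ndim != 1 or ref.size < 2 or np.any(np.diff(ref) < 0) or ref[-1] <= ref[0]:
        raise ValueError("reference_landmarks must be non-decreasing with at "
                         "least two distinct values")
    own = _image_landmarks(vol, percentiles)
    if own.size != ref.size:
        raise ValueError("landmark count mismatch between image and reference")
    # np.interp requires strictly increasing abscissae; collapse ties
    keep = np.concatenate(([True], np.diff(own) > 0))
    mapped = np.interp(vol.data, own[keep], ref[keep], left=ref[0], right=ref[-1])
    return vol.with_data(mapped)
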