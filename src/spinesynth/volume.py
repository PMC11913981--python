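"""3D image volumes: NIfTI I/O, orientation, resampling, intensity handling.

The package-wide carrier for MRI data is :class:`ImageVolume`, a dense 3D
scalar grid plus a 4x4 voxel-to-world affine in millimetres.  The working
orientation throughout the pipeline is ``RIP`` (axis 0 increases to the
subject's Right, axis 1 to Inferior, axis 2 to Posterior): axis 0 is the
through-plane direction of a sagittal stack and axis 1 runs down the spine.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy import ndimage


__all__ = [
    "ImageVolume",
    "CropRecord",
    "load_nifti",
    "save_nifti",
    "reorient",
    "resample",
    "rescale_intensity",
    "pad_to_multiple",
    "crop_to_record",
    "color_jitter",
]

#: default working orientation: Right, Inferior, Posterior
DEFAULT_ORIENTATION = "RIP"


@dataclass
class ImageVolume:
    """A 3D scalar image with world geometry.

    Parameters
    ----------
    data
        3D array of intensities (scanner units or normalized).
    affine
        4x4 voxel-index -> world-mm transform.
    """

    data: np.ndarray
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3D volume, got shape {self.data.shape}")
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise ValueError("affine is singular")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("volume contains non-finite intensities")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def spacing(self) -> np.ndarray:
        """Voxel spacing in mm, per axis (column norms of the affine)."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    @property
    def orientation(self) -> str:
        """Three-letter axis code (nibabel convention, e.g. ``RIP``)."""
        labels = (("L", "R"), ("P", "A"), ("I", "S"))
        ornt = nib.orientations.io_orientation(self.affine)
        return "".join(labels[int(ax)][int(flip > 0)] for ax, flip in ornt)

    def voxel_to_world(self, idx) -> np.ndarray:
        idx = np.atleast_2d(np.asarray(idx, dtype=float))
        hom = np.c_[idx, np.ones(len(idx))]
        return np.squeeze((self.affine @ hom.T).T[:, :3])

    def world_to_voxel(self, xyz) -> np.ndarray:
        xyz = np.atleast_2d(np.asarray(xyz, dtype=float))
        hom = np.c_[xyz, np.ones(len(xyz))]
        return np.squeeze((np.linalg.inv(self.affine) @ hom.T).T[:, :3])

    def copy(self) -> "ImageVolume":
        return ImageVolume(self.data.copy(), self.affine.copy())


@dataclass
class CropRecord:
    """Bookkeeping to undo :func:`pad_to_multiple` exactly."""

    pad_before: np.ndarray
    pad_after: np.ndarray
    original_shape: np.ndarray

    def __post_init__(self) -> None:
        self.pad_before = np.asarray(self.pad_before, dtype=int)
        self.pad_after = np.asarray(self.pad_after, dtype=int)
        self.original_shape = np.asarray(self.original_shape, dtype=int)


def load_nifti(path: str | Path) -> ImageVolume:
    img = nib.load(str(path))
    return ImageVolume(np.asarray(img.dataobj, dtype=np.float32), img.affine)


def save_nifti(vol: ImageVolume, path: str | Path) -> None:
    nib.save(nib.Nifti1Image(np.asarray(vol.data, dtype=np.float32), vol.affine), str(path))


_VALID_LETTERS = set("LRAPIS")


def _validate_code(code: str) -> tuple[str, ...]:
    code = code.upper()
    if len(code) != 3 or any(c not in _VALID_LETTERS for c in code):
        raise ValueError(f"invalid orientation code {code!r}: use 3 letters from LRAPIS")
    axes = {"L": 0, "R": 0, "A": 1, "P": 1, "I": 2, "S": 2}
    if sorted(axes[c] for c in code) != [0, 1, 2]:
        raise ValueError(f"orientation code {code!r} does not name three distinct axes")
    return tuple(code)


def reorient(vol: ImageVolume, target_code: str = DEFAULT_ORIENTATION) -> ImageVolume:
    """Permute/flip voxel axes so the volume's axis code equals ``target_code``.

    World-space content is unchanged: data and affine are transformed
    consistently via nibabel's orientation machinery.
    """
    code = _validate_code(target_code)
    src = nib.orientations.io_orientation(vol.affine)
    dst = nib.orientations.axcodes2ornt(code, (("L", "R"), ("P", "A"), ("I", "S")))
    xform = nib.orientations.ornt_transform(src, dst)
    data = nib.orientations.apply_orientation(vol.data, xform)
    affine = vol.affine @ nib.orientations.inv_ornt_aff(xform, vol.shape)
    return ImageVolume(data, affine)


def resample(
    vol: ImageVolume,
    target_spacing,
    order: int = 1,
) -> ImageVolume:
    """Resample onto a grid with the requested spacing (mm), preserving world extent.

    ``order`` is the spline interpolation order: 0 nearest, 1 linear, 3 cubic.
    A degenerate axis of length 1 forces nearest-neighbour interpolation.
    """
    if order not in (0, 1, 3):
        raise ValueError("order must be one of 0 (nearest), 1 (linear), 3 (cubic)")
    target_spacing = np.asarray(target_spacing, dtype=float)
    if np.any(target_spacing <= 0):
        raise ValueError("target spacing must be positive")
    spacing = vol.spacing
    scale = target_spacing / spacing
    if np.allclose(scale, 1.0, atol=1e-9):
        return vol.copy()
    new_shape = np.maximum(1, np.round(np.asarray(vol.shape) / scale)).astype(int)
    if order > 0 and any(s == 1 for s in vol.shape):
        order = 0
    # map output voxel index -> input voxel index: i_in = scale * i_out
    matrix = np.diag(scale)
    out = ndimage.affine_transform(
        np.asarray(vol.data, dtype=float),
        matrix,
        output_shape=tuple(new_shape),
        order=order,
        mode="nearest",
    )
    new_affine = vol.affine.copy()
    new_affine[:3, :3] = vol.affine[:3, :3] @ np.diag(scale)
    return ImageVolume(out, new_affine)


def rescale_intensity(vol: ImageVolume) -> ImageVolume:
    """Map intensities from ``[0, max]`` onto ``[-1, 1]``.

    Negative values (rare interpolation undershoot) are clipped to 0 with a
    warning; an all-zero volume maps to the background value -1.
    """
    data = np.asarray(vol.data, dtype=float)
    if data.min() < 0:
        warnings.warn("negative intensities clipped to 0 before rescaling", stacklevel=2)
        data = np.clip(data, 0, None)
    vmax = data.max()
    if vmax == 0:
        warnings.warn("all-zero volume: rescaled output set to -1 everywhere", stacklevel=2)
        return ImageVolume(np.full_like(data, -1.0), vol.affine.copy())
    return ImageVolume(2.0 * data / vmax - 1.0, vol.affine.copy())


def pad_to_multiple(vol: ImageVolume, multiple: int = 8, fill: float = -1.0):
    """Pad each axis up to the next multiple of ``multiple`` with ``fill``.

    The fill default -1 is the background (air) level after
    :func:`rescale_intensity`.  Returns the padded volume and a
    :class:`CropRecord` that inverts the padding bit-exactly.
    """
    if multiple < 1:
        raise ValueError("multiple must be >= 1")
    shape = np.asarray(vol.shape)
    target = -(-shape // multiple) * multiple
    total = target - shape
    before = total // 2
    after = total - before
    data = np.pad(
        vol.data,
        list(zip(before.tolist(), after.tolist())),
        mode="constant",
        constant_values=fill,
    )
    affine = vol.affine.copy()
    affine[:3, 3] = (vol.affine @ np.r_[-before.astype(float), 1.0])[:3]
    rec = CropRecord(before, after, shape)
    return ImageVolume(data, affine), rec


def crop_to_record(vol: ImageVolume, rec: CropRecord) -> ImageVolume:
    """Undo :func:`pad_to_multiple` using its :class:`CropRecord`."""
    b = rec.pad_before
    s = rec.original_shape
    data = vol.data[b[0] : b[0] + s[0], b[1] : b[1] + s[1], b[2] : b[2] + s[2]]
    affine = vol.affine.copy()
    affine[:3, 3] = (vol.affine @ np.r_[b.astype(float), 1.0])[:3]
    return ImageVolume(data.copy(), affine)


def color_jitter(vol: ImageVolume, brightness: float = 1.0, contrast: float = 1.0) -> ImageVolume:
    """Photometric augmentation on ``[-1, 1]``-scaled data.

    Internally maps to a [0, 1] working scale and applies contrast about the
    volume mean followed by a brightness factor, clamped to [0, 1]:
    ``v' = clamp(brightness * (mean + contrast * (v - mean)), 0, 1)``.
    Training draws both factors uniformly from [0.8, 1.2].
    """
    if brightness == 1.0 and contrast == 1.0:
        return vol.copy()
    v01 = (np.asarray(vol.data, dtype=float) + 1.0) / 2.0
    mean = v01.mean()
    out = np.clip(brightness * (mean + contrast * (v01 - mean)), 0.0, 1.0)
    return ImageVolume(out * 2.0 - 1.0, vol.affine.copy())
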