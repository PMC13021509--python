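"""Volume data model, NIfTI I/O, resampling and the analysis-crop convention.

A :class:`Volume` is a 3D scalar grid with a 4x4 voxel-to-world affine.  Voxel
indexing is 0-based; normalized coordinates used by the registration machinery
span [-1, 1] with the extremes at the centers of the first and last voxels.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy import ndimage

from .config import GRID_PRESETS, GridSpec


class VolumeFormatError(ValueError):
    """Raised for inputs that are not plain 3D scalar volumes."""


@dataclass
class Volume:
    data: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))
    space_tag: str = "native"

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float32)
        self.affine = np.asarray(self.affine, dtype=np.float64)
        if self.data.ndim != 3:
            raise VolumeFormatError(
                f"expected a 3D volume, got {self.data.ndim} dimensions")
        if self.affine.shape != (4, 4):
            raise VolumeFormatError("affine must be 4x4")
        if abs(np.linalg.det(self.affine[:3, :3])) <= 0:
            raise VolumeFormatError("affine is singular")

    @property
    def shape(self) -> tuple:
        return self.data.shape

    @property
    def spacing(self) -> np.ndarray:
        """mm per voxel along each axis, derived from the affine."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    def copy(self, data=None) -> "Volume":
        return Volume(self.data.copy() if data is None else data,
                      self.affine.copy(), self.space_tag)


def read_nifti(path) -> Volume:
    """Load a NIfTI-1/2 file as a float32 :class:`Volume`."""
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise VolumeFormatError(
            f"{path}: expected 3D data, found {data.ndim} dimensions "
            f"(shape {data.shape})")
    return Volume(data.astype(np.float32), img.affine)


def write_nifti(v: Volume, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    nib.save(nib.Nifti1Image(v.data.astype(np.float32), v.affine), str(path))
    return path


def normalized_grid(shape) -> np.ndarray:
    """Identity sampling grid (3, D, H, W) in normalized [-1, 1] coordinates."""
    axes = [np.linspace(-1.0, 1.0, n, dtype=np.float32) if n > 1
            else np.zeros(1, dtype=np.float32) for n in shape]
    return np.stack(np.meshgrid(*axes, indexing="ij"), axis=0)


_ORDER = {"bspline": 3, "trilinear": 1, "nearest": 0}


def resample_to_grid(v: Volume, target: GridSpec, transform=None,
                     interpolation: str = "trilinear") -> Volume:
    """Resample ``v`` onto ``target``'s canonical grid.

    ``transform`` is a 4x4 world-to-world matrix mapping coordinates of ``v``
    into the target space (identity by default).  Out-of-field voxels are 0.
    """
    if interpolation not in _ORDER:
        raise ValueError(f"unknown interpolation {interpolation!r}")
    transform = np.eye(4) if transform is None else np.asarray(transform, float)
    if abs(np.linalg.det(transform)) < 1e-12:
        raise ValueError("singular transform")
    # output index -> target world -> source world -> source index
    m = np.linalg.inv(v.affine) @ np.linalg.inv(transform) @ target.affine
    out = ndimage.affine_transform(
        v.data.astype(np.float64), m[:3, :3], offset=m[:3, 3],
        output_shape=tuple(target.shape), order=_ORDER[interpolation],
        mode="constant", cval=0.0,
        prefilter=_ORDER[interpolation] > 1)
    return Volume(out.astype(np.float32), target.affine, space_tag="template")


def _matching_preset(shape) -> GridSpec:
    for spec in GRID_PRESETS.values():
        if tuple(spec.shape) == tuple(shape):
            return spec
    raise ValueError(f"volume shape {tuple(shape)} matches no grid preset")


def crop_to_analysis_grid(v: Volume, spec: GridSpec | None = None) -> Volume:
    """Extract the analysis crop of a high-resolution volume.

    Warns if nonzero voxels fall outside the crop (tissue touching the crop
    boundary would be lost).
    """
    spec = _matching_preset(v.shape) if spec is None else spec
    if tuple(v.shape) != tuple(spec.shape):
        raise ValueError(f"volume shape {v.shape} does not match grid {spec.shape}")
    o, c = spec.crop_origin, spec.crop_shape
    sl = tuple(slice(o[i], o[i] + c[i]) for i in range(3))
    outside = v.data.copy()
    outside[sl] = 0.0
    if np.any(outside != 0):
        warnings.warn("nonzero voxels outside the analysis crop are discarded",
                      stacklevel=2)
    cropped = v.data[sl].copy()
    aff = v.affine.copy()
    aff[:3, 3] += aff[:3, :3] @ np.asarray(o, float)
    return Volume(cropped, aff, v.space_tag)


def uncrop_from_analysis_grid(v: Volume, spec: GridSpec) -> Volume:
    """Inverse of :func:`crop_to_analysis_grid`; pads back with zeros."""
    o, c = spec.crop_origin, spec.crop_shape
    if tuple(v.shape) != tuple(c):
        raise ValueError(f"volume shape {v.shape} does not match crop {c}")
    full = np.zeros(tuple(spec.shape), dtype=np.float32)
    sl = tuple(slice(o[i], o[i] + c[i]) for i in range(3))
    full[sl] = v.data
    aff = v.affine.copy()
    aff[:3, 3] -= aff[:3, :3] @ np.asarray(o, float)
    return Volume(full, aff, v.space_tag)
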