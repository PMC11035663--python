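"""Core domain types, NIfTI I/O and intensity normalization.

Coordinate convention used throughout the package: arrays are indexed
``(depth, width, height)`` with 0-based voxel indices.  Voxels outside the
image bounds are treated as background for every neighbourhood operation
(surface extraction, dilation, thinning), so masks behave as if embedded in
an infinite background.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

__all__ = [
    "VolumeImage",
    "LabelMap",
    "ProbabilityMap",
    "DistanceMap",
    "DomainRecord",
    "load_volume",
    "load_label",
    "save_volume",
    "save_label",
    "normalize_intensity",
]


class DegenerateInputError(ValueError):
    """Raised when an input is valid in shape but degenerate in content."""


@dataclass
class VolumeImage:
    """A 3D scalar image with voxel spacing (mm) and orientation metadata.

    Parameters
    ----------
    data : ndarray of shape (D, W, H)
        Finite real-valued voxel grid.
    spacing : tuple of 3 floats
        Strictly positive voxel dimensions in mm per axis.
    affine : ndarray (4, 4), optional
        Orientation matrix, passed through I/O unchanged.
    """

    data: np.ndarray
    spacing: tuple = (1.0, 1.0, 1.0)
    affine: np.ndarray = field(default=None, repr=False)

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3D volume, got shape {self.data.shape}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("volume contains non-finite values")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be 3 positive values, got {self.spacing}")
        if self.affine is None:
            self.affine = np.diag(list(self.spacing) + [1.0])

    @property
    def shape(self):
        return self.data.shape


@dataclass
class LabelMap:
    """A binary mask on the same lattice as its paired volume (vessel = 1)."""

    data: np.ndarray
    spacing: tuple = (1.0, 1.0, 1.0)
    affine: np.ndarray = field(default=None, repr=False)

    def __post_init__(self):
        arr = np.asarray(self.data)
        if arr.ndim != 3:
            raise ValueError(f"expected a 3D mask, got shape {arr.shape}")
        vals = np.unique(arr)
        if not np.isin(vals, (0, 1)).all():
            raise ValueError("label map values must be exactly 0 or 1")
        self.data = arr.astype(np.uint8)
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be 3 positive values, got {self.spacing}")
        if self.affine is None:
            self.affine = np.diag(list(self.spacing) + [1.0])

    @property
    def shape(self):
        return self.data.shape

    def count(self) -> int:
        return int(self.data.sum())


@dataclass
class ProbabilityMap:
    """A 3D grid of probabilities in [0, 1] on the input lattice."""

    data: np.ndarray
    spacing: tuple = (1.0, 1.0, 1.0)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3D map, got shape {self.data.shape}")
        if self.data.min() < -1e-9 or self.data.max() > 1 + 1e-9:
            raise ValueError("probabilities must lie in [0, 1]")
        np.clip(self.data, 0.0, 1.0, out=self.data)

    @property
    def shape(self):
        return self.data.shape

    def threshold(self, t: float = 0.5) -> LabelMap:
        return LabelMap((self.data >= t).astype(np.uint8), spacing=self.spacing)


@dataclass
class DistanceMap:
    """Per-voxel distance values; zero on background voxels by construction."""

    data: np.ndarray
    spacing: tuple = (1.0, 1.0, 1.0)
    units: str = "voxel"

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3D map, got shape {self.data.shape}")
        if self.data.min() < 0:
            raise ValueError("distance map must be non-negative")

    @property
    def shape(self):
        return self.data.shape


@dataclass
class DomainRecord:
    """One-hot true domain label and a predicted domain probability vector."""

    true_label: np.ndarray
    prediction: np.ndarray = None

    def __post_init__(self):
        t = np.asarray(self.true_label, dtype=np.float64)
        if t.ndim != 1:
            raise ValueError("true_label must be a vector")
        if not (np.isin(t, (0, 1)).all() and t.sum() == 1):
            raise ValueError("true_label must be one-hot")
        self.true_label = t
        if self.prediction is not None:
            p = np.asarray(self.prediction, dtype=np.float64)
            if p.shape != t.shape:
                raise ValueError("prediction length must match true_label")
            if p.min() < 0 or p.max() > 1 or abs(p.sum() - 1.0) > 1e-6:
                raise ValueError("prediction must be a probability vector")
            self.prediction = p

    @property
    def n_domains(self) -> int:
        return self.true_label.size

    @property
    def domain_index(self) -> int:
        return int(np.argmax(self.true_label))


def _check_3d(img_data: np.ndarray, path) -> np.ndarray:
    data = np.squeeze(img_data)
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3D image, got shape {img_data.shape}")
    return data


def load_volume(path) -> VolumeImage:
    """Load a NIfTI file as a :class:`VolumeImage` (no resampling)."""
    img = nib.load(str(path))
    data = _check_3d(np.asanyarray(img.dataobj), path)
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return VolumeImage(np.asarray(data, dtype=np.float64), spacing=spacing, affine=np.asarray(img.affine))


def load_label(path) -> LabelMap:
    """Load a NIfTI file as a binary :class:`LabelMap` (values must be 0/1)."""
    img = nib.load(str(path))
    data = _check_3d(np.asanyarray(img.dataobj), path)
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return LabelMap(np.rint(data).astype(np.uint8), spacing=spacing, affine=np.asarray(img.affine))


def _affine_for(obj):
    aff = getattr(obj, "affine", None)
    if aff is None:
        aff = np.diag(list(obj.spacing) + [1.0])
    return np.asarray(aff, dtype=np.float64)


def save_volume(v: VolumeImage, path) -> None:
    img = nib.Nifti1Image(np.asarray(v.data, dtype=np.float32), _affine_for(v))
    img.header.set_zooms(v.spacing)
    nib.save(img, str(path))


def save_label(m, path) -> None:
    """Write a LabelMap (or ProbabilityMap thresholded upstream) as uint8 NIfTI."""
    img = nib.Nifti1Image(np.asarray(m.data, dtype=np.uint8), _affine_for(m))
    img.header.set_zooms(m.spacing)
    nib.save(img, str(path))


def save_probability(p: ProbabilityMap, path, spacing=None) -> None:
    sp = spacing if spacing is not None else p.spacing
    img = nib.Nifti1Image(np.asarray(p.data, dtype=np.float32), np.diag(list(sp) + [1.0]))
    img.header.set_zooms(sp)
    nib.save(img, str(path))


def normalize_intensity(v: VolumeImage) -> VolumeImage:
    """Per-volume z-score: output has mean 0 and standard deviation 1.

    Raises
    ------
    DegenerateInputError
        If the volume has (near-)zero intensity variance.
    """
    mu = float(v.data.mean())
    sd = float(v.data.std())
    if sd < 1e-12:
        raise DegenerateInputError("cannot normalize a constant volume (zero variance)")
    return VolumeImage((v.data - mu) / sd, spacing=v.spacing, affine=v.affine)
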