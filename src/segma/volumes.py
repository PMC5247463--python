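"""Volume containers and NIfTI-1 I/O.

All computation in this package happens on a shared voxel grid: images are
assumed to have been brain-extracted, bias-corrected and linearly registered
to a common space before they reach us.  Voxel indices are 0-based and the
axis order (x, y, z) is the stored array order; world coordinates (the
affine) are carried for round-tripping but never used in computation.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence, Union

import nibabel as nib
import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "ScalarVolume",
    "LabelVolume",
    "BinaryMask",
    "AtlasSet",
    "ValidationError",
    "read_volume",
    "read_labels",
    "write_volume",
    "write_labels",
    "check_grid_compatible",
]


class ValidationError(ValueError):
    """Raised when an input violates a container or grid contract."""


def _default_affine(spacing: Sequence[float]) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = spacing
    return aff


@dataclass
class ScalarVolume:
    """A 3D scalar intensity image on a regular grid.

    Parameters
    ----------
    data : ndarray, shape (nx, ny, nz)
        Real-valued intensities; must be finite everywhere.
    spacing : tuple of float
        Voxel edge lengths in mm, strictly positive.
    affine : ndarray, shape (4, 4), optional
        Grid-to-world map; defaults to a diagonal scaling by ``spacing``.
    """

    data: np.ndarray
    spacing: tuple = (1.0, 1.0, 1.0)
    affine: np.ndarray = None

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValidationError(
                f"expected 3D volume, got {self.data.ndim}D with shape {self.data.shape}"
            )
        if not np.all(np.isfinite(self.data)):
            raise ValidationError("volume contains NaN/Inf voxels")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValidationError(f"spacing must be three positive values, got {self.spacing}")
        if self.affine is None:
            self.affine = _default_affine(self.spacing)
        self.affine = np.asarray(self.affine, dtype=np.float64)

    @property
    def shape(self) -> tuple:
        return self.data.shape


@dataclass
class LabelVolume:
    """A 3D integer label map; 0 is reserved for background."""

    data: np.ndarray
    spacing: tuple = (1.0, 1.0, 1.0)
    affine: np.ndarray = None

    def __post_init__(self):
        arr = np.asarray(self.data)
        if arr.ndim != 3:
            raise ValidationError(
                f"expected 3D label map, got {arr.ndim}D with shape {arr.shape}"
            )
        if not np.issubdtype(arr.dtype, np.integer):
            rounded = np.rint(arr)
            if not np.all(np.isfinite(arr)) or np.any(np.abs(arr - rounded) > 1e-6):
                raise ValidationError("label map contains non-integer voxel values")
            arr = rounded
        arr = arr.astype(np.int32)
        if arr.min() < 0:
            raise ValidationError("label values must be non-negative")
        self.data = arr
        self.spacing = tuple(float(s) for s in self.spacing)
        if self.affine is None:
            self.affine = _default_affine(self.spacing)
        self.affine = np.asarray(self.affine, dtype=np.float64)

    @property
    def shape(self) -> tuple:
        return self.data.shape

    @property
    def vocabulary(self) -> tuple:
        """Sorted non-background labels present in the map."""
        labs = np.unique(self.data)
        return tuple(int(v) for v in labs if v != 0)


@dataclass
class BinaryMask:
    """A 3D {0,1} mask on the companion grid."""

    data: np.ndarray

    def __post_init__(self):
        arr = np.asarray(self.data)
        if arr.ndim != 3:
            raise ValidationError(f"expected 3D mask, got shape {arr.shape}")
        self.data = arr.astype(bool)

    @property
    def shape(self) -> tuple:
        return self.data.shape

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())


@dataclass
class AtlasSet:
    """Ordered collection of (image, label) atlas pairs on one grid."""

    images: list
    labels: list
    masks: list = field(default=None)

    def __post_init__(self):
        if len(self.images) != len(self.labels):
            raise ValidationError("images and labels must pair up one-to-one")
        if self.masks is None:
            self.masks = [BinaryMask(lab.data > 0) for lab in self.labels]
        if len(self.masks) != len(self.images):
            raise ValidationError("one mask per atlas required")
        check_grid_compatible(self.images + self.labels)

    def __len__(self) -> int:
        return len(self.images)

    def __iter__(self) -> Iterator[tuple]:
        return iter(zip(self.images, self.labels, self.masks))

    def subset(self, indices: Sequence[int]) -> "AtlasSet":
        return AtlasSet(
            images=[self.images[i] for i in indices],
            labels=[self.labels[i] for i in indices],
            masks=[self.masks[i] for i in indices],
        )

    @property
    def vocabulary(self) -> tuple:
        vocab = set()
        for lab in self.labels:
            vocab.update(lab.vocabulary)
        return tuple(sorted(vocab))


def read_volume(path: Union[str, Path]) -> ScalarVolume:
    """Read a 3D scalar NIfTI-1 image.

    Rejects 4D inputs and non-finite voxels rather than coercing them.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValidationError(f"expected 3D volume, got {data.ndim}D in {path.name}")
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return ScalarVolume(data=np.asarray(data, np.float64), spacing=spacing, affine=img.affine)


def read_labels(path: Union[str, Path]) -> LabelVolume:
    """Read a 3D integer label map; fractional voxel values are rejected."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValidationError(f"expected 3D label map, got {data.ndim}D in {path.name}")
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    lab = LabelVolume(data=data, spacing=spacing, affine=img.affine)
    if not lab.vocabulary:
        logger.warning("label map %s contains only background", path.name)
    return lab


def write_volume(volume: ScalarVolume, path: Union[str, Path]) -> None:
    img = nib.Nifti1Image(volume.data.astype(np.float64), volume.affine)
    img.header.set_zooms(volume.spacing)
    nib.save(img, str(path))


def write_labels(labels: LabelVolume, path: Union[str, Path],
                 names: dict = None) -> None:
    """Write a label map; optionally a sidecar JSON mapping label -> name."""
    img = nib.Nifti1Image(labels.data.astype(np.int16), labels.affine)
    img.header.set_zooms(labels.spacing)
    nib.save(img, str(path))
    if names is not None:
        side = Path(str(path)).with_suffix("").with_suffix("")
        side = side.parent / (side.name + "_labels.json")
        side.write_text(json.dumps({str(k): v for k, v in names.items()}, indent=2))


def check_grid_compatible(volumes: Sequence, spacing_tol: float = 1e-4) -> None:
    """Verify all volumes share one grid (shape equal, spacing within tolerance).

    Raises :class:`ValidationError` naming the first offending volume.
    """
    if len(volumes) < 2:
        return
    ref = volumes[0]
    for i, vol in enumerate(volumes[1:], start=1):
        if tuple(vol.shape) != tuple(ref.shape):
            raise ValidationError(
                f"volume {i} has shape {tuple(vol.shape)}, expected {tuple(ref.shape)}"
            )
        sp_ref = getattr(ref, "spacing", None)
        sp = getattr(vol, "spacing", None)
        if sp_ref is not None and sp is not None:
            if any(abs(a - b) > spacing_tol for a, b in zip(sp_ref, sp)):
                raise ValidationError(
                    f"volume {i} has spacing {sp}, expected {sp_ref} (tol {spacing_tol} mm)"
                )
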