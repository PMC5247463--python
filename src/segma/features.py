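"""Per-voxel appearance features: intensity, derivatives, gradient orientation.

Each voxel is described by a ten-dimensional vector

    f_v = [ I, |Ix|, |Iy|, |Iz|, r, theta, phi, |Ixx|, |Iyy|, |Izz| ]

where I is the (standardized) intensity, Ix/Iy/Iz are first-order central
differences computed with the kernel (-1, 0, 1), Ixx/Iyy/Izz second-order
differences with the kernel (-1, 2, -1), r is the gradient magnitude
sqrt(Ix^2 + Iy^2 + Iz^2), theta the azimuth angle of the gradient in
[0, 2*pi) and phi its zenith angle in [0, pi].  Signed derivatives are kept
internally (the angles need them); the feature vector stores their norms.

Derivatives are taken in voxel units by default (no division by spacing);
set ``spacing_scaled=True`` to divide by 2*spacing / spacing^2 for strongly
anisotropic grids.  Boundaries use replicate padding.  A zero gradient gets
theta = phi = 0 by convention so features stay deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.ndimage import correlate1d

from .volumes import BinaryMask, ScalarVolume, ValidationError

__all__ = [
    "FEATURE_NAMES",
    "FEATURE_GROUPS",
    "FeatureField",
    "first_derivatives",
    "second_derivatives",
    "gradient_orientation",
    "compute_features",
    "export_feature_field",
]

FEATURE_NAMES = (
    "intensity",
    "abs_dx", "abs_dy", "abs_dz",
    "grad_magnitude", "azimuth", "zenith",
    "abs_dxx", "abs_dyy", "abs_dzz",
)

#: The four feature groups used by the drop-one-group ablation; they
#: partition the ten features.
FEATURE_GROUPS = {
    "intensity": (0,),
    "first_derivatives": (1, 2, 3),
    "orientation": (4, 5, 6),
    "second_derivatives": (7, 8, 9),
}

_FIRST_KERNEL = np.array([-1.0, 0.0, 1.0])
_SECOND_KERNEL = np.array([-1.0, 2.0, -1.0])


@dataclass
class FeatureField:
    """Per-voxel feature vectors over a grid, shape (nx, ny, nz, 10)."""

    data: np.ndarray
    spacing: tuple = (1.0, 1.0, 1.0)

    def __post_init__(self):
        self.data = np.asarray(self.data, np.float64)
        if self.data.ndim != 4 or self.data.shape[-1] != len(FEATURE_NAMES):
            raise ValidationError(
                f"feature field must have shape (nx, ny, nz, {len(FEATURE_NAMES)})"
            )

    @property
    def grid_shape(self) -> tuple:
        return self.data.shape[:3]

    def matrix(self) -> np.ndarray:
        """All voxels as an (n_voxels, 10) design matrix (C order)."""
        return self.data.reshape(-1, self.data.shape[-1])


def _check_extent(data: np.ndarray) -> None:
    if any(s < 3 for s in data.shape):
        raise ValidationError(
            f"derivative kernels need >= 3 voxels per axis, got shape {data.shape}"
        )


def first_derivatives(volume: ScalarVolume, spacing_scaled: bool = False):
    """Signed central differences Ix, Iy, Iz with replicate padding.

    Ix(v) = I(v + x̂) − I(v − x̂) in voxel units (divided by 2·spacing when
    ``spacing_scaled``).
    """
    _check_extent(volume.data)
    out = []
    for axis in range(3):
        d = correlate1d(volume.data, _FIRST_KERNEL, axis=axis, mode="nearest")
        if spacing_scaled:
            d = d / (2.0 * volume.spacing[axis])
        out.append(d)
    return tuple(out)


def second_derivatives(volume: ScalarVolume, spacing_scaled: bool = False):
    """Signed second differences Ixx, Iyy, Izz with kernel (−1, 2, −1).

    Note the sign convention: for I = x² the interior value is −2.
    """
    _check_extent(volume.data)
    out = []
    for axis in range(3):
        d = correlate1d(volume.data, _SECOND_KERNEL, axis=axis, mode="nearest")
        if spacing_scaled:
            d = d / (volume.spacing[axis] ** 2)
        out.append(d)
    return tuple(out)


def gradient_orientation(Ix: np.ndarray, Iy: np.ndarray, Iz: np.ndarray):
    """Gradient magnitude r, azimuth theta in [0, 2π), zenith phi in [0, π].

    At voxels with r = 0 both angles are set to 0.
    """
    if not (Ix.shape == Iy.shape == Iz.shape):
        raise ValidationError("derivative fields must share one grid")
    r = np.sqrt(Ix ** 2 + Iy ** 2 + Iz ** 2)
    theta = np.mod(np.arctan2(Iy, Ix), 2.0 * np.pi)
    with np.errstate(invalid="ignore", divide="ignore"):
        phi = np.arccos(np.clip(np.divide(Iz, r, out=np.zeros_like(r), where=r > 0),
                                -1.0, 1.0))
    zero = r == 0
    theta[zero] = 0.0
    phi[zero] = 0.0
    return r, theta, phi


def compute_features(volume: ScalarVolume, mask: Optional[BinaryMask] = None,
                     spacing_scaled: bool = False) -> FeatureField:
    """Assemble the ten-dimensional feature vector at every voxel.

    Out-of-mask voxels carry zero vectors; they are never used for training
    or prediction but keep the field grid-shaped.
    """
    Ix, Iy, Iz = first_derivatives(volume, spacing_scaled)
    Ixx, Iyy, Izz = second_derivatives(volume, spacing_scaled)
    r, theta, phi = gradient_orientation(Ix, Iy, Iz)
    data = np.stack(
        [
            volume.data,
            np.abs(Ix), np.abs(Iy), np.abs(Iz),
            r, theta, phi,
            np.abs(Ixx), np.abs(Iyy), np.abs(Izz),
        ],
        axis=-1,
    )
    if mask is not None:
        if tuple(mask.shape) != tuple(volume.shape):
            raise ValidationError("mask grid does not match volume grid")
        data[~mask.data] = 0.0
    return FeatureField(data=data, spacing=volume.spacing)


def export_feature_field(field: FeatureField, path) -> None:
    """Write the feature field as a 4D NIfTI (one volume per feature).

    Debugging aid: the 4th dimension follows :data:`FEATURE_NAMES` order.
    """
    import nibabel as nib

    affine = np.eye(4)
    affine[0, 0], affine[1, 1], affine[2, 2] = field.spacing
    nib.save(nib.Nifti1Image(field.data, affine), str(path))
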