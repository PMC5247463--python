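"""Synthetic brain-like phantom populations.

Real neonatal/adult cohorts cannot ship with the package, so every stage of
the pipeline is exercised on 3D phantoms that keep the properties the method
actually depends on: nested smooth tissue regions (CSF / GM / WM / deep-GM
style topology), class-specific intensity means with a controllable
contrast-to-noise ratio, a smooth multiplicative bias field, and
inter-subject anatomical variability realized as smooth random warps of one
base anatomy.

Geometry is concentric perturbed ellipsoids: a normalized radial field is
modulated by a smooth random bump field and thresholded at radii chosen so
each class occupies an equal share of the head volume.  Classes are numbered
outward-in (1 = outermost shell, n_classes = innermost core); 0 is
background.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy.ndimage import gaussian_filter, map_coordinates

from .volumes import AtlasSet, BinaryMask, LabelVolume, ScalarVolume, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "PhantomParams",
    "generate_phantom",
    "generate_population",
    "generate_second_modality",
    "smooth_displacement",
    "apply_warp",
]

# sub-stream tags so geometry, per-subject draws and the second modality
# never share a random stream
_GEOMETRY_TAG = 0
_PHANTOM_TAG = 1
_SUBJECT_TAG = 100
_MODALITY2_TAG = 999


@dataclass
class PhantomParams:
    """Generation parameters for one phantom population.

    Defaults emulate a 4-class anatomy at a contrast-to-noise ratio of 3
    (smallest pairwise class-mean gap 30 over noise SD 10).  The class-mean
    ordering follows adult T1-weighted contrast: CSF darkest (10), cortical
    GM intermediate (40), WM brightest (100), deep GM between GM and WM
    (70) — tissue intensity is deliberately *not* monotone with depth, as
    in real anatomy.  ``shell_radii`` are the nested-boundary radii as
    fractions of the head radius; the default 4-class profile
    (1.0, 0.88, 0.62, 0.40) gives a thin outer CSF shell, a cortical-GM
    ribbon, a thick WM compartment and a compact deep-GM core.
    """

    shape: Tuple[int, int, int] = (48, 48, 48)
    n_classes: int = 4
    class_means: Tuple[float, ...] = (10.0, 40.0, 100.0, 70.0)
    noise_sd: float = 10.0
    bias_amplitude: float = 0.2
    warp_sd: float = 0.5
    warp_smoothing: float = 4.0
    shell_radii: Optional[Tuple[float, ...]] = None
    seed: int = 0

    def __post_init__(self):
        self.shape = tuple(int(s) for s in self.shape)
        if len(self.shape) != 3 or any(s < 8 for s in self.shape):
            raise ValidationError(f"shape must be a triple of sizes >= 8, got {self.shape}")
        if self.n_classes < 2:
            raise ValidationError("need at least 2 classes")
        self.class_means = tuple(float(m) for m in self.class_means)
        if len(self.class_means) != self.n_classes:
            raise ValidationError(
                f"{self.n_classes} classes require {self.n_classes} class means, "
                f"got {len(self.class_means)}"
            )
        if len(set(self.class_means)) != self.n_classes:
            raise ValidationError("class means must be pairwise distinct")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")
        if not (0 <= self.bias_amplitude < 0.5):
            raise ValidationError("bias_amplitude must lie in [0, 0.5)")
        if self.warp_sd < 0:
            raise ValidationError("warp_sd must be >= 0")
        if self.shell_radii is None:
            if self.n_classes == 4:
                self.shell_radii = (1.0, 0.88, 0.62, 0.40)
            else:
                self.shell_radii = tuple(np.linspace(1.0, 0.35, self.n_classes))
        self.shell_radii = tuple(float(r) for r in self.shell_radii)
        if len(self.shell_radii) != self.n_classes:
            raise ValidationError("one shell radius per class required")
        if list(self.shell_radii) != sorted(self.shell_radii, reverse=True) \
                or self.shell_radii[0] > 1.0 or self.shell_radii[-1] <= 0:
            raise ValidationError("shell_radii must decrease from <=1.0 and stay positive")

    @property
    def cnr(self) -> float:
        """Contrast-to-noise ratio: min pairwise class-mean gap / noise_sd."""
        means = np.sort(np.asarray(self.class_means))
        gap = float(np.min(np.diff(means)))
        return float("inf") if self.noise_sd == 0 else gap / self.noise_sd

    def metadata(self) -> dict:
        return {
            "shape": list(self.shape),
            "n_classes": self.n_classes,
            "class_means": list(self.class_means),
            "noise_sd": self.noise_sd,
            "bias_amplitude": self.bias_amplitude,
            "warp_sd": self.warp_sd,
            "warp_smoothing": self.warp_smoothing,
            "shell_radii": list(self.shell_radii),
            "seed": self.seed,
            "cnr": self.cnr if np.isfinite(self.cnr) else None,
        }


def _radial_field(params: PhantomParams) -> np.ndarray:
    """Normalized perturbed-ellipsoid radius: <1 inside the head, 1 at its edge."""
    shape = np.asarray(params.shape, float)
    center = (shape - 1) / 2.0
    # slightly anisotropic semi-axes so no axis is privileged
    semi = shape * np.array([0.42, 0.45, 0.40])
    ix, iy, iz = np.indices(params.shape)
    rho = np.sqrt(
        ((ix - center[0]) / semi[0]) ** 2
        + ((iy - center[1]) / semi[1]) ** 2
        + ((iz - center[2]) / semi[2]) ** 2
    )
    rng = np.random.default_rng([params.seed, _GEOMETRY_TAG])
    bump = gaussian_filter(rng.standard_normal(params.shape), sigma=min(params.shape) / 6.0)
    peak = np.max(np.abs(bump))
    if peak > 0:
        bump *= 0.08 / peak
    return rho * (1.0 + bump)


def _base_labels(params: PhantomParams) -> np.ndarray:
    rho = _radial_field(params)
    lab = np.zeros(params.shape, dtype=np.int32)
    for i, r in enumerate(params.shell_radii):
        lab[rho < r] = i + 1
    return lab


def _render(labels: np.ndarray, class_means: Sequence[float]) -> np.ndarray:
    lut = np.concatenate([[0.0], np.asarray(class_means, float)])
    return lut[labels]


def _bias_field(shape, amplitude: float, rng: np.random.Generator) -> np.ndarray:
    if amplitude == 0:
        return np.zeros(shape)
    raw = gaussian_filter(rng.standard_normal(shape), sigma=min(shape) / 4.0)
    peak = np.max(np.abs(raw))
    return raw * (amplitude / peak) if peak > 0 else raw


def smooth_displacement(shape, warp_sd: float, rng: np.random.Generator,
                        smoothing: float = 4.0) -> np.ndarray:
    """Band-limited random displacement field, one vector per voxel.

    White noise per component is Gaussian-smoothed (``smoothing`` voxels)
    then rescaled so each component has standard deviation ``warp_sd``
    voxels over the grid.
    """
    disp = np.empty((3,) + tuple(shape))
    for c in range(3):
        raw = gaussian_filter(rng.standard_normal(shape), sigma=smoothing)
        sd = raw.std()
        disp[c] = raw * (warp_sd / sd) if sd > 0 else raw
    return disp


def _jacobian_positive(disp: np.ndarray) -> bool:
    """True iff the map x -> x + u(x) has positive Jacobian determinant everywhere."""
    grads = np.empty(disp.shape[:1] + (3,) + disp.shape[1:])
    for c in range(3):
        for ax, g in enumerate(np.gradient(disp[c])):
            grads[c, ax] = g
    jac = np.moveaxis(grads, (0, 1), (-2, -1))  # (..., 3, 3) = du_c/dx_ax
    jac = jac + np.eye(3)
    return bool(np.all(np.linalg.det(jac) > 0))


def apply_warp(data: np.ndarray, displacement: np.ndarray, order: int) -> np.ndarray:
    """Resample ``data`` through the map out(v) = in(v + u(v)).

    order=1 gives trilinear interpolation (images), order=0 nearest
    neighbour (label maps); edges replicate.
    """
    coords = np.indices(data.shape).astype(float) + displacement
    return map_coordinates(data, coords, order=order, mode="nearest")


def _subject_displacement(params: PhantomParams, rng: np.random.Generator) -> np.ndarray:
    for attempt in range(5):
        disp = smooth_displacement(params.shape, params.warp_sd, rng, params.warp_smoothing)
        if _jacobian_positive(disp):
            return disp
        logger.warning("displacement field folds the grid (attempt %d), regenerating",
                       attempt + 1)
    raise ValidationError(
        f"warp_sd={params.warp_sd} keeps producing folding displacement fields"
    )


def _finish(labels: np.ndarray, clean: np.ndarray, params: PhantomParams,
            rng: np.random.Generator):
    bias = _bias_field(params.shape, params.bias_amplitude, rng)
    image = clean * (1.0 + bias)
    if params.noise_sd > 0:
        image = image + rng.normal(0.0, params.noise_sd, params.shape)
    return (
        ScalarVolume(image),
        LabelVolume(labels),
        BinaryMask(labels > 0),
    )


def generate_phantom(params: PhantomParams):
    """Generate one phantom: (image, labels, brain mask).

    Labels are nested smoothed ellipsoidal shells; the image is the per-class
    mean intensity modulated by a smooth multiplicative bias field plus
    additive Gaussian noise.  Deterministic given ``params.seed``.
    """
    labels = _base_labels(params)
    counts = np.bincount(labels.ravel(), minlength=params.n_classes + 1)
    if np.any(counts[1:] == 0):
        raise ValidationError("phantom geometry produced an empty class; enlarge the grid")
    clean = _render(labels, params.class_means)
    rng = np.random.default_rng([params.seed, _PHANTOM_TAG])
    return _finish(labels, clean, params, rng)


def generate_population(n_subjects: int, params: PhantomParams) -> AtlasSet:
    """Generate a population: one base anatomy under per-subject smooth warps.

    Each subject gets an independent displacement field (σ = ``warp_sd``
    voxels, rejected and redrawn if it folds the grid), an independent bias
    field and independent noise.  Images are resampled trilinearly, labels
    by nearest neighbour, so image and labels stay consistent.
    """
    if n_subjects < 2:
        raise ValidationError("a population needs at least 2 subjects")
    base_labels = _base_labels(params)
    if np.any(np.bincount(base_labels.ravel(), minlength=params.n_classes + 1)[1:] == 0):
        raise ValidationError("phantom geometry produced an empty class; enlarge the grid")
    base_clean = _render(base_labels, params.class_means)

    images, labels, masks = [], [], []
    for i in range(n_subjects):
        rng = np.random.default_rng([params.seed, _SUBJECT_TAG + i])
        if params.warp_sd > 0:
            disp = _subject_displacement(params, rng)
            lab_i = apply_warp(base_labels, disp, order=0)
            clean_i = apply_warp(base_clean, disp, order=1)
        else:
            lab_i, clean_i = base_labels, base_clean
        img, lab, mask = _finish(lab_i, clean_i, params, rng)
        images.append(img)
        labels.append(lab)
        masks.append(mask)
    return AtlasSet(images=images, labels=labels, masks=masks)


def generate_second_modality(volume: ScalarVolume, labels: LabelVolume,
                             params: PhantomParams) -> ScalarVolume:
    """Re-render the same anatomy with the class-mean order reversed.

    Emulates acquiring a second structural contrast (e.g. T2w next to T1w):
    identical geometry, inverted tissue contrast, independent bias and noise
    draws.
    """
    if tuple(volume.shape) != tuple(labels.shape):
        raise ValidationError("volume and labels must share one grid")
    reversed_means = tuple(reversed(params.class_means))
    clean = _render(labels.data, reversed_means)
    rng = np.random.default_rng([params.seed, _MODALITY2_TAG])
    img, _, _ = _finish(labels.data, clean, params, rng)
    return img
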