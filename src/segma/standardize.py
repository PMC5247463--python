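"""Histogram-landmark intensity standardization (Nyul–Udupa style).

MR intensities are not comparable across subjects; classification across a
population therefore requires mapping every image onto a common intensity
scale first.  The standard scale is defined by landmark percentiles (here
min, deciles 10–90, max) averaged over a training population; each image is
then mapped piecewise-linearly so its own landmark percentiles land on the
standard values, with linear extrapolation beyond the end landmarks.
Landmarks are always computed within the brain mask.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .volumes import BinaryMask, ScalarVolume, ValidationError

__all__ = [
    "DEFAULT_PERCENTILES",
    "StandardizationModel",
    "fit_standard_scale",
    "apply_standardization",
]

DEFAULT_PERCENTILES = (0.0, 10.0, 20.0, 30.0, 40.0, 50.0, 60.0, 70.0, 80.0, 90.0, 100.0)

_MIN_MASK_VOXELS = 100


def _separate(values: np.ndarray) -> np.ndarray:
    """Make a non-decreasing landmark sequence strictly increasing."""
    values = np.asarray(values, float).copy()
    span = values[-1] - values[0]
    eps = 1e-6 * max(1.0, abs(span))
    for i in range(1, len(values)):
        if values[i] <= values[i - 1]:
            values[i] = values[i - 1] + eps
    return values


def _mask_percentiles(volume: ScalarVolume, mask: BinaryMask,
                      percentiles: Sequence[float]) -> np.ndarray:
    vals = volume.data[mask.data]
    if vals.size < _MIN_MASK_VOXELS:
        raise ValidationError(
            f"only {vals.size} in-mask voxels; need >= {_MIN_MASK_VOXELS} for "
            "stable percentiles"
        )
    if np.ptp(vals) == 0:
        raise ValidationError("constant-intensity volume: percentiles are degenerate")
    return np.percentile(vals, percentiles)


@dataclass
class StandardizationModel:
    """Fitted standard scale: matched (percentile, landmark value) lists."""

    percentiles: tuple
    landmarks: np.ndarray

    def __post_init__(self):
        self.percentiles = tuple(float(p) for p in self.percentiles)
        if any(not (0 <= p <= 100) for p in self.percentiles):
            raise ValidationError("percentiles must lie in [0, 100]")
        if list(self.percentiles) != sorted(self.percentiles):
            raise ValidationError("percentiles must be sorted")
        self.landmarks = np.asarray(self.landmarks, float)
        if len(self.landmarks) != len(self.percentiles):
            raise ValidationError("one landmark value per percentile required")
        if np.any(np.diff(self.landmarks) <= 0):
            raise ValidationError("standard-scale landmarks must be strictly increasing")

    def to_json(self, path=None) -> str:
        payload = json.dumps(
            {"percentiles": list(self.percentiles), "landmarks": self.landmarks.tolist()},
            indent=2,
        )
        if path is not None:
            Path(path).write_text(payload)
        return payload

    @classmethod
    def from_json(cls, source) -> "StandardizationModel":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        d = json.loads(text)
        return cls(percentiles=tuple(d["percentiles"]), landmarks=np.asarray(d["landmarks"]))


def fit_standard_scale(volumes: Sequence[ScalarVolume], masks: Sequence[BinaryMask],
                       percentiles: Sequence[float] = DEFAULT_PERCENTILES,
                       ) -> StandardizationModel:
    """Fit the standard intensity scale on a population.

    The standard landmark values are the mean over volumes of each volume's
    within-mask intensity percentiles, epsilon-separated to stay strictly
    increasing.
    """
    if len(volumes) == 0:
        raise ValidationError("need at least one volume to fit a standard scale")
    if len(volumes) != len(masks):
        raise ValidationError("one mask per volume required")
    per_vol = np.stack([
        _mask_percentiles(vol, mask, percentiles) for vol, mask in zip(volumes, masks)
    ])
    landmarks = _separate(per_vol.mean(axis=0))
    return StandardizationModel(percentiles=tuple(percentiles), landmarks=landmarks)


def apply_standardization(volume: ScalarVolume, mask: BinaryMask,
                          model: StandardizationModel) -> ScalarVolume:
    """Map a volume onto the standard scale.

    Piecewise-linear interpolation between the volume's own within-mask
    landmark percentiles and the standard-scale values; linear extrapolation
    beyond the end landmarks; out-of-mask voxels are set to 0.
    """
    own = _separate(_mask_percentiles(volume, mask, model.percentiles))
    std = model.landmarks
    vals = volume.data[mask.data]
    mapped = np.interp(vals, own, std)
    # np.interp clamps outside [own[0], own[-1]]; extend the end segments linearly
    lo = vals < own[0]
    if np.any(lo):
        slope = (std[1] - std[0]) / (own[1] - own[0])
        mapped[lo] = std[0] + slope * (vals[lo] - own[0])
    hi = vals > own[-1]
    if np.any(hi):
        slope = (std[-1] - std[-2]) / (own[-1] - own[-2])
        mapped[hi] = std[-1] + slope * (vals[hi] - own[-1])
    out = np.zeros_like(volume.data)
    out[mask.data] = mapped
    return ScalarVolume(out, spacing=volume.spacing, affine=volume.affine)
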