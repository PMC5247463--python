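"""Comparison methods: majority-vote label fusion and a global random forest.

The global forest is the classical whole-image approach this package's
window-local method is measured against: one classifier trained on voxels
sampled across the whole brain of every atlas (default 100,000 per atlas),
using either the full ten-feature vector or the intensity feature alone,
then applied to every in-mask target voxel.  Majority vote simply takes the
per-voxel modal label over the aligned atlas label maps.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .features import FEATURE_GROUPS, compute_features
from .segmentation import (ForestParams, _fit_forest, _vote_predict, derive_seed)
from .volumes import (AtlasSet, BinaryMask, LabelVolume, ScalarVolume,
                      ValidationError, check_grid_compatible)

logger = logging.getLogger(__name__)

__all__ = ["GlobalRFConfig", "majority_vote", "global_rf_segment"]


@dataclass
class GlobalRFConfig:
    """Settings for the global random-forest baseline."""

    samples_per_atlas: int = 100_000
    feature_set: str = "full"  # "full" (all ten) or "intensity"
    forest: ForestParams = field(default_factory=ForestParams)
    seed: Optional[int] = None  # defaults to forest.seed

    def __post_init__(self):
        if self.samples_per_atlas < 1:
            raise ValidationError("samples_per_atlas must be >= 1")
        if self.feature_set not in ("full", "intensity"):
            raise ValidationError("feature_set must be 'full' or 'intensity'")
        if self.seed is None:
            self.seed = self.forest.seed


def majority_vote(atlas_labels: Sequence[LabelVolume]) -> LabelVolume:
    """Per-voxel modal label over aligned label maps; ties take the lowest label."""
    if len(atlas_labels) == 0:
        raise ValidationError("majority vote needs at least one label map")
    check_grid_compatible(list(atlas_labels))
    stack = np.stack([lab.data for lab in atlas_labels])
    vocab = np.unique(stack)
    counts = np.stack([(stack == v).sum(axis=0) for v in vocab], axis=-1)
    # argmax takes the first maximum; vocab is sorted, so ties go low
    fused = vocab[np.argmax(counts, axis=-1)].astype(np.int32)
    ref = atlas_labels[0]
    return LabelVolume(fused, spacing=ref.spacing, affine=ref.affine)


def global_rf_segment(target: ScalarVolume, mask: BinaryMask, atlases: AtlasSet,
                      config: GlobalRFConfig = None) -> LabelVolume:
    """Segment with one forest trained on voxels sampled across whole atlases.

    Per atlas, ``samples_per_atlas`` in-mask voxels are drawn uniformly
    without replacement (capped at the in-mask count, with a warning) and
    kept in grid order.  Prediction uses the same hard per-tree vote and
    lowest-label tie-break as the window-local method, so with the window
    spanning the whole grid the two routes are interchangeable.
    """
    config = config or GlobalRFConfig()
    check_grid_compatible([target] + list(atlases.images) + list(atlases.labels))
    if tuple(mask.shape) != tuple(target.shape):
        raise ValidationError("target mask grid does not match target grid")

    cols = list(range(10)) if config.feature_set == "full" else list(FEATURE_GROUPS["intensity"])

    rows, labs = [], []
    rng = np.random.default_rng(derive_seed(config.seed, 1))
    for i, (img, lab, m) in enumerate(atlases):
        feats = compute_features(img, m).data[..., cols]
        flat_idx = np.flatnonzero(m.data.ravel())
        if flat_idx.size == 0:
            continue
        n_take = min(config.samples_per_atlas, flat_idx.size)
        if n_take < config.samples_per_atlas:
            logger.warning("atlas %d has only %d in-mask voxels (requested %d)",
                           i, flat_idx.size, config.samples_per_atlas)
        take = np.sort(rng.choice(flat_idx, size=n_take, replace=False))
        rows.append(feats.reshape(-1, feats.shape[-1])[take])
        lab_flat = np.where(m.data, lab.data, 0).astype(np.int32).ravel()
        labs.append(lab_flat[take])
    if not rows:
        raise ValidationError("no in-mask atlas voxels to train from")
    X = np.concatenate(rows)
    y = np.concatenate(labs)

    target_feats = compute_features(target, mask).data[..., cols]
    test_idx = np.flatnonzero(mask.data.ravel())
    X_test = target_feats.reshape(-1, len(cols))[test_idx]

    out = np.zeros(int(np.prod(target.shape)), dtype=np.int32)
    uniq = np.unique(y)
    if uniq.size == 1:
        out[test_idx] = uniq[0]
    else:
        forest = _fit_forest(X, y, config.forest, derive_seed(config.seed, 0))
        out[test_idx] = _vote_predict(forest, X_test)
    return LabelVolume(out.reshape(target.shape), spacing=target.spacing,
                       affine=target.affine)
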