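"""Sparsity-based selection of representative atlases.

Labelling training images is expensive, so rather than using every candidate
atlas we select a small subset that covers the population's variability: the
candidates are embedded in a low-dimensional space (PCA of vectorized
in-mask intensities) and a subset "uniformly" spread over that space is
picked by a deterministic greedy rule — the candidate closest to the pool
centroid first, then repeatedly the candidate farthest (in min-distance
terms) from everything already selected.  This needs no target image at all,
so one selection serves a whole cohort.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Union

import numpy as np

from .volumes import BinaryMask, ScalarVolume, ValidationError, check_grid_compatible

__all__ = ["EmbeddingConfig", "SelectionResult", "embed_pool", "select_atlases"]


@dataclass
class EmbeddingConfig:
    """PCA embedding settings.

    ``n_components=None`` keeps the smallest number of components explaining
    at least ``variance_target`` of the variance, capped at pool size − 1.
    """

    n_components: Optional[int] = None
    variance_target: float = 0.95

    def __post_init__(self):
        if self.n_components is not None and self.n_components < 1:
            raise ValidationError("n_components must be >= 1")
        if not (0 < self.variance_target <= 1):
            raise ValidationError("variance_target must lie in (0, 1]")


@dataclass
class SelectionResult:
    """Greedy atlas selection outcome."""

    indices: List[int]
    coordinates: np.ndarray
    distances: np.ndarray

    def __post_init__(self):
        if len(set(self.indices)) != len(self.indices):
            raise ValidationError("selected indices must be unique")


def embed_pool(volumes: Sequence[ScalarVolume],
               masks: Union[BinaryMask, Sequence[BinaryMask]],
               config: EmbeddingConfig = EmbeddingConfig()) -> np.ndarray:
    """Embed candidate volumes as low-dimensional points.

    Within-mask intensities (common mask = intersection when several masks
    are given) are vectorized, mean-centred across the pool and projected
    onto the top principal directions.  Deterministic sign convention: the
    largest-magnitude loading of each component is made positive.

    Returns an (n_volumes, n_components) coordinate array.
    """
    n = len(volumes)
    if n < 2:
        raise ValidationError("need at least 2 volumes to embed")
    check_grid_compatible(list(volumes))
    if isinstance(masks, BinaryMask):
        common = masks.data
    else:
        common = np.logical_and.reduce([m.data for m in masks])
    if not common.any():
        raise ValidationError("common mask (intersection) is empty")
    X = np.stack([vol.data[common] for vol in volumes])
    Xc = X - X.mean(axis=0, keepdims=True)
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    var = S ** 2
    total = var.sum()
    if total == 0:
        # all volumes identical: a single zero-variance coordinate
        return np.zeros((n, 1))
    if config.n_components is not None:
        d = min(config.n_components, n - 1)
    else:
        frac = np.cumsum(var) / total
        d = int(np.searchsorted(frac, config.variance_target) + 1)
        d = min(d, n - 1)
    coords = U[:, :d] * S[:d]
    for j in range(d):
        lead = np.argmax(np.abs(Vt[j]))
        if Vt[j, lead] < 0:
            coords[:, j] = -coords[:, j]
    return coords


def select_atlases(coordinates: np.ndarray, k: int) -> SelectionResult:
    """Greedy farthest-point subset of the embedded pool.

    The first pick is the candidate closest to the pool centroid; each
    subsequent pick maximizes its minimum Euclidean distance to all already
    selected candidates.  Ties break toward the lowest candidate index.
    """
    coords = np.atleast_2d(np.asarray(coordinates, float))
    if coords.ndim != 2:
        raise ValidationError("coordinates must be an (n, d) array")
    n = coords.shape[0]
    if not (1 <= k <= n):
        raise ValidationError(f"k must lie in [1, {n}], got {k}")
    diff = coords[:, None, :] - coords[None, :, :]
    distances = np.sqrt((diff ** 2).sum(axis=-1))

    centroid = coords.mean(axis=0)
    first = int(np.argmin(np.linalg.norm(coords - centroid, axis=1)))
    selected = [first]
    min_dist = distances[first].copy()
    while len(selected) < k:
        min_dist[selected] = -np.inf
        nxt = int(np.argmax(min_dist))  # argmax returns the lowest tied index
        selected.append(nxt)
        min_dist = np.minimum(min_dist, distances[nxt])
    return SelectionResult(indices=selected, coordinates=coords, distances=distances)
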