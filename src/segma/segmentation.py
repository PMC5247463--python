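"""Sliding-window local random-forest segmentation.

The target grid is tiled into small cubic windows (default 5×5×5).  For
each window a dedicated random-forest classifier is trained on the feature
vectors of the *same voxel locations* in the k aligned atlas images — k·w
training rows for a window of w voxels — and then classifies all w target
voxels of the window at once.  Classifying per window rather than per voxel
cuts the number of classifier invocations by a factor w (125 for a 5³
window), and keeps each classification problem local: a window typically
contains only the couple of tissue classes actually present there, which is
what makes the local forests robust to smooth intensity inhomogeneity and
low global contrast.

Windows tile the grid without overlap (stride = window side) so each voxel
is classified exactly once; a smaller ``stride`` yields overlapping windows
whose predictions are fused by per-voxel majority vote.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
from sklearn.ensemble import RandomForestClassifier

from .features import FEATURE_NAMES, compute_features
from .volumes import (AtlasSet, BinaryMask, LabelVolume, ScalarVolume,
                      ValidationError, check_grid_compatible)

__all__ = [
    "WindowSpec",
    "ForestParams",
    "SegmentationResult",
    "derive_seed",
    "tile_windows",
    "gather_training",
    "classify_window",
    "segment",
]


def derive_seed(global_seed: int, index: int) -> int:
    """Stable per-unit seed from (global seed, unit index).

    Uses NumPy's SeedSequence so the derivation is platform-independent and
    insensitive to iteration order or parallel scheduling.
    """
    state = np.random.SeedSequence([int(global_seed), int(index)]).generate_state(1)[0]
    return int(state % (2 ** 31))


@dataclass(frozen=True)
class WindowSpec:
    """One axis-aligned tile of the grid: origin, per-axis extent, linear index."""

    origin: Tuple[int, int, int]
    extent: Tuple[int, int, int]
    index: int

    @property
    def slices(self) -> tuple:
        return tuple(slice(o, o + e) for o, e in zip(self.origin, self.extent))

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.extent))


@dataclass
class ForestParams:
    """Random-forest hyperparameters for the per-window classifiers."""

    n_trees: int = 10
    max_depth: Optional[int] = 20
    min_leaf: int = 1
    features_per_split: int = 4  # ceil(sqrt(10))
    seed: int = 0

    def __post_init__(self):
        if self.n_trees < 1:
            raise ValidationError("n_trees must be >= 1")
        if self.features_per_split < 1 or self.features_per_split > len(FEATURE_NAMES):
            raise ValidationError(
                f"features_per_split must lie in [1, {len(FEATURE_NAMES)}]"
            )
        if self.min_leaf < 1:
            raise ValidationError("min_leaf must be >= 1")


@dataclass
class SegmentationResult:
    """Predicted labels plus a per-window training log."""

    labels: LabelVolume
    n_windows: int
    n_trained: int
    n_constant: int
    n_excluded_empty: int
    w_side: int
    stride: int
    params: ForestParams

    def log(self) -> dict:
        return {
            "n_windows": self.n_windows,
            "n_trained": self.n_trained,
            "n_constant": self.n_constant,
            "n_excluded_empty": self.n_excluded_empty,
            "w_side": self.w_side,
            "stride": self.stride,
            "n_trees": self.params.n_trees,
            "max_depth": self.params.max_depth,
            "min_leaf": self.params.min_leaf,
            "features_per_split": self.params.features_per_split,
            "seed": self.params.seed,
        }


def tile_windows(shape: Sequence[int], w_side: int,
                 mask: Optional[BinaryMask] = None,
                 stride: Optional[int] = None) -> List[WindowSpec]:
    """Tile the grid into windows of side ``w_side``.

    Windows start at the grid origin with the given stride (default: the
    window side, i.e. non-overlapping) and are clipped at the far faces.
    Windows that do not intersect the mask are excluded.  The linear index
    enumerates the full origin lattice in lexicographic (x, y, z) order, so
    a window keeps its index regardless of the mask.
    """
    if w_side < 1:
        raise ValidationError("window side must be >= 1")
    stride = w_side if stride is None else int(stride)
    if stride < 1:
        raise ValidationError("stride must be >= 1")
    shape = tuple(int(s) for s in shape)
    starts = [range(0, s, stride) for s in shape]
    windows = []
    for index, origin in enumerate(itertools.product(*starts)):
        extent = tuple(min(w_side, s - o) for o, s in zip(origin, shape))
        win = WindowSpec(origin=origin, extent=extent, index=index)
        if mask is not None and not mask.data[win.slices].any():
            continue
        windows.append(win)
    return windows


def gather_training(window: WindowSpec, atlas_features: Sequence[np.ndarray],
                    atlas_labels: Sequence[np.ndarray]) -> tuple:
    """Stack the k·w training rows for one window.

    ``atlas_features`` are (nx, ny, nz, f) arrays, ``atlas_labels`` integer
    grids with out-of-atlas-mask voxels already set to 0 (background) so
    near-boundary windows learn to predict background.  Rows are ordered
    atlas-major, window voxels in C order within each atlas.
    """
    if len(atlas_features) == 0:
        raise ValidationError("no atlases to train from")
    sl = window.slices
    X = np.concatenate([f[sl].reshape(-1, f.shape[-1]) for f in atlas_features])
    y = np.concatenate([lab[sl].ravel() for lab in atlas_labels])
    return X, y


def _fit_forest(X: np.ndarray, y: np.ndarray, params: ForestParams,
                seed: int) -> RandomForestClassifier:
    forest = RandomForestClassifier(
        n_estimators=params.n_trees,
        max_depth=params.max_depth,
        min_samples_leaf=params.min_leaf,
        max_features=min(params.features_per_split, X.shape[1]),
        bootstrap=True,
        random_state=seed,
        n_jobs=1,
    )
    return forest.fit(X, y)


def _vote_predict(forest: RandomForestClassifier, X: np.ndarray) -> np.ndarray:
    """Hard majority vote over trees; ties break toward the lowest label."""
    classes = forest.classes_
    votes = np.zeros((X.shape[0], classes.size), dtype=np.int32)
    rows = np.arange(X.shape[0])
    for est in forest.estimators_:
        # sub-estimators predict encoded class indices 0..n-1
        votes[rows, est.predict(X).astype(np.intp)] += 1
    # argmax returns the first (lowest) class on ties; classes_ is sorted
    return classes[np.argmax(votes, axis=1)].astype(np.int32)


def classify_window(test_matrix: np.ndarray, train_matrix: np.ndarray,
                    train_labels: np.ndarray, params: ForestParams,
                    window_seed: int) -> np.ndarray:
    """Classify the voxels of one window.

    If all training labels agree, that label is assigned to every test
    voxel without fitting a forest; otherwise a forest of bagged,
    feature-subsampled trees is fitted and each test voxel gets the
    majority class over trees (ties toward the lowest label value).
    Deterministic given ``window_seed``.
    """
    train_labels = np.asarray(train_labels)
    if train_labels.size == 0:
        raise ValidationError("empty training set for window")
    if train_matrix.shape[0] != train_labels.shape[0]:
        raise ValidationError(
            f"{train_matrix.shape[0]} training rows but {train_labels.shape[0]} labels"
        )
    uniq = np.unique(train_labels)
    if uniq.size == 1:
        return np.full(test_matrix.shape[0], uniq[0], dtype=np.int32)
    forest = _fit_forest(train_matrix, train_labels, params, window_seed)
    return _vote_predict(forest, test_matrix)


def segment(target: ScalarVolume, mask: BinaryMask, atlases: AtlasSet,
            w_side: int = 5, params: ForestParams = None,
            feature_indices: Optional[Sequence[int]] = None,
            stride: Optional[int] = None) -> SegmentationResult:
    """Segment a target volume with per-window local forests.

    Parameters
    ----------
    target : ScalarVolume
        Standardized target image, co-registered with the atlases.
    mask : BinaryMask
        Target brain mask; out-of-mask voxels receive label 0.
    atlases : AtlasSet
        Standardized atlas images with label maps on the same grid.
    w_side : int
        Window side in voxels (default 5).
    params : ForestParams
        Forest hyperparameters; ``params.seed`` is the global seed from
        which each window derives its own seed via its linear index.
    feature_indices : sequence of int, optional
        Columns of the ten-feature vector to use (ablation support).
    stride : int, optional
        Window stride; default equals ``w_side`` (no overlap).  Smaller
        strides overlap windows and fuse predictions by majority vote.
    """
    params = params or ForestParams()
    check_grid_compatible([target] + list(atlases.images) + list(atlases.labels))
    if tuple(mask.shape) != tuple(target.shape):
        raise ValidationError("target mask grid does not match target grid")
    if not mask.data.any():
        raise ValidationError("target mask is empty")
    if len(atlases) == 0:
        raise ValidationError("at least one atlas is required")

    idx = None if feature_indices is None else list(feature_indices)

    def _feats(vol, m):
        data = compute_features(vol, m).data
        return data if idx is None else data[..., idx]

    target_feats = _feats(target, mask)
    atlas_feats = [_feats(img, m) for img, _, m in atlases]
    atlas_labs = [np.where(m.data, lab.data, 0).astype(np.int32)
                  for _, lab, m in atlases]

    stride_eff = w_side if stride is None else int(stride)
    all_windows = tile_windows(target.shape, w_side, mask=None, stride=stride_eff)
    windows = [w for w in all_windows if mask.data[w.slices].any()]
    n_excluded = len(all_windows) - len(windows)

    overlap = stride_eff < w_side
    out = np.zeros(target.shape, dtype=np.int32)
    if overlap:
        vocab = np.unique(np.concatenate([np.unique(l) for l in atlas_labs]))
        vote_counts = np.zeros(target.shape + (vocab.size,), dtype=np.int16)
        pos = {int(v): i for i, v in enumerate(vocab)}

    n_trained = n_constant = 0
    for win in windows:
        X_train, y_train = gather_training(win, atlas_feats, atlas_labs)
        X_test = target_feats[win.slices].reshape(-1, target_feats.shape[-1])
        if np.unique(y_train).size == 1:
            n_constant += 1
        else:
            n_trained += 1
        pred = classify_window(X_test, X_train, y_train, params,
                               derive_seed(params.seed, win.index))
        block = pred.reshape(win.extent)
        if overlap:
            for v in np.unique(block):
                vote_counts[win.slices + (pos[int(v)],)] += (block == v)
        else:
            out[win.slices] = block

    if overlap:
        out = vocab[np.argmax(vote_counts, axis=-1)].astype(np.int32)
    out[~mask.data] = 0
    return SegmentationResult(
        labels=LabelVolume(out, spacing=target.spacing, affine=target.affine),
        n_windows=len(windows),
        n_trained=n_trained,
        n_constant=n_constant,
        n_excluded_empty=n_excluded,
        w_side=w_side,
        stride=stride_eff,
        params=params,
    )
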