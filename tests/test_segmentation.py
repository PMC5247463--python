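import numpy as np
import pytest

from segma import (AtlasSet, BinaryMask, ForestParams, GlobalRFConfig,
                   PhantomParams, ValidationError, classify_window,
                   derive_seed, gather_training, generate_population,
                   global_rf_segment, segment, tile_windows)
from segma.segmentation import WindowSpec


def brute_force_tiles(shape, w):
    """Independent enumeration of clipped tiles."""
    tiles = []
    for ox in range(0, shape[0], w):
        for oy in range(0, shape[1], w):
            for oz in range(0, shape[2], w):
                ext = (min(w, shape[0] - ox), min(w, shape[1] - oy),
                       min(w, shape[2] - oz))
                tiles.append(((ox, oy, oz), ext))
    return tiles


def test_full_mask_cube_tiling_counts():
    wins = tile_windows((10, 10, 10), 5, BinaryMask(np.ones((10, 10, 10))))
    assert len(wins) == 8
    assert all(w.extent == (5, 5, 5) for w in wins)


def test_clipped_tiling_matches_brute_force():
    shape = (12, 12, 12)
    wins = tile_windows(shape, 5)
    expected = brute_force_tiles(shape, 5)
    assert len(wins) == 27
    assert [(w.origin, w.extent) for w in wins] == expected
    far = [w for w in wins if w.origin == (10, 10, 10)]
    assert far[0].extent == (2, 2, 2)


def test_empty_mask_gives_no_windows():
    wins = tile_windows((10, 10, 10), 5, BinaryMask(np.zeros((10, 10, 10))))
    assert wins == []


def test_window_larger_than_grid_is_single_clipped_window():
    wins = tile_windows((6, 6, 6), 10)
    assert len(wins) == 1
    assert wins[0].extent == (6, 6, 6)


def test_tiling_partitions_every_voxel_exactly_once():
    shape = (11, 9, 13)
    cover = np.zeros(shape, dtype=int)
    for w in tile_windows(shape, 4):
        cover[w.slices] += 1
    assert np.all(cover == 1)


def test_gather_training_row_counts(rng):
    shape = (10, 10, 10)
    feats = [rng.normal(size=shape + (10,)) for _ in range(5)]
    labs = [rng.integers(0, 3, size=shape) for _ in range(5)]
    win = WindowSpec((0, 0, 0), (5, 5, 5), 0)
    X, y = gather_training(win, feats, labs)
    assert X.shape == (5 * 125, 10)
    assert y.shape == (625,)

    clipped = WindowSpec((8, 0, 0), (2, 5, 5), 1)
    X, y = gather_training(clipped, feats[:1], labs[:1])
    assert X.shape == (50, 10)


def test_gather_training_outside_atlas_mask_is_background(rng):
    shape = (6, 6, 6)
    lab = np.where(np.zeros(shape, bool), 1, 0)  # all background after masking
    feats = [np.zeros(shape + (10,))]
    win = WindowSpec((0, 0, 0), (6, 6, 6), 0)
    _, y = gather_training(win, feats, [lab])
    assert np.all(y == 0)


def test_classify_window_constant_training_shortcut(rng):
    X_test = rng.normal(size=(10, 10))
    X_train = rng.normal(size=(20, 10))
    y = np.full(20, 2)
    out = classify_window(X_test, X_train, y, ForestParams(), 123)
    assert np.all(out == 2)


def test_classify_window_separable_two_class(rng):
    """Widely separated intensity classes are recovered perfectly."""
    n = 200
    X_train = np.zeros((n, 10))
    y = np.repeat([1, 2], n // 2)
    X_train[:, 0] = np.where(y == 1, 10.0, 100.0) + rng.normal(0, 1.0, n)
    X_test = np.zeros((40, 10))
    y_test = np.repeat([1, 2], 20)
    X_test[:, 0] = np.where(y_test == 1, 10.0, 100.0) + rng.normal(0, 1.0, 40)
    out = classify_window(X_test, X_train, y, ForestParams(), 7)
    assert np.array_equal(out, y_test)


def test_classify_window_deterministic(rng):
    X_train = rng.normal(size=(100, 10))
    y = rng.integers(1, 4, size=100)
    X_test = rng.normal(size=(30, 10))
    a = classify_window(X_test, X_train, y, ForestParams(), 55)
    b = classify_window(X_test, X_train, y, ForestParams(), 55)
    assert np.array_equal(a, b)


def test_classify_window_row_mismatch_rejected(rng):
    with pytest.raises(ValidationError, match="rows"):
        classify_window(rng.normal(size=(5, 10)), rng.normal(size=(6, 10)),
                        np.ones(5), ForestParams(), 1)


def test_derive_seed_stable_and_bounded():
    assert derive_seed(7, 0) == derive_seed(7, 0)
    assert derive_seed(7, 0) != derive_seed(7, 1)
    assert 0 <= derive_seed(2 ** 30, 10 ** 6) < 2 ** 31


@pytest.fixture(scope="module")
def clean_population():
    params = PhantomParams(shape=(20, 20, 20), noise_sd=0.0, bias_amplitude=0.0,
                           warp_sd=0.0, seed=21)
    return params, generate_population(3, params)


def test_zero_noise_segmentation_recovers_truth(clean_population):
    """Identical noiseless atlases reproduce ground truth exactly."""
    _, pop = clean_population
    result = segment(pop.images[0], pop.masks[0], pop.subset([1, 2]),
                     w_side=5, params=ForestParams(seed=3))
    assert np.array_equal(result.labels.data, pop.labels[0].data)


def test_segment_deterministic(tiny_population):
    pop = tiny_population
    kwargs = dict(w_side=5, params=ForestParams(seed=9))
    a = segment(pop.images[0], pop.masks[0], pop.subset([1, 2]), **kwargs)
    b = segment(pop.images[0], pop.masks[0], pop.subset([1, 2]), **kwargs)
    assert np.array_equal(a.labels.data, b.labels.data)


def test_segment_out_of_mask_is_background(tiny_population):
    pop = tiny_population
    res = segment(pop.images[0], pop.masks[0], pop.subset([1, 2]),
                  params=ForestParams(seed=9))
    assert np.all(res.labels.data[~pop.masks[0].data] == 0)
    assert res.n_windows == res.n_trained + res.n_constant


def test_whole_grid_window_equals_global_classifier(tiny_population):
    """One grid-sized window is the global forest, bit for bit."""
    pop = tiny_population
    shape = pop.images[0].shape
    full = BinaryMask(np.ones(shape))
    atlases = AtlasSet(images=pop.images[1:3], labels=pop.labels[1:3],
                       masks=[full, full])
    params = ForestParams(seed=31)
    win_res = segment(pop.images[0], full, atlases, w_side=max(shape),
                      params=params)
    glob = global_rf_segment(
        pop.images[0], full, atlases,
        GlobalRFConfig(samples_per_atlas=10 ** 6, forest=params))
    assert np.array_equal(win_res.labels.data, glob.data)


def test_segment_refuses_mismatched_grids(tiny_population):
    pop = tiny_population
    bad_mask = BinaryMask(np.ones((10, 10, 10)))
    with pytest.raises(ValidationError):
        segment(pop.images[0], bad_mask, pop.subset([1]))


def test_overlapping_stride_still_covers_mask(tiny_population):
    pop = tiny_population
    res = segment(pop.images[0], pop.masks[0], pop.subset([1, 2]),
                  w_side=6, stride=3, params=ForestParams(seed=2))
    assert np.all(res.labels.data[pop.masks[0].data] >= 0)
    assert np.all(res.labels.data[~pop.masks[0].data] == 0)
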