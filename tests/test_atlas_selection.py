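import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from segma import (BinaryMask, EmbeddingConfig, PhantomParams, ScalarVolume,
                   ValidationError, embed_pool, generate_phantom,
                   select_atlases)
from segma.phantom import apply_warp, smooth_displacement


def greedy_reference(coords, k):
    """Independent re-implementation of the selection rule as explicit loops."""
    coords = np.asarray(coords, float)
    n = len(coords)
    centroid = coords.mean(axis=0)
    best, best_d = 0, np.inf
    for i in range(n):
        d = np.linalg.norm(coords[i] - centroid)
        if d < best_d:
            best, best_d = i, d
    chosen = [best]
    while len(chosen) < k:
        cand_best, cand_dist = None, -np.inf
        for i in range(n):
            if i in chosen:
                continue
            d = min(np.linalg.norm(coords[i] - coords[j]) for j in chosen)
            if d > cand_dist:
                cand_best, cand_dist = i, d
        chosen.append(cand_best)
    return chosen


def test_collinear_pool_picks_centre_then_lowest_tied_end():
    coords = np.array([[0.0], [1.0], [2.0]])
    sel = select_atlases(coords, 2)
    assert sel.indices == [1, 0]  # centre first; 0 and 2 tie, lowest wins


def test_k_equals_pool_returns_all_in_greedy_order(rng):
    coords = rng.normal(size=(6, 3))
    sel = select_atlases(coords, 6)
    assert sorted(sel.indices) == list(range(6))
    assert sel.indices == greedy_reference(coords, 6)


def test_k_one_returns_centroid_closest(rng):
    coords = rng.normal(size=(7, 2))
    sel = select_atlases(coords, 1)
    centroid = coords.mean(axis=0)
    assert sel.indices == [int(np.argmin(np.linalg.norm(coords - centroid, axis=1)))]


def test_k_beyond_pool_rejected(rng):
    with pytest.raises(ValidationError):
        select_atlases(rng.normal(size=(3, 2)), 4)


@settings(deadline=None, max_examples=60, derandomize=True)
@given(
    n=st.integers(2, 8),
    k=st.integers(1, 3),
    dim=st.integers(1, 3),
    seed=st.integers(0, 10_000),
)
def test_greedy_matches_explicit_loop_oracle(n, k, dim, seed):
    if k > n:
        k = n
    coords = np.random.default_rng(seed).normal(size=(n, dim))
    assert select_atlases(coords, k).indices == greedy_reference(coords, k)


def test_selection_nesting_and_spread_monotonicity(rng):
    coords = rng.normal(size=(8, 2))
    prev_indices, prev_spread = None, np.inf
    for k in range(1, 9):
        sel = select_atlases(coords, k)
        if prev_indices is not None:
            assert sel.indices[:-1] == prev_indices
        if k >= 2:
            sub = coords[sel.indices]
            d = np.linalg.norm(sub[:, None] - sub[None, :], axis=-1)
            spread = d[np.triu_indices(k, 1)].min()
            assert spread <= prev_spread + 1e-12
            prev_spread = spread
        prev_indices = sel.indices


def test_two_volume_embedding_symmetric(rng):
    a = ScalarVolume(rng.normal(size=(10, 10, 10)))
    b = ScalarVolume(rng.normal(size=(10, 10, 10)))
    mask = BinaryMask(np.ones((10, 10, 10)))
    coords = embed_pool([a, b], mask)
    assert coords.shape == (2, 1)
    assert coords[0, 0] == pytest.approx(-coords[1, 0])


def test_identical_volumes_embed_at_origin(rng):
    vol = ScalarVolume(rng.normal(size=(10, 10, 10)))
    mask = BinaryMask(np.ones((10, 10, 10)))
    coords = embed_pool([vol, ScalarVolume(vol.data.copy()),
                         ScalarVolume(vol.data.copy())], mask)
    np.testing.assert_allclose(coords, 0.0, atol=1e-9)
    assert np.all(coords == coords[0])  # zero variance: all points coincide


def test_embedding_deterministic(rng):
    vols = [ScalarVolume(rng.normal(size=(8, 8, 8))) for _ in range(5)]
    mask = BinaryMask(np.ones((8, 8, 8)))
    a = embed_pool(vols, mask)
    b = embed_pool(vols, mask)
    np.testing.assert_array_equal(a, b)


def test_first_component_tracks_warp_amplitude():
    """Phantoms warped by scaled copies of one field order along PC1."""
    params = PhantomParams(shape=(20, 20, 20), noise_sd=0.0, bias_amplitude=0.0,
                           warp_sd=0.0, seed=9)
    img, lab, mask = generate_phantom(params)
    disp = smooth_displacement(params.shape, 1.0, np.random.default_rng(42))
    amplitudes = [0.0, 0.5, 1.0, 1.5, 2.0]
    vols = [ScalarVolume(apply_warp(img.data, a * disp, order=1))
            for a in amplitudes]
    coords = embed_pool(vols, mask, EmbeddingConfig(n_components=1))
    rank_corr = np.corrcoef(np.argsort(np.argsort(coords[:, 0])),
                            np.arange(len(amplitudes)))[0, 1]
    assert abs(rank_corr) == pytest.approx(1.0)
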