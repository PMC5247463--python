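import numpy as np
import pytest

from segma import (BinaryMask, ScalarVolume, ValidationError, compute_features,
                   first_derivatives, gradient_orientation, second_derivatives)
from segma.features import FEATURE_GROUPS, FEATURE_NAMES


def brute_force_kernel(data, kernel, axis):
    """Nested-loop correlation with replicate padding: the independent oracle."""
    out = np.zeros_like(data, dtype=float)
    nx, ny, nz = data.shape
    for i in range(nx):
        for j in range(ny):
            for k in range(nz):
                acc = 0.0
                for off, w in zip((-1, 0, 1), kernel):
                    idx = [i, j, k]
                    idx[axis] = min(max(idx[axis] + off, 0), data.shape[axis] - 1)
                    acc += w * data[tuple(idx)]
                out[i, j, k] = acc
    return out


def ramp_volume(axis, n=7):
    grids = np.indices((n, n, n)).astype(float)
    return ScalarVolume(grids[axis])


def test_ramp_first_derivative_interior_and_faces():
    vol = ramp_volume(0)
    Ix, Iy, Iz = first_derivatives(vol)
    assert np.all(Ix[1:-1] == 2.0)       # I(v+1) - I(v-1) on a unit ramp
    assert np.all(Ix[0] == 1.0)          # replicate padding halves the step
    assert np.all(Ix[-1] == 1.0)
    assert np.all(Iy == 0.0) and np.all(Iz == 0.0)


def test_constant_volume_has_zero_derivatives():
    vol = ScalarVolume(np.full((5, 5, 5), 3.5))
    for d in (*first_derivatives(vol), *second_derivatives(vol)):
        assert np.all(d == 0.0)


def test_parabola_second_derivative():
    x = np.indices((9, 5, 5)).astype(float)[0]
    Ixx, Iyy, Izz = second_derivatives(ScalarVolume(x ** 2))
    assert np.all(Ixx[1:-1] == -2.0)     # -(x-1)^2 + 2x^2 - (x+1)^2 = -2
    assert np.all(Iyy == 0.0) and np.all(Izz == 0.0)


def test_linear_ramp_second_derivative_zero_interior():
    Ixx, _, _ = second_derivatives(ramp_volume(0))
    assert np.all(Ixx[1:-1] == 0.0)


def test_too_small_axis_rejected():
    with pytest.raises(ValidationError, match=">= 3"):
        first_derivatives(ScalarVolume(np.zeros((2, 5, 5))))


@pytest.mark.parametrize("kernel_fn,kernel", [
    (first_derivatives, (-1.0, 0.0, 1.0)),
    (second_derivatives, (-1.0, 2.0, -1.0)),
])
def test_kernels_match_nested_loop_oracle(kernel_fn, kernel, rng):
    # integer-valued volumes keep every kernel sum exact in floating point,
    # so the comparison is bit-exact independent of summation order
    for _ in range(3):
        data = rng.integers(-100, 100, size=(5, 5, 5)).astype(float)
        fields = kernel_fn(ScalarVolume(data))
        for axis in range(3):
            expected = brute_force_kernel(data, kernel, axis)
            np.testing.assert_array_equal(fields[axis], expected)


@pytest.mark.parametrize("g,expected", [
    ((2.0, 0.0, 0.0), (2.0, 0.0, np.pi / 2)),
    ((0.0, 0.0, 3.0), (3.0, 0.0, 0.0)),
    ((0.0, 0.0, -3.0), (3.0, 0.0, np.pi)),
    ((0.0, 0.0, 0.0), (0.0, 0.0, 0.0)),
    ((0.0, 1.0, 0.0), (1.0, np.pi / 2, np.pi / 2)),
    ((-1.0, 0.0, 0.0), (1.0, np.pi, np.pi / 2)),
])
def test_gradient_orientation_reference_points(g, expected):
    arr = lambda v: np.full((1, 1, 1), v)
    r, theta, phi = gradient_orientation(arr(g[0]), arr(g[1]), arr(g[2]))
    assert (r[0, 0, 0], theta[0, 0, 0], phi[0, 0, 0]) == pytest.approx(expected)


def test_orientation_invariants_on_random_fields(rng):
    data = rng.normal(size=(9, 9, 9))
    vol = ScalarVolume(data)
    Ix, Iy, Iz = first_derivatives(vol)
    r, theta, phi = gradient_orientation(Ix, Iy, Iz)
    np.testing.assert_allclose(r ** 2, Ix ** 2 + Iy ** 2 + Iz ** 2, rtol=1e-9)
    assert np.all((theta >= 0) & (theta < 2 * np.pi))
    assert np.all((phi >= 0) & (phi <= np.pi))


def test_axis_swap_symmetry(rng):
    """Swapping x and y swaps |Ix| and |Iy| and reflects the azimuth."""
    data = rng.normal(size=(8, 8, 8))
    feats = compute_features(ScalarVolume(data)).data
    swapped = compute_features(ScalarVolume(data.swapaxes(0, 1))).data
    swapped_back = swapped.swapaxes(0, 1)
    np.testing.assert_allclose(swapped_back[..., 1], feats[..., 2], atol=1e-12)
    np.testing.assert_allclose(swapped_back[..., 2], feats[..., 1], atol=1e-12)
    r = feats[..., 4]
    theta = feats[..., 5]
    theta_swapped = swapped_back[..., 5]
    nonzero = r > 1e-9
    expected = np.mod(np.pi / 2 - theta[nonzero], 2 * np.pi)
    np.testing.assert_allclose(theta_swapped[nonzero], expected, atol=1e-9)


def test_feature_vector_layout(rng):
    assert len(FEATURE_NAMES) == 10
    covered = sorted(i for idx in FEATURE_GROUPS.values() for i in idx)
    assert covered == list(range(10))

    data = rng.normal(size=(6, 6, 6))
    field = compute_features(ScalarVolume(data))
    assert field.data.shape == (6, 6, 6, 10)


def test_constant_volume_feature_vector():
    field = compute_features(ScalarVolume(np.full((5, 5, 5), 42.0)))
    vec = field.data[2, 2, 2]
    assert vec[0] == 42.0
    assert np.all(vec[1:] == 0.0)


def test_ramp_feature_vector_interior():
    n = 7
    vol = ramp_volume(0, n)
    vec = compute_features(vol).data[3, 3, 3]
    np.testing.assert_allclose(
        vec, [3.0, 2.0, 0.0, 0.0, 2.0, 0.0, np.pi / 2, 0.0, 0.0, 0.0])


def test_out_of_mask_vectors_are_zero(rng):
    data = rng.normal(size=(6, 6, 6)) + 10.0
    mask = np.zeros((6, 6, 6), bool)
    mask[2:4, 2:4, 2:4] = True
    field = compute_features(ScalarVolume(data), BinaryMask(mask))
    assert np.all(field.data[~mask] == 0.0)
    assert np.any(field.data[mask] != 0.0)


def test_feature_field_export_round_trip(tmp_path, rng):
    import nibabel as nib
    from segma.features import export_feature_field

    field = compute_features(ScalarVolume(rng.normal(size=(5, 5, 5))))
    path = tmp_path / "features.nii.gz"
    export_feature_field(field, path)
    back = np.asanyarray(nib.load(str(path)).dataobj)
    assert back.shape == (5, 5, 5, 10)
    np.testing.assert_allclose(back, field.data, rtol=1e-6)
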