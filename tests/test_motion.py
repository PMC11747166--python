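"""Motion-model tests: B-spline basis oracles, DVF composition, warping,
fixed-point inversion and mask propagation."""

import numpy as np
import pytest

from cbctmotion.grids import DisplacementField, VolumeGrid
from cbctmotion.motion import (MBCBasis, compose_dvf, invert_dvf, mask_com,
                               propagate_mask, warp_volume)


def bspline_basis_1d(u):
    return np.array([(1 - u) ** 3 / 6.0,
                     (3 * u ** 3 - 6 * u ** 2 + 4) / 6.0,
                     (-3 * u ** 3 + 3 * u ** 2 + 3 * u + 1) / 6.0,
                     u ** 3 / 6.0])


def oracle_bspline(point, origin, extent, coef):
    """Direct tensor-product cubic B-spline evaluation at one point."""
    n = coef.shape[0]
    val = 0.0
    weights, cells = [], []
    for ax in range(3):
        s = (point[ax] - origin[ax]) / extent[ax] * (n - 3)
        s = min(max(s, 0.0), n - 3 - 1e-12)
        c = int(np.floor(s))
        weights.append(bspline_basis_1d(s - c))
        cells.append(c)
    for a in range(4):
        for b in range(4):
            for cc in range(4):
                val += (weights[0][a] * weights[1][b] * weights[2][cc]
                        * coef[cells[0] + a, cells[1] + b, cells[2] + cc])
    return val


@pytest.fixture
def grid():
    return VolumeGrid.centered((12, 10, 8), (10.0, 10.0, 10.0))


@pytest.fixture
def basis(grid, rng):
    b = MBCBasis.for_volume(grid)
    b.init_random(rng)
    return b


def test_basis_structure(basis):
    assert len(basis.coef) == 3
    assert [basis.coef[i][0].shape for i in range(3)] \
        == [(6, 6, 6), (12, 12, 12), (24, 24, 24)]


def test_zero_coefficients_give_zero_field(grid):
    b = MBCBasis.for_volume(grid)
    assert np.all(b.eval_basis(grid, 0, 0).data == 0.0)


def test_partition_of_unity_constant_reproduction(grid):
    b = MBCBasis.for_volume(grid)
    for level in range(3):
        b.coef[level][1].data[:] = 3.7
        field = b.eval_basis(grid, level, 1).data
        np.testing.assert_allclose(field, 3.7, rtol=1e-12)


@pytest.mark.parametrize("level", [0, 1, 2])
def test_basis_matches_tensor_product_oracle(level, grid, basis, rng):
    field = basis.eval_basis(grid, level, 2).data
    coef = basis.coef[level][2].data
    pts = grid.voxel_centers().reshape(grid.shape + (3,))
    for _ in range(25):
        idx = tuple(rng.integers(0, s) for s in grid.shape)
        expected = oracle_bspline(pts[idx], basis.origin, basis.extent, coef)
        np.testing.assert_allclose(field[idx], expected, atol=1e-10)


def test_compose_zero_scores_and_single_term(grid, basis):
    zero = compose_dvf(basis, np.zeros((3, 3)), grid)
    assert np.all(zero.vectors == 0.0)
    scores = np.zeros((3, 3))
    scores[0, 0] = 2.0
    d = compose_dvf(basis, scores, grid)
    np.testing.assert_allclose(d.vectors[..., 0],
                               2.0 * basis.eval_basis(grid, 0, 0).data,
                               atol=1e-12)
    assert np.all(d.vectors[..., 1:] == 0.0)


def test_compose_matches_brute_force_sum(grid, basis, rng):
    scores = rng.normal(size=(3, 3))
    d = compose_dvf(basis, scores, grid)
    for _ in range(100):
        idx = tuple(rng.integers(0, s) for s in grid.shape)
        for k in range(3):
            expected = sum(scores[i, k]
                           * basis.eval_basis(grid, i, k).data[idx]
                           for i in range(3))
            np.testing.assert_allclose(d.vectors[idx + (k,)], expected,
                                       atol=1e-10)


def test_compose_linearity_in_scores(grid, basis, rng):
    s1, s2 = rng.normal(size=(3, 3)), rng.normal(size=(3, 3))
    d1 = compose_dvf(basis, s1, grid).vectors
    d2 = compose_dvf(basis, s2, grid).vectors
    d12 = compose_dvf(basis, 0.3 * s1 + 1.7 * s2, grid).vectors
    np.testing.assert_allclose(d12, 0.3 * d1 + 1.7 * d2, atol=1e-9)


def test_warp_identity(smooth_blob):
    dvf = DisplacementField(np.zeros(smooth_blob.shape + (3,)),
                            smooth_blob.spacing, smooth_blob.origin)
    np.testing.assert_allclose(warp_volume(smooth_blob, dvf).values,
                               smooth_blob.values, atol=1e-14)


def test_warp_integer_shift(smooth_blob):
    vec = np.zeros(smooth_blob.shape + (3,))
    vec[..., 2] = smooth_blob.spacing[2]        # +1 voxel in z (in mm)
    dvf = DisplacementField(vec, smooth_blob.spacing, smooth_blob.origin)
    warped = warp_volume(smooth_blob, dvf).values
    np.testing.assert_allclose(warped[:, :, :-1], smooth_blob.values[:, :, 1:],
                               atol=1e-12)


def test_warp_matches_per_voxel_oracle(smooth_blob, rng):
    from scipy.ndimage import map_coordinates
    shape = smooth_blob.shape
    vec = rng.normal(0.0, 1.5, size=shape + (3,))
    dvf = DisplacementField(vec, smooth_blob.spacing, smooth_blob.origin)
    warped = warp_volume(smooth_blob, dvf).values
    base = np.stack(np.meshgrid(*[np.arange(s) for s in shape],
                                indexing="ij"), axis=-1).astype(float)
    coords = (base + vec / smooth_blob.spacing).reshape(-1, 3).T
    expected = map_coordinates(smooth_blob.values, coords, order=1,
                               mode="grid-constant", cval=0.0).reshape(shape)
    np.testing.assert_allclose(warped, expected, atol=1e-10)


def _smooth_dvf(grid, amplitude, rng=None):
    pts = grid.voxel_centers().reshape(grid.shape + (3,))
    ext = grid.extent_mm
    vec = np.zeros(grid.shape + (3,))
    phase = pts[..., 0] / ext[0] * np.pi
    vec[..., 2] = amplitude * np.sin(phase) * np.cos(
        pts[..., 1] / ext[1] * np.pi / 2)
    vec[..., 1] = 0.4 * amplitude * np.cos(phase)
    return DisplacementField(vec, grid.spacing, grid.origin)


def test_invert_zero_and_constant(smooth_blob):
    zero = DisplacementField(np.zeros(smooth_blob.shape + (3,)),
                             smooth_blob.spacing, smooth_blob.origin)
    assert np.all(invert_dvf(zero).vectors == 0.0)
    vec = np.zeros(smooth_blob.shape + (3,))
    vec[..., 0] = 3.0
    const = DisplacementField(vec, smooth_blob.spacing, smooth_blob.origin)
    inv1 = invert_dvf(const, iterations=1)
    np.testing.assert_allclose(inv1.vectors[..., 0], -3.0, atol=1e-12)


def test_fixed_point_inverse_composition_residual():
    grid = VolumeGrid.centered((24, 24, 16), (6.0, 6.0, 6.0))
    dvf = _smooth_dvf(grid, 10.0)
    inv = invert_dvf(dvf)                        # default: 3 iterations
    from cbctmotion._kernels import trilinear_gather
    base = grid.voxel_centers()
    coords = (base + inv.vectors.reshape(-1, 3) - grid.origin) / grid.spacing
    d_at = trilinear_gather(np.ascontiguousarray(dvf.vectors),
                            np.ascontiguousarray(coords))
    residual = np.linalg.norm(d_at + inv.vectors.reshape(-1, 3), axis=1)
    assert np.median(residual) < 0.5


def test_warp_inverse_warp_recovers_volume_interior():
    grid = VolumeGrid.centered((24, 24, 16), (6.0, 6.0, 6.0))
    pts = grid.voxel_centers().reshape(grid.shape + (3,))
    r2 = (pts ** 2).sum(axis=-1)
    vol = grid.like(0.02 * np.exp(-r2 / (2 * 30.0 ** 2)))
    dvf = _smooth_dvf(grid, 8.0)
    forward = warp_volume(vol, dvf)
    back = warp_volume(forward, invert_dvf(dvf))
    interior = np.s_[4:-4, 4:-4, 3:-3]
    re = np.linalg.norm(back.values[interior] - vol.values[interior]) \
        / np.linalg.norm(vol.values[interior])
    assert re < 0.05


def test_propagate_mask_identity_shift_and_empty_flag(smooth_blob):
    mask = np.zeros(smooth_blob.shape, dtype=bool)
    mask[8:12, 8:12, 8:12] = True
    zero = DisplacementField(np.zeros(smooth_blob.shape + (3,)),
                             smooth_blob.spacing, smooth_blob.origin)
    same, empty = propagate_mask(mask, zero)
    assert not empty and np.array_equal(same, mask)

    vec = np.zeros(smooth_blob.shape + (3,))
    vec[..., 0] = smooth_blob.spacing[0]
    shifted, _ = propagate_mask(mask, DisplacementField(
        vec, smooth_blob.spacing, smooth_blob.origin))
    assert np.array_equal(shifted[7:11], mask[8:12])

    vec[..., 0] = 1e4                            # pushes mask out of volume
    gone, empty = propagate_mask(mask, DisplacementField(
        vec, smooth_blob.spacing, smooth_blob.origin))
    assert empty and not gone.any()


def test_mask_com_exact_fractional_centroid():
    mask = np.zeros((5, 5, 5), dtype=bool)
    mask[1, 2, 3] = True
    mask[3, 2, 3] = True
    com = mask_com(mask, (2.0, 2.0, 2.0), (-4.0, -4.0, -4.0))
    np.testing.assert_allclose(com, [0.0, 0.0, 2.0])
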