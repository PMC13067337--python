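"""Rotation algebra, sampling grids, and resampling."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cardiofuse.geometry import (
    EulerAngles,
    RotationMatrix,
    Volume3D,
    affine_grid,
    euler_derivatives,
    euler_to_matrix,
    matrix_to_world,
    resample_3d,
    resample_3d_with_grad,
    rotate_volume,
    rotate_volume_matrix,
    warp_2d,
)


def manual_matrix_product(a_deg, b_deg, g_deg):
    """Independent oracle: elementwise 3x3 products of the printed factors."""
    a, b, g = np.deg2rad([a_deg, b_deg, g_deg])
    ry = [[np.cos(a), 0, np.sin(a)], [0, 1, 0], [-np.sin(a), 0, np.cos(a)]]
    rx = [[1, 0, 0], [0, np.cos(b), -np.sin(b)], [0, np.sin(b), np.cos(b)]]
    rz = [[np.cos(g), -np.sin(g), 0], [np.sin(g), np.cos(g), 0], [0, 0, 1]]

    def mul(p, q):
        return [
            [sum(p[i][k] * q[k][j] for k in range(3)) for j in range(3)]
            for i in range(3)
        ]

    return np.array(mul(mul(ry, rx), rz))


class TestEulerToMatrix:
    def test_identity(self):
        assert np.allclose(euler_to_matrix(EulerAngles(0, 0, 0)).m, np.eye(3))

    def test_alpha_90_matches_printed_factor(self):
        m = euler_to_matrix(EulerAngles(90, 0, 0)).m
        assert np.allclose(m, [[0, 0, 1], [0, 1, 0], [-1, 0, 0]], atol=1e-15)

    def test_matches_bruteforce_product(self):
        m = euler_to_matrix(EulerAngles(30, 45, 60)).m
        assert np.abs(m - manual_matrix_product(30, 45, 60)).max() < 1e-12

    def test_yxy_convention_third_factor(self):
        # for the alternative reading the third factor rotates about y again
        m = euler_to_matrix(EulerAngles(0, 0, 90), convention="yxy").m
        assert np.allclose(m, [[0, 0, 1], [0, 1, 0], [-1, 0, 0]], atol=1e-15)

    def test_unknown_convention_rejected(self):
        with pytest.raises(ValueError):
            euler_to_matrix(EulerAngles(1, 2, 3), convention="zyz")

    @settings(max_examples=200, derandomize=True)
    @given(st.tuples(*[st.floats(-180, 180) for _ in range(3)]))
    def test_always_proper_rotation(self, angles):
        m = euler_to_matrix(EulerAngles(*angles)).m
        assert np.allclose(m.T @ m, np.eye(3), atol=1e-9)
        assert abs(np.linalg.det(m) - 1.0) < 1e-9

    def test_derivatives_match_finite_differences(self):
        ang = EulerAngles(25, -40, 75)
        dms = euler_derivatives(ang)
        h = 1e-5
        for k in range(3):
            up = list(ang.as_tuple())
            dn = list(ang.as_tuple())
            up[k] += h
            dn[k] -= h
            fd = (
                euler_to_matrix(EulerAngles(*up)).m
                - euler_to_matrix(EulerAngles(*dn)).m
            ) / (2 * h)
            assert np.abs(fd - dms[k]).max() < 1e-8


class TestAngleCanonicalization:
    def test_wraps_into_range(self):
        a = EulerAngles(190, -700, 360)
        assert a.alpha_deg == pytest.approx(-170)
        assert a.beta_deg == pytest.approx(20)
        assert a.gamma_deg == pytest.approx(0)

    def test_rejects_non_finite(self):
        with pytest.raises(ValueError):
            EulerAngles(np.nan, 0, 0)


class TestRotationMatrixType:
    def test_rejects_non_orthonormal(self):
        with pytest.raises(ValueError):
            RotationMatrix(np.eye(3) * 2)

    def test_rejects_reflection(self):
        with pytest.raises(ValueError):
            RotationMatrix(np.diag([1.0, 1.0, -1.0]))

    def test_json_roundtrip(self):
        m = euler_to_matrix(EulerAngles(10, 20, 30))
        assert np.allclose(RotationMatrix.from_json(m.to_json()).m, m.m)


class TestMatrixToWorld:
    def test_isotropic_unchanged(self):
        m = euler_to_matrix(EulerAngles(10, 20, 30))
        out = matrix_to_world(m, (1.0, 1.0, 1.0), (32, 32, 32))
        assert np.array_equal(out, m.m)

    def test_identity_any_spacing(self):
        out = matrix_to_world(RotationMatrix(np.eye(3)), (1, 1, 2), (16, 16, 16))
        assert np.allclose(out, np.eye(3))

    def test_rejects_bad_spacing(self):
        with pytest.raises(ValueError):
            matrix_to_world(RotationMatrix(np.eye(3)), (1.0, 0.0, 1.0))

    def test_rod_length_preserved_anisotropic(self):
        # a rod along the sagittal axis, voxels twice as long axially;
        # rotating 90 degrees between those axes must preserve mm length
        shape = (41, 41, 41)
        spacing = (2.0, 1.0, 1.0)
        vol = np.zeros(shape)
        vol[20, 20, 8:33] = 1.0  # 25 voxels * 1 mm = 25 mm along sagittal
        v = Volume3D(vol, spacing)
        rot = rotate_volume_matrix(
            v, euler_to_matrix(EulerAngles(90, 0, 0)), mode="nearest"
        )
        occupied = np.argwhere(rot.data > 0.5)
        extent_mm = (occupied.max(0) - occupied.min(0)) * np.array(spacing)
        assert abs(extent_mm.max() - 24.0) / 24.0 < 0.1  # 24 mm center-to-center


class TestAffineGrid:
    def test_identity_grid_is_normalized_coords(self):
        g = affine_grid(RotationMatrix(np.eye(3)), (5, 4, 3))
        assert np.allclose(g[0, :, 0, 0], np.linspace(-1, 1, 5))
        assert np.allclose(g[1, 0, :, 0], np.linspace(-1, 1, 4))
        assert np.allclose(g[2, 0, 0, :], np.linspace(-1, 1, 3))

    def test_center_voxel_fixed_point(self):
        m = euler_to_matrix(EulerAngles(33, -71, 12))
        g = affine_grid(m, (9, 9, 9))
        assert np.allclose(g[:, 4, 4, 4], 0.0, atol=1e-12)

    def test_inverse_composition_is_identity(self):
        m = euler_to_matrix(EulerAngles(20, 40, -30))
        assert np.abs(m.m @ m.m.T - np.eye(3)).max() < 1e-9
        g = affine_grid(m.m @ m.m.T, (6, 6, 6))
        gid = affine_grid(RotationMatrix(np.eye(3)), (6, 6, 6))
        assert np.abs(g - gid).max() < 1e-9

    def test_empty_shape_rejected(self):
        with pytest.raises(ValueError):
            affine_grid(RotationMatrix(np.eye(3)), (0, 4, 4))


def loop_trilinear(data, grid):
    """Scalar-loop interpolation oracle."""
    out = np.zeros(grid.shape[1:])
    n = data.shape
    for i in range(grid.shape[1]):
        for j in range(grid.shape[2]):
            for k in range(grid.shape[3]):
                f = [(grid[ax, i, j, k] + 1) / 2 * (n[ax] - 1) for ax in range(3)]
                c0 = [int(np.floor(x)) for x in f]
                acc = 0.0
                for corner in range(8):
                    w, ok, idx = 1.0, True, []
                    for ax in range(3):
                        o = (corner >> ax) & 1
                        ci = c0[ax] + o
                        w *= (f[ax] - c0[ax]) if o else (1 - (f[ax] - c0[ax]))
                        if ci < 0 or ci >= n[ax]:
                            ok = False
                            ci = 0
                        idx.append(ci)
                    if ok:
                        acc += w * data[idx[0], idx[1], idx[2]]
                out[i, j, k] = acc
    return out


class TestResample:
    def test_identity_exact(self, rng):
        v = Volume3D(rng.random((12, 12, 12)))
        g = affine_grid(RotationMatrix(np.eye(3)), v.shape)
        assert np.abs(resample_3d(v, g).data - v.data).max() < 1e-12

    def test_matches_loop_oracle(self, rng):
        v = Volume3D(rng.random((16, 16, 16)))
        g = affine_grid(euler_to_matrix(EulerAngles(17, -42, 63)), (10, 10, 10))
        assert np.abs(resample_3d(v, g).data - loop_trilinear(v.data, g)).max() < 1e-6

    def test_double_180_is_involution(self, rng):
        v = Volume3D(rng.random((16, 16, 16)))
        out = rotate_volume(rotate_volume(v, EulerAngles(180, 0, 0)),
                            EulerAngles(180, 0, 0))
        interior = (slice(2, -2),) * 3
        assert np.abs(out.data[interior] - v.data[interior]).max() < 1e-4

    def test_nearest_keeps_binary(self, rng):
        v = Volume3D((rng.random((16, 16, 16)) > 0.5).astype(float))
        g = affine_grid(euler_to_matrix(EulerAngles(25, 10, -5)), v.shape)
        out = resample_3d(v, g, mode="nearest").data
        assert set(np.unique(out)) <= {0.0, 1.0}

    def test_mass_conserved_for_interior_blob(self, rng):
        n = 32
        ax = np.arange(n) - (n - 1) / 2
        x, y, z = np.meshgrid(ax, ax, ax, indexing="ij")
        blob = np.exp(-(x**2 + y**2 + z**2) / (2 * 4.0**2))
        v = Volume3D(blob)
        out = rotate_volume(v, EulerAngles(35, -50, 20))
        assert abs(out.data.sum() - blob.sum()) / blob.sum() < 0.01

    def test_shape_mismatch_rejected(self, rng):
        v = Volume3D(rng.random((8, 8, 8)))
        with pytest.raises(ValueError):
            resample_3d(v, np.zeros((2, 8, 8, 8)))

    def test_grad_matches_finite_differences(self, rng):
        from scipy.ndimage import gaussian_filter

        v = Volume3D(gaussian_filter(rng.random((12, 12, 12)), 1.5))
        g = affine_grid(euler_to_matrix(EulerAngles(10, 5, -8)), (6, 6, 6))
        out, grad = resample_3d_with_grad(v, g)
        h = 1e-6
        for ax in range(3):
            gp = g.copy()
            gp[ax] += h
            gm = g.copy()
            gm[ax] -= h
            fd = (resample_3d(v, gp).data - resample_3d(v, gm).data) / (2 * h)
            assert np.abs(fd - grad[ax]).max() < 1e-4


class TestRotateVolume:
    def test_zero_angles_identity(self, rng):
        v = Volume3D(rng.random((10, 10, 10)))
        assert np.abs(rotate_volume(v, EulerAngles(0, 0, 0)).data - v.data).max() < 1e-12

    def test_rotate_then_inverse_dice(self):
        n = 48
        ax = np.arange(n) - (n - 1) / 2
        x, y, z = np.meshgrid(ax, ax, ax, indexing="ij")
        mask = ((x / 8) ** 2 + (y / 8) ** 2 + (z / 18) ** 2 <= 1).astype(float)
        v = Volume3D(mask)
        m = euler_to_matrix(EulerAngles(25, -40, 15))
        fwd = rotate_volume_matrix(v, m)
        back = rotate_volume_matrix(fwd, m.transpose())
        a = back.data > 0.5
        b = mask > 0.5
        dice = 2 * (a & b).sum() / (a.sum() + b.sum())
        assert dice >= 0.98

    def test_center_voxel_fixed_point(self):
        v = np.zeros((15, 15, 15))
        v[7, 7, 7] = 1.0
        out = rotate_volume(Volume3D(v), EulerAngles(73, -11, 129))
        assert np.unravel_index(np.argmax(out.data), out.data.shape) == (7, 7, 7)


def loop_bilinear(image, fld):
    h, w = image.shape
    out = np.zeros_like(image, dtype=float)
    for r in range(h):
        for c in range(w):
            fr, fc = r + fld[0, r, c], c + fld[1, r, c]
            r0, c0 = int(np.floor(fr)), int(np.floor(fc))
            dr, dc = fr - r0, fc - c0
            acc = 0.0
            for orr, occ in [(0, 0), (0, 1), (1, 0), (1, 1)]:
                ri, ci = r0 + orr, c0 + occ
                if 0 <= ri < h and 0 <= ci < w:
                    wgt = (dr if orr else 1 - dr) * (dc if occ else 1 - dc)
                    acc += wgt * image[ri, ci]
            out[r, c] = acc
    return out


class TestWarp2D:
    def test_zero_field_identity(self, rng):
        img = rng.random((9, 11))
        assert np.abs(warp_2d(img, np.zeros((2, 9, 11))) - img).max() < 1e-12

    def test_constant_shift_matches_integer_shift(self, rng):
        img = rng.random((10, 10))
        fld = np.zeros((2, 10, 10))
        fld[0] = 1.0  # sample one row down
        out = warp_2d(img, fld)
        assert np.abs(out[:-1] - img[1:]).max() < 1e-12
        assert np.abs(out[-1]).max() < 1e-12  # zero fill at the border

    def test_matches_loop_oracle(self, rng):
        img = rng.random((12, 13))
        fld = rng.normal(0, 1.5, (2, 12, 13))
        assert np.abs(warp_2d(img, fld) - loop_bilinear(img, fld)).max() <= 1e-6

    def test_shape_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            warp_2d(rng.random((8, 8)), np.zeros((2, 9, 9)))

    def test_nearest_binary(self, rng):
        img = (rng.random((12, 12)) > 0.5).astype(float)
        fld = rng.normal(0, 1.0, (2, 12, 12))
        out = warp_2d(img, fld, mode="nearest")
        assert set(np.unique(out)) <= {0.0, 1.0}
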