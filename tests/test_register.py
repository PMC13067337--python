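"""CMR preprocessing and nonrigid registration (classical and learned)."""

import numpy as np
import pytest

from cardiofuse.geometry import warp_2d
from cardiofuse.metrics import dice
from cardiofuse.register import (
    CMRStack,
    SDNConfig,
    SDNModel,
    classical_nonrigid_register,
    crop_to_fov,
    detect_lv_center,
    jacobian_determinant,
    make_pseudo_label_cmr,
    register_cmr,
    rigid_motion_correct,
    select_contrast_frames,
    train_sdn,
    uncrop_from_fov,
)


def ring(size, r_in, r_out, c=None):
    c = c or (size / 2, size / 2)
    rr, cc = np.meshgrid(np.arange(size), np.arange(size), indexing="ij")
    d2 = (rr - c[0]) ** 2 + (cc - c[1]) ** 2
    return ((d2 <= r_out**2) & (d2 > r_in**2)).astype(float)


def disk(size, r, c=None, value=1.0):
    c = c or (size / 2, size / 2)
    rr, cc = np.meshgrid(np.arange(size), np.arange(size), indexing="ij")
    return np.where((rr - c[0]) ** 2 + (cc - c[1]) ** 2 <= r**2, value, 0.0)


def indexed_stack(n_slices=2, n_frames=90, size=16):
    """Frames whose mean encodes the time index, for selection tests."""
    frames = np.zeros((n_slices, n_frames, size, size))
    for t in range(n_frames):
        frames[:, t] = t
    return CMRStack(frames)


class TestSelectContrastFrames:
    def test_identity_when_k_equals_n(self):
        stack = indexed_stack()
        out = select_contrast_frames(stack, stack.n_frames)
        assert np.array_equal(out.frames, stack.frames)

    def test_last_ten_of_ninety(self):
        out = select_contrast_frames(indexed_stack(), 10)
        assert out.n_frames == 10
        assert np.array_equal(np.unique(out.frames), np.arange(80, 90))

    def test_invalid_k_rejected(self):
        with pytest.raises(ValueError):
            select_contrast_frames(indexed_stack(), 0)
        with pytest.raises(ValueError):
            select_contrast_frames(indexed_stack(), 91)


class TestRigidMotionCorrect:
    def _shifted_stack(self, shifts):
        rng = np.random.default_rng(0)
        from scipy.ndimage import gaussian_filter, shift as ndshift

        base = gaussian_filter(disk(48, 10, c=(22, 26)), 1.0)
        base += rng.normal(0, 0.005, base.shape)
        frames = np.stack(
            [ndshift(base, s, order=1) for s in shifts] + [base]
        )
        return CMRStack(frames[None])

    def test_recovers_injected_shifts(self):
        shifts = [(3, -2), (-3, 1), (2, 3)]
        stack = self._shifted_stack(shifts)
        corrected, transforms = rigid_motion_correct(stack)
        for s, t in zip(shifts, transforms[0][:-1]):
            # aligning back needs the opposite displacement
            assert abs(t.shift[0] + s[0]) <= 0.5
            assert abs(t.shift[1] + s[1]) <= 0.5
        assert transforms[0][-1] == transforms[0][-1].__class__()

    def test_aligned_stack_near_identity(self):
        stack = self._shifted_stack([(0, 0), (0, 0)])
        _, transforms = rigid_motion_correct(stack)
        for t in transforms[0]:
            assert abs(t.rotation_deg) <= 0.2
            assert max(abs(t.shift[0]), abs(t.shift[1])) <= 0.2

    def test_constant_frames_warn_identity(self):
        stack = CMRStack(np.zeros((1, 3, 16, 16)))
        with pytest.warns(UserWarning):
            _, transforms = rigid_motion_correct(stack)
        assert all(t.shift == (0.0, 0.0) for t in transforms[0])

    def test_single_frame_rejected(self):
        with pytest.raises(ValueError):
            rigid_motion_correct(CMRStack(np.zeros((1, 1, 8, 8))))


class TestHoughCenter:
    def test_bright_disk_located(self):
        img = disk(80, 12, c=(40, 30))
        center, radius = detect_lv_center(img, (6, 20))
        assert abs(center[0] - 40) <= 1 and abs(center[1] - 30) <= 1
        assert abs(radius - 12) <= 1

    def test_prefers_stronger_circle(self):
        img = disk(96, 12, c=(30, 30)) + disk(96, 6, c=(70, 70), value=0.5)
        center, radius = detect_lv_center(img, (4, 20))
        assert abs(radius - 12) <= 1
        assert abs(center[0] - 30) <= 1

    def test_flat_image_rejected(self):
        with pytest.raises(ValueError, match="circular"):
            detect_lv_center(np.zeros((64, 64)), (4, 20))

    def test_bad_radius_range_rejected(self):
        with pytest.raises(ValueError):
            detect_lv_center(disk(32, 5), (10, 40))


class TestCrop:
    def test_exact_fov_shape(self, rng):
        out = crop_to_fov(rng.random((200, 200)), (100, 100), (105, 75))
        assert out.shape == (105, 75)

    def test_centered_identity(self, rng):
        img = rng.random((21, 21))
        out = crop_to_fov(img, (10, 10), (21, 21))
        assert np.array_equal(out, img)

    def test_corner_zero_padded(self, rng):
        img = rng.random((40, 40))
        out = crop_to_fov(img, (0, 0), (20, 20))
        assert np.all(out[:10, :] == 0) or np.all(out[:, :10] == 0)
        assert out[10:, 10:].max() > 0

    def test_crop_uncrop_lossless_inside_window(self, rng):
        img = rng.random((60, 60))
        center = (25, 33)
        patch = crop_to_fov(img, center, (21, 17))
        back = uncrop_from_fov(patch, center, (60, 60))
        r0, c0 = 25 - 10, 33 - 8
        assert np.array_equal(back[r0:r0 + 21, c0:c0 + 17],
                              img[r0:r0 + 21, c0:c0 + 17])

    def test_invalid_fov_rejected(self, rng):
        with pytest.raises(ValueError):
            crop_to_fov(rng.random((10, 10)), (5, 5), (0, 5))


class TestClassicalRegistration:
    def test_identical_masks_identity_field(self):
        m = ring(64, 10, 16)
        fld = classical_nonrigid_register(m, m.copy())
        assert np.abs(fld).max() <= 0.5
        warped = warp_2d(m, fld, "nearest") > 0.5
        assert dice(warped, m) == 1.0

    def test_thickness_mismatch_harmonized(self):
        moving = ring(64, 10, 18)
        fixed = ring(64, 10, 16)
        assert dice(moving, fixed) <= 0.85
        fld = classical_nonrigid_register(moving, fixed, levels=6, grid_reg=0.6)
        warped = warp_2d(moving, fld, "nearest") > 0.5
        assert dice(warped, fixed) >= 0.90
        jac = jacobian_determinant(fld)
        assert (jac >= 0).mean() >= 0.99

    def test_pyramid_depth_helps_on_large_displacement(self):
        # a radius change this large needs the coarse levels; the easy
        # thickness-only pair converges fully at any depth
        moving = ring(64, 6, 10)
        fixed = ring(64, 12, 18)
        d6 = dice(
            warp_2d(moving, classical_nonrigid_register(moving, fixed, levels=6),
                    "nearest") > 0.5,
            fixed,
        )
        d1 = dice(
            warp_2d(moving, classical_nonrigid_register(moving, fixed, levels=1),
                    "nearest") > 0.5,
            fixed,
        )
        assert d6 >= d1

    def test_never_worsens_overlap(self):
        moving = ring(64, 9, 14, c=(36, 28))
        fixed = ring(64, 10, 16)
        before = dice(moving, fixed)
        fld = classical_nonrigid_register(moving, fixed)
        after = dice(warp_2d(moving, fld, "nearest") > 0.5, fixed)
        assert after >= before

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            classical_nonrigid_register(np.zeros((32, 32)), ring(32, 5, 9))

    def test_zero_field_jacobian_is_one(self):
        jac = jacobian_determinant(np.zeros((2, 16, 16)))
        assert np.allclose(jac, 1.0)


class TestPseudoLabelCMR:
    def test_identical_walls_near_identity(self, rng):
        wall = ring(64, 10, 16)
        slice_img = wall * 0.6 + disk(64, 10, value=0.9)
        warped, fld = make_pseudo_label_cmr(slice_img, wall, wall.copy())
        assert np.abs(warped - slice_img).max() < 0.05

    def test_thickness_pair_overlaps_after(self):
        cmr_wall = ring(64, 10, 17)
        ct_wall = ring(64, 10, 15)
        slice_img = cmr_wall * 0.6
        warped, fld = make_pseudo_label_cmr(slice_img, cmr_wall, ct_wall)
        warped_wall = warp_2d(cmr_wall, fld, "nearest") > 0.5
        assert dice(warped_wall, ct_wall) >= 0.9

    def test_empty_fixed_mask_rejected(self):
        with pytest.raises(ValueError):
            make_pseudo_label_cmr(ring(32, 5, 9), ring(32, 5, 9),
                                  np.zeros((32, 32)))


def tiny_triplets(n, rng, size=32):
    """Shift-only pairs with analytic pseudo-labels (no classical step)."""
    out, masks = [], []
    for _ in range(n):
        shift = rng.integers(-2, 3, 2)
        fixed_wall = ring(size, 6, 10)
        moving_wall = ring(size, 6, 10, c=(size / 2 + shift[0], size / 2 + shift[1]))
        ctca = fixed_wall * 0.45 + disk(size, 6, value=0.9)
        cmr = moving_wall * 0.6 + disk(
            size, 6, c=(size / 2 + shift[0], size / 2 + shift[1]), value=0.9
        )
        pseudo = fixed_wall * 0.6 + disk(size, 6, value=0.9)
        out.append((ctca, cmr, pseudo))
        masks.append({"ctca_wall": fixed_wall, "cmr_wall": moving_wall})
    return out, masks


class TestSDN:
    def test_zero_epochs_returns_initialization(self, rng):
        triplets, _ = tiny_triplets(2, rng)
        model, history = train_sdn(triplets, SDNConfig(epochs=0, seed=1))
        assert history.empty
        # zero-initialized head predicts the identity deformation
        fld = model.predict_field(triplets[0][0], triplets[0][1])
        assert np.abs(fld).max() == 0.0

    def test_loss_decreases(self, rng):
        triplets, _ = tiny_triplets(6, rng)
        _, history = train_sdn(
            triplets, SDNConfig(epochs=5, seed=0, learning_rate=1e-3)
        )
        assert history["loss"].iloc[-1] < history["loss"].iloc[0]

    def test_seeded_determinism(self, rng):
        triplets, _ = tiny_triplets(3, rng)
        _, h1 = train_sdn(triplets, SDNConfig(epochs=2, seed=7))
        _, h2 = train_sdn(triplets, SDNConfig(epochs=2, seed=7))
        assert np.array_equal(h1["loss"].to_numpy(), h2["loss"].to_numpy())

    def test_inference_deterministic_and_shape_checked(self, rng):
        triplets, _ = tiny_triplets(2, rng)
        model, _ = train_sdn(triplets, SDNConfig(epochs=1, seed=0))
        w1, f1 = register_cmr(model, triplets[0][0], triplets[0][1])
        w2, f2 = register_cmr(model, triplets[0][0], triplets[0][1])
        assert np.array_equal(w1, w2) and np.array_equal(f1, f2)
        with pytest.raises(ValueError):
            register_cmr(model, triplets[0][0], triplets[0][1][:16])

    def test_empty_dataset_rejected(self):
        with pytest.raises(ValueError):
            train_sdn([], SDNConfig())

    def test_checkpoint_roundtrip(self, rng, tmp_path):
        triplets, _ = tiny_triplets(2, rng)
        model, _ = train_sdn(triplets, SDNConfig(epochs=1, seed=0))
        path = tmp_path / "sdn.npz"
        model.save(path)
        loaded = SDNModel.load(path)
        f1 = model.predict_field(triplets[0][0], triplets[0][1])
        f2 = loaded.predict_field(triplets[0][0], triplets[0][1])
        assert np.array_equal(f1, f2)
        assert loaded.config == model.config


class TestCMRStackType:
    def test_invalid_dimensions_rejected(self):
        with pytest.raises(ValueError):
            CMRStack(np.zeros((3, 16, 16)))

    def test_invalid_spacing_rejected(self):
        with pytest.raises(ValueError):
            CMRStack(np.zeros((1, 2, 8, 8)), slice_spacing_mm=0.0)

    def test_last_frames_shape(self):
        stack = indexed_stack(n_slices=3, n_frames=5, size=8)
        assert stack.last_frames().shape == (3, 8, 8)
        assert np.all(stack.last_frames() == 4)
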