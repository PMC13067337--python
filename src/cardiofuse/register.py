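"""CMR preprocessing and LV-wall registration.

Covers the classical chain (contrast-frame selection, rigid motion
correction of the perfusion time series, Hough-based LV-center cropping,
multiresolution B-spline nonrigid mask registration producing pseudo-label
CMR) and the learned 2D nonrigid deformation network (SDN) trained under
pseudo-label supervision.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage, optimize
from scipy.interpolate import BSpline
from skimage.transform import hough_circle, hough_circle_peaks, rotate as _sk_rotate

from .geometry import warp_2d, warp_2d_with_grad
from . import _nets

__all__ = [
    "CMRStack",
    "RigidTransform2D",
    "SDNConfig",
    "select_contrast_frames",
    "rigid_motion_correct",
    "detect_lv_center",
    "crop_to_fov",
    "classical_nonrigid_register",
    "make_pseudo_label_cmr",
    "train_sdn",
    "register_cmr",
    "jacobian_determinant",
]


@dataclass
class CMRStack:
    """Short-axis perfusion frames indexed (slice, time); slice 1 is most basal."""

    frames: np.ndarray  # (n_slices, n_frames, H, W)
    slice_spacing_mm: float = 8.0
    pixel_spacing_mm: tuple[float, float] = (1.0, 1.0)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 4:
            raise ValueError("frames must be (n_slices, n_frames, H, W)")
        if self.slice_spacing_mm <= 0 or any(s <= 0 for s in self.pixel_spacing_mm):
            raise ValueError("spacings must be positive")
        self.pixel_spacing_mm = tuple(float(s) for s in self.pixel_spacing_mm)

    @property
    def n_slices(self) -> int:
        return self.frames.shape[0]

    @property
    def n_frames(self) -> int:
        return self.frames.shape[1]

    def last_frames(self) -> np.ndarray:
        """The final (highest-contrast) frame of each slice, shape (n_slices, H, W)."""
        return self.frames[:, -1]


@dataclass(frozen=True)
class RigidTransform2D:
    rotation_deg: float = 0.0
    shift: tuple[float, float] = (0.0, 0.0)


@dataclass
class SDNConfig:
    """Hyper-parameters of the 2D nonrigid deformation network."""

    unet_depth: int = 2
    base_width: int = 8
    smoothness_weight: float = 0.01
    learning_rate: float = 1e-4
    epochs: int = 30
    seed: int = 0

    def __post_init__(self) -> None:
        if self.smoothness_weight < 0:
            raise ValueError("smoothness_weight must be >= 0")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")


def select_contrast_frames(stack: CMRStack, k: int) -> CMRStack:
    """Keep the last ``k`` time points of each slice (the highest-contrast tail)."""
    if k <= 0:
        raise ValueError(f"k must be positive, got {k}")
    if k > stack.n_frames:
        raise ValueError(f"k={k} exceeds n_frames={stack.n_frames}")
    return replace(stack, frames=stack.frames[:, -k:].copy())


def _apply_rigid(img: np.ndarray, t: RigidTransform2D) -> np.ndarray:
    out = img
    if t.rotation_deg != 0.0:
        out = _sk_rotate(out, t.rotation_deg, preserve_range=True, order=1)
    if t.shift != (0.0, 0.0):
        out = ndimage.shift(out, t.shift, order=1, mode="constant", cval=0.0)
    return out


def _best_rigid(moving: np.ndarray, fixed: np.ndarray,
                rot_grid: np.ndarray, shift_max: int) -> RigidTransform2D:
    # coarse grid over rotations; per rotation, best integer shift by
    # FFT cross-correlation, then quadratic sub-pixel refinement
    best = (np.inf, RigidTransform2D())
    for rot in rot_grid:
        m = _sk_rotate(moving, rot, preserve_range=True, order=1) if rot else moving
        corr = np.real(np.fft.ifft2(np.fft.fft2(fixed) * np.conj(np.fft.fft2(m))))
        corr = np.fft.fftshift(corr)
        h, w = corr.shape
        cy, cx = h // 2, w // 2
        win = corr[cy - shift_max:cy + shift_max + 1, cx - shift_max:cx + shift_max + 1]
        iy, ix = np.unravel_index(np.argmax(win), win.shape)
        du, dv = float(iy - shift_max), float(ix - shift_max)
        # sub-pixel: fit a parabola through the correlation peak per axis
        for ax, dlt in ((0, "du"), (1, "dv")):
            i = (iy, ix)[ax]
            if 0 < i < win.shape[ax] - 1:
                if ax == 0:
                    c0, c1, c2 = win[i - 1, ix], win[i, ix], win[i + 1, ix]
                else:
                    c0, c1, c2 = win[iy, i - 1], win[iy, i], win[iy, i + 1]
                denom = c0 - 2 * c1 + c2
                if abs(denom) > 1e-12:
                    frac = 0.5 * (c0 - c2) / denom
                    if dlt == "du":
                        du += float(np.clip(frac, -0.5, 0.5))
                    else:
                        dv += float(np.clip(frac, -0.5, 0.5))
        cand = RigidTransform2D(float(rot), (du, dv))
        mse = float(np.mean((_apply_rigid(moving, cand) - fixed) ** 2))
        if mse < best[0]:
            best = (mse, cand)
    return best[1]


def rigid_motion_correct(
    stack: CMRStack, max_rotation_deg: float = 5.0, max_shift_px: int = 8
) -> tuple[CMRStack, list[list[RigidTransform2D]]]:
    """Rigidly align every frame of each slice to that slice's last frame.

    Search is coarse-to-fine: a rotation grid with FFT-correlation shifts,
    then a refined rotation grid around the coarse optimum.  The reference
    (last) frame always gets the identity transform.
    """
    if stack.n_frames < 2:
        raise ValueError("motion correction needs at least 2 frames")
    out = stack.frames.copy()
    transforms: list[list[RigidTransform2D]] = []
    for s in range(stack.n_slices):
        fixed = stack.frames[s, -1]
        per_slice: list[RigidTransform2D] = []
        degenerate = float(np.ptp(fixed)) < 1e-12
        if degenerate:
            warnings.warn("constant reference frame; returning identity transforms")
        for t in range(stack.n_frames):
            if t == stack.n_frames - 1 or degenerate:
                per_slice.append(RigidTransform2D())
                continue
            moving = stack.frames[s, t]
            if float(np.ptp(moving)) < 1e-12:
                warnings.warn("constant frame; identity transform")
                per_slice.append(RigidTransform2D())
                continue
            coarse = _best_rigid(
                moving, fixed, np.arange(-max_rotation_deg, max_rotation_deg + 1e-9, 2.5),
                max_shift_px,
            )
            fine = _best_rigid(
                moving, fixed,
                coarse.rotation_deg + np.arange(-2.0, 2.0 + 1e-9, 0.5),
                max_shift_px,
            )
            per_slice.append(fine)
            out[s, t] = _apply_rigid(moving, fine)
        transforms.append(per_slice)
    return replace(stack, frames=out), transforms


def detect_lv_center(
    image: np.ndarray, radius_range_px: tuple[int, int], peak_threshold: float = 0.25
) -> tuple[tuple[int, int], int]:
    """Locate the LV by a circular Hough transform on a Sobel edge map."""
    image = np.asarray(image, dtype=float)
    lo, hi = int(radius_range_px[0]), int(radius_range_px[1])
    if lo < 1 or hi <= lo or hi >= min(image.shape):
        raise ValueError(f"invalid radius range {radius_range_px}")
    grad = np.hypot(ndimage.sobel(image, axis=0), ndimage.sobel(image, axis=1))
    if grad.max() <= 1e-12:
        raise ValueError("no circular structure")
    edges = grad > 0.5 * grad.max()
    radii = np.arange(lo, hi + 1)
    acc = hough_circle(edges, radii)
    _accums, cx, cy, rad = hough_circle_peaks(acc, radii, total_num_peaks=1)
    if len(_accums) == 0 or _accums[0] < peak_threshold:
        raise ValueError("no circular structure")
    # hough_circle_peaks returns x=columns, y=rows
    return (int(cy[0]), int(cx[0])), int(rad[0])


def crop_to_fov(
    image: np.ndarray, center: tuple[int, int], fov: tuple[int, int] = (105, 75)
) -> np.ndarray:
    """Fixed-FOV crop centered on ``center``; out-of-bounds regions zero-pad."""
    image = np.asarray(image)
    fh, fw = int(fov[0]), int(fov[1])
    if fh <= 0 or fw <= 0:
        raise ValueError(f"fov must be positive, got {fov}")
    out = np.zeros((fh, fw), dtype=float)
    r0 = int(round(center[0])) - fh // 2
    c0 = int(round(center[1])) - fw // 2
    rs, re = max(r0, 0), min(r0 + fh, image.shape[0])
    cs, ce = max(c0, 0), min(c0 + fw, image.shape[1])
    if rs < re and cs < ce:
        out[rs - r0:re - r0, cs - c0:ce - c0] = image[rs:re, cs:ce]
    return out


def uncrop_from_fov(
    patch: np.ndarray, center: tuple[int, int], out_shape: tuple[int, int]
) -> np.ndarray:
    """Paste a fixed-FOV patch back into a zero canvas (inverse of crop_to_fov)."""
    fh, fw = patch.shape
    out = np.zeros(out_shape, dtype=float)
    r0 = int(round(center[0])) - fh // 2
    c0 = int(round(center[1])) - fw // 2
    rs, re = max(r0, 0), min(r0 + fh, out_shape[0])
    cs, ce = max(c0, 0), min(c0 + fw, out_shape[1])
    if rs < re and cs < ce:
        out[rs:re, cs:ce] = patch[rs - r0:re - r0, cs - c0:ce - c0]
    return out


# ---------------------------------------------------------------------------
# classical multiresolution B-spline mask registration
# ---------------------------------------------------------------------------

def _signed_distance(mask: np.ndarray) -> np.ndarray:
    """Signed distance transform (negative inside) of a binary mask, in pixels."""
    m = mask.astype(bool)
    if not m.any():
        raise ValueError("empty mask")
    inside = ndimage.distance_transform_edt(m)
    outside = ndimage.distance_transform_edt(~m)
    return outside - inside


def _bspline_basis(n_pixels: int, n_ctrl: int) -> np.ndarray:
    """Dense (n_pixels, n_ctrl) cubic B-spline design matrix on a uniform grid."""
    k = 3
    # clamped knot vector covering [0, n_pixels-1]
    inner = np.linspace(0, n_pixels - 1, n_ctrl - k + 1)
    t = np.concatenate([[inner[0]] * k, inner, [inner[-1]] * k])
    x = np.arange(n_pixels, dtype=float)
    mat = BSpline.design_matrix(x, t, k).toarray()
    return mat


def _bending_energy_and_grad(fld: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean squared second finite differences of the field, with its adjoint."""
    energy = 0.0
    grad = np.zeros_like(fld)
    n = fld[0].size
    for comp in range(2):
        for ax in (0, 1):
            d2 = np.diff(fld[comp], n=2, axis=ax)
            energy += float(np.sum(d2**2)) / n
            # adjoint of the second-difference operator
            g = np.zeros_like(fld[comp])
            sl = [slice(None), slice(None)]
            sl_a = list(sl); sl_a[ax] = slice(0, -2)
            sl_b = list(sl); sl_b[ax] = slice(1, -1)
            sl_c = list(sl); sl_c[ax] = slice(2, None)
            g[tuple(sl_a)] += d2
            g[tuple(sl_b)] -= 2 * d2
            g[tuple(sl_c)] += d2
            grad[comp] += 2.0 * g / n
    return energy, grad


def _downsample(img: np.ndarray, factor: int) -> np.ndarray:
    if factor == 1:
        return img
    return ndimage.zoom(img, 1.0 / factor, order=1, grid_mode=True, mode="nearest")


def _register_level(
    moving: np.ndarray,
    fixed: np.ndarray,
    init_field: np.ndarray,
    grid_reg: float,
    ctrl_spacing_px: float = 8.0,
    maxiter: int = 80,
) -> np.ndarray:
    h, w = fixed.shape
    ncu = max(4, int(round(h / ctrl_spacing_px)) + 3)
    ncv = max(4, int(round(w / ctrl_spacing_px)) + 3)
    bu = _bspline_basis(h, ncu)
    bv = _bspline_basis(w, ncv)
    # least-squares projection of the initial field onto the control grid
    pu = np.linalg.pinv(bu)
    pv = np.linalg.pinv(bv)
    c0 = np.stack([pu @ init_field[i] @ pv.T for i in range(2)])

    npix = fixed.size

    def objective(cflat: np.ndarray):
        c = cflat.reshape(2, ncu, ncv)
        fld = np.stack([bu @ c[i] @ bv.T for i in range(2)])
        warped, d_du, d_dv = warp_2d_with_grad(moving, fld)
        resid = warped - fixed
        mse = float(np.mean(resid**2))
        dmse = 2.0 * resid / npix
        gfield = np.stack([dmse * d_du, dmse * d_dv])
        bend, gbend = _bending_energy_and_grad(fld)
        gfield = gfield + grid_reg * gbend
        gc = np.stack([bu.T @ gfield[i] @ bv for i in range(2)])
        return mse + grid_reg * bend, gc.ravel()

    res = optimize.minimize(
        objective, c0.ravel(), jac=True, method="L-BFGS-B",
        options={"maxiter": maxiter, "ftol": 1e-12, "gtol": 1e-10},
    )
    c = res.x.reshape(2, ncu, ncv)
    return np.stack([bu @ c[i] @ bv.T for i in range(2)])


def classical_nonrigid_register(
    moving_mask: np.ndarray,
    fixed_mask: np.ndarray,
    levels: int = 6,
    grid_reg: float = 0.6,
) -> np.ndarray:
    """Multiresolution cubic B-spline free-form deformation between binary masks.

    Binary masks are softened to signed distance maps before the MSE term
    (binary MSE has zero gradient almost everywhere); the objective is
    ``MSE + grid_reg * bending_energy``.  The returned dense field never
    worsens mask overlap: if the optimum would, the zero field is returned.
    """
    moving_mask = np.asarray(moving_mask)
    fixed_mask = np.asarray(fixed_mask)
    if moving_mask.shape != fixed_mask.shape:
        raise ValueError("mask shapes differ")
    if levels < 1:
        raise ValueError("levels must be >= 1")
    # distance maps saturate a few wall-thicknesses out so the data term
    # concentrates near the boundary; dividing by the cap makes grid_reg
    # dimensionless
    cap = 8.0
    sd_m = np.clip(_signed_distance(moving_mask), -cap, cap) / cap
    sd_f = np.clip(_signed_distance(fixed_mask), -cap, cap) / cap

    h, w = fixed_mask.shape
    # centroid pre-alignment absorbs any residual bulk shift (the pipeline
    # crops both modalities about the LV center, so this is normally small)
    com_m = ndimage.center_of_mass(moving_mask > 0.5)
    com_f = ndimage.center_of_mass(fixed_mask > 0.5)
    fld = np.zeros((2, h, w))
    fld[0] += com_m[0] - com_f[0]
    fld[1] += com_m[1] - com_f[1]
    for lev in range(levels - 1, -1, -1):
        factor = 2**lev
        if min(h, w) // factor < 8:
            continue
        m_l = _downsample(sd_m, factor)
        f_l = _downsample(sd_f, factor)
        init = np.stack(
            [_downsample(fld[i], factor) for i in range(2)]
        ) / factor
        fld_l = _register_level(m_l, f_l, init, grid_reg)
        fld = np.stack(
            [
                ndimage.zoom(fld_l[i] * factor,
                             (h / fld_l.shape[1], w / fld_l.shape[2]),
                             order=1, mode="nearest")
                for i in range(2)
            ]
        )

    from .metrics import dice  # local import to avoid a cycle

    before = dice(moving_mask > 0.5, fixed_mask > 0.5)
    warped = warp_2d(moving_mask.astype(float), fld, mode="nearest") > 0.5
    after = dice(warped, fixed_mask > 0.5)
    if after < before:
        return np.zeros_like(fld)
    return fld


def jacobian_determinant(fld: np.ndarray) -> np.ndarray:
    """Per-pixel Jacobian determinant of the map ``p -> p + field(p)``."""
    du_dr, du_dc = np.gradient(fld[0])
    dv_dr, dv_dc = np.gradient(fld[1])
    return (1.0 + du_dr) * (1.0 + dv_dc) - du_dc * dv_dr


def make_pseudo_label_cmr(
    cmr_slice: np.ndarray,
    cmr_wall_mask: np.ndarray,
    ctca_wall_mask: np.ndarray,
    levels: int = 6,
    grid_reg: float = 0.6,
) -> tuple[np.ndarray, np.ndarray]:
    """Warp a CMR slice so its LV wall matches the CTCA wall mask.

    The deformation is estimated between the wall masks only and then applied
    to the CMR intensity slice; the warped slice is the SDN's training target.
    """
    if not np.asarray(ctca_wall_mask).any():
        raise ValueError("empty mask")
    fld = classical_nonrigid_register(cmr_wall_mask, ctca_wall_mask,
                                      levels=levels, grid_reg=grid_reg)
    return warp_2d(cmr_slice, fld), fld


# ---------------------------------------------------------------------------
# learned 2D nonrigid deformation network (SDN)
# ---------------------------------------------------------------------------

@dataclass
class SDNModel:
    """U-Net deformation predictor plus its training configuration."""

    net: _nets.UNet2D
    config: SDNConfig

    def predict_field(self, ctca_slice: np.ndarray, cmr_slice: np.ndarray) -> np.ndarray:
        x = np.stack([np.asarray(ctca_slice, float), np.asarray(cmr_slice, float)])
        fld, _cache = self.net.forward(x)
        return fld

    def save(self, path) -> None:
        self.net.save(path, extra={"sdn_config": self.config.__dict__})

    @classmethod
    def load(cls, path) -> "SDNModel":
        net, extra = _nets.UNet2D.load(path)
        return cls(net, SDNConfig(**extra["sdn_config"]))


def _smoothness(fld: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean squared first differences of the field, with gradient."""
    energy = 0.0
    grad = np.zeros_like(fld)
    n = fld[0].size
    for comp in range(2):
        for ax in (0, 1):
            d = np.diff(fld[comp], axis=ax)
            energy += float(np.sum(d**2)) / n
            g = np.zeros_like(fld[comp])
            sl_a = [slice(None)] * 2
            sl_b = [slice(None)] * 2
            sl_a[ax] = slice(0, -1)
            sl_b[ax] = slice(1, None)
            g[tuple(sl_a)] -= d
            g[tuple(sl_b)] += d
            grad[comp] += 2.0 * g / n
    return energy, grad


def train_sdn(
    dataset: list[tuple[np.ndarray, np.ndarray, np.ndarray]],
    config: SDNConfig,
) -> tuple[SDNModel, "pd.DataFrame"]:
    """Train the SDN on (ctca_slice, cmr_slice, pseudo_label_cmr) triplets.

    The network sees the concatenated fixed (CTCA) and moving (CMR) slices and
    predicts a dense displacement field; the loss is the MSE between the
    warped CMR and the pseudo-label CMR plus a small field-smoothness penalty.
    """
    import pandas as pd

    if not dataset:
        raise ValueError("empty dataset")
    shapes = {tuple(np.asarray(c).shape) for c, m, p in dataset}
    if len(shapes) != 1:
        raise ValueError("all slices must share one shape")

    rng = np.random.default_rng(config.seed)
    net = _nets.UNet2D(
        in_channels=2, out_channels=2, base_width=config.base_width,
        depth=config.unet_depth, rng=rng,
    )
    opt = _nets.Adam(net.parameters(), lr=config.learning_rate)
    history = []
    n = len(dataset)
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        losses = []
        for i in order:
            ctca, cmr, pseudo = (np.asarray(a, float) for a in dataset[i])
            x = np.stack([ctca, cmr])
            fld, cache = net.forward(x)
            warped, d_du, d_dv = warp_2d_with_grad(cmr, fld)
            resid = warped - pseudo
            mse = float(np.mean(resid**2))
            dmse = 2.0 * resid / resid.size
            gfield = np.stack([dmse * d_du, dmse * d_dv])
            smooth, gsmooth = _smoothness(fld)
            loss = mse + config.smoothness_weight * smooth
            if not np.isfinite(loss):
                raise FloatingPointError("NaN loss during SDN training")
            gfield = gfield + config.smoothness_weight * gsmooth
            grads = net.backward(gfield, cache)
            opt.step(grads)
            losses.append(loss)
        history.append({"epoch": epoch, "loss": float(np.mean(losses))})
    return SDNModel(net, config), pd.DataFrame(history, columns=["epoch", "loss"])


def register_cmr(
    model: SDNModel, ctca_slice: np.ndarray, cmr_slice: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Predict the LV-wall-registered CMR slice and the deformation field."""
    ctca_slice = np.asarray(ctca_slice, float)
    cmr_slice = np.asarray(cmr_slice, float)
    if ctca_slice.shape != cmr_slice.shape:
        raise ValueError("slice shapes differ")
    fld = model.predict_field(ctca_slice, cmr_slice)
    return warp_2d(cmr_slice, fld), fld
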