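"""Rotation algebra, sampling grids, and 3D/2D resampling.

The package-wide axis-role convention is: array index 0 = axial (S-I),
index 1 = coronal (A-P), index 2 = sagittal (R-L).  A "short-axis slice"
is therefore a fixed-index-2 (sagittal-plane) slice.

Rotation semantics: :func:`rotate_volume` resamples the input on the grid
``g(v) = M @ n(v)`` where ``n(v)`` is the normalized coordinate of output
voxel ``v`` ([-1, 1] spans the centers of the first/last voxels, 0 is the
geometric volume center).  The sampled *content* therefore appears rotated
by ``M^-1``; composing a rotation with its transpose is the identity.
Rotations are about the volume center and carry no translation component.

Angles are degrees at every public surface; radians are internal only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Volume3D",
    "EulerAngles",
    "RotationMatrix",
    "euler_to_matrix",
    "rotation_about_axis",
    "matrix_to_world",
    "affine_grid",
    "resample_3d",
    "resample_3d_with_grad",
    "euler_derivatives",
    "rotate_volume",
    "rotate_volume_matrix",
    "warp_2d",
]

_ORTHO_TOL = 1e-9


@dataclass
class Volume3D:
    """A 3D scalar image with per-axis voxel spacing in millimeters."""

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"Volume3D requires 3D data, got {self.data.ndim}D")
        self.spacing = tuple(float(s) for s in self.spacing)
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"non-positive spacing {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def copy(self) -> "Volume3D":
        return Volume3D(self.data.copy(), self.spacing)


def _canonical_deg(x: float) -> float:
    """Wrap an angle into [-180, 180]."""
    x = float(x)
    if not np.isfinite(x):
        raise ValueError(f"non-finite angle {x}")
    wrapped = (x + 180.0) % 360.0 - 180.0
    # keep +180 as +180 rather than -180
    if wrapped == -180.0 and x > 0:
        wrapped = 180.0
    return wrapped


@dataclass(frozen=True)
class EulerAngles:
    """Reorientation angles (alpha, beta, gamma) in degrees, each in [-180, 180]."""

    alpha_deg: float
    beta_deg: float
    gamma_deg: float

    def __post_init__(self) -> None:
        for name in ("alpha_deg", "beta_deg", "gamma_deg"):
            object.__setattr__(self, name, _canonical_deg(getattr(self, name)))

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.alpha_deg, self.beta_deg, self.gamma_deg)


@dataclass(frozen=True)
class RotationMatrix:
    """A proper rotation: orthonormal 3x3 with determinant +1."""

    m: np.ndarray = field(default_factory=lambda: np.eye(3))

    def __post_init__(self) -> None:
        m = np.asarray(self.m, dtype=float)
        if m.shape != (3, 3):
            raise ValueError(f"rotation matrix must be 3x3, got {m.shape}")
        if not np.allclose(m.T @ m, np.eye(3), atol=1e-8):
            raise ValueError("matrix is not orthonormal")
        if not np.isclose(np.linalg.det(m), 1.0, atol=1e-8):
            raise ValueError("matrix determinant is not +1")
        object.__setattr__(self, "m", m)

    def transpose(self) -> "RotationMatrix":
        return RotationMatrix(self.m.T)

    def to_json(self) -> list[float]:
        return [float(x) for x in self.m.ravel()]

    @classmethod
    def from_json(cls, values) -> "RotationMatrix":
        return cls(np.asarray(values, dtype=float).reshape(3, 3))


def _ry(rad: float) -> np.ndarray:
    c, s = np.cos(rad), np.sin(rad)
    return np.array([[c, 0.0, s], [0.0, 1.0, 0.0], [-s, 0.0, c]])


def _rx(rad: float) -> np.ndarray:
    c, s = np.cos(rad), np.sin(rad)
    return np.array([[1.0, 0.0, 0.0], [0.0, c, -s], [0.0, s, c]])


def _rz(rad: float) -> np.ndarray:
    c, s = np.cos(rad), np.sin(rad)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def euler_to_matrix(
    angles: EulerAngles, convention: str = "as_printed_yxz"
) -> RotationMatrix:
    """Compose the reorientation rotation R(alpha, beta, gamma).

    ``as_printed_yxz`` (default) composes Ry(alpha) @ Rx(beta) @ Rz(gamma);
    ``yxy`` composes Ry(alpha) @ Rx(beta) @ Ry(gamma).  Both conventions are
    exposed because the two readings differ only in the third factor's axis.
    """
    a, b, g = (np.deg2rad(v) for v in angles.as_tuple())
    if convention == "as_printed_yxz":
        third = _rz(g)
    elif convention == "yxy":
        third = _ry(g)
    else:
        raise ValueError(f"unknown euler convention {convention!r}")
    return RotationMatrix(_ry(a) @ _rx(b) @ third)


def rotation_about_axis(axis: int, angle_deg: float) -> RotationMatrix:
    """Elementary rotation about one array axis (0 axial, 1 coronal, 2 sagittal).

    Rotating about axis 0 moves content within the axial (coronal-sagittal)
    plane, about axis 1 within the coronal (axial-sagittal) plane.
    """
    rad = np.deg2rad(angle_deg)
    if axis == 0:
        return RotationMatrix(_rx(rad))
    if axis == 1:
        return RotationMatrix(_ry(rad))
    if axis == 2:
        return RotationMatrix(_rz(rad))
    raise ValueError(f"axis must be 0, 1 or 2, got {axis}")


def _half_extents_mm(shape, spacing) -> np.ndarray:
    # [-1, 1] spans voxel centers, so the physical half-extent is (N-1)*s/2;
    # degenerate single-voxel axes get a unit extent to stay invertible.
    return np.array(
        [max(n - 1, 1) * s / 2.0 for n, s in zip(shape, spacing)], dtype=float
    )


def matrix_to_world(
    matrix: RotationMatrix,
    spacing: tuple[float, float, float],
    shape: tuple[int, int, int] | None = None,
) -> np.ndarray:
    """Re-express a rotation for the normalized-grid sampler in world (mm) space.

    The sampler works in normalized coordinates where each axis is squashed to
    [-1, 1]; a rotation applied there is rigid in millimeters only when the
    physical half-extents of all axes agree.  This returns ``S^-1 R S`` with
    ``S`` the per-axis half-extent scaling, so the transform is rigid in mm
    even for anisotropic voxels.  For isotropic spacing on a cubic grid the
    input matrix is returned unchanged.  The result is a plain 3x3 array: for
    anisotropic voxels it is no longer orthonormal in normalized coordinates.
    """
    spacing = tuple(float(s) for s in spacing)
    if any(s <= 0 for s in spacing):
        raise ValueError(f"non-positive spacing {spacing}")
    if shape is None:
        h = np.asarray(spacing, dtype=float)
    else:
        h = _half_extents_mm(shape, spacing)
    if np.allclose(h, h[0]):
        return np.asarray(matrix.m, dtype=float)
    s = np.diag(h)
    s_inv = np.diag(1.0 / h)
    return s_inv @ matrix.m @ s


def affine_grid(matrix: RotationMatrix | np.ndarray, out_shape) -> np.ndarray:
    """Sampling grid ``g(v) = M @ n(v)`` about the volume center, no translation.

    Returns an array of shape ``(3,) + out_shape`` holding, for each output
    voxel, the normalized source coordinate to sample.
    """
    out_shape = tuple(int(n) for n in out_shape)
    if len(out_shape) != 3 or any(n <= 0 for n in out_shape):
        raise ValueError(f"invalid output shape {out_shape}")
    m = matrix.m if isinstance(matrix, RotationMatrix) else np.asarray(matrix, float)
    axes = [
        np.linspace(-1.0, 1.0, n) if n > 1 else np.zeros(1) for n in out_shape
    ]
    n0, n1, n2 = np.meshgrid(*axes, indexing="ij")
    coords = np.stack([n0, n1, n2])  # (3, *out_shape)
    return np.tensordot(m, coords, axes=([1], [0]))


def _normalized_to_index(grid: np.ndarray, shape) -> np.ndarray:
    idx = np.empty_like(grid)
    for ax, n in enumerate(shape):
        if n > 1:
            idx[ax] = (grid[ax] + 1.0) * (n - 1) / 2.0
        else:
            idx[ax] = grid[ax] * 0.0
    return idx


def _gather_corners(data: np.ndarray, f: np.ndarray):
    """Pad-by-one zero border so out-of-bounds clipping lands on zeros."""
    padded = np.pad(np.asarray(data, dtype=float), 1)
    c0 = np.floor(f).astype(np.int64)
    d = f - c0
    # shift into padded index space and clip; anything outside [-1, N] clips
    # into the zero border, which is the fill value anyway
    idx = [np.clip(c0[ax] + 1, 0, data.shape[ax] + 1) for ax in range(3)]
    idx1 = [np.clip(c0[ax] + 2, 0, data.shape[ax] + 1) for ax in range(3)]
    strides = (
        (data.shape[1] + 2) * (data.shape[2] + 2),
        data.shape[2] + 2,
        1,
    )
    flat = padded.ravel()
    vals = {}
    for corner in range(8):
        offs = [(corner >> ax) & 1 for ax in range(3)]
        lin = sum(
            (idx1[ax] if offs[ax] else idx[ax]) * strides[ax] for ax in range(3)
        )
        vals[tuple(offs)] = flat[lin]
    return vals, d


def resample_3d(volume: Volume3D, grid: np.ndarray, mode: str = "trilinear") -> Volume3D:
    """Sample a volume on a normalized grid; out-of-bounds voxels fill with 0."""
    data = volume.data
    grid = np.asarray(grid, dtype=float)
    if grid.ndim != 4 or grid.shape[0] != 3:
        raise ValueError(f"grid must have shape (3, i, j, k), got {grid.shape}")
    f = _normalized_to_index(grid, data.shape)
    out_shape = grid.shape[1:]

    if mode == "nearest":
        idx = np.rint(f).astype(np.int64)
        valid = np.ones(out_shape, dtype=bool)
        for ax, n in enumerate(data.shape):
            valid &= (idx[ax] >= 0) & (idx[ax] < n)
        idx_c = [np.clip(idx[ax], 0, data.shape[ax] - 1) for ax in range(3)]
        out = np.where(valid, data[idx_c[0], idx_c[1], idx_c[2]], 0)
        return Volume3D(out.astype(data.dtype, copy=False), volume.spacing)

    if mode != "trilinear":
        raise ValueError(f"unknown mode {mode!r}")

    v, d = _gather_corners(data, f)
    d0, d1, d2 = d
    e0, e1, e2 = 1.0 - d0, 1.0 - d1, 1.0 - d2
    out = (
        e0 * (e1 * (e2 * v[0, 0, 0] + d2 * v[0, 0, 1])
              + d1 * (e2 * v[0, 1, 0] + d2 * v[0, 1, 1]))
        + d0 * (e1 * (e2 * v[1, 0, 0] + d2 * v[1, 0, 1])
                + d1 * (e2 * v[1, 1, 0] + d2 * v[1, 1, 1]))
    )
    return Volume3D(out, volume.spacing)


def resample_3d_with_grad(volume: Volume3D, grid: np.ndarray):
    """Trilinear resample plus ∂out/∂grid (normalized coordinates).

    Returns ``(out, grad)`` with ``grad`` of shape ``(3,) + out_shape``; this
    is the sampler's backward pass needed to train the reorientation
    spatial transformer.
    """
    data = volume.data
    grid = np.asarray(grid, dtype=float)
    f = _normalized_to_index(grid, data.shape)
    v, d = _gather_corners(data, f)
    d0, d1, d2 = d
    e0, e1, e2 = 1.0 - d0, 1.0 - d1, 1.0 - d2
    # interpolate pairwise along axis 2, then 1, then 0, keeping partials
    a00 = e2 * v[0, 0, 0] + d2 * v[0, 0, 1]
    a01 = e2 * v[0, 1, 0] + d2 * v[0, 1, 1]
    a10 = e2 * v[1, 0, 0] + d2 * v[1, 0, 1]
    a11 = e2 * v[1, 1, 0] + d2 * v[1, 1, 1]
    b0 = e1 * a00 + d1 * a01
    b1 = e1 * a10 + d1 * a11
    out = e0 * b0 + d0 * b1
    g0 = b1 - b0
    g1 = e0 * (a01 - a00) + d0 * (a11 - a10)
    g2 = (
        e0 * (e1 * (v[0, 0, 1] - v[0, 0, 0]) + d1 * (v[0, 1, 1] - v[0, 1, 0]))
        + d0 * (e1 * (v[1, 0, 1] - v[1, 0, 0]) + d1 * (v[1, 1, 1] - v[1, 1, 0]))
    )
    # chain rule index -> normalized coordinate
    scale = [
        (n - 1) / 2.0 if n > 1 else 0.0 for n in data.shape
    ]
    grad = np.stack([g0 * scale[0], g1 * scale[1], g2 * scale[2]])
    return Volume3D(out, volume.spacing), grad


def euler_derivatives(
    angles: EulerAngles, convention: str = "as_printed_yxz"
) -> list[np.ndarray]:
    """Derivatives dM/d(angle) of :func:`euler_to_matrix`, per degree."""
    a, b, g = (np.deg2rad(v) for v in angles.as_tuple())
    ca, sa = np.cos(a), np.sin(a)
    cb, sb = np.cos(b), np.sin(b)
    cg, sg = np.cos(g), np.sin(g)
    dry = np.array([[-sa, 0, ca], [0, 0, 0], [-ca, 0, -sa]])
    drx = np.array([[0, 0, 0], [0, -sb, -cb], [0, cb, -sb]])
    ry, rx = _ry(a), _rx(b)
    if convention == "as_printed_yxz":
        third = _rz(g)
        dthird = np.array([[-sg, -cg, 0], [cg, -sg, 0], [0, 0, 0]])
    elif convention == "yxy":
        third = _ry(g)
        dthird = np.array([[-sg, 0, cg], [0, 0, 0], [-cg, 0, -sg]])
    else:
        raise ValueError(f"unknown euler convention {convention!r}")
    k = np.pi / 180.0
    return [
        k * (dry @ rx @ third),
        k * (ry @ drx @ third),
        k * (ry @ rx @ dthird),
    ]


def rotate_volume_matrix(
    volume: Volume3D, matrix: RotationMatrix, mode: str = "trilinear"
) -> Volume3D:
    """Resample with ``g(v) = A @ n(v)`` where A is the world-corrected matrix."""
    a = matrix_to_world(matrix, volume.spacing, volume.shape)
    grid = affine_grid(a, volume.shape)
    return resample_3d(volume, grid, mode=mode)


def rotate_volume(
    volume: Volume3D,
    angles: EulerAngles,
    mode: str = "trilinear",
    convention: str = "as_printed_yxz",
) -> Volume3D:
    """Rotate a volume about its center by the given reorientation angles."""
    return rotate_volume_matrix(volume, euler_to_matrix(angles, convention), mode=mode)


def warp_2d(image: np.ndarray, fld: np.ndarray, mode: str = "bilinear") -> np.ndarray:
    """Warp a 2D image: ``out(p) = image(p + field(p))``, zero fill outside.

    ``field`` has shape (2, H, W) in pixels: component 0 displaces rows,
    component 1 displaces columns.
    """
    image = np.asarray(image, dtype=float)
    fld = np.asarray(fld, dtype=float)
    if image.ndim != 2:
        raise ValueError("image must be 2D")
    if fld.shape != (2,) + image.shape:
        raise ValueError(f"field shape {fld.shape} does not match image {image.shape}")
    h, w = image.shape
    rr, cc = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
    fr = rr + fld[0]
    fc = cc + fld[1]

    if mode == "nearest":
        ir = np.rint(fr).astype(np.int64)
        ic = np.rint(fc).astype(np.int64)
        valid = (ir >= 0) & (ir < h) & (ic >= 0) & (ic < w)
        out = np.where(
            valid, image[np.clip(ir, 0, h - 1), np.clip(ic, 0, w - 1)], 0.0
        )
        return out
    if mode != "bilinear":
        raise ValueError(f"unknown mode {mode!r}")

    r0 = np.floor(fr).astype(np.int64)
    c0 = np.floor(fc).astype(np.int64)
    dr = fr - r0
    dc = fc - c0
    out = np.zeros_like(image, dtype=float)
    for orr in (0, 1):
        for occ in (0, 1):
            ri = r0 + orr
            ci = c0 + occ
            wgt = (dr if orr else 1.0 - dr) * (dc if occ else 1.0 - dc)
            valid = (ri >= 0) & (ri < h) & (ci >= 0) & (ci < w)
            out += wgt * np.where(
                valid, image[np.clip(ri, 0, h - 1), np.clip(ci, 0, w - 1)], 0.0
            )
    return out


def warp_2d_with_grad(image: np.ndarray, fld: np.ndarray):
    """Bilinear warp plus its partial derivatives w.r.t. the field components.

    Returns ``(out, d_out/d_du, d_out/d_dv)``; used by the registration
    optimizers, which need analytic gradients through the sampler.
    """
    image = np.asarray(image, dtype=float)
    h, w = image.shape
    rr, cc = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
    fr = rr + fld[0]
    fc = cc + fld[1]
    r0 = np.floor(fr).astype(np.int64)
    c0 = np.floor(fc).astype(np.int64)
    dr = fr - r0
    dc = fc - c0

    vals = {}
    for orr in (0, 1):
        for occ in (0, 1):
            ri = r0 + orr
            ci = c0 + occ
            valid = (ri >= 0) & (ri < h) & (ci >= 0) & (ci < w)
            vals[(orr, occ)] = np.where(
                valid, image[np.clip(ri, 0, h - 1), np.clip(ci, 0, w - 1)], 0.0
            )
    v00, v01 = vals[(0, 0)], vals[(0, 1)]
    v10, v11 = vals[(1, 0)], vals[(1, 1)]
    out = (
        v00 * (1 - dr) * (1 - dc)
        + v01 * (1 - dr) * dc
        + v10 * dr * (1 - dc)
        + v11 * dr * dc
    )
    d_du = (v10 - v00) * (1 - dc) + (v11 - v01) * dc
    d_dv = (v01 - v00) * (1 - dr) + (v11 - v10) * dr
    return out, d_du, d_dv
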