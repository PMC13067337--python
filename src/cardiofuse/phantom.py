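"""Seeded synthetic cardiac phantom: CTCA-like volumes, masks, CMR-like stacks.

The phantom emulates the acquisition geometry the pipeline assumes: a
contrast-CT-like volume containing a truncated prolate-ellipsoid LV (bright
cavity, intermediate wall, dark background), an RV crescent abutting the
wall, a coronary tube on the epicardial surface, and a 3-slice x N-frame
short-axis CMR perfusion stack with a smooth enhancement time course, a
modality-dependent (thicker) LV wall, and a configurable hypoperfused
sector.  Geometry is evaluated analytically at the requested orientation,
so masks are crisp at any rotation and outputs are bit-deterministic for a
fixed config and seed.

Canonical (unrotated) frame: the LV long axis lies along array index 2
(the sagittal, R-L axis) with the apex toward increasing sagittal index;
``long_axis_orientation`` tilts the anatomy exactly as
:func:`cardiofuse.geometry.rotate_volume` would.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .geometry import EulerAngles, Volume3D, euler_to_matrix, rotate_volume
from .register import CMRStack

__all__ = [
    "PhantomConfig",
    "PhantomSample",
    "make_phantom",
    "apply_random_rotation",
    "make_rotated_dataset",
    "write_sample",
]

# synthetic look-alike intensity levels (post min-max normalization scale)
_BG = 0.05
_CT_CAVITY = 0.90
_CT_WALL = 0.45
_CT_RV = 0.65
_CT_CORONARY = 0.85
_CAVITY_TRUNCATION = 0.55  # basal truncation plane at -0.55 * long semi-axis


@dataclass
class PhantomConfig:
    """All knobs of the synthetic heart; defaults mirror the emulated protocol."""

    grid_size: int = 96
    voxel_spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    lv_long_semiaxis_mm: float = 32.0
    lv_short_semiaxis_mm: float = 15.0
    wall_thickness_mm: float = 5.0
    wall_thickness_cmr_scale: float = 1.25
    long_axis_orientation: EulerAngles = field(
        default_factory=lambda: EulerAngles(0.0, 0.0, 0.0)
    )
    coronary_radius_mm: float = 1.8
    deficit_sector: tuple[float, float, float] = (0.0, 90.0, 0.5)
    noise_sigma: float = 0.01
    n_frames: int = 90
    n_slices: int = 3
    cmr_slice_spacing_mm: float = 8.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "lv_long_semiaxis_mm", "lv_short_semiaxis_mm", "wall_thickness_mm",
            "coronary_radius_mm", "cmr_slice_spacing_mm",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.wall_thickness_cmr_scale <= 0:
            raise ValueError("wall_thickness_cmr_scale must be positive")
        if not 0.0 <= self.deficit_sector[2] <= 1.0:
            raise ValueError("hypoperfusion fraction must be in [0, 1]")
        if self.n_slices < 1:
            raise ValueError("n_slices must be >= 1")
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if isinstance(self.long_axis_orientation, (tuple, list)):
            self.long_axis_orientation = EulerAngles(*self.long_axis_orientation)
        self.voxel_spacing_mm = tuple(float(s) for s in self.voxel_spacing_mm)

    def to_json(self) -> dict:
        d = dataclasses.asdict(self)
        d["long_axis_orientation"] = list(self.long_axis_orientation.as_tuple())
        return d

    @classmethod
    def from_json(cls, d: dict) -> "PhantomConfig":
        d = dict(d)
        if "long_axis_orientation" in d:
            d["long_axis_orientation"] = EulerAngles(*d["long_axis_orientation"])
        for key in ("voxel_spacing_mm", "deficit_sector"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class PhantomSample:
    """One synthetic study: CT volume, masks, CMR stack, and ground truth."""

    ctca: Volume3D
    lv_cavity_mask: Volume3D
    lv_wall_mask: Volume3D
    coronary_mask: Volume3D
    cmr_stack: CMRStack
    cmr_wall_masks: list[np.ndarray]
    cmr_cavity_masks: list[np.ndarray]
    perfusion_map: list[np.ndarray]
    perfusion_volume: Volume3D
    true_orientation: EulerAngles
    cmr_slice_positions_mm: list[float]
    config: "PhantomConfig | None" = None


def _canonical_coords(config: PhantomConfig) -> np.ndarray:
    """World-mm coordinates of every voxel, rotated into the canonical frame."""
    n = config.grid_size
    sp = config.voxel_spacing_mm
    ax = [(np.arange(n) - (n - 1) / 2.0) * sp[i] for i in range(3)]
    x0, x1, x2 = np.meshgrid(*ax, indexing="ij")
    x = np.stack([x0, x1, x2])
    m = euler_to_matrix(config.long_axis_orientation).m
    return np.tensordot(m, x, axes=([1], [0]))


def _lv_shapes(u: np.ndarray, a: float, b: float, t: float):
    """Cavity / wall membership of canonical coordinates for wall thickness t."""
    cavity = (u[0] / b) ** 2 + (u[1] / b) ** 2 + (u[2] / a) ** 2 <= 1.0
    outer = (u[0] / (b + t)) ** 2 + (u[1] / (b + t)) ** 2 + (u[2] / (a + t)) ** 2 <= 1.0
    keep = u[2] >= -_CAVITY_TRUNCATION * a
    cavity &= keep
    wall = outer & ~cavity & keep
    return cavity, wall


def _coronary_curve(config: PhantomConfig, n_points: int = 240) -> np.ndarray:
    """A tubular artery's centerline on the epicardial surface (canonical mm)."""
    a = config.lv_long_semiaxis_mm + config.wall_thickness_mm
    b = config.lv_short_semiaxis_mm + config.wall_thickness_mm
    s = np.linspace(-_CAVITY_TRUNCATION * a * 0.95, 0.92 * a, n_points)
    phi = 0.6 + 1.1 * s / a  # gentle azimuthal drift, LAD-like course
    r = b * np.sqrt(np.clip(1.0 - (s / a) ** 2, 0.0, None))
    return np.stack([r * np.cos(phi), r * np.sin(phi), s], axis=1)


def _enhancement_curve(n_frames: int) -> np.ndarray:
    """Smooth first-pass-like enhancement, strictly non-decreasing to the end."""
    t = np.arange(n_frames, dtype=float) / max(n_frames - 1, 1)
    logistic = 1.0 / (1.0 + np.exp(-(t - 0.35) / 0.08))
    curve = 0.97 * (logistic - logistic[0]) / (logistic[-1] - logistic[0])
    return curve + 0.03 * t  # small upward drift keeps the plateau monotone


def _sector_mask(u0: np.ndarray, u1: np.ndarray, sector) -> np.ndarray:
    center_deg, width_deg, _frac = sector
    phi = np.rad2deg(np.arctan2(u1, u0))
    diff = (phi - center_deg + 180.0) % 360.0 - 180.0
    return np.abs(diff) <= width_deg / 2.0


def _slice_positions(config: PhantomConfig) -> list[float]:
    """Sagittal mm positions of the CMR slices, most basal first.

    Slice 1 sits at the basal-most position where the cavity cross-section
    keeps >= 50% of its maximal area (the same anchor rule the cross-modal
    slice mapping uses); later slices step toward the apex.
    """
    a = config.lv_long_semiaxis_mm
    base = max(-_CAVITY_TRUNCATION * a, -a / np.sqrt(2.0))
    return [base + k * config.cmr_slice_spacing_mm for k in range(config.n_slices)]


def make_phantom(config: PhantomConfig) -> PhantomSample:
    """Generate one synthetic study from the config (bit-deterministic)."""
    a = config.lv_long_semiaxis_mm
    b = config.lv_short_semiaxis_mm
    t = config.wall_thickness_mm
    half_fov = min(
        (config.grid_size - 1) * s / 2.0 for s in config.voxel_spacing_mm
    )
    if max(a, b) + t >= half_fov:
        raise ValueError("phantom exceeds field of view")

    rng = np.random.default_rng(config.seed)
    u = _canonical_coords(config)
    cavity, wall = _lv_shapes(u, a, b, t)

    # RV crescent: an offset chamber clipped away from the LV epicardium
    rv_center = np.array([0.0, -(b + t + 0.55 * b), -0.15 * a])
    du = u - rv_center[:, None, None, None]
    rv = (du[0] / (0.8 * b)) ** 2 + (du[1] / (0.9 * b)) ** 2 + (du[2] / (0.8 * a)) ** 2 <= 1.0
    outer = (u[0] / (b + t)) ** 2 + (u[1] / (b + t)) ** 2 + (u[2] / (a + t)) ** 2 <= 1.0
    rv &= ~outer

    # coronary tube on the epicardial surface
    curve = _coronary_curve(config)
    rad = config.coronary_radius_mm
    flat = u.reshape(3, -1).T
    bbox_lo = curve.min(axis=0) - (rad + 2.0)
    bbox_hi = curve.max(axis=0) + (rad + 2.0)
    cand = np.all((flat >= bbox_lo) & (flat <= bbox_hi), axis=1)
    coronary = np.zeros(flat.shape[0], dtype=bool)
    if cand.any():
        tree = cKDTree(curve)
        dist, _ = tree.query(flat[cand])
        coronary[np.flatnonzero(cand)[dist <= rad]] = True
    coronary = coronary.reshape(cavity.shape)
    coronary &= ~cavity

    ct = np.full(cavity.shape, _BG)
    ct[rv] = _CT_RV
    ct[wall] = _CT_WALL
    ct[cavity] = _CT_CAVITY
    ct[coronary] = _CT_CORONARY
    if config.noise_sigma > 0:
        ct = ct + rng.normal(0.0, config.noise_sigma, ct.shape)
    ct = np.clip(ct, 0.0, 1.0)
    ct = (ct - ct.min()) / max(ct.max() - ct.min(), 1e-12)  # min-max normalize

    sp = config.voxel_spacing_mm
    ctca = Volume3D(ct, sp)
    cavity_mask = Volume3D(cavity.astype(np.uint8), sp)
    wall_mask = Volume3D(wall.astype(np.uint8), sp)
    coronary_mask = Volume3D(coronary.astype(np.uint8), sp)

    # ground-truth perfusion on the CT wall: reduced plateau in the sector
    sector = _sector_mask(u[0], u[1], config.deficit_sector)
    perf3d = np.zeros(cavity.shape)
    perf3d[wall] = 1.0
    perf3d[wall & sector] = 1.0 - config.deficit_sector[2]
    perfusion_volume = Volume3D(perf3d, sp)

    stack, cmr_wall_masks, cmr_cavity_masks, perfusion_map, positions = _make_cmr(
        config, rng
    )

    return PhantomSample(
        ctca=ctca,
        lv_cavity_mask=cavity_mask,
        lv_wall_mask=wall_mask,
        coronary_mask=coronary_mask,
        cmr_stack=stack,
        cmr_wall_masks=cmr_wall_masks,
        cmr_cavity_masks=cmr_cavity_masks,
        perfusion_map=perfusion_map,
        perfusion_volume=perfusion_volume,
        true_orientation=config.long_axis_orientation,
        cmr_slice_positions_mm=positions,
        config=config,
    )


def _make_cmr(config: PhantomConfig, rng: np.random.Generator):
    """Short-axis CMR-like stack in the canonical frame (CMR is acquired
    short-axis regardless of how the CT happens to be oriented)."""
    n = config.grid_size
    sp = config.voxel_spacing_mm
    a = config.lv_long_semiaxis_mm
    b = config.lv_short_semiaxis_mm
    t_cmr = config.wall_thickness_mm * config.wall_thickness_cmr_scale

    ax = [(np.arange(n) - (n - 1) / 2.0) * sp[i] for i in range(2)]
    u0, u1 = np.meshgrid(*ax, indexing="ij")
    rr2 = u0**2 + u1**2
    sector = _sector_mask(u0, u1, config.deficit_sector)
    frac = config.deficit_sector[2]
    enh = _enhancement_curve(config.n_frames)
    enh_wall = np.concatenate([[0.0] * min(3, config.n_frames - 1),
                               enh[: config.n_frames - min(3, config.n_frames - 1)]])

    positions = _slice_positions(config)
    frames = np.zeros((config.n_slices, config.n_frames, n, n))
    wall_masks, cavity_masks, perf_maps = [], [], []
    for s_idx, u2 in enumerate(positions):
        r_cav2 = b**2 * max(1.0 - (u2 / a) ** 2, 0.0)
        r_out2 = (b + t_cmr) ** 2 * max(1.0 - (u2 / (a + t_cmr)) ** 2, 0.0)
        cav = rr2 <= r_cav2
        wal = (rr2 <= r_out2) & ~cav
        perf = np.zeros((n, n))
        perf[wal] = 1.0
        perf[wal & sector] = 1.0 - frac
        wall_masks.append(wal.astype(np.uint8))
        cavity_masks.append(cav.astype(np.uint8))
        perf_maps.append(perf)
        for f_idx in range(config.n_frames):
            img = np.full((n, n), _BG)
            img[wal] = 0.20 + 0.45 * enh_wall[f_idx] * perf[wal]
            img[cav] = 0.15 + 0.75 * enh[f_idx]
            if config.noise_sigma > 0:
                img = img + rng.normal(0.0, config.noise_sigma, img.shape)
            frames[s_idx, f_idx] = np.clip(img, 0.0, 1.0)
    # per-stack min-max normalization, mirroring the CT preprocessing
    lo, hi = frames.min(), frames.max()
    frames = (frames - lo) / max(hi - lo, 1e-12)
    stack = CMRStack(
        frames,
        slice_spacing_mm=config.cmr_slice_spacing_mm,
        pixel_spacing_mm=(sp[0], sp[1]),
    )
    return stack, wall_masks, cavity_masks, perf_maps, positions


def make_short_axis_slice_pair(
    size: int,
    rng: np.random.Generator,
    r_cavity_px: float = 15.0,
    wall_thickness_px: float = 5.0,
    wall_thickness_cmr_scale: float = 1.25,
    cmr_shift_px: tuple[float, float] = (0.0, 0.0),
    deficit_sector: tuple[float, float, float] = (0.0, 90.0, 0.5),
    rv_azimuth_deg: float = 180.0,
    noise_sigma: float = 0.01,
) -> dict:
    """Matched CTCA / CMR short-axis slices at the cropped-LV scale.

    The CTCA slice shows the bright cavity disk, the intermediate wall
    ring, an RV crescent at ``rv_azimuth_deg``, and a coronary dot on the
    epicardium; the CMR slice has the thicker wall with its plateau
    enhancement and deficit sector, shifted in-plane by ``cmr_shift_px``
    (residual inter-modality misalignment).  Returns a dict with images,
    wall masks, and the perfusion map.
    """
    c0 = size / 2.0
    rr, cc = np.meshgrid(np.arange(size), np.arange(size), indexing="ij")

    def rings(center, r_cav, r_out):
        d2 = (rr - center[0]) ** 2 + (cc - center[1]) ** 2
        cav = d2 <= r_cav**2
        return cav, (d2 <= r_out**2) & ~cav

    center_ct = (c0, c0)
    cav_ct, wall_ct = rings(center_ct, r_cavity_px, r_cavity_px + wall_thickness_px)
    # RV crescent: offset disk clipped outside the epicardium
    az = np.deg2rad(rv_azimuth_deg)
    rv_c = (c0 + 1.4 * r_cavity_px * np.cos(az), c0 + 1.4 * r_cavity_px * np.sin(az))
    d2rv = (rr - rv_c[0]) ** 2 + (cc - rv_c[1]) ** 2
    rv = (d2rv <= (0.9 * r_cavity_px) ** 2) & ~cav_ct & ~wall_ct
    cor_az = az + np.deg2rad(110.0)
    cor_r = r_cavity_px + wall_thickness_px + 1.5
    cor_c = (c0 + cor_r * np.cos(cor_az), c0 + cor_r * np.sin(cor_az))
    cor = ((rr - cor_c[0]) ** 2 + (cc - cor_c[1]) ** 2) <= 2.0**2

    ctca = np.full((size, size), _BG)
    ctca[rv] = _CT_RV
    ctca[wall_ct] = _CT_WALL
    ctca[cav_ct] = _CT_CAVITY
    ctca[cor & ~cav_ct] = _CT_CORONARY
    ctca = np.clip(ctca + rng.normal(0.0, noise_sigma, ctca.shape), 0.0, 1.0)

    center_mr = (c0 + cmr_shift_px[0], c0 + cmr_shift_px[1])
    t_mr = wall_thickness_px * wall_thickness_cmr_scale
    cav_mr, wall_mr = rings(center_mr, r_cavity_px, r_cavity_px + t_mr)
    sector = _sector_mask(rr - center_mr[0], cc - center_mr[1], deficit_sector)
    perf = np.zeros((size, size))
    perf[wall_mr] = 1.0
    perf[wall_mr & sector] = 1.0 - deficit_sector[2]
    cmr = np.full((size, size), _BG)
    cmr[wall_mr] = 0.20 + 0.44 * perf[wall_mr]
    cmr[cav_mr] = 0.90
    cmr = np.clip(cmr + rng.normal(0.0, noise_sigma, cmr.shape), 0.0, 1.0)

    return {
        "ctca": ctca,
        "ctca_wall": wall_ct.astype(np.uint8),
        "cmr": cmr,
        "cmr_wall": wall_mr.astype(np.uint8),
        "perfusion": perf,
    }


def apply_random_rotation(
    volume: Volume3D, range_deg: tuple[float, float], seed: int
) -> tuple[Volume3D, EulerAngles]:
    """Rotate by per-axis angles sampled uniformly from ``range_deg``."""
    lo, hi = float(range_deg[0]), float(range_deg[1])
    if lo > hi or lo < -180.0 or hi > 180.0:
        raise ValueError(f"rotation range must lie within [-180, 180], got {range_deg}")
    rng = np.random.default_rng(seed)
    angles = EulerAngles(*rng.uniform(lo, hi, size=3))
    return rotate_volume(volume, angles), angles


def make_rotated_dataset(
    base_config: PhantomConfig,
    n: int,
    rotation_range_deg: tuple[float, float],
    seed: int,
    jitter_frac: float = 0.05,
) -> list[PhantomSample]:
    """Generate ``n`` phantoms at random orientations with mild size jitter.

    Each sample's anatomy is generated analytically at its sampled
    orientation (no resampling blur); ``true_orientation`` carries the
    ground-truth tilt.  Size jitter emulates inter-subject variability.
    """
    lo, hi = rotation_range_deg
    rng = np.random.default_rng(seed)
    samples = []
    for i in range(n):
        angles = EulerAngles(*rng.uniform(lo, hi, size=3))
        jit = 1.0 + rng.uniform(-jitter_frac, jitter_frac, size=3)
        cfg = dataclasses.replace(
            base_config,
            long_axis_orientation=angles,
            lv_long_semiaxis_mm=base_config.lv_long_semiaxis_mm * jit[0],
            lv_short_semiaxis_mm=base_config.lv_short_semiaxis_mm * jit[1],
            wall_thickness_mm=base_config.wall_thickness_mm * jit[2],
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        samples.append(make_phantom(cfg))
    return samples


def write_sample(sample: PhantomSample, out_dir, config: PhantomConfig | None = None):
    """Write a sample as NIfTI files plus a JSON sidecar with ground truth."""
    import pathlib

    from .fuse_io import write_volume

    out = pathlib.Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_volume(sample.ctca, out / "ctca.nii.gz")
    write_volume(sample.lv_cavity_mask, out / "lv_cavity_mask.nii.gz")
    write_volume(sample.lv_wall_mask, out / "lv_wall_mask.nii.gz")
    write_volume(sample.coronary_mask, out / "coronary_mask.nii.gz")
    write_volume(sample.perfusion_volume, out / "perfusion_volume.nii.gz")

    import nibabel as nib

    st = sample.cmr_stack
    # 4D layout (x, y, slice, time)
    arr = np.transpose(st.frames, (2, 3, 0, 1))
    affine = np.diag([st.pixel_spacing_mm[0], st.pixel_spacing_mm[1],
                      st.slice_spacing_mm, 1.0])
    nib.save(nib.Nifti1Image(arr.astype(np.float32), affine), out / "cmr_stack.nii.gz")
    for i, (wm, pm) in enumerate(zip(sample.cmr_wall_masks, sample.perfusion_map)):
        aff2 = np.diag([st.pixel_spacing_mm[0], st.pixel_spacing_mm[1], 1.0, 1.0])
        nib.save(nib.Nifti1Image(wm[..., None].astype(np.uint8), aff2),
                 out / f"cmr_wall_mask_{i:02d}.nii.gz")
        nib.save(nib.Nifti1Image(pm[..., None].astype(np.float32), aff2),
                 out / f"cmr_perfusion_{i:02d}.nii.gz")

    sidecar = {
        "true_orientation_deg": list(sample.true_orientation.as_tuple()),
        "cmr_slice_positions_mm": [float(p) for p in sample.cmr_slice_positions_mm],
    }
    if config is not None:
        sidecar["config"] = config.to_json()
    (out / "sample.json").write_text(json.dumps(sidecar, indent=2))
    return out
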