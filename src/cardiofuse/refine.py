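"""Deterministic anatomical-prior refinement of a reoriented CTCA volume.

Given the LV mask, the LV long axis is measured in the axial and coronal
display planes and corrective in-plane rotations are applied until it lies
along the R-L direction; the corrected volume is the pseudo-label used to
fine-tune the reorientation network.

Display conventions (documented once, used everywhere): each plane is
drawn with the sagittal (R-L) axis pointing right; the axial plane has the
coronal axis up, the coronal plane has the axial axis up.  A positive
angle is counterclockwise in the displayed plane.  The deviation angle of
the long axis is its counterclockwise angle from the R-L direction, so a
corrective rotation by minus the deviation aligns it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import (
    EulerAngles,
    RotationMatrix,
    Volume3D,
    rotate_volume_matrix,
    rotation_about_axis,
)

__all__ = [
    "AxisEstimate",
    "estimate_axis",
    "align_long_axis",
    "apply_in_plane_rotation",
    "make_pseudo_label_ctca",
]

_MIN_ELONGATION = 1.05


@dataclass(frozen=True)
class AxisEstimate:
    """LV long-axis measurement: center, apex, and per-plane deviations."""

    center: tuple[float, float, float]
    apex: tuple[float, float, float]
    dev_axial_deg: float
    dev_coronal_deg: float

    def to_json(self) -> dict:
        return {
            "center_voxel": list(self.center),
            "apex_voxel": list(self.apex),
            "dev_axial_deg": self.dev_axial_deg,
            "dev_coronal_deg": self.dev_coronal_deg,
        }


def _principal_axis(coords_mm: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Unit principal axis of a weighted point cloud (second-moment eigenvector).

    Fractional weights let a partial-volume (interpolated) mask contribute
    smoothly, which suppresses the aliasing bias a hard-thresholded
    resampled mask would introduce.
    """
    w = weights / weights.sum()
    mean = w @ coords_mm
    centered = coords_mm - mean
    cov = (centered * w[:, None]).T @ centered
    evals, evecs = np.linalg.eigh(cov)
    if np.sqrt(evals[-1] / max(evals[-2], 1e-12)) < _MIN_ELONGATION:
        raise ValueError("degenerate long axis")
    return evecs[:, -1]


def estimate_axis(lv_mask: Volume3D) -> AxisEstimate:
    """Measure the LV long axis and its axial/coronal-plane deviations.

    The center is the in-slice centroid of the mask on the short-axis
    (sagittal) slice through the mask centroid; the apex is the rightmost
    (maximal sagittal index) mask voxel, ties broken by proximity to the
    center ray.  The axis *direction* is taken from the mask's principal
    second-moment eigenvector, oriented toward the apex — for an
    ellipsoidal LV this coincides with the center-to-apex chord but is
    sub-voxel accurate.
    """
    values = np.clip(np.asarray(lv_mask.data, dtype=float), 0.0, 1.0)
    mask = values > 0.5
    if not mask.any():
        raise ValueError("empty mask")
    soft = values > 0.05  # partial-volume fringe participates in the moments
    coords = np.argwhere(soft).astype(float)
    wts = values[soft]
    vox = np.argwhere(mask).astype(float)
    spacing = np.asarray(lv_mask.spacing)
    centroid = (wts @ coords) / wts.sum()

    cross_idx = int(round(centroid[2]))
    in_slice = vox[vox[:, 2] == cross_idx]
    if len(in_slice) == 0:
        in_slice = vox
    center = (float(in_slice[:, 0].mean()), float(in_slice[:, 1].mean()),
              float(cross_idx))

    sag_max = vox[:, 2].max()
    tip = vox[vox[:, 2] >= sag_max - 1]  # apical cap, sub-voxel via its centroid
    d2 = (tip[:, 0] - center[0]) ** 2 + (tip[:, 1] - center[1]) ** 2
    apex_arr = tip[d2 <= d2.min() + 2.0].mean(axis=0)
    apex = tuple(float(v) for v in apex_arr)

    if np.linalg.norm(np.asarray(apex) - np.asarray(center)) < 2.0:
        raise ValueError("degenerate long axis")

    axis = _principal_axis(coords * spacing, wts)
    if axis[2] < 0 or (axis[2] == 0 and axis[0] + axis[1] < 0):
        axis = -axis  # orient toward the apex (+sagittal)
    dev_axial = float(np.rad2deg(np.arctan2(axis[1], axis[2])))
    dev_coronal = float(np.rad2deg(np.arctan2(axis[0], axis[2])))
    return AxisEstimate(center, apex, dev_axial, dev_coronal)


def apply_in_plane_rotation(
    volume: Volume3D, plane: str, angle_deg: float, mode: str = "trilinear"
) -> Volume3D:
    """Rotate the volume content by ``angle_deg`` CCW in a display plane."""
    if plane == "axial":
        m = rotation_about_axis(0, angle_deg)
    elif plane == "coronal":
        m = rotation_about_axis(1, -angle_deg)
    else:
        raise ValueError(f"plane must be 'axial' or 'coronal', got {plane!r}")
    return rotate_volume_matrix(volume, m, mode=mode)


def align_long_axis(
    volume: Volume3D,
    lv_mask: Volume3D,
    order: tuple[str, str] = ("axial", "coronal"),
    max_sweeps: int = 3,
    tol_deg: float = 0.1,
) -> tuple[Volume3D, Volume3D, EulerAngles]:
    """Align the LV long axis with the R-L direction by in-plane rotations.

    Each sweep corrects the axial then the coronal plane, re-estimating the
    deviation between corrections (the planes are coupled for large tilts,
    and the discrete mask adds estimation noise); sweeps repeat until both
    residuals drop below ``tol_deg`` or ``max_sweeps`` is reached.  Returns
    the corrected volume, the corrected mask (trilinear, fractional), and
    the total applied angles: ``alpha`` = coronal-plane correction,
    ``beta`` = axial-plane correction, ``gamma`` = 0, in the display CCW
    convention.
    """
    applied = {"axial": 0.0, "coronal": 0.0}
    soft_mask = Volume3D(
        np.clip(np.asarray(lv_mask.data, dtype=float), 0.0, 1.0), lv_mask.spacing
    )
    msk = soft_mask
    m_total = np.eye(3)

    for _sweep in range(max_sweeps):
        converged = True
        for plane in order:
            est = estimate_axis(msk)
            dev = est.dev_axial_deg if plane == "axial" else est.dev_coronal_deg
            if abs(dev) <= tol_deg:
                continue
            converged = False
            # incremental correction acts on the *current* content, which in
            # grid-matrix composition means right-multiplying the total; the
            # mask is re-resampled from the original each time (trilinear,
            # kept fractional) so interpolation error never compounds
            if plane == "axial":
                m_inc = rotation_about_axis(0, -dev).m
            else:
                m_inc = rotation_about_axis(1, dev).m
            m_total = m_total @ m_inc
            applied[plane] += -dev
            msk = rotate_volume_matrix(soft_mask, RotationMatrix(m_total))
        if converged:
            break
    rm = RotationMatrix(m_total)
    vol = rotate_volume_matrix(volume, rm, mode="trilinear")
    # the corrected mask keeps its fractional (partial-volume) values: a
    # hard-thresholded resample of a resampled mask carries correlated
    # aliasing that biases downstream moment estimates; threshold at 0.5
    # wherever a crisp mask is needed
    out_mask = rotate_volume_matrix(soft_mask, rm, mode="trilinear")
    return vol, out_mask, EulerAngles(applied["coronal"], applied["axial"], 0.0)


def make_pseudo_label_ctca(
    reoriented: Volume3D, lv_mask: Volume3D
) -> tuple[Volume3D, Volume3D, EulerAngles]:
    """Refine a network-reoriented CTCA into the fine-tuning target."""
    if not (np.asarray(lv_mask.data) > 0.5).any():
        raise ValueError("empty mask")
    return align_long_axis(reoriented, lv_mask)
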