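"""Evaluation suite: aspect ratio, Dice, long-axis deviation, Hausdorff.

All metrics are computed per short-axis slice and averaged across the
slices of a volume; the long-axis deviation angles are volume-level
(measured on the 3D LV mask) and reported as magnitudes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .geometry import Volume3D

__all__ = [
    "MetricsReport",
    "aspect_ratio",
    "dice",
    "hausdorff",
    "evaluate_reorientation",
]


@dataclass
class MetricsReport:
    """Per-slice metric values and their per-volume summaries."""

    ar_mean: float
    ar_per_slice: list[float]
    dsc_mean: float
    dsc_per_slice: list[float]
    la_dev_axial_deg: float
    la_dev_coronal_deg: float
    hd_mm: float                      # max over slices (conservative)
    hd_mean_mm: float
    hd_per_slice_mm: list[float]
    n_slices_used: int

    def to_json(self) -> dict:
        return {
            "ar": {"mean": self.ar_mean, "per_slice": self.ar_per_slice},
            "dsc": {"mean": self.dsc_mean, "per_slice": self.dsc_per_slice},
            "la_dev_axial_deg": self.la_dev_axial_deg,
            "la_dev_coronal_deg": self.la_dev_coronal_deg,
            "hd_mm": self.hd_mm,
            "hd_mean_mm": self.hd_mean_mm,
            "hd_per_slice_mm": self.hd_per_slice_mm,
            "n_slices_used": self.n_slices_used,
        }

    def table_row(self) -> dict:
        """One-row summary in the standard column order."""
        return {
            "AR": self.ar_mean,
            "DSC": self.dsc_mean,
            "LA Dev ANG1": self.la_dev_axial_deg,
            "LA Dev ANG2": self.la_dev_coronal_deg,
        }


def aspect_ratio(lv_mask_slice: np.ndarray) -> float:
    """Minor/major principal-extent ratio of a 2D mask cross-section.

    Extents come from the second-moment eigenvalues (extent = 4 sqrt(lambda),
    exact for a filled ellipse); the ratio is <= 1, and 1 for an isotropic
    cross-section.
    """
    mask = np.asarray(lv_mask_slice) > 0.5
    npix = int(mask.sum())
    if npix == 0:
        raise ValueError("empty mask")
    if npix == 1:
        raise ValueError("degenerate")
    pts = np.argwhere(mask).astype(float)
    centered = pts - pts.mean(axis=0)
    cov = centered.T @ centered / npix
    cov += np.eye(2) / 12.0  # per-pixel variance of the unit square
    evals = np.linalg.eigvalsh(cov)
    return float(np.sqrt(max(evals[0], 0.0) / evals[1]))


def dice(mask_a: np.ndarray, mask_b: np.ndarray) -> float:
    """Dice similarity 2|A∩B| / (|A|+|B|); 1.0 when both masks are empty."""
    a = np.asarray(mask_a) > 0.5
    b = np.asarray(mask_b) > 0.5
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch {a.shape} vs {b.shape}")
    total = int(a.sum()) + int(b.sum())
    if total == 0:
        return 1.0
    return 2.0 * int(np.logical_and(a, b).sum()) / total


def _boundary_points(mask: np.ndarray) -> np.ndarray:
    m = np.asarray(mask) > 0.5
    eroded = ndimage.binary_erosion(m)
    return np.argwhere(m & ~eroded).astype(float)


def hausdorff(mask_a: np.ndarray, mask_b: np.ndarray, spacing_mm=1.0) -> float:
    """Symmetric Hausdorff distance between mask boundaries, in millimeters."""
    a = np.asarray(mask_a) > 0.5
    b = np.asarray(mask_b) > 0.5
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch {a.shape} vs {b.shape}")
    if not a.any() or not b.any():
        raise ValueError("empty mask")
    sp = np.atleast_1d(np.asarray(spacing_mm, dtype=float))
    if sp.size == 1:
        sp = np.full(a.ndim, sp[0])
    pa = _boundary_points(a) * sp
    pb = _boundary_points(b) * sp
    d_ab = cKDTree(pb).query(pa)[0].max()
    d_ba = cKDTree(pa).query(pb)[0].max()
    return float(max(d_ab, d_ba))


def evaluate_reorientation(
    reoriented_ctca_lv_mask: Volume3D,
    reference_cmr_wall_masks: list[np.ndarray],
    slice_mapping,
) -> MetricsReport:
    """Score a reoriented CTCA against the reference CMR wall masks.

    AR is computed per mapped slice on the filled LV cross-section of the
    CTCA wall mask; DSC compares the CTCA wall ring with the CMR wall mask
    on the shared in-plane grid; the long-axis deviations come from the 3D
    mask; HD is reported as the per-slice maximum (mean also recorded).
    """
    from .refine import estimate_axis

    indices = list(slice_mapping.indices())
    if not indices:
        raise ValueError("empty slice mapping")
    if len(indices) != len(reference_cmr_wall_masks):
        raise ValueError("mapping length does not match reference masks")
    wall = np.asarray(reoriented_ctca_lv_mask.data) > 0.5
    spacing = reoriented_ctca_lv_mask.spacing

    ar_list, dsc_list, hd_list = [], [], []
    for idx, ref in zip(indices, reference_cmr_wall_masks):
        ctca_slice = wall[:, :, idx]
        filled = ndimage.binary_fill_holes(ctca_slice)
        ar_list.append(aspect_ratio(filled))
        dsc_list.append(dice(ctca_slice, ref))
        hd_list.append(hausdorff(ctca_slice, ref, (spacing[0], spacing[1])))

    filled3d = Volume3D(
        ndimage.binary_fill_holes(wall).astype(np.uint8), spacing
    )
    est = estimate_axis(filled3d)
    return MetricsReport(
        ar_mean=float(np.mean(ar_list)),
        ar_per_slice=ar_list,
        dsc_mean=float(np.mean(dsc_list)),
        dsc_per_slice=dsc_list,
        la_dev_axial_deg=abs(est.dev_axial_deg),
        la_dev_coronal_deg=abs(est.dev_coronal_deg),
        hd_mm=float(np.max(hd_list)),
        hd_mean_mm=float(np.mean(hd_list)),
        hd_per_slice_mm=hd_list,
        n_slices_used=len(indices),
    )
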