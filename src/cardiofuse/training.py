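"""Phantom-scale study runs: dataset builders and end-to-end training helpers.

These helpers wire the synthetic generator to the two trainable models at
desk scale: the reorientation network trains on phantoms tilted within a
configurable range, and the deformation network trains on short-axis slice
triplets whose CMR wall is thicker than the CTCA wall and mildly shifted
in-plane (emulating residual through-plane / temporal misalignment between
the modalities).  The desk-scale optimizer settings here (larger step sizes
than the emulated protocol's 1e-4) compensate for the much smaller number
of gradient steps; see the methods note.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from . import phantom as ph
from .geometry import EulerAngles, rotate_volume
from .refine import align_long_axis
from .register import SDNConfig, make_pseudo_label_cmr, train_sdn
from .reorient import (
    LossWeights,
    ReorientModelConfig,
    build_slice_mapping,
    train_reorientation,
)

__all__ = [
    "scaled_phantom_config",
    "make_reorient_dataset",
    "train_reorient_on_phantoms",
    "evaluate_reorientation_recovery",
    "make_sdn_triplets",
    "train_sdn_on_phantoms",
    "evaluate_sdn_on_triplets",
]

_REFERENCE_GRID = 96


def scaled_phantom_config(grid_size: int, seed: int = 0, **overrides) -> ph.PhantomConfig:
    """Default phantom geometry scaled from the 96-voxel reference grid."""
    s = grid_size / _REFERENCE_GRID
    cfg = ph.PhantomConfig(
        grid_size=grid_size,
        lv_long_semiaxis_mm=32.0 * s,
        lv_short_semiaxis_mm=15.0 * s,
        wall_thickness_mm=5.0 * s,
        coronary_radius_mm=max(1.8 * s, 0.8),
        cmr_slice_spacing_mm=max(8.0 * s, 2.0),
        seed=seed,
    )
    return dataclasses.replace(cfg, **overrides) if overrides else cfg


def make_reorient_dataset(
    n_samples: int,
    grid_size: int = 48,
    rotation_range_deg: float = 30.0,
    seed: int = 0,
    n_frames: int = 12,
):
    """Build (rotated CTCA, template, CMR slices) triplets plus the mapping.

    The template is the noise-matched aligned phantom; each sample is
    generated analytically at its random orientation so the ground-truth
    tilt is exact.  Phantom CMR frames share the CT in-plane grid, so no
    cross-grid resampling is needed before the cross-modal loss.
    """
    base = scaled_phantom_config(grid_size, seed=seed, n_frames=n_frames)
    template_sample = ph.make_phantom(base)
    template = template_sample.ctca
    mapping = build_slice_mapping(
        template, template_sample.lv_cavity_mask,
        base.cmr_slice_spacing_mm, base.n_slices,
    )
    samples = ph.make_rotated_dataset(
        base, n_samples, (-rotation_range_deg, rotation_range_deg), seed=seed + 1
    )
    dataset = [
        (s.ctca, template, list(s.cmr_stack.last_frames())) for s in samples
    ]
    return dataset, samples, template_sample, mapping


def train_reorient_on_phantoms(
    n_samples: int = 200,
    grid_size: int = 48,
    rotation_range_deg: float = 30.0,
    epochs: int = 20,
    seed: int = 0,
    learning_rate: float = 3e-3,
    batch_size: int = 4,
    weights: LossWeights = LossWeights(),
):
    """Train the reorientation network on rotated phantoms; returns aux data."""
    dataset, samples, template_sample, mapping = make_reorient_dataset(
        n_samples, grid_size, rotation_range_deg, seed
    )
    config = ReorientModelConfig(
        input_size=grid_size,
        epochs=epochs,
        learning_rate=learning_rate,
        batch_size=batch_size,
        seed=seed,
    )
    model, history = train_reorientation(dataset, config, weights, mapping)
    aux = {
        "samples": samples,
        "template_sample": template_sample,
        "mapping": mapping,
        "config": config,
    }
    return model, history, aux


def evaluate_reorientation_recovery(
    model,
    heldout: list[ph.PhantomSample],
    refine: bool = True,
):
    """Reorient held-out phantoms and score long-axis recovery.

    For each sample: predict angles, rotate volume and masks, optionally
    apply the anatomical refinement, then measure the residual long-axis
    deviation (max of the two plane deviations, in degrees) and the Dice of
    the refined cavity mask against the same phantom generated already
    aligned.  Returns a list of per-sample dicts.
    """
    from .refine import estimate_axis
    from .metrics import dice

    results = []
    for s in heldout:
        angles = model.predict(s.ctca)
        vol = rotate_volume(s.ctca, angles)
        cavity = rotate_volume(s.lv_cavity_mask, angles, mode="nearest")
        if refine:
            vol, cavity, _applied = align_long_axis(vol, cavity)
        est = estimate_axis(cavity)
        la_dev = max(abs(est.dev_axial_deg), abs(est.dev_coronal_deg))
        gt_cfg = dataclasses.replace(
            s.config, long_axis_orientation=EulerAngles(0.0, 0.0, 0.0)
        )
        gt = ph.make_phantom(gt_cfg)
        dsc = dice(cavity.data, gt.lv_cavity_mask.data)
        results.append(
            {"la_dev_deg": la_dev, "cavity_dice": dsc,
             "predicted_angles": angles.as_tuple()}
        )
    return results


# ---------------------------------------------------------------------------
# SDN slice triplets
# ---------------------------------------------------------------------------

def make_sdn_triplets(
    n_samples: int,
    size: int = 64,
    seed: int = 0,
    max_shift_px: float = 3.0,
    levels: int = 6,
    grid_reg: float = 0.6,
):
    """(ctca_slice, cmr_slice, pseudo_label) triplets with their wall masks.

    Slices come from the phantom's short-axis slice-pair generator at the
    cropped-LV scale (the SDN sees LV-centered crops, so the ring size does
    not shrink with the slice size): the CMR wall is thicker by the
    modality scale (jittered around 1.25), carries a perfusion-deficit
    sector, and the whole CMR slice is shifted in-plane by up to
    ``max_shift_px`` emulating residual inter-modality misalignment.  The
    pseudo-label comes from the classical multiresolution mask
    registration.
    """
    rng = np.random.default_rng(seed)
    triplets, masks = [], []
    for _ in range(n_samples):
        pair = ph.make_short_axis_slice_pair(
            size,
            rng,
            r_cavity_px=15.0 * rng.uniform(0.85, 1.15),
            wall_thickness_px=5.0 * rng.uniform(0.85, 1.15),
            wall_thickness_cmr_scale=rng.uniform(1.15, 1.35),
            cmr_shift_px=tuple(rng.uniform(-max_shift_px, max_shift_px, size=2)),
            deficit_sector=(rng.uniform(-180, 180), 90.0, rng.uniform(0.0, 0.6)),
            rv_azimuth_deg=rng.uniform(-180, 180),
        )
        pseudo, _fld = make_pseudo_label_cmr(
            pair["cmr"], pair["cmr_wall"], pair["ctca_wall"],
            levels=levels, grid_reg=grid_reg,
        )
        triplets.append((pair["ctca"], pair["cmr"], pseudo))
        masks.append({"ctca_wall": pair["ctca_wall"], "cmr_wall": pair["cmr_wall"]})
    return triplets, masks


def train_sdn_on_phantoms(
    n_samples: int = 100,
    size: int = 64,
    epochs: int = 30,
    seed: int = 0,
    learning_rate: float = 1e-3,
    smoothness_weight: float = 0.01,
):
    """Train the deformation network on phantom slice triplets."""
    triplets, masks = make_sdn_triplets(n_samples, size, seed)
    config = SDNConfig(
        epochs=epochs, seed=seed, learning_rate=learning_rate,
        smoothness_weight=smoothness_weight,
    )
    model, history = train_sdn(triplets, config)
    return model, history, {"triplets": triplets, "masks": masks, "config": config}


def evaluate_sdn_on_triplets(model, triplets, masks):
    """Pre/post-registration wall Dice of the SDN on held-out triplets."""
    from .geometry import warp_2d
    from .metrics import dice

    rows = []
    for (ctca, cmr, _pseudo), m in zip(triplets, masks):
        pre = dice(m["cmr_wall"], m["ctca_wall"])
        fld = model.predict_field(ctca, cmr)
        warped_wall = warp_2d(m["cmr_wall"].astype(float), fld, "nearest") > 0.5
        post = dice(warped_wall, m["ctca_wall"])
        rows.append({"dice_pre": pre, "dice_post": post})
    return rows
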