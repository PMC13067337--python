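"""Self-supervised reorientation network for CTCA short-axis alignment.

A localization network predicts three Euler angles from the CTCA volume; a
spatial-transformer resampler rotates the volume by them.  Training is
self-supervised: the reoriented volume is compared to a fixed manually
oriented template (single-modal MSE) and, slice-by-slice through the
cross-modal slice mapping, to the subject's short-axis CMR frames
(cross-modal MSE).  Fine-tuning replaces the template with per-sample
pseudo-label volumes from the deterministic refinement.

Gradients flow analytically end to end: through the trilinear sampler
(the standard spatial-transformer backward pass), the grid generator, the
Euler-angle rotation composition, and the localization network.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np

from . import _nets
from .geometry import (
    EulerAngles,
    Volume3D,
    affine_grid,
    euler_derivatives,
    euler_to_matrix,
    matrix_to_world,
    resample_3d_with_grad,
    rotate_volume,
)

__all__ = [
    "ReorientModelConfig",
    "LossWeights",
    "SliceMapping",
    "ReorientModel",
    "single_modal_loss",
    "cross_modal_loss",
    "cross_modal_loss_mi",
    "total_loss",
    "build_slice_mapping",
    "predict_angles",
    "train_reorientation",
    "fine_tune",
]


@dataclass
class ReorientModelConfig:
    """Localization-network and optimizer settings."""

    input_size: int = 48
    pooled_size: int = 12           # mean-pool factor applied before the dense head
    hidden: tuple[int, ...] = (128, 64)
    angle_bound_deg: float = 180.0  # scaled-tanh output head bound
    learning_rate: float = 1e-4
    epochs: int = 20
    batch_size: int = 4
    augment: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.input_size < 16:
            raise ValueError("input cube size must be >= 16")
        if self.input_size % self.pooled_size:
            raise ValueError("pooled_size must divide input_size")
        self.hidden = tuple(int(h) for h in self.hidden)


@dataclass(frozen=True)
class LossWeights:
    """Weights of the single-modal (mu1) and cross-modal (mu2) loss terms."""

    mu1: float = 0.6
    mu2: float = 0.4

    def __post_init__(self) -> None:
        if self.mu1 < 0 or self.mu2 < 0:
            raise ValueError("loss weights must be non-negative")


@dataclass(frozen=True)
class SliceMapping:
    """Sagittal-slice indices of the reoriented CTCA matched to CMR slices."""

    anchor_index: int
    step_voxels: int
    n_slices: int

    def __post_init__(self) -> None:
        if self.step_voxels < 1:
            raise ValueError("step_voxels must be >= 1")

    def indices(self) -> list[int]:
        return [self.anchor_index + k * self.step_voxels for k in range(self.n_slices)]


# ---------------------------------------------------------------------------
# losses
# ---------------------------------------------------------------------------

def single_modal_loss(reoriented: Volume3D | np.ndarray,
                      template: Volume3D | np.ndarray) -> float:
    """Mean squared error between the reoriented volume and the template."""
    p = reoriented.data if isinstance(reoriented, Volume3D) else np.asarray(reoriented)
    t = template.data if isinstance(template, Volume3D) else np.asarray(template)
    if p.shape != t.shape:
        raise ValueError(f"shape mismatch {p.shape} vs {t.shape}")
    return float(np.mean((np.asarray(p, float) - np.asarray(t, float)) ** 2))


def cross_modal_loss(ctca_slices: list[np.ndarray], cmr_slices: list[np.ndarray]) -> float:
    """MSE between mapped reoriented-CTCA slices and the matching CMR slices."""
    if len(ctca_slices) != len(cmr_slices):
        raise ValueError("slice lists differ in length")
    if not ctca_slices:
        raise ValueError("empty slice lists")
    total = 0.0
    count = 0
    for p, r in zip(ctca_slices, cmr_slices):
        p = np.asarray(p, float)
        r = np.asarray(r, float)
        if p.shape != r.shape:
            raise ValueError(f"slice shape mismatch {p.shape} vs {r.shape}")
        total += float(np.sum((p - r) ** 2))
        count += p.size
    return total / count


def cross_modal_loss_mi(
    ctca_slices: list[np.ndarray], cmr_slices: list[np.ndarray], n_bins: int = 32
) -> float:
    """Negated mutual information variant of the cross-modal loss.

    MI (in nats) is computed from the joint intensity histogram of each
    slice pair with values clipped to [0, 1], then averaged over pairs and
    negated so that lower is better, matching the MSE direction.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    if len(ctca_slices) != len(cmr_slices):
        raise ValueError("slice lists differ in length")
    if not ctca_slices:
        raise ValueError("empty slice lists")
    mis = []
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    for p, r in zip(ctca_slices, cmr_slices):
        p = np.clip(np.asarray(p, float).ravel(), 0.0, 1.0)
        r = np.clip(np.asarray(r, float).ravel(), 0.0, 1.0)
        if p.shape != r.shape:
            raise ValueError("slice shape mismatch")
        joint, _, _ = np.histogram2d(p, r, bins=[edges, edges])
        pj = joint / joint.sum()
        px = pj.sum(axis=1, keepdims=True)
        py = pj.sum(axis=0, keepdims=True)
        nz = pj > 0
        mi = float(np.sum(pj[nz] * np.log(pj[nz] / (px @ py)[nz])))
        mis.append(mi)
    return -float(np.mean(mis))


def total_loss(l_sing: float, l_cross: float, weights: LossWeights) -> float:
    """Weighted sum  mu1 * Lsing + mu2 * Lcross."""
    if l_sing < 0 or l_cross < 0:
        raise ValueError("losses must be non-negative")
    return weights.mu1 * l_sing + weights.mu2 * l_cross


# ---------------------------------------------------------------------------
# cross-modal slice mapping
# ---------------------------------------------------------------------------

def build_slice_mapping(
    volume: Volume3D,
    lv_mask: Volume3D,
    cmr_slice_spacing_mm: float,
    n_slices: int,
) -> SliceMapping:
    """Map CMR slices onto sagittal slices of a reoriented CTCA volume.

    The anchor (CMR slice 1) is the basal-most sagittal slice whose LV
    cross-section keeps at least 50% of the maximal cross-section area;
    subsequent slices step toward the apex by the CMR slice spacing
    expressed in sagittal voxels.
    """
    if n_slices < 1:
        raise ValueError("n_slices must be >= 1")
    mask = np.asarray(lv_mask.data) > 0.5
    areas = mask.sum(axis=(0, 1))
    if areas.max() == 0:
        raise ValueError("LV not found")
    threshold = 0.5 * areas.max()
    anchor = int(np.argmax(areas >= threshold))
    step = max(int(round(cmr_slice_spacing_mm / volume.spacing[2])), 1)
    last = anchor + (n_slices - 1) * step
    if last >= volume.shape[2]:
        raise ValueError("mapping exceeds volume")
    return SliceMapping(anchor_index=anchor, step_voxels=step, n_slices=n_slices)


# ---------------------------------------------------------------------------
# localization network
# ---------------------------------------------------------------------------

def _pool_features(data: np.ndarray, pooled: int) -> np.ndarray:
    n = data.shape[0]
    f = n // pooled
    feat = data[: pooled * f, : pooled * f, : pooled * f].reshape(
        pooled, f, pooled, f, pooled, f
    ).mean(axis=(1, 3, 5))
    feat = feat.ravel()
    std = feat.std()
    return (feat - feat.mean()) / (std if std > 1e-8 else 1.0)


class ReorientModel:
    """Localization MLP over mean-pooled volume features, scaled-tanh head."""

    def __init__(self, config: ReorientModelConfig,
                 rng: np.random.Generator | None = None):
        self.config = config
        rng = rng if rng is not None else np.random.default_rng(config.seed)
        sizes = [config.pooled_size**3, *config.hidden, 3]
        self.net = _nets.MLP(sizes, rng)
        # zero-init the output layer: the transformer starts at the identity
        # rotation, keeping the scaled-tanh head out of saturation
        self.net.weights[-1][...] = 0.0
        self.net.biases[-1][...] = 0.0

    def _forward(self, volume: Volume3D):
        data = np.asarray(volume.data, float)
        if volume.shape != (self.config.input_size,) * 3:
            # prediction on foreign grids resizes to the model's input cube;
            # training always presents native-size volumes
            from scipy.ndimage import zoom

            factors = [self.config.input_size / n for n in volume.shape]
            data = zoom(data, factors, order=1, grid_mode=True, mode="nearest")
        x = _pool_features(data, self.config.pooled_size)
        raw, acts = self.net.forward(x)
        th = np.tanh(raw)
        angles = self.config.angle_bound_deg * th
        return angles, th, acts

    def predict(self, volume: Volume3D) -> EulerAngles:
        angles, _, _ = self._forward(volume)
        return EulerAngles(*angles)

    def save(self, path) -> None:
        cfg = dataclasses.asdict(self.config)
        cfg["hidden"] = list(cfg["hidden"])
        from . import __version__

        self.net.save(path, extra={"reorient_config": cfg, "version": __version__})

    @classmethod
    def load(cls, path) -> "ReorientModel":
        net, extra = _nets.MLP.load(path)
        cfg = dict(extra["reorient_config"])
        cfg["hidden"] = tuple(cfg["hidden"])
        model = cls.__new__(cls)
        model.config = ReorientModelConfig(**cfg)
        model.net = net
        return model


def predict_angles(model: ReorientModel, volume: Volume3D) -> EulerAngles:
    """Predict reorientation angles; deterministic for a fixed model."""
    if model is None:
        raise ValueError("uninitialized model")
    return model.predict(volume)


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

def _sample_loss(
    volume: Volume3D,
    angles: np.ndarray,
    template: Volume3D | None,
    cmr_slices: list[np.ndarray] | None,
    mapping: SliceMapping | None,
    weights: LossWeights,
) -> tuple[float, float, float]:
    """(Lsing, Lcross, Ltotal) of rotating ``volume`` by ``angles``."""
    reoriented = rotate_volume(volume, EulerAngles(*angles))
    l_sing = single_modal_loss(reoriented, template) if template is not None else 0.0
    if cmr_slices is not None and mapping is not None and weights.mu2 > 0:
        ctca_slices = [reoriented.data[:, :, i] for i in mapping.indices()]
        l_cross = cross_modal_loss(ctca_slices, cmr_slices)
    else:
        l_cross = 0.0
    return l_sing, l_cross, total_loss(l_sing, l_cross, weights)


def _loss_and_angle_grad(
    volume: Volume3D,
    angles: np.ndarray,
    template: Volume3D | None,
    cmr_slices: list[np.ndarray] | None,
    mapping: SliceMapping | None,
    weights: LossWeights,
):
    """Ltotal and its analytic gradient w.r.t. the three angles (degrees).

    Chain: loss -> reoriented voxels -> sampling grid -> rotation matrix ->
    Euler angles.  ``resample_3d_with_grad`` supplies ∂out/∂grid;
    ``euler_derivatives`` supplies dM/dθ.
    """
    ea = EulerAngles(*angles)
    m = euler_to_matrix(ea)
    a = matrix_to_world(m, volume.spacing, volume.shape)
    grid = affine_grid(a, volume.shape)
    reoriented, samp_grad = resample_3d_with_grad(volume, grid)
    p = reoriented.data

    dldp = np.zeros_like(p)
    l_sing = 0.0
    if template is not None:
        t = np.asarray(template.data, float)
        resid = p - t
        l_sing = float(np.mean(resid**2))
        dldp += weights.mu1 * 2.0 * resid / resid.size
    l_cross = 0.0
    if cmr_slices is not None and mapping is not None and weights.mu2 > 0:
        idx = mapping.indices()
        npix = sum(np.asarray(cmr_slices[j]).size for j in range(len(idx)))
        acc = 0.0
        for j, i in enumerate(idx):
            r = np.asarray(cmr_slices[j], float)
            resid = p[:, :, i] - r
            acc += float(np.sum(resid**2))
            dldp[:, :, i] += weights.mu2 * 2.0 * resid / npix
        l_cross = acc / npix

    dldgrid = dldp[None] * samp_grad  # (3, *shape)
    ncoords = affine_grid(np.eye(3), volume.shape)
    dlda = np.einsum("ixyz,jxyz->ij", dldgrid, ncoords)
    # A = S^-1 M S  =>  dL/dM = S^-1 dL/dA S  (S diagonal)
    from .geometry import _half_extents_mm

    h = _half_extents_mm(volume.shape, volume.spacing)
    if not np.allclose(h, h[0]):
        dldm = (dlda / h[:, None]) * h[None, :]
    else:
        dldm = dlda
    dms = euler_derivatives(ea)
    grad = np.array([float(np.sum(dldm * dm)) for dm in dms])
    return l_sing, l_cross, total_loss(l_sing, l_cross, weights), grad


def _run_training(
    model: ReorientModel,
    samples: list[dict],
    weights: LossWeights,
    config: ReorientModelConfig,
    rng: np.random.Generator,
) -> "pd.DataFrame":
    import pandas as pd

    opt = _nets.Adam(model.net.parameters(), lr=config.learning_rate)
    history = []
    n = len(samples)
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        ep_sing, ep_cross, ep_total = [], [], []
        grads_acc = None
        in_batch = 0
        for pos, i in enumerate(order):
            s = samples[i]
            volume = s["volume"]
            if config.augment:
                delta = EulerAngles(*rng.uniform(-10.0, 10.0, size=3))
                volume = rotate_volume(volume, delta)
            angles, th, acts = model._forward(volume)
            l_sing, l_cross, l_total, d_angles = _loss_and_angle_grad(
                volume, angles, s["template"], s.get("cmr_slices"),
                s.get("mapping"), weights,
            )
            if not np.isfinite(l_total):
                raise FloatingPointError(
                    f"NaN loss at epoch {epoch}, sample {i}: "
                    f"Lsing={l_sing} Lcross={l_cross}"
                )
            d_raw = d_angles * config.angle_bound_deg * (1.0 - th**2)
            grads = model.net.backward(d_raw, acts)
            if grads_acc is None:
                grads_acc = grads
            else:
                grads_acc = [a + g for a, g in zip(grads_acc, grads)]
            in_batch += 1
            if in_batch == config.batch_size or pos == n - 1:
                opt.step([g / in_batch for g in grads_acc])
                grads_acc, in_batch = None, 0
            ep_sing.append(l_sing)
            ep_cross.append(l_cross)
            ep_total.append(l_total)
        history.append(
            {
                "epoch": epoch,
                "Lsing": float(np.mean(ep_sing)),
                "Lcross": float(np.mean(ep_cross)),
                "Ltotal": float(np.mean(ep_total)),
            }
        )
    return pd.DataFrame(history, columns=["epoch", "Lsing", "Lcross", "Ltotal"])


def train_reorientation(
    dataset: list[tuple],
    config: ReorientModelConfig,
    weights: LossWeights = LossWeights(),
    slice_mapping: SliceMapping | None = None,
) -> tuple[ReorientModel, "pd.DataFrame"]:
    """Train the reorientation network self-supervised.

    ``dataset`` holds tuples ``(rotated_volume, template, cmr_slices)``;
    ``cmr_slices`` may be None to train single-modal only.  The cross-modal
    slice mapping is shared across samples (the template fixes the target
    orientation) and may be passed explicitly; otherwise the cross-modal
    term is skipped.  Returns the model and a per-epoch loss history.
    """
    if not dataset:
        raise ValueError("empty dataset")
    shapes = {tuple(s[0].shape) for s in dataset}
    if len(shapes) != 1:
        raise ValueError("all volumes must share one shape")

    rng = np.random.default_rng(config.seed)
    model = ReorientModel(config, rng)
    samples = [
        {
            "volume": s[0],
            "template": s[1],
            "cmr_slices": s[2] if len(s) > 2 else None,
            "mapping": slice_mapping,
        }
        for s in dataset
    ]
    history = _run_training(model, samples, weights, config, rng)
    return model, history


def fine_tune(
    model: ReorientModel,
    dataset: list[tuple[Volume3D, Volume3D]],
    config: ReorientModelConfig | None = None,
) -> tuple[ReorientModel, "pd.DataFrame"]:
    """Fine-tune with the single-modal loss against per-sample pseudo-labels."""
    if not dataset:
        raise ValueError("empty dataset")
    cfg = config if config is not None else model.config
    rng = np.random.default_rng(cfg.seed + 1)
    samples = [
        {"volume": v, "template": pseudo, "cmr_slices": None, "mapping": None}
        for v, pseudo in dataset
    ]
    history = _run_training(model, samples, LossWeights(1.0, 0.0), cfg, rng)
    return model, history
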