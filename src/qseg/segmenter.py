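"""2.5D segmentation: per-view 2D conv nets over [embedding ++ b0] slices.

Per view (axial/coronal/sagittal) a 2D encoder-decoder with skip
connections consumes slices of shape (a, b, C) with C = L + 3: the L
embedding channels of the slice plus the mean-b0 slice and its two
immediate neighbors (embedding neighbors are deliberately not included).
Input and output interpolation layers carry the scale-augmentation
contract: the interpolation scale factor is randomized during training and
pinned to 1.0 (a bit-wise no-op) at inference.

Training draws, per slice, a subset of N measurements applied identically
to every voxel of that slice, with no q-space rotation.  Three schemes are
supported: ``pretrain_frozen`` (encoder untouched), ``scratch_seg_only``
(encoder updated by the segmentation objective), and
``multitask_seg_recon`` (an additional per-voxel reconstruction pass with
rotation and sub-sampling updates encoder and decoder jointly).
"""

from __future__ import annotations

import enum
import hashlib
import json
from dataclasses import dataclass

import numpy as np

from . import nn
from .encoder import (
    EncoderConfig,
    SetCodec,
    featurize_observations,
    featurize_queries,
)
from .errors import (
    ConfigurationError,
    ContractViolationError,
    InvalidArgumentError,
    ShapeError,
)
from .phantom import DWIVolume
from .qspace import AcquisitionScheme, sample_rotation_batch

__all__ = [
    "VIEW_AXES",
    "TrainScheme",
    "LossConfig",
    "SegTrainConfig",
    "SegmentationVolume",
    "TrainingVolume",
    "SegNet2D",
    "embed_volume",
    "assemble_slice_input",
    "compute_class_weights",
    "segmentation_loss",
    "boundary_map",
    "prepare_training_volume",
    "train_view",
    "predict_segmentation",
    "save_segnet",
    "load_segnet",
]

VIEW_AXES = {"sagittal": 0, "coronal": 1, "axial": 2}


class TrainScheme(str, enum.Enum):
    PRETRAIN_FROZEN = "pretrain_frozen"
    SCRATCH_SEG_ONLY = "scratch_seg_only"
    MULTITASK_SEG_RECON = "multitask_seg_recon"


@dataclass(frozen=True)
class LossConfig:
    """Composite-loss configuration.

    ``class_weights`` follow median-frequency balancing (the class at the
    median frequency has weight 1); ``edge_boost`` multiplies the
    cross-entropy weight of voxels within one voxel of a label boundary;
    ``dice_weight`` mixes in the soft multi-class Dice loss.
    """

    class_weights: np.ndarray
    edge_boost: float = 2.0
    dice_weight: float = 1.0

    def __post_init__(self):
        w = np.asarray(self.class_weights, dtype=np.float64)
        if np.any(w <= 0) or self.edge_boost <= 0 or self.dice_weight < 0:
            raise ConfigurationError("loss weights must be positive")
        object.__setattr__(self, "class_weights", w)


@dataclass
class SegTrainConfig:
    """Desk-scale training knobs for one view network."""

    steps: int = 400
    batch_slices: int = 2          # paper default batch size
    lr: float = 1e-4               # paper default, constant
    base_width: int = 16
    edge_boost: float = 2.0
    dice_weight: float = 1.0
    scale_augment: bool = True
    scale_mean: float = 1.0
    scale_sd: float = 0.1
    scale_clip: tuple = (0.8, 1.2)
    recon_batch: int = 1024        # voxels per reconstruction pass (multitask)
    recon_weight: float = 1.0


@dataclass
class SegmentationVolume:
    labels: np.ndarray
    class_count: int
    spacing: float = 1.0


# ---------------------------------------------------------------------------
# Backbone
# ---------------------------------------------------------------------------

class SegNet2D(nn.Module):
    """Two-level 2D encoder-decoder with skip connection and interpolation
    layers at input and output (the randomized-scale augmentation target)."""

    def __init__(self, in_ch: int, n_classes: int, base_width: int = 16, seed: int = 0):
        rng = np.random.default_rng(seed)
        f = base_width
        self.in_ch = in_ch
        self.n_classes = n_classes
        self.base_width = f
        self.rin = nn.BilinearResize()
        self.c1a, self.r1a = nn.Conv2d(rng, in_ch, f), nn.ReLU()
        self.c1b, self.r1b = nn.Conv2d(rng, f, f), nn.ReLU()
        self.pool = nn.MaxPool2()
        self.c2a, self.r2a = nn.Conv2d(rng, f, 2 * f), nn.ReLU()
        self.c2b, self.r2b = nn.Conv2d(rng, 2 * f, 2 * f), nn.ReLU()
        self.up = nn.UpsampleNearest2()
        self.c3a, self.r3a = nn.Conv2d(rng, 3 * f, f), nn.ReLU()
        self.c3b, self.r3b = nn.Conv2d(rng, f, f), nn.ReLU()
        self.out = nn.Conv2d(rng, f, n_classes, k=1)
        self.rout = nn.BilinearResize()

    def forward(self, x: np.ndarray, scale: float = 1.0) -> np.ndarray:
        """x (B, H, W, C) -> logits (B, H, W, S).

        ``scale`` sets the inner working resolution; 1.0 short-circuits both
        interpolation layers (bit-wise identity).
        """
        b, h, w, c = x.shape
        if c != self.in_ch:
            raise ShapeError(f"expected {self.in_ch} input channels, got {c}")
        hs = max(8, 2 * int(round(h * scale / 2)))
        ws = max(8, 2 * int(round(w * scale / 2)))
        x = self.rin.forward(x.astype(nn.DTYPE), hs, ws)
        a = self.r1b.forward(self.c1b.forward(self.r1a.forward(self.c1a.forward(x))))
        p = self.pool.forward(a)
        d = self.r2b.forward(self.c2b.forward(self.r2a.forward(self.c2a.forward(p))))
        u = self.up.forward(d)
        self._split = a.shape[-1]
        cat = np.concatenate([a, u], axis=-1)
        e = self.r3b.forward(self.c3b.forward(self.r3a.forward(self.c3a.forward(cat))))
        logits = self.out.forward(e)
        return self.rout.forward(logits, h, w)

    def backward(self, g: np.ndarray) -> np.ndarray:
        g = self.rout.backward(g.astype(nn.DTYPE))
        g = self.out.backward(g)
        g = self.c3a.backward(self.r3a.backward(self.c3b.backward(self.r3b.backward(g))))
        ga, gu = g[..., : self._split], g[..., self._split:]
        g = self.up.backward(gu)
        g = self.c2a.backward(self.r2a.backward(self.c2b.backward(self.r2b.backward(g))))
        g = self.pool.backward(g)
        g = ga + g
        g = self.c1a.backward(self.r1a.backward(self.c1b.backward(self.r1b.backward(g))))
        return self.rin.backward(g)

    def param_digest(self) -> str:
        h = hashlib.sha256()
        for a in self.state_arrays():
            h.update(a.tobytes())
        return h.hexdigest()


# ---------------------------------------------------------------------------
# Embedding volumes and slice assembly
# ---------------------------------------------------------------------------

def _checked_b0(mean_b0: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """In-mask b0 values, guarded by the degenerate-voxel floor
    (1e-6 x median in-mask b0)."""
    from .errors import DegenerateVoxelError

    b0 = mean_b0[mask]
    eps = 1e-6 * float(np.median(b0)) if b0.size else 0.0
    if np.any(b0 <= eps):
        raise DegenerateVoxelError(
            f"{int((b0 <= eps).sum())} in-mask voxel(s) have mean b0 at or "
            f"below the floor {eps:.3g}"
        )
    return b0


def embed_volume(
    dwi: DWIVolume,
    mask: np.ndarray,
    model: SetCodec,
    subset_indices: np.ndarray,
    chunk: int = 16384,
) -> np.ndarray:
    """Encode every in-mask voxel and scatter into a (W, H, D, L) volume.

    The encoder runs only on gathered in-mask voxels; all other voxels are
    zero in every embedding channel.  Equals dense voxel-by-voxel encoding
    restricted to the mask.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != dwi.data.shape[:3]:
        raise ShapeError(
            f"mask shape {mask.shape} does not match volume shape {dwi.data.shape[:3]}"
        )
    idx = np.asarray(subset_indices, dtype=int)
    if idx.size == 0 or idx.min() < 0 or idx.max() >= dwi.scheme.M:
        raise InvalidArgumentError("subset_indices out of range for the scheme")
    cfg = model.config
    out = np.zeros(mask.shape + (cfg.L,), dtype=np.float32)
    n_vox = int(mask.sum())
    if n_vox == 0:
        return out
    bvecs = dwi.scheme.bvecs[idx]
    bvals = dwi.scheme.bvals[idx]
    b0 = _checked_b0(dwi.mean_b0, mask)
    sig = np.clip(dwi.data[mask][:, idx] / b0[:, None], 0.0, cfg.clip_max)
    geom = featurize_queries(bvecs, bvals, cfg.bval_scale).astype(np.float32)
    emb = np.empty((n_vox, cfg.L), dtype=np.float32)
    n = len(idx)
    for start in range(0, n_vox, chunk):
        s = sig[start:start + chunk]
        b = len(s)
        feats = np.concatenate(
            [np.broadcast_to(geom, (b, n, geom.shape[-1])), s[..., None]], axis=-1
        )
        emb[start:start + chunk], _ = model.encode_forward(feats, mask=None)
    out[mask] = emb
    return out


def assemble_slice_input(
    emb_volume: np.ndarray, mean_b0: np.ndarray, index: int, view: str
) -> np.ndarray:
    """Build one (a, b, L + 3) slice input.

    Channel order: the L embedding channels of the slice at ``index``
    (no neighboring embedding slices), then the mean-b0 slices at
    ``index - 1``, ``index``, ``index + 1``.  Missing neighbors at the
    volume edge are edge-replicated.
    """
    if view not in VIEW_AXES:
        raise InvalidArgumentError(
            f"unknown view {view!r}; expected one of {sorted(VIEW_AXES)}"
        )
    axis = VIEW_AXES[view]
    size = emb_volume.shape[axis]
    if not 0 <= index < size:
        raise InvalidArgumentError(f"slice index {index} out of range [0, {size})")
    emb_slice = np.take(emb_volume, index, axis=axis)
    b0_slices = [
        np.take(mean_b0, min(max(index + d, 0), size - 1), axis=axis)[..., None]
        for d in (-1, 0, 1)
    ]
    return np.concatenate([emb_slice] + b0_slices, axis=-1)


# ---------------------------------------------------------------------------
# Loss
# ---------------------------------------------------------------------------

def compute_class_weights(label_volume: np.ndarray, num_classes: int) -> np.ndarray:
    """Median-frequency class weights: w_c = median(frequencies) / freq_c."""
    labels = np.asarray(label_volume)
    counts = np.bincount(labels.reshape(-1), minlength=num_classes).astype(float)
    missing = np.flatnonzero(counts == 0)
    if missing.size:
        raise ConfigurationError(
            f"classes absent from the training labels: {missing.tolist()}"
        )
    freqs = counts / counts.sum()
    return np.median(freqs) / freqs


def boundary_map(labels: np.ndarray) -> np.ndarray:
    """Voxels with at least one face-neighbor holding a different label."""
    labels = np.asarray(labels)
    edge = np.zeros(labels.shape, dtype=bool)
    for axis in range(labels.ndim):
        sl_a = [slice(None)] * labels.ndim
        sl_b = [slice(None)] * labels.ndim
        sl_a[axis] = slice(1, None)
        sl_b[axis] = slice(None, -1)
        diff = labels[tuple(sl_a)] != labels[tuple(sl_b)]
        edge[tuple(sl_a)] |= diff
        edge[tuple(sl_b)] |= diff
    return edge


_PROB_FLOOR = 1e-7


def _loss_terms(probs, labels, loss_cfg: LossConfig, edge_mask):
    """Cross-entropy and Dice terms plus the gradient w.r.t. probabilities."""
    s = probs.shape[-1]
    flat_p = probs.reshape(-1, s).astype(np.float64)
    flat_t = labels.reshape(-1)
    n = len(flat_t)
    w = loss_cfg.class_weights[flat_t].copy()
    if edge_mask is not None:
        w[edge_mask.reshape(-1)] *= loss_cfg.edge_boost
    p_true = np.clip(flat_p[np.arange(n), flat_t], _PROB_FLOOR, None)
    ce = float((w * -np.log(p_true)).mean())

    onehot = np.zeros_like(flat_p)
    onehot[np.arange(n), flat_t] = 1.0
    inter = (flat_p * onehot).sum(axis=0)
    psum = flat_p.sum(axis=0)
    tsum = onehot.sum(axis=0)
    eps = 1e-6
    dice_per_class = 1.0 - (2 * inter + eps) / (psum + tsum + eps)
    dice = float(dice_per_class.mean())

    # gradient w.r.t. probabilities
    g = np.zeros_like(flat_p)
    g[np.arange(n), flat_t] = -w / (p_true * n)
    denom = (psum + tsum + eps) ** 2
    g_dice = -(2 * onehot * (psum + tsum + eps) - (2 * inter + eps)) / denom / s
    g += loss_cfg.dice_weight * g_dice
    return ce, dice, g.reshape(probs.shape)


def segmentation_loss(pred_probs, target_labels, loss_cfg: LossConfig,
                      edge_mask=None) -> float:
    """Composite loss: median-frequency weighted cross-entropy with edge
    boost, plus ``dice_weight`` times the soft multi-class Dice loss.

    ``pred_probs`` must be normalized per voxel (sum to 1 within 1e-5).
    """
    probs = np.asarray(pred_probs, dtype=np.float64)
    sums = probs.sum(axis=-1)
    if np.any(np.abs(sums - 1.0) > 1e-5):
        raise ContractViolationError(
            "pred_probs rows must sum to 1 within 1e-5; worst deviation "
            f"{np.abs(sums - 1.0).max():.3g}"
        )
    ce, dice, _ = _loss_terms(probs, np.asarray(target_labels), loss_cfg, edge_mask)
    return ce + loss_cfg.dice_weight * dice


def _softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def _loss_and_grad_logits(logits, labels, loss_cfg: LossConfig, edge_mask):
    """Fused softmax + composite loss; returns (loss, dloss/dlogits)."""
    probs = _softmax(logits.astype(np.float64))
    ce, dice, g_probs = _loss_terms(probs, labels, loss_cfg, edge_mask)
    inner = (g_probs * probs).sum(axis=-1, keepdims=True)
    g_logits = probs * (g_probs - inner)
    return ce + loss_cfg.dice_weight * dice, g_logits.astype(nn.DTYPE)


# ---------------------------------------------------------------------------
# Training data preparation
# ---------------------------------------------------------------------------

@dataclass
class TrainingVolume:
    """One phantom/participant prepared for slice-wise training."""

    shape: tuple
    signals: np.ndarray      # (V, M_dw) normalized in-mask signals
    coords: np.ndarray       # (V, 3) in-mask voxel coordinates
    mask: np.ndarray         # (W, H, D) bool
    labels: np.ndarray       # (W, H, D) int
    edges: np.ndarray        # (W, H, D) bool, label-boundary voxels
    zb0: np.ndarray          # (W, H, D) z-scored mean b0
    rows_by_view: dict       # view -> list over slice index of row-index arrays


def prepare_training_volume(
    dwi: DWIVolume, mask: np.ndarray, labels: np.ndarray, config: EncoderConfig
) -> TrainingVolume:
    """Normalize, z-score the b0, and index in-mask voxels per view slice."""
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != dwi.data.shape[:3] or labels.shape != mask.shape:
        raise ShapeError("dwi, mask, and labels must share the 3D grid shape")
    dw = dwi.scheme.dw_indices
    b0 = _checked_b0(dwi.mean_b0, mask)
    signals = np.clip(
        dwi.data[mask][:, dw] / b0[:, None], 0.0, config.clip_max
    ).astype(np.float32)
    coords = np.argwhere(mask)
    mu = float(dwi.mean_b0[mask].mean())
    sd = float(dwi.mean_b0[mask].std()) or 1.0
    zb0 = ((dwi.mean_b0 - mu) / sd).astype(np.float32)
    rows_by_view = {}
    for view, axis in VIEW_AXES.items():
        per_slice = [np.array([], dtype=int)] * mask.shape[axis]
        order = np.argsort(coords[:, axis], kind="stable")
        sl = coords[order, axis]
        bounds = np.searchsorted(sl, np.arange(mask.shape[axis] + 1))
        for i in range(mask.shape[axis]):
            per_slice[i] = order[bounds[i]:bounds[i + 1]]
        rows_by_view[view] = per_slice
    return TrainingVolume(
        shape=mask.shape, signals=signals, coords=coords, mask=mask,
        labels=np.asarray(labels), edges=boundary_map(labels), zb0=zb0,
        rows_by_view=rows_by_view,
    )


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

def _slice_plane_axes(axis: int):
    return tuple(a for a in range(3) if a != axis)


def _truncated_normal(rng, mean, sd, lo, hi):
    for _ in range(100):
        v = rng.normal(mean, sd)
        if lo <= v <= hi:
            return v
    return float(np.clip(v, lo, hi))


def train_view(
    view: str,
    volumes: list[TrainingVolume],
    scheme: TrainScheme,
    encoder: SetCodec,
    acq_scheme: AcquisitionScheme,
    config: SegTrainConfig,
    seed: int = 0,
    class_weights: np.ndarray | None = None,
    segnet: SegNet2D | None = None,
):
    """Train one view network under the chosen scheme.

    Per step, ``batch_slices`` random slices are drawn; per slice a subset
    of N ~ U[n_min, M] measurements is drawn and applied identically to all
    voxels of that slice (no q-space rotation in the segmentation pass).
    The interpolation scale factor is drawn from a truncated normal
    distribution per step.

    ``pretrain_frozen`` never touches the encoder; ``scratch_seg_only``
    updates it from the segmentation objective; ``multitask_seg_recon``
    additionally runs a per-voxel reconstruction pass (with rotation and
    sub-sampling) whose MSE updates encoder and decoder, both updates being
    applied in a single joint optimizer step.

    Returns (segnet, history).
    """
    if view not in VIEW_AXES:
        raise InvalidArgumentError(f"unknown view {view!r}")
    scheme = TrainScheme(scheme)
    if encoder is None:
        raise ConfigurationError(f"training scheme {scheme.value} requires an encoder")
    if not volumes:
        raise InvalidArgumentError("need at least one training volume")
    shapes = {v.shape for v in volumes}
    if len(shapes) != 1:
        raise ShapeError(f"training volumes must share one grid shape, got {shapes}")

    ecfg = encoder.config
    dw = acq_scheme.dw_indices
    dirs = acq_scheme.bvecs[dw]
    bvals_dw = acq_scheme.bvals[dw]
    m = len(dw)
    if m < ecfg.n_min:
        raise ConfigurationError(f"scheme has {m} directions, fewer than n_min={ecfg.n_min}")
    geom = featurize_queries(dirs, bvals_dw, ecfg.bval_scale).astype(np.float32)

    n_classes = int(max(v.labels.max() for v in volumes)) + 1
    if class_weights is None:
        class_weights = compute_class_weights(
            np.concatenate([v.labels.reshape(-1) for v in volumes]), n_classes
        )
    loss_cfg = LossConfig(class_weights, config.edge_boost, config.dice_weight)

    axis = VIEW_AXES[view]
    plane = _slice_plane_axes(axis)
    slice_pool = [
        (vi, si)
        for vi, vol in enumerate(volumes)
        for si in range(vol.shape[axis])
        if len(vol.rows_by_view[view][si]) > 0
    ]

    rng = np.random.default_rng(seed)
    if segnet is None:
        segnet = SegNet2D(ecfg.L + 3, n_classes, config.base_width,
                          seed=int(rng.integers(2**31)))
    trainable = list(segnet.params())
    if scheme is not TrainScheme.PRETRAIN_FROZEN:
        trainable += encoder.pre.params() + encoder.post.params()
    if scheme is TrainScheme.MULTITASK_SEG_RECON:
        trainable += encoder.dec.params()
    opt = nn.Adam(trainable, lr=config.lr)

    recon_pool = np.concatenate([v.signals for v in volumes]) \
        if scheme is TrainScheme.MULTITASK_SEG_RECON else None

    history = {"seg_loss": []}
    if scheme is TrainScheme.MULTITASK_SEG_RECON:
        history["recon_loss"] = []

    h, w = [volumes[0].shape[a] for a in plane]
    c = ecfg.L + 3

    for _ in range(config.steps):
        picks = [slice_pool[i] for i in rng.integers(0, len(slice_pool), config.batch_slices)]
        # per-slice subset draw; encoder runs once over all gathered voxels
        all_feats, all_valid, slice_meta = [], [], []
        n_max = 0
        for vi, si in picks:
            vol = volumes[vi]
            rows = vol.rows_by_view[view][si]
            n = int(rng.integers(ecfg.n_min, m + 1))
            cols = rng.permutation(m)[:n]
            n_max = max(n_max, n)
            sig = vol.signals[rows][:, cols]
            feats = np.concatenate(
                [np.broadcast_to(geom[cols], (len(rows), n, geom.shape[-1])),
                 sig[..., None]], axis=-1)
            all_feats.append(feats)
            all_valid.append(n)
            slice_meta.append((vol, rows, si))
        n_total = sum(len(f) for f in all_feats)
        feats_pad = np.zeros((n_total, n_max, 8), dtype=np.float32)
        valid = np.zeros((n_total, n_max), dtype=bool)
        pos = 0
        for feats, n in zip(all_feats, all_valid):
            feats_pad[pos:pos + len(feats), :n] = feats
            valid[pos:pos + len(feats), :n] = True
            pos += len(feats)
        emb, ecache = encoder.encode_forward(feats_pad, valid)

        x = np.zeros((len(picks), h, w, c), dtype=np.float32)
        targets = np.empty((len(picks), h, w), dtype=np.int64)
        edges = np.empty((len(picks), h, w), dtype=bool)
        pos = 0
        for bi, (vol, rows, si) in enumerate(slice_meta):
            pc = vol.coords[rows][:, plane]
            x[bi, pc[:, 0], pc[:, 1], :ecfg.L] = emb[pos:pos + len(rows)]
            pos += len(rows)
            for ci, d in enumerate((-1, 0, 1)):
                j = min(max(si + d, 0), vol.shape[axis] - 1)
                x[bi, :, :, ecfg.L + ci] = np.take(vol.zb0, j, axis=axis)
            targets[bi] = np.take(vol.labels, si, axis=axis)
            edges[bi] = np.take(vol.edges, si, axis=axis)

        scale = _truncated_normal(rng, config.scale_mean, config.scale_sd,
                                  *config.scale_clip) if config.scale_augment else 1.0
        logits = segnet.forward(x, scale=scale)
        loss, g_logits = _loss_and_grad_logits(logits, targets, loss_cfg, edges)
        opt.zero_grad()
        g_x = segnet.backward(g_logits)
        if scheme is not TrainScheme.PRETRAIN_FROZEN:
            g_emb = np.empty_like(emb)
            pos = 0
            for bi, (vol, rows, si) in enumerate(slice_meta):
                pc = vol.coords[rows][:, plane]
                g_emb[pos:pos + len(rows)] = g_x[bi, pc[:, 0], pc[:, 1], :ecfg.L]
                pos += len(rows)
            encoder.encode_backward(ecache, g_emb)
        history["seg_loss"].append(float(loss))

        if scheme is TrainScheme.MULTITASK_SEG_RECON:
            r_loss = _reconstruction_pass(
                encoder, recon_pool, dirs, bvals_dw, config.recon_batch,
                config.recon_weight, rng)
            history["recon_loss"].append(r_loss)
        opt.step()
    return segnet, history


def _reconstruction_pass(encoder, pool, dirs, bvals_dw, batch, weight, rng) -> float:
    """Voxel-based reconstruction pass with rotation + sub-sampling
    augmentation; accumulates gradients into encoder and decoder."""
    cfg = encoder.config
    m = len(dirs)
    idx = rng.integers(0, len(pool), size=min(batch, len(pool)))
    sig = pool[idx]
    b = len(sig)
    n_per_voxel = rng.integers(cfg.n_min, m + 1, size=b)
    rank = np.argsort(np.argsort(rng.random((b, m)), axis=1), axis=1)
    valid = rank < n_per_voxel[:, None]
    rot = sample_rotation_batch(rng, b)
    bv = np.einsum("bij,mj->bmi", rot, dirs)
    ofeats = featurize_observations(
        bv, np.broadcast_to(bvals_dw, (b, m)), sig, cfg.bval_scale)
    qfeats = featurize_queries(bv, np.broadcast_to(bvals_dw, (b, m)), cfg.bval_scale)
    emb, ecache = encoder.encode_forward(ofeats, valid)
    preds, dcache = encoder.decode_forward(qfeats, emb)
    resid = preds - sig
    g_emb = encoder.decode_backward(dcache, weight * (2.0 / resid.size) * resid)
    encoder.encode_backward(ecache, g_emb)
    return float((resid**2).mean())


# ---------------------------------------------------------------------------
# Inference
# ---------------------------------------------------------------------------

def predict_segmentation(
    dwi: DWIVolume,
    mask: np.ndarray,
    per_view_nets: dict,
    encoder: SetCodec,
    subset_indices: np.ndarray,
    batch_slices: int = 8,
    spacing: float = 1.0,
    return_probs: bool = False,
):
    """Segment a volume by aggregating per-view slice predictions.

    The embedding volume is computed once for the given measurement subset;
    each supplied view produces a 3D probability volume slice by slice
    (scale pinned to 1.0); views are combined by an unweighted voxel-wise
    mean; the final label is the argmax (ties toward the lowest class
    index) and out-of-mask voxels are forced to background.
    """
    if not per_view_nets:
        raise InvalidArgumentError("need trained parameters for at least one view")
    for v in per_view_nets:
        if v not in VIEW_AXES:
            raise InvalidArgumentError(f"unknown view {v!r}")
    mask = np.asarray(mask, dtype=bool)
    emb = embed_volume(dwi, mask, encoder, subset_indices)
    mu = float(dwi.mean_b0[mask].mean()) if mask.any() else 0.0
    sd = float(dwi.mean_b0[mask].std()) or 1.0 if mask.any() else 1.0
    zb0 = ((dwi.mean_b0 - mu) / sd).astype(np.float32)

    any_net = next(iter(per_view_nets.values()))
    s = any_net.n_classes
    prob_sum = np.zeros(mask.shape + (s,), dtype=np.float32)
    for view, net in per_view_nets.items():
        axis = VIEW_AXES[view]
        size = mask.shape[axis]
        for start in range(0, size, batch_slices):
            stack = np.stack([
                assemble_slice_input(emb, zb0, i, view)
                for i in range(start, min(start + batch_slices, size))
            ])
            probs = _softmax(net.forward(stack, scale=1.0))
            for off in range(len(stack)):
                sl = [slice(None)] * 3
                sl[axis] = start + off
                prob_sum[tuple(sl)] += probs[off]
    mean_probs = prob_sum / len(per_view_nets)
    labels = mean_probs.argmax(axis=-1).astype(np.int32)
    labels[~mask] = 0
    seg = SegmentationVolume(labels=labels, class_count=s, spacing=spacing)
    return (seg, mean_probs) if return_probs else seg


# ---------------------------------------------------------------------------
# Per-view checkpoints
# ---------------------------------------------------------------------------

def save_segnet(path, net: SegNet2D) -> None:
    meta = {"in_ch": net.in_ch, "n_classes": net.n_classes, "base_width": net.base_width}
    arrays = {f"p{i}": a for i, a in enumerate(net.state_arrays())}
    np.savez(path, meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8), **arrays)


def load_segnet(path) -> SegNet2D:
    with np.load(path) as npz:
        meta = json.loads(bytes(npz["meta"]).decode())
        arrays = [npz[f"p{i}"] for i in range(sum(1 for k in npz.files if k.startswith("p")))]
    net = SegNet2D(meta["in_ch"], meta["n_classes"], meta["base_width"], seed=0)
    net.load_state_arrays(arrays)
    return net
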