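"""Per-voxel set encoder/decoder for unstructured diffusion measurements.

The encoder maps a variable-length, unordered observation set of
(b-vector, b-value, normalized signal) triplets to a fixed-length
diffusion embedding; the decoder predicts the signal for an arbitrary
query (b-vector, b-value) from that embedding.

Two invariances are architectural:

* permutation invariance over the set, via symmetric mean pooling;
* antipodal sign invariance (g and -g are the same measurement), because
  every b-vector enters only through the six unique entries of its
  symmetric outer product g g^T — an even function of g.

Pre-training minimizes the mean squared error of reconstructing all M
scheme signals from random subsets of N measurements, with per-voxel
subset-size, subset-choice, and joint q-space rotation augmentation.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass

import numpy as np

from . import nn
from .errors import (
    ConfigurationError,
    DegenerateVoxelError,
    InvalidArgumentError,
)
from .qspace import AcquisitionScheme, sample_rotation_batch

__all__ = [
    "ObservationSet",
    "QueryVector",
    "DiffusionEmbedding",
    "EncoderConfig",
    "SetCodec",
    "VoxelDataset",
    "normalize_signals",
    "normalize_volume",
    "featurize_measurement",
    "featurize_observations",
    "featurize_queries",
    "encode",
    "decode",
    "reconstruct",
    "pretrain_reconstruction",
    "save_checkpoint",
    "load_checkpoint",
    "scheme_fingerprint",
]


@dataclass(frozen=True)
class ObservationSet:
    """Parallel sequences of N b-vectors, b-values, and normalized signals."""

    bvecs: np.ndarray   # (N, 3)
    bvals: np.ndarray   # (N,)
    signals: np.ndarray  # (N,)

    def __post_init__(self):
        bvecs = np.atleast_2d(np.asarray(self.bvecs, dtype=float))
        bvals = np.atleast_1d(np.asarray(self.bvals, dtype=float))
        signals = np.atleast_1d(np.asarray(self.signals, dtype=float))
        if len(bvecs) < 1:
            raise InvalidArgumentError("observation set must contain N >= 1 measurements")
        if not (len(bvecs) == len(bvals) == len(signals)):
            raise InvalidArgumentError(
                "bvecs, bvals, and signals must have equal length; got "
                f"{len(bvecs)}, {len(bvals)}, {len(signals)}"
            )
        object.__setattr__(self, "bvecs", bvecs)
        object.__setattr__(self, "bvals", bvals)
        object.__setattr__(self, "signals", signals)

    @property
    def N(self) -> int:
        return len(self.bvals)


@dataclass(frozen=True)
class QueryVector:
    bvec: np.ndarray
    bval: float

    def __post_init__(self):
        v = np.asarray(self.bvec, dtype=float).reshape(3)
        if self.bval > 0 and abs(np.linalg.norm(v) - 1.0) > 1e-6:
            raise InvalidArgumentError("query b-vector must be unit norm for bval > 0")
        object.__setattr__(self, "bvec", v)


@dataclass(frozen=True)
class DiffusionEmbedding:
    values: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.values, dtype=np.float32).reshape(-1)
        if not np.all(np.isfinite(v)):
            raise InvalidArgumentError("embedding contains non-finite values")
        object.__setattr__(self, "values", v)

    @property
    def L(self) -> int:
        return len(self.values)


@dataclass(frozen=True)
class EncoderConfig:
    """Hyper-parameters of the set codec.

    ``L`` is the embedding length; ``hidden_width`` the feature dimension of
    the per-measurement, post-pooling, and decoder stages; ``*_depth`` the
    number of affine layers per stage.  ``bval_scale`` normalizes b-values
    (default 1000 s/mm^2, the single-shell working regime); ``clip_max``
    bounds normalized signals; ``n_min`` is the smallest subset size drawn
    during augmentation.
    """

    L: int = 32
    hidden_width: int = 64
    pre_depth: int = 3
    post_depth: int = 2
    dec_depth: int = 3
    bval_scale: float = 1000.0
    clip_max: float = 2.0
    n_min: int = 5

    def __post_init__(self):
        if self.L < 1:
            raise ConfigurationError("embedding length L must be >= 1")
        if self.hidden_width < self.L:
            raise ConfigurationError("hidden_width must be >= L")


N_OBS_FEATURES = 8   # 6 outer-product entries + scaled b-value + signal
N_QUERY_FEATURES = 7


# ---------------------------------------------------------------------------
# Normalization and featurization
# ---------------------------------------------------------------------------

def normalize_signals(dwi_voxel, mean_b0_voxel: float, clip_max: float = 2.0,
                      eps: float = 1e-6):
    """Divide a voxel's signals by its mean b0 and clip to [0, clip_max].

    Raises
    ------
    DegenerateVoxelError
        If ``mean_b0_voxel <= eps``.  Callers inside the brain mask must
        handle (not silently skip) this.
    """
    if mean_b0_voxel <= eps:
        raise DegenerateVoxelError(
            f"mean b0 value {mean_b0_voxel!r} is at or below the floor {eps!r}"
        )
    return np.clip(np.asarray(dwi_voxel, dtype=float) / mean_b0_voxel, 0.0, clip_max)


def normalize_volume(data: np.ndarray, mean_b0: np.ndarray, mask: np.ndarray,
                     clip_max: float = 2.0) -> np.ndarray:
    """Normalize a 4D volume voxel-wise by the mean b0, inside the mask.

    The degeneracy floor is 1e-6 times the median in-mask b0 value.  Returns
    float32, zeros outside the mask.
    """
    b0_med = float(np.median(mean_b0[mask])) if np.any(mask) else 0.0
    eps = 1e-6 * b0_med
    b0 = mean_b0[mask]
    if np.any(b0 <= eps):
        n_bad = int((b0 <= eps).sum())
        raise DegenerateVoxelError(
            f"{n_bad} in-mask voxel(s) have mean b0 at or below the floor {eps:.3g}"
        )
    out = np.zeros(data.shape, dtype=np.float32)
    out[mask] = np.clip(data[mask] / b0[:, None], 0.0, clip_max)
    return out


def _outer_features(bvecs: np.ndarray) -> np.ndarray:
    """Six unique entries of g g^T in fixed (xx, xy, xz, yy, yz, zz) order.

    Even in g by construction, so sign flips change nothing bit-wise.
    """
    x, y, z = bvecs[..., 0], bvecs[..., 1], bvecs[..., 2]
    return np.stack([x * x, x * y, x * z, y * y, y * z, z * z], axis=-1)


def featurize_observations(bvecs, bvals, signals, bval_scale: float = 1000.0) -> np.ndarray:
    """Per-measurement feature rows (..., 8)."""
    bvecs = np.asarray(bvecs, dtype=float)
    bvals = np.asarray(bvals, dtype=float)
    signals = np.asarray(signals, dtype=float)
    return np.concatenate(
        [_outer_features(bvecs), (bvals / bval_scale)[..., None], signals[..., None]],
        axis=-1,
    )


def featurize_queries(bvecs, bvals, bval_scale: float = 1000.0) -> np.ndarray:
    """Query feature rows (..., 7): outer product + scaled b-value."""
    bvecs = np.asarray(bvecs, dtype=float)
    bvals = np.asarray(bvals, dtype=float)
    return np.concatenate(
        [_outer_features(bvecs), (bvals / bval_scale)[..., None]], axis=-1
    )


def featurize_measurement(bvec, bval, signal, bval_scale: float = 1000.0) -> np.ndarray:
    """Feature vector of a single measurement (8,)."""
    return featurize_observations(
        np.asarray(bvec, dtype=float).reshape(1, 3),
        np.atleast_1d(float(bval)),
        np.atleast_1d(float(signal)),
        bval_scale,
    )[0]


# ---------------------------------------------------------------------------
# Model
# ---------------------------------------------------------------------------

class SetCodec(nn.Module):
    """Encoder (per-measurement MLP -> mean pool -> post MLP -> L) and
    decoder (query features ++ embedding -> MLP -> scalar signal).

    Both stages open with a fixed multiplicative interaction expansion —
    products of the (even) outer-product direction features with the signal
    (encoder side) and with the embedding entries (decoder side).  These are
    deterministic functions of the stage inputs, so permutation and
    antipodal-sign invariance are untouched, while the tensor-model
    structure (direction x signal and direction x representation products)
    no longer has to be approximated by ReLU layers.

    The decoder's output layer is zero-initialized, so an untrained model
    predicts exactly its output bias for any query.
    """

    def __init__(self, config: EncoderConfig, seed: int = 0):
        rng = np.random.default_rng(seed)
        h, L = config.hidden_width, config.L
        self.config = config

        n_obs_in = N_OBS_FEATURES + 13      # + log-signal, g g^T x {signal, log-signal}
        n_dec_in = N_QUERY_FEATURES + L + 6 * L  # + g g^T x embedding products
        pre_layers = [nn.Dense(rng, n_obs_in, h), nn.ReLU()]
        for _ in range(config.pre_depth - 1):
            pre_layers += [nn.Dense(rng, h, h), nn.ReLU()]
        self.pre = nn.Sequential(*pre_layers)

        post_layers = []
        for _ in range(config.post_depth - 1):
            post_layers += [nn.Dense(rng, h, h), nn.ReLU()]
        post_layers += [nn.Dense(rng, h, L)]
        self.post = nn.Sequential(*post_layers)

        dec_layers = [nn.Dense(rng, n_dec_in, h), nn.ReLU()]
        for _ in range(config.dec_depth - 2):
            dec_layers += [nn.Dense(rng, h, h), nn.ReLU()]
        dec_layers += [nn.Dense(rng, h, 1, zero_init=True)]
        self.dec = nn.Sequential(*dec_layers)

    # -- batched forward/backward used by training loops ----------------

    @staticmethod
    def _expand_obs(rows: np.ndarray) -> np.ndarray:
        """(R, 8) feature rows -> (R, 21).

        Appends the floored log-signal and the products of the six g g^T
        entries with signal and log-signal.  For the mono-exponential
        tensor model log S is linear in the tensor, so the pooled means of
        these products are (nearly) sufficient statistics for the
        least-squares tensor estimate.
        """
        s = rows[:, 7:8]
        log_s = np.log(np.clip(s, 5e-3, None), dtype=rows.dtype)
        g6 = rows[:, :6]
        return np.concatenate([rows, log_s, g6 * s, g6 * log_s], axis=1)

    def encode_forward(self, feats: np.ndarray, mask: np.ndarray | None = None):
        """feats (B, M, 8); mask (B, M) selects the active subset per voxel.

        Returns (emb (B, L), cache).  Masked-out rows do not contribute to
        the pooled mean and receive zero gradient.
        """
        b, m, f = feats.shape
        rows = np.ascontiguousarray(feats.reshape(b * m, f), dtype=nn.DTYPE)
        h = self.pre.forward(self._expand_obs(rows)).reshape(b, m, -1)
        if mask is None:
            counts = None
            pooled = h.mean(axis=1)
        else:
            counts = mask.sum(axis=1).astype(nn.DTYPE)
            if np.any(counts < 1):
                raise InvalidArgumentError("every voxel needs at least one active measurement")
            pooled = (h * mask[..., None]).sum(axis=1) / counts[:, None]
        emb = self.post.forward(np.ascontiguousarray(pooled, dtype=nn.DTYPE))
        return emb, (b, m, mask, counts)

    def encode_backward(self, cache, g_emb: np.ndarray) -> None:
        b, m, mask, counts = cache
        gp = self.post.backward(np.ascontiguousarray(g_emb, dtype=nn.DTYPE))
        if mask is None:
            grows = np.broadcast_to(gp[:, None, :] / m, (b, m, gp.shape[-1]))
        else:
            grows = gp[:, None, :] * (mask[..., None] / counts[:, None, None])
        self.pre.backward(np.ascontiguousarray(grows.reshape(b * m, -1), dtype=nn.DTYPE))

    def decode_forward(self, qfeats: np.ndarray, emb: np.ndarray):
        """qfeats (B, Q, 7), emb (B, L) -> predictions (B, Q).

        Decoder rows: [query features (7) | embedding (L) | products of the
        6 outer-product query features with the L embedding entries (6L)].
        """
        b, q, f = qfeats.shape
        L = emb.shape[1]
        qf = np.ascontiguousarray(qfeats.reshape(b * q, f), dtype=nn.DTYPE)
        er = np.repeat(emb.astype(nn.DTYPE), q, axis=0)
        prod = (qf[:, :6, None] * er[:, None, :]).reshape(b * q, 6 * L)
        rows = np.concatenate([qf, er, prod], axis=1)
        preds = self.dec.forward(rows).reshape(b, q)
        return preds, (b, q, f, L, qf)

    def decode_backward(self, cache, g_pred: np.ndarray) -> np.ndarray:
        """Returns the gradient w.r.t. the embedding, (B, L)."""
        b, q, f, L, qf = cache
        grows = self.dec.backward(
            np.ascontiguousarray(g_pred.reshape(b * q, 1), dtype=nn.DTYPE)
        )
        g_emb_rows = grows[:, f:f + L]
        g_prod = grows[:, f + L:].reshape(b * q, 6, L)
        g_emb_rows = g_emb_rows + (qf[:, :6, None] * g_prod).sum(axis=1)
        return g_emb_rows.reshape(b, q, L).sum(axis=1)

    def param_digest(self) -> str:
        """SHA-256 over all parameter bytes; detects any parameter change."""
        h = hashlib.sha256()
        for a in self.state_arrays():
            h.update(a.tobytes())
        return h.hexdigest()


# ---------------------------------------------------------------------------
# Public single-voxel API
# ---------------------------------------------------------------------------

def encode(obs: ObservationSet, model: SetCodec) -> DiffusionEmbedding:
    """Encode one observation set into a fixed-length embedding.

    Invariant to measurement order and to sign flips of any subset of the
    b-vectors.
    """
    feats = featurize_observations(
        obs.bvecs, obs.bvals, obs.signals, model.config.bval_scale
    )[None]
    emb, _ = model.encode_forward(feats, mask=None)
    return DiffusionEmbedding(emb[0])


def decode(query: QueryVector, emb: DiffusionEmbedding, model: SetCodec) -> float:
    """Predict the normalized signal for one query vector."""
    if emb.L != model.config.L:
        raise ConfigurationError(
            f"embedding length {emb.L} does not match configured L={model.config.L}"
        )
    qf = featurize_queries(
        query.bvec[None], np.atleast_1d(query.bval), model.config.bval_scale
    )[None]
    preds, _ = model.decode_forward(qf, emb.values[None])
    return float(preds[0, 0])


def reconstruct(model: SetCodec, obs: ObservationSet,
                query_bvecs: np.ndarray, query_bvals: np.ndarray) -> np.ndarray:
    """Predict normalized signals for a batch of queries from one set."""
    emb = encode(obs, model)
    qf = featurize_queries(
        np.atleast_2d(query_bvecs), np.atleast_1d(query_bvals), model.config.bval_scale
    )[None]
    preds, _ = model.decode_forward(qf, emb.values[None])
    return preds[0]


# ---------------------------------------------------------------------------
# Reconstruction pre-training
# ---------------------------------------------------------------------------

@dataclass
class VoxelDataset:
    """Per-voxel normalized signals over the diffusion-weighted directions
    of one scheme: training and validation splits, shapes (V, M_dw)."""

    train_signals: np.ndarray
    val_signals: np.ndarray


def pretrain_reconstruction(
    dataset: VoxelDataset,
    scheme: AcquisitionScheme,
    config: EncoderConfig,
    seed: int = 0,
    epochs: int = 100,
    batch_size: int = 4096,
    lr: float = 0.005,
    lr_drop_factor: float = 0.1,
    rotate: bool = True,
    model: SetCodec | None = None,
):
    """Pre-train the codec to reconstruct all M signals from random subsets.

    Per training step and voxel: a subset size N is drawn uniformly in
    [n_min, M], N of M measurements are chosen without replacement, a Haar
    rotation is applied jointly to observation and query b-vectors, all M
    signals are predicted, and the mean squared error against the reference
    signals is minimized.  The learning rate drops by ``lr_drop_factor`` at
    the halfway epoch (paper regime: 0.005 -> 0.0005 after 50 of 100).
    Deterministic given ``seed``.

    Returns
    -------
    (model, history) where history holds per-epoch train/val MSE.
    """
    dirs = scheme.bvecs[scheme.dw_indices]
    bvals_dw = scheme.bvals[scheme.dw_indices]
    m = len(dirs)
    if m < config.n_min:
        raise ConfigurationError(
            f"scheme has {m} diffusion-weighted measurements, fewer than n_min={config.n_min}"
        )
    train = np.asarray(dataset.train_signals, dtype=nn.DTYPE)
    val = np.asarray(dataset.val_signals, dtype=nn.DTYPE)
    if train.ndim != 2 or train.shape[1] != m:
        raise ConfigurationError(
            f"training signals must be (V, {m}), got {train.shape}"
        )

    rng = np.random.default_rng(seed)
    if model is None:
        model = SetCodec(config, seed=int(rng.integers(2**31)))
    opt = nn.Adam(model.params(), lr=lr)
    n_train = len(train)
    steps_per_epoch = max(1, n_train // batch_size)
    history = {"train_mse": [], "val_mse": [], "lr": []}

    for epoch in range(epochs):
        opt.lr = lr * (lr_drop_factor if epoch >= epochs // 2 else 1.0)
        perm = rng.permutation(n_train)
        epoch_loss = 0.0
        for step in range(steps_per_epoch):
            idx = perm[step * batch_size:(step + 1) * batch_size]
            sig = train[idx]
            b = len(sig)
            n_per_voxel = rng.integers(config.n_min, m + 1, size=b)
            rank = np.argsort(np.argsort(rng.random((b, m)), axis=1), axis=1)
            mask = rank < n_per_voxel[:, None]
            if rotate:
                rot = sample_rotation_batch(rng, b)
                bv = np.einsum("bij,mj->bmi", rot, dirs)
            else:
                bv = np.broadcast_to(dirs, (b, m, 3))
            ofeats = featurize_observations(
                bv, np.broadcast_to(bvals_dw, (b, m)), sig, config.bval_scale
            )
            qfeats = featurize_queries(
                bv, np.broadcast_to(bvals_dw, (b, m)), config.bval_scale
            )
            emb, ecache = model.encode_forward(ofeats, mask)
            preds, dcache = model.decode_forward(qfeats, emb)
            resid = preds - sig
            epoch_loss += float((resid**2).mean())
            opt.zero_grad()
            g_pred = (2.0 / resid.size) * resid
            g_emb = model.decode_backward(dcache, g_pred)
            model.encode_backward(ecache, g_emb)
            opt.step()
        history["train_mse"].append(epoch_loss / steps_per_epoch)
        history["val_mse"].append(
            float(_full_set_mse(model, val, dirs, bvals_dw, config))
        )
        history["lr"].append(opt.lr)
    return model, history


def _full_set_mse(model, signals, dirs, bvals_dw, config, chunk=8192) -> float:
    """Deterministic validation: full observation set, no rotation."""
    if len(signals) == 0:
        return float("nan")
    m = len(dirs)
    total, count = 0.0, 0
    qf1 = featurize_queries(dirs, bvals_dw, config.bval_scale)
    for start in range(0, len(signals), chunk):
        sig = signals[start:start + chunk]
        b = len(sig)
        ofeats = featurize_observations(
            np.broadcast_to(dirs, (b, m, 3)),
            np.broadcast_to(bvals_dw, (b, m)), sig, config.bval_scale
        )
        emb, _ = model.encode_forward(ofeats, mask=None)
        preds, _ = model.decode_forward(np.broadcast_to(qf1, (b, m, qf1.shape[-1])), emb)
        total += float(((preds - sig) ** 2).sum())
        count += sig.size
    return total / count


# ---------------------------------------------------------------------------
# Checkpoints
# ---------------------------------------------------------------------------

def scheme_fingerprint(scheme: AcquisitionScheme) -> str:
    h = hashlib.sha256()
    h.update(np.round(scheme.bvecs, 6).tobytes())
    h.update(np.round(scheme.bvals, 6).tobytes())
    return h.hexdigest()


def save_checkpoint(path, model: SetCodec, scheme: AcquisitionScheme | None = None) -> None:
    """Single-file archive: parameters + config + scheme fingerprint."""
    meta = {
        "config": asdict(model.config),
        "fingerprint": scheme_fingerprint(scheme) if scheme is not None else None,
    }
    arrays = {f"p{i}": a for i, a in enumerate(model.state_arrays())}
    np.savez(path, meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
             **arrays)


def load_checkpoint(path, scheme: AcquisitionScheme | None = None) -> SetCodec:
    with np.load(path) as npz:
        meta = json.loads(bytes(npz["meta"]).decode())
        arrays = [npz[f"p{i}"] for i in range(sum(1 for k in npz.files if k.startswith("p")))]
    config = EncoderConfig(**meta["config"])
    if scheme is not None and meta["fingerprint"] is not None:
        if scheme_fingerprint(scheme) != meta["fingerprint"]:
            raise ConfigurationError(
                "checkpoint was trained on a different acquisition scheme"
            )
    model = SetCodec(config, seed=0)
    model.load_state_arrays(arrays)
    return model
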