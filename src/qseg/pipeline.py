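"""Pipeline orchestration: simulate -> pretrain -> train -> segment -> evaluate.

Every stochastic stage receives a seed derived deterministically (SHA-256)
from the global seed and the stage name, so a re-run with an identical
configuration reproduces all deterministic artifacts checksum-for-checksum.
Artifacts are written under ``out_dir/<stage>/`` and recorded in a run
manifest with per-file checksums.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import evaluation as ev
from . import io as qio
from .encoder import (
    EncoderConfig, SetCodec, VoxelDataset, load_checkpoint,
    pretrain_reconstruction, save_checkpoint,
)
from .errors import ConfigurationError, DependencyError
from .phantom import (
    build_phantom, default_class_specs, default_scheme, noise_sigma_for_snr,
    simulate_acquisition,
)
from .qspace import read_gradient_table, subsample_max_coverage, write_gradient_table
from .segmenter import (
    SegTrainConfig, TrainScheme, compute_class_weights, load_segnet,
    predict_segmentation, prepare_training_volume, save_segnet, train_view,
)

logger = logging.getLogger("qseg")

STAGES = ("simulate", "pretrain", "train", "segment", "evaluate", "report")

#: default tissue label -> region group
DEFAULT_GROUP_MAP = {
    1: "white-matter",
    2: "cortical-gm",
    3: "vent-csf",
    4: "subcortical-gm",
    5: "cerebellum",
}


@dataclass
class PhantomStageConfig:
    shape: tuple = (64, 64, 64)
    n_train: int = 8
    n_test: int = 2
    n_directions: int = 90
    n_b0: int = 3
    bval: float = 1000.0
    snr: float = 25.0
    spacing: float = 1.0


@dataclass
class PretrainStageConfig:
    L: int = 16
    hidden_width: int = 32
    pre_depth: int = 2
    post_depth: int = 2
    dec_depth: int = 3
    n_min: int = 5
    epochs: int = 30
    batch_size: int = 512
    lr: float = 0.005
    max_voxels: int = 30000
    val_voxels: int = 2000

    def encoder_config(self) -> EncoderConfig:
        return EncoderConfig(
            L=self.L, hidden_width=self.hidden_width, pre_depth=self.pre_depth,
            post_depth=self.post_depth, dec_depth=self.dec_depth, n_min=self.n_min,
        )


@dataclass
class TrainStageConfig:
    scheme: str = "pretrain_frozen"
    views: tuple = ("axial", "coronal", "sagittal")
    steps: int = 400
    lr: float = 1e-3          # desk-scale default; the reference regime is 1e-4
    base_width: int = 16
    edge_boost: float = 2.0
    dice_weight: float = 1.0
    scale_augment: bool = True

    def seg_config(self) -> SegTrainConfig:
        return SegTrainConfig(
            steps=self.steps, lr=self.lr, base_width=self.base_width,
            edge_boost=self.edge_boost, dice_weight=self.dice_weight,
            scale_augment=self.scale_augment,
        )


@dataclass
class EvalStageConfig:
    direction_counts: tuple = (90, 30, 10)
    group_map: dict = field(default_factory=lambda: dict(DEFAULT_GROUP_MAP))


@dataclass
class RunConfig:
    out_dir: str = "qseg_run"
    seed: int = 0
    verbosity: int = 1
    phantom: PhantomStageConfig = field(default_factory=PhantomStageConfig)
    pretrain: PretrainStageConfig = field(default_factory=PretrainStageConfig)
    train: TrainStageConfig = field(default_factory=TrainStageConfig)
    evaluate: EvalStageConfig = field(default_factory=EvalStageConfig)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        kwargs = dict(raw)
        for name, sub in (("phantom", PhantomStageConfig),
                          ("pretrain", PretrainStageConfig),
                          ("train", TrainStageConfig),
                          ("evaluate", EvalStageConfig)):
            if name in kwargs and isinstance(kwargs[name], dict):
                section = dict(kwargs[name])
                if name == "evaluate" and "group_map" in section:
                    section["group_map"] = {int(k): v for k, v in section["group_map"].items()}
                kwargs[name] = sub(**{
                    k: tuple(v) if isinstance(v, list) else v for k, v in section.items()
                })
        return cls(**{
            k: tuple(v) if isinstance(v, list) and k != "out_dir" else v
            for k, v in kwargs.items()
        })

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True, default=str).encode()
        ).hexdigest()


def derive_seed(global_seed: int, stage: str) -> int:
    """Stable, platform-independent per-stage seed (SHA-256 based)."""
    digest = hashlib.sha256(f"{global_seed}:{stage}".encode()).hexdigest()
    return int(digest[:12], 16)


def _sha256_file(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for block in iter(lambda: fh.read(1 << 20), b""):
            h.update(block)
    return h.hexdigest()


# ---------------------------------------------------------------------------
# Stage implementations (file based)
# ---------------------------------------------------------------------------

def _subject_ids(cfg: RunConfig):
    train = [f"train-{i:02d}" for i in range(cfg.phantom.n_train)]
    test = [f"test-{i:02d}" for i in range(cfg.phantom.n_test)]
    return train, test


def _stage_simulate(cfg: RunConfig, out: Path) -> list[Path]:
    p = cfg.phantom
    scheme = default_scheme(p.n_directions, p.n_b0, p.bval,
                            seed=derive_seed(cfg.seed, "scheme"))
    out.mkdir(parents=True, exist_ok=True)
    write_gradient_table(scheme, out / "scheme.bvec", out / "scheme.bval")
    files = [out / "scheme.bvec", out / "scheme.bval"]
    train, test = _subject_ids(cfg)
    for sid in train + test:
        sub = out / sid
        sub.mkdir(exist_ok=True)
        seed = derive_seed(cfg.seed, f"simulate/{sid}")
        phantom = build_phantom(p.shape, default_class_specs(), seed=seed,
                                spacing=p.spacing)
        sigma = noise_sigma_for_snr(phantom, p.snr) if p.snr else 0.0
        dwi = simulate_acquisition(phantom, scheme, sigma, seed=seed + 1)
        qio.write_volume(dwi.data.astype(np.float32), sub / "dwi.nii", p.spacing)
        qio.write_volume(dwi.mean_b0.astype(np.float32), sub / "meanb0.nii", p.spacing)
        qio.write_volume(phantom.mask, sub / "mask.nii", p.spacing)
        qio.write_volume(phantom.labels, sub / "labels.nii", p.spacing)
        files += [sub / "dwi.nii", sub / "meanb0.nii", sub / "mask.nii", sub / "labels.nii"]
        logger.info("simulated %s (shape %s, sigma %.4g)", sid, p.shape, sigma)
    return files


def _load_subject(data_dir: Path, sid: str, scheme):
    from .phantom import DWIVolume

    sub = data_dir / sid
    for name in ("dwi.nii", "meanb0.nii", "mask.nii", "labels.nii"):
        if not (sub / name).exists():
            raise DependencyError(f"missing artifact {sub / name}; run the simulate stage")
    dwi_data, spacing, aff = qio.read_volume(sub / "dwi.nii")
    b0, _, aff2 = qio.read_volume(sub / "meanb0.nii")
    qio.check_aligned(dwi_data.shape, aff, b0.shape, aff2, f"{sid} dwi/meanb0")
    if dwi_data.shape[-1] != scheme.M:
        raise ConfigurationError(
            f"{sid}: DWI has {dwi_data.shape[-1]} volumes but the gradient table has {scheme.M}"
        )
    mask = qio.read_volume(sub / "mask.nii")[0].astype(bool)
    labels = qio.read_label_volume(sub / "labels.nii")[0]
    dwi = DWIVolume(data=dwi_data, scheme=scheme, mean_b0=b0)
    return dwi, mask, labels, spacing[0]


def _read_scheme(data_dir: Path):
    bvec, bval = data_dir / "scheme.bvec", data_dir / "scheme.bval"
    if not bvec.exists() or not bval.exists():
        raise DependencyError(f"missing gradient table in {data_dir}; run the simulate stage")
    return read_gradient_table(bvec, bval)


def _stage_pretrain(cfg: RunConfig, data_dir: Path, out: Path) -> list[Path]:
    scheme = _read_scheme(data_dir)
    train_ids, _ = _subject_ids(cfg)
    if not train_ids:
        raise ConfigurationError("no training subjects configured")
    rng = np.random.default_rng(derive_seed(cfg.seed, "pretrain/voxels"))
    pools = []
    for sid in train_ids:
        dwi, mask, labels, _ = _load_subject(data_dir, sid, scheme)
        tissue = mask & (labels > 0)  # white matter, gray matter, CSF voxels
        b0 = dwi.mean_b0[tissue]
        sig = np.clip(dwi.data[tissue][:, scheme.dw_indices] / b0[:, None], 0.0, 2.0)
        pools.append(sig.astype(np.float32))
    pool = np.concatenate(pools)
    perm = rng.permutation(len(pool))
    n_val = min(cfg.pretrain.val_voxels, len(pool) // 10)
    val = pool[perm[:n_val]]
    train = pool[perm[n_val:n_val + cfg.pretrain.max_voxels]]
    dataset = VoxelDataset(train_signals=train, val_signals=val)
    model, history = pretrain_reconstruction(
        dataset, scheme, cfg.pretrain.encoder_config(),
        seed=derive_seed(cfg.seed, "pretrain"),
        epochs=cfg.pretrain.epochs, batch_size=cfg.pretrain.batch_size,
        lr=cfg.pretrain.lr,
    )
    out.mkdir(parents=True, exist_ok=True)
    save_checkpoint(out / "encoder.npz", model, scheme)
    (out / "history.json").write_text(json.dumps(history, indent=2))
    logger.info("pretrain: final val MSE %.3g", history["val_mse"][-1])
    return [out / "encoder.npz", out / "history.json"]


def _stage_train(cfg: RunConfig, data_dir: Path, pretrain_dir: Path, out: Path) -> list[Path]:
    scheme = _read_scheme(data_dir)
    train_scheme = TrainScheme(cfg.train.scheme)
    if train_scheme is TrainScheme.PRETRAIN_FROZEN:
        ckpt = pretrain_dir / "encoder.npz"
        if not ckpt.exists():
            raise DependencyError(
                "training scheme pretrain_frozen requires the pretrain stage "
                f"(missing {ckpt})"
            )
        encoder = load_checkpoint(ckpt, scheme)
    else:
        encoder = SetCodec(cfg.pretrain.encoder_config(),
                           seed=derive_seed(cfg.seed, "train/encoder"))
    train_ids, _ = _subject_ids(cfg)
    volumes = []
    for sid in train_ids:
        dwi, mask, labels, _ = _load_subject(data_dir, sid, scheme)
        volumes.append(prepare_training_volume(dwi, mask, labels, encoder.config))
    n_classes = int(max(v.labels.max() for v in volumes)) + 1
    weights = compute_class_weights(
        np.concatenate([v.labels.reshape(-1) for v in volumes]), n_classes)
    out.mkdir(parents=True, exist_ok=True)
    files = []
    history_all = {}
    for view in cfg.train.views:
        t0 = time.time()
        net, history = train_view(
            view, volumes, train_scheme, encoder, scheme, cfg.train.seg_config(),
            seed=derive_seed(cfg.seed, f"train/{view}"), class_weights=weights,
        )
        save_segnet(out / f"segnet-{view}.npz", net)
        files.append(out / f"segnet-{view}.npz")
        history_all[view] = history
        logger.info("trained %s view in %.1fs, final loss %.3g",
                    view, time.time() - t0, history["seg_loss"][-1])
    if train_scheme is not TrainScheme.PRETRAIN_FROZEN:
        save_checkpoint(out / "encoder.npz", encoder, scheme)
        files.append(out / "encoder.npz")
    (out / "history.json").write_text(json.dumps(history_all, indent=2))
    files.append(out / "history.json")
    return files


def _trained_encoder(cfg: RunConfig, scheme, pretrain_dir: Path, train_dir: Path):
    if TrainScheme(cfg.train.scheme) is TrainScheme.PRETRAIN_FROZEN:
        return load_checkpoint(pretrain_dir / "encoder.npz", scheme)
    return load_checkpoint(train_dir / "encoder.npz", scheme)


def _stage_segment(cfg: RunConfig, data_dir: Path, pretrain_dir: Path,
                   train_dir: Path, out: Path) -> list[Path]:
    scheme = _read_scheme(data_dir)
    nets = {}
    for view in cfg.train.views:
        path = train_dir / f"segnet-{view}.npz"
        if not path.exists():
            raise DependencyError(f"missing trained view network {path}; run the train stage")
        nets[view] = load_segnet(path)
    encoder = _trained_encoder(cfg, scheme, pretrain_dir, train_dir)
    _, test_ids = _subject_ids(cfg)
    out.mkdir(parents=True, exist_ok=True)
    files = []
    for sid in test_ids:
        dwi, mask, _, spacing = _load_subject(data_dir, sid, scheme)
        for k in cfg.evaluate.direction_counts:
            subset = subsample_max_coverage(scheme, k)
            seg = predict_segmentation(dwi, mask, nets, encoder, subset,
                                       spacing=spacing)
            path = out / f"{sid}_dirs-{k}_seg.nii"
            qio.write_volume(seg.labels, path, spacing)
            files.append(path)
            logger.info("segmented %s with %d directions", sid, k)
    return files


def _stage_evaluate(cfg: RunConfig, data_dir: Path, seg_dir: Path, out: Path) -> list[Path]:
    scheme = _read_scheme(data_dir)
    _, test_ids = _subject_ids(cfg)
    records = []
    for sid in test_ids:
        _, _, ref, spacing = _load_subject(data_dir, sid, scheme)
        regions = sorted(int(v) for v in np.unique(ref) if v != 0)
        for k in cfg.evaluate.direction_counts:
            path = seg_dir / f"{sid}_dirs-{k}_seg.nii"
            if not path.exists():
                raise DependencyError(f"missing segmentation {path}; run the segment stage")
            pred = qio.read_label_volume(path)[0]
            df = ev.compute_metric_records(pred, ref, regions, sid, spacing)
            df["directions"] = k
            records.append(df)
    metrics = pd.concat(records, ignore_index=True)
    out.mkdir(parents=True, exist_ok=True)
    metrics_path = out / "metrics.tsv"
    metrics.to_csv(metrics_path, sep="\t", index=False, float_format="%.6g")
    present = set(metrics["region"])
    group_map = {r: g for r, g in cfg.evaluate.group_map.items() if r in present}
    grouped = []
    for k, sub in metrics.groupby("directions"):
        g = ev.group_metrics(sub, group_map)
        g["directions"] = k
        grouped.append(g)
    grouped_path = out / "grouped.tsv"
    pd.concat(grouped, ignore_index=True).to_csv(
        grouped_path, sep="\t", index=False, float_format="%.6g")
    return [metrics_path, grouped_path]


def _stage_report(cfg: RunConfig, eval_dir: Path, out: Path) -> list[Path]:
    metrics_path = eval_dir / "metrics.tsv"
    if not metrics_path.exists():
        raise DependencyError(f"missing {metrics_path}; run the evaluate stage")
    metrics = pd.read_csv(metrics_path, sep="\t")
    out.mkdir(parents=True, exist_ok=True)
    lines = ["per-direction-count mean metrics", "=" * 40]
    summary = metrics.groupby(["directions", "metric"])["value"].mean()
    lines.append(summary.to_string())
    counts = sorted(metrics["directions"].unique(), reverse=True)
    if len(counts) >= 2:
        ref_k = counts[0]
        lines += ["", f"signed-rank tests vs {ref_k}-direction input", "-" * 40]
        for k in counts[1:]:
            for metric, alt in (("DSC", "less"), ("HD99", "greater")):
                a = metrics.query("directions == @ref_k and metric == @metric")
                b = metrics.query("directions == @k and metric == @metric")
                join = a.merge(b, on=["participant", "region"], suffixes=("_ref", "_k"))
                diffs = (join["value_k"] - join["value_ref"]).dropna()
                # alternative: the sparser input is WORSE (lower DSC / higher HD99)
                try:
                    p = ev.wilcoxon_one_sided(diffs, alternative=alt)
                    mark = ev.significance_marker(p)
                except Exception:
                    p, mark = float("nan"), "undefined"
                lines.append(f"{metric} {k} vs {ref_k}: p = {p:.4g} ({mark})")
    path = out / "report.txt"
    path.write_text("\n".join(lines) + "\n")
    return [path]


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------

def run_pipeline(config: RunConfig, stages=("simulate",)) -> dict:
    """Execute the requested stages in order and write a run manifest.

    Returns the manifest dict: config hash, per-stage seeds, and a checksum
    for every output file.  Re-running with an identical configuration
    reproduces identical checksums for all deterministic stages.
    """
    for stage in stages:
        if stage not in STAGES:
            raise ConfigurationError(f"unknown stage {stage!r}; expected one of {STAGES}")
    base = Path(config.out_dir)
    base.mkdir(parents=True, exist_ok=True)
    dirs = {s: base / s for s in STAGES}
    dirs["simulate"] = base / "data"
    manifest_path = base / "manifest.json"
    manifest = (json.loads(manifest_path.read_text())
                if manifest_path.exists() else {"stages": {}})
    manifest["config_hash"] = config.config_hash()
    manifest["seed"] = config.seed
    runners = {
        "simulate": lambda: _stage_simulate(config, dirs["simulate"]),
        "pretrain": lambda: _stage_pretrain(config, dirs["simulate"], dirs["pretrain"]),
        "train": lambda: _stage_train(config, dirs["simulate"], dirs["pretrain"],
                                      dirs["train"]),
        "segment": lambda: _stage_segment(config, dirs["simulate"], dirs["pretrain"],
                                          dirs["train"], dirs["segment"]),
        "evaluate": lambda: _stage_evaluate(config, dirs["simulate"], dirs["segment"],
                                            dirs["evaluate"]),
        "report": lambda: _stage_report(config, dirs["evaluate"], dirs["report"]),
    }
    for stage in stages:
        t0 = time.time()
        files = runners[stage]()
        manifest["stages"][stage] = {
            "seed": derive_seed(config.seed, stage),
            "elapsed_s": round(time.time() - t0, 2),
            "files": {str(f.relative_to(base)): _sha256_file(f) for f in files},
        }
        manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
        logger.info("stage %s done in %.1fs (%d files)",
                    stage, time.time() - t0, len(files))
    return manifest
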