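"""Training loop, learning-rate schedule, checkpointing and inference helpers.

The recipe: Adam (β₁ = 0.9), batch size 4, initial learning rate 1e-4
annealed along a cosine to 1e-5 at the final epoch, the double (global +
local) BCE-Dice objective, validation each epoch, best-by-validation-DSC and
last checkpoints, and a CSV history of per-epoch loss components and
metrics.  All randomness (initialization, shuffling) derives from one seed.
"""

from __future__ import annotations

import csv
import dataclasses
import json
import math
import pathlib

import numpy as np
import yaml

from . import image_io
from .exceptions import DivergenceError, EmptyDatasetError
from .grad import engine
from .grad.optim import Adam
from .losses import LossConfig, total_loss
from .metrics import evaluate_dataset, pr_curve
from .network import DLGRAFENet, NetworkConfig

CHECKPOINT_SCHEMA = "polypseg-checkpoint-v1"


@dataclasses.dataclass
class TrainConfig:
    """Optimization schedule, seeding and dataset locations."""

    batch_size: int = 4
    epochs: int = 200
    initial_lr: float = 1e-4
    min_lr: float = 1e-5
    beta1: float = 0.9
    seed: int = 0
    validate_every_epoch: bool = True
    loss: LossConfig = dataclasses.field(default_factory=LossConfig)
    network: NetworkConfig = dataclasses.field(default_factory=NetworkConfig)
    train_images: str | None = None
    train_masks: str | None = None
    val_images: str | None = None
    val_masks: str | None = None
    out_dir: str = "runs/default"

    def __post_init__(self):
        if self.batch_size < 1:
            raise ValueError("batch_size must be ≥ 1")
        if self.min_lr > self.initial_lr:
            raise ValueError("min_lr must not exceed initial_lr")
        if self.epochs < 1:
            raise ValueError("epochs must be ≥ 1")

    @classmethod
    def from_yaml(cls, path):
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "loss" in raw:
            raw["loss"] = LossConfig(**raw["loss"])
        if "network" in raw:
            raw["network"] = NetworkConfig.from_dict(raw["network"])
        known = {f.name for f in dataclasses.fields(cls)}
        return cls(**{k: v for k, v in raw.items() if k in known})


def lr_at_epoch(cfg: TrainConfig, epoch: int) -> float:
    """Cosine annealing from ``initial_lr`` (epoch 0) to ``min_lr`` (last epoch)."""
    if not 0 <= epoch < cfg.epochs:
        raise ValueError(f"epoch {epoch} outside [0, {cfg.epochs})")
    if cfg.epochs == 1:
        return cfg.initial_lr
    t = epoch / (cfg.epochs - 1)
    return cfg.min_lr + 0.5 * (cfg.initial_lr - cfg.min_lr) * (1.0 + math.cos(math.pi * t))


def save_checkpoint(path, model: DLGRAFENet, extra=None):
    """Flat parameter-name → array map plus the architecture config and a schema tag."""
    path = pathlib.Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    meta = {"schema": CHECKPOINT_SCHEMA, "network": model.config.to_dict()}
    if extra:
        meta.update(extra)
    np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
             **model.state_dict())


def load_checkpoint(path) -> DLGRAFENet:
    path = pathlib.Path(path)
    if not path.exists():
        raise FileNotFoundError(f"checkpoint not found: {path}")
    with np.load(path) as npz:
        meta = json.loads(bytes(npz["__meta__"]).decode())
        if meta.get("schema") != CHECKPOINT_SCHEMA:
            raise ValueError(f"unrecognized checkpoint schema in {path}")
        state = {k: npz[k] for k in npz.files if k != "__meta__"}
    model = DLGRAFENet(NetworkConfig.from_dict(meta["network"]))
    model.load_state_dict(state)
    return model


def predict_probabilities(model: DLGRAFENet, images: np.ndarray,
                          batch_size: int = 4) -> np.ndarray:
    """Inference-mode forward over (N, 3, S, S) images → (N, 1, S, S) probabilities."""
    model.eval()
    out = []
    with engine.no_grad():
        for i in range(0, len(images), batch_size):
            res = model(images[i:i + batch_size].astype(np.float32))
            out.append(res.prediction.data)
    return np.concatenate(out, axis=0)


@dataclasses.dataclass
class TrainResult:
    history: list
    best_checkpoint: pathlib.Path
    last_checkpoint: pathlib.Path
    history_csv: pathlib.Path
    model: DLGRAFENet


def _load_split(images_dir, masks_dir, size):
    manifest = image_io.list_pairs(images_dir, masks_dir)
    return image_io.load_batch(manifest, size)


def train(cfg: TrainConfig, max_steps: int | None = None,
          data: tuple | None = None, log=None) -> TrainResult:
    """Run the full training loop.

    ``data`` may supply pre-loaded ``(train_images, train_masks)`` arrays
    (NCHW float and NHW binary) to bypass the filesystem; otherwise the
    directories in ``cfg`` are read.  ``max_steps`` caps the number of
    optimizer updates (useful for short calibration runs).
    """
    size = cfg.network.input_size
    if data is not None:
        images, masks = data
        images = np.asarray(images, dtype=np.float32)
        masks = np.asarray(masks)
    else:
        if not cfg.train_images or not cfg.train_masks:
            raise EmptyDatasetError("no training data: set train_images/train_masks")
        images, masks = _load_split(cfg.train_images, cfg.train_masks, size)
    if len(images) == 0:
        raise EmptyDatasetError("empty training set")

    val = None
    if cfg.validate_every_epoch and cfg.val_images and cfg.val_masks:
        val = _load_split(cfg.val_images, cfg.val_masks, size)

    rng = np.random.default_rng(cfg.seed)
    model = DLGRAFENet(cfg.network, seed=int(rng.integers(0, 2**31 - 1)))
    optimizer = Adam(model.parameters(), lr=cfg.initial_lr, beta1=cfg.beta1)
    loss_cfg = cfg.loss
    if not cfg.network.use_local_loss:
        loss_cfg = dataclasses.replace(loss_cfg, lambda_local=0.0)

    out_dir = pathlib.Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    history_csv = out_dir / "history.csv"
    best_path = out_dir / "best.npz"
    last_path = out_dir / "last.npz"

    n = len(images)
    steps_done = 0
    best_dsc = -1.0
    history = []
    fields = ["epoch", "lr", "loss", "loss_global", "loss_local", "val_dsc"]
    with open(history_csv, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=fields)
        writer.writeheader()
        for epoch in range(cfg.epochs):
            if max_steps is not None and steps_done >= max_steps:
                break
            lr = lr_at_epoch(cfg, epoch)
            optimizer.lr = lr
            model.train()
            order = rng.permutation(n)
            ep_loss, ep_global, ep_local, n_batches = 0.0, 0.0, 0.0, 0
            for start in range(0, n, cfg.batch_size):
                if max_steps is not None and steps_done >= max_steps:
                    break
                idx = order[start:start + cfg.batch_size]
                xb = images[idx]
                qb = masks[idx][:, None].astype(np.float32)
                out = model(xb)
                loss, comps = total_loss(out, qb, loss_cfg)
                if not np.isfinite(comps["total"]):
                    raise DivergenceError(
                        f"non-finite loss at epoch {epoch}, step {steps_done}: {comps}")
                optimizer.zero_grad()
                loss.backward()
                optimizer.step()
                steps_done += 1
                n_batches += 1
                ep_loss += comps["total"]
                ep_global += comps["global"]
                ep_local += comps["local"]
            if n_batches == 0:
                break
            row = {
                "epoch": epoch,
                "lr": lr,
                "loss": ep_loss / n_batches,
                "loss_global": ep_global / n_batches,
                "loss_local": ep_local / n_batches,
                "val_dsc": "",
            }
            if val is not None:
                probs = predict_probabilities(model, val[0], cfg.batch_size)
                summary, _ = evaluate_dataset(list(probs[:, 0]), list(val[1]))
                row["val_dsc"] = summary.dsc
                if summary.dsc > best_dsc:
                    best_dsc = summary.dsc
                    save_checkpoint(best_path, model, {"epoch": epoch,
                                                       "val_dsc": summary.dsc})
            writer.writerow(row)
            fh.flush()
            history.append(row)
            if log is not None:
                log(f"epoch {epoch}: lr={lr:.3g} loss={row['loss']:.5f} "
                    f"global={row['loss_global']:.5f} local={row['loss_local']:.5f}"
                    + (f" val_dsc={row['val_dsc']:.4f}" if row["val_dsc"] != "" else ""))
    save_checkpoint(last_path, model, {"epochs_run": len(history)})
    if not best_path.exists():
        save_checkpoint(best_path, model, {"epochs_run": len(history)})
    return TrainResult(history=history, best_checkpoint=best_path,
                       last_checkpoint=last_path, history_csv=history_csv,
                       model=model)


def evaluate_model(predict_fn, manifest, input_size: int, threshold: float = 0.5,
                   thresholds_for_pr=None):
    """Evaluate an arbitrary predictor over a manifest.

    ``predict_fn`` maps (N, 3, S, S) images to (N, 1, S, S) probabilities —
    a trained model or any oracle stub.  Returns
    ``(summary, per_image_rows, pr_points)``.
    """
    images, masks = image_io.load_batch(manifest, input_size)
    probs = predict_fn(images)
    p_list = [probs[i, 0] for i in range(len(probs))]
    q_list = [masks[i] for i in range(len(masks))]
    summary, per_image = evaluate_dataset(p_list, q_list, threshold)
    rows = [
        {"identifier": entry.identifier, **m.as_dict()}
        for entry, m in zip(manifest, per_image)
    ]
    pr_points = None
    if thresholds_for_pr is not None:
        pr_points = pr_curve(p_list, q_list, thresholds_for_pr)
    return summary, rows, pr_points


def evaluate_checkpoint(checkpoint, images_dir, masks_dir, out_csv,
                        threshold: float = 0.5, pr_csv=None, batch_size: int = 4):
    """Load a checkpoint, run inference, write per-image + summary metric rows."""
    model = load_checkpoint(checkpoint)
    manifest = image_io.list_pairs(images_dir, masks_dir)
    thresholds = [i / 20 for i in range(1, 20)] if pr_csv else None
    summary, rows, pr_points = evaluate_model(
        lambda imgs: predict_probabilities(model, imgs, batch_size),
        manifest, model.config.input_size, threshold, thresholds)
    out_csv = pathlib.Path(out_csv)
    out_csv.parent.mkdir(parents=True, exist_ok=True)
    with open(out_csv, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=["identifier", "dsc", "precision",
                                                "recall", "iou"])
        writer.writeheader()
        writer.writerows(rows)
        writer.writerow({"identifier": "summary", **summary.as_dict()})
    if pr_csv:
        with open(pr_csv, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["threshold", "precision", "recall"])
            for t, (prec, rec) in zip(thresholds, pr_points):
                writer.writerow([t, prec, rec])
    return summary


def predict_to_dir(checkpoint, images_dir, out_dir, threshold: float = 0.5,
                   batch_size: int = 4):
    """Write one binary PNG mask per input image, matched by filename stem."""
    model = load_checkpoint(checkpoint)
    images_dir = pathlib.Path(images_dir)
    out_dir = pathlib.Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    size = model.config.input_size
    stems = []
    batch, names = [], []

    def flush():
        if not batch:
            return
        probs = predict_probabilities(model, np.stack(batch), batch_size)
        for name, prob in zip(names, probs):
            image_io.save_mask(prob[0], threshold, out_dir / f"{name}.png")
        batch.clear()
        names.clear()

    from PIL import Image
    for path in sorted(images_dir.iterdir()):
        if path.suffix.lower() not in (".png", ".jpg", ".jpeg"):
            continue
        with Image.open(path) as im:
            arr = np.asarray(im.convert("RGB").resize((size, size), Image.BILINEAR),
                             dtype=np.float32) / 255.0
        batch.append(arr.transpose(2, 0, 1))
        names.append(path.stem)
        stems.append(path.stem)
        if len(batch) >= batch_size:
            flush()
    flush()
    return stems
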