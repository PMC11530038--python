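"""Training loop: Adam + cross-entropy, he_normal init, best-DSC selection."""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from . import metrics as M
from .attention import AttentionGate
from .backbone import DenseAttentionUNet, ModelConfig
from .data import ImagePair, augment, dataset_statistics
from .nn import Adam, BatchNorm2d, Conv2d, Linear
from .nn import functional as F
from .nn.tensor import DTYPE, Tensor, no_grad

logger = logging.getLogger(__name__)

AG_INIT_STD = 0.02  # attention-gate weights: zero-mean normal


@dataclass
class TrainConfig:
    batch_size: int = 8
    learning_rate: float = 1e-4
    epochs: int = 200
    beta1: float = 0.9
    seed: int = 0
    device: str = "cpu"
    select_metric: str = "dsc"
    p_flip: float = 0.5
    p_scale: float = 0.5
    augment: bool = True

    def __post_init__(self):
        if self.select_metric not in M.METRIC_NAMES:
            raise ValueError(f"select_metric must be one of {M.METRIC_NAMES}")
        if self.device != "cpu":
            raise ValueError("only device='cpu' is supported")

    @classmethod
    def small(cls, seed: int = 0) -> "TrainConfig":
        """Desk-scale preset used by the end-to-end phantom check."""
        return cls(epochs=25, seed=seed)


@dataclass
class TrainHistory:
    records: List[Dict[str, float]] = field(default_factory=list)
    best_epoch: int = -1

    def to_csv(self, path) -> None:
        import csv

        cols = ["epoch", "train_loss", "val_loss", *M.METRIC_NAMES]
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(cols)
            for rec in self.records:
                writer.writerow([rec[c] for c in cols])

    def metric_series(self, name: str) -> List[float]:
        return [rec[name] for rec in self.records]


def initialize_weights(model, scheme: str = "he_normal", seed: int = 0):
    """He-normal conv/linear weights, zero biases, identity BN.

    Attention-gate projections instead use a zero-mean normal with a small
    fixed standard deviation. Deterministic under ``seed``.
    """
    if scheme != "he_normal":
        raise ValueError(f"unknown init scheme {scheme!r}")
    rng = np.random.default_rng(seed)
    ag_modules = set()
    for m in model.modules():
        if isinstance(m, AttentionGate):
            for sub in m.modules():
                ag_modules.add(id(sub))
    for m in model.modules():
        if isinstance(m, Conv2d):
            if id(m) in ag_modules:
                std = AG_INIT_STD
            else:
                fan_in = m.in_channels * m.kernel_size**2
                std = np.sqrt(2.0 / fan_in)
            m.weight.data = rng.normal(0.0, std, m.weight.data.shape).astype(DTYPE)
            if m.bias is not None:
                m.bias.data = np.zeros_like(m.bias.data)
        elif isinstance(m, Linear):
            std = AG_INIT_STD if id(m) in ag_modules else np.sqrt(2.0 / m.in_features)
            m.weight.data = rng.normal(0.0, std, m.weight.data.shape).astype(DTYPE)
            if m.bias is not None:
                m.bias.data = np.zeros_like(m.bias.data)
        elif isinstance(m, BatchNorm2d):
            m.weight.data = np.ones_like(m.weight.data)
            m.bias.data = np.zeros_like(m.bias.data)
            m.running_mean = np.zeros_like(m.running_mean)
            m.running_var = np.ones_like(m.running_var)
    return model


def loss(logits: Tensor, mask: np.ndarray) -> Tensor:
    """Mean per-pixel cross-entropy between 2-channel logits and a binary mask."""
    if logits.data.shape[1] != 2:
        raise ValueError(f"expected 2 logit channels, got {logits.data.shape[1]}")
    mask = np.asarray(mask)
    if mask.ndim == 2:
        mask = mask[None]
    if mask.shape != (logits.data.shape[0], *logits.data.shape[2:]):
        raise ValueError(f"mask shape {mask.shape} incompatible with logits {logits.data.shape}")
    if not np.all(np.isin(np.unique(mask), (0, 1))):
        raise ValueError("mask must be binary")
    return F.softmax_cross_entropy(logits, mask.astype(np.int64))


def _stack(pairs: Sequence[ImagePair], mean: float, std: float):
    imgs = np.stack([(p.image - mean) / std for p in pairs]).astype(DTYPE)[:, None]
    masks = np.stack([p.mask for p in pairs]).astype(np.int64)
    return imgs, masks


def predict(model: DenseAttentionUNet, images: np.ndarray,
            mean: float = 0.0, std: float = 1.0, batch_size: int = 8) -> np.ndarray:
    """Argmax segmentation masks for a batch of (N, H, W) images in [0, 1].

    Ties in the two softmax channels resolve to background (class 0).
    """
    images = np.asarray(images, dtype=np.float64)
    if images.ndim == 2:
        images = images[None]
    h, w = images.shape[1:]
    if h % 16 or w % 16:
        raise ValueError(f"input spatial dims must be divisible by 16; got {h}x{w}")
    model.eval()
    out = np.empty(images.shape, dtype=np.uint8)
    with no_grad():
        for lo in range(0, images.shape[0], batch_size):
            batch = ((images[lo : lo + batch_size] - mean) / std).astype(DTYPE)[:, None]
            logits = model(Tensor(batch))
            out[lo : lo + batch.shape[0]] = np.argmax(logits.data, axis=1).astype(np.uint8)
    return out


def evaluate_model(model: DenseAttentionUNet, pairs: Sequence[ImagePair],
                   mean: float, std: float, batch_size: int = 8) -> M.MetricReport:
    images = np.stack([p.image for p in pairs])
    preds = predict(model, images, mean, std, batch_size)
    return M.evaluate_dataset([(pred, p.mask) for pred, p in zip(preds, pairs)])


def train(model: DenseAttentionUNet, train_set: Sequence[ImagePair],
          val_set: Sequence[ImagePair], cfg: TrainConfig,
          norm_stats: Optional[Tuple[float, float]] = None,
          ) -> Tuple[Dict, TrainHistory]:
    """Run the full loop; returns (best checkpoint payload, history).

    Normalization statistics are computed from the training split (unless
    supplied) and stored with the checkpoint. Model selection keeps the
    epoch with the best validation ``select_metric``.
    """
    if len(train_set) == 0 or len(val_set) == 0:
        raise ValueError("train and validation sets must be non-empty")
    rng = np.random.default_rng(cfg.seed)
    mean, std = norm_stats if norm_stats is not None else dataset_statistics(train_set)
    if std <= 0:
        raise ValueError("training images are constant; cannot standardize")
    optimizer = Adam(model.parameters(), lr=cfg.learning_rate, beta1=cfg.beta1)
    history = TrainHistory()
    metric_idx = M.METRIC_NAMES.index(cfg.select_metric)
    best_value = -np.inf
    best_state = {k: v.copy() for k, v in model.state_dict().items()}
    for epoch in range(cfg.epochs):
        model.train()
        order = rng.permutation(len(train_set))
        epoch_loss = 0.0
        n_batches = 0
        for lo in range(0, len(order), cfg.batch_size):
            idx = order[lo : lo + cfg.batch_size]
            batch_pairs = [train_set[i] for i in idx]
            if cfg.augment:
                batch_pairs = [
                    augment(p, rng, p_flip=cfg.p_flip, p_scale=cfg.p_scale)
                    for p in batch_pairs
                ]
            imgs, masks = _stack(batch_pairs, mean, std)
            logits = model(Tensor(imgs))
            batch_loss = F.softmax_cross_entropy(logits, masks)
            if not np.isfinite(batch_loss.data):
                raise RuntimeError(
                    f"non-finite loss {batch_loss.data} at epoch {epoch}; aborting"
                )
            optimizer.zero_grad()
            batch_loss.backward()
            optimizer.step()
            epoch_loss += float(batch_loss.data)
            n_batches += 1
        model.eval()
        val_loss = 0.0
        val_pairs = []
        with no_grad():
            for lo in range(0, len(val_set), cfg.batch_size):
                chunk = val_set[lo : lo + cfg.batch_size]
                val_imgs, val_masks = _stack(chunk, mean, std)
                val_logits = model(Tensor(val_imgs))
                val_loss += float(
                    F.softmax_cross_entropy(val_logits, val_masks).data
                ) * len(chunk)
                preds = np.argmax(val_logits.data, axis=1).astype(np.uint8)
                val_pairs.extend((pr, p.mask) for pr, p in zip(preds, chunk))
        val_loss /= len(val_set)
        report = M.evaluate_dataset(val_pairs)
        record = {
            "epoch": epoch,
            "train_loss": epoch_loss / max(n_batches, 1),
            "val_loss": val_loss,
        }
        record.update(dict(zip(M.METRIC_NAMES, report.mean_of_each)))
        history.records.append(record)
        value = report.mean_of_each[metric_idx]
        if value > best_value:
            best_value = value
            history.best_epoch = epoch
            best_state = {k: v.copy() for k, v in model.state_dict().items()}
        logger.info(
            "epoch %d: train_loss=%.4f val_loss=%.4f dsc=%.4f",
            epoch, record["train_loss"], val_loss, record["dsc"],
        )
    checkpoint = {
        "model_config": model.cfg.to_dict(),
        "state": best_state,
        "norm_mean": mean,
        "norm_std": std,
        "history": history,
        "train_config": asdict(cfg),
    }
    return checkpoint, history


def save_checkpoint(checkpoint: Dict, path) -> None:
    """Serialize config + weights + normalization stats + history (npz)."""
    meta = {
        "model_config": checkpoint["model_config"],
        "norm_mean": checkpoint["norm_mean"],
        "norm_std": checkpoint["norm_std"],
        "train_config": checkpoint.get("train_config"),
        "history": {
            "records": checkpoint["history"].records,
            "best_epoch": checkpoint["history"].best_epoch,
        }
        if isinstance(checkpoint.get("history"), TrainHistory)
        else checkpoint.get("history"),
    }
    arrays = {f"param/{k}": v for k, v in checkpoint["state"].items()}
    np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
             **arrays)


def load_checkpoint(path) -> Tuple[DenseAttentionUNet, Dict]:
    """Rebuild the model from a checkpoint; returns (model, metadata)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"checkpoint not found: {path}")
    try:
        with np.load(path, allow_pickle=False) as data:
            meta = json.loads(bytes(data["__meta__"]).decode())
            state = {
                k[len("param/"):]: data[k] for k in data.files if k.startswith("param/")
            }
    except (ValueError, KeyError, json.JSONDecodeError) as exc:
        raise ValueError(f"malformed checkpoint {path}: {exc}") from exc
    model = DenseAttentionUNet(ModelConfig.from_dict(meta["model_config"]))
    model.load_state_dict(state)
    model.eval()
    return model, meta
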