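"""Training loop, batch iteration and checkpointing.

Samples may have unequal lengths; batches are bucketed by the
(T_audio, T_video) pair so every batch is exactly rectangular and no
padding/masking enters the forward pass.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .model import AsymModel
from .nn import Adam, Tensor, bce_with_logits, no_grad

logger = logging.getLogger(__name__)


@dataclass
class Sample:
    sample_id: str
    audio: np.ndarray
    video: np.ndarray
    label: int

    def __post_init__(self):
        self.audio = np.asarray(self.audio, dtype=np.float32)
        self.video = np.asarray(self.video, dtype=np.float32)


@dataclass
class TrainConfig:
    epochs: int = 16
    lr: float = 8e-5
    weight_decay: float = 1e-3
    batch_size: int = 16
    patience: int | None = None   # early stop on stagnant validation accuracy
    log_every: int = 0


def _bucket_batches(samples: list[Sample], batch_size: int,
                    rng: np.random.Generator | None) -> list[list[Sample]]:
    buckets: dict[tuple[int, int], list[Sample]] = {}
    order = list(samples)
    if rng is not None:
        perm = rng.permutation(len(order))
        order = [order[i] for i in perm]
    for s in order:
        buckets.setdefault((s.audio.shape[0], s.video.shape[0]), []).append(s)
    batches = []
    for group in buckets.values():
        for i in range(0, len(group), batch_size):
            batches.append(group[i:i + batch_size])
    if rng is not None:
        perm = rng.permutation(len(batches))
        batches = [batches[i] for i in perm]
    return batches


def _stack_batch(batch: list[Sample]) -> tuple[Tensor, Tensor, np.ndarray]:
    audio = Tensor(np.stack([s.audio for s in batch]))
    video = Tensor(np.stack([s.video for s in batch]))
    labels = np.array([s.label for s in batch], dtype=np.float32)
    return audio, video, labels


def predict_proba(model: AsymModel, samples: list[Sample],
                  batch_size: int = 16) -> np.ndarray:
    """Per-sample positive-class probabilities, in input order."""
    model.eval()
    probs = np.empty(len(samples), dtype=np.float64)
    index = {id(s): i for i, s in enumerate(samples)}
    with no_grad():
        for batch in _bucket_batches(samples, batch_size, rng=None):
            audio, video, _ = _stack_batch(batch)
            logits = model(audio, video).data.astype(np.float64)
            p = 1.0 / (1.0 + np.exp(-logits))
            for s, pi in zip(batch, p):
                probs[index[id(s)]] = pi
    return probs


def accuracy(model: AsymModel, samples: list[Sample],
             batch_size: int = 16) -> float:
    probs = predict_proba(model, samples, batch_size)
    labels = np.array([s.label for s in samples])
    return float(((probs >= 0.5).astype(int) == labels).mean())


def train_model(model: AsymModel, train_samples: list[Sample],
                val_samples: list[Sample] | None, cfg: TrainConfig,
                rng: np.random.Generator) -> list[dict]:
    """Adam + binary cross-entropy; returns the per-epoch history.

    With ``cfg.patience`` set, training stops once validation accuracy has
    not improved for that many epochs and the best parameters are restored.
    """
    opt = Adam(model.parameters(), lr=cfg.lr, weight_decay=cfg.weight_decay)
    history: list[dict] = []
    best_acc, best_state, since_best = -1.0, None, 0
    for epoch in range(1, cfg.epochs + 1):
        model.train()
        losses, n_correct, n_seen = [], 0, 0
        for batch in _bucket_batches(train_samples, cfg.batch_size, rng):
            audio, video, labels = _stack_batch(batch)
            logits = model(audio, video)
            loss = bce_with_logits(logits, labels)
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(loss.item())
            n_correct += int(((logits.data >= 0.0) == labels.astype(bool)).sum())
            n_seen += len(batch)
        row = {"epoch": epoch, "train_loss": float(np.mean(losses)),
               "train_acc": n_correct / n_seen}
        if val_samples:
            row["val_acc"] = accuracy(model, val_samples, cfg.batch_size)
            if row["val_acc"] > best_acc:
                best_acc, since_best = row["val_acc"], 0
                if cfg.patience is not None:
                    best_state = {k: v.copy()
                                  for k, v in model.state_dict().items()}
            else:
                since_best += 1
        history.append(row)
        if cfg.log_every and epoch % cfg.log_every == 0:
            logger.info("epoch %d: %s", epoch, row)
        if cfg.patience is not None and since_best >= cfg.patience:
            logger.info("early stop at epoch %d (best val acc %.4f)",
                        epoch, best_acc)
            break
    if best_state is not None:
        model.load_state_dict(best_state)
    return history


def save_checkpoint(model: AsymModel, path) -> None:
    np.savez(path, **model.state_dict())


def load_checkpoint(model: AsymModel, path) -> None:
    with np.load(path) as data:
        model.load_state_dict({k: data[k] for k in data.files})
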