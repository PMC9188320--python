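"""Training protocol for the dual-branch network.

Fixed-epoch training (no early stopping) with Adam, batch size 64 and a
per-epoch checkpoint; the returned model is the checkpoint minimizing
validation cross-entropy (earliest epoch on ties). Defaults follow the
reference protocol: learning rate 2e-4 for the BiLSTM path and 2e-6 for
a pretrained transformer (a randomly initialized small transformer
trains fine at 2e-4; pass ``lr`` explicitly), 100 epochs.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from sleepscan.nn.embeddings import encode_batch
from sleepscan.nn.network import DualBranchNet, Encoder
from sleepscan.segmenter import CLASS_ORDER, Candidate

__all__ = ["TrainConfig", "SeqDataset", "make_dataset", "train_seq", "predict_proba", "TrainedSeqModel"]

DEFAULT_LR = {Encoder.BILSTM: 2e-4, Encoder.TRANSFORMER: 2e-4}
PRETRAINED_TRANSFORMER_LR = 2e-6


@dataclass(frozen=True)
class TrainConfig:
    batch_size: int = 64
    lr: float | None = None  # None -> encoder default
    epochs: int = 100
    seed: int = 0
    checkpoint_dir: str | None = None

    def __post_init__(self):
        if self.lr is not None and self.lr <= 0:
            raise ValueError("lr must be positive")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")


@dataclass
class SeqDataset:
    """Encoded candidate batch: structured features, token ids, mask, one-hot targets."""

    structured: np.ndarray
    ids: np.ndarray
    mask: np.ndarray
    targets: np.ndarray
    report_ids: tuple[str, ...] = ()

    def __len__(self) -> int:
        return len(self.ids)


def make_dataset(cands: Sequence[Candidate], vocab: dict[str, int], max_len: int = 32) -> SeqDataset:
    ids, mask = encode_batch([c.window for c in cands], vocab, max_len)
    structured = np.array([c.structured for c in cands], dtype=float)
    targets = np.zeros((len(cands), len(CLASS_ORDER)))
    for i, c in enumerate(cands):
        targets[i, CLASS_ORDER.index(c.label)] = 1.0
    return SeqDataset(
        structured=structured, ids=ids, mask=mask, targets=targets,
        report_ids=tuple(c.report_id for c in cands),
    )


@dataclass
class TrainedSeqModel:
    """A trained network with its token vocabulary and training log."""

    net: DualBranchNet
    vocab: dict[str, int]
    best_epoch: int
    log: list[dict] = field(default_factory=list)

    def predict_proba(self, data: SeqDataset, batch_size: int = 64) -> np.ndarray:
        return predict_proba(self.net, data, batch_size)


def _eval_loss(net: DualBranchNet, data: SeqDataset, batch_size: int = 256) -> float:
    total = 0.0
    n = 0
    for lo in range(0, len(data), batch_size):
        sl = slice(lo, lo + batch_size)
        logits = net.forward(
            data.structured[sl] if net.spec.use_structured else None,
            data.ids[sl], data.mask[sl], train=False,
        )
        loss, _ = net.loss_and_grad(logits, data.targets[sl])
        total += loss * (sl.indices(len(data))[1] - lo)
        n += sl.indices(len(data))[1] - lo
    return total / max(n, 1)


def train_seq(
    net: DualBranchNet,
    train_data: SeqDataset,
    val_data: SeqDataset,
    cfg: TrainConfig,
    vocab: dict[str, int] | None = None,
) -> TrainedSeqModel:
    """Train with per-epoch checkpointing; return the best-validation model.

    Train and validation sets must come from disjoint report sets; this
    is the caller's contract (enforced when report ids are present).
    """
    if len(train_data) == 0 or len(val_data) == 0:
        raise ValueError("train and validation sets must be nonempty")
    if train_data.report_ids and val_data.report_ids:
        overlap = set(train_data.report_ids) & set(val_data.report_ids)
        if overlap:
            raise ValueError(f"train/validation report overlap: {sorted(overlap)[:3]}...")

    lr = cfg.lr if cfg.lr is not None else DEFAULT_LR[net.spec.encoder]
    opt = net.make_optimizer(lr)
    rng = np.random.default_rng(cfg.seed)
    n = len(train_data)
    log: list[dict] = []
    best_val = np.inf
    best_epoch = -1
    best_weights = None
    ckpt_dir = Path(cfg.checkpoint_dir) if cfg.checkpoint_dir else None
    if ckpt_dir:
        ckpt_dir.mkdir(parents=True, exist_ok=True)

    for epoch in range(1, cfg.epochs + 1):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for lo in range(0, n, cfg.batch_size):
            idx = order[lo : lo + cfg.batch_size]
            net.zero_grads()
            logits = net.forward(
                train_data.structured[idx] if net.spec.use_structured else None,
                train_data.ids[idx], train_data.mask[idx], train=True,
            )
            loss, dlogits = net.loss_and_grad(logits, train_data.targets[idx])
            net.backward(dlogits)
            opt.step()
            epoch_loss += loss * len(idx)
        train_loss = epoch_loss / n
        val_loss = _eval_loss(net, val_data)
        log.append({"epoch": epoch, "train_loss": train_loss, "val_loss": val_loss})
        if ckpt_dir:
            np.savez(ckpt_dir / f"epoch{epoch:04d}.npz", *net.get_weights())
        if val_loss < best_val:  # strict: earliest epoch wins ties
            best_val = val_loss
            best_epoch = epoch
            best_weights = net.get_weights()

    net.set_weights(best_weights)
    if ckpt_dir:
        with open(ckpt_dir / "training_log.csv", "w", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=["epoch", "train_loss", "val_loss"])
            writer.writeheader()
            writer.writerows(log)
    return TrainedSeqModel(net=net, vocab=vocab or {}, best_epoch=best_epoch, log=log)


def predict_proba(net: DualBranchNet, data: SeqDataset, batch_size: int = 64) -> np.ndarray:
    """Per-candidate class scores in [0, 1], batched inference (eval mode)."""
    out = np.zeros((len(data), len(CLASS_ORDER)))
    for lo in range(0, len(data), batch_size):
        sl = slice(lo, lo + batch_size)
        logits = net.forward(
            data.structured[sl] if net.spec.use_structured else None,
            data.ids[sl], data.mask[sl], train=False,
        )
        out[sl] = net.scores(logits)
    return out
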