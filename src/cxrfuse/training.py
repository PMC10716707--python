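"""Multilabel pretraining of the two-branch network with the asymmetric
focal loss, plus index filtering for the public 14-label CXR corpus.

The reference training recipe is batch size 8, 1000 steps per epoch,
100 epochs, AdamW with learning rate 1e-4 and weight decay 1e-5; the
``desk_scale`` profile shrinks steps and epochs for CPU-scale runs while
keeping the optimizer settings.
"""

from __future__ import annotations

import copy
import logging
import warnings
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

from .loss import LossParams, asl_focal_loss, asl_focal_loss_grad
from .model import FusionNet
from .nn.optim import AdamW
from .preprocess import AugmentParams, augment

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class TrainConfig:
    batch_size: int = 8
    steps_per_epoch: int = 1000
    epochs: int = 100
    optimizer: str = "adamw"
    learning_rate: float = 1e-4
    weight_decay: float = 1e-5
    seed: int = 0
    device: str = "cpu"
    val_fraction: float = 0.2

    def __post_init__(self) -> None:
        for f in ("batch_size", "steps_per_epoch", "epochs"):
            if getattr(self, f) < 1:
                raise ValueError(f"{f} must be positive")
        if self.optimizer != "adamw":
            raise ValueError("only the adamw optimizer is supported")

    @classmethod
    def desk_scale(cls, epochs: int = 10, steps_per_epoch: int = 60,
                   seed: int = 0) -> "TrainConfig":
        return cls(epochs=epochs, steps_per_epoch=steps_per_epoch, seed=seed)


def _macro_auc(y_true: np.ndarray, scores: np.ndarray) -> float:
    """Mean per-label ROC-AUC over labels with both classes present."""
    aucs = []
    for j in range(y_true.shape[1]):
        col = y_true[:, j]
        if 0 < col.sum() < len(col):
            aucs.append(roc_auc_score(col, scores[:, j]))
    return float(np.mean(aucs)) if aucs else float("nan")


def pretrain(model: FusionNet, images: np.ndarray, labels: np.ndarray,
             cfg: TrainConfig | None = None,
             loss_params: LossParams | None = None,
             checkpoint_dir: str | Path | None = None,
             augment_params: AugmentParams | None = None,
             ) -> tuple[FusionNet, pd.DataFrame]:
    """Train the network on a multilabel image stream.

    A seeded validation split (``cfg.val_fraction`` of the stream) is
    carved out; per-epoch train/validation loss and validation macro AUC
    are recorded, and the parameters of the best validation epoch are
    restored at the end (and written to ``checkpoint_dir`` if given).

    When ``augment_params`` is given, each training batch receives one
    random affine draw per image; validation images are never augmented.
    """
    cfg = cfg or TrainConfig()
    loss_params = loss_params or LossParams()
    log.info("pretraining with config %s, loss %s", asdict(cfg),
             asdict(loss_params))
    images = np.asarray(images, dtype=float)
    labels = np.asarray(labels)
    rng = np.random.default_rng(cfg.seed)
    n = len(images)
    perm = rng.permutation(n)
    n_val = max(1, int(round(cfg.val_fraction * n)))
    val_idx, train_idx = perm[:n_val], perm[n_val:]
    xtr, ytr = images[train_idx], labels[train_idx]
    xva, yva = images[val_idx], labels[val_idx]

    opt = AdamW(model.params(), lr=cfg.learning_rate,
                weight_decay=cfg.weight_decay)
    aug_rng = np.random.default_rng(cfg.seed + 1)
    history = []
    best = (np.inf, None)
    for epoch in range(cfg.epochs):
        losses = []
        for _ in range(cfg.steps_per_epoch):
            take = rng.choice(len(xtr), size=min(cfg.batch_size, len(xtr)),
                              replace=False)
            xb = xtr[take]
            if augment_params is not None:
                xb = np.stack([augment(im, augment_params, aug_rng)
                               for im in xb])
            p = model.forward(xb, train=True)
            loss = asl_focal_loss(p, ytr[take], loss_params)
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"training diverged: non-finite loss at epoch {epoch}")
            opt.zero_grad()
            model.backward(asl_focal_loss_grad(p, ytr[take], loss_params))
            opt.step()
            losses.append(loss)
        pva = model.extract_latent(xva, layer=-1, batch_size=32)
        val_loss = asl_focal_loss(pva, yva, loss_params)
        record = {"epoch": epoch,
                  "train_loss": float(np.mean(losses)),
                  "val_loss": float(val_loss),
                  "val_auc": _macro_auc(yva, pva)}
        history.append(record)
        log.info("epoch %(epoch)d: train %(train_loss).4f "
                 "val %(val_loss).4f auc %(val_auc).4f", record)
        if val_loss < best[0]:
            best = (val_loss, copy.deepcopy(
                {name: p.value.copy() for name, p in model.params()}))

    if best[1] is not None:
        for name, p in model.params():
            p.value[...] = best[1][name]
    hist = pd.DataFrame(history)
    hist.attrs["config"] = asdict(cfg)
    hist.attrs["loss_params"] = asdict(loss_params)
    if checkpoint_dir is not None:
        ckdir = Path(checkpoint_dir)
        ckdir.mkdir(parents=True, exist_ok=True)
        model.save(ckdir / "best")
        hist.to_csv(ckdir / "history.csv", index=False)
    return model, hist


def filter_chestxray14_index(metadata_csv: str | Path,
                             train_list: str | Path,
                             test_list: str | Path,
                             val_fraction: float = 0.2,
                             seed: int = 0) -> dict:
    """Filter the 14-label corpus index to images with at least one
    finding and partition by the official train/test lists, carving a
    seeded validation subset (default 20%) from the training part.

    Returns a dict with ``train``, ``val``, ``test`` id lists, the
    per-image label matrix, and the count of list ids missing from the
    metadata (also emitted as a warning).
    """
    meta = pd.read_csv(metadata_csv)
    id_col = "Image Index" if "Image Index" in meta.columns else meta.columns[0]
    lab_col = ("Finding Labels" if "Finding Labels" in meta.columns
               else meta.columns[1])
    meta = meta.set_index(id_col)
    diseased = meta[meta[lab_col].str.strip() != "No Finding"]

    def read_list(p):
        text = Path(p).read_text().split()
        return [t for t in text if t]

    def partition(ids):
        known = [i for i in ids if i in diseased.index]
        return known, len(ids) - len([i for i in ids if i in meta.index])

    train_ids, miss_tr = partition(read_list(train_list))
    test_ids, miss_te = partition(read_list(test_list))
    missing = miss_tr + miss_te
    if missing:
        warnings.warn(f"{missing} split-list ids absent from metadata; excluded")
    if not train_ids or not test_ids:
        warnings.warn("empty partition after filtering")

    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(train_ids))
    n_val = int(round(val_fraction * len(train_ids)))
    val_ids = [train_ids[i] for i in sorted(perm[:n_val])]
    tr_ids = [train_ids[i] for i in sorted(perm[n_val:])]

    def label_matrix(ids):
        from .schema import DISEASE_LABELS
        rows = np.zeros((len(ids), len(DISEASE_LABELS)), dtype=int)
        for r, i in enumerate(ids):
            found = set(str(diseased.loc[i, lab_col]).split("|"))
            for j, d in enumerate(DISEASE_LABELS):
                if d.replace("_", " ") in found or d in found:
                    rows[r, j] = 1
        return rows

    return {
        "train": tr_ids, "val": val_ids, "test": test_ids,
        "train_labels": label_matrix(tr_ids),
        "val_labels": label_matrix(val_ids),
        "test_labels": label_matrix(test_ids),
        "n_missing": missing,
        "n_train_total": len(train_ids),
        "n_test": len(test_ids),
    }
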