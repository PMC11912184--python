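"""Data splitting, stratified cross-validation, and masked Adam training.

Gradients are derived by hand for the fixed five-layer architecture and
projected through the connectivity masks at every step, so weights at
mask == 0 positions receive exactly zero gradient and the forward output is
provably independent of them. The schedule follows the published recipe:
Adam, initial learning rate 0.008, halved every 50 epochs (the decay factor
itself is configurable). Model selection is by validation AUC.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

from .network import (
    Activations,
    ModelParams,
    OmicsTensor,
    bce_loss,
    forward,
    total_loss,
)

__all__ = ["Splits", "TrainConfig", "TrainResult", "split_data", "kfold_splits",
           "train", "gradients"]


@dataclass
class Splits:
    train_idx: np.ndarray
    val_idx: np.ndarray
    test_idx: np.ndarray

    def __post_init__(self) -> None:
        self.train_idx = np.asarray(self.train_idx, dtype=int)
        self.val_idx = np.asarray(self.val_idx, dtype=int)
        self.test_idx = np.asarray(self.test_idx, dtype=int)
        all_idx = np.concatenate([self.train_idx, self.val_idx, self.test_idx])
        if len(np.unique(all_idx)) != len(all_idx):
            raise ValueError("splits overlap")


def split_data(
    n: int,
    y: Sequence[float],
    ratios: tuple[float, float, float] = (0.85, 0.05, 0.10),
    seed: int = 0,
) -> Splits:
    """Stratified train/validation/test split at the 0.85:0.05:0.10 ratio.

    Rounding rule (documented): within each class, train and validation get
    the floor of their proportional share and the remainder goes to test;
    e.g. n = 1892 with balanced classes yields 1608/94/190.
    """
    if abs(sum(ratios) - 1.0) > 1e-9:
        raise ValueError("ratios must sum to 1")
    y = np.asarray(y)
    if len(y) != n:
        raise ValueError("labels length must equal n")
    rng = np.random.default_rng(seed)
    r_train, r_val, _ = ratios
    train_parts, val_parts, test_parts = [], [], []
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        rng.shuffle(idx)
        n_c = len(idx)
        n_tr = int(np.floor(n_c * r_train))
        n_va = int(np.floor(n_c * r_val))
        train_parts.append(idx[:n_tr])
        val_parts.append(idx[n_tr:n_tr + n_va])
        test_parts.append(idx[n_tr + n_va:])
    splits = Splits(
        np.sort(np.concatenate(train_parts)),
        np.sort(np.concatenate(val_parts)),
        np.sort(np.concatenate(test_parts)),
    )
    for name, part in (("validation", splits.val_idx), ("test", splits.test_idx)):
        if len(part) and len(np.unique(y[part])) < len(np.unique(y)):
            import logging
            logging.getLogger("gpcnet.training").warning(
                "%s split does not contain every class (n too small)", name)
    return splits


def kfold_splits(
    y: Sequence[float], k: int = 5, seed: int = 0,
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Stratified k-fold index pairs (train, test), label-balanced per fold."""
    y = np.asarray(y)
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > len(y):
        raise ValueError(f"k={k} exceeds sample count {len(y)}")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    return [(tr, te) for tr, te in skf.split(np.zeros(len(y)), y)]


@dataclass
class TrainConfig:
    lr0: float = 0.008
    decay_every: int = 50
    decay_factor: float = 0.5
    epochs: int = 300
    batch_size: int | None = None     # None: full batch if N <= 2000 else 64
    alpha: tuple[float, float, float] = (1.0, 1.0, 1.0)
    seed: int = 0
    adam_beta1: float = 0.9
    adam_beta2: float = 0.999
    adam_eps: float = 1e-8

    def __post_init__(self) -> None:
        if self.lr0 <= 0:
            raise ValueError("lr0 must be positive")
        if self.decay_every < 1:
            raise ValueError("decay_every must be >= 1")
        if not (0.0 < self.decay_factor <= 1.0):
            raise ValueError("decay_factor must lie in (0, 1]")

    def lr_at(self, epoch: int) -> float:
        return self.lr0 * self.decay_factor ** (epoch // self.decay_every)


@dataclass
class TrainResult:
    params: ModelParams
    history: pd.DataFrame
    best_epoch: int
    best_val_auc: float


_GRAD_KEYS = ("w_gene", "b_gene", "w_gp", "b_p", "w_pc", "b_c",
              "head_gene_w", "head_gene_b", "head_pathway_w", "head_pathway_b",
              "head_out_w", "head_out_b")


def _act_deriv(h: np.ndarray, kind: str) -> np.ndarray:
    return 1.0 - h * h if kind == "tanh" else np.ones_like(h)


def gradients(
    params: ModelParams,
    x_values: np.ndarray,
    y: np.ndarray,
    alpha: tuple[float, float, float] = (1.0, 1.0, 1.0),
) -> tuple[float, dict[str, np.ndarray | float]]:
    """Loss and exact gradients of the three-head objective (reverse mode).

    Inter-layer weight gradients are multiplied by the masks, mirroring the
    Hadamard product in the forward pass.
    """
    n = x_values.shape[0]
    acts: Activations = forward(x_values, params)
    loss = total_loss(acts, y, alpha)
    a1, a2, a3 = alpha
    # d(mean BCE)/d(logit) = (p - y)/N; clipping is inactive except at saturation
    dl1 = a1 * (acts.p1 - y) / n
    dl2 = a2 * (acts.p2 - y) / n
    dl3 = a3 * (acts.p3 - y) / n

    g: dict[str, np.ndarray | float] = {}
    g["head_out_w"] = acts.h3.T @ dl3
    g["head_out_b"] = float(dl3.sum())
    g["head_pathway_w"] = acts.h2.T @ dl2
    g["head_pathway_b"] = float(dl2.sum())
    g["head_gene_w"] = acts.h1.T @ dl1
    g["head_gene_b"] = float(dl1.sum())

    kind = params.activation
    dh3 = dl3[:, None] * params.head_out_w
    dz3 = dh3 * _act_deriv(acts.h3, kind)
    g["w_pc"] = params.mask_pc * (acts.h2.T @ dz3)
    g["b_c"] = dz3.sum(axis=0)

    dh2 = dl2[:, None] * params.head_pathway_w + dz3 @ params.effective_w_pc().T
    dz2 = dh2 * _act_deriv(acts.h2, kind)
    g["w_gp"] = params.mask_gp * (acts.h1.T @ dz2)
    g["b_p"] = dz2.sum(axis=0)

    dh1 = dl1[:, None] * params.head_gene_w + dz2 @ params.effective_w_gp().T
    dz1 = dh1 * _act_deriv(acts.h1, kind)
    g["w_gene"] = np.einsum("ng,ngj->gj", dz1, x_values)
    g["b_gene"] = dz1.sum(axis=0)
    return loss, g


class _Adam:
    def __init__(self, params: ModelParams, cfg: TrainConfig) -> None:
        self.cfg = cfg
        self.t = 0
        self.m = {k: np.zeros_like(np.asarray(getattr(params, k), dtype=float))
                  for k in _GRAD_KEYS}
        self.v = {k: np.zeros_like(np.asarray(getattr(params, k), dtype=float))
                  for k in _GRAD_KEYS}

    def step(self, params: ModelParams, grads: dict, lr: float) -> None:
        c = self.cfg
        self.t += 1
        bc1 = 1.0 - c.adam_beta1 ** self.t
        bc2 = 1.0 - c.adam_beta2 ** self.t
        for k in _GRAD_KEYS:
            gk = np.asarray(grads[k], dtype=float)
            self.m[k] = c.adam_beta1 * self.m[k] + (1 - c.adam_beta1) * gk
            self.v[k] = c.adam_beta2 * self.v[k] + (1 - c.adam_beta2) * gk * gk
            update = lr * (self.m[k] / bc1) / (np.sqrt(self.v[k] / bc2) + c.adam_eps)
            current = getattr(params, k)
            if np.isscalar(current) or np.ndim(current) == 0:
                setattr(params, k, float(current - update))
            else:
                setattr(params, k, current - update)


def _safe_auc(y: np.ndarray, scores: np.ndarray) -> float:
    if len(np.unique(y)) < 2:
        return float("nan")
    return float(roc_auc_score(y, scores))


def train(
    params: ModelParams,
    x: OmicsTensor | np.ndarray,
    y: Sequence[float],
    cfg: TrainConfig,
    train_idx: Sequence[int] | None = None,
    val_idx: Sequence[int] | None = None,
) -> TrainResult:
    """Fit the network with masked Adam; returns the best-val-AUC checkpoint.

    ``history`` records epoch, learning rate, train/val loss and val AUC.
    With no validation split (or a single-class one) selection falls back to
    the final epoch. Diverging loss (NaN/inf) aborts with a diagnostic.
    """
    values = x.values if isinstance(x, OmicsTensor) else np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    train_idx = np.arange(len(y)) if train_idx is None else np.asarray(train_idx, dtype=int)
    val_idx = np.asarray([] if val_idx is None else val_idx, dtype=int)
    x_tr, y_tr = values[train_idx], y[train_idx]
    x_va, y_va = values[val_idx], y[val_idx]

    n_tr = len(train_idx)
    batch = cfg.batch_size if cfg.batch_size else (n_tr if n_tr <= 2000 else 64)
    rng = np.random.default_rng(cfg.seed)
    params = params.copy()
    opt = _Adam(params, cfg)

    rows = []
    best = {"epoch": -1, "auc": -np.inf, "params": params.copy()}
    for epoch in range(cfg.epochs):
        lr = cfg.lr_at(epoch)
        order = rng.permutation(n_tr) if batch < n_tr else np.arange(n_tr)
        epoch_loss = 0.0
        for start in range(0, n_tr, batch):
            sel = order[start:start + batch]
            loss, grads = gradients(params, x_tr[sel], y_tr[sel], cfg.alpha)
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"training diverged at epoch {epoch} (loss={loss}); "
                    "reduce the learning rate or rescale the inputs")
            epoch_loss += loss * len(sel)
            opt.step(params, grads, lr)
        epoch_loss /= n_tr

        if len(val_idx):
            acts_va = forward(x_va, params)
            val_loss = total_loss(acts_va, y_va, cfg.alpha)
            val_auc = _safe_auc(y_va, acts_va.p3)
        else:
            val_loss, val_auc = float("nan"), float("nan")
        rows.append({"epoch": epoch, "lr": lr, "train_loss": epoch_loss,
                     "val_loss": val_loss, "val_auc": val_auc})
        if np.isfinite(val_auc) and val_auc > best["auc"]:
            best = {"epoch": epoch, "auc": val_auc, "params": params.copy()}

    history = pd.DataFrame(rows)
    if best["epoch"] < 0:    # no usable validation signal: keep final weights
        best = {"epoch": cfg.epochs - 1, "auc": float("nan"), "params": params}
    return TrainResult(params=best["params"], history=history,
                       best_epoch=int(best["epoch"]), best_val_auc=float(best["auc"]))
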