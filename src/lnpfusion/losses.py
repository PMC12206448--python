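"""Hybrid training loss (MSE + weighted cross-modal triplet loss) and metrics.

The triplet term aligns the pooled per-molecule embeddings of the two branches
in one space.  For a batch of b molecules the bank holds 2b embeddings (b from
the 3D branch, b from the aligned sequence branch) with duplicated labels.
Anchors are the b 3D-branch embeddings; a positive partner is any other bank
member whose label lies within tau of the anchor's, a negative partner is a
sequence-branch member whose label differs by more than tau.  Each valid
triplet contributes

    L = max(d(anchor, positive) - d(anchor, negative) + margin, 0)

with Euclidean d, and the loss is the sum over valid triplets divided by
(np + eps), where np counts the triplets with L > 0 (the "positive losses").

Metrics are the standard regression quartet: MSE, MAE, R^2 (1 - SS_res/SS_tot)
and the Pearson correlation coefficient.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn import metrics as skmetrics

from .minigrad import Tensor, concat

__all__ = ["TripletConfig", "EmbeddingBank", "triplet_loss", "hybrid_loss", "metrics"]


@dataclass
class TripletConfig:
    margin: float = 1.0
    beta: float = 6.0  # 6 for scaffold splitting, 3 for cliff splitting
    eps: float = 1e-16
    tau: float = 1.0  # log2 label-distance threshold separating pos from neg partners

    def __post_init__(self):
        if self.margin < 0 or self.beta < 0 or self.eps <= 0:
            raise ValueError("require margin >= 0, beta >= 0, eps > 0")


@dataclass
class EmbeddingBank:
    """Pooled per-molecule embeddings from both branches plus labels (size b each)."""

    z1: Tensor | np.ndarray  # (b, width)
    z2: Tensor | np.ndarray  # (b, width)
    labels: np.ndarray = field(default_factory=lambda: np.array([]))

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=np.float64)

    @property
    def b(self) -> int:
        return len(self.labels)


def _pairwise_dist(a: Tensor, bank: Tensor) -> Tensor:
    """Euclidean distances between rows of a (b, w) and rows of bank (2b, w)."""
    diff = a.reshape(a.shape[0], 1, a.shape[1]) - bank.reshape(1, bank.shape[0], bank.shape[1])
    return ((diff * diff).sum(axis=2) + 1e-12).sqrt()


def triplet_loss(bank: EmbeddingBank, cfg: TripletConfig) -> Tensor:
    """Cross-modal triplet loss over the 2b-embedding bank (see module docstring)."""
    if bank.b < 2:
        raise ValueError("triplet loss needs a batch of at least 2 molecules")
    z1 = bank.z1 if isinstance(bank.z1, Tensor) else Tensor(bank.z1)
    z2 = bank.z2 if isinstance(bank.z2, Tensor) else Tensor(bank.z2)
    b = bank.b
    all_emb = concat([z1, z2], axis=0)  # (2b, w)
    labels2 = np.concatenate([bank.labels, bank.labels])
    dists = _pairwise_dist(z1, all_emb)  # (b, 2b): anchor i -> bank j

    dy = np.abs(bank.labels[:, None] - labels2[None, :])  # (b, 2b)
    pos_ok = dy <= cfg.tau
    pos_ok[np.arange(b), np.arange(b)] = False  # anchor is bank entry i (z1 side)
    neg_ok = dy > cfg.tau
    neg_ok[:, :b] = False  # negatives come from the z2 side

    # L[i, p, n] = relu(d(i, p) - d(i, n) + margin) over valid (p, n) pairs
    L = (dists.reshape(b, 2 * b, 1) - dists.reshape(b, 1, 2 * b) + cfg.margin).relu()
    mask = (pos_ok[:, :, None] & neg_ok[:, None, :]).astype(np.float64)
    np_count = float(((L.data > 0) & (mask > 0)).sum())
    return (L * mask).sum() * (1.0 / (np_count + cfg.eps))


def hybrid_loss(pred, truth, bank: EmbeddingBank | None, cfg: TripletConfig):
    """MSE + beta * triplet loss; returns (total, components dict)."""
    pred_t = pred if isinstance(pred, Tensor) else Tensor(pred)
    truth = np.asarray(truth, dtype=np.float64)
    if pred_t.data.size == 0:
        raise ValueError("empty batch")
    if pred_t.data.size != truth.size:
        raise ValueError("prediction and truth lengths differ")
    err = pred_t.reshape(-1) - truth
    mse = (err * err).mean()
    if cfg.beta > 0 and bank is not None and bank.b >= 2:
        trip = triplet_loss(bank, cfg)
    else:
        trip = Tensor(0.0)
    total = mse + trip * cfg.beta
    return total, {
        "mse": float(mse.data),
        "triplet": float(trip.data),
        "total": float(total.data),
    }


_UNDEFINED = None  # sentinel for metrics undefined on constant truth


def metrics(pred, truth) -> dict:
    """MSE, MAE, R^2 and PCC; R^2/PCC are None (with a warning) on constant truth."""
    pred = np.asarray(pred, dtype=np.float64)
    truth = np.asarray(truth, dtype=np.float64)
    if pred.size != truth.size:
        raise ValueError("prediction and truth lengths differ")
    if pred.size < 2:
        raise ValueError("need at least 2 points")
    out = {
        "mse": float(skmetrics.mean_squared_error(truth, pred)),
        "mae": float(skmetrics.mean_absolute_error(truth, pred)),
    }
    if np.allclose(truth, truth[0]):
        warnings.warn("constant truth: R^2 and PCC are undefined")
        out["r2"] = _UNDEFINED
        out["pcc"] = _UNDEFINED
        return out
    out["r2"] = float(skmetrics.r2_score(truth, pred))
    if np.allclose(pred, pred[0]):
        out["pcc"] = _UNDEFINED
        warnings.warn("constant predictions: PCC is undefined")
    else:
        out["pcc"] = float(stats.pearsonr(pred, truth).statistic)
    return out
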