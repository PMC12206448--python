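"""Molecule 3D transformer: biased self-attention over atoms.

The branch consumes the four structural inputs (atom types, coordinates,
pairwise Euclidean distances, bond-type codes) and produces one feature row per
heavy atom.  Interatomic geometry enters attention as an additive pair bias:
distances are expanded on a bank of Gaussian radial kernels and projected to
one logit per attention head, bond-type codes are embedded to per-head logits,
and a trainable sigmoid gate blends the two terms:

    bias = g * bond_term + (1 - g) * dist_term,   g = sigmoid(theta).

Attention is then softmax(Q K^T / sqrt(d) + bias) V per head.

A masked-atom pretraining interface is included: corrupt a molecule (mask a
fraction of atom types, add uniform coordinate noise), then train three heads —
atom-type classification (cross-entropy, weight 1), coordinate regression
(smooth L1, weight 5) and pairwise-distance regression (smooth L1, weight 10) —
on the corrupted targets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .chemio import ATOM_MASK_ID, Molecule3DRecord
from .minigrad import Parameter, Tensor, concat
from .nn import Embedding, LayerNorm, Linear, Module

__all__ = [
    "PairBias",
    "CorruptionPlan",
    "GaussianPairBias",
    "gaussian_pair_bias",
    "biased_attention",
    "corrupt",
    "smooth_l1",
    "cross_entropy",
    "pretrain_losses",
    "Encoder3D",
    "PretrainHeads",
]

N_BOND_CODES = 5  # 0 none, 1 single, 2 double, 3 triple, 4 aromatic


@dataclass
class PairBias:
    """Additive attention bias, one (n, n) logit matrix per head."""

    bias: Tensor  # (n, n, H)
    gate: float  # sigmoid of the trainable gate scalar, in (0, 1)

    @property
    def n_heads(self) -> int:
        return self.bias.shape[-1]


@dataclass
class CorruptionPlan:
    """Masked atoms plus noisy coordinates for one pretraining example."""

    masked_atom_indices: np.ndarray
    noisy_coords: np.ndarray
    mask_rate: float = 0.15
    noise_halfwidth: float = 1.0
    seed: int = 0


class GaussianPairBias(Module):
    """Distance + bond-type pair bias with a trainable blend gate.

    Distances are featurized by ``n_kernels`` Gaussian radial basis functions
    with fixed centers spanning [0, 12] Å and width equal to the center
    spacing; kernel-to-head weights are Gaussian-initialized.  Bond codes get a
    per-head embedding.  ``gate_logit`` is a trainable scalar; its sigmoid
    blends the two terms.
    """

    def __init__(
        self,
        n_heads: int,
        n_kernels: int = 32,
        max_dist: float = 12.0,
        rng: np.random.Generator | None = None,
    ):
        rng = rng or np.random.default_rng(0)
        self.n_heads = n_heads
        self.centers = np.linspace(0.0, max_dist, n_kernels)
        self.width = max(self.centers[1] - self.centers[0], 1e-3) if n_kernels > 1 else 1.0
        self.kernel_weights = Parameter(rng.normal(0.0, 0.1, size=(n_kernels, n_heads)))
        self.bond_embed = Embedding(N_BOND_CODES, n_heads, rng, scale=0.1)
        self.gate_logit = Parameter(np.zeros(1))

    def __call__(self, dist: np.ndarray, bonds: np.ndarray) -> PairBias:
        return gaussian_pair_bias(dist, bonds, self)


def gaussian_pair_bias(dist: np.ndarray, bonds: np.ndarray, params: GaussianPairBias) -> PairBias:
    """Expand distances on Gaussian kernels, embed bonds, blend with the gate."""
    dist = np.asarray(dist, dtype=np.float64)
    if np.isnan(dist).any():
        raise ValueError("NaN in distance matrix")
    n = dist.shape[0]
    # (n, n, K) radial features — constants w.r.t. the graph
    rbf = np.exp(-((dist[:, :, None] - params.centers[None, None, :]) ** 2)
                 / (2.0 * params.width**2))
    dist_term = Tensor(rbf.reshape(n * n, -1)) @ params.kernel_weights  # (n*n, H)
    dist_term = dist_term.reshape(n, n, params.n_heads)
    bond_term = params.bond_embed(np.asarray(bonds, dtype=np.intp).ravel())
    bond_term = bond_term.reshape(n, n, params.n_heads)
    gate = params.gate_logit.sigmoid()  # (1,)
    bias = bond_term * gate + dist_term * (1.0 - gate)
    return PairBias(bias=bias, gate=float(gate.data[0]))


def biased_attention(q: Tensor, k: Tensor, v: Tensor, bias: Tensor | np.ndarray) -> Tensor:
    """softmax(Q K^T / sqrt(d) + bias) V for one head.

    Rows of the attention matrix are probability vectors (sum to 1) before
    multiplying V.
    """
    d = q.shape[-1]
    if d == 0:
        raise ValueError("head width d must be >= 1")
    bias = bias if isinstance(bias, Tensor) else Tensor(bias)
    logits = (q @ k.T) * (1.0 / np.sqrt(d)) + bias
    return logits.softmax(axis=-1) @ v


def corrupt(
    record: Molecule3DRecord,
    rate: float = 0.15,
    halfwidth: float = 1.0,
    seed: int = 0,
) -> CorruptionPlan:
    """Mask round(rate*n) atoms (>=1 when rate>0) and add uniform coordinate noise."""
    if not 0.0 <= rate <= 1.0:
        raise ValueError(f"mask rate must lie in [0, 1], got {rate}")
    n = record.n_atoms
    rng = np.random.default_rng(seed)
    n_mask = int(np.floor(rate * n + 0.5))
    if rate > 0 and n >= 1:
        n_mask = max(n_mask, 1)
    masked = np.sort(rng.choice(n, size=n_mask, replace=False)) if n_mask else np.array([], dtype=np.intp)
    noise = rng.uniform(-halfwidth, halfwidth, size=record.coords.shape) if halfwidth > 0 else 0.0
    return CorruptionPlan(
        masked_atom_indices=masked.astype(np.intp),
        noisy_coords=record.coords + noise,
        mask_rate=rate,
        noise_halfwidth=halfwidth,
        seed=seed,
    )


def smooth_l1(pred: Tensor, target: np.ndarray, beta: float = 1.0) -> Tensor:
    """Huber-style smooth L1, mean over elements: quadratic below beta, linear above."""
    diff = pred - Tensor(np.asarray(target, dtype=np.float64))
    absdiff = diff.abs()
    quad_mask = (absdiff.data < beta).astype(np.float64)  # constant a.e.
    quad = diff * diff * (0.5 / beta)
    lin = absdiff - 0.5 * beta
    return (quad * quad_mask + lin * (1.0 - quad_mask)).mean()


def cross_entropy(logits: Tensor, targets: np.ndarray) -> Tensor:
    """Mean cross-entropy of integer targets under row-wise softmax logits."""
    targets = np.asarray(targets, dtype=np.intp)
    shift = logits - Tensor(logits.data.max(axis=-1, keepdims=True))
    logz = shift.exp().sum(axis=-1, keepdims=True).log()
    logp = shift - logz
    picked = logp[np.arange(len(targets)), targets]
    return -picked.mean()


def pretrain_losses(
    pred_types: Tensor,
    pred_coords: Tensor,
    pred_dists: Tensor,
    truth: dict,
    weights: tuple[float, float, float] = (1.0, 5.0, 10.0),
) -> tuple[Tensor, dict[str, float]]:
    """Weighted pretraining objective on corrupted targets.

    total = w_type * CE(masked atom types)
          + w_coord * smoothL1(masked-atom coordinates)
          + w_dist * smoothL1(corrupted pairwise distances)

    ``truth`` carries 'types' (k,), 'coords' (k, 3), 'dists' (p,); predictions
    are restricted to the corrupted atoms/pairs.  With no corrupted atoms the
    type/coordinate terms are zero and a warning is emitted.
    """
    w_type, w_coord, w_dist = weights
    components: dict[str, float] = {}
    zero = Tensor(0.0)
    if pred_types is None or len(truth.get("types", [])) == 0:
        warnings.warn("no corrupted atoms: type and coordinate loss terms are zero")
        type_loss = coord_loss = zero
    else:
        type_loss = cross_entropy(pred_types, truth["types"])
        coord_loss = smooth_l1(pred_coords, truth["coords"])
    dist_loss = smooth_l1(pred_dists, truth["dists"]) if truth.get("dists") is not None and np.size(truth["dists"]) else zero
    total = type_loss * w_type + coord_loss * w_coord + dist_loss * w_dist
    components["type_ce"] = float(type_loss.data)
    components["coord_smooth_l1"] = float(coord_loss.data)
    components["dist_smooth_l1"] = float(dist_loss.data)
    components["total"] = float(total.data)
    return total, components


class _Block(Module):
    """Pre-norm transformer block: biased multi-head attention + 2-layer FFN."""

    def __init__(self, width: int, n_heads: int, rng: np.random.Generator):
        assert width % n_heads == 0
        self.n_heads = n_heads
        self.head_dim = width // n_heads
        self.wq = Linear(width, width, rng)
        self.wk = Linear(width, width, rng)
        self.wv = Linear(width, width, rng)
        self.wo = Linear(width, width, rng)
        self.ff1 = Linear(width, 2 * width, rng)
        self.ff2 = Linear(2 * width, width, rng)
        self.norm1 = LayerNorm(width)
        self.norm2 = LayerNorm(width)

    def __call__(self, x: Tensor, bias: PairBias) -> Tensor:
        h = self.norm1(x)
        q, k, v = self.wq(h), self.wk(h), self.wv(h)
        heads = []
        for head in range(self.n_heads):
            sl = slice(head * self.head_dim, (head + 1) * self.head_dim)
            heads.append(
                biased_attention(q[:, sl], k[:, sl], v[:, sl], bias.bias[:, :, head])
            )
        x = x + self.wo(concat(heads, axis=1))
        h = self.norm2(x)
        return x + self.ff2(self.ff1(h).relu())


class Encoder3D(Module):
    """Stack of biased-attention blocks producing per-atom features z1 (n, width)."""

    def __init__(
        self,
        width: int = 512,
        n_layers: int = 6,
        n_heads: int = 8,
        n_kernels: int = 32,
        n_atom_types: int = 30,
        seed: int = 0,
    ):
        rng = np.random.default_rng(seed)
        self.width = width
        self.atom_embed = Embedding(n_atom_types, width, rng)
        self.pair_bias = GaussianPairBias(n_heads, n_kernels, rng=rng)
        self.blocks = [_Block(width, n_heads, rng) for _ in range(n_layers)]
        self.final_norm = LayerNorm(width)

    def __call__(
        self,
        record: Molecule3DRecord,
        masked_atoms: np.ndarray | None = None,
        coords: np.ndarray | None = None,
    ) -> Tensor:
        """Encode one molecule; optionally with masked atom types / noisy coords."""
        type_ids = record.atom_type_ids()
        if masked_atoms is not None and len(masked_atoms):
            type_ids = type_ids.copy()
            type_ids[masked_atoms] = ATOM_MASK_ID
        if coords is None:
            dist = record.dist
        else:
            delta = coords[:, None, :] - coords[None, :, :]
            dist = np.sqrt((delta**2).sum(axis=-1))
        bias = self.pair_bias(dist, record.bonds)
        x = self.atom_embed(type_ids)
        for block in self.blocks:
            x = block(x, bias)
        return self.final_norm(x)

    def encode(self, record: Molecule3DRecord) -> Tensor:
        return self(record)


class PretrainHeads(Module):
    """Type / coordinate / pairwise-distance prediction heads for pretraining."""

    def __init__(self, width: int, n_atom_types: int = 30, seed: int = 0):
        rng = np.random.default_rng(seed + 101)
        self.type_head = Linear(width, n_atom_types, rng)
        self.coord_head = Linear(width, 3, rng)
        self.dist_head = Linear(width, 1, rng)

    def __call__(self, z: Tensor, plan: CorruptionPlan, record: Molecule3DRecord):
        """Predictions restricted to corrupted atoms and pairs touching them."""
        masked = plan.masked_atom_indices
        n = record.n_atoms
        pred_types = self.type_head(z.take_rows(masked)) if len(masked) else None
        if len(masked):
            pred_coords = self.coord_head(z.take_rows(masked)) + Tensor(plan.noisy_coords[masked])
        else:
            pred_coords = None
        pairs_i, pairs_j = [], []
        masked_set = set(int(i) for i in masked)
        for i in range(n):
            for j in range(i + 1, n):
                if i in masked_set or j in masked_set:
                    pairs_i.append(i)
                    pairs_j.append(j)
        if pairs_i:
            zi = z.take_rows(np.array(pairs_i, dtype=np.intp))
            zj = z.take_rows(np.array(pairs_j, dtype=np.intp))
            pred_dists = self.dist_head(zi * zj).reshape(-1).abs()
        else:
            pred_dists = None
        truth = {
            "types": record.atom_type_ids()[masked] if len(masked) else np.array([], dtype=np.intp),
            "coords": record.coords[masked] if len(masked) else np.zeros((0, 3)),
            "dists": record.dist[pairs_i, pairs_j] if pairs_i else np.array([]),
        }
        return pred_types, pred_coords, pred_dists, truth
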