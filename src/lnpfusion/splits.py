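"""Scaffold and cliff dataset splitting.

Scaffold splitting groups molecules by Bemis-Murcko scaffold and assigns whole
groups greedily (largest first, ties broken by scaffold string) to train, then
validation, then test — a scaffold never straddles two sets, so the test set
probes generalization to unseen cores.

Cliff splitting clusters molecules by spectral clustering on an ECFP Tanimoto
similarity (affinity) matrix, then stratifies within each cluster: a seeded 10%
draw goes to the test set and the remainder is split 8:2 into train and
validation.  Because structurally similar molecules share clusters, cliff pairs
are spread across sets in proportion, rather than being severed by the split.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem.Scaffolds import MurckoScaffold
from sklearn.cluster import SpectralClustering

from .chemio import LipidRecord
from .cliffs import ecfp

__all__ = ["SplitAssignment", "SingleScaffoldError", "scaffold_split", "cliff_split"]


class SingleScaffoldError(ValueError):
    """All molecules share one scaffold; scaffold splitting cannot partition them."""


@dataclass
class SplitAssignment:
    """Per-molecule train/val/test labels with provenance."""

    assignment: dict[str, str]  # id -> {train, val, test}
    method: str  # scaffold | cliff
    seed: int
    cluster_ids: dict[str, int] = field(default_factory=dict)  # cliff method only

    def ids(self, subset: str) -> list[str]:
        return [i for i, s in self.assignment.items() if s == subset]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": list(self.assignment),
                "set": [self.assignment[i] for i in self.assignment],
                "cluster_id": [self.cluster_ids.get(i, -1) for i in self.assignment],
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame, method: str = "unknown", seed: int = 0):
        return cls(
            assignment=dict(zip(df["id"].astype(str), df["set"])),
            method=method,
            seed=seed,
            cluster_ids=dict(zip(df["id"].astype(str), df.get("cluster_id", -1))),
        )


def scaffold_split(
    records: list[LipidRecord],
    fractions: tuple[float, float, float] = (0.8, 0.1, 0.1),
    seed: int = 0,
) -> SplitAssignment:
    """Greedy Bemis-Murcko scaffold split (deterministic; seed recorded only)."""
    records = list(records)
    if len(records) < 3:
        raise ValueError("scaffold split needs at least 3 molecules")
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    groups: dict[str, list[str]] = {}
    for rec in records:
        scaffold = MurckoScaffold.MurckoScaffoldSmiles(
            mol=Chem.MolFromSmiles(rec.smiles), includeChirality=False
        )
        groups.setdefault(scaffold, []).append(rec.id)
    if len(groups) == 1:
        raise SingleScaffoldError(
            "all molecules share a single Bemis-Murcko scaffold; "
            "use cliff_split or random splitting instead"
        )
    ordered = sorted(groups.items(), key=lambda kv: (-len(kv[1]), kv[0]))
    n = len(records)
    n_train = fractions[0] * n
    n_val = fractions[1] * n
    assignment: dict[str, str] = {}
    counts = {"train": 0, "val": 0, "test": 0}
    for scaffold, ids in ordered:
        if counts["train"] + len(ids) <= round(n_train) or counts["train"] == 0:
            dest = "train"
        elif counts["val"] + len(ids) <= round(n_val) or counts["val"] == 0:
            dest = "val"
        else:
            dest = "test"
        for mol_id in ids:
            assignment[mol_id] = dest
        counts[dest] += len(ids)
    return SplitAssignment(assignment=assignment, method="scaffold", seed=seed)


def cliff_split(
    records: list[LipidRecord],
    k: int = 5,
    test_frac: float = 0.10,
    train_val: tuple[float, float] = (0.8, 0.2),
    seed: int = 0,
    radius: int = 2,
    n_bits: int = 2048,
) -> SplitAssignment:
    """Spectral-cluster-stratified split on an ECFP Tanimoto affinity matrix."""
    records = list(records)
    n = len(records)
    if n < k:
        raise ValueError(f"need at least k={k} molecules, got {n}")
    fps = np.stack([ecfp(r.smiles, radius, n_bits) for r in records]).astype(np.float64)
    inter = fps @ fps.T
    bits = fps.sum(axis=1)
    union = bits[:, None] + bits[None, :] - inter
    affinity = np.where(union > 0, inter / np.maximum(union, 1e-12), 1.0)
    if k == 1:
        labels = np.zeros(n, dtype=int)
    else:
        sc = SpectralClustering(
            n_clusters=k, affinity="precomputed", random_state=int(seed) & 0x7FFFFFFF,
            assign_labels="discretize",
        )
        labels = sc.fit_predict(affinity)
    labels = _merge_small_clusters(labels, affinity, min_size=3)

    rng = np.random.default_rng(seed)
    assignment: dict[str, str] = {}
    cluster_ids: dict[str, int] = {}
    for cluster in np.unique(labels):
        idx = np.flatnonzero(labels == cluster)
        idx = idx[rng.permutation(len(idx))]
        n_test = int(np.floor(test_frac * len(idx) + 0.5))
        test_idx = idx[:n_test]
        rest = idx[n_test:]
        n_train = int(np.floor(train_val[0] / sum(train_val) * len(rest) + 0.5))
        train_idx, val_idx = rest[:n_train], rest[n_train:]
        for i in test_idx:
            assignment[records[i].id] = "test"
        for i in train_idx:
            assignment[records[i].id] = "train"
        for i in val_idx:
            assignment[records[i].id] = "val"
        for i in idx:
            cluster_ids[records[i].id] = int(cluster)
    return SplitAssignment(
        assignment=assignment, method="cliff", seed=seed, cluster_ids=cluster_ids
    )


def _merge_small_clusters(labels: np.ndarray, affinity: np.ndarray, min_size: int) -> np.ndarray:
    labels = labels.copy()
    while True:
        sizes = {c: int((labels == c).sum()) for c in np.unique(labels)}
        small = [c for c, s in sizes.items() if s < min_size]
        if not small or len(sizes) == 1:
            return labels
        c = small[0]
        members = labels == c
        best, best_sim = None, -1.0
        for other in sizes:
            if other == c:
                continue
            sim = affinity[np.ix_(members, labels == other)].mean()
            if sim > best_sim:
                best, best_sim = other, sim
        warnings.warn(f"merging cluster {c} (size {sizes[c]}) into nearest cluster {best}")
        labels[members] = best
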