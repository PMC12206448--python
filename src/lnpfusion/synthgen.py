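"""Synthetic combinatorial ionizable-lipid libraries with known ground truth.

The generator emulates the structure of a combinatorial lipid screen: an
amine-bearing head group (varying alkyl/aminoalkyl/heterocyclic substituent)
attached to a central tertiary amine carrying two ester-linked hydrocarbon
tails of varying length,

    R-N(CH2CH2-O-C(=O)-(CH2)_t-H)2 ,

giving n_heads x n_tails molecules.  Labels live on a log2-like transfection
scale and are a linear function of interpretable descriptors (carbon count as
tail-length proxy, basic-amine count, ester count) plus Gaussian noise, so
learnability and parameter recovery are guaranteed by construction.

Transfection cliffs are injected as single-atom twins: one chain CH2 carbon of
a parent molecule is substituted by nitrogen (C -> N) and the twin's label is
shifted by ``gap_log2``.  The substitution site is chosen, among all eligible
chain carbons, to maximize the structure-similarity triple, and each injected
pair is verified at generation time to satisfy the screening thresholds
(structure similarity > 0.9, TD > 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from rdkit import Chem

from .chemio import LipidRecord, canonicalize
from .cliffs import similarity_triple, transfection_difference

__all__ = [
    "SyntheticLibrary",
    "generate_library",
    "assign_labels",
    "inject_cliffs",
    "descriptors",
]

#: head-group substituents on the central nitrogen (attachment at string end)
HEAD_FRAGMENTS: list[str] = [
    "C", "C1CCCCC1", "CC", "C1CCN(CC1)CC", "CCC",
    "C1COCCN1CC", "CCCC", "c1ccccc1CC", "CCCCC", "C1CCCN1CC",
    "CCO", "C1CN(C)CCN1CC", "CCCO", "C1CCCC1", "CN(C)CC",
    "c1ccccc1CCC", "CCN(C)CC", "C1CCOC1CC", "CN(C)CCC", "C1CCNC1CC",
    "CCN(CC)CC", "C1CCCCC1C", "OCCC", "CC(C)CC",
]

_ESTER_SMARTS = Chem.MolFromSmarts("[CX3](=O)[OX2][#6]")
_AMINE_SMARTS = Chem.MolFromSmarts("[NX3;!$(N-C=O)]")

DEFAULT_COEFFS = {
    "intercept": -22.0,
    "carbon": 0.45,  # per carbon atom (tail-length proxy)
    "amine": 1.8,  # per basic nitrogen
    "ester": 0.8,  # per ester linkage
}


@dataclass
class SyntheticLibrary:
    records: list[LipidRecord]
    provenance: dict = field(default_factory=dict)

    def __iter__(self):
        return iter(self.records)

    def __len__(self):
        return len(self.records)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": [r.id for r in self.records],
                "smiles": [r.smiles for r in self.records],
                "label": [r.label for r in self.records],
                "cell_line": [r.cell_line for r in self.records],
            }
        )


def generate_library(n_heads: int = 20, n_tails: int = 10, seed: int = 0) -> SyntheticLibrary:
    """Enumerate n_heads x n_tails head/tail combinations (deterministic under seed)."""
    if n_heads < 1 or n_tails < 1:
        raise ValueError("n_heads and n_tails must be >= 1")
    if n_heads > len(HEAD_FRAGMENTS):
        raise ValueError(f"at most {len(HEAD_FRAGMENTS)} head groups available")
    rng = np.random.default_rng(seed)
    heads = HEAD_FRAGMENTS[:n_heads]
    tail_lengths = [6 + i for i in range(n_tails)]
    records = []
    for hi, head in enumerate(heads):
        for ti, tlen in enumerate(tail_lengths):
            chain = "C" * tlen
            smiles = canonicalize(f"{head}N(CCOC(=O){chain})CCOC(=O){chain}")
            records.append(
                LipidRecord(id=f"L{hi:02d}T{ti:02d}", smiles=smiles, cell_line="Hela")
            )
    provenance = {
        "n_heads": n_heads,
        "n_tails": n_tails,
        "heads": heads,
        "tail_lengths": tail_lengths,
        "seed": int(seed),
    }
    return SyntheticLibrary(records=records, provenance=provenance)


def descriptors(smiles: str) -> dict[str, int]:
    """Interpretable descriptors driving the synthetic label model."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparseable SMILES: {smiles!r}")
    return {
        "carbon": sum(1 for a in mol.GetAtoms() if a.GetSymbol() == "C"),
        "amine": len(mol.GetSubstructMatches(_AMINE_SMARTS)),
        "ester": len(mol.GetSubstructMatches(_ESTER_SMARTS)),
    }


def assign_labels(
    library: SyntheticLibrary,
    coeffs: dict[str, float] | None = None,
    noise_sd: float = 0.5,
    seed: int = 0,
) -> SyntheticLibrary:
    """label = linear(descriptors) + N(0, noise_sd^2), log2-like scale."""
    if not library.records:
        raise ValueError("empty library")
    coeffs = {**DEFAULT_COEFFS, **(coeffs or {})}
    rng = np.random.default_rng(seed)
    for rec in library.records:
        desc = descriptors(rec.smiles)
        label = coeffs["intercept"] + sum(coeffs[k] * desc[k] for k in ("carbon", "amine", "ester"))
        if noise_sd > 0:
            label += rng.normal(0.0, noise_sd)
        rec.label = float(label)
    library.provenance.update({"coeffs": coeffs, "noise_sd": noise_sd, "label_seed": int(seed)})
    return library


def _chain_carbon_candidates(mol: Chem.Mol) -> list[int]:
    """Aliphatic, acyclic CH2 carbons with exactly two carbon neighbors."""
    out = []
    for atom in mol.GetAtoms():
        if atom.GetSymbol() != "C" or atom.GetIsAromatic() or atom.IsInRing():
            continue
        nbrs = atom.GetNeighbors()
        if len(nbrs) == 2 and all(n.GetSymbol() == "C" for n in nbrs):
            out.append(atom.GetIdx())
    return out


def _substitute_to_n(smiles: str, atom_idx: int) -> str | None:
    mol = Chem.MolFromSmiles(smiles)
    rw = Chem.RWMol(mol)
    rw.GetAtomWithIdx(atom_idx).SetAtomicNum(7)
    try:
        Chem.SanitizeMol(rw)
    except Exception:
        return None
    return Chem.MolToSmiles(rw)


def inject_cliffs(
    library: SyntheticLibrary,
    n_pairs: int = 20,
    gap_log2: float = 5.0,
    seed: int = 0,
    sim_threshold: float = 0.9,
    td_threshold: float = 1.0,
) -> tuple[SyntheticLibrary, list[tuple[str, str]]]:
    """Add single-atom-substituted twins with labels shifted by gap_log2.

    Every injected pair is checked at generation time to pass the screening
    thresholds; parents whose best twin falls short are skipped and another
    parent is drawn.  Returns the augmented library and the injected pair ids.
    The canonical atom indices of the substituted atom in parent and twin are
    recorded in provenance["key_atom_truth"].
    """
    if not library.records or library.records[0].label is None:
        raise ValueError("library must be labelled before injecting cliffs")
    existing = {r.smiles for r in library.records}
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(library.records))
    injected: list[tuple[str, str]] = []
    key_truth: dict[str, int] = {}
    new_records: list[LipidRecord] = []
    for idx in order:
        if len(injected) >= n_pairs:
            break
        parent = library.records[idx]
        if any(parent.id == a for a, _ in injected):
            continue
        mol = Chem.MolFromSmiles(parent.smiles)
        best = None
        for cand in _chain_carbon_candidates(mol):
            twin_smiles = _substitute_to_n(parent.smiles, cand)
            if twin_smiles is None or twin_smiles in existing:
                continue
            triple = similarity_triple(parent.smiles, twin_smiles)
            sim = triple.mean()
            if best is None or sim > best[1]:
                best = (twin_smiles, sim, cand)
        if best is None or best[1] <= sim_threshold:
            continue
        twin_smiles, sim, cand = best
        td = transfection_difference(parent.label, parent.label + gap_log2)
        if td <= td_threshold:
            raise ValueError(f"gap_log2={gap_log2} does not clear the TD threshold")
        sign = 1.0 if rng.random() < 0.5 else -1.0
        twin_id = parent.id + "_t"
        twin = LipidRecord(
            id=twin_id,
            smiles=twin_smiles,
            label=parent.label + sign * gap_log2,
            cell_line=parent.cell_line,
        )
        existing.add(twin_smiles)
        new_records.append(twin)
        injected.append((parent.id, twin_id))
        key_truth[parent.id] = int(cand)
        key_truth[twin_id] = _canonical_index(twin_smiles, parent.smiles, cand)
    if len(injected) < n_pairs:
        raise ValueError(
            f"only {len(injected)} of {n_pairs} requested cliff pairs could be injected"
        )
    library.records.extend(new_records)
    library.provenance.update(
        {
            "injected_pairs": injected,
            "gap_log2": gap_log2,
            "cliff_seed": int(seed),
            "key_atom_truth": key_truth,
        }
    )
    return library, injected


def _canonical_index(twin_canonical: str, parent_smiles: str, parent_atom_idx: int) -> int:
    """Index of the substituted atom in the twin's canonical atom order."""
    mol = Chem.MolFromSmiles(parent_smiles)
    rw = Chem.RWMol(mol)
    rw.GetAtomWithIdx(parent_atom_idx).SetAtomicNum(7)
    Chem.SanitizeMol(rw)
    twin = rw.GetMol()
    Chem.MolToSmiles(twin)
    order = [int(x) for x in twin.GetProp("_smilesAtomOutputOrder").strip("[]").split(",") if x]
    return order.index(parent_atom_idx)
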