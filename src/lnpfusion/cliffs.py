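"""Transfection-cliff analytics: similarity scores, screening, key atoms.

A transfection cliff is a pair of structurally near-identical ionizable lipids
with a large transfection-efficiency gap.  Structure similarity is the mean of
three components, each in [0, 1]:

* substructure similarity — Tanimoto coefficient c/(a+b-c) on ECFP bits
  (radius 2, 2048 bits by default),
* scaffold similarity — Tanimoto on the 166 MACCS structural keys,
* SMILES similarity — 1 - Levenshtein(s1, s2) / max(|s1|, |s2|).

With labels m1, m2 in log2 units, the transfection difference is the absolute
log10 fold change TD = |log10(2^(m2-m1))| = |m2-m1| * log10(2).  A pair is a
cliff when structure similarity > 0.9 and TD > 1 (both strict).

Key atoms of a cliff pair are the atoms outside a maximum common substructure
mapping between the two molecules.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from itertools import combinations

import edlib
import numpy as np
from rdkit import Chem
from rdkit.Chem import MACCSkeys, rdFMCS
from rdkit.Chem import rdFingerprintGenerator

from .chemio import LipidRecord

__all__ = [
    "SimilarityTriple",
    "CliffPair",
    "ScreenResult",
    "ecfp",
    "maccs",
    "tanimoto",
    "smiles_similarity",
    "similarity_triple",
    "structure_similarity",
    "transfection_difference",
    "screen_cliffs",
    "key_atoms",
]

LOG10_2 = math.log10(2.0)


@dataclass
class SimilarityTriple:
    subs: float  # ECFP Tanimoto
    scas: float  # MACCS Tanimoto
    smis: float  # normalized Levenshtein similarity

    def mean(self) -> float:
        return (self.subs + self.scas + self.smis) / 3.0


@dataclass
class CliffPair:
    id_a: str
    id_b: str
    similarity: SimilarityTriple
    structure_similarity: float
    td: float
    key_atoms: tuple[list[int], list[int]] | None = None


@dataclass
class ScreenResult:
    """Screened cliff pairs plus audit counters."""

    pairs: list[CliffPair]
    n_pairs_evaluated: int
    n_pairs_skipped: int  # missing labels
    n_molecules: int

    def molecule_participation(self) -> float:
        """Fraction of screened molecules appearing in at least one cliff pair."""
        if not self.n_molecules:
            return 0.0
        involved = {m for p in self.pairs for m in (p.id_a, p.id_b)}
        return len(involved) / self.n_molecules


_ECFP_GEN_CACHE: dict[tuple[int, int], object] = {}


def ecfp(mol_or_smiles, radius: int = 2, n_bits: int = 2048) -> np.ndarray:
    """ECFP (Morgan) fingerprint as a 0/1 numpy bitset."""
    mol = _as_mol(mol_or_smiles)
    key = (radius, n_bits)
    if key not in _ECFP_GEN_CACHE:
        _ECFP_GEN_CACHE[key] = rdFingerprintGenerator.GetMorganGenerator(
            radius=radius, fpSize=n_bits
        )
    fp = _ECFP_GEN_CACHE[key].GetFingerprint(mol)
    arr = np.zeros(n_bits, dtype=np.uint8)
    for bit in fp.GetOnBits():
        arr[bit] = 1
    return arr


def maccs(mol_or_smiles) -> np.ndarray:
    """166-key MACCS fingerprint as a 0/1 numpy bitset (bit 0 unused by RDKit)."""
    fp = MACCSkeys.GenMACCSKeys(_as_mol(mol_or_smiles))
    arr = np.zeros(fp.GetNumBits(), dtype=np.uint8)
    for bit in fp.GetOnBits():
        arr[bit] = 1
    return arr


def _as_mol(mol_or_smiles) -> Chem.Mol:
    if isinstance(mol_or_smiles, Chem.Mol):
        return mol_or_smiles
    mol = Chem.MolFromSmiles(mol_or_smiles)
    if mol is None:
        raise ValueError(f"unparseable SMILES: {mol_or_smiles!r}")
    return mol


def tanimoto(fp_a: np.ndarray, fp_b: np.ndarray) -> float:
    """c / (a + b - c) on bitsets; 1.0 when both are empty (degenerate convention)."""
    fp_a = np.asarray(fp_a).astype(bool)
    fp_b = np.asarray(fp_b).astype(bool)
    if fp_a.shape != fp_b.shape:
        raise ValueError(f"bitset length mismatch: {fp_a.shape} vs {fp_b.shape}")
    a = int(fp_a.sum())
    b = int(fp_b.sum())
    c = int((fp_a & fp_b).sum())
    if a + b == 0:
        return 1.0
    return c / (a + b - c)


def smiles_similarity(s1: str, s2: str) -> float:
    """1 - Levenshtein(s1, s2) / max(|s1|, |s2|)."""
    if not s1 or not s2:
        raise ValueError("SMILES similarity undefined for empty strings")
    d = edlib.align(s1, s2, task="distance")["editDistance"]
    return 1.0 - d / max(len(s1), len(s2))


def similarity_triple(smiles_a: str, smiles_b: str, radius: int = 2, n_bits: int = 2048) -> SimilarityTriple:
    return SimilarityTriple(
        subs=tanimoto(ecfp(smiles_a, radius, n_bits), ecfp(smiles_b, radius, n_bits)),
        scas=tanimoto(maccs(smiles_a), maccs(smiles_b)),
        smis=smiles_similarity(smiles_a, smiles_b),
    )


def structure_similarity(triple: SimilarityTriple) -> float:
    """Arithmetic mean of the three similarity components."""
    return triple.mean()


def transfection_difference(m1: float, m2: float) -> float:
    """TD = |log10(2^(m2 - m1))| = |m2 - m1| * log10(2), labels in log2 units."""
    return abs(m2 - m1) * LOG10_2


def screen_cliffs(
    records: list[LipidRecord],
    sim_threshold: float = 0.9,
    td_threshold: float = 1.0,
    radius: int = 2,
    n_bits: int = 2048,
    compute_key_atoms: bool = False,
) -> ScreenResult:
    """Evaluate all unordered pairs and keep the transfection cliffs.

    Strict thresholds: structure_similarity > sim_threshold AND TD >
    td_threshold.  Pairs with a missing label are skipped with a warning.
    Output sorted by TD descending.
    """
    records = list(records)
    n = len(records)
    ecfps = {}
    maccss = {}
    for rec in records:
        if rec.label is not None:
            ecfps[rec.id] = ecfp(rec.smiles, radius, n_bits)
            maccss[rec.id] = maccs(rec.smiles)
    pairs: list[CliffPair] = []
    n_eval = 0
    n_skip = 0
    for ra, rb in combinations(records, 2):
        n_eval += 1
        if ra.label is None or rb.label is None:
            n_skip += 1
            continue
        td = transfection_difference(ra.label, rb.label)
        if td <= td_threshold:
            continue  # similarity cannot rescue a sub-threshold TD
        triple = SimilarityTriple(
            subs=tanimoto(ecfps[ra.id], ecfps[rb.id]),
            scas=tanimoto(maccss[ra.id], maccss[rb.id]),
            smis=smiles_similarity(ra.smiles, rb.smiles),
        )
        sim = triple.mean()
        if sim > sim_threshold:
            ka = key_atoms(ra.smiles, rb.smiles) if compute_key_atoms else None
            pairs.append(CliffPair(ra.id, rb.id, triple, sim, td, ka))
    if n_skip:
        warnings.warn(f"skipped {n_skip} pairs with missing labels")
    pairs.sort(key=lambda p: (-p.td, p.id_a, p.id_b))
    return ScreenResult(pairs, n_eval, n_skip, n)


def key_atoms(smiles_a: str, smiles_b: str, timeout_s: int = 10) -> tuple[list[int], list[int]]:
    """Atoms outside a maximum-common-substructure mapping, per molecule.

    Falls back to a canonical-rank diff (flagged via warning) on MCS timeout.
    """
    mol_a = _as_mol(smiles_a)
    mol_b = _as_mol(smiles_b)
    res = rdFMCS.FindMCS([mol_a, mol_b], timeout=timeout_s)
    if res.canceled or not res.smartsString:
        warnings.warn("MCS search timed out; falling back to canonical-rank diff")
        return _rank_diff(mol_a, mol_b)
    patt = Chem.MolFromSmarts(res.smartsString)
    match_a = mol_a.GetSubstructMatch(patt)
    match_b = mol_b.GetSubstructMatch(patt)
    extra_a = sorted(set(range(mol_a.GetNumAtoms())) - set(match_a))
    extra_b = sorted(set(range(mol_b.GetNumAtoms())) - set(match_b))
    return extra_a, extra_b


def _rank_diff(mol_a: Chem.Mol, mol_b: Chem.Mol) -> tuple[list[int], list[int]]:
    sym_a = [a.GetSymbol() for a in mol_a.GetAtoms()]
    sym_b = [a.GetSymbol() for a in mol_b.GetAtoms()]
    extra_a = [i for i, (x, y) in enumerate(zip(sym_a, sym_b)) if x != y]
    extra_b = list(extra_a)
    extra_a += list(range(len(sym_b), len(sym_a)))
    extra_b += list(range(len(sym_a), len(sym_b)))
    return extra_a, extra_b
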