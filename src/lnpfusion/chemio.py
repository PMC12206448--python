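"""Chemical I/O: dataset parsing, 3D featurization, SMILES tokenization.

Every molecule is canonicalized once on entry (RDKit canonical SMILES) and the
canonical string is re-parsed, so that atom index i of the molecule, row i of
the 3D feature matrices, and the i-th atom token of the SMILES string all refer
to the same heavy atom.  That 1:1 alignment is what lets the fusion block gather
per-atom sequence features against per-atom 3D features; it is checked, never
assumed — a mismatch raises :class:`AlignmentError`.

Hydrogens are excluded everywhere: SMILES atom tokens carry no explicit
hydrogens, so heavy-atom-only featurization keeps both branches on the same
atom set.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from rdkit import Chem, RDLogger
from rdkit.Chem import AllChem
from scipy.spatial.distance import pdist, squareform

RDLogger.DisableLog("rdApp.*")

__all__ = [
    "LipidRecord",
    "Molecule3DRecord",
    "TokenizedSMILES",
    "ParseReport",
    "SchemaError",
    "EmptyDatasetError",
    "AlignmentError",
    "ATOM_TYPES",
    "SMILES_VOCAB",
    "canonicalize",
    "parse_dataset",
    "featurize_3d",
    "tokenize",
    "read_sdf",
]


class SchemaError(ValueError):
    """Required column missing from the input table."""


class EmptyDatasetError(ValueError):
    """No valid rows survived parsing."""


class AlignmentError(RuntimeError):
    """SMILES atom tokens do not align 1:1 with the molecule's heavy atoms."""


# --------------------------------------------------------------------------
# vocabularies
# --------------------------------------------------------------------------

#: 30-symbol atom-type vocabulary: 26 common elements plus 4 special tokens.
ATOM_TYPES: list[str] = [
    "[PAD]", "[UNK]", "[CLS]", "[MASK]",
    "C", "N", "O", "S", "P", "F", "Cl", "Br", "I", "B",
    "Si", "Se", "Na", "K", "Li", "Mg", "Ca", "Zn", "Fe", "Cu",
    "Mn", "Al", "Sn", "As", "Te", "H",
]
assert len(ATOM_TYPES) == 30
ATOM_TYPE_TO_ID = {s: i for i, s in enumerate(ATOM_TYPES)}
ATOM_MASK_ID = ATOM_TYPE_TO_ID["[MASK]"]
ATOM_UNK_ID = ATOM_TYPE_TO_ID["[UNK]"]


def _build_smiles_vocab() -> dict[str, int]:
    tokens = ["[PAD]", "[UNK]", "[CLS]", "[SEP]"]
    tokens += list("CcNnOoSsPpFIBb") + ["Cl", "Br"]
    tokens += [
        "[C@H]", "[C@@H]", "[C@]", "[C@@]", "[CH]", "[CH2]", "[C-]",
        "[N+]", "[N-]", "[NH+]", "[NH2+]", "[NH3+]", "[nH]", "[n+]", "[n-]",
        "[O-]", "[OH]", "[O+]", "[o+]", "[S+]", "[s+]", "[S-]", "[Se]", "[se]",
        "[Si]", "[P+]", "[PH]", "[B-]", "[H]", "[2H]", "[3H]", "[I-]", "[Na+]", "[K+]",
    ]
    tokens += list("()=#-+/\\.:~@*$%")
    tokens += [str(d) for d in range(10)]
    tokens += [f"%{d}" for d in range(10, 31)]
    vocab = {tok: i for i, tok in enumerate(tokens)}
    assert len(vocab) == 100, len(vocab)
    return vocab


#: 100-entry SMILES token vocabulary (fixed, deterministic).
SMILES_VOCAB: dict[str, int] = _build_smiles_vocab()
SMILES_UNK_ID = SMILES_VOCAB["[UNK]"]

_TOKEN_RE = re.compile(
    r"(\[[^\]]+\]|Br|Cl|B|C|N|O|S|P|F|I|b|c|n|o|s|p"
    r"|\(|\)|\.|=|#|-|\+|\\|/|:|~|@|\?|>|\*|\$|%\d{2}|\d)"
)
_ATOM_ORGANIC = set("BCNOSPFI") | {"Br", "Cl"} | set("bcnosp")
_BRACKET_ELEM_RE = re.compile(r"\[(?:\d+)?([A-Za-z][a-z]?)")

_BOND_CODES = {
    Chem.BondType.SINGLE: 1,
    Chem.BondType.DOUBLE: 2,
    Chem.BondType.TRIPLE: 3,
    Chem.BondType.AROMATIC: 4,
}


# --------------------------------------------------------------------------
# domain types
# --------------------------------------------------------------------------


@dataclass
class LipidRecord:
    """One ionizable lipid: canonical SMILES plus optional log2 transfection label."""

    id: str
    smiles: str
    label: float | None = None
    cell_line: str = "other"

    def __post_init__(self):
        if self.label is not None and not np.isfinite(self.label):
            raise ValueError(f"record {self.id}: label must be finite, got {self.label}")


@dataclass
class Molecule3DRecord:
    """Heavy-atom 3D structure: symbols, coordinates (Å), distances, bond codes."""

    atom_symbols: list[str]
    coords: np.ndarray  # (n, 3) Å
    dist: np.ndarray  # (n, n) Å
    bonds: np.ndarray  # (n, n) int codes: 0 none, 1 single, 2 double, 3 triple, 4 aromatic
    fallback_2d: bool = False

    @property
    def n_atoms(self) -> int:
        return len(self.atom_symbols)

    def atom_type_ids(self) -> np.ndarray:
        return np.array(
            [ATOM_TYPE_TO_ID.get(s, ATOM_UNK_ID) for s in self.atom_symbols], dtype=np.intp
        )


@dataclass
class TokenizedSMILES:
    """Token ids plus the positions of atom tokens (atom-level alignment handle)."""

    token_ids: np.ndarray  # (m,) int
    atom_positions: np.ndarray  # (n,) strictly increasing indices into tokens
    tokens: list[str] = field(default_factory=list)

    @property
    def n_tokens(self) -> int:
        return len(self.token_ids)

    @property
    def n_atoms(self) -> int:
        return len(self.atom_positions)


@dataclass
class ParseReport:
    """Valid records plus per-row rejection diagnostics."""

    records: list[LipidRecord]
    rejected: list[tuple[int, str, str]]  # (row number, smiles, reason)

    def __iter__(self):
        return iter(self.records)

    def __len__(self):
        return len(self.records)


# --------------------------------------------------------------------------
# operations
# --------------------------------------------------------------------------


def canonicalize(smiles: str) -> str:
    """RDKit canonical SMILES; raises ValueError on unparseable input."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparseable SMILES: {smiles!r}")
    return Chem.MolToSmiles(mol)


def _mol_from_canonical(smiles: str) -> Chem.Mol:
    """Parse a canonical SMILES so atom indices follow string reading order."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparseable SMILES: {smiles!r}")
    return mol


def _normalize_cell_line(value) -> str:
    text = str(value).strip().lower() if value is not None and value == value else ""
    if text.startswith("hela"):
        return "Hela"
    if text.startswith("raw"):
        return "RAW"
    return "other"


def parse_dataset(path, schema: dict[str, str] | None = None) -> ParseReport:
    """Read a CSV of lipids into canonical :class:`LipidRecord` objects.

    ``schema`` maps the logical column names {id, smiles, label, cell_line} to
    the CSV's actual column names.  Only ``smiles`` is mandatory; missing ids
    are synthesized from row numbers, missing labels stay ``None``.
    """
    schema = {**{"id": "id", "smiles": "smiles", "label": "label", "cell_line": "cell_line"},
              **(schema or {})}
    df = pd.read_csv(path)
    if schema["smiles"] not in df.columns:
        raise SchemaError(f"column {schema['smiles']!r} not found in {path}")
    records, rejected = [], []
    for row_no, row in enumerate(df.to_dict(orient="records"), start=1):
        raw = row[schema["smiles"]]
        try:
            smiles = canonicalize(str(raw))
        except ValueError as exc:
            rejected.append((row_no, str(raw), str(exc)))
            continue
        label = None
        if schema["label"] in row and pd.notna(row[schema["label"]]):
            label = float(row[schema["label"]])
        rec_id = str(row[schema["id"]]) if schema["id"] in row else f"row{row_no}"
        records.append(
            LipidRecord(
                id=rec_id,
                smiles=smiles,
                label=label,
                cell_line=_normalize_cell_line(row.get(schema["cell_line"])),
            )
        )
    if not records:
        raise EmptyDatasetError(f"no valid SMILES rows in {path}")
    return ParseReport(records=records, rejected=rejected)


def _bond_matrix(mol: Chem.Mol) -> np.ndarray:
    n = mol.GetNumAtoms()
    bonds = np.zeros((n, n), dtype=np.int64)
    for bond in mol.GetBonds():
        i, j = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        code = _BOND_CODES.get(bond.GetBondType(), 1)
        bonds[i, j] = bonds[j, i] = code
    return bonds


def featurize_3d(record, seed: int = 0, relax: bool = False) -> Molecule3DRecord:
    """Embed one low-energy conformer (distance geometry, fixed seed).

    Heavy atoms only; hydrogens are added for embedding and dropped afterwards
    (heavy-atom indices are preserved by RDKit's AddHs).  If embedding fails
    after a retry, falls back to flat 2D coordinates and flags the record.
    """
    smiles = record.smiles if isinstance(record, LipidRecord) else canonicalize(record)
    mol = _mol_from_canonical(smiles)
    n = mol.GetNumAtoms()
    symbols = [a.GetSymbol() for a in mol.GetAtoms()]
    bonds = _bond_matrix(mol)
    if n == 1:
        zero = np.zeros((1, 1))
        return Molecule3DRecord(symbols, np.zeros((1, 3)), zero, zero.astype(float), False)

    fallback = False
    molh = Chem.AddHs(mol)
    conf_ok = False
    for attempt in range(2):
        params = AllChem.ETKDGv3()
        params.randomSeed = (int(seed) + attempt) & 0x7FFFFFFF
        if AllChem.EmbedMolecule(molh, params) == 0:
            conf_ok = True
            break
    if conf_ok:
        if relax:
            AllChem.MMFFOptimizeMolecule(molh)
        conf = molh.GetConformer()
        coords = np.array([list(conf.GetAtomPosition(i)) for i in range(n)])
    else:
        AllChem.Compute2DCoords(mol)
        conf = mol.GetConformer()
        coords = np.array([list(conf.GetAtomPosition(i)) for i in range(n)])
        fallback = True

    dist = squareform(pdist(coords))
    return Molecule3DRecord(symbols, coords, dist, bonds, fallback)


def tokenize(record) -> TokenizedSMILES:
    """Deterministic regex tokenization with verified atom/token alignment.

    Atom tokens (organic-subset symbols, aromatic lowercase, bracket atoms) map
    1:1, in order, onto the heavy atoms of the canonical parse; syntax tokens
    (ring digits, bonds, branches) are excluded from ``atom_positions``.
    """
    smiles = record.smiles if isinstance(record, LipidRecord) else canonicalize(record)
    tokens = _TOKEN_RE.findall(smiles)
    if "".join(tokens) != smiles:
        raise AlignmentError(f"tokenizer failed to cover SMILES {smiles!r}")
    atom_positions, atom_elements = [], []
    for pos, tok in enumerate(tokens):
        if tok.startswith("["):
            match = _BRACKET_ELEM_RE.match(tok)
            if match is None:
                raise AlignmentError(f"cannot read element from bracket token {tok!r}")
            atom_positions.append(pos)
            atom_elements.append(match.group(1).capitalize())
        elif tok in _ATOM_ORGANIC:
            atom_positions.append(pos)
            atom_elements.append(tok.capitalize())
    mol = _mol_from_canonical(smiles)
    mol_symbols = [a.GetSymbol() for a in mol.GetAtoms()]
    if len(atom_positions) != len(mol_symbols):
        raise AlignmentError(
            f"{smiles!r}: {len(atom_positions)} atom tokens vs "
            f"{len(mol_symbols)} heavy atoms"
        )
    for tok_elem, mol_elem in zip(atom_elements, mol_symbols):
        if tok_elem != mol_elem:
            raise AlignmentError(
                f"{smiles!r}: token element {tok_elem} != atom element {mol_elem}"
            )
    ids = np.array([SMILES_VOCAB.get(t, SMILES_UNK_ID) for t in tokens], dtype=np.intp)
    return TokenizedSMILES(ids, np.array(atom_positions, dtype=np.intp), tokens)


def read_sdf(path) -> list[Molecule3DRecord]:
    """Read molecules with trusted 3D coordinates from an SDF file."""
    out = []
    for mol in Chem.SDMolSupplier(str(path), removeHs=True):
        if mol is None or mol.GetNumConformers() == 0:
            continue
        conf = mol.GetConformer()
        n = mol.GetNumAtoms()
        coords = np.array([list(conf.GetAtomPosition(i)) for i in range(n)])
        dist = squareform(pdist(coords)) if n > 1 else np.zeros((1, 1))
        out.append(
            Molecule3DRecord(
                [a.GetSymbol() for a in mol.GetAtoms()], coords, dist, _bond_matrix(mol)
            )
        )
    return out
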