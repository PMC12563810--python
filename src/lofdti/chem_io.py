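"""Molecular graph construction, protein tokenization and dataset plumbing.

Atom featurization follows the canonical 74-dimensional scheme: eight
chemical attribute blocks concatenated per atom (see :data:`FEATURE_BLOCKS`
for the exact slot table).  Proteins are strings over a 25-symbol amino
acid alphabet (:data:`PROTEIN_ALPHABET`); characters outside it map to the
catch-all symbol ``X``.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from rdkit import Chem
from rdkit import RDLogger

RDLogger.DisableLog("rdApp.error")

__all__ = [
    "ATOM_TYPES",
    "FEATURE_BLOCKS",
    "FEATURE_DIM",
    "N_ATTRIBUTE_BLOCKS",
    "PROTEIN_ALPHABET",
    "MolecularGraph",
    "BatchedGraphs",
    "ProteinTokens",
    "InteractionRecord",
    "SplitSpec",
    "smiles_to_graph",
    "featurize_atoms",
    "pad_batch",
    "tokenize_protein",
    "pad_token_batch",
    "read_interactions",
    "read_fasta",
    "split_dataset",
]

# 43 common elements; anything else falls into the trailing "other" slot.
ATOM_TYPES = [
    "C", "N", "O", "S", "F", "Si", "P", "Cl", "Br", "Mg", "Na", "Ca", "Fe",
    "As", "Al", "I", "B", "V", "K", "Tl", "Yb", "Sb", "Sn", "Ag", "Pd", "Co",
    "Se", "Ti", "Zn", "H", "Li", "Ge", "Cu", "Au", "Ni", "Cd", "In", "Mn",
    "Zr", "Cr", "Pt", "Hg", "Pb",
]

_HYBRIDIZATIONS = [
    Chem.rdchem.HybridizationType.SP,
    Chem.rdchem.HybridizationType.SP2,
    Chem.rdchem.HybridizationType.SP3,
    Chem.rdchem.HybridizationType.SP3D,
]

# name -> (start, stop, kind); kind "onehot" blocks carry exactly one 1.
FEATURE_BLOCKS: dict[str, tuple[int, int, str]] = {
    "atom_type": (0, 44, "onehot"),          # 43 elements + other
    "degree": (44, 55, "onehot"),            # 0..10
    "implicit_hs": (55, 62, "onehot"),       # 0..5, 6+
    "formal_charge": (62, 63, "scalar"),
    "radical_electrons": (63, 64, "scalar"),
    "hybridization": (64, 69, "onehot"),     # sp, sp2, sp3, sp3d, other
    "aromatic": (69, 70, "flag"),
    "total_hs": (70, 74, "onehot"),          # 0, 1, 2, 3+
}
FEATURE_DIM = 74
N_ATTRIBUTE_BLOCKS = len(FEATURE_BLOCKS)

# 20 standard residues + B, Z, U, O + X as catch-all = 25 symbols.
PROTEIN_ALPHABET = "ACDEFGHIKLMNPQRSTVWYBZUOX"
_AA_INDEX = {aa: i for i, aa in enumerate(PROTEIN_ALPHABET)}
_CATCHALL_INDEX = _AA_INDEX["X"]


@dataclass
class MolecularGraph:
    """Heavy-atom molecular graph with raw per-atom features."""

    atom_features: np.ndarray          # (n_real, 74)
    edges: list[tuple[int, int]]       # undirected, stored once with i < j
    n_real: int
    node_mask: np.ndarray              # bool, length = padded size
    smiles: str = ""

    @property
    def n_nodes(self) -> int:
        return len(self.node_mask)


@dataclass
class BatchedGraphs:
    """Zero-padded graph batch ready for the drug encoder."""

    features: np.ndarray     # (B, max_nodes, 74)
    adjacency: np.ndarray    # (B, max_nodes, max_nodes), symmetric 0/1
    mask: np.ndarray         # (B, max_nodes) bool, True at real atoms
    n_real: np.ndarray       # (B,)


@dataclass
class ProteinTokens:
    indices: np.ndarray      # (length,), values in 0..24
    length: int


@dataclass
class InteractionRecord:
    smiles: str
    sequence: str
    label: int


@dataclass
class SplitSpec:
    ratios: tuple[float, float, float] = (7.0, 1.0, 2.0)
    seed: int = 0


def _onehot(value, choices: list, catch_all: bool = True) -> list[float]:
    vec = [0.0] * (len(choices) + (1 if catch_all else 0))
    try:
        vec[choices.index(value)] = 1.0
    except ValueError:
        if not catch_all:
            raise
        vec[-1] = 1.0
    return vec


def _atom_features(atom: Chem.Atom) -> np.ndarray:
    row = (
        _onehot(atom.GetSymbol(), ATOM_TYPES)
        + _onehot(atom.GetDegree(), list(range(10)))
        + _onehot(atom.GetNumImplicitHs(), list(range(6)))
        + [float(atom.GetFormalCharge())]
        + [float(atom.GetNumRadicalElectrons())]
        + _onehot(atom.GetHybridization(), _HYBRIDIZATIONS)
        + [1.0 if atom.GetIsAromatic() else 0.0]
        + _onehot(min(atom.GetTotalNumHs(), 3), list(range(3)))
    )
    return np.array(row)


def featurize_atoms(mol: Chem.Mol) -> np.ndarray:
    """Stack the 74-dim raw feature rows for every heavy atom of ``mol``."""
    feats = np.stack([_atom_features(a) for a in mol.GetAtoms()])
    assert feats.shape[1] == FEATURE_DIM
    return feats


def smiles_to_graph(smiles: str) -> MolecularGraph:
    """Parse a SMILES string into a featurized heavy-atom graph.

    Aromaticity and implicit hydrogens are perceived by RDKit before
    featurization; hydrogens are features, not nodes.
    """
    if not smiles:
        raise ValueError("empty SMILES string")
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"could not parse SMILES: {smiles!r}")
    edges = sorted(
        (min(b.GetBeginAtomIdx(), b.GetEndAtomIdx()),
         max(b.GetBeginAtomIdx(), b.GetEndAtomIdx()))
        for b in mol.GetBonds()
    )
    feats = featurize_atoms(mol)
    n = mol.GetNumAtoms()
    return MolecularGraph(
        atom_features=feats,
        edges=edges,
        n_real=n,
        node_mask=np.ones(n, dtype=bool),
        smiles=smiles,
    )


def pad_batch(graphs: list[MolecularGraph], max_nodes: int) -> BatchedGraphs:
    """Pad graphs with zero-feature dummy nodes to a common node count."""
    for g in graphs:
        if g.n_real > max_nodes:
            raise ValueError(
                f"graph with {g.n_real} atoms exceeds max_nodes={max_nodes}"
            )
    B = len(graphs)
    feats = np.zeros((B, max_nodes, FEATURE_DIM))
    adj = np.zeros((B, max_nodes, max_nodes))
    mask = np.zeros((B, max_nodes), dtype=bool)
    for i, g in enumerate(graphs):
        feats[i, : g.n_real] = g.atom_features
        mask[i, : g.n_real] = True
        for a, b in g.edges:
            adj[i, a, b] = 1.0
            adj[i, b, a] = 1.0
    return BatchedGraphs(
        features=feats,
        adjacency=adj,
        mask=mask,
        n_real=np.array([g.n_real for g in graphs]),
    )


def tokenize_protein(sequence: str) -> ProteinTokens:
    """Map a protein sequence to indices over the 25-symbol alphabet.

    Unknown characters map to the catch-all symbol ``X`` (index 24).
    """
    if not sequence:
        raise ValueError("empty protein sequence")
    idx = np.array(
        [_AA_INDEX.get(c, _CATCHALL_INDEX) for c in sequence.upper()],
        dtype=np.intp,
    )
    return ProteinTokens(indices=idx, length=len(idx))


def pad_token_batch(tokens: list[ProteinTokens],
                    max_len: int | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Right-pad token sequences; returns (indices (B, L), mask (B, L))."""
    L = max(t.length for t in tokens) if max_len is None else max_len
    B = len(tokens)
    idx = np.full((B, L), _CATCHALL_INDEX, dtype=np.intp)
    mask = np.zeros((B, L), dtype=bool)
    for i, t in enumerate(tokens):
        if t.length > L:
            raise ValueError(f"sequence of length {t.length} exceeds max_len={L}")
        idx[i, : t.length] = t.indices
        mask[i, : t.length] = True
    return idx, mask


def read_interactions(path: str | Path) -> list[InteractionRecord]:
    """Read a comma-separated interaction table with header smiles,sequence,label."""
    records: list[InteractionRecord] = []
    with open(path, newline="", encoding="utf-8") as handle:
        reader = csv.DictReader(handle)
        required = {"smiles", "sequence", "label"}
        if reader.fieldnames is None or not required.issubset(reader.fieldnames):
            raise ValueError(
                f"{path}: expected columns smiles,sequence,label, got {reader.fieldnames}"
            )
        for i, row in enumerate(reader, start=2):  # 1-based incl. header
            raw = row["label"].strip()
            try:
                value = float(raw)
            except ValueError:
                raise ValueError(f"{path}: row {i}: non-numeric label {raw!r}") from None
            if value not in (0.0, 1.0):
                raise ValueError(f"{path}: row {i}: label must be 0 or 1, got {raw!r}")
            records.append(
                InteractionRecord(row["smiles"].strip(), row["sequence"].strip(), int(value))
            )
    return records


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read protein sequences from a FASTA file (id -> sequence)."""
    from Bio import SeqIO

    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def split_dataset(
    records: list, spec: SplitSpec
) -> tuple[list, list, list]:
    """Random 3-way partition with sizes proportional to ``spec.ratios``."""
    n = len(records)
    if n < 10:
        raise ValueError(f"need at least 10 records to split, got {n}")
    w = np.asarray(spec.ratios, dtype=float)
    if w.sum() <= 0 or (w < 0).any():
        raise ValueError("split ratios must be non-negative with positive sum")
    order = np.random.default_rng(spec.seed).permutation(n)
    n_train = int(np.floor(n * w[0] / w.sum()))
    n_val = int(np.floor(n * w[1] / w.sum()))
    train = [records[i] for i in order[:n_train]]
    val = [records[i] for i in order[n_train : n_train + n_val]]
    test = [records[i] for i in order[n_train + n_val :]]
    return train, val, test
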