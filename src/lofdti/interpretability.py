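"""Attention-based attribution: rank residue-atom pairs and drug atoms.

The residue-by-atom cross-attention map is extracted from the fusion
module (head-averaged), stripped of padding rows/columns, and the top
fraction (default 20%) of entries is selected; the selected pairs are
projected onto drug atoms with per-atom aggregate weights, yielding a
highlight specification for molecule depiction.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from math import ceil
from pathlib import Path

import numpy as np

from .chem_io import InteractionRecord, MolecularGraph
from .model import LoFDTI, prepare_records

__all__ = ["AttributionResult", "extract_attention", "remove_virtual_nodes",
           "top_fraction_indices", "map_to_atoms", "explain"]

DEFAULT_FRACTION = 0.20


@dataclass
class AttributionResult:
    selected_indices: list[tuple[int, int]]
    atom_ids: set[int]
    residue_ids: set[int]
    atom_weights: dict[int, float]
    fraction: float
    attention: np.ndarray = field(repr=False, default=None)


def extract_attention(model: LoFDTI, record: InteractionRecord) -> np.ndarray:
    """Head-averaged protein-to-drug attention for one pair.

    Returns a (n_residues, n_atoms_padded) matrix whose rows sum to 1.
    """
    if not model.config.use_gca:
        raise ValueError("model was trained without the cross-attention module; "
                         "no attention map is available")
    data = prepare_records([record], k=model.config.kmer_k)
    _, infos = model.predict_proba(data, return_attention=True)
    bundle = infos[0]["protein_to_drug"]
    att = bundle.att_map            # (1, heads, residues, atoms)
    return att.mean(axis=1)[0]


def remove_virtual_nodes(att: np.ndarray, node_mask: np.ndarray,
                         residue_length: int | None = None) -> np.ndarray:
    """Drop dummy-atom columns and any rows beyond the true residue count."""
    att = np.asarray(att)
    node_mask = np.asarray(node_mask, dtype=bool)
    if node_mask.shape[0] != att.shape[1]:
        raise ValueError(
            f"mask length {node_mask.shape[0]} does not match "
            f"{att.shape[1]} attention columns"
        )
    if not node_mask.any():
        raise ValueError("attention map has no real atom columns")
    trimmed = att[:, node_mask]
    if residue_length is not None:
        trimmed = trimmed[:residue_length]
    return trimmed


def top_fraction_indices(att: np.ndarray,
                         fraction: float = DEFAULT_FRACTION) -> list[tuple[int, int]]:
    """(row, col) pairs of the ceil(fraction * n_entries) largest entries.

    Ties break by higher weight, then lower row, then lower column.
    """
    att = np.asarray(att)
    if att.size == 0:
        raise ValueError("empty attention matrix")
    if not (0.0 < fraction <= 1.0):
        raise ValueError(f"fraction must lie in (0, 1], got {fraction}")
    n_select = ceil(fraction * att.size)
    rows, cols = np.unravel_index(np.arange(att.size), att.shape)
    order = np.lexsort((cols, rows, -att.ravel()))
    chosen = order[:n_select]
    return [(int(rows[i]), int(cols[i])) for i in chosen]


def map_to_atoms(pairs: list[tuple[int, int]], graph: MolecularGraph,
                 att: np.ndarray | None = None,
                 fraction: float = DEFAULT_FRACTION) -> AttributionResult:
    """Project selected (residue, atom) pairs onto unique drug atoms.

    Per-atom weight is the sum of that atom's selected attention entries
    (zero when ``att`` is not supplied).  The weights double as a
    highlight specification for a molecule-drawing backend.
    """
    atom_weights: dict[int, float] = {}
    residues: set[int] = set()
    for r, c in pairs:
        if c >= graph.n_real or c < 0:
            raise IndexError(f"atom index {c} out of range for a "
                             f"{graph.n_real}-atom molecule")
        w = float(att[r, c]) if att is not None else 0.0
        atom_weights[c] = atom_weights.get(c, 0.0) + w
        residues.add(r)
    return AttributionResult(
        selected_indices=list(pairs),
        atom_ids=set(atom_weights),
        residue_ids=residues,
        atom_weights=atom_weights,
        fraction=fraction,
        attention=att,
    )


def explain(model: LoFDTI, record: InteractionRecord,
            fraction: float = DEFAULT_FRACTION) -> AttributionResult:
    """End-to-end attribution for one drug-protein pair."""
    from .chem_io import smiles_to_graph

    graph = smiles_to_graph(record.smiles)
    att = extract_attention(model, record)
    mask = np.zeros(att.shape[1], dtype=bool)
    mask[: graph.n_real] = True
    trimmed = remove_virtual_nodes(att, mask, residue_length=len(record.sequence))
    pairs = top_fraction_indices(trimmed, fraction)
    return map_to_atoms(pairs, graph, att=trimmed, fraction=fraction)


def write_report(result: AttributionResult, out_dir: str | Path) -> None:
    """Write (residue, atom, weight) CSV and an atom-highlight file."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "pairs.csv", "w", newline="", encoding="utf-8") as handle:
        writer = csv.writer(handle)
        writer.writerow(["residue", "atom", "weight"])
        for r, c in result.selected_indices:
            w = result.attention[r, c] if result.attention is not None else ""
            writer.writerow([r, c, w])
    with open(out / "highlights.csv", "w", newline="", encoding="utf-8") as handle:
        writer = csv.writer(handle)
        writer.writerow(["atom", "weight"])
        for atom in sorted(result.atom_weights):
            writer.writerow([atom, result.atom_weights[atom]])
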