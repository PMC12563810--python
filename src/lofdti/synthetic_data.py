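"""Synthetic interaction datasets with a plantable drug-protein rule.

A pair is positive exactly when the drug contains a marker substructure
(default: a carboxylic acid group, matched by graph substructure search,
not by string inspection) AND the protein contains a planted sequence
motif.  Labels can then be flipped with a configurable noise rate.  The
generator emits the same CSV dialect the data loaders read, so every
training and evaluation path runs without downloads.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from rdkit import Chem

from .chem_io import PROTEIN_ALPHABET, InteractionRecord

__all__ = ["SyntheticSpec", "MARKER_TEMPLATES", "PLAIN_TEMPLATES",
           "generate_dataset", "class_balance", "rule_labels", "write_csv"]

# valid SMILES templates containing the default marker (carboxylic acid) ...
MARKER_TEMPLATES = [
    "CC(=O)O",                  # acetic acid
    "CCC(=O)O",                 # propionic acid
    "CC(C)C(=O)O",              # isobutyric acid
    "OC(=O)c1ccccc1",           # benzoic acid
    "NCC(=O)O",                 # glycine
    "OC(=O)CCC(=O)O",           # succinic acid
    "CC(O)C(=O)O",              # lactic acid
    "OC(=O)Cc1ccccc1",          # phenylacetic acid
    "CCCCCC(=O)O",              # hexanoic acid
    "OC(=O)c1ccccc1O",          # salicylic acid
]
# ... and marker-free templates (note the amide/ester decoys).
PLAIN_TEMPLATES = [
    "CCO",                      # ethanol
    "c1ccccc1",                 # benzene
    "CCN",                      # ethylamine
    "CCOCC",                    # diethyl ether
    "c1ccncc1",                 # pyridine
    "CC(C)O",                   # isopropanol
    "CC(=O)N",                  # acetamide (decoy)
    "CC(=O)OC",                 # methyl acetate (decoy)
    "c1ccc2ccccc2c1",           # naphthalene
    "CNC",                      # dimethylamine
]

DEFAULT_MARKER_SMARTS = "[CX3](=O)[OX2H1]"


@dataclass
class SyntheticSpec:
    n_pairs: int = 1000
    n_drugs: int = 20
    n_proteins: int = 50
    marker_smarts: str = DEFAULT_MARKER_SMARTS
    motif: str = "MKYWFH"
    noise_rate: float = 0.0
    protein_length: tuple[int, int] = (50, 100)
    marker_fraction: float = 0.5
    motif_fraction: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if not (0.0 <= self.noise_rate < 0.5):
            raise ValueError(f"noise_rate must lie in [0, 0.5), got {self.noise_rate}")
        if len(self.motif) < 3:
            raise ValueError("motif must be at least 3 residues long")
        bad = set(self.motif) - set(PROTEIN_ALPHABET)
        if bad:
            raise ValueError(f"motif contains symbols outside the alphabet: {bad}")
        lo, hi = self.protein_length
        if lo > hi or lo < 1:
            raise ValueError(f"invalid protein length range {self.protein_length}")
        if len(self.motif) > lo:
            raise ValueError(
                f"motif of length {len(self.motif)} cannot be planted in "
                f"proteins as short as {lo}"
            )
        if Chem.MolFromSmarts(self.marker_smarts) is None:
            raise ValueError(f"invalid marker SMARTS {self.marker_smarts!r}")


def _has_marker(smiles: str, smarts: str) -> bool:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"template is not valid SMILES: {smiles!r}")
    return mol.HasSubstructMatch(Chem.MolFromSmarts(smarts))


def _sample_proteins(spec: SyntheticSpec, rng: np.random.Generator) -> list[str]:
    lo, hi = spec.protein_length
    proteins = []
    for i in range(spec.n_proteins):
        length = int(rng.integers(lo, hi + 1))
        seq = "".join(PROTEIN_ALPHABET[j] for j in rng.integers(0, 25, size=length))
        if rng.random() < spec.motif_fraction:
            pos = int(rng.integers(0, length - len(spec.motif) + 1))
            seq = seq[:pos] + spec.motif + seq[pos + len(spec.motif):]
        proteins.append(seq)
    return proteins


def _sample_drugs(spec: SyntheticSpec, rng: np.random.Generator) -> list[str]:
    markers = [s for s in MARKER_TEMPLATES if _has_marker(s, spec.marker_smarts)]
    plains = [s for s in PLAIN_TEMPLATES if not _has_marker(s, spec.marker_smarts)]
    if not markers or not plains:
        raise ValueError(
            f"marker SMARTS {spec.marker_smarts!r} does not split the template "
            "library into marker and marker-free drugs"
        )
    drugs = []
    for i in range(spec.n_drugs):
        pool = markers if rng.random() < spec.marker_fraction else plains
        drugs.append(pool[int(rng.integers(0, len(pool)))])
    return drugs


def rule_labels(records: list[InteractionRecord],
                spec: SyntheticSpec) -> np.ndarray:
    """The generating rule itself (a perfect oracle on noiseless data)."""
    pattern = Chem.MolFromSmarts(spec.marker_smarts)
    out = []
    for rec in records:
        mol = Chem.MolFromSmiles(rec.smiles)
        out.append(int(mol.HasSubstructMatch(pattern) and spec.motif in rec.sequence))
    return np.array(out)


def generate_dataset(spec: SyntheticSpec) -> list[InteractionRecord]:
    rng = np.random.default_rng(spec.seed)
    drugs = _sample_drugs(spec, rng)
    proteins = _sample_proteins(spec, rng)
    records: list[InteractionRecord] = []
    for _ in range(spec.n_pairs):
        smiles = drugs[int(rng.integers(0, len(drugs)))]
        seq = proteins[int(rng.integers(0, len(proteins)))]
        label = int(_has_marker(smiles, spec.marker_smarts) and spec.motif in seq)
        # the flip variate is always drawn so the record stream is identical
        # across noise rates under one seed
        if rng.random() < spec.noise_rate:
            label = 1 - label
        records.append(InteractionRecord(smiles=smiles, sequence=seq, label=label))
    return records


def class_balance(records: list[InteractionRecord]) -> float:
    if not records:
        raise ValueError("empty record list")
    return float(np.mean([r.label for r in records]))


def write_csv(records: list[InteractionRecord], path: str | Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as handle:
        writer = csv.writer(handle)
        writer.writerow(["smiles", "sequence", "label"])
        for rec in records:
            writer.writerow([rec.smiles, rec.sequence, rec.label])
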