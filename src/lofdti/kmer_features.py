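"""Length-invariant k-mer composition vectors with Gaussian random projection.

A protein sequence over the 25-symbol alphabet is scanned with a sliding
window of size ``k`` (default 3), giving a count vector over the
lexicographic k-mer vocabulary of size ``25**k = 15625``.  Counts are
normalized to frequencies summing to 1, then compressed by a random
projection whose entries are i.i.d. N(0, 1/d) — an approximately
distance-preserving (Johnson–Lindenstrauss) map.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .chem_io import PROTEIN_ALPHABET, tokenize_protein

__all__ = [
    "vocabulary_size",
    "KmerVector",
    "ProjectionMatrix",
    "count_kmers",
    "normalize_counts",
    "kmer_frequencies",
    "make_projection",
    "project",
    "export_sparse",
]


def vocabulary_size(alphabet_size: int = len(PROTEIN_ALPHABET), k: int = 3) -> int:
    return alphabet_size ** k


@dataclass
class KmerVector:
    counts: np.ndarray
    frequencies: np.ndarray
    D: int


@dataclass
class ProjectionMatrix:
    R: np.ndarray     # (D, d)
    d: int
    seed: int


def count_kmers(sequence: str, k: int = 3) -> np.ndarray:
    """Count all length-``k`` windows of ``sequence`` over the protein alphabet.

    The vocabulary is ordered lexicographically by token index, so the
    window (t0, t1, t2) occupies slot t0*25**2 + t1*25 + t2.
    """
    if len(sequence) < k:
        raise ValueError(
            f"sequence of length {len(sequence)} is shorter than k={k}"
        )
    tokens = tokenize_protein(sequence).indices
    base = len(PROTEIN_ALPHABET)
    counts = np.zeros(base ** k, dtype=np.int64)
    # positional index of each window via Horner's rule
    idx = np.zeros(len(tokens) - k + 1, dtype=np.int64)
    for j in range(k):
        idx = idx * base + tokens[j : len(tokens) - k + 1 + j]
    np.add.at(counts, idx, 1)
    return counts


def normalize_counts(counts: np.ndarray) -> np.ndarray:
    total = counts.sum()
    if total <= 0:
        raise ValueError("cannot normalize an all-zero count vector")
    return counts / total


def kmer_frequencies(sequence: str, k: int = 3) -> KmerVector:
    counts = count_kmers(sequence, k=k)
    return KmerVector(counts=counts, frequencies=normalize_counts(counts), D=len(counts))


def make_projection(D: int, d: int, seed: int) -> ProjectionMatrix:
    """Gaussian random projection with entries ~ N(0, 1/d)."""
    if d < 1 or D < 1:
        raise ValueError(f"projection dimensions must be positive, got D={D}, d={d}")
    if D < d:
        raise ValueError(f"target dimension d={d} exceeds source dimension D={D}")
    rng = np.random.default_rng(seed)
    R = rng.normal(0.0, 1.0 / np.sqrt(d), size=(D, d))
    return ProjectionMatrix(R=R, d=d, seed=seed)


def project(frequencies: np.ndarray, projection: ProjectionMatrix) -> np.ndarray:
    frequencies = np.asarray(frequencies)
    if frequencies.shape[-1] != projection.R.shape[0]:
        raise ValueError(
            f"frequency vector of length {frequencies.shape[-1]} does not match "
            f"projection input dimension {projection.R.shape[0]}"
        )
    return frequencies @ projection.R


def export_sparse(vector: KmerVector, path: str | Path, k: int = 3) -> None:
    """Write nonzero k-mer counts as tab-separated (kmer, count, frequency)."""
    base = len(PROTEIN_ALPHABET)
    with open(path, "w", encoding="utf-8") as handle:
        handle.write("kmer\tcount\tfrequency\n")
        for idx in np.flatnonzero(vector.counts):
            chars = []
            value = int(idx)
            for _ in range(k):
                chars.append(PROTEIN_ALPHABET[value % base])
                value //= base
            kmer = "".join(reversed(chars))
            handle.write(
                f"{kmer}\t{vector.counts[idx]}\t{vector.frequencies[idx]:.10g}\n"
            )
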