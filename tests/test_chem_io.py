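"""chem_io: SMILES parsing, 74-dim featurization, padding, tokenization,
tables and splits.  Graph examples are checked against RDKit directly as
an independent oracle."""

import numpy as np
import pytest
from rdkit import Chem

from lofdti.chem_io import (FEATURE_BLOCKS, FEATURE_DIM, N_ATTRIBUTE_BLOCKS,
                            PROTEIN_ALPHABET, InteractionRecord, SplitSpec,
                            pad_batch, read_interactions, smiles_to_graph,
                            split_dataset, tokenize_protein)


# -- smiles_to_graph -------------------------------------------------------

def test_methane_single_node():
    g = smiles_to_graph("C")
    assert g.n_real == 1 and g.edges == []


def test_ethane_two_nodes_one_edge():
    g = smiles_to_graph("CC")
    assert g.n_real == 2 and g.edges == [(0, 1)]


@pytest.mark.parametrize("smiles", ["C1CC", "not_smiles", "C(("])
def test_unparsable_smiles_raises_with_string(smiles):
    with pytest.raises(ValueError, match="SMILES"):
        smiles_to_graph(smiles)


def test_empty_smiles_rejected():
    with pytest.raises(ValueError):
        smiles_to_graph("")


@pytest.mark.parametrize("smiles", ["CCO", "c1ccccc1", "CC(=O)O", "C1CCCCC1N"])
def test_graph_matches_rdkit_oracle(smiles):
    mol = Chem.MolFromSmiles(smiles)
    g = smiles_to_graph(smiles)
    assert g.n_real == mol.GetNumAtoms()
    assert len(g.edges) == mol.GetNumBonds()
    oracle_edges = {
        tuple(sorted((b.GetBeginAtomIdx(), b.GetEndAtomIdx())))
        for b in mol.GetBonds()
    }
    assert set(g.edges) == oracle_edges


# -- featurization ---------------------------------------------------------

def test_feature_rows_have_74_entries():
    g = smiles_to_graph("CCO")
    assert g.atom_features.shape == (3, FEATURE_DIM)
    assert FEATURE_DIM == 74


def test_eight_attribute_blocks_cover_row():
    assert N_ATTRIBUTE_BLOCKS == 8
    spans = sorted(v[:2] for v in FEATURE_BLOCKS.values())
    assert spans[0][0] == 0 and spans[-1][1] == FEATURE_DIM
    for (a, b), (c, d) in zip(spans, spans[1:]):
        assert b == c  # contiguous, non-overlapping


def test_aromatic_carbon_flag_matches_rdkit():
    g = smiles_to_graph("c1ccccc1")
    lo, hi, _ = FEATURE_BLOCKS["aromatic"]
    assert np.all(g.atom_features[:, lo:hi] == 1.0)
    g2 = smiles_to_graph("C1CCCCC1")
    assert np.all(g2.atom_features[:, lo:hi] == 0.0)


def test_neutral_carbon_has_zero_charge_slot():
    g = smiles_to_graph("C")
    lo, hi, _ = FEATURE_BLOCKS["formal_charge"]
    assert g.atom_features[0, lo] == 0.0


def test_charged_atom_records_formal_charge():
    g = smiles_to_graph("[NH4+]")
    lo, _, _ = FEATURE_BLOCKS["formal_charge"]
    assert g.atom_features[0, lo] == 1.0


def test_onehot_blocks_have_exactly_one_hot():
    for smiles in ["CCO", "c1ccncc1", "CC(=O)O", "[Fe]", "C[Se]C"]:
        g = smiles_to_graph(smiles)
        for name, (lo, hi, kind) in FEATURE_BLOCKS.items():
            if kind == "onehot":
                sums = g.atom_features[:, lo:hi].sum(axis=1)
                assert np.all(sums == 1.0), (smiles, name)


def test_featurization_deterministic():
    a = smiles_to_graph("OC(=O)c1ccccc1").atom_features
    b = smiles_to_graph("OC(=O)c1ccccc1").atom_features
    np.testing.assert_array_equal(a, b)


# -- padding ---------------------------------------------------------------

def test_pad_batch_mask_counts():
    g = smiles_to_graph("CCCCC")
    batch = pad_batch([g], max_nodes=50)
    assert batch.mask.sum() == 5
    assert batch.mask.shape == (1, 50)


def test_pad_batch_dummy_rows_zero_and_no_dummy_edges():
    g = smiles_to_graph("CCO")
    batch = pad_batch([g], max_nodes=10)
    assert np.all(batch.features[0, 3:] == 0.0)
    assert np.all(batch.adjacency[0, 3:, :] == 0.0)
    assert np.all(batch.adjacency[0, :, 3:] == 0.0)


def test_pad_batch_oversized_graph_errors():
    g = smiles_to_graph("C" * 60)
    with pytest.raises(ValueError, match="60"):
        pad_batch([g], max_nodes=50)


def test_adjacency_symmetric():
    batch = pad_batch([smiles_to_graph("c1ccccc1O")], max_nodes=8)
    np.testing.assert_array_equal(batch.adjacency[0], batch.adjacency[0].T)


# -- tokenization ----------------------------------------------------------

def test_tokenize_basic():
    toks = tokenize_protein("ACD")
    assert toks.length == 3
    assert np.all(toks.indices < 25)


def test_alphabet_has_25_symbols():
    assert len(PROTEIN_ALPHABET) == 25
    assert len(set(PROTEIN_ALPHABET)) == 25


def test_tokenize_deterministic():
    a = tokenize_protein("MKWYTV").indices
    b = tokenize_protein("MKWYTV").indices
    np.testing.assert_array_equal(a, b)


def test_unknown_character_maps_to_catch_all():
    toks = tokenize_protein("A*J")
    x_index = PROTEIN_ALPHABET.index("X")
    assert toks.indices[1] == x_index and toks.indices[2] == x_index


def test_empty_sequence_rejected():
    with pytest.raises(ValueError):
        tokenize_protein("")


# -- interaction tables ----------------------------------------------------

def _write(tmp_path, text):
    p = tmp_path / "pairs.csv"
    p.write_text(text)
    return p


def test_read_interactions_well_formed(tmp_path):
    p = _write(tmp_path, "smiles,sequence,label\nCC,ACD,1\nCCO,MKW,0\nC,AAA,1\n")
    records = read_interactions(p)
    assert len(records) == 3
    assert records[0] == InteractionRecord("CC", "ACD", 1)


def test_read_interactions_non_binary_label(tmp_path):
    p = _write(tmp_path, "smiles,sequence,label\nCC,ACD,0.5\n")
    with pytest.raises(ValueError, match="row 2"):
        read_interactions(p)


def test_read_interactions_missing_column(tmp_path):
    p = _write(tmp_path, "smiles,label\nCC,1\n")
    with pytest.raises(ValueError, match="columns"):
        read_interactions(p)


def test_read_interactions_header_only(tmp_path):
    p = _write(tmp_path, "smiles,sequence,label\n")
    assert read_interactions(p) == []


def test_read_fasta(tmp_path):
    from lofdti.chem_io import read_fasta
    p = tmp_path / "seqs.fasta"
    p.write_text(">p1\nMKWYACD\n>p2\nAAAA\nCCCC\n")
    seqs = read_fasta(p)
    assert seqs == {"p1": "MKWYACD", "p2": "AAAACCCC"}


# -- splitting -------------------------------------------------------------

def test_split_100_records_is_70_10_20():
    records = list(range(100))
    tr, va, te = split_dataset(records, SplitSpec(seed=0))
    assert (len(tr), len(va), len(te)) == (70, 10, 20)


def test_split_partitions_input():
    records = list(range(37))
    tr, va, te = split_dataset(records, SplitSpec(seed=3))
    assert sorted(tr + va + te) == records
    assert not (set(tr) & set(va)) and not (set(va) & set(te)) and not (set(tr) & set(te))


def test_split_deterministic_under_seed():
    records = list(range(50))
    a = split_dataset(records, SplitSpec(seed=7))
    b = split_dataset(records, SplitSpec(seed=7))
    assert a == b
    c = split_dataset(records, SplitSpec(seed=8))
    assert a != c


def test_split_sizes_sum_for_all_n():
    for n in range(10, 1001, 37):
        tr, va, te = split_dataset(list(range(n)), SplitSpec(seed=1))
        assert len(tr) + len(va) + len(te) == n


def test_split_too_small_rejected():
    with pytest.raises(ValueError):
        split_dataset(list(range(9)), SplitSpec())
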