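"""Model assembly, metrics (with independent oracles), training loop
bookkeeping, checkpointing and the multi-run protocol."""

import numpy as np
import pytest
from scipy.stats import mannwhitneyu

from lofdti.chem_io import InteractionRecord
from lofdti.model import (LoFDTI, ModelConfig, compute_metrics,
                          evaluate_protocol, load_checkpoint, predict_records,
                          prepare_records, save_checkpoint, train)
from lofdti.synthetic_data import SyntheticSpec, generate_dataset


# -- metrics ---------------------------------------------------------------

def test_perfect_separation():
    scores = np.array([0.1, 0.2, 0.8, 0.9])
    labels = np.array([0, 0, 1, 1])
    m = compute_metrics(scores, labels)
    assert m.auroc == 1.0 and m.accuracy == 1.0
    assert m.sensitivity == 1.0 and m.specificity == 1.0


def test_inverted_two_point_ranking():
    m = compute_metrics(np.array([0.2, 0.8]), np.array([1, 0]))
    assert m.auroc == 0.0


def test_random_scores_auroc_near_half():
    rng = np.random.default_rng(0)
    scores = rng.random(1000)
    labels = rng.integers(0, 2, 1000)
    m = compute_metrics(scores, labels)
    assert abs(m.auroc - 0.5) < 0.05


def test_single_class_labels_rejected():
    with pytest.raises(ValueError, match="single class"):
        compute_metrics(np.array([0.1, 0.9]), np.array([1, 1]))


def test_auroc_equals_mann_whitney_oracle():
    """AUROC == U / (n_pos * n_neg) on 100 random score/label sets."""
    rng = np.random.default_rng(1)
    for _ in range(100):
        n = int(rng.integers(10, 60))
        labels = rng.integers(0, 2, n)
        if len(np.unique(labels)) < 2:
            continue
        scores = rng.normal(size=n) + labels * rng.random()
        u = mannwhitneyu(scores[labels == 1], scores[labels == 0],
                         alternative="two-sided").statistic
        oracle = u / ((labels == 1).sum() * (labels == 0).sum())
        m = compute_metrics(scores, labels)
        assert abs(m.auroc - oracle) < 1e-10


def test_metric_identities_on_random_confusion_tables():
    """Recompute accuracy/precision/sensitivity/specificity from counts."""
    rng = np.random.default_rng(2)
    for _ in range(200):
        n = int(rng.integers(20, 80))
        labels = rng.integers(0, 2, n)
        if len(np.unique(labels)) < 2:
            continue
        scores = rng.random(n)
        m = compute_metrics(scores, labels)
        total = m.tp + m.tn + m.fp + m.fn
        assert total == n
        assert m.accuracy == pytest.approx((m.tp + m.tn) / total)
        if m.tp + m.fp:
            assert m.precision == pytest.approx(m.tp / (m.tp + m.fp))
        if m.tp + m.fn:
            assert m.sensitivity == pytest.approx(m.tp / (m.tp + m.fn))
        if m.tn + m.fp:
            assert m.specificity == pytest.approx(m.tn / (m.tn + m.fp))
        # counts consistent with the reported threshold
        pred = scores >= m.threshold
        assert m.tp == int(np.sum(pred & (labels == 1)))


def test_f1_threshold_is_optimal_by_brute_force():
    rng = np.random.default_rng(3)
    from sklearn.metrics import f1_score
    for _ in range(20):
        labels = rng.integers(0, 2, 30)
        if len(np.unique(labels)) < 2:
            continue
        scores = rng.random(30)
        m = compute_metrics(scores, labels)
        best = max(f1_score(labels, scores >= t) for t in np.unique(scores))
        assert m.f1 == pytest.approx(best, abs=1e-12)


# -- forward behaviour -----------------------------------------------------

def test_forward_probabilities_in_open_interval(fast_config, tiny_records):
    model = LoFDTI(fast_config).eval()
    probs = predict_records(model, tiny_records[:10])
    assert probs.shape == (10,)
    assert np.all(probs > 0.0) and np.all(probs < 1.0)


def test_forward_deterministic_in_eval_mode(fast_config, tiny_records):
    model = LoFDTI(fast_config).eval()
    a = predict_records(model, tiny_records[:8])
    b = predict_records(model, tiny_records[:8])
    np.testing.assert_array_equal(a, b)


def test_batch_size_probabilities(fast_config, tiny_records):
    model = LoFDTI(fast_config).eval()
    data = prepare_records(tiny_records[:33])
    probs = model.predict_proba(data, batch_size=16)
    assert probs.shape == (33,)


def test_fused_padding_invariance(fast_config):
    """Criterion: fused outputs unchanged by dummy-node count."""
    model = LoFDTI(fast_config).eval()
    rec = InteractionRecord("CC(=O)O", "MKWYACDEFGHIKLMNPQRST", 1)
    base = predict_records(model, [rec])
    # same single pair inside a batch with much larger molecules/proteins,
    # forcing heavy padding of this record
    big = InteractionRecord("C1CCCCC1CCCCCCOC(=O)CCCCC", "A" * 80, 0)
    data = prepare_records([rec, big])
    padded = model.predict_proba(data)[0]
    assert abs(padded - base[0]) < 1e-10


# -- training --------------------------------------------------------------

def test_train_history_bookkeeping(fast_config, tiny_records):
    tr, va = tiny_records[:40], tiny_records[40:]
    model, hist = train(tr, va, fast_config)
    assert len(hist) == fast_config.max_epochs
    assert sum(h["selected"] for h in hist) == 1
    selected = [h for h in hist if h["selected"]][0]
    assert selected["val_auroc"] == max(h["val_auroc"] for h in hist)


def test_train_empty_split_rejected(fast_config, tiny_records):
    with pytest.raises(ValueError):
        train([], tiny_records[:5], fast_config)
    with pytest.raises(ValueError):
        train(tiny_records[:5], [], fast_config)


def test_training_reduces_loss_on_separable_data():
    recs = generate_dataset(
        SyntheticSpec(n_pairs=160, seed=9, protein_length=(30, 40)))
    cfg = ModelConfig(drug_dim=32, protein_dim=32, hidden_dim=32, kmer_dim=32,
                      n_heads=2, n_gin_layers=2, n_residual_blocks=1,
                      max_epochs=20, learning_rate=1e-3, batch_size=32, seed=1)
    _, hist = train(recs[:128], recs[128:], cfg)
    assert hist[19]["train_loss"] < hist[0]["train_loss"]


def test_train_reproducible_loss_trajectory(fast_config, tiny_records):
    tr, va = tiny_records[:40], tiny_records[40:]
    _, h1 = train(tr, va, fast_config)
    _, h2 = train(tr, va, fast_config)
    assert [e["train_loss"] for e in h1] == [e["train_loss"] for e in h2]


def test_unidirectional_mode_returns_single_attention_map(tiny_records):
    base = dict(drug_dim=16, protein_dim=16, hidden_dim=16, kmer_dim=16,
                n_heads=2, n_gin_layers=1, n_residual_blocks=1, seed=0)
    uni = LoFDTI(ModelConfig(bidirectional=False, **base)).eval()
    data = prepare_records(tiny_records[:4])
    _, infos = uni.predict_proba(data, return_attention=True)
    assert set(infos[0]) == {"protein_to_drug"}
    bi = LoFDTI(ModelConfig(bidirectional=True, **base)).eval()
    _, infos = bi.predict_proba(data, return_attention=True)
    assert set(infos[0]) == {"protein_to_drug", "drug_to_protein"}


def test_no_gca_mode_produces_no_attention(tiny_records):
    cfg = ModelConfig(drug_dim=16, protein_dim=16, hidden_dim=16, kmer_dim=16,
                      n_heads=2, n_gin_layers=1, n_residual_blocks=1,
                      use_gca=False, seed=0)
    model = LoFDTI(cfg).eval()
    _, infos = model.predict_proba(prepare_records(tiny_records[:4]),
                                   return_attention=True)
    assert infos[0] == {}


def test_oversized_molecule_rejected_at_collation(fast_config):
    from dataclasses import replace
    cfg = replace(fast_config, max_nodes=5)
    model = LoFDTI(cfg).eval()
    rec = InteractionRecord("CCCCCCCCCC", "MKWYACD", 0)
    with pytest.raises(ValueError, match="max_nodes"):
        model.predict_proba(prepare_records([rec]))


# -- checkpointing ---------------------------------------------------------

def test_checkpoint_roundtrip(tmp_path, fast_config, tiny_records):
    model = LoFDTI(fast_config).eval()
    before = predict_records(model, tiny_records[:6])
    path = str(tmp_path / "model.npz")
    save_checkpoint(model, path)
    restored = load_checkpoint(path)
    after = predict_records(restored, tiny_records[:6])
    np.testing.assert_allclose(after, before, atol=1e-12)


def test_checkpoint_rejects_foreign_archive(tmp_path):
    path = str(tmp_path / "junk.npz")
    np.savez(path, a=np.zeros(3))
    with pytest.raises(ValueError, match="checkpoint"):
        load_checkpoint(path)


# -- protocol --------------------------------------------------------------

def test_protocol_run_count_and_variance(tiny_records):
    cfg = ModelConfig(drug_dim=16, protein_dim=16, hidden_dim=16, kmer_dim=16,
                      n_heads=2, n_gin_layers=1, n_residual_blocks=1,
                      max_epochs=1, learning_rate=1e-3, batch_size=32, seed=0)
    summary = evaluate_protocol(tiny_records, cfg, n_runs=5)
    assert len(summary.per_run) == 5
    assert set(summary.mean) == set(summary.std)
    assert 0 <= summary.selected_run < 5
    single = evaluate_protocol(tiny_records, cfg, n_runs=1)
    assert all(v == 0.0 for v in single.std.values())
    assert "mean ± std" in single.table()


# -- config validation -----------------------------------------------------

def test_default_config_matches_reference_settings():
    cfg = ModelConfig()
    assert cfg.optimizer == "adam"
    assert cfg.learning_rate == 1e-5
    assert cfg.max_epochs == 100
    assert cfg.batch_size == 64
    assert cfg.n_residual_blocks == 2
    assert cfg.n_gin_layers == 4
    assert cfg.kernel_sizes == (3, 6, 9)
    assert cfg.n_heads == 4
    assert cfg.pool_size == 3


def test_config_validation_errors():
    with pytest.raises(ValueError):
        ModelConfig(optimizer="sgd")
    with pytest.raises(ValueError):
        ModelConfig(gating_mode="nope")
    with pytest.raises(ValueError):
        ModelConfig(hidden_dim=30, n_heads=4)
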