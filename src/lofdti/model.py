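"""Full predictor: encoders + gated cross-attention + MLP head, with
training loop, evaluation metrics and the multi-run protocol.

Defaults follow the reference hyperparameters (Adam, lr 1e-5, 100 epochs,
batch 64, 2 residual blocks, 4 GIN layers, kernels [3, 6, 9], 4 attention
heads, pooling size 3).  That schedule is benchmark-scale; tests and the
synthetic-data demos use a documented fast profile (smaller widths, higher
learning rate, fewer epochs).

Threshold-dependent metrics (accuracy, sensitivity, specificity,
precision) are reported at the F1-optimal threshold; AUROC/AUPRC are
threshold-free, with the standard definitions throughout
(sensitivity = TP/(TP+FN), specificity = TN/(TN+FP)).
"""

from __future__ import annotations

import copy
import json
from dataclasses import asdict, dataclass, replace

import numpy as np
import scipy.sparse as sp
from sklearn.metrics import average_precision_score, roc_auc_score

from .autograd import Parameter, Tensor, concat
from .chem_io import (BatchedGraphs, InteractionRecord, SplitSpec,
                      pad_batch, pad_token_batch, smiles_to_graph,
                      split_dataset, tokenize_protein)
from .drug_encoder import DrugEncoder
from .gca import GCABlock, masked_pool
from .kmer_features import make_projection, kmer_frequencies, vocabulary_size
from .layers import MLP, Adam, Module
from .model_config import ModelConfig

__all__ = ["ModelConfig", "EvalMetrics", "RunSummary", "PreparedData",
           "LoFDTI", "prepare_records", "compute_metrics", "train",
           "predict_records", "evaluate_protocol", "save_checkpoint",
           "load_checkpoint"]

CHECKPOINT_VERSION = 1


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

@dataclass
class EvalMetrics:
    tp: int
    tn: int
    fp: int
    fn: int
    auroc: float
    auprc: float
    accuracy: float
    sensitivity: float
    specificity: float
    precision: float
    f1: float
    threshold: float

    def as_dict(self) -> dict[str, float]:
        return asdict(self)


def _f1_optimal_threshold(scores: np.ndarray, labels: np.ndarray) -> float:
    """Threshold maximizing F1 (prediction rule: score >= threshold).

    Candidates are midpoints between consecutive distinct scores plus the
    minimum score; ties resolve to the lower threshold.
    """
    distinct = np.unique(scores)
    candidates = np.concatenate([[distinct[0]], (distinct[:-1] + distinct[1:]) / 2.0])
    best_t, best_f1 = candidates[0], -1.0
    n_pos = labels.sum()
    for t in candidates:
        pred = scores >= t
        tp = int(np.sum(pred & (labels == 1)))
        fp = int(np.sum(pred & (labels == 0)))
        fn = int(n_pos - tp)
        denom = 2 * tp + fp + fn
        f1 = 2 * tp / denom if denom else 0.0
        if f1 > best_f1:
            best_f1, best_t = f1, t
    return float(best_t)


def compute_metrics(scores, labels) -> EvalMetrics:
    scores = np.asarray(scores, dtype=float).ravel()
    labels = np.asarray(labels, dtype=int).ravel()
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have equal length")
    if len(np.unique(labels)) < 2:
        raise ValueError("AUROC undefined: labels contain a single class")
    auroc = float(roc_auc_score(labels, scores))
    auprc = float(average_precision_score(labels, scores))
    t = _f1_optimal_threshold(scores, labels)
    pred = scores >= t
    tp = int(np.sum(pred & (labels == 1)))
    tn = int(np.sum(~pred & (labels == 0)))
    fp = int(np.sum(pred & (labels == 0)))
    fn = int(np.sum(~pred & (labels == 1)))
    precision = tp / (tp + fp) if tp + fp else 0.0
    sensitivity = tp / (tp + fn) if tp + fn else 0.0
    f1 = (2 * precision * sensitivity / (precision + sensitivity)
          if precision + sensitivity else 0.0)
    return EvalMetrics(
        tp=tp, tn=tn, fp=fp, fn=fn,
        auroc=auroc, auprc=auprc,
        accuracy=(tp + tn) / len(labels),
        sensitivity=sensitivity,
        specificity=tn / (tn + fp) if tn + fp else 0.0,
        precision=precision,
        f1=f1,
        threshold=t,
    )


@dataclass
class RunSummary:
    per_run: list[EvalMetrics]
    mean: dict[str, float]
    std: dict[str, float]
    selected_run: int

    def table(self) -> str:
        keys = ["auroc", "auprc", "accuracy", "sensitivity", "specificity"]
        lines = ["metric\tmean ± std"]
        for k in keys:
            lines.append(f"{k}\t{self.mean[k]:.3f} ± {self.std[k]:.3f}")
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# data preparation
# ---------------------------------------------------------------------------

@dataclass
class PreparedData:
    graphs: list
    token_indices: list[np.ndarray]
    kmer: sp.csr_matrix            # (n, 25**k) frequency rows
    labels: np.ndarray

    def __len__(self) -> int:
        return len(self.graphs)


def prepare_records(records: list[InteractionRecord], k: int = 3) -> PreparedData:
    """Featurize once: graphs, protein tokens and sparse k-mer frequencies."""
    graphs, tokens, rows, cols, vals = [], [], [], [], []
    for i, rec in enumerate(records):
        graphs.append(smiles_to_graph(rec.smiles))
        tokens.append(tokenize_protein(rec.sequence).indices)
        kv = kmer_frequencies(rec.sequence, k=k)
        nz = np.flatnonzero(kv.counts)
        rows.extend([i] * len(nz))
        cols.extend(nz.tolist())
        vals.extend(kv.frequencies[nz].tolist())
    D = vocabulary_size(k=k)
    kmer = sp.csr_matrix(
        (vals, (rows, cols)), shape=(len(records), D)
    )
    labels = np.array([rec.label for rec in records], dtype=float)
    return PreparedData(graphs=graphs, token_indices=tokens, kmer=kmer, labels=labels)


# ---------------------------------------------------------------------------
# the network
# ---------------------------------------------------------------------------

class LoFDTI(Module):
    def __init__(self, config: ModelConfig):
        super().__init__()
        self.config = config
        rng = np.random.default_rng(config.seed)
        self.drug_encoder = DrugEncoder(
            config.drug_dim, config.n_gin_layers, rng,
            variant=config.encoder_variant, use_jk=config.use_jk,
        )
        from .protein_encoder import ProteinEncoder
        self.protein_encoder = ProteinEncoder(
            config.protein_dim, config.n_residual_blocks,
            list(config.kernel_sizes), rng,
            dropout=config.dropout, use_residual=config.use_residual,
        )
        if config.use_gca:
            self.gca_protein = GCABlock(
                config.protein_dim, config.drug_dim, config.hidden_dim,
                config.n_heads, rng, config.gating_mode, config.static_alpha,
            )
            self.gca_drug = (
                GCABlock(config.drug_dim, config.protein_dim, config.hidden_dim,
                         config.n_heads, rng, config.gating_mode,
                         config.static_alpha)
                if config.bidirectional else None
            )
            f_dim = config.hidden_dim * 2
        else:
            self.gca_protein = None
            self.gca_drug = None
            f_dim = config.protein_dim + config.drug_dim
        if config.use_kmer:
            proj = make_projection(vocabulary_size(k=config.kmer_k),
                                   config.kmer_dim, seed=config.seed + 10_000)
            self.kmer_projection = Parameter(proj.R)
            self.kmer_projection.requires_grad = config.kmer_trainable
            f_dim += config.kmer_dim
        else:
            self.kmer_projection = None
        self.head = MLP([f_dim, config.hidden_dim, 1], rng)

    # -- forward --------------------------------------------------------
    def forward_batch(self, batch: BatchedGraphs, token_idx: np.ndarray,
                      token_mask: np.ndarray, kmer_rows: np.ndarray | None,
                      return_attention: bool = False):
        """Returns (logits (B,1), info dict)."""
        cfg = self.config
        d_mask3 = batch.mask[..., None].astype(float)
        p_mask3 = token_mask[..., None].astype(float)
        drug_emb = self.drug_encoder(batch)
        xd = drug_emb.h_JK
        xp = self.protein_encoder(token_idx, p_mask3)
        info: dict = {}
        if cfg.use_gca:
            bundle_p = self.gca_protein(xp, xd, key_mask=batch.mask)
            hp = bundle_p.H * Tensor(p_mask3)
            info["protein_to_drug"] = bundle_p
            if self.gca_drug is not None:
                bundle_d = self.gca_drug(xd, xp, key_mask=token_mask)
                hd = bundle_d.H * Tensor(d_mask3)
                info["drug_to_protein"] = bundle_d
            else:
                hd = xd
            parts = [masked_pool(hp, token_mask, cfg.pool_size),
                     masked_pool(hd, batch.mask, cfg.pool_size)]
        else:  # concatenation-fusion ablation
            parts = [masked_pool(xp, token_mask, cfg.pool_size),
                     masked_pool(xd, batch.mask, cfg.pool_size)]
        if self.kmer_projection is not None:
            if kmer_rows is None:
                raise ValueError("model was built with use_kmer but no k-mer input given")
            parts.append(Tensor(kmer_rows) @ self.kmer_projection)
        f = concat(parts, axis=-1)
        logits = self.head(f)
        if return_attention:
            return logits, info
        return logits, {}

    def predict_proba(self, data: PreparedData, batch_size: int | None = None,
                      return_attention: bool = False):
        """Eval-mode probabilities for a prepared dataset."""
        was_training = self.training
        self.eval()
        bs = batch_size or self.config.batch_size
        probs, infos = [], []
        for lo in range(0, len(data), bs):
            idx = np.arange(lo, min(lo + bs, len(data)))
            logits, info = self.forward_batch(*_collate(self, data, idx),
                                              return_attention=return_attention)
            probs.append(logits.sigmoid().data.ravel())
            if return_attention:
                infos.append(info)
        if was_training:
            self.train()
        out = np.concatenate(probs)
        return (out, infos) if return_attention else out


def _collate(model: LoFDTI, data: PreparedData, idx: np.ndarray):
    cfg = model.config
    graphs = [data.graphs[i] for i in idx]
    n_max = max(g.n_real for g in graphs)
    if cfg.max_nodes is not None:
        if n_max > cfg.max_nodes:
            raise ValueError(
                f"molecule with {n_max} atoms exceeds max_nodes={cfg.max_nodes}"
            )
    batch = pad_batch(graphs, n_max)
    from .chem_io import ProteinTokens
    toks = [ProteinTokens(data.token_indices[i], len(data.token_indices[i]))
            for i in idx]
    token_idx, token_mask = pad_token_batch(toks)
    kmer_rows = (np.asarray(data.kmer[idx].todense())
                 if cfg.use_kmer else None)
    return batch, token_idx, token_mask, kmer_rows


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

def _bce_with_logits(logits: Tensor, labels: np.ndarray) -> Tensor:
    """mean( softplus(z) - y*z ), numerically stable BCE."""
    y = labels.reshape(logits.shape)
    return (logits.softplus() - logits * y).mean()


def train(train_records, val_records, config: ModelConfig,
          model: LoFDTI | None = None):
    """Train with Adam + binary cross-entropy; keep the best-val-AUROC state.

    Returns (model, history) where history is a list of per-epoch dicts.
    """
    if not train_records or not val_records:
        raise ValueError("training and validation sets must be non-empty")
    train_data = (train_records if isinstance(train_records, PreparedData)
                  else prepare_records(train_records, k=config.kmer_k))
    val_data = (val_records if isinstance(val_records, PreparedData)
                else prepare_records(val_records, k=config.kmer_k))
    if model is None:
        model = LoFDTI(config)
    optimizer = Adam(model.parameters(), lr=config.learning_rate)
    rng = np.random.default_rng(config.seed + 1)
    history: list[dict] = []
    best_auroc, best_state, best_epoch = -np.inf, None, -1
    n = len(train_data)
    for epoch in range(config.max_epochs):
        model.train()
        order = rng.permutation(n)
        losses = []
        for lo in range(0, n, config.batch_size):
            idx = order[lo : lo + config.batch_size]
            model.zero_grad()
            logits, _ = model.forward_batch(*_collate(model, train_data, idx))
            loss = _bce_with_logits(logits, train_data.labels[idx])
            loss.backward()
            optimizer.step()
            losses.append(float(loss.data))
        val_scores = model.predict_proba(val_data)
        entry = {"epoch": epoch, "train_loss": float(np.mean(losses))}
        if len(np.unique(val_data.labels)) > 1:
            entry["val_auroc"] = float(roc_auc_score(val_data.labels, val_scores))
            entry["val_auprc"] = float(
                average_precision_score(val_data.labels, val_scores))
        else:
            entry["val_auroc"] = float("nan")
            entry["val_auprc"] = float("nan")
        history.append(entry)
        if entry["val_auroc"] == entry["val_auroc"] and entry["val_auroc"] > best_auroc:
            best_auroc = entry["val_auroc"]
            best_state = copy.deepcopy(model.state_dict())
            best_epoch = epoch
    if best_state is not None:
        model.load_state_dict(best_state)
    model.eval()
    for entry in history:
        entry["selected"] = entry["epoch"] == best_epoch
    return model, history


def predict_records(model: LoFDTI, records: list[InteractionRecord]) -> np.ndarray:
    return model.predict_proba(prepare_records(records, k=model.config.kmer_k))


def evaluate_protocol(records: list[InteractionRecord], config: ModelConfig,
                      n_runs: int = 5) -> RunSummary:
    """Independent split/train/test cycles; mean ± std per metric.

    Each run re-splits 7:1:2 with a distinct seed.
    """
    per_run: list[EvalMetrics] = []
    val_aurocs: list[float] = []
    for run in range(n_runs):
        run_config = replace(config, seed=config.seed + run)
        tr, va, te = split_dataset(records, SplitSpec(seed=run_config.seed))
        model, history = train(tr, va, run_config)
        val_aurocs.append(max(h["val_auroc"] for h in history))
        te_data = prepare_records(te, k=config.kmer_k)
        per_run.append(compute_metrics(model.predict_proba(te_data), te_data.labels))
    keys = ["auroc", "auprc", "accuracy", "sensitivity", "specificity", "precision"]
    values = {k: np.array([getattr(m, k) for m in per_run]) for k in keys}
    return RunSummary(
        per_run=per_run,
        mean={k: float(v.mean()) for k, v in values.items()},
        std={k: float(v.std()) for k, v in values.items()},
        selected_run=int(np.argmax(val_aurocs)),
    )


# ---------------------------------------------------------------------------
# checkpointing
# ---------------------------------------------------------------------------

def save_checkpoint(model: LoFDTI, path: str) -> None:
    state = model.state_dict()
    meta = json.dumps({"version": CHECKPOINT_VERSION,
                       "config": model.config.to_dict()})
    with open(path, "wb") as handle:  # write to the exact path given
        np.savez(handle, __meta__=np.array(meta), **state)


def load_checkpoint(path: str) -> LoFDTI:
    archive = np.load(path, allow_pickle=False)
    if "__meta__" not in archive:
        raise ValueError(f"{path}: not a lofdti checkpoint (missing metadata)")
    meta = json.loads(str(archive["__meta__"]))
    if meta.get("version") != CHECKPOINT_VERSION:
        raise ValueError(f"{path}: unsupported checkpoint version {meta.get('version')}")
    config = ModelConfig.from_dict(meta["config"])
    model = LoFDTI(config)
    model.load_state_dict({k: archive[k] for k in archive.files if k != "__meta__"})
    model.eval()
    return model
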