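# lofdti

Locality-aware drug–target interaction (DTI) prediction with token-level
interpretability:

* **Drug encoder** — SMILES → molecular graph (RDKit), 74-dimensional raw
  atom features (8 attribute blocks), a linear projection, stacked GIN
  layers with learnable ε, mask-aware batch norm, and jumping-knowledge
  aggregation (concatenate all layer outputs, project back). A GCN layer
  is available as an ablation drop-in.
* **Protein encoder** — 25-symbol amino-acid tokenizer, learnable
  embedding, and residual 1-D convolution blocks with multi-scale kernels
  (3, 6, 9 in series), each convolution followed by batch norm, ReLU and
  dropout. Residue count is preserved end to end.
* **3-mer branch** — length-invariant 3-mer frequency vectors
  (25³ = 15,625 slots, normalized to sum 1) compressed by a Gaussian
  N(0, 1/d) random projection; the projection can be frozen (static) or
  trained (dynamic).
* **Gated cross-attention (GCA)** — multi-head scaled dot-product
  attention between residue and atom tokens (padding keys masked), fused
  with the projected query through a gate
  `H = α·A + (1−α)·Proj(Q)` where α is fixed, 0.5, or a learned
  per-token sigmoid. Bidirectional by default; gated outputs are
  max-pooled (window 3) and mean-reduced into the fused vector `f`,
  classified by an MLP head.
* **Interpretability** — extract the head-averaged residue×atom attention
  map, drop virtual (padding) nodes, keep the top 20 % of entries, and
  project them onto drug atoms with aggregate weights.
* **Synthetic data** — generator with a plantable rule (drug carboxylic
  acid substructure ∧ protein sequence motif ⇒ positive, optional label
  noise) so every pipeline stage runs without downloads.

No deep-learning framework is required: the network runs on a small
NumPy reverse-mode autograd engine included in the package
(`lofdti.autograd`, `lofdti.layers`).

## CLI

```bash
lofdti simulate --n-pairs 2000 --seed 1 --out pairs.csv
lofdti train --config cfg.yaml --data pairs.csv --out model.npz --history history.csv
lofdti eval --checkpoint model.npz --data pairs.csv
lofdti predict --checkpoint model.npz --data pairs.csv --out preds.csv
lofdti explain --checkpoint model.npz --smiles "CC(=O)O" --sequence MKYWFHACD --fraction 0.2 --out report/
lofdti ablate --config cfg.yaml --data pairs.csv --variants full,no_jk,no_gca
```

Interaction tables are UTF-8 CSV with header `smiles,sequence,label`
(labels in {0,1}). Configs are strict-schema YAML; an empty config
reproduces the reference hyperparameters (Adam, lr 1e-5, 100 epochs,
batch 64, 2 residual blocks, 4 GIN layers, kernels [3,6,9], 4 heads,
pooling size 3). Every ablation variant (`use_jk`, `use_residual`,
`use_gca`, `encoder_variant: gcn`, `gating_mode`, `use_kmer`,
`bidirectional`, `n_heads`) is reachable from config alone. Exit codes:
0 ok, 1 user error, 2 internal error.

Checkpoints are NumPy `.npz` archives holding every parameter plus a
JSON metadata entry (`version` field and full model config), so
`lofdti eval/predict/explain` rebuild the exact architecture.

### Atom feature layout (74 = 8 blocks)

| block | slots | encoding |
|---|---|---|
| atom type | 44 | one-hot over 43 elements + other |
| degree | 11 | one-hot 0–9 + 10⁺ |
| implicit hydrogens | 7 | one-hot 0–5 + 6⁺ |
| formal charge | 1 | integer |
| radical electrons | 1 | integer |
| hybridization | 5 | one-hot sp, sp², sp³, sp³d + other |
| aromaticity | 1 | flag |
| total hydrogens | 4 | one-hot 0–2 + 3⁺ |

Protein alphabet (25): `ACDEFGHIKLMNPQRSTVWYBZUOX`; unknown characters
map to `X`.

## Evaluation protocol

`lofdti.model.evaluate_protocol` runs n independent 7:1:2
split/train/test cycles (distinct seeds), selects each run's checkpoint
by best validation AUROC, and reports mean ± std per metric. AUROC and
AUPRC are threshold-free; accuracy, sensitivity, specificity and
precision are reported at the F1-optimal threshold with the standard
definitions (sensitivity = TP/(TP+FN), specificity = TN/(TN+FP)).
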