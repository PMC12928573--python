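# crossddi

Cross-view contrastive learning for drug–drug interaction (DDI) prediction.

Adverse interactions between co-administered drugs are a central concern in
polypharmacy; predicting them from chemical structure alone lets candidate
pairs be flagged before clinical evidence exists.  `crossddi` models each
drug in two complementary views of the same molecule:

* a **graph view** — the molecule is decomposed into pharmacophore
  subgraphs by BRICS fragmentation, each fragment's atom/bond one-hots are
  projected into a token matrix `X' = [X'_V ‖ X'_E]` and encoded by
  multi-head self-attention (no positional encoding: the tokens form a set),
  then pooled into an embedding `z_mol`;
* a **sequence view** — the SMILES string is tokenized at the atom level and
  encoded by a BERT-style transformer into contextual token embeddings
  `H = (h_1, …, h_n)`, mean-pooled into `h_mol`.

Training aligns the two views of the same drug and separates different drugs
with a cosine-similarity contrastive loss at temperature τ,

    L = −log [ e^{s(z_A,h_A)/τ} + e^{s(z_B,h_B)/τ} ]
             / [ e^{s(z_A,z_B)/τ} + e^{s(z_A,h_B)/τ} + e^{s(h_A,z_B)/τ} + e^{s(h_A,h_B)/τ} ],

after which the views are fused per drug by bidirectional cross-attention
and a drug pair (A, B) is scored as `ŷ = σ(MLP([d_A ; d_B]))`.  The package
includes the full evaluation protocol — stratified warm-start
cross-validation, drug-disjoint cold-start splits with per-split negative
sampling, confusion/rank metrics, Kruskal–Wallis + Mann–Whitney + Holm
statistics — and a synthetic benchmark generator that plants a recoverable
pharmacophore-pair interaction rule, so the entire pipeline is testable
without external datasets.  The neural components run on a small built-in
reverse-mode autodiff engine over NumPy; no deep-learning framework is
required.

## Worked example

```python
import crossddi as cd

# synthetic benchmark: 300 drugs, 3000 labeled pairs, 10% label noise
ds = cd.make_dataset(n_drugs=300, n_pairs=3000, noise=0.1, seed=7)
print(ds.drugs.head(2))
#    drug_id                                   smiles
# 0  SYN0000  CCNc1cc(C2CCC(C3CNC(C4CCCCC4)C3)CC2)co1
# 1  SYN0001     c1cc(-c2ccsc2)cc(C2CNC(c3ccoc3)C2)n1

plan = cd.make_warm_split(ds.triplets, k=5, seed=0)
cfg = cd.TrainConfig(d=32, cl_epochs=5, epochs=45, seed=0)
result = cd.train_model(ds.drugs, ds.triplets, plan, cfg)
r = result.report
print(f"AUROC {r.auroc:.3f}  ACC {r.accuracy:.3f}  F1 {r.f1:.3f}")
# AUROC 0.916  ACC 0.883  F1 0.863
```

The planted rule labels a pair positive when one drug contains a furan and
the other a thiophene ring, then flips 10% of labels.  An AUROC of ~0.92
against the noisy labels means near-perfect recovery of the rule: with 10%
flip noise the best achievable AUROC on this test fold is ~0.91 (see
`docs/methods.md` for the ceiling argument), so the model has essentially
learned the interaction rule from structure alone.

A command-line interface mirrors the library:

```bash
crossddi synth --n-drugs 300 --n-pairs 3000 --noise 0.1 --seed 7 --out-dir data/
crossddi decompose --drugs data/drugs.tsv --out fragments.json
crossddi train --drugs data/drugs.tsv --ddis data/ddis.tsv --mode warm --seed 0
crossddi ablate --variant no_graph_view --drugs data/drugs.tsv --ddis data/ddis.tsv
```

## Layout

- `src/crossddi/molgraph.py` — SMILES parsing, BRICS decomposition, featurization
- `src/crossddi/graph_encoder.py`, `seq_encoder.py` — the two view encoders
- `src/crossddi/core.py` — contrastive loss, cross-attention fusion, prediction head
- `src/crossddi/experiment.py` — splits, negative sampling, training, ablation
- `src/crossddi/metrics.py` — metrics and statistical comparison
- `src/crossddi/synthetic.py` — benchmark generator with planted signal
- `src/crossddi/autodiff.py` — the reverse-mode engine everything trains on
- `docs/methods.md` — model, defaults, numerical choices, limitations
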