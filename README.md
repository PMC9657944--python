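# epitarget

Multi-target bioactivity prediction for epigenetic drug discovery.

Epigenetic regulators — histone deacetylases (HDAC), histone methyl-
transferases (HMT), histone demethylases (HDM), histone acetyltransferases
(HAT) and DNA methyltransferases (DNMT) — are pursued as drug targets both
individually and, increasingly, in combination: many useful inhibitors act
on several of these proteins at once (polypharmacology). `epitarget`
implements an integrated pipeline for predicting, from a compound's SMILES
string alone, which epigenetic protein targets it is likely to inhibit, and
whether its predicted target profile is significantly enriched in any one
target family.

## Method

The pipeline has four stages:

1. **Quantized molecular graph.** Each SMILES is parsed (RDKit) into a graph
   of heavy atoms with per-atom features (element, degree, charge, implicit
   H count, aromaticity, hybridization, ring membership) and per-bond
   features (order, conjugation, ring). Every chemical bond contributes two
   directed edges.

2. **Message-passing encoder.** Three graph-neural-network variants share
   the node-embedding template *h*ᵢᵗ = *U*(*h*ᵢᵗ⁻¹, *m*ᵢᵗ), where *m*ᵢᵗ
   aggregates the states of atom *i*'s neighborhood over *T* steps:
   - **GCN** — *U* is a ReLU over linear maps of the previous state and the
     summed neighbor states;
   - **GGNN** — *U* is a gated recurrent unit consuming the same message;
   - **DMPNN** — hidden states live on *directed bonds*: the message into
     edge (v→w) sums the states of edges (k→v) excluding the reverse edge
     (w→v), so information never immediately bounces back.

   Each encoder is trained per target with a logistic head on binary
   active/inactive labels (binary cross-entropy, Adam); the molecular
   feature is the penultimate readout vector. The encoders are implemented
   in NumPy on a small reverse-mode autodiff core, so training is exactly
   reproducible from a seed on any machine.

3. **Gradient boosting.** The extracted embeddings feed a regularized
   gradient-boosted tree ensemble (XGBoost, logistic objective with
   per-tree L1/L2 penalties), one binary classifier per protein target.
   A Morgan-fingerprint (ECFP4-style) baseline plugs into the same slot
   for head-to-head comparison.

4. **Multi-target assembly + polypharmacology test.** The per-target
   classifiers are assembled into one multi-target predictor (column j of
   the prediction matrix is exactly classifier j — assembly introduces no
   coupling). For a compound called active on *n* of the *N* registered
   targets, *k* of which lie in a family of size *K*, family enrichment is
   the exact hypergeometric upper tail
   P(X ≥ k) = Σⱼ C(K,j)·C(N−K,n−j)/C(N,n), flagged significant at p < 0.05.

Activity values (IC₅₀/EC₅₀/Kᵢ/K_d in µM) are binarized at 10 µM
(≤ 10 active, > 10 inactive), and a target enters the registry only with at
least 30 active and 30 inactive compounds. Evaluation uses the
imbalance-aware metrics MCC, F1 and balanced accuracy, stratified five-fold
cross-validation with the encoder refit per fold, and a multi-target
protocol that scores only (compound, target) pairs with known labels among
compounds having ≥ 2 known-active targets (TPR / NPV / FDR).

Because public bioactivity extractions cannot ship with the package, a
synthetic-data module generates valence-safe molecules with planted
pharmacophore motifs (amide, carboxylic acid, phenol, nitrile,
sulfonamide) whose labels follow exact structure–activity rules, at any
size and noise level.

## Worked example

```python
import numpy as np
import epitarget as et

records, registry = et.generate_dataset(
    et.SynthSpec(n_molecules=400, label_noise=0.1, seed=7))
smiles = [r.smiles for r in records]
y = np.array([1 if r.labels["T1"] == "active" else 0 for r in records])

res = et.crossvalidate(
    smiles, y,
    et.EncoderConfig(kind="dmpnn", hidden_dim=64, epochs=12, learning_rate=3e-3),
    et.BoosterConfig(seed=0), n_folds=5, seed=0)
print(f"T1 (amide motif)  AUC {res['mean']['auc']:.3f} ± {res['sd']['auc']:.3f}  "
      f"BA {res['mean']['ba']:.3f}  MCC {res['mean']['mcc']:.3f}")

p = et.hypergeom_pvalue(24, 10, 10, 10)
print(f"P(all 10 predicted-active targets fall in the 10-member HDAC group) = {p:.2e}")
```

prints

```
T1 (amide motif)  AUC 0.836 ± 0.062  BA 0.815  MCC 0.630
P(all 10 predicted-active targets fall in the 10-member HDAC group) = 5.10e-07
```

The first line is held-out five-fold performance of DMPNN + boosting on a
400-molecule task whose labels follow a planted amide rule with 10% label
noise (the noise caps attainable AUC well below 1). The second is the
enrichment p-value for a compound predicted active on all ten HDAC targets
of a 24-target registry and nothing else — strong evidence of an
HDAC-family binder.

The same workflow is available from the shell:

```bash
epitarget synth --targets 5 --n 1000 --noise 0.1 --seed 42 --out data/
epitarget train --data data/dataset.csv --target-map data/target_map.csv \
    --encoder dmpnn --out model.zip
epitarget predict --model model.zip --smiles query.csv --out pred/
epitarget polypharm --model model.zip --smiles query.csv --out poly/
```

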