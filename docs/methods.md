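# Methods notes

## Problem setting

Given a compound's SMILES and a registry of epigenetic protein targets
partitioned into object families (HDAC, HMT, HDM, HAT, DNMT), the package
predicts a per-target active/inactive call and tests each family for
enrichment among the predicted-active targets. Activity is a binary
quantity derived from potency: a compound is *active* on a target when its
measured IC₅₀/EC₅₀/Kᵢ/K_d is ≤ 10 µM, *inactive* when strictly above
10 µM. Targets qualify for modeling only with ≥ 30 compounds in **each**
class; this per-class reading keeps every per-target task a learnable
binary problem, and the filter report always lists the dropped targets
with their counts.

Duplicate (compound, target) rows with identical labels are deduplicated
silently; with conflicting labels they are a hard error — no majority
voting, because no principled resolution rule exists at the data layer.
Unknown labels are preserved as `unknown` and never imputed.

## Molecular graphs

Heavy atoms only; hydrogens enter as an implicit-H-count feature rather
than as nodes, keeping graphs small. Atom features: element one-hot over
{C, N, O, S, F, Cl, Br, I, P, B, Si} plus an "other" slot, degree, formal
charge, implicit H count, aromaticity flag, hybridization one-hot
(SP/SP2/SP3/other), ring membership. Bond features: order one-hot
(single/double/triple/aromatic), conjugation, ring. This is the de-facto
standard feature set for message-passing property prediction. A
feature-scheme fingerprint travels with every checkpoint and archive;
loading refuses on mismatch. Multi-fragment SMILES (salts) keep the
largest fragment.

Each bond appears as two directed edges with a `reverse_index` involution;
the graph invariants (involution without fixed points, incoming-edge
bookkeeping, 2·n_bonds directed edges) are asserted in tests on arbitrary
molecules.

## Encoders

All three encoders share the update template h_i^t = U(h_i^{t−1}, m_i^t),
t = 1…T, h⁰ a learned ReLU projection of the atom features:

* **GCN**: m_i = Σ_{j∈N(i)} h_j; U = ReLU(W_self·h + W_msg·m + b).
* **GGNN**: the same summed message through a linear map, consumed by a
  standard GRU (update gate z, reset gate r, tanh candidate).
* **DMPNN**: states on directed edges. Initial edge state
  e⁰_{vw} = ReLU(W_i·[x_v ∥ b_vw]); update
  h^t_{vw} = ReLU(e⁰_{vw} + W_h·(Σ_{k∈N(v)\{w}} h^{t−1}_{kv})) — a skip
  connection to the initial state and the *incoming-minus-reverse* message
  rule; final atom state ReLU(W_o·[x_v ∥ Σ incoming edge states]).

Weights are shared across propagation steps. Readout is mean pooling by
default (sum is available); mean keeps embedding scale independent of
molecule size. The classification head is a single logistic unit; training
minimizes binary cross-entropy with Adam. The molecular feature handed to
the boosting stage is the penultimate (pre-head) readout vector.

The encoders run on a purpose-built NumPy reverse-mode autodiff core.
Neighborhood aggregation, edge gathering and readout are expressed as
sparse-matrix products with prebuilt CSR operators per batch, which makes
the backward pass an exact transpose product; gradients are verified
against central finite differences in the test suite. Mini-batch
membership is drawn once per training from the seed and batch *order* is
reshuffled each epoch — all arithmetic is plain double-precision NumPy, so
two runs with the same seed produce bit-identical weights.

Inference embeds one molecule per forward pass. This costs a little
throughput but makes "batch of one equals batch of many" true by
construction rather than up to BLAS blocking effects.

Default hyperparameters: hidden_dim 128 (tests and the acceptance study
use 64 or less), depth T = 3, epochs 30, learning rate 1e-3, batch size
50, no dropout, no early stopping (a fixed epoch budget is simpler to
reproduce). Class imbalance is reported, not reweighted. One encoder is
trained per target; nothing in the code prevents sharing one encoder
across targets, but per-target encoders match the per-target classifier
structure of the assembly.

## Boosting stage

The gradient-boosted stage is XGBoost's native booster (logistic
objective, per-tree L1/L2 penalties, histogram trees, single thread for
determinism): n_trees 200, max_depth 6, learning rate 0.1, λ = 1, α = 0.
The regularization contract is asserted behaviorally — increasing λ never
decreases training loss. The decision threshold is 0.5 and configurable;
calls are `probability ≥ threshold` everywhere.

The Morgan baseline uses radius 2 and 2048 bits (the ECFP4-equivalent
setting) and emits matrices in the same shape as GNN embeddings, so the
two featurizers are interchangeable throughout evaluation and the
multi-target assembly.

## Multi-target assembly and enrichment

The assembled predictor is literally the ordered set of per-target
pipelines; a test asserts bitwise equality between the assembly's matrix
and independent single-target runs. The polypharmacology test treats the
registry as the population (N targets), the family as the success set
(K), the compound's predicted-active targets as the draw (n) and the
in-family hits as the observation (k); the p-value is the exact upper
tail P(X ≥ k) (computed via `scipy.stats.hypergeom.sf`, cross-checked in
tests against enumeration over all C(N,n) subsets for N ≤ 12). α = 0.05
on raw p-values; a Bonferroni option across families exists but is off by
default. A compound with no predicted-active target reports p = 1 for
every family. The draws count predicted-active *targets* of a compound
(not compounds); this is the only parametrization consistent with
per-compound, per-family significance calls.

## Evaluation protocols

Metrics are computed from explicit TP/TN/FP/FN counts with the standard
formulas (MCC, F1, BA, precision, recall/TPR, NPV = TN/(TN+FN),
FDR = FP/(FP+TP)); any zero-denominator case is *undefined* and propagates
as NaN, never as 0. ROC-AUC is the rank-sum (Mann–Whitney) statistic with
average ranks for ties.

Cross-validation is stratified by label and seed-controlled; within each
fold the encoder is trained on the training split only — held-out
molecules never reach the encoder — and the SHA-256 of each fold's
training SMILES is recorded so leakage is auditable. The external test
split is stratified 80/20 by default. Aggregates are reported fold-wise as
mean ± sd.

The multi-target protocol restricts to compounds with at least two
known-active targets, pools (compound, target) pairs whose true label is
known, ignores unknown-label pairs entirely, and reports pooled TPR, NPV
and FDR (pooling over pairs, not averaging per compound).

## Synthetic data

The generator assembles molecules from an alkyl backbone decorated with
motif-free fragments (chains, rings, an ether) and, per target the
molecule should hit, a carrier fragment containing that target's motif:
amide, carboxylic acid, phenol, nitrile, sulfonamide. All attachments are
C–C single bonds at designated carbons, so assembly is valence-safe and
can never create or destroy a motif; consequently the label oracle
(SMARTS substructure match on the emitted molecule) coincides with the
planted assignment. Exactly round(active_fraction·n) molecules carry each
motif; labels are then flipped with the configured noise probability.
Motifs are detectable within 3 bond hops, matching the default
message-passing depth. The multilabel fixture additionally plants
overlapping motifs (a controlled share of molecules active on ≥ 2
targets) and masks a share of labels as unknown, exercising the
known-label-only protocol.

What the generator does *not* emulate: realistic chemical-space coverage,
ChEMBL-like property distributions, activity cliffs, assay noise
structure, or scaffold bias between train and test. Passing tests
therefore demonstrate that the machinery is correct and that learnable
structure is recovered under label noise — not that any particular
real-world performance level will be met.

## Study scales

The planted-rule recovery study runs at 1,000 molecules × 5 targets with
10% label noise and five-fold CV per target (encoder: hidden 64, T = 3,
12 epochs, lr 3e-3 — a short schedule that the separable synthetic task
saturates); the permutation-null check runs at 200–300 molecules with a
lighter encoder, since a null holds at any scale; the acceptance script's
CV study uses 600 molecules × 3 targets. These sizes were chosen as the
smallest at which fold metrics are stable; everything scales up by
changing `SynthSpec` and the encoder config.

## Numerical choices and degenerate inputs

* Sigmoid inputs are clipped at ±60 before exponentiation; the BCE loss is
  evaluated in the stable log-sum-exp form on logits.
* Glorot-uniform weight initialization, zero biases; Adam with β = (0.9,
  0.999), ε = 1e-8.
* A zero-atom graph is rejected; a single-atom molecule propagates with
  empty messages (the GRU then reduces to its closed zero-input form, and
  DMPNN edge sets are empty).
* Encoder training requires both classes; non-finite loss aborts with the
  epoch and learning rate in the message.
* Ties in ROC scores contribute ½ via average ranks.
* p-values use the survival function directly; no log-space evaluation is
  needed at registry sizes (N ≤ a few dozen).

## Known limitations

* CPU-scale only: the NumPy encoders are intended for datasets of
  10³–10⁴ molecules, not ChEMBL-scale pretraining.
* No hyperparameter search; defaults are sensible but untuned per task.
* No structure standardization beyond largest-fragment selection; no
  stereochemistry-aware features; no 3D information.
* The enrichment test needs a registry substantially larger than a family
  before small p-values are attainable (with K = 1 and n = 1 the minimum
  p is 1/N); on small synthetic registries significance calls are
  conservative by construction.
* Per-target encoders ignore cross-target signal; a shared-encoder
  multi-task variant is a natural extension.
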