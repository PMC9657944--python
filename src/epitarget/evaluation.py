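"""Classification metrics and the validation protocols.

Metrics are the imbalance-aware set used throughout this pipeline:

    MCC = (TP·TN − FP·FN) / √((TP+FP)(TP+FN)(TN+FP)(TN+FN))
    F1  = 2·TP / (2·TP + FP + FN)
    BA  = ½·TP/(TP+FN) + ½·TN/(TN+FP)

together with precision, recall (= TPR), NPV = TN/(TN+FN) and
FDR = FP/(FP+TP). Any metric whose denominator vanishes is *undefined*
and reported as NaN — never silently 0.

Validation protocols:

* stratified five-fold cross-validation where the encoder is refit on
  each training split (held-out molecules never reach the encoder);
* a stratified external test split;
* the multi-target protocol: restrict to compounds with at least two
  known-active targets, pool (compound, target) pairs whose true label
  is known, and report TPR / NPV / FDR on that pool.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.model_selection import StratifiedKFold, train_test_split

from .chem_io import MoleculeRecord, ACTIVE, INACTIVE, smiles_to_graph
from .encoders import EncoderConfig, train_encoder
from .baseline_fingerprints import FingerprintConfig, morgan_matrix
from .boosted_classifier import BoosterConfig, train_booster


class EvaluationError(ValueError):
    pass


# ----------------------------------------------------------------------
# Confusion counts and point metrics
# ----------------------------------------------------------------------

@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise EvaluationError("confusion counts must be non-negative")
        if self.tp + self.tn + self.fp + self.fn == 0:
            raise EvaluationError("empty confusion table")

    @classmethod
    def from_predictions(cls, y_true, y_pred) -> "ConfusionCounts":
        y_true = np.asarray(y_true).astype(int)
        y_pred = np.asarray(y_pred).astype(int)
        return cls(
            tp=int(((y_true == 1) & (y_pred == 1)).sum()),
            tn=int(((y_true == 0) & (y_pred == 0)).sum()),
            fp=int(((y_true == 0) & (y_pred == 1)).sum()),
            fn=int(((y_true == 1) & (y_pred == 0)).sum()),
        )


def mcc(c: ConfusionCounts) -> float:
    denom = (
        (c.tp + c.fp) * (c.tp + c.fn) * (c.tn + c.fp) * (c.tn + c.fn)
    )
    if denom == 0:
        return math.nan
    return (c.tp * c.tn - c.fp * c.fn) / math.sqrt(denom)


def f1(c: ConfusionCounts) -> float:
    denom = 2 * c.tp + c.fp + c.fn
    if denom == 0:
        return math.nan
    return 2 * c.tp / denom


def balanced_accuracy(c: ConfusionCounts) -> float:
    if c.tp + c.fn == 0 or c.tn + c.fp == 0:
        return math.nan
    return 0.5 * c.tp / (c.tp + c.fn) + 0.5 * c.tn / (c.tn + c.fp)


def precision_recall(c: ConfusionCounts) -> tuple[float, float]:
    prec = c.tp / (c.tp + c.fp) if c.tp + c.fp else math.nan
    rec = c.tp / (c.tp + c.fn) if c.tp + c.fn else math.nan
    return prec, rec


def tpr(c: ConfusionCounts) -> float:
    return c.tp / (c.tp + c.fn) if c.tp + c.fn else math.nan


def npv(c: ConfusionCounts) -> float:
    return c.tn / (c.tn + c.fn) if c.tn + c.fn else math.nan


def fdr(c: ConfusionCounts) -> float:
    return c.fp / (c.fp + c.tp) if c.fp + c.tp else math.nan


def roc_auc(scores, labels) -> float:
    """Rank-based AUC: P(score_active > score_inactive) + ½·P(tie)."""
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels).astype(int)
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        return math.nan
    ranks = rankdata(scores)  # average ranks handle ties
    return (ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)


def all_metrics(c: ConfusionCounts) -> dict[str, float]:
    prec, rec = precision_recall(c)
    return {
        "mcc": mcc(c), "f1": f1(c), "ba": balanced_accuracy(c),
        "precision": prec, "recall": rec,
        "tpr": tpr(c), "npv": npv(c), "fdr": fdr(c),
    }


# ----------------------------------------------------------------------
# Fold plans and cross-validation
# ----------------------------------------------------------------------

@dataclass
class FoldPlan:
    n_folds: int
    assignments: np.ndarray  # fold index per record
    seed: int

    def folds(self):
        for f in range(self.n_folds):
            test = np.where(self.assignments == f)[0]
            train = np.where(self.assignments != f)[0]
            yield train, test


def make_fold_plan(labels, n_folds: int = 5, seed: int = 0) -> FoldPlan:
    """Label-stratified fold assignment, reproducible from the seed."""
    labels = np.asarray(labels).astype(int)
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    assign = np.zeros(len(labels), dtype=np.int64)
    for f, (_, test) in enumerate(skf.split(np.zeros(len(labels)), labels)):
        assign[test] = f
    return FoldPlan(n_folds, assign, seed)


def external_split(labels, test_fraction: float = 0.2, seed: int = 0):
    """Stratified external test split (default 80/20)."""
    idx = np.arange(len(labels))
    tr, te = train_test_split(
        idx, test_size=test_fraction, random_state=seed,
        stratify=np.asarray(labels).astype(int),
    )
    return np.sort(tr), np.sort(te)


def _featurize_factory(featurizer, seed: int):
    """Returns fit(smiles, labels) → transform(smiles) → matrix.

    `featurizer` is an EncoderConfig (GNN trained on the training split
    only) or a FingerprintConfig (stateless Morgan bits).
    """
    if isinstance(featurizer, FingerprintConfig):
        def fit(smiles, labels):
            return lambda s: morgan_matrix(s, featurizer)
        return fit
    if isinstance(featurizer, EncoderConfig):
        def fit(smiles, labels):
            cfg = EncoderConfig(**{**featurizer.__dict__, "seed": seed})
            graphs = [smiles_to_graph(s) for s in smiles]
            model = train_encoder(graphs, labels, cfg)
            return lambda s: model.embed([smiles_to_graph(x) for x in s])
        return fit
    raise EvaluationError(f"unknown featurizer {featurizer!r}")


def crossvalidate(
    smiles: list[str],
    labels,
    featurizer,
    booster_cfg: BoosterConfig = BoosterConfig(),
    plan: FoldPlan | None = None,
    n_folds: int = 5,
    seed: int = 0,
) -> dict:
    """Stratified k-fold CV of featurizer + boosted classifier.

    For each fold the featurizer is fit on the training split only (a
    GNN encoder never sees held-out molecules; the checksum of each
    fold's training SMILES is recorded so leakage is auditable), then
    the booster is trained on the training embeddings and all metrics
    are evaluated on the held-out fold.

    Returns {"folds": DataFrame, "mean": Series, "sd": Series,
    "train_checksums": [...]}.
    """
    labels = np.asarray(labels).astype(int)
    if plan is None:
        plan = make_fold_plan(labels, n_folds, seed)
    rows, checksums = [], []
    for f, (train, test) in enumerate(plan.folds()):
        tr_labels, te_labels = labels[train], labels[test]
        if len(np.unique(tr_labels)) < 2 or len(np.unique(te_labels)) < 2:
            raise EvaluationError(
                f"fold {f} lost a class; use stratified folds or more data"
            )
        tr_smiles = [smiles[i] for i in train]
        te_smiles = [smiles[i] for i in test]
        checksums.append(
            hashlib.sha256("\n".join(tr_smiles).encode()).hexdigest()
        )
        transform = _featurize_factory(featurizer, seed=plan.seed * 1000 + f)(
            tr_smiles, tr_labels
        )
        clf = train_booster(transform(tr_smiles), tr_labels, booster_cfg)
        proba, calls = clf.predict(transform(te_smiles))
        counts = ConfusionCounts.from_predictions(te_labels, calls)
        row = {"fold": f, **all_metrics(counts),
               "auc": roc_auc(proba, te_labels)}
        rows.append(row)
    folds = pd.DataFrame(rows).set_index("fold")
    return {
        "folds": folds,
        "mean": folds.mean(),
        "sd": folds.std(ddof=1),
        "train_checksums": checksums,
    }


# ----------------------------------------------------------------------
# Multi-target validation (known-label pairs only)
# ----------------------------------------------------------------------

def multitarget_validation(model, records: list[MoleculeRecord],
                           min_known_active: int = 2) -> dict:
    """Pooled TPR / NPV / FDR over known (compound, target) pairs.

    Only compounds with ≥ ``min_known_active`` known-active targets are
    eligible; pairs with unknown labels are excluded from the counts.
    """
    from .multitarget import predict_multitarget  # local import, avoids cycle

    eligible = [
        r for r in records
        if sum(1 for v in r.labels.values() if v == ACTIVE) >= min_known_active
    ]
    if not eligible:
        raise EvaluationError(
            f"no compound has ≥ {min_known_active} known-active targets"
        )
    smiles = [r.smiles for r in eligible]
    _, calls, failed = predict_multitarget(model, smiles)
    tp = tn = fp = fn = 0
    for i, r in enumerate(eligible):
        if i in failed:
            continue
        for t in model.registry.targets:
            lab = r.labels.get(t)
            if lab == ACTIVE:
                if calls.iloc[i][t]:
                    tp += 1
                else:
                    fn += 1
            elif lab == INACTIVE:
                if calls.iloc[i][t]:
                    fp += 1
                else:
                    tn += 1
            # unknown labels are never counted
    c = ConfusionCounts(tp, tn, fp, fn)
    return {
        "n_eligible_compounds": len(eligible),
        "n_known_pairs": tp + tn + fp + fn,
        "counts": c,
        "tpr": tpr(c),
        "npv": npv(c),
        "fdr": fdr(c),
    }
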