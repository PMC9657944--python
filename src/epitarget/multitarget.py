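"""Multi-target assembly and the polypharmacology significance test.

The multi-target predictor is the ordered collection of per-target
(featurizer, boosted classifier) pairs; its prediction matrix column j
is *exactly* the j-th single-target classifier applied to each molecule
— assembly introduces no coupling.

For a compound called active on n of the N registered targets, of which
k fall inside an object group of size K (HDAC, HMT, HDM, HAT, DNMT),
polypharmacology enrichment is the upper-tail hypergeometric probability

    P(X ≥ k) = Σ_{j=k}^{min(n,K)} C(K,j) C(N−K, n−j) / C(N, n),

flagged significant when p < alpha (default 0.05). A compound with no
predicted-active target reports p = 1 for every group.
"""

from __future__ import annotations

import json
import zipfile
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .chem_io import TargetRegistry, smiles_to_graph, DEFAULT_SCHEME, SmilesParseError
from .encoders import EncoderModel
from .baseline_fingerprints import FingerprintConfig, morgan_matrix
from .boosted_classifier import TargetClassifier


class MultiTargetError(ValueError):
    pass


# ----------------------------------------------------------------------
# Featurizers: one interface for GNN embeddings and Morgan bits
# ----------------------------------------------------------------------

class GNNFeaturizer:
    kind = "gnn"

    def __init__(self, encoder: EncoderModel):
        self.encoder = encoder

    def transform(self, smiles_list: list[str]) -> np.ndarray:
        return self.encoder.embed([smiles_to_graph(s) for s in smiles_list])


class MorganFeaturizer:
    kind = "morgan"

    def __init__(self, config: FingerprintConfig = FingerprintConfig()):
        self.config = config

    def transform(self, smiles_list: list[str]) -> np.ndarray:
        return morgan_matrix(smiles_list, self.config)


@dataclass
class MultiTargetModel:
    """Ordered per-target classifiers sharing one target registry."""

    registry: TargetRegistry
    members: dict[str, tuple[object, TargetClassifier]]  # target_id → (featurizer, clf)
    version: dict = field(default_factory=dict)

    def __post_init__(self):
        if set(self.members) != set(self.registry.targets):
            raise MultiTargetError(
                "classifier set does not match registry: "
                f"{sorted(self.members)} vs {self.registry.targets}"
            )


def predict_multitarget(
    model: MultiTargetModel, smiles_list: list[str]
) -> tuple[pd.DataFrame, pd.DataFrame, list[int]]:
    """Per-target probabilities and binary calls for each molecule.

    Returns (probability frame, call frame, failed row indices); rows of
    unparseable SMILES are reported and filled with NaN / 0, the rest
    are still computed.
    """
    failed = []
    ok_idx, ok_smiles = [], []
    for i, s in enumerate(smiles_list):
        try:
            smiles_to_graph(s)
            ok_idx.append(i)
            ok_smiles.append(s)
        except SmilesParseError:
            failed.append(i)
    n, targets = len(smiles_list), model.registry.targets
    proba = np.full((n, len(targets)), np.nan)
    calls = np.zeros((n, len(targets)), dtype=np.int64)
    for j, t in enumerate(targets):
        featurizer, clf = model.members[t]
        if ok_smiles:
            feats = featurizer.transform(ok_smiles)
            p, c = clf.predict(feats)
            proba[ok_idx, j] = p
            calls[ok_idx, j] = c
    proba_df = pd.DataFrame(proba, columns=targets)
    call_df = pd.DataFrame(calls, columns=targets)
    return proba_df, call_df, failed


# ----------------------------------------------------------------------
# Hypergeometric enrichment
# ----------------------------------------------------------------------

def hypergeom_pvalue(N: int, K: int, n: int, k: int) -> float:
    """Upper-tail P(X ≥ k) for k group hits among n draws from N targets."""
    if not (0 <= K <= N and 0 <= n <= N):
        raise MultiTargetError(f"inconsistent counts N={N}, K={K}, n={n}")
    if not (max(0, n + K - N) <= k <= min(n, K)):
        raise MultiTargetError(
            f"k={k} outside support [{max(0, n + K - N)}, {min(n, K)}] "
            f"for N={N}, K={K}, n={n}"
        )
    # survival function is P(X > k-1) = P(X ≥ k)
    return float(hypergeom.sf(k - 1, N, K, n))


@dataclass
class PolypharmResult:
    compound_id: str
    smiles: str
    calls: dict[str, int]                 # target → 0/1
    n_active: int                         # predicted-active targets (n)
    groups: dict[str, dict]               # group → {K, k, p_value, significant}


def polypharmacology_report(
    model: MultiTargetModel,
    smiles_list: list[str],
    compound_ids: list[str] | None = None,
    alpha: float = 0.05,
    bonferroni: bool = False,
) -> list[PolypharmResult]:
    """Per-compound per-group hypergeometric enrichment of predicted calls."""
    groups = model.registry.groups()
    if len(groups) < 2:
        raise MultiTargetError("polypharmacology report needs ≥ 2 object groups")
    if compound_ids is None:
        compound_ids = [f"cmpd{i}" for i in range(len(smiles_list))]
    _, call_df, failed = predict_multitarget(model, smiles_list)
    N = len(model.registry.targets)
    thresh = alpha / len(groups) if bonferroni else alpha
    results = []
    for i, (cid, smi) in enumerate(zip(compound_ids, smiles_list)):
        if i in failed:
            continue
        row = call_df.iloc[i]
        n = int(row.sum())
        per_group = {}
        for gname, gtargets in groups.items():
            K = len(gtargets)
            k = int(row[gtargets].sum())
            p = 1.0 if n == 0 else hypergeom_pvalue(N, K, n, k)
            per_group[gname] = {
                "K": K, "k": k, "n": n, "N": N,
                "p_value": p, "significant": bool(p < thresh),
            }
        results.append(
            PolypharmResult(cid, smi, row.to_dict(), n, per_group)
        )
    return results


def polypharm_frame(results: list[PolypharmResult]) -> pd.DataFrame:
    """Long-format report: one row per compound × object group."""
    rows = []
    for r in results:
        for g, d in r.groups.items():
            rows.append({"compound_id": r.compound_id, "group": g, **d})
    return pd.DataFrame(rows)


# ----------------------------------------------------------------------
# Training the full assembly
# ----------------------------------------------------------------------

def train_multitarget(
    records,
    registry: TargetRegistry,
    featurizer_cfg,
    booster_cfg=None,
    seed: int = 0,
) -> MultiTargetModel:
    """Train one per-target (featurizer, booster) pair per registry target.

    ``featurizer_cfg`` is an :class:`~epitarget.encoders.EncoderConfig`
    (a fresh encoder is trained per target on that target's labeled
    molecules) or a :class:`FingerprintConfig` (shared stateless Morgan
    bits). Records with unknown label for a target are excluded from
    that target's training set.
    """
    from .chem_io import ACTIVE, INACTIVE
    from .encoders import EncoderConfig, train_encoder
    from .boosted_classifier import BoosterConfig, train_booster

    if booster_cfg is None:
        booster_cfg = BoosterConfig(seed=seed)
    members = {}
    for j, t in enumerate(registry.targets):
        labeled = [r for r in records if r.labels.get(t) in (ACTIVE, INACTIVE)]
        smiles = [r.smiles for r in labeled]
        y = np.array([1 if r.labels[t] == ACTIVE else 0 for r in labeled])
        if isinstance(featurizer_cfg, FingerprintConfig):
            feat = MorganFeaturizer(featurizer_cfg)
        elif isinstance(featurizer_cfg, EncoderConfig):
            cfg = EncoderConfig(**{**featurizer_cfg.__dict__, "seed": seed + j})
            graphs = [smiles_to_graph(s) for s in smiles]
            feat = GNNFeaturizer(train_encoder(graphs, y, cfg))
        else:
            raise MultiTargetError(f"unknown featurizer config {featurizer_cfg!r}")
        clf = train_booster(feat.transform(smiles), y, booster_cfg, target_id=t)
        members[t] = (feat, clf)
    return MultiTargetModel(registry, members, {"seed": seed})


# ----------------------------------------------------------------------
# Archive (zip with manifest + per-target model files)
# ----------------------------------------------------------------------

def save_model(model: MultiTargetModel, path) -> None:
    path = Path(path)
    import tempfile

    manifest = {
        "targets": model.registry.targets,
        "object_group": model.registry.object_group,
        "scheme": DEFAULT_SCHEME.fingerprint(),
        "version": model.version,
        "members": {},
    }
    with zipfile.ZipFile(path, "w") as zf, tempfile.TemporaryDirectory() as td:
        td = Path(td)
        for t in model.registry.targets:
            feat, clf = model.members[t]
            entry = {"featurizer": feat.kind,
                     "decision_threshold": clf.decision_threshold}
            clf_file = td / f"{t}.booster.json"
            clf.save(clf_file)
            zf.write(clf_file, f"{t}.booster.json")
            if feat.kind == "gnn":
                enc_file = td / f"{t}.encoder.npz"
                feat.encoder.save(enc_file)
                zf.write(enc_file, f"{t}.encoder.npz")
            else:
                entry["fingerprint"] = {"radius": feat.config.radius,
                                        "n_bits": feat.config.n_bits}
            manifest["members"][t] = entry
        zf.writestr("manifest.json", json.dumps(manifest, indent=2))


def load_model(path) -> MultiTargetModel:
    path = Path(path)
    import tempfile

    with zipfile.ZipFile(path) as zf:
        names = set(zf.namelist())
        if "manifest.json" not in names:
            raise MultiTargetError(f"archive {path} has no manifest.json")
        manifest = json.loads(zf.read("manifest.json"))
        if manifest.get("scheme") != DEFAULT_SCHEME.fingerprint():
            raise MultiTargetError(
                "archive feature scheme does not match this installation"
            )
        registry = TargetRegistry(manifest["targets"], manifest["object_group"])
        members = {}
        with tempfile.TemporaryDirectory() as td:
            td = Path(td)
            for t in registry.targets:
                entry = manifest["members"].get(t)
                if entry is None or f"{t}.booster.json" not in names:
                    raise MultiTargetError(f"archive missing files for target {t}")
                zf.extract(f"{t}.booster.json", td)
                clf = TargetClassifier.load(
                    td / f"{t}.booster.json", t, entry["decision_threshold"]
                )
                if entry["featurizer"] == "gnn":
                    zf.extract(f"{t}.encoder.npz", td)
                    feat = GNNFeaturizer(EncoderModel.load(td / f"{t}.encoder.npz"))
                else:
                    fc = entry.get("fingerprint", {})
                    feat = MorganFeaturizer(FingerprintConfig(**fc))
                members[t] = (feat, clf)
    return MultiTargetModel(registry, members, manifest.get("version", {}))
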