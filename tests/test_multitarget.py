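"""Multi-target assembly and hypergeometric enrichment."""

import itertools
from math import comb

import numpy as np
import pytest

from epitarget import (
    BoosterConfig, FingerprintConfig, TargetRegistry,
    hypergeom_pvalue, polypharmacology_report, polypharm_frame,
    predict_multitarget, train_multitarget, save_model, load_model,
)
from epitarget.multitarget import MultiTargetModel, MultiTargetError


def brute_force_tail(N, K, n, k):
    """P(X ≥ k) by enumeration over all C(N,n) draws."""
    hits = total = 0
    group = set(range(K))
    for draw in itertools.combinations(range(N), n):
        total += 1
        if len(group.intersection(draw)) >= k:
            hits += 1
    return hits / total


class TestHypergeom:
    @pytest.mark.parametrize("N,K,n,k,expected", [
        (24, 10, 5, 0, 1.0),
        (24, 10, 5, 5, comb(10, 5) / comb(24, 5)),
        (24, 24, 3, 3, 1.0),
        (24, 10, 10, 10, comb(10, 10) / comb(24, 10)),
        (24, 1, 1, 1, 1 / 24),
    ])
    def test_known_values(self, N, K, n, k, expected):
        assert hypergeom_pvalue(N, K, n, k) == pytest.approx(expected, rel=1e-12)

    def test_matches_enumeration_small_populations(self):
        for N in range(1, 9):
            for K in range(N + 1):
                for n in range(N + 1):
                    for k in range(max(0, n + K - N), min(n, K) + 1):
                        assert hypergeom_pvalue(N, K, n, k) == pytest.approx(
                            brute_force_tail(N, K, n, k), abs=1e-12), (N, K, n, k)

    def test_tail_from_minimum_is_one(self):
        for N in range(1, 20):
            for K in range(N + 1):
                for n in range(N + 1):
                    k0 = max(0, n + K - N)
                    assert hypergeom_pvalue(N, K, n, k0) == pytest.approx(1.0, abs=1e-12)

    def test_monotone_nonincreasing_in_k(self):
        for N, K, n in [(24, 10, 5), (24, 6, 12), (30, 15, 10)]:
            ks = range(max(0, n + K - N), min(n, K) + 1)
            ps = [hypergeom_pvalue(N, K, n, k) for k in ks]
            assert all(b <= a + 1e-15 for a, b in zip(ps, ps[1:]))

    def test_invalid_counts_rejected(self):
        with pytest.raises(MultiTargetError):
            hypergeom_pvalue(10, 12, 3, 1)
        with pytest.raises(MultiTargetError):
            hypergeom_pvalue(10, 5, 3, 4)   # k > min(n, K)
        with pytest.raises(MultiTargetError):
            hypergeom_pvalue(10, 9, 9, 7)   # k < n + K − N


# ----------------------------------------------------------------------
# Stub model: fixed per-(compound, target) calls, real registry math
# ----------------------------------------------------------------------

def paper_like_registry():
    """24 targets: 10 HDAC, 6 HDM, 5 HMT, 2 HAT, 1 DNMT."""
    spec = [("HDAC", 10), ("HDM", 6), ("HMT", 5), ("HAT", 2), ("DNMT", 1)]
    targets, groups = [], {}
    for g, n in spec:
        for i in range(n):
            t = f"{g}{i+1}"
            targets.append(t)
            groups[t] = g
    return TargetRegistry(targets, groups)


class StubFeaturizer:
    kind = "stub"

    def transform(self, smiles_list):
        return np.arange(len(smiles_list), dtype=float).reshape(-1, 1)


class StubClassifier:
    decision_threshold = 0.5

    def __init__(self, target_id, call_by_row):
        self.target_id = target_id
        self.call_by_row = call_by_row

    def predict(self, features):
        rows = features[:, 0].astype(int)
        calls = np.array([self.call_by_row.get(r, 0) for r in rows])
        return calls.astype(float), calls


def stub_model(registry, active_map):
    """active_map: {row index → set of active targets}."""
    members = {}
    for t in registry.targets:
        calls = {r: int(t in acts) for r, acts in active_map.items()}
        members[t] = (StubFeaturizer(), StubClassifier(t, calls))
    return MultiTargetModel(registry, members)


class TestPolypharm:
    def test_all_hdac_active_is_significant(self):
        reg = paper_like_registry()
        hdac = [t for t in reg.targets if reg.object_group[t] == "HDAC"]
        model = stub_model(reg, {0: set(hdac)})
        res = polypharmacology_report(model, ["CCO"], ["drug0"])
        hd = res[0].groups["HDAC"]
        assert hd["k"] == 10 and hd["n"] == 10
        assert hd["p_value"] == pytest.approx(1 / comb(24, 10), rel=1e-9)
        assert hd["significant"]

    def test_no_active_targets_all_pvalues_one(self):
        reg = paper_like_registry()
        model = stub_model(reg, {0: set()})
        res = polypharmacology_report(model, ["CCO"])
        assert all(d["p_value"] == 1.0 and not d["significant"]
                   for d in res[0].groups.values())

    def test_singleton_group_single_hit(self):
        reg = paper_like_registry()
        model = stub_model(reg, {0: {"DNMT1"}})
        res = polypharmacology_report(model, ["CCO"])
        d = res[0].groups["DNMT"]
        assert d["p_value"] == pytest.approx(1 / 24, rel=1e-12)
        assert d["significant"]  # 0.0417 < 0.05

    def test_frame_layout(self):
        reg = paper_like_registry()
        model = stub_model(reg, {0: {"DNMT1"}, 1: set()})
        df = polypharm_frame(polypharmacology_report(model, ["CCO", "CCN"]))
        assert len(df) == 2 * 5  # compounds × groups
        assert {"compound_id", "group", "K", "k", "n", "N",
                "p_value", "significant"} <= set(df.columns)

    def test_bonferroni_tightens_alpha(self):
        reg = paper_like_registry()
        model = stub_model(reg, {0: {"DNMT1"}})
        res = polypharmacology_report(model, ["CCO"], bonferroni=True)
        assert not res[0].groups["DNMT"]["significant"]  # 1/24 > 0.05/5


# ----------------------------------------------------------------------
# Real assembly on a small trained model
# ----------------------------------------------------------------------

@pytest.fixture(scope="module")
def trained_model(small_dataset_module):
    records, registry = small_dataset_module
    reg3 = registry.subset(["T1", "T2", "T3"])
    model = train_multitarget(records, reg3, FingerprintConfig(),
                              BoosterConfig(n_trees=25, seed=0), seed=0)
    return records, model


@pytest.fixture(scope="module")
def small_dataset_module():
    from epitarget import SynthSpec, generate_dataset
    return generate_dataset(SynthSpec(n_molecules=120, label_noise=0.0, seed=3))


class TestAssembly:
    def test_matrix_equals_independent_single_target_runs(self, trained_model):
        records, model = trained_model
        smiles = [r.smiles for r in records[:40]]
        proba, calls, failed = predict_multitarget(model, smiles)
        assert failed == []
        for t in model.registry.targets:
            feat, clf = model.members[t]
            p, c = clf.predict(feat.transform(smiles))
            assert np.array_equal(proba[t].to_numpy(), p)
            assert np.array_equal(calls[t].to_numpy(), c)

    def test_single_target_model_degenerates(self, trained_model):
        records, model = trained_model
        reg1 = model.registry.subset(["T1"])
        m1 = MultiTargetModel(reg1, {"T1": model.members["T1"]})
        smiles = [r.smiles for r in records[:10]]
        proba, _, _ = predict_multitarget(m1, smiles)
        feat, clf = model.members["T1"]
        assert np.array_equal(proba["T1"].to_numpy(),
                              clf.predict(feat.transform(smiles))[0])

    def test_registry_permutation_permutes_columns(self, trained_model):
        records, model = trained_model
        perm_targets = ["T3", "T1", "T2"]
        reg_perm = TargetRegistry(
            perm_targets, {t: model.registry.object_group[t] for t in perm_targets})
        m_perm = MultiTargetModel(reg_perm, model.members)
        smiles = [r.smiles for r in records[:10]]
        p1, _, _ = predict_multitarget(model, smiles)
        p2, _, _ = predict_multitarget(m_perm, smiles)
        assert list(p2.columns) == perm_targets
        for t in perm_targets:
            assert np.array_equal(p1[t].to_numpy(), p2[t].to_numpy())

    def test_parse_failures_reported_rows_still_computed(self, trained_model):
        records, model = trained_model
        smiles = [records[0].smiles, "((bad", records[1].smiles]
        proba, calls, failed = predict_multitarget(model, smiles)
        assert failed == [1]
        assert np.isnan(proba.iloc[1]).all()
        assert not np.isnan(proba.iloc[0]).any()

    def test_archive_roundtrip(self, trained_model, tmp_path):
        records, model = trained_model
        path = tmp_path / "model.zip"
        save_model(model, path)
        loaded = load_model(path)
        smiles = [r.smiles for r in records[:15]]
        p1, c1, _ = predict_multitarget(model, smiles)
        p2, c2, _ = predict_multitarget(loaded, smiles)
        assert np.allclose(p1.to_numpy(), p2.to_numpy())
        assert np.array_equal(c1.to_numpy(), c2.to_numpy())

    def test_corrupt_archive_rejected(self, tmp_path):
        bad = tmp_path / "bad.zip"
        import zipfile
        with zipfile.ZipFile(bad, "w") as zf:
            zf.writestr("nothing.txt", "x")
        with pytest.raises(MultiTargetError, match="manifest"):
            load_model(bad)

    def test_member_registry_mismatch_rejected(self, trained_model):
        records, model = trained_model
        reg2 = model.registry.subset(["T1", "T2"])
        with pytest.raises(MultiTargetError):
            MultiTargetModel(reg2, model.members)
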