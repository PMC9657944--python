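"""Compound–activity tables and quantized molecular graphs.

This module owns the data layer of the pipeline: reading long-format
compound–activity CSV files, binarizing potency values at the 10 µM
cutoff, filtering targets that lack enough examples of either class,
and converting SMILES strings into the directed molecular graphs the
message-passing encoders consume.

Conventions
-----------
* Activity values are concentrations in µM (IC50/EC50/Ki/Kd); a value
  ≤ 10 µM is "active", > 10 µM is "inactive".
* Hydrogens are implicit: heavy atoms only are materialized as graph
  nodes, with the implicit-H count carried as an atom feature.
* Every chemical bond contributes two directed edges (u→v and v→u);
  ``reverse_index`` maps each directed edge to its mate.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit import RDLogger

RDLogger.DisableLog("rdApp.*")

ACTIVE = "active"
INACTIVE = "inactive"
UNKNOWN = "unknown"

ACTIVITY_THRESHOLD_UM = 10.0

#: Object groups of the epigenetic target families.
KNOWN_GROUPS = ("HDAC", "HMT", "HDM", "HAT", "DNMT")


class ValidationError(ValueError):
    """A record or table violated a data-layer contract."""


class SmilesParseError(ValueError):
    """A SMILES string could not be parsed into a molecule."""

    def __init__(self, smiles: str, reason: str = "unparseable"):
        self.smiles = smiles
        super().__init__(f"cannot parse SMILES {smiles!r}: {reason}")


@dataclass
class MoleculeRecord:
    """One compound with per-target activity labels.

    ``labels`` maps target_id to one of {"active", "inactive", "unknown"};
    ``activity_values`` optionally carries the underlying µM potencies.
    """

    compound_id: str
    smiles: str
    labels: dict[str, str] = field(default_factory=dict)
    activity_values: dict[str, float] = field(default_factory=dict)

    def validate(self) -> None:
        for t, lab in self.labels.items():
            if lab not in (ACTIVE, INACTIVE, UNKNOWN):
                raise ValidationError(
                    f"record {self.compound_id}: bad label {lab!r} for target {t}"
                )
            v = self.activity_values.get(t)
            if v is not None and lab != UNKNOWN:
                expected = binarize_activity(v, record_id=self.compound_id)
                if expected != lab:
                    raise ValidationError(
                        f"record {self.compound_id}, target {t}: label {lab!r} "
                        f"contradicts activity {v} µM (10 µM rule says {expected!r})"
                    )


@dataclass
class TargetRegistry:
    """Ordered target list plus the target → object-group mapping."""

    targets: list[str]
    object_group: dict[str, str]

    def __post_init__(self):
        for t in self.targets:
            if t not in self.object_group:
                raise ValidationError(f"target {t} has no object group")
        groups = set(self.object_group.values())
        unknown = groups - set(KNOWN_GROUPS)
        if unknown:
            # extensible: extra group names are allowed but must be declared
            # consistently; we only warn via the registry report.
            pass

    def groups(self) -> dict[str, list[str]]:
        """Targets per object group, preserving registry order."""
        out: dict[str, list[str]] = {}
        for t in self.targets:
            out.setdefault(self.object_group[t], []).append(t)
        return out

    def subset(self, targets: list[str]) -> "TargetRegistry":
        keep = [t for t in self.targets if t in set(targets)]
        return TargetRegistry(keep, {t: self.object_group[t] for t in keep})


@dataclass
class MolGraph:
    """Quantized molecular graph.

    Atom/bond feature rows follow the scheme in :class:`FeatureScheme`.
    ``directed_edges[e] = (u, v)`` means edge e points u→v; the two
    directions of one chemical bond are adjacent-by-pairing through
    ``reverse_index`` (an involution without fixed points).
    """

    n_atoms: int
    atom_features: np.ndarray  # (n_atoms, d_a)
    n_bonds: int
    bond_features: np.ndarray  # (n_bonds, d_b)
    directed_edges: list[tuple[int, int]]
    reverse_index: np.ndarray  # (2*n_bonds,)
    atom_incoming: list[list[int]]  # per atom: directed edges pointing to it

    def check_invariants(self) -> None:
        assert len(self.directed_edges) == 2 * self.n_bonds
        rev = self.reverse_index
        for e in range(len(self.directed_edges)):
            assert rev[rev[e]] == e and rev[e] != e
            u, v = self.directed_edges[e]
            ru, rv = self.directed_edges[rev[e]]
            assert (ru, rv) == (v, u)
        seen = sorted(e for lst in self.atom_incoming for e in lst)
        assert seen == list(range(2 * self.n_bonds))
        for v, lst in enumerate(self.atom_incoming):
            for e in lst:
                assert self.directed_edges[e][1] == v


# ----------------------------------------------------------------------
# Feature scheme
# ----------------------------------------------------------------------

_ELEMENTS = ["C", "N", "O", "S", "F", "Cl", "Br", "I", "P", "B", "Si"]
_HYBRID = [
    Chem.HybridizationType.SP,
    Chem.HybridizationType.SP2,
    Chem.HybridizationType.SP3,
]
_BOND_ORDERS = [
    Chem.BondType.SINGLE,
    Chem.BondType.DOUBLE,
    Chem.BondType.TRIPLE,
    Chem.BondType.AROMATIC,
]


@dataclass(frozen=True)
class FeatureScheme:
    """Atom/bond featurization specification.

    Atom vector: element one-hot (len(elements)+1 with "other" slot),
    degree (scalar), formal charge, implicit H count, aromaticity flag,
    hybridization one-hot (+other), ring-membership flag.
    Bond vector: bond-order one-hot {single,double,triple,aromatic},
    conjugation flag, ring flag.
    """

    elements: tuple[str, ...] = tuple(_ELEMENTS)

    @property
    def atom_dim(self) -> int:
        return len(self.elements) + 1 + 1 + 1 + 1 + 1 + len(_HYBRID) + 1 + 1

    @property
    def bond_dim(self) -> int:
        return len(_BOND_ORDERS) + 2

    def fingerprint(self) -> str:
        """Stable identifier used to refuse mixing incompatible models."""
        return f"v1:{','.join(self.elements)}:{self.atom_dim}:{self.bond_dim}"

    def atom_vector(self, atom: Chem.Atom) -> np.ndarray:
        v = np.zeros(self.atom_dim)
        sym = atom.GetSymbol()
        idx = self.elements.index(sym) if sym in self.elements else len(self.elements)
        v[idx] = 1.0
        o = len(self.elements) + 1
        v[o] = atom.GetDegree()
        v[o + 1] = atom.GetFormalCharge()
        v[o + 2] = atom.GetTotalNumHs()
        v[o + 3] = 1.0 if atom.GetIsAromatic() else 0.0
        hyb = atom.GetHybridization()
        hidx = _HYBRID.index(hyb) if hyb in _HYBRID else len(_HYBRID)
        v[o + 4 + hidx] = 1.0
        v[o + 4 + len(_HYBRID) + 1] = 1.0 if atom.IsInRing() else 0.0
        return v

    def bond_vector(self, bond: Chem.Bond) -> np.ndarray:
        v = np.zeros(self.bond_dim)
        bt = bond.GetBondType()
        if bt in _BOND_ORDERS:
            v[_BOND_ORDERS.index(bt)] = 1.0
        v[len(_BOND_ORDERS)] = 1.0 if bond.GetIsConjugated() else 0.0
        v[len(_BOND_ORDERS) + 1] = 1.0 if bond.IsInRing() else 0.0
        return v


DEFAULT_SCHEME = FeatureScheme()


# ----------------------------------------------------------------------
# Operations
# ----------------------------------------------------------------------

def binarize_activity(value: float, record_id: str | None = None) -> str:
    """Binarize a µM potency at the 10 µM rule: ≤ 10 active, > 10 inactive."""
    who = f" (record {record_id})" if record_id else ""
    if not (isinstance(value, (int, float)) and math.isfinite(value)):
        raise ValidationError(f"activity value {value!r} is not finite{who}")
    if value <= 0:
        raise ValidationError(f"activity value {value!r} is not positive{who}")
    return ACTIVE if value <= ACTIVITY_THRESHOLD_UM else INACTIVE


def label_counts(records: list[MoleculeRecord], registry: TargetRegistry) -> pd.DataFrame:
    """Per-target counts of active / inactive / unknown labels."""
    rows = []
    for t in registry.targets:
        c = {ACTIVE: 0, INACTIVE: 0, UNKNOWN: 0}
        for r in records:
            lab = r.labels.get(t)
            if lab is not None:
                c[lab] += 1
        rows.append({"target_id": t, "active": c[ACTIVE],
                     "inactive": c[INACTIVE], "unknown": c[UNKNOWN]})
    return pd.DataFrame(rows)


def filter_targets(
    records: list[MoleculeRecord],
    registry: TargetRegistry,
    min_per_class: int = 30,
) -> tuple[TargetRegistry, pd.DataFrame]:
    """Keep targets with ≥ ``min_per_class`` actives AND inactives.

    Returns the filtered registry and a per-target count report that
    includes the dropped targets.
    """
    if not records:
        raise ValidationError("cannot filter targets on an empty record list")
    counts = label_counts(records, registry)
    counts["retained"] = (counts["active"] >= min_per_class) & (
        counts["inactive"] >= min_per_class
    )
    keep = counts.loc[counts["retained"], "target_id"].tolist()
    if not keep:
        raise ValidationError(
            "no target survives the per-class filter; counts:\n"
            + counts.to_string(index=False)
        )
    return registry.subset(keep), counts


def smiles_to_graph(smiles: str, scheme: FeatureScheme = DEFAULT_SCHEME) -> MolGraph:
    """Convert a SMILES string to a :class:`MolGraph`.

    Multi-fragment inputs (salts) keep the largest fragment. Explicit
    hydrogens are folded into the implicit-H atom feature.
    """
    if not smiles:
        raise SmilesParseError(smiles, "empty string")
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise SmilesParseError(smiles)
    frags = Chem.GetMolFrags(mol, asMols=True)
    if len(frags) > 1:
        mol = max(frags, key=lambda m: m.GetNumAtoms())
    n_atoms = mol.GetNumAtoms()
    if n_atoms == 0:
        raise SmilesParseError(smiles, "no heavy atoms")
    atom_features = np.stack([scheme.atom_vector(a) for a in mol.GetAtoms()])
    n_bonds = mol.GetNumBonds()
    bond_features = (
        np.stack([scheme.bond_vector(b) for b in mol.GetBonds()])
        if n_bonds
        else np.zeros((0, scheme.bond_dim))
    )
    directed_edges: list[tuple[int, int]] = []
    reverse_index = np.zeros(2 * n_bonds, dtype=np.int64)
    for b in mol.GetBonds():
        u, v = b.GetBeginAtomIdx(), b.GetEndAtomIdx()
        e = len(directed_edges)
        directed_edges.append((u, v))
        directed_edges.append((v, u))
        reverse_index[e] = e + 1
        reverse_index[e + 1] = e
    atom_incoming: list[list[int]] = [[] for _ in range(n_atoms)]
    for e, (_, v) in enumerate(directed_edges):
        atom_incoming[v].append(e)
    return MolGraph(
        n_atoms=n_atoms,
        atom_features=atom_features,
        n_bonds=n_bonds,
        bond_features=bond_features,
        directed_edges=directed_edges,
        reverse_index=reverse_index,
        atom_incoming=atom_incoming,
    )


def canonical_smiles(smiles: str) -> str:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise SmilesParseError(smiles)
    return Chem.MolToSmiles(mol)


# ----------------------------------------------------------------------
# Dataset I/O (long CSV)
# ----------------------------------------------------------------------

LONG_COLUMNS = ["compound_id", "smiles", "target_id"]


def read_target_map(path) -> TargetRegistry:
    df = pd.read_csv(path, dtype=str)
    missing = {"target_id", "object_group"} - set(df.columns)
    if missing:
        raise ValidationError(f"target map missing columns {sorted(missing)}")
    return TargetRegistry(
        df["target_id"].tolist(),
        dict(zip(df["target_id"], df["object_group"])),
    )


def read_dataset(
    path,
    registry: TargetRegistry | None = None,
) -> tuple[list[MoleculeRecord], TargetRegistry, dict]:
    """Read a long-format compound–activity CSV.

    Columns: compound_id, smiles, target_id, and at least one of
    activity_um / label. Unknown labels are preserved, never imputed.
    Returns (records, registry, load_report).
    """
    df = pd.read_csv(path, dtype={"compound_id": str, "smiles": str, "target_id": str})
    missing = set(LONG_COLUMNS) - set(df.columns)
    if missing:
        raise ValidationError(f"dataset missing required columns {sorted(missing)}")
    has_value = "activity_um" in df.columns
    has_label = "label" in df.columns
    if not has_value and not has_label:
        raise ValidationError("dataset needs an 'activity_um' or 'label' column")

    records: dict[str, MoleculeRecord] = {}
    failed: list[str] = []
    conflicts: list[str] = []
    n_parsed = 0
    for row in df.itertuples(index=False):
        cid, smi, tgt = row.compound_id, row.smiles, row.target_id
        lab = None
        val = None
        if has_value and not pd.isna(getattr(row, "activity_um", np.nan)):
            val = float(row.activity_um)
            lab = binarize_activity(val, record_id=cid)
        if has_label and isinstance(getattr(row, "label", None), str):
            explicit = row.label.strip().lower()
            if explicit not in (ACTIVE, INACTIVE, UNKNOWN):
                raise ValidationError(
                    f"record {cid}: bad label {row.label!r} for target {tgt}"
                )
            if lab is not None and explicit != UNKNOWN and explicit != lab:
                raise ValidationError(
                    f"record {cid}, target {tgt}: explicit label {explicit!r} "
                    f"contradicts activity {val} µM"
                )
            lab = lab or explicit
        if lab is None:
            lab = UNKNOWN
        rec = records.get(cid)
        if rec is None:
            if Chem.MolFromSmiles(smi) is None:
                failed.append(cid)
                continue
            rec = MoleculeRecord(cid, smi)
            records[cid] = rec
            n_parsed += 1
        prev = rec.labels.get(tgt)
        if prev is not None and prev != lab:
            conflicts.append(f"{cid}/{tgt}: {prev} vs {lab}")
            continue
        rec.labels[tgt] = lab
        if val is not None:
            rec.activity_values[tgt] = val
    if conflicts:
        raise ValidationError(
            "conflicting duplicate (compound, target) labels: " + "; ".join(conflicts)
        )
    seen_targets = sorted({t for r in records.values() for t in r.labels})
    if registry is None:
        # no target map supplied: register targets with a placeholder group
        registry = TargetRegistry(seen_targets, dict.fromkeys(seen_targets, "UNASSIGNED"))
    else:
        stray = set(seen_targets) - set(registry.targets)
        if stray:
            raise ValidationError(f"targets {sorted(stray)} absent from registry")
    out = list(records.values())
    for r in out:
        r.validate()
    report = {
        "n_rows": int(len(df)),
        "n_compounds": len(out),
        "n_parse_failures": len(failed),
        "parse_failures": failed,
        "per_target": label_counts(out, registry).to_dict(orient="records"),
    }
    return out, registry, report


def write_dataset(records: list[MoleculeRecord], registry: TargetRegistry, path) -> None:
    """Write records in the long CSV schema (round-trips with read_dataset)."""
    rows = []
    for r in records:
        for t in registry.targets:
            if t in r.labels:
                rows.append(
                    {
                        "compound_id": r.compound_id,
                        "smiles": r.smiles,
                        "target_id": t,
                        "activity_um": r.activity_values.get(t, ""),
                        "label": r.labels[t],
                    }
                )
    pd.DataFrame(rows, columns=LONG_COLUMNS + ["activity_um", "label"]).to_csv(
        path, index=False
    )


def write_target_map(registry: TargetRegistry, path) -> None:
    pd.DataFrame(
        {"target_id": registry.targets,
         "object_group": [registry.object_group[t] for t in registry.targets]}
    ).to_csv(path, index=False)


def write_load_report(report: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2)
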