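"""Synthetic compound–activity datasets with planted structure–activity rules.

Molecules are assembled valence-safely from drug-like fragments: an
alkyl backbone decorated with ring/chain/ether fragments plus, for each
target the molecule should hit, a carrier fragment containing that
target's pharmacophore motif (amide, carboxylic acid, phenol, nitrile,
sulfonamide — each detectable within 3 bond hops, matching the default
message-passing depth). The *label* is then recomputed from the emitted
structure by SMARTS substructure matching, so labels are exactly the
planted rule, optionally flipped with a given noise probability.

Every emitted SMILES parses; everything is reproducible from the seed.
The generator emulates the multi-target activity structure of a real
chemogenomic extraction (overlapping actives, unknown labels), not its
chemical-space coverage or property distributions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem

from .chem_io import (
    ACTIVE, INACTIVE, UNKNOWN, KNOWN_GROUPS,
    MoleculeRecord, TargetRegistry,
)


class GenerationError(RuntimeError):
    pass


#: motif name → (SMARTS pattern, carrier fragment; attachment atom is index 0)
MOTIF_LIBRARY: dict[str, tuple[str, str]] = {
    "amide": ("[CX3](=O)[NX3]", "CC(=O)NC"),
    "carboxylic_acid": ("[CX3](=O)[OX2H1]", "CC(=O)O"),
    "phenol": ("[OX2H][c]", "Cc1ccc(O)cc1"),
    "nitrile": ("[CX2]#[NX1]", "CC#N"),
    "sulfonamide": ("[SX4](=O)(=O)[NX3]", "CS(=O)(=O)N"),
}

#: motif-free decoration fragments (attachment atom is index 0)
BASE_FRAGMENTS = ["C", "CC", "CCC", "CC(C)C", "C1CCCCC1", "C1CCCC1", "c1ccccc1", "CCOC"]


@dataclass
class SynthSpec:
    """Conditions of one synthetic study."""

    n_molecules: int = 1000
    motif_smarts: dict[str, str] = field(
        default_factory=lambda: {
            f"T{i+1}": MOTIF_LIBRARY[name][0]
            for i, name in enumerate(MOTIF_LIBRARY)
        }
    )
    motif_fragments: dict[str, str] | None = None
    base_alphabet: list[str] = field(default_factory=lambda: list(BASE_FRAGMENTS))
    label_noise: float = 0.1
    active_fraction: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if not (0.0 <= self.label_noise < 0.5):
            raise GenerationError("label_noise must be in [0, 0.5)")
        if not (0.0 < self.active_fraction < 1.0):
            raise GenerationError("active_fraction must be in (0, 1)")
        if self.motif_fragments is None:
            by_smarts = {s: frag for s, frag in MOTIF_LIBRARY.values()}
            try:
                self.motif_fragments = {
                    t: by_smarts[s] for t, s in self.motif_smarts.items()
                }
            except KeyError as e:
                raise GenerationError(
                    f"no carrier fragment known for motif {e}; "
                    "pass motif_fragments explicitly"
                )
        for t, smarts in self.motif_smarts.items():
            patt = Chem.MolFromSmarts(smarts)
            if patt is None:
                raise GenerationError(f"invalid SMARTS {smarts!r} for target {t}")
            frag = Chem.MolFromSmiles(self.motif_fragments[t])
            if frag is None or not frag.HasSubstructMatch(patt):
                raise GenerationError(
                    f"carrier fragment for target {t} does not contain its motif"
                )


def default_registry(targets: list[str]) -> TargetRegistry:
    groups = {t: KNOWN_GROUPS[i % len(KNOWN_GROUPS)] for i, t in enumerate(targets)}
    return TargetRegistry(list(targets), groups)


def _assemble(rng: np.random.Generator, base_alphabet: list[str],
              motif_frags: list[str], max_attempts: int = 20) -> str:
    """Backbone + fragments → canonical SMILES; valence-safe by design."""
    for _ in range(max_attempts):
        n_base = int(rng.integers(1, 4))
        frags = [str(rng.choice(base_alphabet)) for _ in range(n_base)] + motif_frags
        order = rng.permutation(len(frags))
        frags = [frags[i] for i in order]
        backbone_len = len(frags) + int(rng.integers(0, 3))
        mol = Chem.RWMol(Chem.MolFromSmiles("C" * backbone_len))
        ok = True
        for i, frag_smi in enumerate(frags):
            frag = Chem.MolFromSmiles(frag_smi)
            offset = mol.GetNumAtoms()
            mol = Chem.RWMol(Chem.CombineMols(mol, frag))
            mol.AddBond(i, offset, Chem.BondType.SINGLE)
        try:
            out = mol.GetMol()
            Chem.SanitizeMol(out)
        except Exception:
            ok = False
        if ok:
            return Chem.MolToSmiles(out)
    raise GenerationError("could not assemble a valid molecule")


def generate_dataset(
    spec: SynthSpec,
) -> tuple[list[MoleculeRecord], TargetRegistry]:
    """Emit a multi-target dataset whose labels follow the planted rules.

    For each target, exactly round(active_fraction · n) molecules carry
    its motif fragment; the recorded label is the substructure-match
    verdict on the assembled molecule, flipped with probability
    ``label_noise``.
    """
    rng = np.random.default_rng(spec.seed)
    targets = list(spec.motif_smarts)
    n = spec.n_molecules
    carriers = {
        t: set(rng.permutation(n)[: round(spec.active_fraction * n)])
        for t in targets
    }
    patterns = {t: Chem.MolFromSmarts(s) for t, s in spec.motif_smarts.items()}
    records = []
    structural_hits = {t: 0 for t in targets}
    for i in range(n):
        motif_frags = [spec.motif_fragments[t] for t in targets if i in carriers[t]]
        smi = _assemble(rng, spec.base_alphabet, motif_frags)
        mol = Chem.MolFromSmiles(smi)
        labels = {}
        for t in targets:
            hit = mol.HasSubstructMatch(patterns[t])
            structural_hits[t] += hit
            if rng.random() < spec.label_noise:
                hit = not hit
            labels[t] = ACTIVE if hit else INACTIVE
        records.append(MoleculeRecord(f"M{i:05d}", smi, labels))
    registry = default_registry(targets)
    for t in targets:
        prev = structural_hits[t] / n
        if abs(prev - spec.active_fraction) > 0.05:
            raise GenerationError(
                f"achieved motif prevalence {prev:.3f} for {t} strays from "
                f"{spec.active_fraction:.3f}"
            )
    return records, registry


def make_multilabel_fixture(
    n_targets: int = 5,
    overlap: float = 0.3,
    seed: int = 0,
    n_molecules: int = 150,
    unknown_fraction: float = 0.15,
    active_fraction: float = 0.6,
) -> tuple[list[MoleculeRecord], TargetRegistry]:
    """Dataset where a controlled share of molecules hit ≥ 2 targets.

    Active molecules get one primary motif; a fraction ``overlap`` of
    them additionally carry every other motif with probability
    ``overlap``. A share of labels is masked as unknown to exercise
    known-label-only validation. Labels here are noise-free (the match
    oracle's verdict, pre-masking).
    """
    if n_targets < 2:
        raise GenerationError("need at least two targets")
    names = list(MOTIF_LIBRARY)
    if n_targets > len(names):
        raise GenerationError(f"at most {len(names)} built-in motifs")
    targets = [f"T{i+1}" for i in range(n_targets)]
    smarts = {t: MOTIF_LIBRARY[names[i]][0] for i, t in enumerate(targets)}
    frags = {t: MOTIF_LIBRARY[names[i]][1] for i, t in enumerate(targets)}
    rng = np.random.default_rng(seed)
    patterns = {t: Chem.MolFromSmarts(s) for t, s in smarts.items()}
    n_active = round(active_fraction * n_molecules)
    n_multi = round(overlap * n_active)
    records = []
    for i in range(n_molecules):
        chosen: list[str] = []
        if i < n_active:
            primary = targets[i % n_targets]
            chosen = [primary]
            if i < n_multi:
                extras = [t for t in targets if t != primary
                          and rng.random() < max(overlap, 0.5)]
                if not extras:  # the multi-active share is guaranteed
                    extras = [targets[(i + 1) % n_targets]]
                chosen += extras
        smi = _assemble(rng, BASE_FRAGMENTS, [frags[t] for t in chosen])
        mol = Chem.MolFromSmiles(smi)
        labels = {}
        for t in targets:
            hit = mol.HasSubstructMatch(patterns[t])
            lab = ACTIVE if hit else INACTIVE
            if rng.random() < unknown_fraction:
                lab = UNKNOWN
            labels[t] = lab
        records.append(MoleculeRecord(f"X{i:05d}", smi, labels))
    order = rng.permutation(n_molecules)
    records = [records[i] for i in order]
    return records, default_registry(targets)
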