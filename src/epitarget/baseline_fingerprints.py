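"""Morgan circular-fingerprint baseline features.

Folded ECFP-style bit vectors (default radius 2, 2048 bits — the
ECFP4-equivalent setting) that drop in wherever a GNN embedding matrix
is used, so the boosted classifier can be trained on either featurizer
and the two compared head-to-head.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from rdkit import Chem
from rdkit.Chem import rdFingerprintGenerator

from .chem_io import SmilesParseError


@dataclass(frozen=True)
class FingerprintConfig:
    radius: int = 2
    n_bits: int = 2048

    def __post_init__(self):
        if self.radius < 0:
            raise ValueError("radius must be ≥ 0")
        if self.n_bits <= 0 or (self.n_bits & (self.n_bits - 1)):
            raise ValueError("n_bits must be a positive power of two")


def morgan_fingerprint(smiles: str, config: FingerprintConfig = FingerprintConfig()) -> np.ndarray:
    """Folded Morgan bit vector for one molecule (0/1 float array)."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise SmilesParseError(smiles)
    gen = rdFingerprintGenerator.GetMorganGenerator(
        radius=config.radius, fpSize=config.n_bits
    )
    fp = gen.GetFingerprint(mol)
    arr = np.zeros(config.n_bits, dtype=np.float64)
    for bit in fp.GetOnBits():
        arr[bit] = 1.0
    return arr


def morgan_matrix(smiles_list: list[str],
                  config: FingerprintConfig = FingerprintConfig()) -> np.ndarray:
    """Fingerprint matrix (n_molecules × n_bits), row order preserved."""
    return np.stack([morgan_fingerprint(s, config) for s in smiles_list])
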