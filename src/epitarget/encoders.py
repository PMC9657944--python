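"""Message-passing molecular encoders (GCN, GGNN, DMPNN).

All three encoders share the node-embedding template

    h_i^t = U(h_i^{t-1}, m_i^t)

where ``m_i^t`` aggregates the states of atom i's neighborhood and U is
the architecture-specific update:

* **GCN** — ``h_i^t = ReLU(W_self h_i^{t-1} + W_msg m_i^t + b)`` with
  ``m_i^t`` the sum of neighbor states.
* **GGNN** — the same message, consumed by a gated recurrent unit:
  ``h_i^t = GRU(h_i^{t-1}, m_i^t)``.
* **DMPNN** — hidden states live on *directed bonds*; the message into
  edge (v→w) sums the states of edges (k→v) *excluding* the reverse
  edge (w→v), so information never immediately bounces back. After T
  steps, atom states are formed from the atom's own features plus its
  summed incoming edge states.

Each encoder is trained with a logistic classification head on binary
active/inactive labels (binary cross-entropy, Adam). The molecule
embedding used downstream is the penultimate vector: the order-invariant
readout over atom states, before the head.

Implemented in NumPy on a small reverse-mode autodiff core
(:mod:`epitarget._autodiff`); training is fully deterministic given the
config seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict, field

import numpy as np

from . import _autodiff as ad
from ._autodiff import Tensor
from .chem_io import MolGraph, DEFAULT_SCHEME, FeatureScheme, smiles_to_graph

ENCODER_KINDS = ("gcn", "ggnn", "dmpnn")


class EncoderError(ValueError):
    pass


@dataclass
class EncoderConfig:
    kind: str = "dmpnn"
    hidden_dim: int = 128
    depth: int = 3          # number of message-passing steps T
    readout: str = "mean"   # {"sum", "mean"}
    dropout: float = 0.0
    seed: int = 0
    epochs: int = 30
    learning_rate: float = 1e-3
    batch_size: int = 50

    def __post_init__(self):
        if self.kind not in ENCODER_KINDS:
            raise EncoderError(f"unknown encoder kind {self.kind!r}")
        if self.depth < 1 or self.hidden_dim < 1:
            raise EncoderError("depth and hidden_dim must be ≥ 1")
        if not (0.0 <= self.dropout < 1.0):
            raise EncoderError("dropout must be in [0, 1)")
        if self.readout not in ("sum", "mean"):
            raise EncoderError(f"unknown readout {self.readout!r}")


# ----------------------------------------------------------------------
# Graph batching
# ----------------------------------------------------------------------

@dataclass
class GraphBatch:
    """Several molecular graphs packed into one disjoint union.

    Besides the concatenated feature/index arrays, the batch carries
    prebuilt sparse operators (CSR) so neighborhood aggregation and
    readout are sparse-matrix products with cheap exact backward passes:
    ``adj`` (atom←atom message counts), ``g_src`` (edge ← its source
    atom), ``s_dst`` (atom ← incoming edges) and ``s_mol`` (molecule ←
    its atoms).
    """

    n_mols: int
    n_atoms: int
    n_edges: int
    atom_x: np.ndarray        # (A, d_a)
    edge_b: np.ndarray        # (E, d_b) bond features per directed edge
    edge_src: np.ndarray      # (E,)
    edge_dst: np.ndarray      # (E,)
    edge_rev: np.ndarray      # (E,)
    atom_mol: np.ndarray      # (A,) molecule id per atom
    atoms_per_mol: np.ndarray  # (n_mols,)
    adj: object = None
    adj_T: object = None
    g_src: object = None
    g_src_T: object = None
    s_dst: object = None
    s_dst_T: object = None
    s_mol: object = None
    s_mol_T: object = None
    edge_xb: np.ndarray = None  # (E, d_a + d_b) source-atom ∥ bond features


def build_batch(graphs: list[MolGraph]) -> GraphBatch:
    from scipy import sparse

    atom_x, edge_b, src, dst, rev, mol_of = [], [], [], [], [], []
    a_off = e_off = 0
    counts = []
    for m, g in enumerate(graphs):
        atom_x.append(g.atom_features)
        counts.append(g.n_atoms)
        mol_of.append(np.full(g.n_atoms, m, dtype=np.int64))
        if g.n_bonds:
            # bond feature row e//2 serves both directions of bond e//2
            edge_b.append(np.repeat(g.bond_features, 2, axis=0))
            es = np.array([u for u, _ in g.directed_edges], dtype=np.int64)
            ed = np.array([v for _, v in g.directed_edges], dtype=np.int64)
            src.append(es + a_off)
            dst.append(ed + a_off)
            rev.append(np.asarray(g.reverse_index, dtype=np.int64) + e_off)
        a_off += g.n_atoms
        e_off += 2 * g.n_bonds
    d_b = graphs[0].bond_features.shape[1]
    b = GraphBatch(
        n_mols=len(graphs),
        n_atoms=a_off,
        n_edges=e_off,
        atom_x=np.concatenate(atom_x, axis=0),
        edge_b=np.concatenate(edge_b, axis=0) if edge_b else np.zeros((0, d_b)),
        edge_src=np.concatenate(src) if src else np.zeros(0, dtype=np.int64),
        edge_dst=np.concatenate(dst) if dst else np.zeros(0, dtype=np.int64),
        edge_rev=np.concatenate(rev) if rev else np.zeros(0, dtype=np.int64),
        atom_mol=np.concatenate(mol_of),
        atoms_per_mol=np.asarray(counts, dtype=np.float64),
    )
    E, A, M = b.n_edges, b.n_atoms, b.n_mols
    ones_e = np.ones(E)
    b.g_src = sparse.csr_matrix((ones_e, (np.arange(E), b.edge_src)), shape=(E, A))
    b.s_dst = sparse.csr_matrix((ones_e, (b.edge_dst, np.arange(E))), shape=(A, E))
    b.adj = (b.s_dst @ b.g_src).tocsr()
    b.s_mol = sparse.csr_matrix(
        (np.ones(A), (b.atom_mol, np.arange(A))), shape=(M, A)
    )
    b.g_src_T = b.g_src.T.tocsr()
    b.s_dst_T = b.s_dst.T.tocsr()
    b.adj_T = b.adj.T.tocsr()
    b.s_mol_T = b.s_mol.T.tocsr()
    b.edge_xb = np.concatenate([b.atom_x[b.edge_src], b.edge_b], axis=1)
    return b


# ----------------------------------------------------------------------
# Parameter initialization
# ----------------------------------------------------------------------

def _glorot(rng, fan_in, fan_out):
    s = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-s, s, size=(fan_in, fan_out))


def init_params(kind: str, d_atom: int, d_bond: int, hidden: int, seed: int) -> dict:
    """Architecture-specific trainable parameters as named tensors."""
    rng = np.random.default_rng(seed)
    P: dict[str, Tensor] = {}

    def W(name, fi, fo):
        P[name] = ad.param(_glorot(rng, fi, fo))

    def b(name, n):
        P[name] = ad.param(np.zeros((1, n)))

    if kind == "gcn":
        W("W_in", d_atom, hidden); b("b_in", hidden)
        W("W_self", hidden, hidden); W("W_msg", hidden, hidden); b("b_up", hidden)
    elif kind == "ggnn":
        W("W_in", d_atom, hidden); b("b_in", hidden)
        W("W_msg", hidden, hidden); b("b_msg", hidden)
        for gate in ("z", "r", "h"):
            W(f"W_{gate}", hidden, hidden)   # acts on h^{t-1} (or r*h)
            W(f"U_{gate}", hidden, hidden)   # acts on the message
            b(f"b_{gate}", hidden)
    elif kind == "dmpnn":
        W("W_i", d_atom + d_bond, hidden); b("b_i", hidden)
        W("W_h", hidden, hidden)
        W("W_o", d_atom + hidden, hidden); b("b_o", hidden)
    else:
        raise EncoderError(kind)
    W("head_w", hidden, 1); b("head_b", 1)
    return P


# ----------------------------------------------------------------------
# Forward passes (per-atom hidden states on a batch)
# ----------------------------------------------------------------------

def _atom_states_gcn(batch: GraphBatch, P: dict, depth: int) -> Tensor:
    x = ad.const(batch.atom_x)
    h = ad.relu(ad.add(ad.matmul(x, P["W_in"]), P["b_in"]))
    for _ in range(depth):
        msgs = ad.spmm(batch.adj, batch.adj_T, h)  # sum of neighbor states
        h = ad.relu(
            ad.add(ad.add(ad.matmul(h, P["W_self"]), ad.matmul(msgs, P["W_msg"])),
                   P["b_up"])
        )
    return h


def _atom_states_ggnn(batch: GraphBatch, P: dict, depth: int) -> Tensor:
    x = ad.const(batch.atom_x)
    h = ad.relu(ad.add(ad.matmul(x, P["W_in"]), P["b_in"]))
    for _ in range(depth):
        agg = ad.spmm(batch.adj, batch.adj_T, h)
        m = ad.add(ad.matmul(agg, P["W_msg"]), P["b_msg"])
        z = ad.sigmoid(ad.add(ad.add(ad.matmul(h, P["W_z"]), ad.matmul(m, P["U_z"])), P["b_z"]))
        r = ad.sigmoid(ad.add(ad.add(ad.matmul(h, P["W_r"]), ad.matmul(m, P["U_r"])), P["b_r"]))
        c = ad.tanh(ad.add(ad.add(ad.matmul(ad.mul(r, h), P["W_h"]), ad.matmul(m, P["U_h"])), P["b_h"]))
        # h' = (1-z)*h + z*c
        h = ad.add(ad.mul(ad.add_const(ad.scale(z, -1.0), 1.0), h), ad.mul(z, c))
    return h


def _atom_states_dmpnn(batch: GraphBatch, P: dict, depth: int) -> Tensor:
    x = ad.const(batch.atom_x)
    e0 = ad.relu(ad.add(ad.matmul(ad.const(batch.edge_xb), P["W_i"]), P["b_i"]))
    h = e0
    rev = batch.edge_rev
    for _ in range(depth):
        # sum of states of edges arriving at each atom ...
        into_atom = ad.spmm(batch.s_dst, batch.s_dst_T, h)
        # ... message for edge (v→w) = that sum at v, minus the reverse edge (w→v)
        msg = ad.sub(ad.spmm(batch.g_src, batch.g_src_T, into_atom),
                     ad.permute_rows(h, rev, rev))  # rev is an involution
        h = ad.relu(ad.add(e0, ad.matmul(msg, P["W_h"])))
    incoming = ad.spmm(batch.s_dst, batch.s_dst_T, h)
    return ad.relu(ad.add(ad.matmul(ad.concat([x, incoming], axis=1), P["W_o"]), P["b_o"]))


_ATOM_STATES = {"gcn": _atom_states_gcn, "ggnn": _atom_states_ggnn, "dmpnn": _atom_states_dmpnn}


def readout(atom_states: Tensor, batch: GraphBatch, mode: str) -> Tensor:
    """Order-invariant pooling of per-atom states into molecule embeddings."""
    pooled = ad.spmm(batch.s_mol, batch.s_mol_T, atom_states)
    if mode == "mean":
        pooled = ad.rowscale(pooled, 1.0 / batch.atoms_per_mol)
    return pooled


def _forward(batch: GraphBatch, P: dict, cfg: EncoderConfig) -> tuple[Tensor, Tensor]:
    if batch.n_atoms == 0:
        raise EncoderError("cannot propagate on a graph with zero atoms")
    h = _ATOM_STATES[cfg.kind](batch, P, cfg.depth)
    emb = readout(h, batch, cfg.readout)
    logits = ad.add(ad.matmul(emb, P["head_w"]), P["head_b"])
    return emb, logits


# --- single-graph conveniences used by the mechanics tests -------------

def propagate_gcn(graph: MolGraph, params: dict, depth: int) -> np.ndarray:
    """Per-atom hidden states of the GCN forward pass (no head)."""
    return _atom_states_gcn(build_batch([graph]), params, depth).data


def propagate_ggnn(graph: MolGraph, params: dict, depth: int) -> np.ndarray:
    return _atom_states_ggnn(build_batch([graph]), params, depth).data


def propagate_dmpnn_edges(graph: MolGraph, params: dict, depth: int) -> np.ndarray:
    """Per-directed-edge hidden states after `depth` DMPNN steps."""
    batch = build_batch([graph])
    e0 = ad.relu(ad.add(ad.matmul(ad.const(batch.edge_xb), params["W_i"]), params["b_i"]))
    h = e0
    for _ in range(depth):
        into_atom = ad.spmm(batch.s_dst, batch.s_dst_T, h)
        msg = ad.sub(ad.spmm(batch.g_src, batch.g_src_T, into_atom),
                     ad.permute_rows(h, batch.edge_rev, batch.edge_rev))
        h = ad.relu(ad.add(e0, ad.matmul(msg, params["W_h"])))
    return h.data


def propagate_dmpnn(graph: MolGraph, params: dict, depth: int) -> np.ndarray:
    """Per-atom DMPNN states (edge propagation + atom aggregation)."""
    return _atom_states_dmpnn(build_batch([graph]), params, depth).data


# ----------------------------------------------------------------------
# Trained encoder
# ----------------------------------------------------------------------

@dataclass
class EncoderModel:
    """A trained GNN encoder with its logistic head.

    ``embed`` returns the penultimate representation (readout vector);
    ``predict_proba`` applies the retained head. Both run in inference
    mode (no dropout) and are deterministic.
    """

    config: EncoderConfig
    params: dict
    scheme_fingerprint: str = field(default_factory=lambda: DEFAULT_SCHEME.fingerprint())
    training_report: dict = field(default_factory=dict)

    @property
    def feature_dim(self) -> int:
        return self.config.hidden_dim

    def _check(self, graphs: list[MolGraph]):
        d = graphs[0].atom_features.shape[1]
        expect = self.params["W_in" if self.config.kind != "dmpnn" else "W_i"].data.shape[0]
        if self.config.kind == "dmpnn":
            d = d + graphs[0].bond_features.shape[1]
        if d != expect:
            raise EncoderError(
                f"feature-scheme mismatch: graphs have input dim {d}, model expects {expect}"
            )

    def embed(self, graphs: list[MolGraph]) -> np.ndarray:
        self._check(graphs)
        out = np.zeros((len(graphs), self.feature_dim))
        # one molecule at a time: batching must not change values, and
        # per-graph evaluation makes that true by construction
        for i, g in enumerate(graphs):
            emb, _ = _forward(build_batch([g]), self.params, self.config)
            out[i] = emb.data[0]
        return out

    def predict_proba(self, graphs: list[MolGraph]) -> np.ndarray:
        self._check(graphs)
        out = np.zeros(len(graphs))
        for i, g in enumerate(graphs):
            _, logit = _forward(build_batch([g]), self.params, self.config)
            out[i] = 1.0 / (1.0 + np.exp(-logit.data[0, 0]))
        return out

    def embed_smiles(self, smiles_list: list[str],
                     scheme: FeatureScheme = DEFAULT_SCHEME) -> np.ndarray:
        return self.embed([smiles_to_graph(s, scheme) for s in smiles_list])

    # -- persistence ---------------------------------------------------
    def save(self, path) -> None:
        arrays = {k: v.data for k, v in self.params.items()}
        arrays["__config__"] = np.frombuffer(
            json.dumps({"config": asdict(self.config),
                        "scheme": self.scheme_fingerprint,
                        "report": self.training_report}).encode(), dtype=np.uint8)
        np.savez(path, **arrays)

    @classmethod
    def load(cls, path, scheme: FeatureScheme = DEFAULT_SCHEME) -> "EncoderModel":
        with np.load(path) as z:
            meta = json.loads(bytes(z["__config__"].tobytes()).decode())
            params = {k: ad.param(z[k]) for k in z.files if k != "__config__"}
        if meta["scheme"] != scheme.fingerprint():
            raise EncoderError(
                f"feature-scheme mismatch: checkpoint {meta['scheme']!r} "
                f"vs current {scheme.fingerprint()!r}"
            )
        return cls(EncoderConfig(**meta["config"]), params,
                   meta["scheme"], meta.get("report", {}))


def param_hash(params: dict) -> str:
    import hashlib

    h = hashlib.sha256()
    for k in sorted(params):
        h.update(k.encode())
        h.update(params[k].data.tobytes())
    return h.hexdigest()


def train_encoder(
    graphs: list[MolGraph],
    labels: np.ndarray,
    config: EncoderConfig,
    scheme: FeatureScheme = DEFAULT_SCHEME,
) -> EncoderModel:
    """Train one encoder end-to-end on binary labels for a single target.

    The encoder and its logistic head are optimized jointly with Adam on
    binary cross-entropy; the returned model keeps the head but exposes
    the penultimate readout vector as the molecular feature.
    """
    labels = np.asarray(labels, dtype=np.float64).ravel()
    if len(graphs) != len(labels):
        raise EncoderError("graphs and labels length mismatch")
    if len(np.unique(labels)) < 2:
        raise EncoderError("encoder training needs both classes present")
    d_a = graphs[0].atom_features.shape[1]
    d_b = graphs[0].bond_features.shape[1]
    P = init_params(config.kind, d_a, d_b, config.hidden_dim, config.seed)
    opt = ad.Adam(list(P.values()), lr=config.learning_rate)
    rng = np.random.default_rng(config.seed + 1)
    n = len(graphs)
    # minibatch membership is drawn once (seeded) and the batches are
    # prebuilt; each epoch shuffles only the batch order
    order = rng.permutation(n)
    splits = [order[lo: lo + config.batch_size]
              for lo in range(0, n, config.batch_size)]
    prebuilt = [(idx, build_batch([graphs[i] for i in idx])) for idx in splits]
    losses = []
    for epoch in range(config.epochs):
        epoch_loss = 0.0
        for bi in rng.permutation(len(prebuilt)):
            idx, batch = prebuilt[bi]
            opt.zero_grad()
            emb, logits = _forward(batch, P, config)
            if config.dropout > 0.0:
                keep = (rng.random(emb.data.shape) >= config.dropout) / (1 - config.dropout)
                logits = ad.add(ad.matmul(ad.mul(emb, ad.const(keep)), P["head_w"]),
                                P["head_b"])
            loss = ad.bce_with_logits(logits, labels[idx].reshape(-1, 1))
            if not np.isfinite(loss.data):
                raise EncoderError(
                    f"non-finite loss at epoch {epoch} "
                    f"(learning_rate={config.learning_rate})"
                )
            loss.backward()
            opt.step()
            epoch_loss += float(loss.data) * len(idx)
        losses.append(epoch_loss / n)
    report = {"initial_loss": losses[0], "final_loss": losses[-1], "epoch_losses": losses}
    return EncoderModel(config, P, scheme.fingerprint(), report)
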