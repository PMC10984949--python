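"""Graph isomorphism network (GIN) encoder for molecular graphs.

The encoder maps a batch of :class:`~molfewshot.chem_io.MolecularGraph`
objects to fixed-length graph embeddings plus binary class logits. The node
update at layer *l* is the GIN rule

    h_v <- MLP_l( (1 + eps_l) * h_v + sum_{u in N(v)} (h_u + e_uv) )

with a learnable eps_l, a two-layer ReLU MLP, and learned embedding tables
for the categorical atom/bond codes (atomic number + chirality per atom,
bond type + direction per bond; the edge embedding e_uv is the sum of its
two code embeddings). The graph-level readout sums node states per graph at
every layer; a jumping-knowledge (JK) combination — sum by default — merges
the per-layer readouts into the final embedding fed to a linear 2-class
head. The pre-head embedding is the representation used by the contrastive
objective.

Parameters live in a :class:`ParameterSet`: a flat name->Tensor map plus
non-trainable buffers (batch-norm running statistics). Checkpoints are
NumPy ``.npz`` archives of that flat map, stable across versions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .chem_io import (
    MolecularGraph,
    NUM_ATOM_TYPES,
    NUM_BOND_DIRECTIONS,
    NUM_BOND_TYPES,
    NUM_CHIRALITY_TAGS,
)

_JK_MODES = ("last", "sum", "max", "concat")
_BN_EPS = 1e-5
_BN_MOMENTUM = 0.1


@dataclass
class EncoderConfig:
    n_layers: int = 5
    hidden_dim: int = 32
    jk_mode: str = "sum"
    dropout: float = 0.0
    batch_norm: bool = True
    checkpoint_path: Optional[str] = None

    def __post_init__(self):
        if self.n_layers < 1 or self.hidden_dim < 1:
            raise ValueError("n_layers and hidden_dim must be >= 1")
        if self.jk_mode not in _JK_MODES:
            raise ValueError(f"jk_mode must be one of {_JK_MODES}")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must lie in [0, 1)")

    @property
    def embedding_dim(self) -> int:
        if self.jk_mode == "concat":
            return self.n_layers * self.hidden_dim
        return self.hidden_dim


@dataclass
class EmbeddingBatch:
    """Embeddings, labels and logits for one batch of molecules."""

    embeddings: np.ndarray
    labels: np.ndarray
    logits: np.ndarray

    def __post_init__(self):
        if not (len(self.embeddings) == len(self.labels) == len(self.logits)):
            raise ValueError("row counts disagree across fields")
        for arr in (self.embeddings, self.logits):
            if not np.all(np.isfinite(arr)):
                raise ValueError("non-finite values in embedding batch")


class ParameterSet:
    """Flat name->Tensor parameter map plus non-trainable buffers."""

    def __init__(self, params: dict, buffers: dict):
        self.params = params
        self.buffers = buffers

    def clone(self) -> "ParameterSet":
        return ParameterSet(
            {k: ad.parameter(p.data.copy()) for k, p in self.params.items()},
            {k: b.copy() for k, b in self.buffers.items()},
        )

    def copy_state(self) -> dict:
        state = {f"param:{k}": p.data.copy() for k, p in self.params.items()}
        state.update({f"buffer:{k}": b.copy() for k, b in self.buffers.items()})
        return state

    def save(self, path) -> None:
        np.savez(path, **self.copy_state())


@dataclass
class GraphBatch:
    """Collated graphs: one big disconnected graph with a graph-id vector."""

    node_features: np.ndarray
    edge_index: np.ndarray
    edge_features: np.ndarray
    graph_index: np.ndarray
    n_graphs: int


def collate(graphs: list) -> GraphBatch:
    nodes, eidx, efeat, gidx = [], [], [], []
    offset = 0
    for g, graph in enumerate(graphs):
        if graph.n_atoms < 1:
            raise ValueError("cannot encode an empty graph")
        nodes.append(graph.node_features)
        eidx.append(graph.edge_index + offset)
        efeat.append(graph.edge_features)
        gidx.append(np.full(graph.n_atoms, g, dtype=np.int64))
        offset += graph.n_atoms
    return GraphBatch(
        node_features=np.concatenate(nodes, axis=0),
        edge_index=np.concatenate(eidx, axis=1),
        edge_features=np.concatenate(efeat, axis=0),
        graph_index=np.concatenate(gidx),
        n_graphs=len(graphs),
    )


class GINEncoder:
    """Stateless forward pass; all state lives in a :class:`ParameterSet`."""

    def __init__(self, config: EncoderConfig):
        self.config = config

    # -- initialisation ----------------------------------------------------
    def init_params(self, seed: int = 0) -> ParameterSet:
        cfg = self.config
        rng = np.random.default_rng(seed)
        h = cfg.hidden_dim

        def xavier(fan_in, fan_out):
            bound = np.sqrt(6.0 / (fan_in + fan_out))
            return rng.uniform(-bound, bound, size=(fan_in, fan_out))

        params: dict = {
            "atom_embed.atomic": ad.parameter(xavier(NUM_ATOM_TYPES, h)),
            "atom_embed.chirality": ad.parameter(xavier(NUM_CHIRALITY_TAGS, h)),
        }
        buffers: dict = {}
        for l in range(cfg.n_layers):
            params[f"layer{l}.edge_embed.type"] = ad.parameter(xavier(NUM_BOND_TYPES, h))
            params[f"layer{l}.edge_embed.dir"] = ad.parameter(xavier(NUM_BOND_DIRECTIONS, h))
            params[f"layer{l}.eps"] = ad.parameter(0.0)
            params[f"layer{l}.mlp.W1"] = ad.parameter(xavier(h, 2 * h))
            params[f"layer{l}.mlp.b1"] = ad.parameter(np.zeros(2 * h))
            params[f"layer{l}.mlp.W2"] = ad.parameter(xavier(2 * h, h))
            params[f"layer{l}.mlp.b2"] = ad.parameter(np.zeros(h))
            if cfg.batch_norm:
                params[f"layer{l}.bn.gamma"] = ad.parameter(np.ones(h))
                params[f"layer{l}.bn.beta"] = ad.parameter(np.zeros(h))
                buffers[f"layer{l}.bn.running_mean"] = np.zeros(h)
                buffers[f"layer{l}.bn.running_var"] = np.ones(h)
        params["head.W"] = ad.parameter(xavier(cfg.embedding_dim, 2))
        params["head.b"] = ad.parameter(np.zeros(2))
        return ParameterSet(params, buffers)

    # -- forward -----------------------------------------------------------
    def forward(
        self,
        pset: ParameterSet,
        batch: GraphBatch,
        training: bool = False,
        rng: Optional[np.random.Generator] = None,
    ) -> tuple[Tensor, Tensor]:
        """Return (graph embeddings (n_graphs, d), logits (n_graphs, 2))."""
        cfg = self.config
        P = pset.params
        src, dst = batch.edge_index
        n_nodes = batch.node_features.shape[0]

        h = (P["atom_embed.atomic"].gather_rows(batch.node_features[:, 0])
             + P["atom_embed.chirality"].gather_rows(batch.node_features[:, 1]))
        layer_readouts = []
        for l in range(cfg.n_layers):
            if batch.edge_index.shape[1]:
                msg = (h.gather_rows(src)
                       + P[f"layer{l}.edge_embed.type"].gather_rows(batch.edge_features[:, 0])
                       + P[f"layer{l}.edge_embed.dir"].gather_rows(batch.edge_features[:, 1]))
                agg = msg.segment_sum(dst, n_nodes)
            else:
                agg = ad.constant(np.zeros((n_nodes, cfg.hidden_dim)))
            x = h * (P[f"layer{l}.eps"] + 1.0) + agg
            x = ad.relu(x @ P[f"layer{l}.mlp.W1"] + P[f"layer{l}.mlp.b1"])
            x = x @ P[f"layer{l}.mlp.W2"] + P[f"layer{l}.mlp.b2"]
            if cfg.batch_norm:
                x = self._batch_norm(pset, l, x, training)
            if l < cfg.n_layers - 1:
                x = ad.relu(x)
            if training and cfg.dropout > 0.0:
                if rng is None:
                    raise ValueError("dropout in training mode needs an rng")
                keep = 1.0 - cfg.dropout
                mask = (rng.random(x.shape) < keep).astype(np.float64) / keep
                x = x * ad.constant(mask)
            h = x
            layer_readouts.append(h.segment_sum(batch.graph_index, batch.n_graphs))

        emb = self._jumping_knowledge(layer_readouts)
        logits = emb @ P["head.W"] + P["head.b"]
        return emb, logits

    def _batch_norm(self, pset: ParameterSet, l: int, x: Tensor, training: bool) -> Tensor:
        gamma = pset.params[f"layer{l}.bn.gamma"]
        beta = pset.params[f"layer{l}.bn.beta"]
        if training and x.shape[0] > 1:
            mu = x.mean(axis=0, keepdims=True)
            centered = x - mu
            var = (centered * centered).mean(axis=0, keepdims=True)
            xhat = centered / (var + _BN_EPS).sqrt()
            m = _BN_MOMENTUM
            n = x.shape[0]
            pset.buffers[f"layer{l}.bn.running_mean"] *= 1 - m
            pset.buffers[f"layer{l}.bn.running_mean"] += m * mu.data.ravel()
            pset.buffers[f"layer{l}.bn.running_var"] *= 1 - m
            pset.buffers[f"layer{l}.bn.running_var"] += m * var.data.ravel() * n / max(n - 1, 1)
        else:
            mu = ad.constant(pset.buffers[f"layer{l}.bn.running_mean"])
            var = ad.constant(pset.buffers[f"layer{l}.bn.running_var"])
            xhat = (x - mu) / (var + _BN_EPS).sqrt()
        return xhat * gamma + beta

    def _jumping_knowledge(self, readouts: list) -> Tensor:
        mode = self.config.jk_mode
        if mode == "last":
            return readouts[-1]
        if mode == "sum":
            out = readouts[0]
            for r in readouts[1:]:
                out = out + r
            return out
        if mode == "max":
            out = readouts[0]
            for r in readouts[1:]:
                out = ad.maximum(out, r)
            return out
        return ad.concatenate(readouts, axis=1)  # concat


def encode(
    config: EncoderConfig,
    graphs: list,
    pset: ParameterSet,
    labels: Optional[np.ndarray] = None,
) -> EmbeddingBatch:
    """Evaluation-mode encoding of a list of graphs into an EmbeddingBatch."""
    enc = GINEncoder(config)
    emb, logits = enc.forward(pset, collate(graphs), training=False)
    if labels is None:
        labels = np.zeros(len(graphs), dtype=np.int64)
    return EmbeddingBatch(embeddings=emb.data, labels=np.asarray(labels), logits=logits.data)


def load_checkpoint(config: EncoderConfig, path) -> ParameterSet:
    """Load a ``.npz`` parameter archive with strict trunk matching.

    The linear head may be absent from the archive (e.g. a pretrained trunk);
    it is then freshly initialised and a warning is emitted. Any shape or
    name mismatch in the trunk raises with the offending entries listed.
    """
    try:
        archive = np.load(path)
    except Exception as exc:  # corrupt archive
        raise IOError(f"cannot read checkpoint {path}: {exc}") from exc
    pset = GINEncoder(config).init_params(seed=0)
    stored = {k: archive[k] for k in archive.files}
    mismatches, missing = [], []
    for name, tensor in pset.params.items():
        key = f"param:{name}"
        is_head = name.startswith("head.")
        if key not in stored:
            if is_head:
                continue
            missing.append(name)
            continue
        if stored[key].shape != tensor.data.shape:
            mismatches.append(f"{name}: archive {stored[key].shape} vs config {tensor.data.shape}")
            continue
        tensor.data = stored[key].astype(np.float64)
    for name in pset.buffers:
        key = f"buffer:{name}"
        if key in stored:
            pset.buffers[name] = stored[key].astype(np.float64)
    if mismatches or missing:
        raise ValueError(
            "checkpoint does not match encoder config; "
            f"mismatched: {mismatches}; missing trunk entries: {sorted(set(missing))}"
        )
    if any(f"param:head.{n}" not in stored for n in ("W", "b")):
        warnings.warn("checkpoint has no classification head; head freshly initialised")
    return pset
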