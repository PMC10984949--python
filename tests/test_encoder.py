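"""GIN encoder contracts: shapes, invariances, hand-computed forward pass."""

import numpy as np
import pytest

from molfewshot import (
    EncoderConfig,
    GINEncoder,
    SyntheticSpec,
    encode,
    generate_family,
    load_checkpoint,
    parse_smiles,
)
from molfewshot.chem_io import MolecularGraph
from molfewshot.encoder import collate


def permute_graph(g: MolecularGraph, perm: np.ndarray) -> MolecularGraph:
    inv = np.empty_like(perm)
    inv[perm] = np.arange(len(perm))
    return MolecularGraph(
        node_features=g.node_features[perm],
        edge_index=inv[g.edge_index],
        edge_features=g.edge_features,
        smiles=g.smiles,
    )


class TestEncodeContracts:
    def test_batch_shape_with_jk_sum(self):
        cfg = EncoderConfig(hidden_dim=32, jk_mode="sum")
        graphs = [parse_smiles(s) for s in
                  ["C", "CCO", "c1ccccc1", "CC(C)C", "CCN", "CO", "CS", "CCC"]]
        batch = encode(cfg, graphs, GINEncoder(cfg).init_params(0))
        assert batch.embeddings.shape == (8, 32)
        assert batch.logits.shape == (8, 2)

    @pytest.mark.parametrize("jk,dim", [("last", 16), ("sum", 16),
                                        ("max", 16), ("concat", 48)])
    def test_embedding_dim_per_jk_mode(self, jk, dim):
        cfg = EncoderConfig(n_layers=3, hidden_dim=16, jk_mode=jk)
        assert cfg.embedding_dim == dim
        batch = encode(cfg, [parse_smiles("CCO")], GINEncoder(cfg).init_params(0))
        assert batch.embeddings.shape == (1, dim)

    def test_node_permutation_invariance(self):
        cfg = EncoderConfig(hidden_dim=16)
        pset = GINEncoder(cfg).init_params(3)
        g = parse_smiles("CC(=O)Oc1ccccc1C(=O)O")
        perm = np.random.default_rng(0).permutation(g.n_atoms)
        a = encode(cfg, [g], pset).embeddings
        b = encode(cfg, [permute_graph(g, perm)], pset).embeddings
        assert np.abs(a - b).max() < 1e-5

    def test_duplicated_graph_duplicates_rows(self):
        cfg = EncoderConfig(hidden_dim=8)
        pset = GINEncoder(cfg).init_params(1)
        g1, g2 = parse_smiles("CCO"), parse_smiles("CCN")
        batch = encode(cfg, [g1, g2, g1], pset)
        assert np.allclose(batch.embeddings[0], batch.embeddings[2])
        assert not np.allclose(batch.embeddings[0], batch.embeddings[1])

    def test_single_atom_matches_hand_evaluated_update(self):
        # one layer, no batch-norm: h = MLP((1+eps) * atom_embedding), summed
        # readout over the single node equals the node state itself
        cfg = EncoderConfig(n_layers=1, hidden_dim=2, jk_mode="last",
                            batch_norm=False)
        enc = GINEncoder(cfg)
        pset = enc.init_params(5)
        g = parse_smiles("C")
        P = {k: v.data for k, v in pset.params.items()}
        h0 = P["atom_embed.atomic"][6] + P["atom_embed.chirality"][0]
        pre = (1.0 + P["layer0.eps"]) * h0
        hidden = np.maximum(pre @ P["layer0.mlp.W1"] + P["layer0.mlp.b1"], 0)
        expected = hidden @ P["layer0.mlp.W2"] + P["layer0.mlp.b2"]
        got = encode(cfg, [g], pset).embeddings[0]
        assert np.allclose(got, expected, atol=1e-12)

    def test_no_non_finite_outputs_on_generator_graphs(self):
        fam = generate_family(SyntheticSpec(n_tasks=10, n_molecules_per_task=100,
                                            positive_fraction=0.2, seed=5))
        graphs = [parse_smiles(s) for s, _ in fam.table.records]
        assert len(graphs) == 1000
        cfg = EncoderConfig(hidden_dim=16)
        pset = GINEncoder(cfg).init_params(2)
        for start in range(0, 1000, 250):
            batch = encode(cfg, graphs[start:start + 250], pset)
            assert np.all(np.isfinite(batch.embeddings))
            assert np.all(np.isfinite(batch.logits))


class TestCheckpoints:
    def test_save_load_round_trip(self, tmp_path):
        cfg = EncoderConfig(hidden_dim=8)
        pset = GINEncoder(cfg).init_params(0)
        path = tmp_path / "enc.npz"
        pset.save(path)
        back = load_checkpoint(cfg, path)
        for k, p in pset.params.items():
            assert np.array_equal(back.params[k].data, p.data), k
        for k, b in pset.buffers.items():
            assert np.array_equal(back.buffers[k], b), k

    def test_missing_head_is_reported_not_silent(self, tmp_path):
        cfg = EncoderConfig(hidden_dim=8)
        pset = GINEncoder(cfg).init_params(0)
        state = {k: v for k, v in pset.copy_state().items()
                 if not k.startswith("param:head.")}
        path = tmp_path / "trunk.npz"
        np.savez(path, **state)
        with pytest.warns(UserWarning, match="head"):
            back = load_checkpoint(cfg, path)
        trunk_key = "layer0.mlp.W1"
        assert np.array_equal(back.params[trunk_key].data, pset.params[trunk_key].data)

    def test_wrong_hidden_dim_lists_mismatches(self, tmp_path):
        pset = GINEncoder(EncoderConfig(hidden_dim=8)).init_params(0)
        path = tmp_path / "enc.npz"
        pset.save(path)
        with pytest.raises(ValueError, match="mismatch"):
            load_checkpoint(EncoderConfig(hidden_dim=16), path)

    def test_empty_graph_rejected(self):
        with pytest.raises(ValueError):
            collate([MolecularGraph(np.zeros((0, 2), dtype=int),
                                    np.zeros((2, 0), dtype=int),
                                    np.zeros((0, 2), dtype=int), "")])
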