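"""GIN and sequence encoders: update rule, pooling, invariances, transfer."""

import numpy as np
import pytest

from dta_transfer.chem_graph import smiles_to_graph
from dta_transfer.encoders import (
    EncoderState,
    FingerprintMismatchError,
    GinEncoder,
    GinEncoderConfig,
    KmerLookupProvider,
    PrecomputedEmbeddingProvider,
    SequenceEncoder,
    SequenceEncoderConfig,
    batch_graphs,
    encode_graph,
    encode_sequence,
    gin_layer,
)
from dta_transfer.chem_graph import permute_graph

GIN_CFG = GinEncoderConfig(
    num_layers=3, hidden_dim=12, readout_hidden=10, output_dim=6
)


# ---------------------------------------------------------------------------
# gin_layer (sum aggregation)


def test_gin_layer_two_connected_nodes_identity_mlp():
    x = np.array([[1.0], [1.0]])
    a = np.array([[0.0, 1.0], [1.0, 0.0]])
    out = gin_layer(x, a, epsilon=0.0)
    assert np.allclose(out, [[2.0], [2.0]])


def test_gin_layer_isolated_node_passthrough():
    out = gin_layer(np.array([[3.5]]), np.zeros((1, 1)), epsilon=0.0)
    assert np.allclose(out, [[3.5]])


def test_gin_layer_triangle_with_epsilon():
    # node 0 of a 3-cycle with features [1,2,3], eps=0.5: 1.5*1 + (2+3) = 6.5
    x = np.array([[1.0], [2.0], [3.0]])
    a = np.ones((3, 3)) - np.eye(3)
    out = gin_layer(x, a, epsilon=0.5)
    assert np.allclose(out[:, 0], [6.5, 7.0, 7.5])


def test_gin_layer_matches_matrix_arithmetic(rng):
    """Sum aggregation equals (1+eps) X + A X on random instances."""
    for _ in range(20):
        n = int(rng.integers(2, 9))
        x = rng.normal(size=(n, 4))
        a = (rng.random((n, n)) < 0.4).astype(float)
        a = np.triu(a, 1)
        a = a + a.T
        eps = float(rng.normal())
        assert np.allclose(gin_layer(x, a, eps), (1 + eps) * x + a @ x)


# ---------------------------------------------------------------------------
# graph encoder


def test_encoder_output_width_independent_of_molecule_size(rng):
    enc = GinEncoder(GIN_CFG, rng)
    for smiles in ("C", "CCO", "c1ccccc1CCN", "C1CCCCC1C(=O)O"):
        assert encode_graph(smiles_to_graph(smiles), enc).shape == (6,)


def test_permutation_invariance_on_random_molecules(small_world, rng):
    enc = GinEncoder(GIN_CFG, rng)
    smiles = list(small_world.chemicals.values())[:50]
    for s in smiles:
        g = smiles_to_graph(s)
        base = encode_graph(g, enc)
        perm = rng.permutation(g.num_nodes)
        assert np.allclose(base, encode_graph(permute_graph(g, perm), enc), atol=1e-6)


def test_single_node_graph_pool_equals_node_vector(rng):
    """Max-pool over one node is that node's post-GIN vector; the readout of
    the pooled vector must then match running the full encoder."""
    enc = GinEncoder(GIN_CFG, rng)
    g = smiles_to_graph("C")
    X, A, mask = batch_graphs([g, g])
    out, cache = enc.forward(X, A, mask)
    assert np.allclose(cache["pooled"][0], cache["H_final"][0, 0])
    assert np.allclose(out[0], out[1])


def test_maxpool_is_coordinatewise(rng):
    enc = GinEncoder(GIN_CFG, rng)
    g1 = smiles_to_graph("CCO")
    g2 = smiles_to_graph("CN")
    X, A, mask = batch_graphs([g1, g2])
    _, cache = enc.forward(X, A, mask)
    H = cache["H_final"]
    manual = np.stack(
        [
            H[0, : g1.num_nodes].max(axis=0),
            H[1, : g2.num_nodes].max(axis=0),
        ]
    )
    assert np.allclose(cache["pooled"], manual)


def test_siamese_shared_weights_bit_identical(rng):
    enc = GinEncoder(GIN_CFG, rng)
    g = smiles_to_graph("CCN")
    assert np.array_equal(encode_graph(g, enc), encode_graph(g, enc))


def test_gin_gradients_match_finite_differences(rng):
    enc = GinEncoder(
        GinEncoderConfig(num_layers=2, hidden_dim=5, readout_hidden=4, output_dim=3),
        rng,
    )
    graphs = [smiles_to_graph(s) for s in ("CCO", "c1ccccc1")]
    X, A, mask = batch_graphs(graphs)
    W = rng.normal(size=(2, 3))

    def loss():
        out, _ = enc.forward(X, A, mask)
        return float((out * W).sum())

    enc.zero_grad()
    _, cache = enc.forward(X, A, mask)
    enc.backward(cache, W)
    for name, p in enc.params.items():
        flat = np.atleast_1d(p).reshape(-1)
        gflat = np.atleast_1d(enc.grads[name]).reshape(-1)
        for i in rng.choice(flat.size, size=min(3, flat.size), replace=False):
            orig = flat[i]
            h = 1e-6
            flat[i] = orig + h
            lp = loss()
            flat[i] = orig - h
            lm = loss()
            flat[i] = orig
            num = (lp - lm) / (2 * h)
            assert abs(num - gflat[i]) < 1e-5 * max(1.0, abs(num)), name


# ---------------------------------------------------------------------------
# sequence encoder


def test_lookup_mean_and_projection():
    prov = KmerLookupProvider(["A", "B"], embedding_dim=2, k=1)
    prov.table[prov.vocab["A"]] = [1.0, 0.0]
    prov.table[prov.vocab["B"]] = [0.0, 1.0]
    cfg = SequenceEncoderConfig(embedding_dim=2, output_dim=1)
    enc = SequenceEncoder(cfg, prov, np.random.default_rng(0))
    # identity-like projection: take first coordinate
    enc.params["proj.W"][...] = np.array([[1.0], [0.0]])
    enc.params["proj.b"][...] = 0.0
    out = encode_sequence("AAB", prov, enc)
    assert np.allclose(out, [2.0 / 3.0])


def test_lookup_provider_order_invariance(rng):
    prov = KmerLookupProvider.fit(["ACDEFG"], 4, k=1, rng=rng)
    cfg = SequenceEncoderConfig(embedding_dim=4, output_dim=2)
    enc = SequenceEncoder(cfg, prov, rng)
    a = encode_sequence("ACDEFG", prov, enc)
    b = encode_sequence("GFEDCA", prov, enc)
    assert np.allclose(a, b)


def test_length_one_sequence_is_projected_token():
    prov = KmerLookupProvider(["A"], embedding_dim=3, k=1)
    cfg = SequenceEncoderConfig(embedding_dim=3, output_dim=2)
    enc = SequenceEncoder(cfg, prov, np.random.default_rng(0))
    out = encode_sequence("A", prov, enc)
    expect = prov.table[prov.vocab["A"]] @ enc.params["proj.W"] + enc.params["proj.b"]
    assert np.allclose(out, expect)


def test_counts_path_matches_per_sequence_path(small_world):
    prov = KmerLookupProvider.fit(small_world.proteins.values(), 8, k=3)
    cfg = SequenceEncoderConfig(embedding_dim=8, output_dim=4)
    enc = SequenceEncoder(cfg, prov, np.random.default_rng(3))
    seqs = list(small_world.proteins.values())[:10]
    counts = np.stack([prov.token_counts(s) for s in seqs])
    batched, _ = enc.forward_counts(counts)
    for i, s in enumerate(seqs):
        assert np.allclose(batched[i], encode_sequence(s, prov, enc), atol=1e-10)


def test_empty_sequence_rejected():
    prov = KmerLookupProvider(["A"], embedding_dim=2, k=1)
    cfg = SequenceEncoderConfig(embedding_dim=2, output_dim=1)
    enc = SequenceEncoder(cfg, prov, np.random.default_rng(0))
    with pytest.raises(ValueError):
        encode_sequence("", prov, enc)


def test_vocabulary_pruning_by_document_frequency():
    prov = KmerLookupProvider.fit(
        ["AAAB", "AAAC", "AAAD"], 2, k=3, min_sequences=2
    )
    assert "AAA" in prov.vocab
    assert "AAB" not in prov.vocab  # appears in one sequence only


def test_precomputed_provider_contract():
    emb = {"MKV": np.arange(6.0).reshape(3, 2)}
    prov = PrecomputedEmbeddingProvider(emb)
    assert prov.embedding_dim == 2
    assert prov.embed("MKV").shape == (3, 2)
    with pytest.raises(KeyError):
        prov.embed("XXXX")


def test_projection_must_reduce_dimension():
    with pytest.raises(ValueError):
        SequenceEncoderConfig(embedding_dim=8, output_dim=8)


# ---------------------------------------------------------------------------
# encoder state / checkpoints


def test_checkpoint_round_trip_bit_exact(tmp_path, rng):
    enc = GinEncoder(GIN_CFG, rng)
    state = EncoderState.from_encoder(enc, meta={"task": "cci"})
    path = tmp_path / "enc.npz"
    state.save(path)
    loaded = EncoderState.load(path)
    assert loaded.fingerprint == state.fingerprint
    assert loaded.meta["task"] == "cci"
    for k, v in state.params.items():
        assert np.array_equal(loaded.params[k], v)
    # applying the loaded state reproduces identical encodings
    enc2 = GinEncoder(GIN_CFG, np.random.default_rng(999))
    loaded.apply_to(enc2)
    g = smiles_to_graph("CCO")
    assert np.array_equal(encode_graph(g, enc), encode_graph(g, enc2))


def test_fingerprint_mismatch_names_fields(rng):
    enc = GinEncoder(GIN_CFG, rng)
    state = EncoderState.from_encoder(enc)
    other = GinEncoderConfig(
        num_layers=4, hidden_dim=12, readout_hidden=10, output_dim=6
    )
    with pytest.raises(FingerprintMismatchError, match="num_layers"):
        state.check_compatible(other)
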