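"""Graph-view encoder: projection, attention oracle, readout, invariance."""

import numpy as np
import pytest

from crossddi.autodiff import Tensor
from crossddi.graph_encoder import GraphEncoder, GraphEncoderConfig, graph_readout
from crossddi.molgraph import FeatureVocab, brics_decompose, parse_smiles
from crossddi.transformer import init_attention, multi_head_self_attention
from crossddi.synthetic import gen_molecules


def loop_attention_oracle(x, wq, wk, wv, wo, heads):
    """Literal nested-loop multi-head self-attention: per head i,
    Q=XWq, K=XWk, V=XWv, softmax(QK^T/sqrt(dk))V, heads concatenated, times Wo."""
    t, d = x.shape
    d_k = d // heads
    head_outputs = []
    for i in range(heads):
        cols = slice(i * d_k, (i + 1) * d_k)
        q, k, v = x @ wq[:, cols], x @ wk[:, cols], x @ wv[:, cols]
        out = np.zeros((t, d_k))
        for row in range(t):
            scores = np.array([q[row] @ k[col] for col in range(t)]) / np.sqrt(d_k)
            scores = np.exp(scores - scores.max())
            weights = scores / scores.sum()
            for col in range(t):
                out[row] += weights[col] * v[col]
        head_outputs.append(out)
    return np.concatenate(head_outputs, axis=1) @ wo


def mhsa(x, params, heads, mask=None):
    out = multi_head_self_attention(
        Tensor(x[None]), params, "attn", heads, mask=mask
    )
    return out.data[0]


@pytest.fixture(scope="module")
def vocab():
    return FeatureVocab()


@pytest.fixture(scope="module")
def encoder(vocab):
    return GraphEncoder(vocab, GraphEncoderConfig(d=8, heads=2, layers=2),
                        np.random.default_rng(7))


def identity_params(d):
    eye = np.eye(d)
    return {f"attn.{name}": Tensor(eye.copy()) for name in ("Wq", "Wk", "Wv", "Wo")}


class TestAttention:
    def test_single_token_identity_weights_is_identity(self):
        x = np.random.default_rng(0).normal(size=(1, 4))
        np.testing.assert_allclose(mhsa(x, identity_params(4), heads=1), x, atol=1e-12)

    def test_identical_rows_give_identical_outputs(self):
        row = np.random.default_rng(1).normal(size=4)
        x = np.stack([row, row])
        out = mhsa(x, identity_params(4), heads=1)
        np.testing.assert_allclose(out[0], out[1], atol=1e-12)

    def test_matches_loop_oracle_on_random_draws(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            t = int(rng.integers(1, 7))
            heads = int(rng.choice([1, 2, 4]))
            d = heads * int(rng.integers(1, 5))
            x = rng.normal(size=(t, d))
            mats = {f"attn.{n}": Tensor(rng.normal(size=(d, d)))
                    for n in ("Wq", "Wk", "Wv", "Wo")}
            expected = loop_attention_oracle(
                x, *(mats[f"attn.{n}"].data for n in ("Wq", "Wk", "Wv", "Wo")), heads
            )
            np.testing.assert_allclose(mhsa(x, mats, heads), expected, atol=1e-6)

    def test_softmax_rows_sum_to_one(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            scores = Tensor(rng.normal(scale=5.0, size=(2, 3, 6, 6)))
            p = scores.softmax().data
            assert (p >= 0).all()
            np.testing.assert_allclose(p.sum(axis=-1), 1.0, atol=1e-6)

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(9)
        params = init_attention(rng, 8, "attn")
        for _ in range(50):
            x = rng.normal(size=(6, 8))
            perm = rng.permutation(6)
            out = mhsa(x, params, heads=2)
            out_perm = mhsa(x[perm], params, heads=2)
            np.testing.assert_allclose(out_perm, out[perm], atol=1e-10)

    def test_masked_keys_are_ignored(self):
        rng = np.random.default_rng(5)
        params = init_attention(rng, 8, "attn")
        x = rng.normal(size=(4, 8))
        mask = np.array([[True, True, True, False]])
        out_masked = multi_head_self_attention(
            Tensor(x[None]), params, "attn", 2, mask=mask
        ).data[0]
        out_short = mhsa(x[:3], params, heads=2)
        np.testing.assert_allclose(out_masked[:3], out_short, atol=1e-10)


class TestProjectAndConcat:
    def test_output_shape(self, encoder, vocab):
        x_v = np.zeros((2, vocab.d_v)); x_v[0, 1] = x_v[1, 2] = 1
        x_e = np.zeros((1, vocab.d_e)); x_e[0, 0] = 1
        assert encoder.project_and_concat(x_v, x_e).shape == (3, 8)

    def test_rows_are_projection_rows(self, encoder, vocab):
        x_v = np.zeros((2, vocab.d_v)); x_v[0, 1] = x_v[1, 3] = 1
        x_e = np.zeros((1, vocab.d_e)); x_e[0, 2] = 1
        out = encoder.project_and_concat(x_v, x_e).data
        np.testing.assert_allclose(out[0], encoder.params["graph.node_proj"].data[1])
        np.testing.assert_allclose(out[1], encoder.params["graph.node_proj"].data[3])
        np.testing.assert_allclose(out[2], encoder.params["graph.edge_proj"].data[2])

    def test_zero_features_give_zero_tokens(self, encoder, vocab):
        out = encoder.project_and_concat(
            np.zeros((2, vocab.d_v)), np.zeros((2, vocab.d_e))
        )
        np.testing.assert_array_equal(out.data, 0.0)

    def test_dimension_mismatch_raises(self, encoder):
        with pytest.raises(ValueError, match="expected D_V"):
            encoder.project_and_concat(np.zeros((2, 3)), np.zeros((1, 4)))

    def test_edge_free_subgraph_yields_node_rows_only(self, encoder, vocab):
        x_v = np.zeros((2, vocab.d_v)); x_v[:, 1] = 1
        assert encoder.project_and_concat(x_v, np.zeros((0, vocab.d_e))).shape == (2, 8)


class TestGraphReadout:
    def test_single_pharmacophore_is_row_mean(self, rng):
        x = rng.normal(size=(5, 4))
        np.testing.assert_allclose(graph_readout([Tensor(x)]).data, x.mean(axis=0))

    def test_two_pharmacophores_average_pooled_vectors(self, rng):
        u, v = rng.normal(size=(3, 4)), rng.normal(size=(6, 4))
        out = graph_readout([Tensor(u), Tensor(v)]).data
        np.testing.assert_allclose(out, (u.mean(0) + v.mean(0)) / 2)

    def test_order_invariance(self, rng):
        mats = [Tensor(rng.normal(size=(k + 2, 4))) for k in range(4)]
        np.testing.assert_allclose(
            graph_readout(mats).data, graph_readout(mats[::-1]).data
        )

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError, match="N >= 1"):
            graph_readout([])

    @pytest.mark.parametrize("mode", ["sum", "max"])
    def test_alternative_modes(self, mode, rng):
        x = rng.normal(size=(3, 4))
        expected = x.sum(axis=0) if mode == "sum" else x.max(axis=0)
        np.testing.assert_allclose(graph_readout([Tensor(x)], mode).data, expected)


class TestMoleculeEncoding:
    def test_embedding_invariant_to_input_atom_ordering(self, encoder):
        # the same molecule written with different atom orders/ring starts
        variants = ["CC(=O)Oc1ccccc1C(=O)O", "OC(=O)c1ccccc1OC(C)=O",
                    "O=C(O)c1ccccc1OC(C)=O"]
        zs = [
            encoder.encode_molecule(brics_decompose(parse_smiles(s))).data
            for s in variants
        ]
        np.testing.assert_allclose(zs[0], zs[1], atol=1e-8)
        np.testing.assert_allclose(zs[0], zs[2], atol=1e-8)

    def test_batched_path_matches_reference_path(self, encoder):
        drugs = gen_molecules(8, seed=13)
        decomposed = [brics_decompose(parse_smiles(s)) for s in drugs["smiles"]]
        batch = encoder.encode_batch([encoder.prepare(d) for d in decomposed])
        for row, dec in enumerate(decomposed):
            single = encoder.encode_molecule(dec)
            np.testing.assert_allclose(batch.data[row], single.data, atol=1e-9)

    def test_determinism(self, encoder):
        dec = brics_decompose(parse_smiles("CCN(CC)C(=O)c1ccccc1"))
        a = encoder.encode_molecule(dec).data
        b = encoder.encode_molecule(dec).data
        np.testing.assert_array_equal(a, b)
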