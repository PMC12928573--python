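"""Contrastive loss, fusion and prediction-head contracts."""

import math

import numpy as np
import pytest

from crossddi.autodiff import Tensor, grad_check
from crossddi.core import (
    ContrastiveConfig,
    CrossAttentionFusion,
    FusionConfig,
    PredictionHead,
    ViewPair,
    bce_loss,
    contrastive_loss_batch,
    contrastive_loss_pair,
    cosine_sim,
    supervised_loss,
    total_objective,
)


class TestCosine:
    def test_self_similarity_is_one(self, rng):
        v = rng.normal(size=6)
        assert cosine_sim(v, v) == pytest.approx(1.0)
        assert cosine_sim(v, -v) == pytest.approx(-1.0)

    def test_orthogonal_vectors(self):
        assert cosine_sim([1.0, 0.0], [0.0, 1.0]) == pytest.approx(0.0)

    def test_scale_invariance(self, rng):
        u, v = rng.normal(size=5), rng.normal(size=5)
        assert cosine_sim(3.7 * u, 0.2 * v) == pytest.approx(cosine_sim(u, v))

    def test_zero_norm_is_an_error(self):
        with pytest.raises(ValueError, match="zero-norm"):
            cosine_sim(np.zeros(3), np.ones(3))


def pair(z_a, h_a, z_b, h_b):
    return (ViewPair("A", np.asarray(z_a, float), np.asarray(h_a, float)),
            ViewPair("B", np.asarray(z_b, float), np.asarray(h_b, float)))


class TestPairLoss:
    def test_all_views_identical_gives_log2(self):
        v = np.array([1.0, 1.0]) / math.sqrt(2)
        a, b = pair(v, v, v, v)
        assert contrastive_loss_pair(a, b, ContrastiveConfig(tau=1.0)) == pytest.approx(
            math.log(2.0)
        )

    @pytest.mark.parametrize(
        "tau, expected", [(1.0, math.log(2) - 1.0), (0.5, math.log(2) - 2.0)]
    )
    def test_orthogonal_drugs_hand_values(self, tau, expected):
        a, b = pair([1, 0], [1, 0], [0, 1], [0, 1])
        assert contrastive_loss_pair(a, b, ContrastiveConfig(tau=tau)) == pytest.approx(
            expected
        )

    def test_symmetry_under_drug_swap(self, rng):
        a, b = pair(*(rng.normal(size=4) for _ in range(4)))
        cfg = ContrastiveConfig(tau=0.7)
        assert contrastive_loss_pair(a, b, cfg) == pytest.approx(
            contrastive_loss_pair(b, a, cfg)
        )

    def test_scale_invariance_of_embeddings(self, rng):
        vecs = [rng.normal(size=4) for _ in range(4)]
        a, b = pair(*vecs)
        a2, b2 = pair(vecs[0] * 10, vecs[1] * 0.01, vecs[2] * 3, vecs[3] * 7)
        cfg = ContrastiveConfig(tau=0.5)
        assert contrastive_loss_pair(a2, b2, cfg) == pytest.approx(
            contrastive_loss_pair(a, b, cfg), abs=1e-6
        )

    def test_nonpositive_temperature_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            ContrastiveConfig(tau=0.0)


class TestBatchLoss:
    def test_two_drug_batch_equals_pair_formula(self, rng):
        for _ in range(20):
            z = rng.normal(size=(2, 8))
            h = rng.normal(size=(2, 8))
            batch = float(contrastive_loss_batch(Tensor(z), Tensor(h)).data)
            scalar = contrastive_loss_pair(
                ViewPair("a", z[0], h[0]), ViewPair("b", z[1], h[1])
            )
            assert batch == pytest.approx(scalar, abs=1e-9)

    def test_three_drug_batch_is_mean_of_pairwise(self, rng):
        z = rng.normal(size=(3, 6))
        h = rng.normal(size=(3, 6))
        cfg = ContrastiveConfig(tau=0.8)
        batch = float(contrastive_loss_batch(Tensor(z), Tensor(h), cfg).data)
        pairs = [
            contrastive_loss_pair(ViewPair(str(i), z[i], h[i]),
                                  ViewPair(str(j), z[j], h[j]), cfg)
            for i, j in [(0, 1), (0, 2), (1, 2)]
        ]
        assert batch == pytest.approx(np.mean(pairs), abs=1e-9)

    def test_vectorized_matches_scalar_oracle_many_draws(self):
        rng = np.random.default_rng(2024)
        for d in (2, 8, 64):
            for tau in (0.1, 0.5, 1.0):
                cfg = ContrastiveConfig(tau=tau)
                for _ in range(10):
                    z, h = rng.normal(size=(2, 2, d))
                    batch = float(contrastive_loss_batch(Tensor(z), Tensor(h), cfg).data)
                    scalar = contrastive_loss_pair(
                        ViewPair("a", z[0], h[0]), ViewPair("b", z[1], h[1]), cfg
                    )
                    assert batch == pytest.approx(scalar, abs=1e-6)

    def test_positive_pair_similarity_decreases_loss(self, rng):
        # push z_a toward h_a while holding everything else fixed
        h_a = np.array([1.0, 0.0]); rest = rng.normal(size=(2, 2))
        cfg = ContrastiveConfig(tau=0.5)

        def loss(alignment):
            z_a = np.array([math.cos(alignment), math.sin(alignment)])
            return contrastive_loss_pair(
                ViewPair("a", z_a, h_a), ViewPair("b", rest[0], rest[1]), cfg
            )

        angles = np.linspace(1.5, 0.0, 8)  # increasing cosine with h_a
        values = [loss(a) for a in angles]
        assert all(x > y for x, y in zip(values, values[1:]))

    def test_batch_mode_runs_and_is_minimized_by_alignment(self, rng):
        cfg = ContrastiveConfig(tau=0.5, mode="batch")
        z = rng.normal(size=(4, 8))
        aligned = float(contrastive_loss_batch(Tensor(z), Tensor(z.copy()), cfg).data)
        shuffled = float(
            contrastive_loss_batch(Tensor(z), Tensor(z[[1, 2, 3, 0]]), cfg).data
        )
        assert aligned < shuffled

    def test_single_drug_batch_rejected(self, rng):
        with pytest.raises(ValueError, match="at least 2"):
            contrastive_loss_batch(Tensor(rng.normal(size=(1, 4))),
                                   Tensor(rng.normal(size=(1, 4))))

    def test_loss_is_differentiable(self, rng):
        z = Tensor(rng.normal(size=(3, 4)), requires_grad=True)
        h = Tensor(rng.normal(size=(3, 4)), requires_grad=True)
        assert grad_check(lambda: contrastive_loss_batch(z, h), {"z": z, "h": h}) < 1e-5


class TestFusion:
    def test_identity_params_fixed_point(self):
        cfg = FusionConfig(d=4, heads=1)
        fusion = CrossAttentionFusion(cfg, np.random.default_rng(0))
        eye = np.eye(4)
        for name in ("Wq", "Wk", "Wv", "Wp"):
            fusion.params[f"fuse.{name}"].data = eye.copy()
        v = np.array([[0.3, -1.2, 0.7, 2.0]])
        fused = fusion.fuse(Tensor(v), Tensor(v.copy()))
        np.testing.assert_allclose(fused.data, v, atol=1e-12)

    def test_output_width_is_fused_width(self, rng):
        fusion = CrossAttentionFusion(FusionConfig(d=8, d_f=5, heads=2),
                                      np.random.default_rng(1))
        out = fusion.fuse(Tensor(rng.normal(size=(3, 8))), Tensor(rng.normal(size=(3, 8))))
        assert out.shape == (3, 5)

    def test_deterministic(self, rng):
        fusion = CrossAttentionFusion(FusionConfig(d=8), np.random.default_rng(2))
        z, h = rng.normal(size=(2, 4, 8))
        a = fusion.fuse(Tensor(z), Tensor(h)).data
        b = fusion.fuse(Tensor(z), Tensor(h)).data
        np.testing.assert_array_equal(a, b)

    def test_shape_mismatch_rejected(self, rng):
        fusion = CrossAttentionFusion(FusionConfig(d=8), np.random.default_rng(2))
        with pytest.raises(ValueError, match="differ"):
            fusion.fuse(Tensor(rng.normal(size=(3, 8))), Tensor(rng.normal(size=(2, 8))))


class TestPredictionHead:
    def test_zero_final_layer_gives_half(self, rng):
        head = PredictionHead(4, np.random.default_rng(0))
        last = head.n_layers - 1
        head.params[f"head.W{last}"].data[:] = 0.0
        head.params[f"head.b{last}"].data[:] = 0.0
        y = head.predict(Tensor(rng.normal(size=(5, 4))), Tensor(rng.normal(size=(5, 4))))
        np.testing.assert_allclose(y.data, 0.5)

    def test_outputs_strictly_inside_unit_interval(self, rng):
        head = PredictionHead(6, np.random.default_rng(1))
        y = head.predict(Tensor(rng.normal(size=(10, 6)) * 5),
                         Tensor(rng.normal(size=(10, 6)) * 5))
        assert ((y.data > 0) & (y.data < 1)).all()

    def test_monotone_in_logit_for_linear_head(self):
        head = PredictionHead(1, np.random.default_rng(2), hidden=())
        head.params["head.W0"].data[:] = 1.0
        head.params["head.b0"].data[:] = 0.0
        inputs = np.linspace(-2, 2, 9).reshape(-1, 1)
        y = head.predict(Tensor(inputs), Tensor(np.zeros_like(inputs))).data
        assert (np.diff(y) > 0).all()

    def test_concatenation_order_matters(self, rng):
        head = PredictionHead(3, np.random.default_rng(3))
        a, b = Tensor(rng.normal(size=(4, 3))), Tensor(rng.normal(size=(4, 3)))
        assert not np.allclose(head.predict(a, b).data, head.predict(b, a).data)


class TestLosses:
    def test_bce_hand_values(self):
        assert supervised_loss(0.5, 1) == pytest.approx(math.log(2.0))
        assert supervised_loss([0.5, 0.5], [1, 0]) == pytest.approx(math.log(2.0))
        assert supervised_loss(1 - 1e-12, 1) == pytest.approx(0.0, abs=1e-9)

    def test_bce_batch_is_mean(self, rng):
        p = rng.uniform(0.05, 0.95, size=6)
        y = rng.integers(0, 2, size=6)
        singles = [supervised_loss(pi, yi) for pi, yi in zip(p, y)]
        assert supervised_loss(p, y) == pytest.approx(np.mean(singles))

    def test_bce_domain_enforced(self):
        with pytest.raises(ValueError, match="strictly"):
            supervised_loss(1.0, 1)

    def test_tensor_bce_matches_scalar(self, rng):
        p = rng.uniform(0.1, 0.9, size=5)
        y = rng.integers(0, 2, size=5).astype(float)
        assert float(bce_loss(Tensor(p), y).data) == pytest.approx(supervised_loss(p, y))

    def test_total_objective_schedules(self):
        assert total_objective(0.7, 0.3, phase="joint", lambda_cl=1.0) == pytest.approx(1.0)
        assert total_objective(0.7, 0.3, phase="joint", lambda_cl=0.0) == pytest.approx(0.7)
        assert total_objective(0.7, 0.3, phase="contrastive") == pytest.approx(0.3)
        assert total_objective(0.7, 0.3, phase="supervised") == pytest.approx(0.7)
        with pytest.raises(ValueError, match="non-negative"):
            total_objective(0.7, 0.3, phase="joint", lambda_cl=-1.0)
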