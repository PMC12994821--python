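"""Integrated gradients and downstream ranking/network analyses."""

import numpy as np
import pandas as pd
import pytest

from aetrans.attribution import (
    AttributionError,
    aggregate_and_rank,
    coexpression_network,
    informative_recovery,
    integrated_gradients,
    pair_integrated_gradients,
)
from aetrans.autograd import Tensor
from aetrans.data import OmicsMatrix


class TestIntegratedGradients:
    def test_input_equal_to_baseline_scores_zero(self):
        f = lambda t: (t * 2.0).sum(axis=-1)
        x = np.full(5, 0.7)
        scores = integrated_gradients(f, x, baseline=x.copy(), n_steps=8)
        np.testing.assert_array_equal(scores, np.zeros(5))

    @pytest.mark.parametrize("n_steps", [1, 10, 100])
    @pytest.mark.parametrize("rule", ["midpoint", "right"])
    def test_linear_model_matches_closed_form(self, n_steps, rule):
        """For F(x) = w.x the exact IG score is w_i * (x_i - x'_i) under any
        gradient-averaging quadrature."""
        rng = np.random.default_rng(3)
        w = rng.normal(size=7)
        x = rng.normal(size=7)
        f = lambda t: (t * w).sum(axis=-1)
        scores = integrated_gradients(f, x, "zeros", n_steps, rule)
        np.testing.assert_allclose(scores, w * x, rtol=1e-6)

    def test_quadratic_right_endpoint_matches_printed_summation(self):
        """F(x)=x^2, x=1, x'=0: the right-endpoint sum at n=1 evaluates the
        gradient at the endpoint only, giving 2; at large n it converges to
        F(1)-F(0)=1."""
        f = lambda t: (t**2).sum(axis=-1)
        s1 = integrated_gradients(f, np.array([1.0]), "zeros", 1, rule="right")
        assert s1[0] == pytest.approx(2.0)
        s_big = integrated_gradients(f, np.array([1.0]), "zeros", 4096, rule="right")
        assert s_big[0] == pytest.approx(1.0, abs=1e-3)

    def test_quadratic_against_fine_riemann_oracle(self):
        """Scores at moderate n agree with an independent fine-grid integral."""
        rng = np.random.default_rng(0)
        a = rng.normal(size=4)

        def f(t):
            return ((t**2) * a).sum(axis=-1)

        x = rng.normal(size=4)
        # oracle: integral of dF/dx_i along path = 2 a_i x_i * int_0^1 alpha dalpha
        fine = np.linspace(0, 1, 200_001)[1:]
        oracle = x * np.array([np.mean(2 * a[i] * fine * x[i]) for i in range(4)])
        scores = integrated_gradients(f, x, "zeros", 64)
        np.testing.assert_allclose(scores, oracle, rtol=1e-3)

    def test_invalid_steps_raise(self):
        with pytest.raises(AttributionError):
            integrated_gradients(lambda t: t.sum(axis=-1), np.ones(3), "zeros", 0)

    def test_completeness_improves_with_steps_on_nonlinear_model(self):
        f = lambda t: (t**3).sum(axis=-1).sigmoid()
        x = np.array([0.9, -0.4, 0.6])

        def gap(n):
            s = integrated_gradients(f, x, "zeros", n)
            fx = f(Tensor(x[None, :])).data[0]
            f0 = f(Tensor(np.zeros((1, 3)))).data[0]
            return abs(s.sum() - (fx - f0))

        assert gap(256) < gap(4)


class TestPairAttribution:
    def test_pair_scores_zero_when_inputs_equal_baseline(self, tiny_model):
        x = np.zeros((2, 30))
        raw = pair_integrated_gradients(tiny_model, x, x, "zeros", n_steps=4)
        np.testing.assert_array_equal(raw["rna"], 0.0)
        np.testing.assert_array_equal(raw["meth"], 0.0)
        np.testing.assert_allclose(raw["completeness_gap"], 0.0, atol=1e-12)

    def test_completeness_gap_small_on_untrained_model(self, tiny_model):
        rng = np.random.default_rng(0)
        raw = pair_integrated_gradients(
            tiny_model, rng.normal(size=(3, 30)), rng.normal(size=(3, 30)),
            "zeros", n_steps=128,
        )
        assert raw["completeness_gap"].max() < 1e-3


class TestAggregation:
    def test_single_sample_aggregate_is_its_scores(self):
        res = aggregate_and_rank(np.array([[1.0, -2.0]]), np.array([[0.5]]),
                                 ["g1", "g2"], ["g1"])
        assert res.table["score"].tolist() == [1.0, 2.0, 0.5]

    def test_opposite_scores_cancel_under_signed_mean_only(self):
        rna = np.array([[3.0], [-3.0]])
        meth = np.array([[0.0], [0.0]])
        abs_res = aggregate_and_rank(rna, meth, ["g"], ["g"], "mean_absolute")
        sgn_res = aggregate_and_rank(rna, meth, ["g"], ["g"], "signed_mean")
        assert abs_res.table["score"].iloc[0] == 3.0
        assert sgn_res.table["score"].iloc[0] == 0.0

    def test_dominant_feature_ranks_first(self):
        rng = np.random.default_rng(0)
        rna = rng.normal(size=(10, 5)) * 0.1
        rna[:, 3] = 5.0
        res = aggregate_and_rank(rna, rng.normal(size=(10, 2)) * 0.1,
                                 [f"g{i}" for i in range(5)], ["h0", "h1"])
        assert res.ranking[0] == ("g3", "expression")

    def test_empty_input_raises(self):
        with pytest.raises(AttributionError):
            aggregate_and_rank(np.empty((0, 3)), np.empty((0, 2)),
                               ["a", "b", "c"], ["d", "e"])

    def test_recovery_counts_per_modality_hits(self):
        rna = np.array([[4.0, 3.0, 0.1, 0.1]])
        meth = np.array([[0.1, 5.0, 0.1, 0.1]])
        res = aggregate_and_rank(rna, meth, list("abcd"), list("wxyz"))
        # informative: rna 'a' (rank 1 of 4), meth 'x' (rank 1) -> full recovery
        assert informative_recovery(res, ["a"], ["x"], multiplier=2) == 1.0
        assert informative_recovery(res, ["c"], ["z"], multiplier=1) == 0.0


class TestCoexpressionNetwork:
    def make_matrix(self, values, feats):
        values = np.asarray(values, dtype=float)
        return OmicsMatrix(
            values=values,
            sample_ids=[f"s{i}" for i in range(values.shape[0])],
            feature_ids=feats,
            labels=[1] * (values.shape[0] // 2) + [0] * (values.shape[0] - values.shape[0] // 2),
            modality="expression",
        )

    def test_duplicated_feature_gives_perfect_edge(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=20)
        m = self.make_matrix(np.column_stack([x, x, rng.normal(size=20)]),
                             ["a", "a_copy", "b"])
        net = coexpression_network(m, ["a", "a_copy", "b"], 0.75)
        edges = net["edges"]
        assert len(edges) == 1
        assert edges.iloc[0]["r"] == pytest.approx(1.0)

    def test_independent_noise_produces_no_edges(self):
        rng = np.random.default_rng(1)
        m = self.make_matrix(rng.normal(size=(200, 10)), [f"g{i}" for i in range(10)])
        net = coexpression_network(m, m.feature_ids, 0.75)
        assert len(net["edges"]) == 0

    def test_shared_factor_forms_one_component(self):
        rng = np.random.default_rng(2)
        factor = rng.normal(size=100)
        loading = 0.95
        trio = np.column_stack([
            loading * factor + np.sqrt(1 - loading**2) * rng.normal(size=100)
            for _ in range(3)
        ])
        noise = rng.normal(size=(100, 2))
        m = self.make_matrix(np.column_stack([trio, noise]),
                             ["t1", "t2", "t3", "n1", "n2"])
        net = coexpression_network(m, m.feature_ids, 0.75)
        nodes = net["nodes"].set_index("feature_id")
        assert len(set(nodes.loc[["t1", "t2", "t3"], "component"])) == 1
        assert nodes.loc["t1", "degree"] == 2
        # correlations verified directly against numpy
        r12 = np.corrcoef(trio[:, 0], trio[:, 1])[0, 1]
        assert r12 > 0.75

    def test_constant_feature_excluded_with_warning(self):
        rng = np.random.default_rng(3)
        m = self.make_matrix(
            np.column_stack([np.full(10, 2.0), rng.normal(size=10)]), ["const", "g"]
        )
        with pytest.warns(UserWarning, match="constant"):
            net = coexpression_network(m, ["const", "g"], 0.75)
        assert "const" not in set(net["nodes"]["feature_id"])

    def test_too_few_samples_raise(self):
        m = self.make_matrix(np.zeros((2, 2)), ["a", "b"])
        with pytest.raises(AttributionError):
            coexpression_network(m, ["a", "b"])
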