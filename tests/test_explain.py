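"""Shapley attribution correctness and the individual habituation response."""

from itertools import permutations

import numpy as np
import pytest

from habitu.explain import (
    AttributionVector,
    attribute,
    global_ranking,
    habituation_response,
    response_vs_pclm,
    shapley_exact,
    shapley_sampled,
    HabituationResponse,
)


def brute_force_shapley(f, x, background):
    """Independent oracle: average marginal contribution over all m!
    feature orderings, coalition value = background-mean of the hybrid."""
    m = len(x)

    def value(subset):
        hybrid = background.copy()
        for j in subset:
            hybrid[:, j] = x[j]
        return f(hybrid).mean()

    phi = np.zeros(m)
    n_orders = 0
    for order in permutations(range(m)):
        n_orders += 1
        s = []
        prev = value(s)
        for j in order:
            s.append(j)
            cur = value(s)
            phi[j] += cur - prev
            prev = cur
    return phi / n_orders


class TestShapley:
    @staticmethod
    def setup_problem(m=3, n_bg=6, seed=0):
        rng = np.random.default_rng(seed)
        background = rng.normal(size=(n_bg, m))
        x = rng.normal(size=m)

        def f(X):
            return 1.0 / (1.0 + np.exp(-(X[:, 0] + 2.0 * X[:, 1] * X[:, 2 % m])))

        return f, x, background

    def test_exact_matches_brute_force(self):
        f, x, background = self.setup_problem()
        phi, base = shapley_exact(f, x, background)
        oracle = brute_force_shapley(f, x, background)
        np.testing.assert_allclose(phi, oracle, atol=1e-9)
        assert base == pytest.approx(f(background).mean())

    def test_linear_model_closed_form(self):
        rng = np.random.default_rng(1)
        m, c = 5, np.array([1.0, -2.0, 0.5, 0.0, 3.0])
        background = rng.normal(size=(30, m))
        x = rng.normal(size=m)
        phi, base = shapley_exact(lambda X: X @ c, x, background)
        np.testing.assert_allclose(phi, c * (x - background.mean(axis=0)), atol=1e-10)

    def test_constant_model_gives_zero(self):
        phi, base = shapley_exact(
            lambda X: np.full(len(X), 0.7), np.ones(4), np.zeros((5, 4))
        )
        np.testing.assert_allclose(phi, 0.0, atol=1e-12)
        assert base == pytest.approx(0.7)

    def test_sampled_converges_to_exact(self):
        f, x, background = self.setup_problem(m=6, n_bg=8, seed=2)
        phi_exact, _ = shapley_exact(f, x, background)
        rng = np.random.default_rng(7)
        phi_sampled, base = shapley_sampled(f, x, background, n_permutations=600, rng=rng)
        np.testing.assert_allclose(phi_sampled, phi_exact, atol=1e-2)

    def test_sampled_additivity_exact(self):
        f, x, background = self.setup_problem(m=6, n_bg=8, seed=3)
        rng = np.random.default_rng(0)
        phi, base = shapley_sampled(f, x, background, n_permutations=10, rng=rng)
        assert base + phi.sum() == pytest.approx(f(x[None, :])[0], abs=1e-12)


class TestFoldAttribution:
    def test_additivity_on_every_fold(self, ideal_cohort_matrix):
        from habitu.model import loo_evaluate

        cm, _ = ideal_cohort_matrix
        _, folds = loo_evaluate(cm, seed=1)
        for i, fold in enumerate(folds):
            att = attribute(fold, rng=np.random.default_rng(i))
            gap = abs(att.base_value + sum(att.phi.values()) - att.model_output)
            assert gap <= 1e-6 * max(1.0, abs(att.model_output))
            assert set(att.phi) == set(fold.selected_keys)


class TestAggregation:
    def test_ranking_uses_absolute_values(self):
        att = AttributionVector("p", {"a": 2.0, "b": -3.0}, 0.0, 0.0)
        r = global_ranking([att])
        assert list(r.per_key) == ["b", "a"]

    def test_opposite_signs_accumulate(self):
        atts = [
            AttributionVector("p", {"e/max_hr": 2.0}, 0.0, 0.0),
            AttributionVector("q", {"e/max_hr": -2.0}, 0.0, 0.0),
        ]
        assert global_ranking(atts).per_key["e/max_hr"] == 4.0

    def test_marker_groups_partition_keys(self):
        atts = [
            AttributionVector(
                "p", {"e/max_hr": 1.0, "f/max_hr": 2.0, "e/ebp": -4.0}, 0.0, 0.0
            )
        ]
        r = global_ranking(atts)
        assert r.per_marker["max_hr"] == 3.0 and r.per_marker["ebp"] == 4.0
        assert sum(r.per_marker.values()) == pytest.approx(sum(r.per_key.values()))


class TestHabituationResponse:
    def test_weighted_sum_arithmetic(self):
        att = AttributionVector("p", {"a": 0.5, "b": -0.25}, 0.0, 0.0)
        r = habituation_response({"a": 1.0, "b": -2.0}, att, pclm_score=40)
        assert r.value == pytest.approx(1.0 * 0.5 + (-2.0) * 0.25)

    def test_zero_weights_give_zero(self):
        att = AttributionVector("p", {"a": 0.0, "b": 0.0}, 0.5, 0.5)
        assert habituation_response({"a": 9.0, "b": -9.0}, att, 20).value == 0.0

    def test_key_mismatch_raises(self):
        att = AttributionVector("p", {"a": 0.5}, 0.0, 0.0)
        with pytest.raises(KeyError):
            habituation_response({"a": 1.0, "b": 2.0}, att, 40)

    def test_nonnegative_when_all_habituating(self):
        att = AttributionVector("p", {"a": -0.5, "b": 0.3}, 0.0, 0.0)
        r = habituation_response({"a": 1.0, "b": 0.2}, att, 50)
        assert r.value >= 0.0


class TestRegression:
    @staticmethod
    def responses(values, pclm):
        return [
            HabituationResponse(f"p{i}", v, s) for i, (v, s) in enumerate(zip(values, pclm))
        ]

    def test_perfect_linear_relation(self):
        r = response_vs_pclm(self.responses([0.0, 1.0, 2.0, 3.0], [20, 30, 40, 50]))
        assert r.correlation == pytest.approx(1.0)
        assert r.slope == pytest.approx(10.0)

    def test_preconditions(self):
        with pytest.raises(ValueError):
            response_vs_pclm(self.responses([0.0, 1.0], [20, 30]))
        with pytest.raises(ValueError):
            response_vs_pclm(self.responses([1.0, 1.0, 1.0], [20, 30, 40]))
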