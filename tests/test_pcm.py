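"""Closed-form PCM probabilities, curves, and the quadrature marginal
likelihood against independent adaptive-integration oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import integrate, stats
from scipy.special import expit

from rosali._engine import LikelihoodEngine
from rosali.data import ResponseData
from rosali.pcm import (
    ItemParameters,
    LatentDistribution,
    category_probabilities,
    curve_table,
    expected_response,
    marginal_loglik,
    response_variance,
)


def brute_probs(theta, thr):
    """Direct evaluation of the unnormalized terms exp(x*theta - sum(delta))."""
    cum = np.concatenate([[0.0], np.cumsum(thr)])
    terms = np.exp(np.arange(len(cum)) * theta - cum)
    return terms / terms.sum()


class TestCategoryProbabilities:
    def test_matches_direct_evaluation(self):
        p = category_probabilities(0.0, [-1.0, 0.0, 1.0])
        np.testing.assert_allclose(p, brute_probs(0.0, [-1, 0, 1]), atol=1e-14)
        np.testing.assert_allclose(
            p, [0.13447, 0.36553, 0.36553, 0.13447], atol=5e-6
        )

    def test_threshold_means_adjacent_categories_equiprobable(self):
        # at theta = delta_1 of a dichotomous item, P(0) = P(1) = 0.5
        p = category_probabilities(0.7, [0.7])
        np.testing.assert_allclose(p, [0.5, 0.5], atol=1e-14)

    def test_low_latent_level_prefers_lowest_category(self):
        # 4-category symptom item: at theta = -4, category 0 dominates
        p = category_probabilities(-4.0, [-1.5, 0.0, 1.5])
        assert p.argmax() == 0

    def test_dichotomous_reduces_to_rasch(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            th, d = rng.normal(size=2) * 2
            p = category_probabilities(th, [d])
            np.testing.assert_allclose(p[1], expit(th - d), rtol=1e-12)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(
        st.floats(-30, 30),
        st.lists(st.floats(-8, 8), min_size=1, max_size=6),
    )
    def test_simplex_property(self, theta, thresholds):
        p = category_probabilities(theta, thresholds)
        assert np.all(p >= 0)
        assert abs(p.sum() - 1.0) < 1e-12

    def test_rejects_nonfinite_inputs(self):
        with pytest.raises(ValueError):
            category_probabilities(np.nan, [0.0])
        with pytest.raises(ValueError):
            category_probabilities(0.0, [np.inf, 0.0])


class TestExpectedResponse:
    def test_symmetric_case_and_derived_value(self):
        assert expected_response(0.0, [-1, 0, 1]) == pytest.approx(1.5, abs=1e-12)
        # oracle: sum x * P(x) with the direct-evaluation probabilities
        oracle = float(np.arange(4) @ brute_probs(1.0, [-1, 0, 1]))
        assert expected_response(1.0, [-1, 0, 1]) == pytest.approx(oracle, abs=1e-14)
        assert oracle == pytest.approx(2.2203, abs=5e-5)

    def test_limits(self):
        assert expected_response(60.0, [-1, 0, 1]) == pytest.approx(3.0, abs=1e-9)
        assert expected_response(-60.0, [-1, 0, 1]) == pytest.approx(0.0, abs=1e-9)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        st.lists(st.floats(-4, 4), min_size=1, max_size=5),
        st.floats(-8, 8),
        st.floats(0.01, 4),
    )
    def test_strictly_increasing_in_theta(self, thresholds, theta, gap):
        lo = expected_response(theta, thresholds)
        hi = expected_response(theta + gap, thresholds)
        assert hi > lo

    def test_variance_oracle(self):
        p = brute_probs(0.0, [-1, 0, 1])
        x = np.arange(4)
        var = float(p @ x**2 - (p @ x) ** 2)
        assert response_variance(0.0, [-1, 0, 1]) == pytest.approx(var, abs=1e-14)
        assert var == pytest.approx(0.78788, abs=5e-6)


class TestCurveTable:
    def test_identical_thresholds_identical_curves(self):
        item = ItemParameters(
            "x", 4, {("G0", "T1"): [-1, 0, 1], ("G1", "T1"): [-1, 0, 1]}
        )
        tab = curve_table(item, [("G0", "T1"), ("G1", "T1")])
        a = tab[tab.group == "G0"].icc.to_numpy()
        b = tab[tab.group == "G1"].icc.to_numpy()
        assert np.max(np.abs(a - b)) == 0.0

    def test_uniform_offset_translates_icc_horizontally(self):
        c = 0.8
        grid = np.arange(-4, 4.01, 0.05)
        item = ItemParameters(
            "x",
            4,
            {("G0", "T1"): [-1, 0, 1], ("G1", "T1"): np.array([-1, 0, 1]) + c},
        )
        tab = curve_table(item, [("G0", "T1"), ("G1", "T1")], theta_grid=grid)
        base = tab[tab.group == "G0"]
        shifted = tab[tab.group == "G1"]
        # shifted curve at theta equals base curve at theta - c
        lhs = shifted.icc.to_numpy()[np.isin(np.round(grid, 4), np.round(grid + c, 4))]
        rhs = base.icc.to_numpy()[np.isin(np.round(grid + c, 4), np.round(grid, 4))]
        assert len(lhs) > 50
        np.testing.assert_allclose(lhs, rhs, atol=1e-10)

    def test_nonuniform_shift_changes_shape(self):
        item = ItemParameters(
            "x",
            4,
            {("G0", "T1"): [-1, 0, 1], ("G1", "T1"): [-2.2, 0.1, 0.9]},
        )
        tab = curve_table(item, [("G0", "T1"), ("G1", "T1")])
        a = tab[tab.group == "G0"]
        b = tab[tab.group == "G1"]
        # horizontal displacement at several ICC levels is non-constant
        disp = []
        for level in (0.8, 1.5, 2.2):
            ta = np.interp(level, a.icc, a.theta)
            tb = np.interp(level, b.icc, b.theta)
            disp.append(ta - tb)
        assert np.ptp(disp) > 0.1

    def test_unknown_cell_rejected(self):
        item = ItemParameters("x", 4, {("G0", "T1"): [-1, 0, 1]})
        with pytest.raises(KeyError):
            curve_table(item, [("G1", "T2")])


def adaptive_marginal_loglik(data, items, latent):
    """Independent oracle: per-person adaptive integration (quad/dblquad)."""
    def person_prob(i):
        glab = data.group_labels[data.groups[i]]
        if data.n_times == 1:
            tlab = data.time_labels[0]
            mu = latent.mu.get((glab, tlab), 0.0)
            sd = np.sqrt(latent.var[tlab])

            def f(th):
                pr = stats.norm.pdf(th, mu, sd)
                for j, it in enumerate(items):
                    x = data.responses[i, j, 0]
                    if x >= 0:
                        thr = (
                            it.thresholds[(glab, tlab)]
                            if isinstance(it.thresholds, dict)
                            else it.thresholds
                        )
                        pr *= brute_probs(th, thr)[x]
                return pr

            v, _ = integrate.quad(f, mu - 10 * sd, mu + 10 * sd, epsabs=1e-13)
            return v
        t1, t2 = data.time_labels
        mu1 = latent.mu.get((glab, t1), 0.0)
        mu2 = latent.mu.get((glab, t2), 0.0)
        cov = np.array(
            [
                [latent.var[t1], latent.cov_t1t2],
                [latent.cov_t1t2, latent.var[t2]],
            ]
        )
        mvn = stats.multivariate_normal([mu1, mu2], cov)

        def f(th2, th1):
            pr = mvn.pdf([th1, th2])
            for j, it in enumerate(items):
                for t, tlab in enumerate(data.time_labels):
                    x = data.responses[i, j, t]
                    if x >= 0:
                        thr = (
                            it.thresholds[(glab, tlab)]
                            if isinstance(it.thresholds, dict)
                            else it.thresholds
                        )
                        pr *= brute_probs([th1, th2][t], thr)[x]
            return pr

        s1, s2 = np.sqrt(np.diag(cov))
        v, _ = integrate.dblquad(
            f, mu1 - 8 * s1, mu1 + 8 * s1,
            lambda _: mu2 - 8 * s2, lambda _: mu2 + 8 * s2,
            epsabs=1e-11,
        )
        return v

    return float(sum(np.log(person_prob(i)) for i in range(data.n_persons)))


class TestMarginalLoglik:
    def test_empty_dataset_gives_zero(self):
        data = ResponseData(
            np.empty((0, 1, 1), dtype=int), np.empty(0, dtype=int),
            ["a"], [2], time_labels=("T1",),
        )
        items = [ItemParameters("a", 2, [0.0])]
        lat = LatentDistribution(mu={}, var={"T1": 1.0})
        assert marginal_loglik(data, items, lat) == 0.0

    def test_symmetric_dichotomous_item(self):
        # delta = 0, Theta ~ N(0,1): marginal P is 1/2 for either category
        for x in (0, 1):
            data = ResponseData(
                np.array([[[x]]]), [0], ["a"], [2], time_labels=("T1",)
            )
            items = [ItemParameters("a", 2, [0.0])]
            lat = LatentDistribution(mu={}, var={"T1": 1.0})
            ll = marginal_loglik(data, items, lat)
            assert ll == pytest.approx(np.log(0.5), abs=1e-10)

    def test_shifted_dichotomous_against_adaptive_oracle(self):
        # response 1 on a delta = 1 item: oracle integral of expit(th-1)*phi
        data = ResponseData(np.array([[[1]]]), [0], ["a"], [2], time_labels=("T1",))
        items = [ItemParameters("a", 2, [1.0])]
        lat = LatentDistribution(mu={}, var={"T1": 1.0})
        oracle, _ = integrate.quad(
            lambda th: expit(th - 1.0) * stats.norm.pdf(th), -12, 12, epsabs=1e-14
        )
        ll = marginal_loglik(data, items, lat, quadrature=50)
        assert ll == pytest.approx(np.log(oracle), abs=1e-8)
        assert np.log(oracle) == pytest.approx(-1.19315, abs=1e-5)

    def test_quadrature_order_guard(self, tiny_data):
        items = [ItemParameters(i, 4, [-1, 0, 1]) for i in "abc"]
        lat = LatentDistribution(
            mu={("G1", "T1"): 0.2, ("G0", "T2"): 0.1, ("G1", "T2"): 0.3},
            var={"T1": 1.0, "T2": 1.0},
            cov_t1t2=0.4,
        )
        with pytest.raises(ValueError):
            marginal_loglik(tiny_data, items, lat, quadrature=4)

    def test_nonpd_covariance_rejected(self, tiny_data):
        with pytest.raises(ValueError):
            LatentDistribution(
                mu={}, var={"T1": 1.0, "T2": 1.0}, cov_t1t2=1.5
            )

    def test_translation_invariance(self, tiny_data):
        """Shifting every threshold and every latent mean by c leaves the
        marginal likelihood unchanged."""
        eng = LikelihoodEngine(tiny_data, quadrature=25)
        rng = np.random.default_rng(7)
        thr = [np.sort(rng.normal(size=3)) for _ in range(3)]
        mu = np.array([[0.0, 0.3], [-0.4, 0.1]])
        var = np.array([1.0, 1.3])
        base = {
            (g, t): [thr[j] for j in range(3)] for g in (0, 1) for t in (0, 1)
        }
        ll0 = eng.compute(base, mu, var, 0.5).loglik
        for c in (-1.7, 0.9):
            shifted = {
                (g, t): [thr[j] + c for j in range(3)]
                for g in (0, 1)
                for t in (0, 1)
            }
            ll1 = eng.compute(shifted, mu + c, var, 0.5).loglik
            assert ll1 == pytest.approx(ll0, abs=1e-8)

    def test_quadrature_matches_adaptive_oracle_cross_sectional(self):
        rng = np.random.default_rng(21)
        resp = rng.integers(0, 4, size=(4, 3, 1))
        resp[0, 1, 0] = -1
        data = ResponseData(resp, [0, 1, 0, 1], ["a", "b", "c"], [4, 4, 4],
                            time_labels=("T1",))
        items = [
            ItemParameters(i, 4, np.sort(rng.normal(scale=1.2, size=3)))
            for i in "abc"
        ]
        lat = LatentDistribution(mu={("G1", "T1"): -0.7}, var={"T1": 1.4})
        ll = marginal_loglik(data, items, lat, quadrature=50)
        oracle = adaptive_marginal_loglik(data, items, lat)
        assert ll == pytest.approx(oracle, abs=1e-6)

    def test_quadrature_matches_adaptive_oracle_longitudinal(self, tiny_data):
        rng = np.random.default_rng(22)
        items = [
            ItemParameters(
                i,
                4,
                {
                    (g, t): np.sort(rng.normal(scale=1.1, size=3))
                    for g in ("G0", "G1")
                    for t in ("T1", "T2")
                },
            )
            for i in "abc"
        ]
        lat = LatentDistribution(
            mu={("G1", "T1"): -0.5, ("G0", "T2"): 0.2, ("G1", "T2"): -0.1},
            var={"T1": 1.0, "T2": 1.3},
            cov_t1t2=0.55,
        )
        ll = marginal_loglik(tiny_data, items, lat, quadrature=50)
        oracle = adaptive_marginal_loglik(tiny_data, items, lat)
        assert ll == pytest.approx(oracle, abs=1e-6)
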