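"""Constrained marginal-ML fitting: recovery, constraints, standard errors,
and likelihood-ratio bookkeeping."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from rosali.data import ResponseData
from rosali.design import ModelSpec, RsTerm
from rosali.model import (
    CrossSectionalPCM,
    LongitudinalPCM,
    likelihood_ratio_test,
)
from rosali.simulate import SimulationScenario, simulate_dataset


@pytest.fixture(scope="module")
def cs_fit(small_cs_data):
    data, sc = small_cs_data
    return CrossSectionalPCM(data, quadrature=15).fit()


@pytest.fixture(scope="module")
def long_fit(small_long_data):
    data, sc = small_long_data
    return LongitudinalPCM(data, quadrature=12).fit()


class TestCrossSectional:
    def test_group_effect_recovery(self, small_cs_data, cs_fit):
        data, sc = small_cs_data
        cs_fit.cov_params()
        mu1 = cs_fit.params["mu_G1_T1"]
        se = cs_fit.bse["mu_G1_T1"]
        assert abs(mu1 - (-0.6)) < 2.5 * se

    def test_threshold_recovery(self):
        """Averaged over replicates, thresholds and the group mean are
        recovered to within 0.15 on data simulated from a known model."""
        sc = SimulationScenario(
            name="recov", n_per_group=(250, 150), n_items=3,
            mu={("G1", "T1"): -0.6, ("G0", "T2"): 0.0, ("G1", "T2"): -0.6},
            missing_rate=0.0,
        )
        acc = []
        for r in range(20):
            data, _ = simulate_dataset(sc, seed=700 + r)
            fit = CrossSectionalPCM(data.at_time("T1"), quadrature=12).fit()
            acc.append(fit.params)
        mean_est = pd.concat(acc, axis=1).mean(axis=1)
        true = {"mu_G1_T1": -0.6}
        for j in range(3):
            for p in (1, 2, 3):
                true[f"delta_item{j + 1}_{p}"] = sc.base_thresholds[j][p - 1]
        for name, tv in true.items():
            assert abs(mean_est[name] - tv) < 0.15, name

    def test_reference_mean_fixed_and_variance_shared(self, cs_fit):
        names = list(cs_fit.params.index)
        assert "mu_G0_T1" not in names  # fixed at 0 by construction
        assert names.count("log_var") == 1  # one shared variance

    def test_all_dif_spec_has_no_group_mean(self, small_cs_data):
        data, _ = small_cs_data
        spec = ModelSpec.for_data(data, longitudinal=False).all_dif("free")
        fit = CrossSectionalPCM(data, spec, quadrature=12).fit()
        assert not any(n.startswith("mu_") for n in fit.params.index)

    def test_group_relabeling_negates_group_effect(self, small_cs_data):
        data, _ = small_cs_data
        df = data.to_dataframe()
        items = {it: 4 for it in data.item_ids}
        a = ResponseData.from_dataframe(df, items, reference_group="G0",
                                        time_order=["T1"])
        b = ResponseData.from_dataframe(df, items, reference_group="G1",
                                        time_order=["T1"])
        fa = CrossSectionalPCM(a, quadrature=12).fit(gtol=1e-6)
        fb = CrossSectionalPCM(b, quadrature=12).fit(gtol=1e-6)
        mu_a = fa.params["mu_G1_T1"]
        mu_b = fb.params["mu_G0_T1"]
        assert mu_b == pytest.approx(-mu_a, abs=1e-5)
        # shared thresholds are expressed relative to the new reference
        # group's mean: they shift by the original group effect
        for j, it in enumerate(a.item_ids):
            for p in (1, 2, 3):
                assert fb.params[f"delta_{it}_{p}"] == pytest.approx(
                    fa.params[f"delta_{it}_{p}"] - mu_a, abs=2e-4
                )

    def test_unobserved_category_errors_toward_collapsing(self):
        resp = np.array([[[0]], [[1]], [[3]], [[0]], [[1]], [[3]]])
        data = ResponseData(resp, [0, 0, 0, 1, 1, 1], ["a"], [4],
                            time_labels=("T1",))
        with pytest.raises(ValueError, match="collapse"):
            CrossSectionalPCM(data, quadrature=10)

    def test_determinism(self, small_cs_data):
        data, _ = small_cs_data
        f1 = CrossSectionalPCM(data, quadrature=12).fit()
        f2 = CrossSectionalPCM(data, quadrature=12).fit()
        assert np.max(np.abs(f1.params - f2.params)) < 1e-10
        assert f1.llf == f2.llf


class TestLongitudinal:
    def test_time_and_group_effect_recovery(self, small_long_data, long_fit):
        data, sc = small_long_data
        long_fit.cov_params()
        for cell, truth in [
            (("mu_G1_T1"), -0.5),
            (("mu_G0_T2"), -0.4),
            (("mu_G1_T2"), -0.7),
        ]:
            assert abs(long_fit.params[cell] - truth) < 2.5 * long_fit.bse[cell]

    def test_variance_and_correlation_recovery(self, small_long_data, long_fit):
        data, sc = small_long_data
        lat = long_fit.latent_distribution().set_index("parameter")
        assert lat.loc["var_T1", "estimate"] == pytest.approx(1.0, abs=0.3)
        assert lat.loc["var_T2", "estimate"] == pytest.approx(1.2, abs=0.35)
        true_corr = 0.5 / np.sqrt(1.0 * 1.2)
        assert lat.loc["corr_T1T2", "estimate"] == pytest.approx(true_corr, abs=0.12)

    def test_all_rs_in_one_group_drops_its_time_effect(self, small_long_data):
        data, _ = small_long_data
        spec = ModelSpec.for_data(data)
        term = RsTerm("by_group", group_forms=(("G1", "free"),))
        for it in data.item_ids:
            spec = spec.with_rs(it, term)
        fit = LongitudinalPCM(data, spec, quadrature=10).fit()
        assert "mu_G1_T2" not in fit.params.index
        est, se, p = fit.time_effect(1)
        assert est == 0.0 and se is None  # structural zero

    def test_zero_covariance_recovered(self):
        sc = SimulationScenario(
            name="rho0", n_per_group=(500, 500), n_items=3,
            mu={("G1", "T1"): 0.0, ("G0", "T2"): 0.0, ("G1", "T2"): 0.0},
            cov_t1t2=0.0, missing_rate=0.0,
        )
        data, _ = simulate_dataset(sc, seed=31)
        fit = LongitudinalPCM(data, quadrature=10).fit()
        rho = np.tanh(fit.params["atanh_corr"])
        assert abs(rho) < 0.1


class TestStandardErrors:
    def test_se_shrinks_like_root_n(self):
        ses = {}
        for n in (200, 800, 3200):
            sc = SimulationScenario(
                name=f"se{n}", n_per_group=(n // 2, n // 2), n_items=3,
                mu={("G1", "T1"): -0.4, ("G0", "T2"): 0.0, ("G1", "T2"): -0.4},
                missing_rate=0.0,
            )
            data, _ = simulate_dataset(sc, seed=int(41 + n))
            fit = CrossSectionalPCM(data.at_time("T1"), quadrature=12).fit()
            ses[n] = fit.bse["mu_G1_T1"]
        for n1, n2 in [(200, 800), (800, 3200)]:
            ratio = ses[n1] / ses[n2]
            assert abs(ratio - 2.0) < 0.5  # 1/sqrt(n) within 25%

    def test_fixed_parameters_carry_no_se(self, cs_fit):
        assert "mu_G0_T1" not in cs_fit.bse.index

    def test_se_requires_convergence(self, small_cs_data):
        data, _ = small_cs_data
        with pytest.warns(RuntimeWarning):
            bad = CrossSectionalPCM(data, quadrature=10).fit(maxiter=1)
        assert not bad.converged
        with pytest.raises(ValueError):
            bad.cov_params()


class TestLikelihoodRatio:
    def test_identical_specs_give_zero_statistic(self, cs_fit):
        tr = likelihood_ratio_test(cs_fit, cs_fit)
        assert tr.statistic == 0.0
        assert tr.df == 0
        assert tr.p_value == 1.0

    def test_df_from_parameter_counts(self, small_cs_data, cs_fit):
        data, _ = small_cs_data
        spec = ModelSpec.for_data(data, longitudinal=False).with_dif(
            "item1", "free"
        )
        full = CrossSectionalPCM(data, spec, quadrature=15).fit()
        tr = likelihood_ratio_test(cs_fit, full)
        assert tr.df == 3  # one 4-category item freed across 2 groups
        assert tr.statistic >= 0

    def test_monotone_nesting(self, small_cs_data, cs_fit):
        data, _ = small_cs_data
        prev = cs_fit
        spec = ModelSpec.for_data(data, longitudinal=False)
        for it in data.item_ids:
            spec = spec.with_dif(it, "free")
            fit = CrossSectionalPCM(data, spec, quadrature=15).fit()
            assert fit.llf >= prev.llf - 1e-6
            prev = fit

    def test_non_nested_rejected(self, small_cs_data, cs_fit):
        data, _ = small_cs_data
        a = ModelSpec.for_data(data, longitudinal=False).with_dif("item1", "free")
        b = ModelSpec.for_data(data, longitudinal=False).with_dif("item2", "free")
        fa = CrossSectionalPCM(data, a, quadrature=10).fit()
        fb = CrossSectionalPCM(data, b, quadrature=10).fit()
        with pytest.raises(ValueError, match="not nested"):
            likelihood_ratio_test(fa, fb)

    def test_null_statistic_is_chi_squared(self):
        """Calibration: LRT statistics from invariant data follow chi2_df."""
        stats_ = []
        for r in range(60):
            sc = SimulationScenario(
                name="nullcal", n_per_group=(60, 60), n_items=2,
                mu={("G1", "T1"): 0.0, ("G0", "T2"): 0.0, ("G1", "T2"): 0.0},
                missing_rate=0.0,
            )
            data, _ = simulate_dataset(sc, seed=500 + r)
            d1 = data.at_time("T1")
            inv = CrossSectionalPCM(d1, quadrature=10).fit()
            spec = ModelSpec.for_data(d1, longitudinal=False).with_dif(
                "item1", "free"
            )
            full = CrossSectionalPCM(d1, spec, quadrature=10).fit()
            stats_.append(likelihood_ratio_test(inv, full).statistic)
        ks = stats.kstest(stats_, stats.chi2(3).cdf)
        assert ks.pvalue > 0.01
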