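import numpy as np
import pytest
from scipy import stats

import coastniche as cn
from coastniche.fast import DistributionSpec, FASTConfig

from oracles import ishigami, ishigami_analytic, sobol_pick_freeze


def uniform_dists(m, lo=0.0, hi=1.0):
    return [DistributionSpec(f"x{i}", "uniform", {"lo": lo, "hi": hi})
            for i in range(m)]


class TestSampleSize:
    def test_paper_configuration(self):
        assert cn.sample_size(4, 416, 15) == 49_935

    def test_small_cases(self):
        assert cn.sample_size(1, 1, 1) == 3
        assert cn.sample_size(2, 8, 3) == 99

    def test_invalid_rejected(self):
        with pytest.raises(ValueError):
            cn.sample_size(0, 416, 15)


class TestFitDistributions:
    def test_uniform_data_accepts_uniform(self):
        rng = np.random.default_rng(0)
        d = cn.fit_distribution(rng.uniform(0, 1, 10_000), "u")
        assert d.family == "uniform"
        assert d.gof_p > d.alpha

    def test_normal_data_accepts_normal(self):
        rng = np.random.default_rng(1)
        d = cn.fit_distribution(rng.normal(5, 2, 10_000), "n")
        assert d.family == "normal"

    def test_constant_flagged_degenerate(self):
        d = cn.fit_distribution(np.ones(100), "c")
        assert d.degenerate
        assert d.ppf(np.array([0.1, 0.9])).tolist() == [1.0, 1.0]

    def test_categorical_matches_observed_proportions(self):
        data = np.array([1.0] * 50 + [2.0] * 30 + [4.0] * 20)
        d = cn.fit_distribution(data, "cat", categorical=True)
        assert d.family == "categorical"
        assert d.params["codes"] == [1.0, 2.0, 4.0]
        np.testing.assert_allclose(d.params["probs"], [0.5, 0.3, 0.2])
        # discrete inverse CDF reproduces the proportions exactly
        q = (np.arange(1000) + 0.5) / 1000
        draws = d.ppf(q)
        np.testing.assert_allclose(
            [np.mean(draws == c) for c in (1.0, 2.0, 4.0)], [0.5, 0.3, 0.2])

    def test_bimodal_falls_back_to_empirical(self):
        rng = np.random.default_rng(2)
        data = np.concatenate([rng.normal(0, 0.2, 5000), rng.normal(10, 0.2, 5000)])
        d = cn.fit_distribution(data, "b")
        assert d.family == "empirical"
        med = d.ppf(np.array([0.25, 0.75]))
        assert med[0] < 2 and med[1] > 8

    def test_stack_distributions_cover_all_layers(self, small_stack):
        dists = cn.fit_distributions(small_stack)
        assert [d.variable for d in dists] == small_stack.layer_names
        kinds = {d.variable: d.family for d in dists}
        assert kinds["Drainage"] == "categorical"


class TestDesign:
    def test_design_columns_uniform(self):
        cfg = FASTConfig(M=4, omega_max=416, m=3, seed=0)
        design = cn.efast_design(uniform_dists(3), cfg)
        assert len(design.blocks) == 3
        assert design.blocks[0].shape == (3329, 3)
        for j in range(3):
            ks = stats.kstest(design.blocks[0][:, j], "uniform")
            assert ks.pvalue > 0.01

    def test_same_seed_identical(self):
        cfg = FASTConfig(M=4, omega_max=64, m=4, seed=9)
        a = cn.efast_design(uniform_dists(4), cfg)
        b = cn.efast_design(uniform_dists(4), cfg)
        for x, y in zip(a.blocks, b.blocks):
            np.testing.assert_array_equal(x, y)

    def test_two_factor_valid_design(self):
        cfg = FASTConfig(M=4, omega_max=16, m=2, seed=0)
        design = cn.efast_design(uniform_dists(2), cfg)
        assert len(design.blocks) == 2
        assert design.blocks[0].shape == (129, 2)
        # complementary frequency distinct and within the band
        assert design.frequencies[0, 1] <= 2
        assert design.frequencies[0, 0] == 16

    def test_band_too_small_rejected(self):
        cfg = FASTConfig(M=4, omega_max=4, m=3, seed=0)  # band = 0
        with pytest.raises(ValueError, match="omega_max"):
            cn.efast_design(uniform_dists(3), cfg)

    def test_mismatched_factor_count_rejected(self):
        cfg = FASTConfig(M=4, omega_max=64, m=5, seed=0)
        with pytest.raises(ValueError, match="distributions"):
            cn.efast_design(uniform_dists(3), cfg)


class TestIndices:
    def test_pure_tone_has_unit_first_order(self):
        omega, M = 16, 4
        ns = 2 * M * omega + 1
        s = -np.pi + 2 * np.pi * (np.arange(ns) + 1) / ns
        y = np.sin(omega * s)
        assert cn.first_order_index(y, omega, M) == pytest.approx(1.0, abs=1e-10)
        assert cn.total_index(y, omega, M) == pytest.approx(1.0, abs=1e-10)

    def test_constant_output_flagged_zero(self):
        y = np.ones(129)
        assert cn.first_order_index(y, 16, 4) == 0.0
        assert cn.total_index(y, 16, 4) == 0.0

    def test_single_factor_identity_model(self):
        cfg = FASTConfig(M=4, omega_max=64, m=3, seed=3)
        res = cn.efast_indices(lambda X: X[:, 1], uniform_dists(3), cfg,
                               n_repeats=3)
        assert res.s_f[1] == pytest.approx(1.0, abs=0.02)
        assert res.s_t[1] == pytest.approx(1.0, abs=0.03)
        assert res.s_f[0] < 0.02 and res.s_f[2] < 0.02
        assert res.s_t[0] < 0.03 and res.s_t[2] < 0.03

    def test_additive_model_no_interactions(self):
        cfg = FASTConfig(M=4, omega_max=128, m=3, seed=4)
        res = cn.efast_indices(lambda X: X[:, 0] + 2 * X[:, 1] + 0.5 * X[:, 2],
                               uniform_dists(3), cfg, n_repeats=3)
        assert np.abs(res.s_t - res.s_f).max() <= 0.03
        # variance shares 1 : 4 : 0.25 over equal-variance inputs
        np.testing.assert_allclose(res.s_f, np.array([1, 4, 0.25]) / 5.25, atol=0.03)

    def test_ishigami_matches_closed_form(self):
        dists = uniform_dists(3, -np.pi, np.pi)
        cfg = FASTConfig(M=4, omega_max=416, m=3, seed=5)
        res = cn.efast_indices(lambda X: ishigami(X), dists, cfg, n_repeats=3)
        sf_true, st_true = ishigami_analytic()
        np.testing.assert_allclose(res.s_f, sf_true, atol=0.05)
        np.testing.assert_allclose(res.s_t, st_true, atol=0.05)

    def test_agrees_with_pick_freeze_monte_carlo(self):
        # independent variance-based oracle on Ishigami and an additive model
        dists = uniform_dists(3, -np.pi, np.pi)
        cfg = FASTConfig(M=4, omega_max=416, m=3, seed=6)
        ppfs = [d.ppf for d in dists]

        res = cn.efast_indices(lambda X: ishigami(X), dists, cfg, n_repeats=3)
        mc_sf, mc_st = sobol_pick_freeze(ishigami, ppfs, n=100_000, seed=1)
        np.testing.assert_allclose(res.s_f, mc_sf, atol=0.05)
        np.testing.assert_allclose(res.s_t, mc_st, atol=0.05)

        add = lambda X: X[:, 0] + 2 * X[:, 1] + 0.5 * X[:, 2]
        res2 = cn.efast_indices(add, dists, cfg, n_repeats=3)
        mc_sf2, mc_st2 = sobol_pick_freeze(add, ppfs, n=100_000, seed=2)
        np.testing.assert_allclose(res2.s_f, mc_sf2, atol=0.05)
        np.testing.assert_allclose(res2.s_t, mc_st2, atol=0.05)

    def test_estimator_bounds_hold(self):
        cfg = FASTConfig(M=4, omega_max=416, m=3, seed=7)
        res = cn.efast_indices(lambda X: ishigami(X),
                               uniform_dists(3, -np.pi, np.pi), cfg, n_repeats=3)
        eps = 0.03
        assert (res.s_f >= -eps).all() and (res.s_f <= 1 + eps).all()
        assert (res.s_t >= res.s_f - eps).all()

    def test_wrong_block_length_rejected(self):
        with pytest.raises(ValueError):
            cn.first_order_index(np.ones(10), 16, 4)


class TestRunGsa:
    def test_ignored_variable_scores_zero(self, small_stack, fitted_model):
        # the fitted model uses only the retained feature layers; add check on
        # a model that provably ignores one layer by zeroing its coefficients
        import copy
        model = copy.deepcopy(fitted_model)
        target = "Bio19"
        for j, d in enumerate(model.features):
            if d.layer == target:
                model.lambdas[j] = 0.0
        cfg = FASTConfig(M=4, omega_max=32, m=small_stack.n_layers, seed=0,
                         n_repeats=2)
        res = cn.run_gsa(model, small_stack, cfg)
        i = res.variables.index(target)
        assert res.s_f[i] <= 0.02
        assert res.s_t[i] <= 0.02

    def test_pure_interaction_model(self):
        # y = x1 * x2 on centered uniforms: no main effects, all interaction
        dists = uniform_dists(3, -1.0, 1.0)
        cfg = FASTConfig(M=4, omega_max=128, m=3, seed=8)
        res = cn.efast_indices(lambda X: X[:, 0] * X[:, 1], dists, cfg,
                               n_repeats=3)
        assert res.s_f[0] <= 0.03
        assert res.s_t[0] >= 0.5
        assert res.s_t[0] - res.s_f[0] > 0.4

    def test_report_sums_are_column_sums(self, small_stack, fitted_model):
        cfg = FASTConfig(M=4, omega_max=32, m=small_stack.n_layers, seed=1,
                         n_repeats=2)
        res = cn.run_gsa(fitted_model, small_stack, cfg)
        df = res.to_frame()
        body = df[df["variable"] != "Sum"]
        total = df[df["variable"] == "Sum"].iloc[0]
        assert total["S_F"] == pytest.approx(body["S_F"].sum(), abs=1e-12)
        assert total["S_T"] == pytest.approx(body["S_T"].sum(), abs=1e-12)
        assert total["diff"] == pytest.approx(body["diff"].sum(), abs=1e-12)


class TestInteractionEffect:
    def _result(self, s_f, s_t):
        m = len(s_f)
        return cn.SensitivityResult(
            variables=[f"v{i}" for i in range(m)],
            s_f=np.asarray(s_f, float), s_t=np.asarray(s_t, float),
            s_f_spread=np.zeros(m), s_t_spread=np.zeros(m))

    def test_equal_indices_give_zero_diff(self):
        res = self._result([0.2, 0.3], [0.2, 0.3])
        df = cn.interaction_effect(res)
        np.testing.assert_allclose(df["diff"], 0.0)

    def test_strictly_decreasing_diff_ranks_one_to_m(self):
        res = self._result([0.0] * 4, [0.4, 0.3, 0.2, 0.1])
        df = cn.interaction_effect(res)
        assert df["rank_diff"].tolist() == [1, 2, 3, 4]

    def test_ties_share_competition_rank(self):
        res = self._result([0.0] * 4, [0.4, 0.2, 0.2, 0.1])
        df = cn.interaction_effect(res)
        assert df["rank_diff"].tolist() == [1, 2, 2, 4]
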