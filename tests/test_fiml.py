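"""FIML estimation: closed forms, recovery, calibration, intervals."""
import math
from dataclasses import replace

import numpy as np
import pytest
from scipy import stats

import twinmr as tm
from twinmr.families import AnalysisDataset, GroupData
from twinmr.fiml import deviance, make_objective, prepare, wald_se
from twinmr.pathmodel import GroupSpec


def _pair_dataset(var, mz, dz):
    """Stack (n,2) MZ and DZ pair arrays into an AnalysisDataset."""
    return AnalysisDataset(
        [var],
        {
            "MZ": GroupData(GroupSpec.mz_pair(), mz, list(range(len(mz)))),
            "DZ": GroupData(GroupSpec.dz_pair(), dz, list(range(len(dz)))),
        },
    )


def _simulate_ace_pairs(rng, n, a, c, e, r_a):
    """Independent oracle simulation of one phenotype in twin pairs."""
    A_shared = rng.standard_normal((n, 1))
    A_unique = rng.standard_normal((n, 2))
    A = math.sqrt(r_a) * A_shared + math.sqrt(1 - r_a) * A_unique
    C = rng.standard_normal((n, 1)) * np.ones((1, 2))
    E = rng.standard_normal((n, 2))
    return a * A + c * C + e * E


class TestSaturated:
    def test_closed_form_deviance_mean_covariance(self):
        res = tm.studies.saturated_closed_form(seed=0)
        assert res["deviance_error"] < 1e-6
        assert res["max_mean_error"] < 1e-5
        assert res["max_cov_error"] < 1e-5

    def test_manual_group_deviance(self):
        # deviance() equals the hand-computed Gaussian deviance per group
        rng = np.random.default_rng(8)
        mz = _simulate_ace_pairs(rng, 300, 0.7, 0.3, 0.6, 1.0)
        dz = _simulate_ace_pairs(rng, 300, 0.7, 0.3, 0.6, 0.5)
        model = tm.build_univariate_ace("y")
        ds = _pair_dataset("y", mz, dz)
        by_hand = 0.0
        for spec, data in ((GroupSpec.mz_pair(), mz), (GroupSpec.dz_pair(), dz)):
            _, Sig = model.implied_moments(spec)
            Sinv = np.linalg.inv(Sig)
            quad = np.einsum("ni,ij,nj->", data, Sinv, data)
            by_hand += len(data) * (
                2 * math.log(2 * math.pi) + math.log(np.linalg.det(Sig))
            ) + quad
        assert deviance(model, ds) == pytest.approx(by_hand, rel=1e-10)


class TestRecovery:
    def test_univariate_ace_parameter_recovery(self):
        # a2=0.6, c2=0.2, e2=0.2 at 5000+5000 pairs: within +-0.03
        rng = np.random.default_rng(123)
        a, c, e = math.sqrt(0.6), math.sqrt(0.2), math.sqrt(0.2)
        mz = _simulate_ace_pairs(rng, 5000, a, c, e, 1.0)
        dz = _simulate_ace_pairs(rng, 5000, a, c, e, 0.5)
        model = tm.build_univariate_ace("y")
        fit = tm.fit_fiml(model, _pair_dataset("y", mz, dz),
                          tm.FitOptions(n_starts=2, seed=0),
                          compute_standardized=False)
        assert fit.converged
        for label, truth in (("a", 0.6), ("c", 0.2), ("e", 0.2)):
            assert fit.estimates[label] ** 2 == pytest.approx(truth, abs=0.03)

    def test_simulator_single_indicator_ace_recovery(self):
        # cross-module: the family simulator's RSB outcome is a pure ACE
        # factor; the univariate pair model recovers its a2/c2
        gp = replace(
            tm.GeneratingParams(),
            g1=0.0, b2=0.0, b1_rev=0.0,
            af2=math.sqrt(0.6), cf2=math.sqrt(0.2), r_a=0.0,
        )
        cfg = tm.SimulationConfig(
            n_mz_pairs=4000, n_dz_pairs=4000, n_sib_pairs=0,
            outcome="RSB", seed=31, params=gp, genotyped_fraction=0.0,
        )
        tab = tm.simulate_families(cfg)
        ds = tm.assemble_analysis_dataset(tab, ["rsb"])
        model = tm.build_univariate_ace("rsb")
        fit = tm.fit_fiml(model, ds, tm.FitOptions(n_starts=2, seed=0),
                          compute_standardized=False)
        assert fit.estimates["a"] ** 2 == pytest.approx(0.6, abs=0.04)
        assert fit.estimates["c"] ** 2 == pytest.approx(0.2, abs=0.04)

    def test_grid_search_oracle_two_parameters(self):
        # dense grid over (a, e) agrees with the optimizer's minimum
        rng = np.random.default_rng(5)
        mz = _simulate_ace_pairs(rng, 400, 0.8, 0.0, 0.6, 1.0)
        dz = _simulate_ace_pairs(rng, 400, 0.8, 0.0, 0.6, 0.5)
        model = tm.build_univariate_ace("y", components="ae")
        ds = _pair_dataset("y", mz, dz)
        fit = tm.fit_fiml(model, ds, tm.FitOptions(n_starts=1, seed=0),
                          compute_standardized=False)
        preps = prepare(ds, model)
        fun = make_objective(model, preps, 1e-7)
        grid = np.arange(0.3, 1.3, 0.005)
        best = min(
            ((fun(np.array([a, e]))[0], a, e) for a in grid for e in grid)
        )
        assert fit.minus2lnL <= best[0] + 1e-6
        assert fit.estimates["a"] == pytest.approx(best[1], abs=0.005)
        assert fit.estimates["e"] == pytest.approx(best[2], abs=0.005)


class TestInvariances:
    def test_family_order_and_member_permutation(self, quarter_scale_fit):
        _, model, ds, fit = quarter_scale_fit
        rng = np.random.default_rng(0)
        p = len(model.observed)
        groups = {}
        for name, gd in ds.groups.items():
            arr = gd.data[rng.permutation(gd.n_units)]
            if gd.spec.name in ("MZ",):  # swap member order within MZ pairs
                arr = np.hstack([arr[:, p:], arr[:, :p]])
            groups[name] = GroupData(gd.spec, arr, gd.family_ids)
        shuffled = AnalysisDataset(ds.variables, groups)
        model.set_theta(np.array([fit.estimates[l]
                                  for l in model.free_parameter_vector()]))
        assert deviance(model, shuffled) == pytest.approx(
            fit.minus2lnL, abs=1e-6
        )

    def test_extra_free_parameter_never_raises_deviance(self, quarter_scale_fit):
        cfg, model, ds, fit = quarter_scale_fit
        spec = tm.MrdocSpec(instrument=tm.PS_SSA, exposure=tm.SSA,
                            outcome=tm.PD, ae_only=False)  # adds C paths
        bigger = tm.build_mrdoc(spec, check_identification=False)
        fit_big = tm.fit_fiml(bigger, ds, tm.FitOptions(n_starts=1, seed=1),
                              compute_standardized=False)
        assert fit_big.minus2lnL <= fit.minus2lnL + 1e-4


class TestLRT:
    def test_identical_models_give_zero(self, quarter_scale_fit):
        *_, fit = quarter_scale_fit
        res = tm.likelihood_ratio_test(fit, fit)
        assert res.chi_square == 0.0 and res.df == 0 and res.p_value == 1.0

    def test_c_drop_on_null_c_data(self):
        # true c2 = 0: dropping C barely moves the deviance (boundary null)
        rng = np.random.default_rng(77)
        mz = _simulate_ace_pairs(rng, 2000, 0.7, 0.0, 0.71, 1.0)
        dz = _simulate_ace_pairs(rng, 2000, 0.7, 0.0, 0.71, 0.5)
        ds = _pair_dataset("y", mz, dz)
        full = tm.fit_fiml(tm.build_univariate_ace("y"), ds,
                           tm.FitOptions(n_starts=2, seed=0),
                           compute_standardized=False)
        nested = tm.fit_fiml(tm.build_univariate_ace("y", components="ae"), ds,
                             tm.FitOptions(n_starts=2, seed=0),
                             compute_standardized=False)
        res = tm.likelihood_ratio_test(full, nested)
        assert res.df == 1
        assert res.chi_square < 4.0
        assert res.p_value > 0.04

    def test_non_nested_labels_rejected(self, quarter_scale_fit):
        *_, fit = quarter_scale_fit
        other = tm.FitResult(estimates={"zzz": 1.0}, minus2lnL=fit.minus2lnL,
                             n_free=1, converged=True, grad_norm=0.0,
                             n_individuals=0)
        with pytest.raises(ValueError, match="not nested"):
            tm.likelihood_ratio_test(fit, other)

    def test_null_chi2_distribution(self):
        # dropping an interior parameter (the mean) under the null: the LRT
        # statistic follows chi2(1) across replicates
        rng = np.random.default_rng(2024)
        stats_ = []
        for _ in range(300):
            mz = _simulate_ace_pairs(rng, 150, 0.7, 0.0, 0.71, 1.0)
            dz = _simulate_ace_pairs(rng, 150, 0.7, 0.0, 0.71, 0.5)
            ds = _pair_dataset("y", mz, dz)
            m_free = tm.build_univariate_ace("y", components="ae",
                                             free_means=True)
            full = tm.fit_fiml(m_free, ds, tm.FitOptions(n_starts=1, seed=0),
                               compute_standardized=False)
            m_fix = tm.build_univariate_ace("y", components="ae")
            nested = tm.fit_fiml(m_fix, ds, tm.FitOptions(n_starts=1, seed=0),
                                 compute_standardized=False)
            stats_.append(max(0.0, nested.minus2lnL - full.minus2lnL))
        ks = stats.kstest(stats_, stats.chi2(1).cdf)
        assert ks.pvalue > 0.01


class TestIntervals:
    def test_profile_ci_matches_wald_in_quadratic_case(self):
        rng = np.random.default_rng(11)
        X = rng.normal(0.3, 1.0, (500, 1))
        ds = AnalysisDataset(
            ["y"], {"s": GroupData(GroupSpec.singleton(), X, list(range(500)))}
        )
        model = tm.build_saturated(["y"])
        fit = tm.fit_fiml(model, ds, tm.FitOptions(n_starts=1, seed=0),
                          compute_standardized=False)
        se = wald_se(model, ds, fit)["mu_y"]
        lo, hi, flag = tm.profile_ci(model, ds, fit, "mu_y")
        assert flag == "ok"
        assert lo == pytest.approx(fit.estimates["mu_y"] - 1.96 * se, abs=1e-3)
        assert hi == pytest.approx(fit.estimates["mu_y"] + 1.96 * se, abs=1e-3)

    def test_boundary_parameter_flagged_one_sided(self):
        rng = np.random.default_rng(13)
        mz = _simulate_ace_pairs(rng, 800, 0.75, 0.0, 0.66, 1.0)
        dz = _simulate_ace_pairs(rng, 800, 0.75, 0.0, 0.66, 0.5)
        ds = _pair_dataset("y", mz, dz)
        model = tm.build_univariate_ace("y")
        fit = tm.fit_fiml(model, ds, tm.FitOptions(n_starts=2, seed=0),
                          compute_standardized=False)
        lo, hi, flag = tm.profile_ci(model, ds, fit, "c")
        assert lo == 0.0
        assert "boundary" in flag

    def test_bootstrap_fallback_brackets_truth(self):
        rng = np.random.default_rng(17)
        X = rng.normal(0.5, 1.0, (400, 1))
        ds = AnalysisDataset(
            ["y"], {"s": GroupData(GroupSpec.singleton(), X, list(range(400)))}
        )
        model = tm.build_saturated(["y"])
        fit = tm.fit_fiml(model, ds, tm.FitOptions(n_starts=1, seed=0),
                          compute_standardized=False)
        lo, hi, flag = tm.bootstrap_ci(model, ds, fit, "mu_y", n_boot=60, seed=3)
        assert flag.startswith("bootstrap")
        assert lo < 0.5 < hi


class TestStandardize:
    def test_variance_proportions_sum_to_one(self, quarter_scale_fit):
        *_, fit = quarter_scale_fit
        props = fit.variance_proportions
        sums = props[[c for c in props.columns if c.startswith("prop_")]].sum(axis=1)
        np.testing.assert_allclose(sums, 1.0, atol=1e-8)

    def test_standardized_invariant_to_indicator_rescaling(self, forward_spec):
        cfg = tm.SimulationConfig(n_mz_pairs=300, n_dz_pairs=500,
                                  n_sib_pairs=0, seed=19,
                                  genotyped_fraction=0.5)
        tab = tm.simulate_families(cfg)
        results = []
        for scale in (1.0, 10.0):
            t = tab.copy()
            # rescale a score indicator: its loading and residual are free
            # (indicator-specific ACE residuals are equality-constrained, so
            # phenotype indicators cannot be rescaled independently)
            t.data["ps_ssi"] = t.data["ps_ssi"] * scale
            model = tm.build_mrdoc(forward_spec, check_identification=False)
            ds = tm.assemble_analysis_dataset(t, list(model.observed))
            fit = tm.fit_fiml(
                model, ds,
                tm.FitOptions(n_starts=2, seed=0, gtol=1e-9, start="scaled"),
            )
            assert fit.converged
            results.append(
                fit.standardized.set_index("label")["standardized"]
            )
        for lab in ("g1", "b1", "l_ps_ssp", "af1", "af2", "r_a"):
            assert results[0][lab] == pytest.approx(results[1][lab], abs=1e-4)

    def test_unit_variance_model_standardized_equals_raw(self):
        model = tm.build_univariate_ace("y")
        # pick coefficients on the unit sphere: observed variance 1
        for lab, val in (("a", 0.6), ("c", 0.0), ("e", 0.8)):
            model.parameters[lab].value = val
        std, _ = tm.standardize(model)
        table = std.set_index("label")
        for lab in ("a", "c", "e"):
            assert table.loc[lab, "standardized"] == pytest.approx(
                table.loc[lab, "raw"], abs=1e-12
            )
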