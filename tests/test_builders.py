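"""Model builders: structure audits, recovery, decomposition arithmetic."""
import math
from dataclasses import replace

import numpy as np
import pytest

import twinmr as tm
from twinmr.pathmodel import GroupSpec


class TestSpecs:
    def test_indicator_in_two_factors_rejected(self):
        with pytest.raises(tm.StructureError, match="two factors"):
            tm.MrdocSpec(
                instrument=tm.PS_SSA,
                exposure=tm.Factor("X", ("ssi", "dep")),
                outcome=tm.PD,
            )

    def test_unknown_direction_rejected(self):
        with pytest.raises(tm.StructureError, match="direction"):
            tm.MrdocSpec(instrument=tm.PS_SSA, exposure=tm.SSA,
                         outcome=tm.PD, direction="sideways")

    def test_empty_factor_rejected(self):
        with pytest.raises(tm.StructureError):
            tm.Factor("empty", ())


class TestStructureAudits:
    def test_free_parameter_counts_deterministic(self, forward_spec):
        # regression guard: builder surface is a pure function of the spec
        m1 = tm.build_mrdoc(forward_spec, check_identification=False)
        assert len(m1.free_parameter_vector()) == 24
        m2 = tm.build_mrdoc(replace(forward_spec, ae_only=False),
                            check_identification=False)
        assert len(m2.free_parameter_vector()) == 24 + 5  # cf1 cf2 r_c cs x2
        m3 = tm.build_phenotypic_mr(forward_spec)
        assert len(m3.free_parameter_vector()) == 21
        m4 = tm.build_biometric_factor_model(tm.SSA, tm.PD)
        assert len(m4.free_parameter_vector()) == 21
        m5 = tm.build_constrained_correlation_model([tm.SSA, tm.PD],
                                                    instrument=tm.PS_SSA)
        assert len(m5.free_parameter_vector()) == 31

    def test_reverse_direction_swaps_roles(self):
        spec = tm.MrdocSpec(instrument=tm.PS_PD, exposure=tm.SSA,
                            outcome=tm.PD, direction="reverse")
        model = tm.build_mrdoc(spec, check_identification=False)
        regs = {k: p.label for k, p in model.regressions.items()}
        assert regs[("PD", "PS_PD")] == "b1"   # instrument hits the outcome
        assert regs[("SSA", "PD")] == "g1"     # causal path runs PD -> SSA
        assert regs[("SSA", "PS_PD")] == "b2"
        assert model.meta["cause"] == "PD" and model.meta["effect"] == "SSA"

    def test_single_indicator_factor_fixed_loading_no_residual(self):
        model = tm.build_constrained_correlation_model([tm.SSA, tm.RSB],
                                                       instrument=tm.PS_SSA)
        par = model.loadings[("rsb", "RSB")]
        assert not par.free and par.value == 1.0
        assert not any(o == "rsb" for o, _ in model.residual_paths)

    def test_within_person_correlations_independent_of_groups(self):
        m2 = tm.build_constrained_correlation_model(
            [tm.SSA, tm.PD], instrument=tm.PS_SSA, zygosity_groups=("MZ", "DZ")
        )
        m1 = tm.build_constrained_correlation_model(
            [tm.SSA, tm.PD], instrument=tm.PS_SSA, zygosity_groups=("MZ",)
        )
        within = lambda m: sorted(
            p.label for p in m.parameters if p.label.startswith("r_")
        )
        assert within(m1) == within(m2)

    def test_correlation_model_instrument_cross_member_fixed(self):
        model = tm.build_constrained_correlation_model(
            [tm.SSA, tm.PD], instrument=tm.PS_SSA
        )
        mz = model.cross_overrides["MZ"][("u_PS_SSA", "u_PS_SSA")]
        dz = model.cross_overrides["DZ"][("u_PS_SSA", "u_PS_SSA")]
        assert (mz.value, mz.free) == (1.0, False)
        assert (dz.value, dz.free) == (0.5, False)

    def test_mrdoc_without_pleiotropy_has_no_b2(self, forward_spec):
        model = tm.build_mrdoc(replace(forward_spec, include_pleiotropy=False),
                               check_identification=False)
        assert "b2" not in model.parameters
        assert ("PD", "PS_SSA") not in model.regressions


class TestDecomposition:
    def test_worked_residual_genetic_product(self):
        dec = tm.decompose_correlation(
            {"g1": 0.13, "af1": 0.75, "r_a": 0.26, "af2": 0.63}, reference=0.25
        )
        assert round(dec.residual_genetic, 2) == 0.12
        assert dec.share_of_reference["causal"] * 100 == pytest.approx(52.0)
        assert dec.implied_correlation == pytest.approx(
            0.13 + 0.75 * 0.26 * 0.63, abs=1e-12
        )

    def test_second_model_worked_example(self):
        dec = tm.decompose_correlation(
            {"g1": 0.16, "af1": 0.75, "r_a": 0.24, "af2": 0.65}, reference=0.28
        )
        assert round(dec.residual_genetic, 2) == 0.12
        assert dec.share_of_reference["causal"] * 100 == pytest.approx(
            57.0, abs=0.5
        )

    def test_null_paths_give_zero_and_flagged_proportions(self):
        dec = tm.decompose_correlation({"g1": 0.0, "r_a": 0.0, "b2": 0.0})
        assert dec.implied_correlation == 0.0
        assert all(v == 0.0 for v in dec.contributions.values())
        with pytest.raises(ZeroDivisionError):
            dec.proportions

    def test_proportions_sum_to_one(self):
        dec = tm.decompose_correlation(
            {"g1": 0.1, "b1": 0.1, "b2": 0.05, "af1": 0.7, "r_a": 0.3,
             "af2": 0.6}
        )
        assert sum(dec.proportions.values()) == pytest.approx(1.0, abs=1e-12)


class TestRecovery:
    def test_correlation_model_recovers_factor_correlation(self, forward_spec):
        gp = tm.GeneratingParams()
        truth = gp.g1 + gp.b1 * gp.b2 + gp.af1 * gp.r_a * gp.af2
        cfg = tm.SimulationConfig(n_mz_pairs=5000, n_dz_pairs=5000,
                                  n_sib_pairs=0, seed=101,
                                  genotyped_fraction=0.4)
        tab = tm.simulate_families(cfg)
        model = tm.build_constrained_correlation_model([tm.SSA, tm.PD],
                                                       instrument=tm.PS_SSA)
        ds = tm.assemble_analysis_dataset(tab, list(model.observed),
                                          mode="pairs")
        fit = tm.fit_fiml(model, ds, tm.FitOptions(n_starts=1, seed=0),
                          compute_standardized=False)
        assert fit.converged
        assert fit.estimates["r_SSA_PD"] == pytest.approx(truth, abs=0.03)

    def test_biometric_factor_heritabilities(self):
        gp = tm.GeneratingParams()
        cfg = tm.SimulationConfig(n_mz_pairs=5000, n_dz_pairs=5000,
                                  n_sib_pairs=0, seed=55,
                                  genotyped_fraction=0.0)
        tab = tm.simulate_families(cfg)
        ds = tm.assemble_analysis_dataset(
            tab, [*tm.SSA.indicators, *tm.PD.indicators]
        )
        model = tm.build_biometric_factor_model(tm.SSA, tm.PD, drop_c=True)
        fit = tm.fit_fiml(model, ds, tm.FitOptions(n_starts=2, seed=0))
        vp = fit.variance_proportions.set_index("variable")
        h2_ssa = gp.af1**2 + gp.b1**2
        h2_pd = (gp.af2**2 + gp.b2**2 + gp.b1_rev**2 + gp.g1**2 * h2_ssa
                 + 2 * gp.g1 * (gp.af2 * gp.af1 * gp.r_a + gp.b2 * gp.b1))
        assert vp.loc["SSA", "prop_A"] == pytest.approx(h2_ssa, abs=0.04)
        assert vp.loc["PD", "prop_A"] == pytest.approx(h2_pd, abs=0.04)

    def test_c_drop_harmless_on_c_free_data(self):
        # generating shared environment is zero: dropping C moves -2lnL
        # by at most sampling noise
        cfg = tm.SimulationConfig(n_mz_pairs=1500, n_dz_pairs=2500,
                                  n_sib_pairs=0, seed=66,
                                  genotyped_fraction=0.0)
        tab = tm.simulate_families(cfg)
        ds = tm.assemble_analysis_dataset(
            tab, [*tm.SSA.indicators, *tm.PD.indicators]
        )
        full = tm.fit_fiml(tm.build_biometric_factor_model(tm.SSA, tm.PD),
                           ds, tm.FitOptions(n_starts=2, seed=0),
                           compute_standardized=False)
        nested = tm.fit_fiml(
            tm.build_biometric_factor_model(tm.SSA, tm.PD, drop_c=True),
            ds, tm.FitOptions(n_starts=2, seed=0),
            compute_standardized=False,
        )
        res = tm.likelihood_ratio_test(full, nested)
        assert res.p_value > 0.05

    def test_e_only_data_show_no_cross_twin_factor_correlation(self):
        gp = replace(tm.GeneratingParams(), af1=0.0, af2=0.0, r_a=0.0,
                     b1=0.0, b2=0.0, b1_rev=0.0, exposure_a_s=0.0,
                     outcome_a_s=0.0)
        cfg = tm.SimulationConfig(n_mz_pairs=3000, n_dz_pairs=3000,
                                  n_sib_pairs=0, seed=77, params=gp,
                                  genotyped_fraction=0.0)
        tab = tm.simulate_families(cfg)
        ds = tm.assemble_analysis_dataset(
            tab, [*tm.SSA.indicators, *tm.PD.indicators]
        )
        model = tm.build_biometric_factor_model(tm.SSA, tm.PD, drop_c=True)
        fit = tm.fit_fiml(model, ds, tm.FitOptions(n_starts=2, seed=0))
        vp = fit.variance_proportions.set_index("variable")
        assert vp.loc["SSA", "prop_A"] == pytest.approx(0.0, abs=0.05)
        assert vp.loc["PD", "prop_A"] == pytest.approx(0.0, abs=0.05)

    def test_phenotypic_mr_consistent_without_confounding(self, forward_spec):
        gp = replace(tm.GeneratingParams(), r_a=0.0, b2=0.0)
        cfg = tm.SimulationConfig(n_mz_pairs=6000, n_dz_pairs=6000,
                                  n_sib_pairs=0, seed=88, params=gp,
                                  genotyped_fraction=1.0)
        tab = tm.simulate_families(cfg)
        model = tm.build_phenotypic_mr(forward_spec)
        ds = tm.assemble_analysis_dataset(tab, list(model.observed),
                                          mode="individuals")
        fit = tm.fit_fiml(model, ds, tm.FitOptions(n_starts=2, seed=0))
        g1 = float(fit.standardized.set_index("label").loc["g1",
                                                           "standardized"])
        assert g1 == pytest.approx(gp.g1, abs=0.03)

    def test_mrdoc_with_and_without_pleiotropy_agree_when_none(self,
                                                               forward_spec):
        gp = replace(tm.GeneratingParams(), b2=0.0)
        cfg = tm.SimulationConfig(seed=99, params=gp, genotyped_fraction=0.4)
        tab = tm.simulate_families(cfg)
        g1s = []
        for spec in (forward_spec,
                     replace(forward_spec, include_pleiotropy=False)):
            model = tm.build_mrdoc(spec, check_identification=False)
            ds = tm.assemble_analysis_dataset(tab, list(model.observed))
            fit = tm.fit_fiml(model, ds, tm.FitOptions(n_starts=1, seed=0))
            g1s.append(float(
                fit.standardized.set_index("label").loc["g1", "standardized"]
            ))
        assert g1s[0] == pytest.approx(g1s[1], abs=0.02)

    def test_directionality_forward_recovers_reverse_attenuates(self):
        # data generated with a forward causal path only
        cfg = tm.SimulationConfig(n_mz_pairs=10_000, n_dz_pairs=10_000,
                                  n_sib_pairs=0, seed=111,
                                  genotyped_fraction=0.4)
        tab = tm.simulate_families(cfg)
        fwd = tm.build_mrdoc(
            tm.MrdocSpec(instrument=tm.PS_SSA, exposure=tm.SSA, outcome=tm.PD),
            check_identification=False,
        )
        ds = tm.assemble_analysis_dataset(tab, list(fwd.observed))
        fit_f = tm.fit_fiml(fwd, ds, tm.FitOptions(n_starts=1, seed=0))
        g_f = float(fit_f.standardized.set_index("label").loc["g1",
                                                              "standardized"])
        rev = tm.build_mrdoc(
            tm.MrdocSpec(instrument=tm.PS_PD, exposure=tm.SSA, outcome=tm.PD,
                         direction="reverse"),
            check_identification=False,
        )
        ds_r = tm.assemble_analysis_dataset(tab, list(rev.observed))
        fit_r = tm.fit_fiml(rev, ds_r, tm.FitOptions(n_starts=1, seed=0))
        g_r = float(fit_r.standardized.set_index("label").loc["g1",
                                                              "standardized"])
        assert g_f == pytest.approx(0.13, abs=0.05)
        assert abs(g_r) < g_f

    def test_phenotypic_mr_zero_paths_zero_instrument_outcome_cov(self,
                                                                  forward_spec):
        model = tm.build_phenotypic_mr(forward_spec)
        model.parameters["g1"].value = 0.0
        model.parameters["b2"].value = 0.0
        _, Sig = model.implied_moments(GroupSpec.singleton())
        i = model.observed.index("ps_ssi")
        j = model.observed.index("dep")
        assert Sig[i, j] == pytest.approx(0.0, abs=1e-12)


def test_generating_params_match_implied_latent_structure(forward_spec):
    # closed-form standardized implied correlation vs the model's
    # path-traced latent moments after applying the generating values
    gp = replace(tm.GeneratingParams(), b1_rev=0.0)
    model = tm.build_mrdoc(forward_spec, check_identification=False,
                           free_means=False)
    tm.builders.apply_generating_params(model, gp)
    lat = model.latent_moments()
    i, j = model.latents.index("SSA"), model.latents.index("PD")
    r = lat[i, j] / math.sqrt(lat[i, i] * lat[j, j])
    expected = gp.g1 + gp.b1 * gp.b2 + gp.af1 * gp.r_a * gp.af2
    assert r == pytest.approx(expected, abs=1e-10)
    # factors are unit variance on the generator's scale
    lx, ly = gp.exposure_loadings[0], gp.outcome_loadings[0]
    assert lat[i, i] == pytest.approx(lx**2, abs=1e-10)
    assert lat[j, j] == pytest.approx(ly**2, abs=1e-10)


class TestBidirectional:
    def test_structure_and_identification(self):
        model = tm.build_bidirectional_mrdoc(tm.SSA, tm.PD, tm.PS_SSA,
                                             tm.PS_PD)
        regs = {k: p.label for k, p in model.regressions.items()}
        assert regs[("PD", "SSA")] == "g1" and regs[("SSA", "PD")] == "g2"
        assert regs[("SSA", "PS_SSA")] == "b1_fwd"
        assert regs[("PD", "PS_PD")] == "b1_rev"
        # two instruments identify both causal paths jointly
        assert model.check_identification().identified

    def test_cyclic_reduced_form_is_finite(self):
        model = tm.build_bidirectional_mrdoc(tm.SSA, tm.PD, tm.PS_SSA,
                                             tm.PS_PD)
        model.parameters["g1"].value = 0.3
        model.parameters["g2"].value = 0.2
        _, Sig = model.implied_moments(GroupSpec.mz_pair())
        assert np.isfinite(Sig).all()
        assert np.all(np.linalg.eigvalsh(Sig) > -1e-10)
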