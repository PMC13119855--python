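"""Exposure model, Monte Carlo propagation and Spearman sensitivities."""

import numpy as np
import pandas as pd
import pytest

from soilrisk import risk
from soilrisk.core_io import METALS, ReferenceDataError, SampleTable

POINT_PARAMS = {
    "IngR": 200.0, "InhR": 7.5, "EF": 350.0, "ED": 6.0, "BW": 15.9,
    "SA": 2800.0, "AF": 0.2, "ABS": 0.001, "PEF": 1.36e9,
    "AT_nc": 2190.0, "AT_ca": 25550.0,
}


def one_sample_table(conc: dict) -> SampleTable:
    row = {"sample_id": "P0", "x": 0.0, "y": 0.0, "depth_layer": "surface", "pH": 7.0}
    row.update({m: conc.get(m, 0.0) for m in METALS})
    return SampleTable(data=pd.DataFrame([row]))


def point_scenario(pop="child", **overrides) -> risk.ExposureScenario:
    params = {k: risk.Dist("point", (v,)) for k, v in POINT_PARAMS.items()}
    params.update(overrides)
    return risk.ExposureScenario(pop, params)


class TestAdd:
    def test_zero_concentration_gives_zero_dose(self):
        for pw in ("ingestion", "dermal", "inhalation"):
            assert risk.add(pw, 0.0, POINT_PARAMS) == 0.0

    def test_unit_conversion_ingestion(self):
        """c = 1e6 with IngR·EF·ED/(BW·AT) = 1 gives ADD exactly 1."""
        p = dict(POINT_PARAMS, IngR=1.0, EF=1.0, ED=1.0, BW=1.0, AT_nc=1.0)
        assert risk.add("ingestion", 1e6, p) == pytest.approx(1.0)

    def test_hand_computed_child_arsenic_dose(self):
        """Survey mean As by ingestion under child point parameters."""
        expected = 8.87 * 200 * 350 * 6 / (15.9 * 2190) * 1e-6
        assert risk.add("ingestion", 8.87, POINT_PARAMS) == pytest.approx(
            expected, rel=1e-12
        )
        assert risk.add("ingestion", 8.87, POINT_PARAMS) == pytest.approx(
            1.0702e-4, rel=1e-3
        )

    def test_linearity_in_concentration(self):
        for pw in ("ingestion", "dermal", "inhalation"):
            a1 = risk.add(pw, 3.0, POINT_PARAMS)
            a2 = risk.add(pw, 6.0, POINT_PARAMS)
            assert a2 == pytest.approx(2 * a1, rel=1e-12)

    def test_horizon_selects_averaging_time(self):
        nc = risk.add("ingestion", 1.0, POINT_PARAMS, "nc")
        ca = risk.add("ingestion", 1.0, POINT_PARAMS, "ca")
        assert nc / ca == pytest.approx(25550.0 / 2190.0, rel=1e-12)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            risk.add("ingestion", 1.0, dict(POINT_PARAMS, BW=0.0))
        with pytest.raises(ValueError):
            risk.add("inhalation", 1.0, dict(POINT_PARAMS, PEF=0.0))
        with pytest.raises(ValueError):
            risk.add("licking", 1.0, POINT_PARAMS)


class TestHazardAndCancer:
    def test_add_equal_rfd_gives_unit_hazard(self, reference):
        rfd = reference.reference_dose("Cu", "ingestion")
        hq, hi = risk.hq_hi({("Cu", "ingestion"): rfd}, reference)
        assert hq["Cu"] == pytest.approx(1.0) and hi == pytest.approx(1.0)

    def test_copper_oral_worked_example(self, reference):
        """Cu oral RfD 0.04; ADD 0.004 contributes HQ 0.1."""
        assert reference.reference_dose("Cu", "ingestion") == 0.04
        hq, _ = risk.hq_hi({("Cu", "ingestion"): 0.004}, reference)
        assert hq["Cu"] == pytest.approx(0.1)

    def test_hi_sums_metals(self, reference):
        rfd_cu = reference.reference_dose("Cu", "ingestion")
        rfd_zn = reference.reference_dose("Zn", "ingestion")
        _, hi = risk.hq_hi(
            {("Cu", "ingestion"): 0.3 * rfd_cu, ("Zn", "ingestion"): 0.4 * rfd_zn},
            reference,
        )
        assert hi == pytest.approx(0.7)

    def test_arsenic_oral_slope_worked_example(self, reference):
        assert reference.slope_factor("As", "ingestion") == 1.5
        cr, tcr = risk.cr_tcr({("As", "ingestion"): 1e-6}, reference)
        assert cr["As"] == pytest.approx(1.5e-6)
        assert risk.NOTABLE_RISK < tcr < risk.UNACCEPTABLE_RISK

    def test_cadmium_zero_dose_zero_risk(self, reference):
        assert reference.slope_factor("Cd", "ingestion") == 6.1
        cr, _ = risk.cr_tcr({("Cd", "ingestion"): 0.0}, reference)
        assert cr["Cd"] == 0.0

    def test_tcr_adds_metals(self, reference):
        cr, tcr = risk.cr_tcr(
            {("As", "ingestion"): 2e-7 / 1.5, ("Cd", "ingestion"): 3e-7 / 6.1},
            reference,
        )
        assert tcr == pytest.approx(5e-7)
        assert tcr < risk.NOTABLE_RISK

    def test_non_carcinogen_slope_factor_rejected(self, reference):
        with pytest.raises(ReferenceDataError, match="Cu"):
            risk.cr_tcr({("Cu", "ingestion"): 1e-6}, reference)

    def test_missing_rfd_names_metal_and_pathway(self, reference):
        ref2 = type(reference)(values=reference.values, rfd={}, sf=reference.sf)
        with pytest.raises(ReferenceDataError, match="Cd.*ingestion"):
            risk.hq_hi({("Cd", "ingestion"): 1.0}, ref2)


class TestMonteCarlo:
    def test_degenerate_point_scenario_gives_constant_draws(self, reference):
        table = one_sample_table({"Cu": 100.0, "As": 5.0})
        res = risk.monte_carlo(table, point_scenario(), reference, n_iter=1000, seed=0)
        assert np.ptp(res.hi) == 0 and np.ptp(res.tcr) == 0
        assert res.exceedance["p_hi_gt_1"] in (0.0, 1.0)

    def test_fixed_seed_reproducible(self, survey, reference):
        table, _ = survey
        sc = risk.ExposureScenario.default("child")
        r1 = risk.monte_carlo(table, sc, reference, n_iter=1000, seed=9)
        r2 = risk.monte_carlo(table, sc, reference, n_iter=1000, seed=9)
        np.testing.assert_array_equal(r1.hi, r2.hi)
        np.testing.assert_array_equal(r1.tcr, r2.tcr)
        assert r1.exceedance == r2.exceedance

    def test_additivity_per_draw(self, survey, reference):
        table, _ = survey
        res = risk.monte_carlo(
            table, risk.ExposureScenario.default("child"), reference,
            n_iter=1000, seed=2,
        )
        np.testing.assert_allclose(res.hi, res.hq.sum(axis=1).to_numpy(), rtol=1e-12)
        np.testing.assert_allclose(res.tcr, res.cr.sum(axis=1).to_numpy(), rtol=1e-12)

    def test_concentration_linearity_per_draw(self, reference):
        t1 = one_sample_table({"As": 5.0, "Cu": 50.0})
        t2 = one_sample_table({"As": 10.0, "Cu": 100.0})
        sc = point_scenario()
        r1 = risk.monte_carlo(t1, sc, reference, n_iter=1000, seed=4)
        r2 = risk.monte_carlo(t2, sc, reference, n_iter=1000, seed=4)
        np.testing.assert_allclose(r2.hi, 2 * r1.hi, rtol=1e-12)
        np.testing.assert_allclose(r2.tcr, 2 * r1.tcr, rtol=1e-12)

    def test_uniform_ingestion_gives_analytic_exceedance(self, reference):
        """With IngR ~ U(0, 2a) calibrated so TCR = 1e-6 at IngR = a,
        P(TCR > 1e-6) is exactly 0.5; the estimate must land within
        3 standard errors at 10000 iterations."""
        c_as = 5.0
        sf = reference.slope_factor("As", "ingestion")
        k = c_as * 350.0 * 6.0 / (15.9 * 25550.0) * 1e-6 * sf  # TCR per unit IngR
        a = risk.NOTABLE_RISK / k
        sc = point_scenario(IngR=risk.Dist("uniform", (0.0, 2 * a)))
        res = risk.monte_carlo(
            one_sample_table({"As": c_as}), sc, reference, n_iter=10000, seed=6
        )
        se = np.sqrt(0.25 / 10000)
        assert abs(res.exceedance["p_tcr_gt_1e6"] - 0.5) <= 3 * se

    def test_2d_mode_reports_outer_spread(self, survey, reference):
        table, _ = survey
        res = risk.monte_carlo(
            table, risk.ExposureScenario.default("child"), reference,
            n_iter=1000, seed=3, mode="2d", n_outer=5, n_inner=1000,
        )
        assert res.outer_exceedance is not None and len(res.outer_exceedance) == 5
        assert res.outer_exceedance["p_tcr_gt_1e6"].between(0, 1).all()

    def test_low_iteration_count_rejected(self, reference):
        with pytest.raises(ValueError):
            risk.monte_carlo(
                one_sample_table({"As": 1.0}), point_scenario(), reference, n_iter=10
            )


class TestSensitivity:
    def test_single_varying_input_has_unit_rank_correlation(self, reference):
        sc = point_scenario(IngR=risk.Dist("uniform", (50.0, 300.0)))
        res = risk.monte_carlo(
            one_sample_table({"Cu": 100.0, "As": 5.0}), sc, reference,
            n_iter=2000, seed=1,
        )
        s = risk.sensitivity(res, "HI")
        assert s.loc["IngR", "rho"] == pytest.approx(1.0)

    def test_body_weight_sensitivity_is_negative(self, reference):
        sc = point_scenario(BW=risk.Dist("lognormal", (15.9, 2.9)))
        res = risk.monte_carlo(
            one_sample_table({"Cu": 100.0, "As": 5.0}), sc, reference,
            n_iter=2000, seed=2,
        )
        assert risk.sensitivity(res, "HI").loc["BW", "rho"] == pytest.approx(-1.0)

    def test_default_scenario_signs(self, survey, reference):
        table, _ = survey
        res = risk.monte_carlo(
            table, risk.ExposureScenario.default("child"), reference,
            n_iter=5000, seed=7,
        )
        s = risk.sensitivity(res, "HI")
        assert s.loc["BW", "rho"] < 0
        assert s.loc["IngR", "rho"] > 0
        assert s["contribution_pct"].sum() == pytest.approx(100.0)

    def test_equal_variance_inputs_get_similar_shares(self, reference):
        """Two independent uniform inputs scaled so their dose terms are
        identically distributed should have |rho| within 0.05."""
        # single metal (Cu): HI = const + b·IngR + c·InhR; choose the
        # InhR range so c·InhR matches the distribution of b·IngR
        scale = (
            1e-6 * 1.36e9
            * reference.reference_dose("Cu", "inhalation")
            / reference.reference_dose("Cu", "ingestion")
        )
        sc = point_scenario(
            IngR=risk.Dist("uniform", (100.0, 300.0)),
            InhR=risk.Dist("uniform", (100.0 * scale, 300.0 * scale)),
        )
        res = risk.monte_carlo(
            one_sample_table({"Cu": 100.0}), sc, reference,
            n_iter=20000, seed=8,
        )
        s = risk.sensitivity(res, "HI")
        assert abs(abs(s.loc["IngR", "rho"]) - abs(s.loc["InhR", "rho"])) < 0.05

    def test_pathway_ordering_under_defaults(self, survey, reference):
        """Mean HI decomposes as ingestion > inhalation > dermal under
        the default exposure parameters."""
        table, _ = survey
        conc = table.concentrations("surface").mean()
        params = {k: d.mean() for k, d in
                  risk.ExposureScenario.default("child").parameters.items()}
        contrib = {}
        for pw in ("ingestion", "dermal", "inhalation"):
            contrib[pw] = sum(
                risk.add(pw, conc[m], params) / reference.reference_dose(m, pw)
                for m in METALS
            )
        assert contrib["ingestion"] > contrib["inhalation"] > contrib["dermal"]
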