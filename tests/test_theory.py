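import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from crevo.sampling import calibrate_pool, make_environment
from crevo.theory import (
    TheoryParams,
    alpha_comm_norm2,
    g_statistics,
    load_calibration_table,
    predict_coexistence,
    predict_dfe_correlation,
    predict_sigma_inv,
    predict_survivors,
)


def params(R=200, R0=40, sat=0.5, perm=0.1, C=1.0):
    return TheoryParams(R=R, R0=R0, S=int(sat * R / perm), S_star=sat * R,
                        C=C)


class TestSigmaInv:
    def test_vanishes_at_full_saturation(self):
        assert predict_sigma_inv(params(sat=1.0), 1 / 40) == pytest.approx(0.0)

    def test_vanishes_when_strains_use_every_resource(self):
        assert predict_sigma_inv(params(R0=200), 1 / 200) == pytest.approx(0.0)

    def test_reference_value_scales_with_C(self):
        # ||d_alpha||=1/40, sat=0.5: 0.025*0.5*sqrt(2)*sqrt(0.8/40)*C
        p = params(sat=0.5, C=1.0)
        expected = 0.025 * 0.5 * np.sqrt(2.0) * np.sqrt(0.8 / 40)
        assert predict_sigma_inv(p, 0.025) == pytest.approx(expected)
        p.C = 1.3
        assert predict_sigma_inv(p, 0.025) == pytest.approx(1.3 * expected)


class TestGStatistics:
    def test_fully_shielded_at_saturation(self):
        out = g_statistics(params(sat=1.0), make_environment(200))
        np.testing.assert_allclose(out["mean"], 0.0)
        assert out["sd"] == pytest.approx(0.0)

    def test_uniform_supply_has_zero_mean(self):
        out = g_statistics(params(sat=0.5), make_environment(200))
        np.testing.assert_allclose(out["mean"], 0.0)
        assert out["sd"] > 0

    def test_supply_skew_enters_mean(self):
        env = make_environment(200, mode="cv", cv=0.2)
        out = g_statistics(params(sat=0.6), env)
        np.testing.assert_allclose(
            out["mean"], 0.4 * (env.K / env.K_bar - 1.0))


class TestCoexistence:
    def test_closed_form_reference_value(self):
        # knockout at full saturation, R=200, R0=40:
        # (1/1) * 2*(1/1600) / (2*0.8/40) = 0.03125
        pred = predict_coexistence(params(sat=1.0), 1 / 40)
        assert pred.P_coex_closed_form == pytest.approx(0.03125)

    def test_quadrature_agrees_with_closed_form_at_zero_dX(self):
        p = params(sat=0.5, C=1.2)
        pred = predict_coexistence(p, 1 / 40, dX=0.0)
        assert pred.P_coex == pytest.approx(pred.P_coex_closed_form,
                                            rel=0.15)

    def test_vanishing_phenotype_cannot_coexist(self):
        pred = predict_coexistence(params(sat=0.5), 1e-9)
        assert pred.P_coex < 1e-12

    def test_direct_cost_enhances_and_benefit_suppresses(self):
        # small-effect mutation so the coexistence threshold is far below
        # the DFE width, where the asymptotic ratio regimes are stated
        p = params(sat=0.5, C=1.0)
        nd = 0.1 / 40
        sigma = predict_sigma_inv(p, nd)
        base = predict_coexistence(p, nd, dX=0.0).P_coex
        costly = predict_coexistence(p, nd, dX=-3 * sigma)
        boosted = predict_coexistence(p, nd, dX=3 * sigma)
        assert costly.P_coex > base > boosted.P_coex
        assert costly.regime == "direct_cost_enhanced"
        assert boosted.regime == "direct_benefit_suppressed"
        # asymptotic factor matches the quadrature ratio within a factor 2
        assert costly.delta_X_factor == pytest.approx(9.0)
        assert 0.5 < (costly.P_coex / base) / costly.delta_X_factor < 2.0
        assert 0.5 < (boosted.P_coex / base) / boosted.delta_X_factor < 2.0

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(sat=st.floats(0.1, 1.0), R0=st.floats(2.0, 199.0),
           scale=st.floats(0.1, 1.0))
    def test_closed_form_properties(self, sat, R0, scale):
        # in [0,1]; decreasing in saturation and in R0; quadratic in effect
        p = params(R0=R0, sat=sat)
        nd = scale / R0
        pred = predict_coexistence(p, nd)
        assert 0.0 <= pred.P_coex_closed_form <= 1.0
        if sat < 0.95:
            p2 = params(R0=R0, sat=sat + 0.05)
            assert predict_coexistence(p2, nd).P_coex_closed_form <= \
                pred.P_coex_closed_form + 1e-12


class TestDFECorrelationPrediction:
    def test_uniform_supply_uncorrelated(self):
        assert predict_dfe_correlation(
            params(sat=0.5), make_environment(200)) == pytest.approx(0.0)

    def test_large_supply_variance_saturates_to_one(self):
        env = make_environment(200, mode="cv", cv=0.9)
        r = predict_dfe_correlation(params(sat=0.9, C=0.5), env)
        assert r > 0.9

    def test_monotone_in_supply_variance(self):
        p = params(sat=0.6)
        rs = [predict_dfe_correlation(p, make_environment(200, mode="cv",
                                                          cv=cv))
              for cv in (0.05, 0.1, 0.2, 0.4)]
        assert all(b > a for a, b in zip(rs, rs[1:]))


class TestSurvivorSurrogate:
    def test_table_is_packaged_and_well_formed(self):
        table = load_calibration_table()
        assert len(table["entries"]) > 10
        for e in table["entries"][:5]:
            assert set(e) >= {"R", "R0", "S", "std_X", "mean_S_star"}

    def test_prediction_bounded_by_R_and_monotone_in_spread(self):
        env = make_environment(200)
        preds = [predict_survivors(1200, sx, 200, 40, env).S_star
                 for sx in (0.002, 0.01, 0.04, 0.1)]
        assert all(p <= 200 for p in preds)
        assert all(b < a for a, b in zip(preds, preds[1:]))

    def test_table_source_used_for_tabulated_ensemble(self):
        pred = predict_survivors(1200, 0.01, 200, 40, make_environment(200))
        assert pred.source == "table"
        assert pred.C > 0

    def test_pilot_fallback_for_untabulated_ensemble(self):
        pred = predict_survivors(40, 0.05, 12, 4, make_environment(12),
                                 n_pilot=4, seed=0)
        assert pred.source == "pilot"
        assert 0 < pred.S_star <= 12


class TestCalibration:
    def test_pool_size_from_definitions(self):
        # target S*/R = 0.5 at S*/S = 0.1 with R=200 implies S = 1000
        cal = calibrate_pool(0.5, 0.1, 200, 40, make_environment(200))
        assert cal.S == 1000

    def test_calibrated_spread_hits_target_saturation(self):
        # feed the calibrated (S, std_X) back through assembly
        from crevo.equilibrium import compute_equilibrium
        from crevo.sampling import sample_pool

        cal = calibrate_pool(0.6, 0.1, 200, 40, make_environment(200))
        env = make_environment(200)
        stars = []
        for sd in range(8):
            pool = sample_pool(200, 40, cal.S, cal.std_X, seed=6000 + sd)
            stars.append(compute_equilibrium(pool, env).n_survivors)
        assert abs(np.mean(stars) / 200 - 0.6) < 0.05 * 0.6 + 0.02

    def test_unreachable_saturation_flagged(self):
        cal = calibrate_pool(1.0, 0.5, 200, 40, make_environment(200))
        assert cal.flag == "closest_achievable" or cal.predicted_S_star >= 190

    def test_invalid_targets_rejected(self):
        env = make_environment(200)
        with pytest.raises(ValueError):
            calibrate_pool(1.5, 0.1, 200, 40, env)
        with pytest.raises(ValueError):
            calibrate_pool(0.5, 0.0, 200, 40, env)


class TestAlphaCommNorm:
    def test_reference_value(self):
        assert alpha_comm_norm2(200, 40) == pytest.approx(2 * 0.8 / 40)
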