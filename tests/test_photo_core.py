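"""Demand-side biochemistry: kinetics, electron transport, rate selection."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from photoensemble.models import MODEL_IDS, all_models, model_from_id
from photoensemble.params import Environment, PhotoParams
from photoensemble.photo_core import (
    ac_gross,
    aj_gross,
    ap_gross,
    assimilation_at_ci,
    demand_a_net,
    electron_transport,
    gamma_star,
    net_assimilation,
    select_rate,
    smaller_root,
)


class TestGammaStar:
    def test_kinetic_constants_value(self):
        p = PhotoParams(ko_kc_ratio=0.21, kc_half=46.0, ko_half=33.0)
        e = Environment(oi=21.0)
        assert gamma_star(p, e) == pytest.approx(0.21 * 46 * 21 / (2 * 33))
        assert gamma_star(p, e) == pytest.approx(3.074, abs=5e-4)

    def test_no_oxygen_no_photorespiration(self):
        assert gamma_star(PhotoParams(), Environment(oi=0.0)) == 0.0

    def test_proportional_to_turnover_ratio(self):
        p = PhotoParams(ko_kc_ratio=0.21)
        p2 = PhotoParams(ko_kc_ratio=0.42)
        e = Environment()
        assert gamma_star(p2, e) == pytest.approx(2 * gamma_star(p, e))

    def test_nonpositive_ko_rejected(self):
        with pytest.raises(ValueError):
            gamma_star(PhotoParams(ko_half=0.0), Environment())


class TestDerivedParameters:
    def test_jmax_linear_in_vcmax(self):
        p = PhotoParams(a_jv=29.1, b_jv=1.6355, vcmax25=50.0)
        assert p.jmax25 == pytest.approx(110.875)

    def test_tpu_scaling(self):
        assert PhotoParams(b_tv=0.167, vcmax25=50.0).tpu25 == pytest.approx(8.35)

    def test_rd_scaling(self):
        assert PhotoParams(b_rv=0.015, vcmax25=200.0).rd == pytest.approx(3.0)

    def test_alpha_i_derived_from_f(self):
        assert PhotoParams(f_loss=0.23).alpha_i == pytest.approx(0.385)


class TestCarboxylation:
    def test_michaelis_menten_value(self):
        p = PhotoParams(vcmax25=50.0, kc_half=40.45, ko_half=27.85)
        e = Environment(oi=21.0)
        # effective K_m = 40.45 (1 + 21/27.85) = 70.95 Pa
        assert ac_gross(40.0, p, e) == pytest.approx(50 * 40 / (40 + 70.95), abs=1e-3)
        assert ac_gross(40.0, p, e) == pytest.approx(18.03, abs=0.01)

    def test_saturates_at_vcmax(self):
        p = PhotoParams(vcmax25=50.0)
        assert ac_gross(1e9, p, Environment()) == pytest.approx(50.0, rel=1e-6)

    def test_zero_at_zero_ci(self):
        assert ac_gross(0.0, PhotoParams(), Environment()) == 0.0

    def test_negative_ci_rejected(self):
        with pytest.raises(ValueError):
            ac_gross(-1.0, PhotoParams(), Environment())


class TestElectronTransport:
    def test_linear_has_no_maximum(self):
        p = PhotoParams(absorptance_a=0.8, f_loss=0.23)
        assert electron_transport(1000.0, p, "linear_cbgb") == pytest.approx(308.0)

    def test_harley_asymptote_is_jmax(self):
        p = PhotoParams()
        j = electron_transport(1e8, p, "hyperbola_harley")
        assert j == pytest.approx(p.jmax25, rel=1e-4)

    def test_nonrect_theta_one_is_minimum(self):
        p = PhotoParams(theta_j=1.0, absorptance_a=0.8, f_loss=0.23)
        j = electron_transport(1000.0, p, "nonrect_fw")
        assert j == pytest.approx(min(308.0, p.jmax25))

    def test_nonrect_smaller_root_value(self):
        p = PhotoParams(theta_j=0.9, absorptance_a=0.8, f_loss=0.23,
                        jmax25_fixed=110.9)
        # smaller root of 0.9 J^2 - (308 + 110.9) J + 308*110.9 = 0
        roots = np.roots([0.9, -(308 + 110.9), 308 * 110.9])
        assert electron_transport(1000.0, p, "nonrect_fw") == pytest.approx(
            roots.min(), rel=1e-9)
        assert electron_transport(1000.0, p, "nonrect_fw") == pytest.approx(105.4, abs=0.1)

    def test_nonpositive_jmax_rejected(self):
        p = PhotoParams(jmax25_fixed=0.0)
        with pytest.raises(ValueError):
            electron_transport(100.0, p, "nonrect_fw")


class TestRubpRegeneration:
    def test_value(self):
        assert aj_gross(40.0, 110.0, 3.07) == pytest.approx(
            (110 / 4) * 40 / (40 + 2 * 3.07))
        assert aj_gross(40.0, 110.0, 3.07) == pytest.approx(23.84, abs=0.01)

    def test_limits(self):
        assert aj_gross(1e9, 110.0, 3.07) == pytest.approx(27.5, rel=1e-6)
        assert aj_gross(0.0, 110.0, 3.07) == 0.0


class TestTpuLimitation:
    def test_closed_cycle_recovers_3tpu(self):
        # with alpha_tpu = 0, the photorespiration factor cancels the Ci ratio
        ci, gstar, tpu = 40.0, 3.07, 8.35
        ap = ap_gross(ci, tpu, 0.0, gstar)
        assert ap * (1 - gstar / ci) == pytest.approx(3 * tpu, rel=1e-12)

    def test_open_cycle_value(self):
        ap = ap_gross(40.0, 8.35, 0.5, 3.07)
        assert ap == pytest.approx(3 * 8.35 * 40 / (40 - 2.5 * 3.07))
        assert ap == pytest.approx(31.0, abs=0.06)

    def test_singular_region_flagged_not_raised(self):
        assert np.isinf(ap_gross(2.0, 8.35, 0.5, 3.07))
        assert np.isinf(ap_gross(0.0, 8.35, 0.0, 3.07))


class TestSmallerRoot:
    def test_theta_one_factorizes_to_minimum(self):
        assert smaller_root(1.0, 18.0, 24.0) == pytest.approx(18.0)

    def test_theta_zero_rectangular_hyperbola(self):
        assert smaller_root(0.0, 10.0, 10.0) == pytest.approx(5.0)

    def test_equal_rates_closed_form(self):
        theta = 0.95
        expected = (1 - np.sqrt(1 - theta)) / theta
        assert smaller_root(theta, 7.0, 7.0) == pytest.approx(7.0 * expected)
        assert smaller_root(0.95, 1.0, 1.0) == pytest.approx(0.8173, abs=5e-5)

    def test_domain(self):
        with pytest.raises(ValueError):
            smaller_root(1.5, 1.0, 2.0)

    def test_matches_grid_search_oracle(self, rng):
        """Dense-grid root location agrees to <=1e-9 relative on 10^3 triples."""
        theta = rng.uniform(0.0, 1.0, 1000)
        x1 = rng.uniform(0.1, 50.0, 1000)
        x2 = rng.uniform(0.1, 50.0, 1000)
        got = smaller_root(theta, x1, x2)
        for i in range(1000):
            z = np.linspace(0.0, min(x1[i], x2[i]), 4000)
            q = theta[i] * z**2 - (x1[i] + x2[i]) * z + x1[i] * x2[i]
            # refine the bracket where the polynomial changes sign
            k = np.flatnonzero(np.diff(np.signbit(q)))[0]
            lo_, hi_ = z[k], z[k + 1]
            for _ in range(60):
                mid = 0.5 * (lo_ + hi_)
                if theta[i] * mid**2 - (x1[i] + x2[i]) * mid + x1[i] * x2[i] > 0:
                    lo_ = mid
                else:
                    hi_ = mid
            assert got[i] == pytest.approx(0.5 * (lo_ + hi_), rel=1e-9, abs=1e-9)

    @settings(deadline=None, max_examples=200)
    @given(theta=st.floats(0.0, 1.0), x1=st.floats(0.0, 1e3), x2=st.floats(0.0, 1e3))
    def test_never_exceeds_minimum(self, theta, x1, x2):
        r = smaller_root(theta, x1, x2)
        assert r <= min(x1, x2) + 1e-9
        assert r >= 0.0


class TestSelection:
    def test_minimum_labels_smallest_rate(self, central):
        cfg = model_from_id("M1211")
        ag, _, state = select_rate(18.0, 23.8, 31.0, cfg, central)
        assert ag == 18.0 and state == "Ac"

    def test_smoothing_with_unit_thetas_equals_minimum(self, central, rng):
        p = central.replace(theta_cj=1.0, theta_cjp=1.0)
        cfg_min = model_from_id("M1211")
        cfg_sm = model_from_id("M1221")
        for _ in range(20):
            rates = rng.uniform(1.0, 40.0, 3)
            ag_min, _, _ = select_rate(*rates, cfg_min, p)
            ag_sm, _, _ = select_rate(*rates, cfg_sm, p)
            assert ag_sm == pytest.approx(ag_min, rel=1e-12)

    def test_triple_colimitation_scalar(self, central):
        p = central.replace(theta_cj=0.95, theta_cjp=0.98)
        cfg = model_from_id("M1221")
        a = 17.3
        ag, _, _ = select_rate(a, a, a, cfg, p)
        assert ag / a == pytest.approx(0.77, abs=5e-3)

    def test_smoothing_below_minimum_with_equality_iff_theta_one(self, rng):
        """10^4 random draws: smoothed A_g <= min(rates); equal only at θ=1."""
        n = 10_000
        ac = rng.uniform(0.5, 40.0, n)
        aj = rng.uniform(0.5, 40.0, n)
        ap = rng.uniform(0.5, 40.0, n)
        theta_cj = rng.uniform(0.0, 1.0, n)
        theta_cjp = rng.uniform(0.0, 1.0, n)
        # exercise the exact-equality branch too
        theta_cj[:500] = 1.0
        theta_cjp[:500] = 1.0
        p = PhotoParams(theta_cj=theta_cj, theta_cjp=theta_cjp)
        cfg = model_from_id("M1221")
        ag, _, _ = select_rate(ac, aj, ap, cfg, p)
        mn = np.minimum(np.minimum(ac, aj), ap)
        assert np.all(ag <= mn + 1e-10)
        both_one = (theta_cj == 1.0) & (theta_cjp == 1.0)
        assert np.allclose(ag[both_one], mn[both_one], rtol=1e-12)
        assert np.all(ag[~both_one] < mn[~both_one])


class TestNetAssimilation:
    def test_compensation_point(self):
        assert net_assimilation(18.0, 3.07, 3.07, 0.75) == pytest.approx(-0.75)

    def test_value(self):
        assert net_assimilation(18.03, 40.0, 3.07, 0.75) == pytest.approx(15.90, abs=0.01)

    def test_zero_ci_rejected(self):
        with pytest.raises(ValueError):
            net_assimilation(10.0, 0.0, 3.0, 0.5)


class TestFullChain:
    def test_tpu_inactive_at_low_ci(self, central, env):
        r1 = assimilation_at_ci(10.0, env, central, model_from_id("M1111"))
        r2 = assimilation_at_ci(10.0, env, central, model_from_id("M1211"))
        assert r1.a_net == pytest.approx(r2.a_net, rel=1e-12)

    def test_smoothing_never_above_minimum_selection(self, central, env):
        # above Γ* (≈3.2 Pa), where the photorespiration factor is positive
        ci = np.linspace(4.0, 120.0, 80)
        for tpu in "12":
            for et in "123":
                a_min = demand_a_net(ci, central, env, model_from_id(f"M1{tpu}1{et}"))
                a_sm = demand_a_net(ci, central, env, model_from_id(f"M1{tpu}2{et}"))
                assert np.all(a_sm <= a_min + 1e-10)

    def test_unit_theta_smoothing_reproduces_minimum_model(self, central, env):
        p = central.replace(theta_cj=1.0, theta_cjp=1.0)
        ci = np.linspace(1.0, 120.0, 200)
        a1 = demand_a_net(ci, p, env, model_from_id("M1111"))
        a2 = demand_a_net(ci, p, env, model_from_id("M1121"))
        np.testing.assert_allclose(a1, a2, rtol=1e-11)

    def test_monotone_in_ci_and_irradiance(self, central):
        """A is non-decreasing in Ci and I for all 12 members.

        With an open photorespiratory cycle (α_tpu > 0) the TPU-limited rate
        genuinely *declines* with Ci (reversed sensitivity), so the Ci sweep
        uses a closed cycle (α_tpu = 0); the I sweep keeps the central value.
        """
        for cfg in all_models():
            p = central.replace(alpha_tpu=0.0)
            lo = 3.3 + 1.0 if cfg.tpu_included else 1.0
            ci = np.linspace(lo, 150.0, 120)
            a = demand_a_net(ci, p, Environment(irradiance=800.0), cfg)
            assert np.all(np.diff(a) >= -1e-9), cfg.model_id
            irr = np.linspace(0.0, 2000.0, 120)
            a_i = demand_a_net(40.0, p, Environment(irradiance=irr), cfg)
            assert np.all(np.diff(a_i) >= -1e-9), cfg.model_id


class TestModelRegistry:
    def test_exactly_twelve_distinct_members(self):
        assert len(MODEL_IDS) == 12
        assert len(set(MODEL_IDS)) == 12

    def test_id_round_trip(self):
        for cfg in all_models():
            assert model_from_id(cfg.model_id) == cfg

    def test_known_combinations(self):
        cbgb = model_from_id("M1223")
        assert cbgb.tpu_included and cbgb.selection == "quadratic_smoothing"
        assert cbgb.etrans_hypothesis == "linear_cbgb"
        fvcb = model_from_id("M1111")
        assert not fvcb.tpu_included and fvcb.selection == "minimum"
        assert fvcb.etrans_hypothesis == "nonrect_fw"

    @pytest.mark.parametrize("bad", ["M1311", "M2111", "M111", "X1111", "M1114"])
    def test_invalid_ids_rejected(self, bad):
        with pytest.raises(ValueError):
            model_from_id(bad)
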