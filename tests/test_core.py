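"""Equilibrium algebra: occupancies, conductivities, rectification, currents."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import kirpop as kp
from kirpop.core import ParameterError

from oracles import balance_occupancy_pocket, balance_occupancy_two_site

conc = st.floats(min_value=0.0, max_value=1e4)
kconst = st.floats(min_value=1e-3, max_value=1e3)
hfactor = st.floats(min_value=0.0, max_value=5.0)


class TestOccupancy:
    def test_drug_free_state(self):
        assert kp.occupancy_pocket(0.0, 6, 6).as_tuple() == (1.0, 0.0, 0.0)
        assert kp.occupancy_two_site(0.0, 0.5, 150).as_tuple() == (1.0, 0.0, 0.0)

    @pytest.mark.parametrize("K", [0.01, 1.0, 42.0])
    def test_pocket_equipartition_at_c_equals_K(self, K):
        occ = kp.occupancy_pocket(K, K, K)
        assert occ.as_array() == pytest.approx([1 / 3] * 3, abs=1e-12)

    def test_pocket_worked_example(self):
        # c=20 mM, K1=K2=6 mM: exact fractions 9/139, 30/139, 100/139
        occ = kp.occupancy_pocket(20.0, 6.0, 6.0)
        assert occ.x0 == pytest.approx(9 / 139, rel=1e-12)
        assert occ.x1 == pytest.approx(30 / 139, rel=1e-12)
        assert occ.x2 == pytest.approx(100 / 139, rel=1e-12)

    def test_two_site_worked_example(self):
        # c=20 mM, K3=0.5, K4=150: exact fractions 15/617, 600/617, 2/617
        occ = kp.occupancy_two_site(20.0, 0.5, 150.0)
        assert occ.x0 == pytest.approx(15 / 617, rel=1e-12)
        assert occ.x1 == pytest.approx(600 / 617, rel=1e-12)
        assert occ.x2 == pytest.approx(2 / 617, rel=1e-12)

    def test_unbound_second_site_is_exactly_empty(self):
        for c in (0.0, 1.0, 1e6):
            assert kp.occupancy_two_site(c, 1.0, math.inf).x2 == 0.0

    @given(c=conc, K1=kconst, K2=kconst)
    def test_pocket_matches_balance_system(self, c, K1, K2):
        occ = kp.occupancy_pocket(c, K1, K2).as_array()
        ref = balance_occupancy_pocket(c, K1, K2)
        assert np.max(np.abs(occ - ref)) < 1e-10

    @given(c=conc, K3=kconst, K4=kconst)
    def test_two_site_matches_balance_system(self, c, K3, K4):
        occ = kp.occupancy_two_site(c, K3, K4).as_array()
        ref = balance_occupancy_two_site(c, K3, K4)
        assert np.max(np.abs(occ - ref)) < 1e-10

    @given(c=conc, K1=kconst, K2=kconst, K3=kconst, K4=kconst)
    def test_triples_normalised_and_bounded(self, c, K1, K2, K3, K4):
        for occ in (kp.occupancy_pocket(c, K1, K2),
                    kp.occupancy_two_site(c, K3, K4)):
            arr = occ.as_array()
            assert abs(arr.sum() - 1.0) < 1e-12
            assert np.all(arr >= 0) and np.all(arr <= 1)

    @given(K1=kconst, K2=kconst)
    def test_pocket_double_occupancy_saturates(self, K1, K2):
        cs = np.geomspace(1e-3, 1e9, 40)
        x2 = kp.occupancy_pocket(cs, K1, K2).x2
        assert np.all(np.diff(x2) >= -1e-12)
        assert x2[-1] > 1 - 1e-3

    @given(K3=kconst, K4=kconst)
    def test_two_site_empty_state_decreases(self, K3, K4):
        cs = np.geomspace(1e-3, 1e6, 40)
        x0 = kp.occupancy_two_site(cs, K3, K4).x0
        assert np.all(np.diff(x0) <= 1e-12)

    @pytest.mark.parametrize("bad", [
        lambda: kp.occupancy_pocket(-1.0, 6, 6),
        lambda: kp.occupancy_pocket(1.0, 0.0, 6),
        lambda: kp.occupancy_pocket(1.0, 6, math.inf),
        lambda: kp.occupancy_two_site(1.0, -0.5, 150),
        lambda: kp.occupancy_two_site(-1.0, 0.5, 150),
    ])
    def test_invalid_inputs_rejected(self, bad):
        with pytest.raises(ParameterError):
            bad()


class TestConductivityFactor:
    @given(a=st.floats(min_value=1e-6, max_value=5.0), c=conc)
    def test_equal_h_population_is_flat(self, a, c):
        pop = kp.PopulationParams(kp.Scheme.SEQUENTIAL_POCKET, (6.0, 6.0),
                                  (a, a, a))
        assert pop.conductivity_factor(c) == pytest.approx(a, rel=1e-12)

    def test_drug_free_factor_is_h0(self, eth_const):
        for _, pop in eth_const.populations:
            assert pop.conductivity_factor(0.0) == pop.h[0]

    def test_worked_example_population1(self, eth_const):
        # Table row I_KAch_CONST, population 1 at 20 mM: (9*0.013+30*0.2+100*0.035)/139
        _, pop1 = eth_const.populations[0]
        expected = (9 * 0.013 + 30 * 0.2 + 100 * 0.035) / 139
        assert kp.population_conductivity_factor(pop1, 20.0) == pytest.approx(
            expected, rel=1e-12)


class TestRectification:
    def test_limits(self):
        r = kp.DEFAULT_RECTIFICATION
        assert kp.rectification_g(-1e4, r) == pytest.approx(0.8 * 3.325, rel=1e-9)
        assert kp.rectification_g(1e4, r) == pytest.approx(0.0, abs=1e-12)

    def test_value_at_minus_80(self):
        # independent arithmetic: 0.8*(0.325/2 + 3/(1+exp(70/52)))
        expected = 0.8 * (0.325 / (1 + math.exp(0.0))
                          + 3.0 / (1 + math.exp(70.0 / 52.0)))
        assert kp.rectification_g(-80.0) == pytest.approx(expected, rel=1e-12)
        assert kp.rectification_g(-80.0) == pytest.approx(0.6256, abs=5e-4)

    def test_monotone_non_increasing_and_positive(self):
        u = np.linspace(-200, 50, 500)
        g = kp.rectification_g(u)
        assert np.all(g > 0)
        assert np.all(np.diff(g) <= 0)

    def test_global_scale_multiplies(self):
        r = kp.RectificationParams(global_scale=0.5)
        assert kp.rectification_g(-110.0, r) == pytest.approx(
            0.5 * kp.rectification_g(-110.0), rel=1e-12)

    def test_invalid_slope_rejected(self):
        with pytest.raises(ParameterError):
            kp.RectificationParams(terms=((1.0, 0.0, 0.0),))


class TestCurrent:
    def test_zero_at_reversal_voltage(self, eth_const):
        assert kp.steady_state_current(eth_const, eth_const.U_K, 20.0) == 0.0

    def test_drug_free_reduces_to_baseline(self, eth_const):
        U = -110.0
        expected = (eth_const.baseline_factor()
                    * kp.rectification_g(U) * (U - eth_const.U_K))
        assert kp.steady_state_current(eth_const, U, 0.0) == pytest.approx(
            expected, rel=1e-12)

    def test_current_ratio_equals_relative_effect_any_reversal(self, eth_const):
        import dataclasses
        for U_K in (-85.0, -92.3):
            m = dataclasses.replace(eth_const, U_K=U_K)
            ratio = (kp.steady_state_current(m, -110.0, 20.0)
                     / kp.steady_state_current(m, -110.0, 0.0))
            assert ratio == pytest.approx(kp.relative_effect(m, 20.0), rel=1e-12)

    @given(U=st.floats(min_value=-140, max_value=-20), c=conc)
    def test_linear_in_driving_force_after_rectification(self, eth_ach, U, c):
        m = eth_ach
        I = kp.steady_state_current(m, U, c)
        slope = I / ((U - m.U_K) * kp.rectification_g(U)) if U != m.U_K else None
        if slope is not None:
            assert slope == pytest.approx(m.conductivity_factor(c), rel=1e-9)


class TestRelativeEffect:
    def test_unity_at_zero_concentration(self, all_components):
        for m in all_components.values():
            assert kp.relative_effect(m, 0.0) == 1.0

    def test_worked_example_const_ethanol_20mM(self, eth_const):
        # brute-force independent arithmetic of the full chain
        x = balance_occupancy_pocket(20.0, 6.0, 6.0)
        fac1 = x @ np.array([0.013, 0.2, 0.035])
        y = balance_occupancy_two_site(20.0, 0.5, 150.0)
        fac2 = y @ np.array([0.09, 0.09, 0.09])
        expected = (0.68 * fac1 + 0.32 * fac2) / (0.68 * 0.013 + 0.32 * 0.09)
        F = kp.relative_effect(eth_const, 20.0)
        assert F == pytest.approx(expected, rel=1e-12)
        assert F == pytest.approx(2.0, abs=0.05)

    def test_voltage_independent_without_override(self, eth_ach):
        vals = [kp.relative_effect(eth_ach, 20.0, U=u)
                for u in np.linspace(-140, -20, 25)]
        assert np.ptp(vals) < 1e-12 * abs(np.mean(vals))

    def test_saturating_limit(self, eth_ach):
        # pocket saturates to state 2; two-site splits K4:K3 between sites
        (f1, pop1), (f2, pop2) = eth_ach.populations
        K3, K4 = pop2.K
        fac2_inf = (pop2.h[1] * K4 + pop2.h[2] * K3) / (K3 + K4)
        expected = (f1 * pop1.h[2] + f2 * fac2_inf) / eth_ach.baseline_factor()
        assert kp.relative_effect(eth_ach, 1e12) == pytest.approx(expected,
                                                                  rel=1e-6)

    def test_degenerate_baseline_rejected(self):
        pop = kp.PopulationParams(kp.Scheme.SEQUENTIAL_POCKET, (6.0, 6.0),
                                  (0.0, 1.0, 1.0))
        m = kp.ModelParams(populations=((1.0, pop),))
        with pytest.raises(kp.DegenerateModelError):
            kp.relative_effect(m, 5.0)

    @given(f1=st.floats(min_value=0.0, max_value=1.0),
           c=conc, K1=kconst, K3=kconst,
           h=st.tuples(*[st.floats(min_value=1e-3, max_value=3.0)] * 6))
    def test_voltage_cancellation_randomised(self, f1, c, K1, K3, h):
        pop1 = kp.PopulationParams(kp.Scheme.SEQUENTIAL_POCKET, (K1, K1),
                                   h[:3])
        pop2 = kp.PopulationParams(kp.Scheme.TWO_SITE, (K3, 10 * K3), h[3:])
        m = kp.ModelParams(populations=((f1, pop1), (1 - f1, pop2)))
        F_alg = kp.relative_effect(m, c)
        for U in (-120.0, -60.0):
            ratio = (kp.steady_state_current(m, U, c)
                     / kp.steady_state_current(m, U, 0.0))
            assert ratio == pytest.approx(F_alg, rel=1e-9)


class TestConcentrationResponse:
    def test_single_population_constituent_equals_total(self):
        pop = kp.PopulationParams(kp.Scheme.SEQUENTIAL_POCKET, (6.0, 6.0),
                                  (0.1, 0.5, 0.2))
        m = kp.ModelParams(populations=((1.0, pop),))
        df = kp.concentration_response(m, [0.0, 1.0, 10.0])
        assert np.allclose(df["I_pop1"], df["I_total"])

    def test_equal_h_population_flat_constituent(self, eth_const):
        df = kp.concentration_response(eth_const, np.geomspace(0.01, 1e3, 30))
        assert np.ptp(df["I_pop2"]) == pytest.approx(0.0, abs=1e-15)
        assert df["I_pop2"].iloc[0] == pytest.approx(0.32 * 0.09, rel=1e-12)

    def test_constituents_sum_to_total_with_voltage(self, eth_ach):
        df = kp.concentration_response(eth_ach, [0.0, 2.0, 50.0], U=-110.0)
        assert np.allclose(df["I_pop1"] + df["I_pop2"], df["I_total"],
                           rtol=1e-12)

    def test_ach_ethanol_biphasic(self, eth_ach):
        c = np.geomspace(0.1, 200, 120)
        F = np.asarray(kp.concentration_response(eth_ach, c)["F"])
        imax = int(F.argmax())
        assert 0 < imax < len(c) - 1
        assert F[imax] > F[0] and F[imax] > F[-1]
        # peak between the inhibition (K3=0.4) and activation (K1=36) scales
        assert 0.4 < c[imax] < 200


class TestIVCurve:
    def test_baseline_when_no_drug_no_shift(self, eth_const):
        u = np.linspace(-120, -20, 21)
        df = kp.iv_curve(eth_const, u, 0.0, delta_f=0.0)
        expected = (eth_const.baseline_factor() * kp.rectification_g(u)
                    * (u - eth_const.U_K))
        assert np.allclose(df["I_control"], expected, rtol=1e-12)
        assert np.allclose(df["I_drug"], expected, rtol=1e-12)

    def test_activation_const_ethanol(self, eth_const):
        u = np.linspace(-120, -90, 16)
        df = kp.iv_curve(eth_const, u, 20.0, delta_f=0.19)
        assert np.all(np.abs(df["I_drug"]) > np.abs(df["I_control"]))

    def test_inhibition_ach_ethanol_large_negative_shift(self, eth_ach):
        u = np.linspace(-120, -90, 16)
        df = kp.iv_curve(eth_ach, u, 20.0, delta_f=-0.6)
        assert np.all(np.abs(df["I_drug"]) < np.abs(df["I_control"]))

    def test_vanishes_at_reversal(self, eth_const):
        df = kp.iv_curve(eth_const, [eth_const.U_K], 20.0, delta_f=0.1)
        assert float(df["I_control"].iloc[0]) == 0.0
        assert float(df["I_drug"].iloc[0]) == 0.0

    def test_out_of_range_redistribution_rejected(self, eth_const):
        with pytest.raises(ParameterError):
            kp.iv_curve(eth_const, [-110.0], 20.0, delta_f=0.5)


class TestModelParams:
    def test_fraction_constraints(self):
        pop = kp.PopulationParams(kp.Scheme.SEQUENTIAL_POCKET, (6.0, 6.0),
                                  (0.1, 0.1, 0.1))
        with pytest.raises(ParameterError):
            kp.ModelParams(populations=((0.6, pop), (0.6, pop)))
        with pytest.raises(ParameterError):
            kp.ModelParams(populations=())

    def test_override_applied_only_at_exact_voltage(self, nic_ach):
        assert nic_ach.at_voltage(-110.0).populations[0][1].h[2] == 0.037
        assert nic_ach.at_voltage(-50.0).populations[0][1].h[2] == 0.085
        assert nic_ach.at_voltage(-109.9).populations[0][1].h[2] == 0.085

    def test_general_n_populations(self):
        pops = tuple(
            (1 / 3, kp.PopulationParams(kp.Scheme.SEQUENTIAL_POCKET,
                                        (k, k), (0.1, 0.2, 0.3)))
            for k in (1.0, 5.0, 20.0))
        m = kp.ModelParams(populations=pops)
        assert m.n_populations == 3
        assert kp.relative_effect(m, 0.0) == 1.0
        assert kp.steady_state_current(m, m.U_K, 3.0) == 0.0
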