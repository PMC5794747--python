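"""Unit and property tests for the gating forward model."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from navclamp import gating_model as gm
from navclamp.gating_model import GateState


class TestBoltzmann:
    def test_midpoint_is_half(self, wt):
        assert gm.boltzmann(wt.act_v12, wt.act_v12, wt.act_k) == pytest.approx(0.5)

    def test_saturates_to_one(self, wt):
        assert gm.boltzmann(500.0, wt.act_v12, wt.act_k) == pytest.approx(1.0, abs=1e-12)

    def test_one_slope_above_midpoint(self, wt):
        # V1/2 + |k| lands at 1/(1+e^-1)
        v = wt.act_v12 + abs(wt.act_k)
        assert gm.boltzmann(v, wt.act_v12, wt.act_k) == pytest.approx(1 / (1 + math.e**-1), abs=1e-6)

    def test_zero_slope_rejected(self):
        with pytest.raises(ValueError):
            gm.boltzmann(0.0, -30.0, 0.0)

    def test_sign_convention_bijective(self, wt):
        # magnitude is used; the reported sign only encodes direction
        assert gm.boltzmann(-20.0, -27.5, -5.8) == gm.boltzmann(-20.0, -27.5, 5.8)

    @given(v=st.floats(-200, 100), v12=st.floats(-120, 0), k=st.floats(1, 20))
    @settings(max_examples=100, derandomize=True)
    def test_bounded_probability(self, v, v12, k):
        p = gm.boltzmann(v, v12, k)
        q = gm.boltzmann(v, v12, k, "falling")
        assert 0.0 <= p <= 1.0 and 0.0 <= q <= 1.0


class TestSteadyStateCurves:
    def test_h_inf_midpoint(self, wt):
        assert gm.h_inf(wt.inact_v12, wt) == pytest.approx(0.5)

    def test_r1451l_availability_at_rest(self, r1451l):
        # hyperpolarized-shifted SSI leaves only ~1/3 of channels available at -85 mV
        assert gm.h_inf(-85.0, r1451l) == pytest.approx(0.327, abs=0.001)

    def test_wt_fully_available_hyperpolarized(self, wt):
        assert gm.h_inf(-140.0, wt) > 0.999

    def test_monotone_on_grid(self, variants_22):
        v = np.arange(-200.0, 100.0, 1.0)
        for p in variants_22.values():
            act = gm.act_inf(v, p)
            hh = gm.h_inf(v, p)
            assert np.all(np.diff(act) > 0)
            assert np.all(np.diff(hh) < 0)


class TestTauH:
    def test_anchors_at_22C(self, variants_22):
        expect = {"WT": 0.46, "R1451C": 0.78, "R1451L": 0.99}
        for name, p in variants_22.items():
            assert gm.tau_h(-10.0, 22.0, p) == pytest.approx(expect[name], rel=1e-9)

    def test_cooling_slows_by_arrhenius_factor(self, wt):
        factor = math.exp((wt.Ea / gm.GAS_CONSTANT_KCAL) * (1 / 283.15 - 1 / 295.15))
        assert gm.tau_h(-10.0, 10.0, wt) == pytest.approx(0.46 * factor, rel=1e-9)
        assert gm.tau_h(-10.0, 10.0, wt) == pytest.approx(1.94, abs=0.01)

    def test_decreasing_in_voltage(self, wt):
        v = np.arange(-50.0, 30.0, 1.0)
        taus = gm.tau_h(v, 22.0, wt)
        assert np.all(np.diff(taus) < 0)

    def test_out_of_range_temperature_warns(self, wt):
        with pytest.warns(UserWarning):
            gm.tau_h(-10.0, 2.0, wt)


class TestArrhenius:
    def test_identity_at_reference(self):
        assert gm.arrhenius_scale(0.46, 22.0, 22.0, 19.9) == pytest.approx(0.46)

    def test_zero_energy_flat(self):
        # Ea -> 0 limit: no temperature dependence
        assert gm.arrhenius_scale(1.0, 22.0, 5.0, 1e-12) == pytest.approx(1.0)

    @given(
        t1=st.floats(5, 35), t2=st.floats(5, 35), t3=st.floats(5, 35),
        ea=st.floats(1, 40),
    )
    @settings(max_examples=50, derandomize=True)
    def test_multiplicative_composition(self, t1, t2, t3, ea):
        a = gm.arrhenius_scale(1.0, t1, t2, ea)
        b = gm.arrhenius_scale(1.0, t2, t3, ea)
        c = gm.arrhenius_scale(1.0, t1, t3, ea)
        assert a * b == pytest.approx(c, rel=1e-12)


class TestStepCurrent:
    def test_zero_at_reversal(self, wt):
        t, i = gm.simulate_step_current(gm.nernst_sodium(22.0), 50.0, 22.0, wt, gmax=100.0)
        assert np.all(i == 0.0)

    def test_no_persistent_current(self, wt):
        # pedestal_C = 0: current decays to (numerically) nothing
        t, i = gm.simulate_step_current(-10.0, 50.0, 22.0, wt, gmax=100.0)
        assert abs(i[-1]) < 1e-6 * np.max(np.abs(i))

    def test_pedestal_leaves_persistent_fraction(self, wt):
        p = wt.model_copy(update={"pedestal_C": 0.05})
        t, i = gm.simulate_step_current(-10.0, 50.0, 22.0, p, gmax=100.0)
        assert abs(i[-1]) == pytest.approx(0.05 * np.max(np.abs(i)), rel=1e-3)

    def test_peak_matches_boltzmann_conductance(self, wt):
        e_na = gm.nernst_sodium(22.0)
        t, i = gm.simulate_step_current(-10.0, 50.0, 22.0, wt, gmax=100.0, E_Na=e_na)
        expected = 100.0 * (-10.0 - e_na) * gm.act_inf(-10.0, wt)
        assert i.min() == pytest.approx(expected, rel=1e-12)

    def test_initial_availability_scales_peak(self, wt):
        e_na = gm.nernst_sodium(22.0)
        full = gm.simulate_step_current(-10.0, 20.0, 22.0, wt, 100.0, e_na)[1]
        half = gm.simulate_step_current(
            -10.0, 20.0, 22.0, wt, 100.0, e_na, initial=GateState(h=0.5)
        )[1]
        assert np.max(np.abs(half)) == pytest.approx(0.5 * np.max(np.abs(full)), rel=1e-12)

    def test_invalid_inputs(self, wt):
        with pytest.raises(ValueError):
            gm.simulate_step_current(-10.0, -1.0, 22.0, wt, 100.0)
        with pytest.raises(ValueError):
            gm.simulate_step_current(-10.0, 50.0, 22.0, wt, -5.0)


class TestSlowAvailability:
    def test_no_conditioning_fully_available(self, wt):
        assert gm.slow_availability(0.0, 0.0, wt) == 1.0

    def test_full_recovery_limit(self, variants_22):
        for p in variants_22.values():
            assert gm.slow_availability(30000.0, 1e7, p) == pytest.approx(1.0, abs=1e-4)

    def test_r1451l_30s_kernel_value(self, r1451l):
        # recovered fraction at t = tau_slow follows the closed form
        k = r1451l.slow_rec_30s
        t = k.tau_slow
        expect = k.a_fast * (1 - math.exp(-t / k.tau_fast)) + (1 - k.a_fast) * (1 - math.exp(-1))
        assert gm.recovery_fraction(t, k) == pytest.approx(expect, rel=1e-12)
        assert k.tau_slow == 1978.0

    def test_entry_kernel_starts_at_one(self, variants_22):
        for p in variants_22.values():
            assert gm.entry_availability(0.0, p) == pytest.approx(1.0)

    def test_kernel_interpolation_continuous(self, wt):
        k_lo = gm.slow_recovery_kernel_for(4000.0, wt)
        k_mid = gm.slow_recovery_kernel_for(11000.0, wt)
        k_hi = gm.slow_recovery_kernel_for(30000.0, wt)
        assert k_lo.tau_slow <= k_mid.tau_slow <= k_hi.tau_slow
        assert gm.slow_recovery_kernel_for(3999.9, wt) == wt.slow_rec_4s

    @given(cond=st.floats(0, 60000), rec=st.floats(0, 20000))
    @settings(max_examples=100, derandomize=True)
    def test_bounded(self, wt, cond, rec):
        assert 0.0 <= gm.slow_availability(cond, rec, wt) <= 1.0


class TestGateState:
    def test_occupancy_bounds_enforced(self):
        with pytest.raises(ValueError):
            GateState(m=1.5)
        with pytest.raises(ValueError):
            GateState(h=-0.1)

    def test_open_fraction_product(self):
        s = GateState(m=0.5, h=0.4, s_avail=0.5)
        assert s.open_fraction == pytest.approx(0.1)


class TestPackagedSets:
    def test_nernst_reversal(self):
        # 150 mM out / 35 mM in gives ~ +37 mV at 22 C, temperature-dependent
        assert gm.nernst_sodium(22.0) == pytest.approx(37.0, abs=0.1)
        assert gm.nernst_sodium(10.0) < gm.nernst_sodium(28.0)

    def test_table_values_22C(self, variants_22):
        t1 = {
            "WT": (-27.5, -5.8, -72.2, 4.2, 1.1, (39, 6.4, 3810), (3.3, 47, 243), (24, 46, 382), 19.9, 699.3),
            "R1451C": (-28.8, -7.6, -78.2, 5.9, 1.1, (36, 10, 4193), (4.2, 43, 291), (59, 54, 726), 22.9, 257.0),
            "R1451L": (-30.7, -7.9, -91.8, 9.4, 1.3, (38, 7.9, 3085), (2.0, 41, 420), (162, 41, 1978), 21.3, 374.5),
        }
        for name, p in variants_22.items():
            av, ak, iv, ik, rec, entry, r4, r30, ea, dens = t1[name]
            assert (p.act_v12, p.act_k) == (av, ak)
            assert (p.inact_v12, p.inact_k) == (iv, ik)
            assert p.rec_fast_tau == rec
            assert (p.slow_entry.tau_fast, p.slow_entry.a_fast * 100, p.slow_entry.tau_slow) == pytest.approx(entry)
            assert (p.slow_rec_4s.tau_fast, p.slow_rec_4s.a_fast * 100, p.slow_rec_4s.tau_slow) == pytest.approx(r4)
            assert (p.slow_rec_30s.tau_fast, p.slow_rec_30s.a_fast * 100, p.slow_rec_30s.tau_slow) == pytest.approx(r30)
            assert p.Ea == ea and p.density == dens

    def test_table_values_10C(self):
        t2 = {
            "WT": (-22.5, -8.4, -79.7, 5.7, 4.4),
            "R1451C": (-16.5, -10.6, -86.4, 10.0, 4.3),
            "R1451L": (-14.7, -12.4, -97.0, 10.2, 3.3),
        }
        for name, (av, ak, iv, ik, rec) in t2.items():
            p = gm.load_variant(name, 10.0)
            assert (p.act_v12, p.act_k, p.inact_v12, p.inact_k) == (av, ak, iv, ik)
            assert p.rec_fast_tau == rec

    def test_unknown_set_rejected(self):
        with pytest.raises(KeyError):
            gm.load_variant("R1448C", 22.0)

    def test_invalid_params_rejected(self, wt):
        doc = wt.model_dump()
        doc["act_k"] = 5.8  # activation slope must be negative in table convention
        with pytest.raises(ValueError):
            gm.VariantParams.model_validate(doc)
        doc = wt.model_dump()
        doc["inact_k"] = -4.2
        with pytest.raises(ValueError):
            gm.VariantParams.model_validate(doc)
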