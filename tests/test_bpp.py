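"""Dipolar (BPP) relaxation theory: limits, monotonicity, ratio inversion."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from relaxochain import (
    BPPParams,
    RelaxationPair,
    fast_motion_r2,
    invert_tau_c_from_ratio,
    t1_bpp,
    t1_over_t2,
    t2_bpp,
    theory_curves,
)
from relaxochain.bpp import dipolar_prefactor_from_distance


class TestParams:
    def test_prefactor_strictly_decreasing_in_distance(self):
        distances = np.linspace(1.0e-10, 3.0e-10, 20)
        pref = [dipolar_prefactor_from_distance(d) for d in distances]
        assert np.all(np.diff(pref) < 0)

    def test_omega0_is_2pi_f(self, bpp_23mhz):
        assert bpp_23mhz.omega0 == pytest.approx(2 * np.pi * 23e6)

    @pytest.mark.parametrize("kwargs", [
        {"larmor_frequency_mhz": -1}, {"interproton_distance_m": 0},
        {"dipolar_prefactor": -5.0},
    ])
    def test_invalid_params_rejected(self, kwargs):
        with pytest.raises(ValueError):
            BPPParams(**kwargs)

    def test_unphysical_pair_rejected(self):
        with pytest.raises(ValueError):
            RelaxationPair(t1_s=0.1, t2_s=0.2, tau_c_s=1e-9)


class TestRelaxationTimes:
    def test_extreme_narrowing_limit(self, bpp_23mhz):
        # for w0*tau_c -> 0 both rates approach (3/2) * prefactor * tau_c
        tau = 1e-13
        rate_limit = 1.5 * bpp_23mhz.dipolar_prefactor * tau
        assert 1 / t1_bpp(tau, bpp_23mhz) == pytest.approx(rate_limit, rel=1e-6)
        assert 1 / t2_bpp(tau, bpp_23mhz) == pytest.approx(rate_limit, rel=1e-6)
        assert t1_bpp(tau, bpp_23mhz) == pytest.approx(t2_bpp(tau, bpp_23mhz), rel=1e-6)

    def test_doubling_prefactor_halves_t1(self, bpp_23mhz):
        doubled = BPPParams(
            larmor_frequency_mhz=23.0,
            dipolar_prefactor=2 * bpp_23mhz.dipolar_prefactor,
        )
        tau = 3e-9
        assert t1_bpp(tau, doubled) == pytest.approx(t1_bpp(tau, bpp_23mhz) / 2)

    def test_t1_minimum_at_omega0_tau_c_0p616(self, bpp_23mhz):
        # dense log-grid oracle for the interior minimum of T1(tau_c)
        tau = np.logspace(-11, -6, 200001)
        t1 = t1_bpp(tau, bpp_23mhz)
        x_min = bpp_23mhz.omega0 * tau[np.argmin(t1)]
        assert x_min == pytest.approx(0.616, abs=0.001)
        # and the minimum is interior and unique: T1 decreases then increases
        sign_changes = np.sum(np.diff(np.sign(np.diff(t1))) != 0)
        assert sign_changes == 1

    def test_t2_strictly_decreasing(self, bpp_23mhz):
        tau = np.logspace(-12, -3, 2000)
        t2 = t2_bpp(tau, bpp_23mhz)
        assert np.all(np.diff(t2) < 0)

    def test_t1_geq_t2_over_1000_correlation_times(self, bpp_23mhz):
        tau = np.logspace(-13, -4, 1000)
        assert np.all(t1_bpp(tau, bpp_23mhz) >= t2_bpp(tau, bpp_23mhz) * (1 - 1e-12))

    @pytest.mark.parametrize("func", [t1_bpp, t2_bpp])
    def test_nonpositive_tau_rejected(self, func, bpp_23mhz):
        with pytest.raises(ValueError):
            func(0.0, bpp_23mhz)

    def test_theory_curves_columns_and_shape(self, bpp_23mhz):
        df = theory_curves(bpp_23mhz, n=50)
        assert list(df.columns) == ["tau_c_s", "t1_s", "t2_s", "ratio"]
        assert len(df) == 50
        assert (df["ratio"] >= 1 - 1e-12).all()


class TestRatio:
    def test_ratio_is_one_at_zero(self):
        assert t1_over_t2(0.0) == 1.0

    def test_ratio_monotone_nondecreasing(self):
        x = np.linspace(0, 100, 5000)
        r = t1_over_t2(x)
        assert np.all(np.diff(r) >= 0)

    def test_ratio_consistent_with_t1_t2_quotient(self, bpp_23mhz):
        tau = np.logspace(-12, -5, 37)
        quotient = t1_bpp(tau, bpp_23mhz) / t2_bpp(tau, bpp_23mhz)
        assert quotient == pytest.approx(t1_over_t2(bpp_23mhz.omega0 * tau), rel=1e-12)

    def test_negative_input_rejected(self):
        with pytest.raises(ValueError):
            t1_over_t2(-0.1)

    @given(st.floats(min_value=0.0, max_value=1e3, allow_nan=False))
    @settings(deadline=None)
    def test_ratio_never_below_one(self, x):
        assert t1_over_t2(x) >= 1.0 - 1e-12


class TestRatioInversion:
    def test_ratio_one_maps_to_lower_bracket(self, bpp_23mhz):
        assert invert_tau_c_from_ratio(1.0, bpp_23mhz) == 1e-13

    @pytest.mark.parametrize("x", [0.1, 1.0, 10.0])
    def test_round_trip(self, x, bpp_23mhz):
        tau = invert_tau_c_from_ratio(t1_over_t2(x), bpp_23mhz)
        assert tau * bpp_23mhz.omega0 == pytest.approx(x, rel=1e-8)

    def test_round_trip_across_two_decades(self, bpp_23mhz):
        for x in np.logspace(-2, 2, 25):
            tau = invert_tau_c_from_ratio(t1_over_t2(x), bpp_23mhz)
            assert tau * bpp_23mhz.omega0 == pytest.approx(x, rel=1e-8)

    def test_subunity_ratio_rejected(self, bpp_23mhz):
        with pytest.raises(ValueError, match="unphysical"):
            invert_tau_c_from_ratio(0.999, bpp_23mhz)


class TestFastMotionLaw:
    def test_direct_substitution(self):
        assert fast_motion_r2(1.0, 1.0, constant=10.0) == 10.0

    def test_linear_in_tau_c(self):
        assert fast_motion_r2(2e-9, 1e9) == pytest.approx(2 * fast_motion_r2(1e-9, 1e9))

    def test_agrees_with_full_theory_in_fast_motion(self, bpp_23mhz):
        # choose M2 so the linear law reproduces the extreme-narrowing rate
        c = 10.0
        m2 = bpp_23mhz.dipolar_prefactor * (3 / 20) * (10 / c)
        tau = 1e-3 / bpp_23mhz.omega0
        assert fast_motion_r2(tau, m2, c) == pytest.approx(
            1 / t2_bpp(tau, bpp_23mhz), rel=0.05
        )

    @pytest.mark.parametrize("tau,m2", [(0, 1), (1, 0), (-1, 1)])
    def test_nonpositive_inputs_rejected(self, tau, m2):
        with pytest.raises(ValueError):
            fast_motion_r2(tau, m2)
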