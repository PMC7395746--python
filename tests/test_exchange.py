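"""Forward-model tests: MQ propagator, Rex, alpha and fast-exchange averaging."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from methylex.exchange import (
    CPMGSchedule,
    ExchangeParams,
    SiteParams,
    alpha_value,
    fast_exchange_shift,
    mq_r2eff,
    mq_r2eff_curve,
    rex_amplitude,
    snap_ncyc,
)

from _oracles import carver_richards_sq_r2eff, dense_mq_r2eff, sq_numeric_r2eff


def single_site(kex, pm, dwc, dwh=0.0, r20=20.0, fields=(500.0, 600.0, 800.0)):
    return ExchangeParams(kex, pm, {"s": SiteParams(dwc, dwh, {f: r20 for f in fields})})


class TestSchedule:
    def test_snapping_is_even_with_minimum_two_pulses(self):
        assert snap_ncyc(20.0, 0.030) == 2  # 20 Hz is not realisable in 30 ms
        assert snap_ncyc(66.7, 0.030) == 2
        assert snap_ncyc(1000.0, 0.030) == 30
        assert all(snap_ncyc(nu, 0.030) % 2 == 0 for nu in (50, 150, 425, 999))

    def test_realised_frequencies_recorded(self):
        sched = CPMGSchedule(0.030, (20.0, 1000.0), 800.0)
        assert sched.realised_nu == pytest.approx((66.666_666, 1000.0), rel=1e-6)

    def test_invalid_schedule_rejected(self):
        with pytest.raises(ValueError):
            CPMGSchedule(-0.01, (100.0,), 800.0)
        with pytest.raises(ValueError):
            CPMGSchedule(0.03, (0.0,), 800.0)


class TestPropagatorLimits:
    def test_no_minor_state_gives_flat_r20(self, schedule_800):
        params = single_site(1950.0, 0.0, 1.0)
        curve = mq_r2eff_curve(params, "s", schedule_800)
        assert curve == pytest.approx(np.full(len(curve), 20.0))

    def test_degenerate_states_give_flat_r20(self, schedule_800):
        params = single_site(1950.0, 0.03, 0.0, 0.0)
        curve = mq_r2eff_curve(params, "s", schedule_800)
        assert curve == pytest.approx(np.full(len(curve), 20.0))

    def test_exchange_fully_refocused_at_high_nu(self):
        params = single_site(1950.0, 0.03, 1.0)
        sched = CPMGSchedule(0.030, (100_000.0,), 800.0)
        assert mq_r2eff(params, "s", sched, 100_000.0) == pytest.approx(20.0, abs=0.05)

    def test_invalid_exchange_params_rejected(self):
        with pytest.raises(ValueError):
            ExchangeParams(-5.0, 0.03, {})
        with pytest.raises(ValueError):
            ExchangeParams(1000.0, 0.6, {})


class TestPropagatorOracle:
    """Agreement with dense Bloch-McConnell integration (<= 1 us RK4 steps)."""

    def test_reference_point_against_dense_integration(self):
        # kex=1950, pm=3 %, dwC=1 ppm at 800 MHz, nu=33.3 Hz (snaps to 66.7)
        params = single_site(1950.0, 0.03, 1.0)
        sched = CPMGSchedule(0.030, (33.3,), 800.0)
        mine = mq_r2eff(params, "s", sched, 33.3)
        ref = dense_mq_r2eff(1950.0, 0.03, 1.0, 0.0, 20.0, 0.030, 33.3, 800.0)[0]
        assert mine == pytest.approx(ref, abs=0.01)

    def test_nonzero_dwh_against_dense_integration(self):
        params = single_site(1100.0, 0.05, 0.5, dwh=0.10)
        sched = CPMGSchedule(0.030, (133.3,), 600.0)
        mine = mq_r2eff(params, "s", sched, 133.3)
        ref = dense_mq_r2eff(1100.0, 0.05, 0.5, 0.10, 20.0, 0.030, 133.3, 600.0)[0]
        assert mine == pytest.approx(ref, abs=0.01)

    def test_dwh_zero_reduces_to_single_quantum(self, schedule_800):
        params = single_site(1950.0, 0.03, 1.0)
        dw_rad = 2 * np.pi * 800.0 * 0.25143 * 1.0
        for nu in schedule_800.nu_cpmg:
            sq = sq_numeric_r2eff(1950.0, 0.03, dw_rad, 20.0, nu, 0.030)
            assert mq_r2eff(params, "s", schedule_800, nu) == pytest.approx(sq, abs=1e-8)

    def test_closed_form_carver_richards_within_its_accuracy(self, schedule_800):
        params = single_site(1950.0, 0.03, 1.0)
        dw_rad = 2 * np.pi * 800.0 * 0.25143 * 1.0
        for nu in schedule_800.nu_cpmg:
            cr = carver_richards_sq_r2eff(1950.0, 0.03, dw_rad, 20.0, nu, 0.030)
            assert mq_r2eff(params, "s", schedule_800, nu) == pytest.approx(cr, abs=1.0)


class TestPropagatorProperties:
    @given(
        kex=st.floats(100.0, 5000.0),
        pm=st.floats(0.005, 0.2),
        dwc=st.floats(0.05, 3.0),
        nu=st.sampled_from([66.7, 200.0, 533.3, 1000.0]),
    )
    @settings(max_examples=60, deadline=None)
    def test_sign_symmetry_and_nonnegative_rex_when_dwh_zero(self, kex, pm, dwc, nu):
        sched = CPMGSchedule(0.030, (nu,), 800.0)
        plus = mq_r2eff(single_site(kex, pm, dwc), "s", sched, nu)
        minus = mq_r2eff(single_site(kex, pm, -dwc), "s", sched, nu)
        assert plus == pytest.approx(minus, abs=1e-9)
        assert plus >= 20.0 - 1e-9  # exchange only adds relaxation

    def test_monotone_decreasing_dispersion_profile(self, schedule_800):
        params = single_site(1950.0, 0.03, 1.0)
        curve = mq_r2eff_curve(params, "s", schedule_800)
        assert np.all(np.diff(curve) < 0)


class TestRexAndAlpha:
    def test_rex_zero_without_minor_state(self, schedule_800):
        assert rex_amplitude(single_site(1950.0, 0.0, 1.0), "s", schedule_800) == 0.0

    def test_rex_fast_exchange_closed_form(self):
        # Luz-Meiboom limit: Rex(nu->0) -> pm(1-pm) dw^2 / kex
        kex, pm, dwc = 20_000.0, 0.03, 0.3
        dw = 2 * np.pi * 800.0 * 0.25143 * dwc
        sched = CPMGSchedule(0.030, (66.7, 200_000.0), 800.0)
        rex = rex_amplitude(single_site(kex, pm, dwc), "s", sched)
        assert rex == pytest.approx(pm * (1 - pm) * dw**2 / kex, rel=0.05)

    def test_rex_intermediate_against_dense_integration(self, schedule_800):
        params = single_site(1500.0, 0.04, 0.8)
        rex = rex_amplitude(params, "s", schedule_800)
        lo = dense_mq_r2eff(1500.0, 0.04, 0.8, 0.0, 20.0, 0.030, 66.7, 800.0)[0]
        hi = dense_mq_r2eff(1500.0, 0.04, 0.8, 0.0, 20.0, 0.030, 1000.0, 800.0)[0]
        assert rex == pytest.approx(lo - hi, abs=0.01)

    def test_alpha_limits(self):
        # limit tests need a nu_max that fully refocuses the exchange
        wide = CPMGSchedule(0.030, (66.7, 50_000.0), 800.0)
        fast = single_site(100_000.0, 0.03, 0.5)
        assert alpha_value(fast, "s", 500.0, 800.0, wide) == pytest.approx(2.0, abs=0.1)
        # slow limit: kex/dw = 0.01 with dw evaluated at the lower field
        dw_rad = 2 * np.pi * 500.0 * 0.25143 * 1.0
        slow = single_site(0.01 * dw_rad, 0.03, 1.0)
        assert alpha_value(slow, "s", 500.0, 800.0, wide) == pytest.approx(0.0, abs=0.1)

    def test_alpha_free_enzyme_regime_exceeds_bound(self, schedule_800):
        # fast kex/dw regime of the free enzyme: alpha must exceed 1.2
        params = single_site(1950.0, 0.03, 0.5)
        alpha = alpha_value(params, "s", 500.0, 800.0, schedule_800)
        assert 1.2 < alpha <= 2.0

    def test_alpha_undefined_for_vanishing_rex(self, schedule_800):
        params = single_site(1950.0, 0.0, 1.0)
        assert np.isnan(alpha_value(params, "s", 500.0, 800.0, schedule_800))

    def test_rex_needs_two_frequencies(self):
        sched = CPMGSchedule(0.030, (66.7,), 800.0)
        with pytest.raises(ValueError):
            rex_amplitude(single_site(1950.0, 0.03, 1.0), "s", sched)


class TestFastExchangeShift:
    @pytest.mark.parametrize(
        "p, expected",
        [
            (0.0, (0.5, 10.0)),
            (1.0, (0.9, 12.0)),
            (0.5, (0.7, 11.0)),
        ],
    )
    def test_population_weighted_average(self, p, expected):
        assert fast_exchange_shift(p, (0.5, 10.0), (0.9, 12.0)) == pytest.approx(expected)

    def test_rejects_population_outside_unit_interval(self):
        with pytest.raises(ValueError):
            fast_exchange_shift(1.2, (0.0, 0.0), (1.0, 1.0))
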