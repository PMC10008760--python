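"""Forward kinetic models: analytic convolution against a numerical oracle,
limiting cases, and the NLS weighting scheme."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pumba import (
    ArterialInputFunction,
    FrameSchedule,
    PK1TC,
    PK2TC,
    PKSRTM,
    TimeActivityCurve,
    compute_weights,
    simulate_tac_1tc,
    simulate_tac_2tc,
    simulate_tac_srtm,
)
from pumba.kinetics import exp_conv

from .conftest import curve_rel_err, numerical_convolution


def irf_2tc(p: PK2TC):
    k2, k3, k4 = p.k2, p.k3, p.k4
    s = k2 + k3 + k4
    disc = np.sqrt(s * s - 4 * k2 * k4)
    th1, th2 = 0.5 * (s + disc), 0.5 * (s - disc)
    return lambda t: (
        p.K1 * (th1 - k3 - k4) * np.exp(-th1 * t) + p.K1 * (k3 + k4 - th2) * np.exp(-th2 * t)
    ) / (th1 - th2)


class TestAnalyticConvolution:
    @pytest.mark.parametrize("K1", [0.1, 0.2, 0.4])
    @pytest.mark.parametrize("BPP", [0.5, 1.0, 3.0])
    @pytest.mark.parametrize("k4", [0.03, 0.05])
    def test_2tc_matches_numerical_oracle(self, aif, schedule, K1, BPP, k4):
        p = PK2TC(K1=K1, VND=0.5, BPP=BPP, k4=k4)
        tac = simulate_tac_2tc(p, aif, schedule)
        oracle = numerical_convolution(
            irf_2tc(p), aif.times, aif.concentrations, schedule.mid_times
        )
        assert curve_rel_err(tac.values, oracle) < 1e-3

    @pytest.mark.parametrize("K1,VT", [(0.1, 2.0), (0.3, 10.0), (0.5, 30.0)])
    def test_1tc_matches_numerical_oracle(self, aif, schedule, K1, VT):
        p = PK1TC(K1=K1, VT=VT)
        tac = simulate_tac_1tc(p, aif, schedule)
        oracle = numerical_convolution(
            lambda t: K1 * np.exp(-p.k2 * t), aif.times, aif.concentrations, schedule.mid_times
        )
        assert curve_rel_err(tac.values, oracle) < 1e-3

    def test_srtm_matches_numerical_oracle(self, aif):
        # fine reference grid so linear interpolation of C_R is accurate
        fine = FrameSchedule.from_durations(np.full(1800, 0.05))
        ref = simulate_tac_1tc(PK1TC(K1=0.4, VT=4.0), aif, fine)
        p = PKSRTM(R1=0.8, k2prime=0.1, BPND=1.5)
        target = simulate_tac_srtm(p, ref, fine)
        ref_t = np.concatenate([[0.0], fine.mid_times])
        ref_c = np.concatenate([[0.0], ref.values])
        conv = numerical_convolution(
            lambda t: np.exp(-p.k2a * t), ref_t, ref_c, fine.mid_times
        )
        oracle = p.R1 * ref.values + (p.k2 - p.R1 * p.k2a) * conv
        assert curve_rel_err(target.values, oracle) < 1e-3

    def test_tissue_concentration_zero_at_time_zero(self, aif):
        assert exp_conv(0.5, aif.times, aif.concentrations, np.array([0.0]))[0] == 0.0

    def test_2tc_reduces_to_1tc_when_binding_vanishes(self, aif, schedule):
        two = simulate_tac_2tc(PK2TC(K1=0.2, VND=0.5, BPP=1e-10, k4=0.05), aif, schedule)
        one = simulate_tac_1tc(PK1TC(K1=0.2, VT=0.5), aif, schedule)
        np.testing.assert_allclose(two.values, one.values, rtol=1e-6, atol=1e-12)

    def test_1tc_irreversible_limit_is_running_integral(self, aif, schedule):
        tac = simulate_tac_1tc(PK1TC(K1=0.1, VT=1e12), aif, schedule)
        integral = exp_conv(0.0, aif.times, aif.concentrations, schedule.mid_times)
        np.testing.assert_allclose(tac.values, 0.1 * integral, rtol=1e-6)

    def test_1tc_linear_in_delivery_at_fixed_efflux(self, aif, schedule):
        # doubling K1 at fixed k2 = K1/VT scales the curve exactly
        a = simulate_tac_1tc(PK1TC(K1=0.1, VT=5.0), aif, schedule)
        b = simulate_tac_1tc(PK1TC(K1=0.2, VT=10.0), aif, schedule)
        np.testing.assert_allclose(b.values, 2.0 * a.values, rtol=1e-12)

    def test_srtm_equals_reference_when_no_binding(self, aif):
        fine = FrameSchedule.from_durations(np.full(900, 0.1))
        ref = simulate_tac_1tc(PK1TC(K1=0.4, VT=4.0), aif, fine)
        target = simulate_tac_srtm(PKSRTM(R1=1.0, k2prime=0.1, BPND=1e-12), ref, fine)
        np.testing.assert_allclose(target.values, ref.values, rtol=1e-9)

    def test_srtm_binding_increases_late_uptake(self, aif):
        fine = FrameSchedule.from_durations(np.full(900, 0.1))
        ref = simulate_tac_1tc(PK1TC(K1=0.4, VT=4.0), aif, fine)
        lo = simulate_tac_srtm(PKSRTM(R1=0.8, k2prime=0.1, BPND=1.0), ref, fine)
        hi = simulate_tac_srtm(PKSRTM(R1=0.8, k2prime=0.1, BPND=2.0), ref, fine)
        peak = np.argmax(lo.values)
        assert np.all(hi.values[peak + 50 :] > lo.values[peak + 50 :])

    def test_2tc_volume_identity(self):
        p = PK2TC(K1=0.2, VND=0.5, BPP=1.3, k4=0.05)
        assert p.VT == pytest.approx(p.VND + p.BPP, abs=1e-15)
        assert p.BPND == pytest.approx(p.BPP / p.VND, abs=1e-15)


class TestTimingTypes:
    def test_schedule_rejects_bad_timing(self):
        with pytest.raises(ValueError):
            FrameSchedule(np.array([0.0, 1.0]), np.array([2.0, 1.0]))  # overlap
        with pytest.raises(ValueError):
            FrameSchedule(np.array([0.0, 1.0]), np.array([1.0, -1.0]))
        with pytest.raises(ValueError):
            FrameSchedule(np.array([1.0, 0.0]), np.array([0.5, 0.5]))

    def test_mid_times(self):
        s = FrameSchedule.from_durations([1.0, 2.0])
        np.testing.assert_allclose(s.mid_times, [0.5, 2.0])

    def test_aif_must_pass_through_origin(self):
        with pytest.raises(ValueError):
            ArterialInputFunction(np.array([0.0, 1.0]), np.array([1.0, 2.0]))
        with pytest.raises(ValueError):
            ArterialInputFunction(np.array([0.5, 1.0]), np.array([0.0, 2.0]))

    def test_schedule_beyond_aif_support_rejected(self, aif):
        long = FrameSchedule.from_durations([200.0])
        with pytest.raises(ValueError):
            simulate_tac_1tc(PK1TC(K1=0.1, VT=5.0), aif, long)

    def test_nonpositive_parameters_rejected(self):
        with pytest.raises(ValueError):
            PK2TC(K1=-0.1, VND=0.5, BPP=1.0, k4=0.05)
        with pytest.raises(ValueError):
            PK1TC(K1=0.1, VT=0.0)


class TestWeights:
    def test_uniform_under_symmetry(self):
        s = FrameSchedule.from_durations([1.0] * 10)
        tac = TimeActivityCurve(s, np.full(10, 5.0))
        w = compute_weights(tac, isotope_halflife=1e12)
        np.testing.assert_allclose(w, 1.0, rtol=1e-9)

    def test_duration_ratio_hand_calculation(self):
        # two frames, durations 1 and 4, equal activity, no decay:
        # var ~ C/dur so weights ~ dur -> ratio 4, normalised to mean 1
        s = FrameSchedule(np.array([0.0, 1.0]), np.array([1.0, 4.0]))
        tac = TimeActivityCurve(s, np.array([5.0, 5.0]))
        w = compute_weights(tac, isotope_halflife=1e12)
        assert w[1] / w[0] == pytest.approx(4.0, rel=1e-9)
        assert w.mean() == pytest.approx(1.0, abs=1e-12)

    @given(scale=st.floats(min_value=1e-3, max_value=1e3))
    @settings(max_examples=25, deadline=None)
    def test_scale_invariance(self, scale):
        s = FrameSchedule.from_durations([0.5, 1.0, 2.0, 5.0])
        values = np.array([1.0, 4.0, 3.0, 2.0])
        base = compute_weights(TimeActivityCurve(s, values))
        scaled = compute_weights(TimeActivityCurve(s, scale * values))
        np.testing.assert_allclose(base, scaled, rtol=1e-9)

    def test_mean_one_and_zero_curve_rejected(self):
        s = FrameSchedule.from_durations([0.5, 1.0, 2.0])
        w = compute_weights(TimeActivityCurve(s, np.array([1.0, 3.0, 2.0])))
        assert w.mean() == pytest.approx(1.0, abs=1e-12)
        with pytest.raises(ValueError):
            compute_weights(TimeActivityCurve(s, np.zeros(3), weights=np.ones(3)))
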