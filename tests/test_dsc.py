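import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from amorphkin import dsc
from amorphkin import synthetic as syn
from amorphkin.io import Thermogram


def _thermogram(T, y, phi=10.0):
    return Thermogram(phi=phi, temperature=T, heat_flow=y)


class TestGlassTransition:
    def test_recovers_planted_midpoint(self, fine_grid):
        truth = syn.DscTruth(Tg_mid=273.0, Tp=None)
        tg = syn.gen_thermogram(truth, 5.0, fine_grid)
        g = dsc.detect_glass_transition(tg, (255.0, 291.0))
        assert g.Tg_mid == pytest.approx(273.0, abs=0.05)
        assert g.Tg_onset < g.Tg_mid < g.Tg_end

    def test_recovers_blend_midpoint(self):
        truth = syn.DscTruth(Tg_mid=279.0, Tp=None)
        grid = np.arange(255.0, 305.0, 0.05)
        tg = syn.gen_thermogram(truth, 10.0, grid)
        g = dsc.detect_glass_transition(tg, (260.0, 298.0))
        assert g.Tg_mid == pytest.approx(279.0, abs=0.05)

    def test_flat_signal_raises(self):
        T = np.arange(250.0, 300.0, 0.5)
        tg = _thermogram(T, np.zeros_like(T))
        with pytest.raises(dsc.DetectionError, match="no glass transition"):
            dsc.detect_glass_transition(tg, (250.0, 300.0))

    def test_step_below_noise_raises(self):
        rng = np.random.default_rng(0)
        T = np.arange(250.0, 300.0, 0.1)
        y = 1e-5 / (1 + np.exp(-(T - 275.0) / 2.0)) + rng.normal(0, 1e-4, T.size)
        tg = _thermogram(T, y)
        with pytest.raises(dsc.DetectionError):
            dsc.detect_glass_transition(tg, (250.0, 300.0))


class TestCrystallizationPeak:
    def test_recovers_planted_peak_and_enthalpy(self, fine_grid):
        truth = syn.DscTruth(Tg_mid=None, Tp=317.3, enthalpy=50.0)
        tg = syn.gen_thermogram(truth, 10.0, fine_grid)
        p = dsc.locate_crystallization_peak(tg, (295.0, 340.0))
        assert p.Tp == pytest.approx(317.3, abs=0.05)
        assert p.enthalpy == pytest.approx(50.0, rel=1e-3)
        assert p.T0 <= p.To < p.Tp < p.Tinf

    def test_onset_sits_on_rising_flank(self, fine_grid):
        truth = syn.DscTruth(Tg_mid=None, Tp=317.3, peak_width=3.0)
        tg = syn.gen_thermogram(truth, 10.0, fine_grid)
        p = dsc.locate_crystallization_peak(tg, (295.0, 340.0))
        # steepest-tangent onset of a Gaussian lies ~2 sigma before the apex
        assert p.Tp - 3 * 3.0 < p.To < p.Tp

    def test_empty_window_raises(self):
        T = np.arange(250.0, 300.0, 0.5)
        tg = _thermogram(T, np.zeros_like(T))
        with pytest.raises(dsc.DetectionError):
            dsc.locate_crystallization_peak(tg, (250.0, 300.0))

    def test_two_comparable_maxima_ambiguous(self):
        T = np.arange(280.0, 340.0, 0.1)
        y = (np.exp(-0.5 * ((T - 300.0) / 2.0) ** 2)
             + 0.9 * np.exp(-0.5 * ((T - 325.0) / 2.0) ** 2))
        tg = _thermogram(T, y)
        with pytest.raises(dsc.DetectionError, match="ambiguous"):
            dsc.locate_crystallization_peak(tg, (280.0, 340.0))


class TestCrystallinity:
    def test_hand_trapezoid_oracle(self):
        # dHc/dT samples (0,1,2,1,0) at 300..304 K: cumulative trapezoid
        # areas are 0.5, 2.0, 3.5 of total 4.0
        T = np.arange(290.0, 311.0, 1.0)
        y = np.zeros_like(T)
        y[(T >= 300) & (T <= 304)] = [0.0, 1.0, 2.0, 1.0, 0.0]
        tg = _thermogram(T, y)
        peak = dsc.CrystallizationPeak(T0=300.0, Tp=302.0, Tinf=304.0, To=301.0,
                                       enthalpy=4.0, baseline=(0.0, 0.0))
        curve = dsc.crystallinity_vs_T(tg, peak)
        X = np.interp([302.0, 303.0], curve.temperature, curve.X_of_T)
        assert X[0] == pytest.approx(0.5)
        assert X[1] == pytest.approx(0.875)

    def test_normalization_and_monotonicity(self, neat_drug_truth, fine_grid):
        tg = syn.gen_thermogram(neat_drug_truth, 10.0, fine_grid)
        p = dsc.locate_crystallization_peak(tg, (295.0, 340.0))
        curve = dsc.crystallinity_vs_T(tg, p)
        assert curve.X_of_T[0] == 0.0
        assert curve.X_of_T[-1] == pytest.approx(1.0, abs=1e-9)
        assert np.all(np.diff(curve.X_of_T) >= 0)

    def test_symmetric_peak_half_conversion_at_apex(self, fine_grid):
        truth = syn.DscTruth(Tg_mid=None, Tp=317.3)
        tg = syn.gen_thermogram(truth, 10.0, fine_grid)
        p = dsc.locate_crystallization_peak(tg, (295.0, 340.0))
        curve = dsc.crystallinity_vs_T(tg, p)
        assert np.interp(p.Tp, curve.temperature, curve.X_of_T) == pytest.approx(
            0.5, abs=1e-4)

    def test_affine_rescaling_invariance(self, neat_drug_truth, fine_grid):
        tg = syn.gen_thermogram(neat_drug_truth, 10.0, fine_grid)
        scaled = Thermogram(phi=tg.phi, temperature=tg.temperature,
                            heat_flow=3.7 * tg.heat_flow + 0.2)
        window = (295.0, 340.0)
        c1 = dsc.crystallinity_vs_T(tg, dsc.locate_crystallization_peak(tg, window))
        c2 = dsc.crystallinity_vs_T(
            scaled, dsc.locate_crystallization_peak(scaled, window))
        np.testing.assert_allclose(c1.X_of_T, c2.X_of_T, atol=1e-9)


class TestTimeDomain:
    def test_time_arithmetic(self):
        # 5 K traversed at 10 K/min is 30 s
        T = np.linspace(312.1, 327.1, 31)
        X = np.linspace(0.0, 1.0, 31)
        curve = dsc.CrystallinityCurve(temperature=T, X_of_T=X, phi=10.0)
        out = dsc.to_time_domain(curve)
        assert out.time[0] == 0.0
        assert np.interp(317.1, T, out.time) == pytest.approx(30.0)
        assert np.all(np.diff(out.time) > 0)

    @given(factor=st.floats(min_value=1.2, max_value=8.0))
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_doubling_rate_scales_time(self, factor):
        T = np.linspace(300.0, 320.0, 41)
        X = np.linspace(0.0, 1.0, 41)
        base = dsc.to_time_domain(
            dsc.CrystallinityCurve(temperature=T, X_of_T=X, phi=10.0))
        fast = dsc.to_time_domain(
            dsc.CrystallinityCurve(temperature=T, X_of_T=X, phi=10.0 * factor))
        np.testing.assert_allclose(fast.time * factor, base.time, rtol=1e-12)


def test_peak_shift_with_rate_matches_series(neat_drug_truth):
    """Recovered Tp increases with heating rate on a planted activation law."""
    from amorphkin._constants import R_GAS
    C_K = np.log(10 / 315.0**2) + 200e3 / (R_GAS * 315.0)
    runs, Tps = syn.gen_thermogram_series(
        200.0, C_K, (5.0, 10.0, 20.0, 30.0), neat_drug_truth)
    recovered = []
    for run in runs:
        p = dsc.locate_crystallization_peak(run, (295.0, run.temperature[-1]))
        recovered.append(p.Tp)
    assert np.all(np.diff(recovered) > 0)
    np.testing.assert_allclose(recovered, Tps, atol=0.05)
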