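import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import gammaln

from amorphkin import dielectric as diel
from amorphkin import synthetic as syn
from amorphkin.io import LossSpectrum


def kww_loss_series(c, beta, K=800):
    """Independent evaluation of the KWW sine transform.

    Convergent series sum_k (-1)^(k+1) Gamma(beta k+1)/k! sin(pi beta k/2)
    c^(-beta k), valid for beta < 1; used as an oracle for the quadrature.
    """
    k = np.arange(1, K + 1)
    terms = ((-1.0) ** (k + 1)
             * np.exp(gammaln(beta * k + 1) - gammaln(k + 1.0))
             * np.sin(np.pi * beta * k / 2.0) * c ** (-beta * k))
    return terms.sum()


class TestHN:
    def test_debye_spectrum_recovered(self):
        f = np.logspace(-4, 3, 50)
        truth = syn.BdsTruth(shape="HN", delta_eps=2.0, tau=1.0, a=1.0, b=1.0)
        spec = syn.gen_loss_spectrum(truth, 295.0, f)
        p = diel.fit_hn(spec)
        assert p.delta_eps == pytest.approx(2.0, rel=1e-3)
        assert p.tau_hn == pytest.approx(1.0, rel=1e-3)
        assert p.a == pytest.approx(1.0, abs=1e-3)
        assert p.b == pytest.approx(1.0, abs=1e-3)

    def test_general_hn_with_conductivity_recovered(self):
        f = np.logspace(-3, 6, 60)
        truth = syn.BdsTruth(delta_eps=5.0, tau=1e-2, a=0.8, b=0.6, sigma_dc=1e-11)
        spec = syn.gen_loss_spectrum(truth, 290.0, f)
        p = diel.fit_hn(spec)
        assert p.delta_eps == pytest.approx(5.0, rel=5e-3)
        assert p.tau_hn == pytest.approx(1e-2, rel=5e-3)
        assert p.a == pytest.approx(0.8, rel=5e-3)
        assert p.b == pytest.approx(0.6, rel=5e-3)
        assert p.sigma_dc == pytest.approx(1e-11, rel=5e-3)

    def test_pure_conductivity_low_frequency_slope(self):
        f = np.logspace(-2, 4, 30)
        truth = syn.BdsTruth(delta_eps=1e-10, tau=1.0, sigma_dc=1e-11)
        spec = syn.gen_loss_spectrum(truth, 295.0, f)
        p = diel.fit_hn(spec)
        w = spec.omega[:10]
        model = diel.hn_loss(w, p.delta_eps, p.tau_hn, p.a, p.b, p.sigma_dc)
        slopes = np.diff(np.log(model)) / np.diff(np.log(w))
        np.testing.assert_allclose(slopes, -1.0, atol=1e-3)

    def test_amplitude_rescaling_covariance(self):
        f = np.logspace(-3, 5, 50)
        truth = syn.BdsTruth(delta_eps=4.0, tau=1e-2, a=0.85, b=0.7, sigma_dc=2e-12)
        spec = syn.gen_loss_spectrum(truth, 290.0, f)
        scaled = LossSpectrum(temperature=290.0, frequency=f,
                              eps_loss=3.0 * spec.eps_loss)
        p1 = diel.fit_hn(spec)
        p2 = diel.fit_hn(scaled)
        assert p2.delta_eps == pytest.approx(3.0 * p1.delta_eps, rel=1e-4)
        assert p2.sigma_dc == pytest.approx(3.0 * p1.sigma_dc, rel=1e-3)
        assert p2.a == pytest.approx(p1.a, rel=1e-5)
        assert p2.b == pytest.approx(p1.b, rel=1e-5)
        assert p2.tau_hn == pytest.approx(p1.tau_hn, rel=1e-4)

    def test_no_peak_no_conductivity_raises(self):
        f = np.logspace(0, 4, 20)
        # monotonically rising flank only, shallower than conductivity
        spec = LossSpectrum(temperature=290.0, frequency=f,
                            eps_loss=0.01 * (f / f[0]) ** 0.3)
        with pytest.raises(diel.FitError):
            diel.fit_hn(spec)


class TestTauAlpha:
    def test_debye_identity(self):
        p = diel.HNParams(delta_eps=1.0, tau_hn=2.5e-3, a=1.0, b=1.0)
        assert diel.tau_alpha_from_hn(p) == pytest.approx(2.5e-3, rel=1e-12)

    def test_scalar_oracle(self):
        # direct evaluation: a=0.7, b=0.5, tau_HN=1e-3 s -> 4.098e-4 s
        p = diel.HNParams(delta_eps=1.0, tau_hn=1e-3, a=0.7, b=0.5)
        assert diel.tau_alpha_from_hn(p) == pytest.approx(4.0982e-4, rel=1e-4)

    @given(a=st.floats(0.3, 1.0), b=st.floats(0.3, 1.0))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_loss_maximum_at_inverse_tau_alpha(self, a, b):
        """Dense-grid peak search confirms omega_max * tau_alpha = 1."""
        tau_hn = 1e-2
        p = diel.HNParams(delta_eps=1.0, tau_hn=tau_hn, a=a, b=b)
        ta = diel.tau_alpha_from_hn(p)
        w = np.geomspace(1e-3 / ta, 1e3 / ta, 400_001)
        loss = diel.hn_loss(w, 1.0, tau_hn, a, b)
        w_max = w[np.argmax(loss)]
        assert w_max * ta == pytest.approx(1.0, rel=1e-4)

    def test_invalid_exponents_rejected(self):
        with pytest.raises(ValueError):
            diel.HNParams(delta_eps=1.0, tau_hn=1.0, a=1.2, b=0.5)


class TestKWWLoss:
    def test_beta_one_equals_debye(self):
        w = np.logspace(-4, 4, 60)
        tau = 0.5
        got = diel.kww_loss(1.0, tau, 2.0, w)
        debye = 2.0 * w * tau / (1.0 + (w * tau) ** 2)
        np.testing.assert_allclose(got, debye, atol=1e-7, rtol=1e-7)

    @pytest.mark.parametrize("beta", [0.5, 0.63, 0.86])
    def test_matches_independent_series(self, beta):
        for c in (0.5, 1.0, 10.0, 1e3):
            got = diel.kww_loss(beta, 1.0, 1.0, np.array([c]))[0]
            want = kww_loss_series(c, beta)
            assert got == pytest.approx(want, rel=1e-6)

    def test_nonnegative_single_interior_maximum(self):
        w = np.logspace(-5, 5, 200)
        y = diel.kww_loss(0.6, 1.0, 1.0, w)
        assert np.all(y >= 0)
        i = int(np.argmax(y))
        assert 0 < i < len(y) - 1
        d = np.sign(np.diff(y))
        # rises once then falls: exactly one sign change
        assert np.count_nonzero(np.diff(d) != 0) == 1

    def test_halfwidth_decreases_with_beta(self):
        """Smaller beta means a broader loss peak (more decades at half max)."""
        w = np.logspace(-6, 6, 400)
        widths = []
        for beta in (0.5, 0.7, 0.9, 1.0):
            y = diel.kww_loss(beta, 1.0, 1.0, w)
            above = w[y >= 0.5 * y.max()]
            widths.append(np.log10(above[-1] / above[0]))
        assert np.all(np.diff(widths) < 0)


class TestFitKWW:
    @pytest.mark.parametrize("beta", [0.86, 0.63])
    def test_recovers_planted_stretching_exponent(self, beta):
        f = np.logspace(-2, 6, 60)
        truth = syn.BdsTruth(shape="KWW", delta_eps=3.0, tau=0.1, beta_kww=beta)
        spec = syn.gen_loss_spectrum(truth, 290.0, f)
        fit = diel.fit_kww(spec)
        assert fit.beta_kww == pytest.approx(beta, abs=0.005)

    def test_debye_input_gives_beta_one(self):
        f = np.logspace(-4, 3, 40)
        truth = syn.BdsTruth(shape="HN", delta_eps=2.0, tau=1.0, a=1.0, b=1.0)
        spec = syn.gen_loss_spectrum(truth, 295.0, f)
        fit = diel.fit_kww(spec)
        assert fit.beta_kww == pytest.approx(1.0, abs=0.01)


class TestVFT:
    def test_roundtrip_recovery(self):
        table = syn.gen_tau_table(1e-14, 10.0, 230.0, np.linspace(260.0, 320.0, 8))
        p = diel.fit_vft(table)
        assert p.tau_vft == pytest.approx(1e-14, rel=5e-3)
        assert p.D_T == pytest.approx(10.0, rel=5e-3)
        assert p.T0_vft == pytest.approx(230.0, rel=5e-3)

    def test_three_points_rejected(self):
        table = syn.gen_tau_table(1e-14, 10.0, 230.0, np.array([280.0, 290.0, 300.0]))
        with pytest.raises(diel.FitError, match="4"):
            diel.fit_vft(table)

    def test_arrhenius_limit_flagged(self):
        # tau = tau0 * exp(Ea_T / T): the T0 -> 0 limit of the VFT law
        T = np.linspace(260.0, 340.0, 10)
        table = diel.TauAlphaTable(temperature=T,
                                   tau_alpha=1e-12 * np.exp(8000.0 / T))
        p = diel.fit_vft(table)
        assert p.arrhenius_degenerate
        # the product D_T*T0 plays the activation-temperature role
        assert p.D_T * p.T0_vft == pytest.approx(8000.0, rel=0.15)


class TestTgFromVFT:
    def test_closed_form_value(self):
        p = diel.VFTParams(tau_vft=1e-14, D_T=10.0, T0_vft=230.0)
        assert diel.tg_from_vft(p) == pytest.approx(292.43, abs=0.01)

    def test_planted_crossing_at_published_tg(self):
        Tg_star, T0, D = 271.0, 230.0, 10.0
        tau_vft = 100.0 * np.exp(-D * T0 / (Tg_star - T0))
        p = diel.VFTParams(tau_vft=tau_vft, D_T=D, T0_vft=T0)
        assert diel.tg_from_vft(p) == pytest.approx(271.0, rel=1e-12)

    def test_inverse_identity(self):
        p = diel.VFTParams(tau_vft=3e-13, D_T=8.5, T0_vft=241.0)
        Tg = diel.tg_from_vft(p)
        tau_at_tg = diel.vft_tau(np.array([Tg]), p.tau_vft, p.D_T, p.T0_vft)[0]
        assert tau_at_tg == pytest.approx(100.0, rel=1e-9)

    def test_slow_tau_vft_rejected(self):
        with pytest.raises(ValueError, match="100"):
            diel.tg_from_vft(diel.VFTParams(tau_vft=200.0, D_T=10.0, T0_vft=230.0))


class TestCrystallizationOnset:
    def _amplitudes(self, T, onset, slope):
        A = np.ones_like(T)
        hot = T > onset
        A[hot] = np.clip(1.0 - slope * (T[hot] - onset), 0.0, None)
        return A

    def test_planted_onset_recovered(self):
        # decay slope 0.06/K puts the 90% crossing within 2 K of 305 K, so
        # the first gridded temperature persistently below trend is 307 K
        T = np.arange(293.0, 312.0, 2.0)
        A = self._amplitudes(T, 305.0, 0.06)
        got = diel.detect_crystallization_onset(T, A)
        assert got == pytest.approx(307.0, abs=1.0)

    def test_constant_amplitude_no_onset(self):
        T = np.arange(293.0, 312.0, 2.0)
        with pytest.raises(diel.FitError, match="no onset"):
            diel.detect_crystallization_onset(T, np.ones_like(T))

    def test_onset_at_last_temperature(self):
        T = np.arange(293.0, 312.0, 2.0)
        A = np.ones_like(T)
        A[-1] = 0.5
        got = diel.detect_crystallization_onset(T, A)
        assert got == T[-1]


def test_end_to_end_dielectric_glass_transition():
    """spectra -> HN -> tau_alpha -> VFT -> Tg recovers the planted value.

    VFT parameters are chosen so tau_alpha = 100 s exactly at 271 K; spectra
    are synthesized at eight temperatures with an HN shape and fitted blind.
    """
    Tg_star, T0, D = 271.0, 230.0, 10.0
    tau_vft = 100.0 * np.exp(-D * T0 / (Tg_star - T0))
    a, b = 0.85, 0.7
    ratio = diel.tau_alpha_from_hn(
        diel.HNParams(delta_eps=1.0, tau_hn=1.0, a=a, b=b))
    taus = []
    temps = np.linspace(275.0, 305.0, 8)
    for T in temps:
        ta_target = diel.vft_tau(np.array([T]), tau_vft, D, T0)[0]
        truth = syn.BdsTruth(delta_eps=4.0, tau=ta_target / ratio, a=a, b=b)
        f_peak = 1.0 / (2 * np.pi * ta_target)
        f = np.logspace(np.log10(f_peak) - 4, np.log10(f_peak) + 4, 45)
        spec = syn.gen_loss_spectrum(truth, T, f)
        taus.append(diel.tau_alpha_from_hn(diel.fit_hn(spec)))
    table = diel.TauAlphaTable(temperature=temps, tau_alpha=np.array(taus))
    Tg = diel.tg_from_vft(diel.fit_vft(table))
    assert Tg == pytest.approx(271.0, abs=1.0)
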