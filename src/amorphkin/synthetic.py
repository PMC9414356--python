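"""Synthetic instrument data with known ground truth.

No raw thermograms or loss spectra are deposited with the study this
package models, so every analysis stage is validated against forward models
that plant known parameters:

* DSC heating runs — linear baseline, a heat-capacity step at the glass
  transition, a Gaussian cold-crystallization exotherm (area set by the
  crystallization enthalpy and the heating rate) and an optional melting
  endotherm, plus i.i.d. Gaussian noise.
* Heating-rate series whose peak temperatures satisfy the Kissinger
  relation exactly at a planted activation energy.
* Crystallinity curves from the one- or two-stage Avrami model.
* Dielectric loss spectra from the HN or KWW shape with a DC-conductivity
  wing, whose alpha-peak amplitude decays linearly in temperature above a
  planted crystallization onset.

All generators are pure functions of (truth, seed): repeated calls are
bit-identical.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from ._constants import EPS0, R_GAS
from .activation import RateSeries
from .dielectric import TauAlphaTable, hn_loss, kww_loss, vft_tau
from .io import LossSpectrum, Thermogram

__all__ = [
    "DscTruth",
    "BdsTruth",
    "gen_thermogram",
    "gen_thermogram_series",
    "solve_kissinger_Tp",
    "kissinger_series",
    "augis_bennett_series",
    "gen_avrami_curve",
    "gen_loss_spectrum",
    "gen_tau_table",
]


@dataclass(frozen=True)
class DscTruth:
    """Planted parameters of one synthetic DSC heating run.

    Defaults are typical of a small-molecule glass former: a 0.35 J/(g K)
    heat-capacity step and a 50 J/g cold-crystallization exotherm.
    """

    Tg_mid: float | None = 273.0
    delta_cp_step: float = 0.35  # J/(g K)
    Tg_width: float = 2.0  # K, 10-90 width scale of the sigmoid
    Tp: float | None = 317.3
    peak_width: float = 3.0  # K, Gaussian sigma
    enthalpy: float = 50.0  # J/g, > 0, exothermic
    Tm: float | None = None
    melt_width: float = 3.0
    melt_enthalpy: float = 60.0
    baseline: tuple[float, float] = (0.0, 0.0)  # intercept, slope vs T
    noise_sd: float = 0.0  # W/g
    seed: int = 0

    def __post_init__(self) -> None:
        if self.Tg_width <= 0 or self.peak_width <= 0 or self.melt_width <= 0:
            raise ValueError("widths must be positive")
        if self.enthalpy <= 0 or self.melt_enthalpy <= 0:
            raise ValueError("enthalpies must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass(frozen=True)
class BdsTruth:
    """Planted parameters of the synthetic dielectric loss response."""

    shape: str = "HN"  # "HN" | "KWW"
    delta_eps: float = 5.0
    tau: float = 1e-2  # s
    a: float = 0.8
    b: float = 0.6
    beta_kww: float = 0.8
    sigma_dc: float = 0.0  # S/m
    eps_inf: float = 3.0
    T_onset: float | None = None  # K; amplitude decays linearly above it
    decay_slope: float = 0.05  # fraction of amplitude lost per K above onset
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.shape not in ("HN", "KWW"):
            raise ValueError("shape must be 'HN' or 'KWW'")
        if self.delta_eps <= 0 or self.tau <= 0:
            raise ValueError("delta_eps and tau must be > 0")
        if not (0 < self.a <= 1 and 0 < self.b <= 1 and 0 < self.beta_kww <= 1):
            raise ValueError("shape exponents must lie in (0, 1]")
        if self.sigma_dc < 0 or self.noise_sd < 0:
            raise ValueError("sigma_dc and noise_sd must be >= 0")


def _gauss_area(T: np.ndarray, center: float, sigma: float) -> np.ndarray:
    """Unit-area Gaussian in temperature."""
    return np.exp(-0.5 * ((T - center) / sigma) ** 2) / (sigma * math.sqrt(2 * math.pi))


def gen_thermogram(
    truth: DscTruth,
    phi: float,
    temperature: np.ndarray,
    sample_id: str = "synthetic",
    Tp_override: float | None = None,
) -> Thermogram:
    """Synthesize one heating run at ``phi`` K/min on the given K grid.

    Exotherm area in the time domain equals the planted enthalpy: the W/g
    amplitude scales with the heating rate in K/s.
    """
    T = np.asarray(temperature, dtype=float)
    phi_K_s = phi / 60.0
    lo, hi = T[0], T[-1]
    Tp = truth.Tp if Tp_override is None else Tp_override

    def _check(center, margin, name):
        if center is not None and not (lo + margin <= center <= hi - margin):
            raise ValueError(f"grid does not cover the {name} at {center} K")

    _check(truth.Tg_mid, 3 * truth.Tg_width, "glass transition")
    _check(Tp, 4 * truth.peak_width, "crystallization peak")
    _check(truth.Tm, 4 * truth.melt_width, "melting peak")

    y = truth.baseline[0] + truth.baseline[1] * T
    if truth.Tg_mid is not None:
        step = 1.0 / (1.0 + np.exp(-(T - truth.Tg_mid) / truth.Tg_width))
        y = y + truth.delta_cp_step * phi_K_s * step
    if Tp is not None:
        y = y + truth.enthalpy * phi_K_s * _gauss_area(T, Tp, truth.peak_width)
    if truth.Tm is not None:
        y = y - truth.melt_enthalpy * phi_K_s * _gauss_area(T, truth.Tm, truth.melt_width)
    if truth.noise_sd > 0:
        rng = np.random.default_rng(truth.seed)
        y = y + rng.normal(0.0, truth.noise_sd, size=T.size)
    return Thermogram(phi=phi, temperature=T, heat_flow=y, sample_id=sample_id)


def solve_kissinger_Tp(E_cr: float, C_K: float, phi: float) -> float:
    """Peak temperature satisfying ln(phi/Tp^2) = C_K - E_cr/(R Tp).

    ``E_cr`` in kJ/mol, ``phi`` in K/min; root searched on [200, 500] K and
    polished to 1e-10 K by Newton iteration.
    """
    E = E_cr * 1e3

    def g(Tp: float) -> float:
        return math.log(phi / Tp**2) - C_K + E / (R_GAS * Tp)

    lo, hi = 200.0, 500.0
    if g(lo) * g(hi) > 0:
        raise ValueError("no Kissinger root in [200, 500] K")
    Tp = brentq(g, lo, hi, xtol=1e-8)
    for _ in range(50):  # Newton polish
        dg = -2.0 / Tp - E / (R_GAS * Tp**2)
        step = g(Tp) / dg
        Tp -= step
        if abs(step) < 1e-10:
            break
    return Tp


def kissinger_series(
    E_cr: float,
    C_K: float,
    phis: tuple[float, ...],
    onset_offset: float = 1.5,
    sample: str = "synthetic",
) -> RateSeries:
    """(phi, Tp, To) series satisfying the Kissinger relation exactly.

    ``onset_offset`` places To at Tp minus a fixed width in K.
    """
    if len(phis) < 3:
        raise ValueError("need at least 3 heating rates")
    entries = []
    for phi in phis:
        Tp = solve_kissinger_Tp(E_cr, C_K, phi)
        entries.append((phi, Tp, Tp - onset_offset))
    return RateSeries(entries=tuple(entries), sample=sample)


def augis_bennett_series(
    E_cr: float,
    C_AG: float,
    phis: tuple[float, ...],
    Tps: tuple[float, ...],
    sample: str = "synthetic",
) -> RateSeries:
    """(phi, Tp, To) series satisfying the Augis–Bennett relation exactly.

    Given fixed peak temperatures, each onset is placed at
    To = Tp - phi*exp(E_cr/(R Tp) - C_AG), in kJ/mol and K/min.
    """
    if len(phis) != len(Tps) or len(phis) < 3:
        raise ValueError("need matching phis and Tps, at least 3 of each")
    E = E_cr * 1e3
    entries = []
    for phi, Tp in zip(phis, Tps):
        width = phi * math.exp(E / (R_GAS * Tp) - C_AG)
        if width <= 0:
            raise ValueError("constructed peak-onset width must be positive")
        entries.append((phi, Tp, Tp - width))
    return RateSeries(entries=tuple(entries), sample=sample)


def gen_thermogram_series(
    E_cr: float,
    C_K: float,
    phis: tuple[float, ...],
    truth: DscTruth,
    temperature: np.ndarray | None = None,
    sample_id: str = "synthetic",
) -> tuple[list[Thermogram], list[float]]:
    """Heating runs whose exotherm peaks follow a planted Kissinger law.

    Returns the thermograms and the planted peak temperatures.  Peak
    temperatures strictly increase with the heating rate (forced by the
    relation for E_cr > 0).
    """
    if E_cr <= 0:
        raise ValueError("E_cr must be positive")
    if len(phis) < 3:
        raise ValueError("need at least 3 heating rates")
    Tps = [solve_kissinger_Tp(E_cr, C_K, phi) for phi in phis]
    if temperature is None:
        lo = (truth.Tg_mid or min(Tps)) - 20.0
        hi = max(Tps) + 25.0
        temperature = np.arange(lo, hi, 0.05)
    runs = [
        gen_thermogram(truth, phi, temperature, sample_id=sample_id, Tp_override=Tp)
        for phi, Tp in zip(phis, Tps)
    ]
    return runs, Tps


def gen_avrami_curve(
    k1: float,
    n: float,
    t: np.ndarray,
    noise_sd: float = 0.0,
    seed: int = 0,
    x: float = 1.0,
    k2: float | None = None,
    m: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Crystallinity series X(t) from the (double-)Avrami forward model.

    With ``x = 1`` (default) the curve is single-stage; otherwise the
    two-stage model with weight ``x`` and stage-2 parameters (k2, m) is
    used.  Gaussian noise is clipped to keep X inside [0, 1].  Returns
    (t, X).
    """
    t = np.asarray(t, dtype=float)
    if k1 <= 0 or n <= 0:
        raise ValueError("k1 and n must be positive")
    if not (0.0 <= x <= 1.0):
        raise ValueError("x must lie in [0, 1]")
    tp = np.power(t, n, where=t > 0, out=np.zeros_like(t))
    X = x * (1.0 - np.exp(-k1 * tp))
    if x < 1.0:
        if k2 is None or m is None or k2 <= 0 or m <= 0:
            raise ValueError("two-stage curve needs positive k2 and m")
        tq = np.power(t, m, where=t > 0, out=np.zeros_like(t))
        X = X + (1.0 - x) * (1.0 - np.exp(-k2 * tq))
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        X = np.clip(X + rng.normal(0.0, noise_sd, size=t.size), 0.0, 1.0)
    return t, X


def gen_loss_spectrum(
    truth: BdsTruth, T: float, frequency: np.ndarray
) -> LossSpectrum:
    """Synthesize a loss spectrum at temperature ``T`` on a Hz grid.

    The KWW branch uses the same one-sided-Fourier-transform quadrature as
    the analysis side, so noiseless spectra satisfy the model to quadrature
    tolerance.  Above the planted crystallization onset the relaxational
    amplitude (not the conductivity) decays linearly in T.
    """
    f = np.asarray(frequency, dtype=float)
    w = 2.0 * np.pi * f
    amp = 1.0
    if truth.T_onset is not None and T > truth.T_onset:
        amp = max(0.0, 1.0 - truth.decay_slope * (T - truth.T_onset))
    if truth.shape == "HN":
        loss = amp * hn_loss(w, truth.delta_eps, truth.tau, truth.a, truth.b)
    else:
        loss = amp * kww_loss(truth.beta_kww, truth.tau, truth.delta_eps, w)
    if truth.sigma_dc > 0:
        loss = loss + truth.sigma_dc / (EPS0 * w)
    if truth.noise_sd > 0:
        rng = np.random.default_rng(truth.seed)
        loss = np.clip(loss + rng.normal(0.0, truth.noise_sd, size=f.size), 0.0, None)
    return LossSpectrum(temperature=T, frequency=f, eps_loss=loss)


def gen_tau_table(
    tau_vft: float, D_T: float, T0: float, temperatures: np.ndarray
) -> TauAlphaTable:
    """Noiseless (T, tau_alpha) table from a planted VFT law."""
    T = np.asarray(temperatures, dtype=float)
    return TauAlphaTable(temperature=T, tau_alpha=vft_tau(T, tau_vft, D_T, T0))
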