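"""Avrami analysis of non-isothermal crystallization curves.

Single-stage model:      X(t) = 1 - exp(-k1 t^n)
Two-stage ("double Avrami") model:

    X(t) = x [1 - exp(-k1 t^n)] + (1 - x) [1 - exp(-k2 t^m)]

with 0 <= x <= 1 weighting the first stage.  The rate constants carry units
of s^-n (s^-m); following the convention of published kinetics tables they
are reported numerically with the exponent alongside.

Fits are unweighted least squares on X(t) directly, initialized from the
ordinary-least-squares Avrami linearization ln(-ln(1-X)) = ln k + n ln t.
The exponent m of the second stage is known to be poorly identified on
sigmoidal data; fits flag it (``m_unreliable``) rather than interpret it.
Model selection uses the small-sample-corrected Akaike criterion with a
two-unit tie band favouring the single-stage model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .dsc import CrystallinityCurve

__all__ = [
    "AvramiFit",
    "DoubleAvramiFit",
    "ModelChoice",
    "KineticsError",
    "avrami",
    "double_avrami",
    "fit_avrami",
    "fit_double_avrami",
    "select_model",
]

DEFAULT_WINDOW = (0.03, 0.97)


class KineticsError(RuntimeError):
    pass


@dataclass(frozen=True)
class AvramiFit:
    k1: float
    n: float
    sigma_k1: float
    sigma_n: float
    rss: float
    window: tuple[float, float]

    def __post_init__(self) -> None:
        if self.k1 <= 0 or self.n <= 0:
            raise ValueError("k1 and n must be positive")


@dataclass(frozen=True)
class DoubleAvramiFit:
    x: float
    k1: float
    n: float
    k2: float
    m: float
    sigma: dict
    rss: float
    window: tuple[float, float]
    m_unreliable: bool = False

    def __post_init__(self) -> None:
        if not (0.0 <= self.x <= 1.0):
            raise ValueError("x must lie in [0, 1]")
        if min(self.k1, self.k2) <= 0 or min(self.n, self.m) <= 0:
            raise ValueError("rate constants and exponents must be positive")


@dataclass(frozen=True)
class ModelChoice:
    chosen: str  # "single" | "double"
    aicc_single: float
    aicc_double: float
    single: AvramiFit
    double: DoubleAvramiFit


def avrami(t: np.ndarray, k1: float, n: float) -> np.ndarray:
    t = np.asarray(t, dtype=float)
    return 1.0 - np.exp(-k1 * np.power(t, n, where=t > 0, out=np.zeros_like(t)))


def double_avrami(
    t: np.ndarray, x: float, k1: float, n: float, k2: float, m: float
) -> np.ndarray:
    return x * avrami(t, k1, n) + (1.0 - x) * avrami(t, k2, m)


def _windowed(curve, window, min_points: int):
    """Accepts a CrystallinityCurve or a plain (t, X) pair."""
    if isinstance(curve, tuple):
        t, X = (np.asarray(a, dtype=float) for a in curve)
    else:
        if curve.time is None or curve.X_of_t is None:
            raise KineticsError("curve has no time axis; call to_time_domain first")
        t = curve.time
        X = curve.X_of_t
    mask = (X >= window[0]) & (X <= window[1]) & (t > 0)
    if mask.sum() < min_points:
        raise KineticsError(
            f"fit window keeps {int(mask.sum())} points; need >= {min_points}"
        )
    return t[mask], X[mask]


def _linearized_init(t: np.ndarray, X: np.ndarray) -> tuple[float, float]:
    """OLS on ln(-ln(1-X)) vs ln t; exact on noiseless single-stage data."""
    z = np.log(-np.log1p(-X))
    n, lnk = np.polyfit(np.log(t), z, 1)
    return math.exp(lnk), float(n)


def fit_avrami(
    curve: CrystallinityCurve, window: tuple[float, float] = DEFAULT_WINDOW
) -> AvramiFit:
    """Fit the single-stage Avrami model on the X window (default 3–97%)."""
    t, X = _windowed(curve, window, 8)
    k0, n0 = _linearized_init(t, X)

    def residuals(p):
        return avrami(t, math.exp(p[0]), p[1]) - X

    sol = least_squares(
        residuals,
        np.array([math.log(k0), np.clip(n0, 0.06, 11.9)]),
        bounds=([-60, 0.05], [30, 12.0]),
        xtol=1e-15, ftol=1e-15, gtol=1e-15,
    )
    if not sol.success:
        raise KineticsError(f"Avrami fit failed: {sol.message}")
    k1 = math.exp(sol.x[0])
    n = float(sol.x[1])
    rss = float(np.sum(sol.fun**2))
    m_pts, n_par = sol.fun.size, 2
    if m_pts > n_par:
        s2 = rss / (m_pts - n_par)
        cov = s2 * np.linalg.pinv(sol.jac.T @ sol.jac)
        sig_lnk, sig_n = np.sqrt(np.clip(np.diag(cov), 0, None))
    else:
        sig_lnk = sig_n = float("nan")
    return AvramiFit(
        k1=k1, n=n, sigma_k1=float(k1 * sig_lnk), sigma_n=float(sig_n),
        rss=rss, window=window,
    )


def fit_double_avrami(
    curve: CrystallinityCurve,
    window: tuple[float, float] = DEFAULT_WINDOW,
    fix: dict | None = None,
) -> DoubleAvramiFit:
    """Fit the two-stage model; ``fix`` may pin any of {"x", "m"} to a value.

    Initialized from the single-stage fit (k1 = k2 = k, n = m = n) with a
    multi-start over x in {0.25, 0.5, 0.75}; the lowest-RSS solution wins.
    """
    fix = dict(fix or {})
    bad = set(fix) - {"x", "m"}
    if bad:
        raise ValueError(f"only x and m may be fixed, got {sorted(bad)}")
    t, X = _windowed(curve, window, 12)
    base = fit_avrami(curve, window)

    names = ["x", "lnk1", "n", "lnk2", "m"]
    free = [nm for nm in names if nm not in fix]

    def unpack(p):
        vals = dict(zip(free, p))
        x = vals.get("x", fix.get("x"))
        m = vals.get("m", fix.get("m"))
        return (
            x,
            math.exp(vals["lnk1"]),
            vals["n"],
            math.exp(vals["lnk2"]),
            m,
        )

    def residuals(p):
        return double_avrami(t, *unpack(p)) - X

    lo = {"x": 1e-6, "lnk1": -60, "n": 0.5, "lnk2": -60, "m": 0.5}
    hi = {"x": 1 - 1e-6, "lnk1": 30, "n": 8.0, "lnk2": 30, "m": 8.0}
    n0 = float(np.clip(base.n, 0.51, 7.99))
    starts = [fix.get("x", xs) for xs in ((0.25, 0.5, 0.75) if "x" not in fix else (None,))]

    best = None
    for xs in starts:
        init = {
            "x": xs,
            "lnk1": math.log(base.k1),
            "n": n0,
            "lnk2": math.log(base.k1),
            "m": float(np.clip(fix.get("m", n0), 0.51, 7.99)),
        }
        p0 = np.array([init[nm] for nm in free])
        try:
            sol = least_squares(
                residuals,
                p0,
                bounds=([lo[nm] for nm in free], [hi[nm] for nm in free]),
                xtol=1e-15, ftol=1e-15, gtol=1e-15,
            )
        except ValueError:
            continue
        if sol.success and (best is None or sol.cost < best.cost):
            best = sol
    if best is None:
        raise KineticsError("double-Avrami fit failed from every start")

    x, k1, n, k2, m = unpack(best.x)
    rss = float(np.sum(best.fun**2))
    m_pts, n_par = best.fun.size, len(free)
    sigma: dict = {nm: float("nan") for nm in names}
    if m_pts > n_par:
        s2 = rss / (m_pts - n_par)
        cov = s2 * np.linalg.pinv(best.jac.T @ best.jac)
        err = np.sqrt(np.clip(np.diag(cov), 0, None))
        for nm, e in zip(free, err):
            if nm.startswith("lnk"):
                key = nm[2:]
                sigma[key] = float(math.exp(dict(zip(free, best.x))[nm]) * e)
            else:
                sigma[nm] = float(e)
    sigma = {k: v for k, v in sigma.items() if k in ("x", "k1", "n", "k2", "m")}
    sig_m = sigma.get("m", float("nan"))
    m_unreliable = bool(m > 6.0 or (np.isfinite(sig_m) and m > 0 and sig_m / m > 0.5))
    return DoubleAvramiFit(
        x=x, k1=k1, n=n, k2=k2, m=m, sigma=sigma, rss=rss,
        window=window, m_unreliable=m_unreliable,
    )


def _aicc(rss: float, n_obs: int, k_par: int) -> float:
    rss = max(rss, 1e-300)
    aic = n_obs * math.log(rss / n_obs) + 2 * k_par
    denom = n_obs - k_par - 1
    return aic + (2 * k_par * (k_par + 1) / denom if denom > 0 else float("inf"))


def select_model(
    curve: CrystallinityCurve, window: tuple[float, float] = DEFAULT_WINDOW
) -> ModelChoice:
    """Choose between the one- and two-stage models by corrected AIC.

    Within a two-unit AICc band the simpler single-stage model is kept.
    """
    single = fit_avrami(curve, window)
    double = fit_double_avrami(curve, window)
    t, X = _windowed(curve, window, 8)
    n_obs = t.size
    a1 = _aicc(single.rss, n_obs, 2)
    a2 = _aicc(double.rss, n_obs, 5)
    chosen = "double" if a2 < a1 - 2.0 else "single"
    return ModelChoice(
        chosen=chosen, aicc_single=a1, aicc_double=a2, single=single, double=double
    )
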