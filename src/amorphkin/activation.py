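"""Activation energy of non-isothermal crystallization.

Two linearizations relate the heating-rate shift of the crystallization
peak to an effective activation energy E_cr (natural logs throughout):

Kissinger:        ln(phi / Tp^2)       = C_K  - E_cr / (R Tp)
Augis–Bennett:    ln(phi / (Tp - To))  = C_AG - E_cr / (R Tp)

Both are ordinary least squares of the left side on 1/Tp; E_cr is
-slope * R.  The choice of heating-rate unit (K/min vs K/s) rescales phi by
a constant, which shifts only the intercept — E_cr is unit-invariant.

The package ships a published (phi, Tg, Tp, To, k1, k2, n) summary table for
flutamide–poly(N-vinylpyrrolidone) dispersions as a typed-in CSV fixture
(:func:`load_reference_kinetics`), so the regressions can be run directly on
printed literature values.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from ._constants import R_GAS

__all__ = [
    "RateSeries",
    "ActivationFit",
    "fit_kissinger",
    "fit_augis_bennett",
    "compare_methods",
    "load_reference_kinetics",
    "rate_series_from_frame",
]


@dataclass(frozen=True)
class RateSeries:
    """(phi, Tp, To) tuples for one sample across heating rates.

    ``entries`` is a list of (phi_K_per_min, Tp_K, To_K-or-None).
    """

    entries: tuple
    sample: str = ""

    def __post_init__(self) -> None:
        entries = tuple(
            (float(phi), float(Tp), None if To is None else float(To))
            for phi, Tp, To in self.entries
        )
        object.__setattr__(self, "entries", entries)
        if len(entries) < 3:
            raise ValueError("a rate series needs at least 3 heating rates")
        phis = [e[0] for e in entries]
        if len(set(phis)) != len(phis) or min(phis) <= 0:
            raise ValueError("heating rates must be distinct and positive")
        for phi, Tp, To in entries:
            if To is not None and not Tp > To:
                raise ValueError(f"entry phi={phi}: require Tp > To")

    @property
    def phi(self) -> np.ndarray:
        return np.array([e[0] for e in self.entries])

    @property
    def Tp(self) -> np.ndarray:
        return np.array([e[1] for e in self.entries])

    @property
    def To(self) -> np.ndarray:
        return np.array([np.nan if e[2] is None else e[2] for e in self.entries])


@dataclass(frozen=True)
class ActivationFit:
    method: str  # "kissinger" | "augis_bennett"
    E_cr: float  # kJ/mol
    intercept: float
    stderr_E: float  # kJ/mol
    r_squared: float

    def __post_init__(self) -> None:
        if self.stderr_E < 0:
            raise ValueError("stderr_E must be >= 0")


def _regress(x: np.ndarray, y: np.ndarray, method: str) -> ActivationFit:
    if np.ptp(x) == 0:
        raise ValueError("zero variance in 1/Tp; cannot regress")
    res = stats.linregress(x, y)
    E = -res.slope * R_GAS / 1e3
    stderr = (res.stderr if np.isfinite(res.stderr) else 0.0) * R_GAS / 1e3
    return ActivationFit(
        method=method,
        E_cr=float(E),
        intercept=float(res.intercept),
        stderr_E=float(abs(stderr)),
        r_squared=float(res.rvalue**2),
    )


def fit_kissinger(series: RateSeries) -> ActivationFit:
    """OLS of ln(phi/Tp^2) on 1/Tp; E_cr = -slope*R, in kJ/mol."""
    Tp = series.Tp
    y = np.log(series.phi / Tp**2)
    return _regress(1.0 / Tp, y, "kissinger")


def fit_augis_bennett(series: RateSeries) -> ActivationFit:
    """OLS of ln(phi/(Tp - To)) on 1/Tp; E_cr = -slope*R, in kJ/mol."""
    To = series.To
    if np.any(np.isnan(To)):
        raise ValueError("Augis–Bennett needs To for every entry")
    Tp = series.Tp
    y = np.log(series.phi / (Tp - To))
    return _regress(1.0 / Tp, y, "augis_bennett")


def compare_methods(series: RateSeries) -> tuple[ActivationFit, ActivationFit, float]:
    """Both fits plus E_cr(Kissinger) - E_cr(Augis–Bennett) in kJ/mol."""
    k = fit_kissinger(series)
    ab = fit_augis_bennett(series)
    return k, ab, k.E_cr - ab.E_cr


def load_reference_kinetics() -> pd.DataFrame:
    """Published flutamide–PVP kinetics summary (typed-in literature values)."""
    with resources.files("amorphkin").joinpath("data/reference_kinetics.csv").open() as fh:
        return pd.read_csv(fh)


def rate_series_from_frame(df: pd.DataFrame, sample: str = "") -> RateSeries:
    """Build a RateSeries from a frame with phi_K_per_min, Tp_K[, To_K]."""
    entries = []
    for _, row in df.iterrows():
        To = row.get("To_K")
        entries.append(
            (row["phi_K_per_min"], row["Tp_K"], None if pd.isna(To) else To)
        )
    return RateSeries(entries=tuple(entries), sample=sample)


def rate_series_from_csv(path: str | Path, sample: str = "") -> RateSeries:
    return rate_series_from_frame(pd.read_csv(path), sample=sample)
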