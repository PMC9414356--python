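"""DSC thermogram processing.

Extracts the glass transition (heat-capacity step), locates the cold
crystallization exotherm, and converts the exotherm into the relative
degree of crystallinity

    X(T) = ∫_{T0}^{T} (dHc/dT) dT  /  ∫_{T0}^{T∞} (dHc/dT) dT,

which is re-indexed onto the time axis of a constant-rate run through
t = (T - T0)/phi (phi in K/s, t in seconds).

Two distinct "onset" temperatures appear in non-isothermal kinetics and are
kept apart deliberately: ``T0``/``Tinf`` bound the integration window of
X(T) (where the baseline-subtracted exotherm first/last exceeds 0.5% of the
peak height), while ``To`` is the tangent-construction onset used by the
Augis–Bennett method (intersection of the steepest ascending tangent with
the baseline), which sits well inside the rising flank.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.integrate import cumulative_trapezoid, trapezoid

from .io import Thermogram

__all__ = [
    "GlassTransition",
    "CrystallizationPeak",
    "CrystallinityCurve",
    "DetectionError",
    "detect_glass_transition",
    "locate_crystallization_peak",
    "crystallinity_vs_T",
    "to_time_domain",
]

#: relative threshold bounding the exotherm integration window
PEAK_BOUND_FRACTION = 0.005


class DetectionError(RuntimeError):
    """A thermal event could not be detected in the requested window."""


@dataclass(frozen=True)
class GlassTransition:
    """Half-step glass transition: onset/midpoint/end plus the Cp step."""

    Tg_onset: float
    Tg_mid: float
    Tg_end: float
    delta_cp: float  # J/(g K)

    def __post_init__(self) -> None:
        if not (self.Tg_onset < self.Tg_mid < self.Tg_end):
            raise ValueError("require Tg_onset < Tg_mid < Tg_end")
        if self.delta_cp <= 0:
            raise ValueError("delta_cp must be > 0")


@dataclass(frozen=True)
class CrystallizationPeak:
    T0: float
    Tp: float
    Tinf: float
    To: float
    enthalpy: float  # J/g
    baseline: tuple[float, float]  # slope, intercept of the linear baseline
    window: tuple[float, float] = (float("nan"), float("nan"))

    def __post_init__(self) -> None:
        if not (self.T0 <= self.To < self.Tp < self.Tinf):
            raise ValueError("require T0 <= To < Tp < Tinf")
        if self.enthalpy <= 0:
            raise ValueError("enthalpy must be > 0")


@dataclass
class CrystallinityCurve:
    temperature: np.ndarray
    X_of_T: np.ndarray
    phi: float  # K/min
    time: np.ndarray | None = None
    X_of_t: np.ndarray | None = None

    def __post_init__(self) -> None:
        T = np.asarray(self.temperature, dtype=float)
        X = np.asarray(self.X_of_T, dtype=float)
        if T.shape != X.shape:
            raise ValueError("temperature and X_of_T lengths differ")
        if np.any(np.diff(X) < -1e-12):
            raise ValueError("X must be monotone non-decreasing")
        if abs(X[0]) > 1e-9 or abs(X[-1] - 1.0) > 1e-9:
            raise ValueError("X must run from 0 at T0 to 1 at Tinf")
        self.temperature = T
        self.X_of_T = np.clip(X, 0.0, 1.0)


def _linefit(T: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    slope, intercept = np.polyfit(T, y, 1)
    return float(slope), float(intercept)


def _window_slice(tg: Thermogram, window: tuple[float, float]) -> slice:
    lo, hi = window
    idx = np.nonzero((tg.temperature >= lo) & (tg.temperature <= hi))[0]
    if idx.size < 8:
        raise DetectionError("window contains too few points")
    return slice(idx[0], idx[-1] + 1)


def detect_glass_transition(
    tg: Thermogram, window: tuple[float, float]
) -> GlassTransition:
    """Detect a heat-capacity step by the tangent/half-step construction.

    Linear baselines are fitted to the outer quarters of the window; Tg_mid
    is where the signal crosses the midline between them, and onset/end are
    the intersections of the steepest tangent with the two baselines.
    """
    sl = _window_slice(tg, window)
    T = tg.temperature[sl]
    y = tg.heat_flow[sl]
    n = T.size
    q = max(n // 4, 3)
    pre = _linefit(T[:q], y[:q])
    post = _linefit(T[-q:], y[-q:])
    noise_sd = float(np.std(y[:q] - np.polyval(pre, T[:q])))
    step = np.polyval(post, T) - np.polyval(pre, T)
    mid_i = n // 2
    step_amp = abs(step[mid_i])
    if not step_amp > 3.0 * noise_sd:
        raise DetectionError("no glass transition detected")

    midline = 0.5 * (np.polyval(pre, T) + np.polyval(post, T))
    d = y - midline
    # first upward crossing of the midline in the central region
    cross = None
    for i in range(q, n - q):
        if d[i] <= 0.0 <= d[i + 1]:
            cross = i
            break
    if cross is None:
        raise DetectionError("no glass transition detected")
    # linear interpolation of the crossing
    f = d[cross] / (d[cross] - d[cross + 1]) if d[cross] != d[cross + 1] else 0.0
    Tg_mid = float(T[cross] + f * (T[cross + 1] - T[cross]))

    dy = np.gradient(y, T)
    j = q + int(np.argmax(dy[q : n - q]))
    slope_t = float(dy[j])
    if slope_t <= max(pre[0], post[0]):
        raise DetectionError("no rising inflection found")
    # tangent through (T[j], y[j]) intersected with each baseline
    def _intersect(line: tuple[float, float]) -> float:
        return (y[j] - slope_t * T[j] - line[1]) / (line[0] - slope_t)

    Tg_onset = _intersect(pre)
    Tg_end = _intersect(post)
    delta_cp = abs(step[np.searchsorted(T, Tg_mid)]) / tg.phi_K_per_s
    return GlassTransition(
        Tg_onset=float(Tg_onset), Tg_mid=Tg_mid, Tg_end=float(Tg_end), delta_cp=delta_cp
    )


def locate_crystallization_peak(
    tg: Thermogram, window: tuple[float, float]
) -> CrystallizationPeak:
    """Locate a single exothermic peak and its kinetic temperatures.

    The baseline is the straight line through the window endpoints.  Tp is
    the maximum of the baseline-subtracted signal (parabolic sub-grid
    refinement); T0/Tinf are the outermost crossings of 0.5% of the peak
    height; To is the intersection of the steepest ascending tangent with
    the baseline; the enthalpy is the trapezoidal area over T divided by
    the heating rate in K/s.
    """
    sl = _window_slice(tg, window)
    T = tg.temperature[sl]
    y = tg.heat_flow[sl]
    n = T.size
    slope = (y[-1] - y[0]) / (T[-1] - T[0])
    intercept = y[0] - slope * T[0]
    yc = y - (slope * T + intercept)

    ip = int(np.argmax(yc))
    height = yc[ip]
    if height <= 0 or ip in (0, n - 1):
        raise DetectionError("no exothermic peak above baseline in window")
    # ambiguity check: another local maximum within 20% of the main height
    interior = np.nonzero(
        (yc[1:-1] > yc[:-2]) & (yc[1:-1] >= yc[2:]) & (yc[1:-1] >= 0.8 * height)
    )[0]
    if interior.size > 1 and np.any(np.abs(interior + 1 - ip) > 2):
        raise DetectionError("ambiguous peak: two comparable maxima in window")

    # parabolic refinement of the apex
    Tp = float(T[ip])
    if 0 < ip < n - 1:
        y1, y2, y3 = yc[ip - 1], yc[ip], yc[ip + 1]
        denom = y1 - 2 * y2 + y3
        if denom < 0:
            Tp = float(T[ip] - 0.5 * (y3 - y1) / denom * (T[ip + 1] - T[ip]))

    thr = PEAK_BOUND_FRACTION * height
    above = yc >= thr
    if not above[ip]:
        raise DetectionError("no signal above threshold")
    lo = ip
    while lo > 0 and above[lo - 1]:
        lo -= 1
    hi = ip
    while hi < n - 1 and above[hi + 1]:
        hi += 1

    def _crossing(i_in: int, i_out: int) -> float:
        if yc[i_out] == yc[i_in]:
            return float(T[i_in])
        f = (yc[i_in] - thr) / (yc[i_in] - yc[i_out])
        return float(T[i_in] + f * (T[i_out] - T[i_in]))

    T0 = _crossing(lo, lo - 1) if lo > 0 else float(T[0])
    Tinf = _crossing(hi, hi + 1) if hi < n - 1 else float(T[-1])

    dy = np.gradient(yc, T)
    j = lo + int(np.argmax(dy[lo : ip + 1]))
    if dy[j] <= 0:
        raise DetectionError("no ascending flank found")
    To = float(T[j] - yc[j] / dy[j])
    To = max(To, T0)
    if not To < Tp:
        raise DetectionError("onset construction failed (To >= Tp)")

    # integrate the whole baseline-subtracted window: the 0.5% bounds define
    # the X(T) normalization range but would clip the exotherm tails here
    area = trapezoid(yc, T)  # (W/g)·K
    enthalpy = float(area / tg.phi_K_per_s)  # J/g
    return CrystallizationPeak(
        T0=T0, Tp=Tp, Tinf=Tinf, To=To, enthalpy=enthalpy,
        baseline=(slope, intercept), window=(float(T[0]), float(T[-1])),
    )


def crystallinity_vs_T(
    tg: Thermogram, peak: CrystallizationPeak
) -> CrystallinityCurve:
    """Relative crystallinity X(T): normalized cumulative exotherm area."""
    T = tg.temperature
    slope, intercept = peak.baseline
    yc = tg.heat_flow - (slope * T + intercept)
    mask = (T >= peak.T0) & (T <= peak.Tinf)
    Tm = T[mask]
    ym = np.clip(yc[mask], 0.0, None)
    cum = cumulative_trapezoid(ym, Tm, initial=0.0)
    total = cum[-1]
    if total <= 0:
        raise DetectionError("total exotherm integral is not positive")
    X = np.clip(cum / total, 0.0, 1.0)
    X[0], X[-1] = 0.0, 1.0
    return CrystallinityCurve(temperature=Tm, X_of_T=X, phi=tg.phi)


def to_time_domain(curve: CrystallinityCurve, phi: float | None = None) -> CrystallinityCurve:
    """Re-index X(T) as X(t) with t = (T - T0)/phi, phi converted to K/s."""
    phi = curve.phi if phi is None else phi
    phi_K_s = phi / 60.0
    t = (curve.temperature - curve.temperature[0]) / phi_K_s
    return replace(curve, phi=phi, time=t, X_of_t=curve.X_of_T.copy())
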