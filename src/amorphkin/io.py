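"""Reading and writing the canonical text formats.

Thermograms and dielectric loss spectra travel as comma-delimited tables
with ``# key=value`` metadata lines before the header row.  One dialect is
used everywhere so round-trips are bit-exact:

Thermogram files::

    # phi_K_per_min=10.0
    # sample=FL
    temperature_K,heat_flow_W_per_g
    300.0,0.0123
    ...

Loss-spectrum files::

    # T_K=295.0
    frequency_Hz,eps_loss
    0.01,1.23
    ...

Internally temperatures are kelvin, times seconds and enthalpies J/g.  The
heating rate ``phi`` is carried in K/min (the unit instrument software and
published kinetics tables use); every computation that needs K/s converts
through :attr:`Thermogram.phi_K_per_s`.  Heat flow is stored exothermic-up;
files written by instruments with the opposite convention are negated on
load via ``exo_down=True``.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml


class FormatError(ValueError):
    """A file does not conform to the canonical dialect."""


class ValidationError(ValueError):
    """Numeric content violates a physical invariant."""


@dataclass(frozen=True)
class Thermogram:
    """One DSC heating run.

    Attributes
    ----------
    phi : float
        Heating rate, K/min (> 0).
    temperature : ndarray
        Strictly increasing grid, K.
    heat_flow : ndarray
        Specific heat flow, W/g, exothermic-up.
    sample_id : str
        Sample label.
    mass : float or None
        Sample mass in mg; metadata only, never used in computation.
    """

    phi: float
    temperature: np.ndarray
    heat_flow: np.ndarray
    sample_id: str = ""
    mass: float | None = None

    def __post_init__(self) -> None:
        T = np.asarray(self.temperature, dtype=float)
        y = np.asarray(self.heat_flow, dtype=float)
        object.__setattr__(self, "temperature", T)
        object.__setattr__(self, "heat_flow", y)
        if self.phi is None or not self.phi > 0:
            raise FormatError("phi: heating rate must be positive")
        if T.shape != y.shape:
            raise ValidationError("temperature and heat_flow lengths differ")
        if T.size < 16:
            raise ValidationError("thermogram needs at least 16 points")
        if not np.all(np.diff(T) > 0):
            raise ValidationError("temperature grid must be strictly increasing")

    @property
    def phi_K_per_s(self) -> float:
        return self.phi / 60.0


@dataclass(frozen=True)
class LossSpectrum:
    """Dielectric loss spectrum at one temperature.

    ``omega`` is the angular frequency 2*pi*f.
    """

    temperature: float
    frequency: np.ndarray
    eps_loss: np.ndarray

    def __post_init__(self) -> None:
        f = np.asarray(self.frequency, dtype=float)
        e = np.asarray(self.eps_loss, dtype=float)
        object.__setattr__(self, "frequency", f)
        object.__setattr__(self, "eps_loss", e)
        if f.shape != e.shape:
            raise ValidationError("frequency and eps_loss lengths differ")
        if f.size < 12:
            raise ValidationError("loss spectrum needs at least 12 points")
        if not np.all(f > 0) or not np.all(np.diff(f) > 0):
            raise ValidationError("frequencies must be positive and strictly increasing")
        if np.any(e < 0):
            raise ValidationError("eps_loss must be non-negative")

    @property
    def omega(self) -> np.ndarray:
        return 2.0 * np.pi * self.frequency


@dataclass
class RunConfig:
    """Configuration for the end-to-end pipeline.

    ``tg_window`` / ``peak_window`` are (low, high) kelvin intervals passed to
    the DSC stage; when ``None`` the stage falls back to a simple heuristic
    split of the temperature range.
    """

    thermograms: list[str] = field(default_factory=list)
    spectra: list[str] = field(default_factory=list)
    outdir: str = "amorphkin-out"
    tg_window: tuple[float, float] | None = None
    peak_window: tuple[float, float] | None = None
    fit_window: tuple[float, float] = (0.03, 0.97)
    onset_threshold: float = 0.90
    exo_down: bool = False
    run_dsc: bool = True
    run_kinetics: bool = True
    run_activation: bool = True
    run_bds: bool = True
    seed: int = 0
    tolerance: float = 1e-8

    def __post_init__(self) -> None:
        if not (isinstance(self.seed, int) and self.seed >= 0):
            raise ValidationError("seed must be a non-negative integer")
        if not self.tolerance > 0:
            raise ValidationError("every tolerance must be > 0")
        if not 0 < self.onset_threshold < 1:
            raise ValidationError("onset_threshold must lie in (0, 1)")
        for name in ("tg_window", "peak_window"):
            w = getattr(self, name)
            if w is not None:
                w = (float(w[0]), float(w[1]))
                if not w[0] < w[1]:
                    raise ValidationError(f"{name} must be an increasing interval")
                setattr(self, name, w)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise FormatError("config file must contain a mapping")
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise FormatError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


def _read_meta_table(path: str | Path) -> tuple[dict[str, str], pd.DataFrame]:
    meta: dict[str, str] = {}
    body_lines: list[str] = []
    with open(path) as fh:
        for line in fh:
            s = line.strip()
            if not s:
                continue
            if s.startswith("#"):
                kv = s.lstrip("#").strip()
                if "=" in kv:
                    k, v = kv.split("=", 1)
                    meta[k.strip()] = v.strip()
            else:
                body_lines.append(line)
    if not body_lines:
        raise FormatError(f"{path}: no table body found")
    table = pd.read_csv(_io.StringIO("".join(body_lines)), float_precision="round_trip")
    return meta, table


def read_thermogram(path: str | Path, exo_down: bool = False) -> Thermogram:
    """Read one thermogram from the canonical CSV dialect.

    Rows are sorted by temperature; duplicate temperatures are collapsed by
    averaging their heat flow.  ``exo_down=True`` negates the signal so that
    exotherms point up internally.
    """
    meta, table = _read_meta_table(path)
    for col in ("temperature_K", "heat_flow_W_per_g"):
        if col not in table.columns:
            raise FormatError(f"{path}: missing column {col}")
    if "phi_K_per_min" not in meta:
        raise FormatError(f"{path}: missing metadata phi")
    try:
        phi = float(meta["phi_K_per_min"])
    except ValueError as exc:
        raise FormatError(f"{path}: phi is not numeric") from exc
    if not phi > 0:
        raise FormatError(f"{path}: phi must be positive")
    df = table[["temperature_K", "heat_flow_W_per_g"]].astype(float)
    df = df.groupby("temperature_K", as_index=False).mean().sort_values("temperature_K")
    hf = df["heat_flow_W_per_g"].to_numpy()
    if exo_down:
        hf = -hf
    mass = float(meta["mass_mg"]) if "mass_mg" in meta else None
    return Thermogram(
        phi=phi,
        temperature=df["temperature_K"].to_numpy(),
        heat_flow=hf,
        sample_id=meta.get("sample", Path(path).stem),
        mass=mass,
    )


def write_thermogram(tg: Thermogram, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# phi_K_per_min={tg.phi!r}\n")
        fh.write(f"# sample={tg.sample_id}\n")
        if tg.mass is not None:
            fh.write(f"# mass_mg={tg.mass!r}\n")
        fh.write("temperature_K,heat_flow_W_per_g\n")
        for T, y in zip(tg.temperature, tg.heat_flow):
            fh.write(f"{float(T)!r},{float(y)!r}\n")


def read_loss_spectrum(path: str | Path) -> LossSpectrum:
    """Read one dielectric loss spectrum; frequencies are sorted on load."""
    meta, table = _read_meta_table(path)
    for col in ("frequency_Hz", "eps_loss"):
        if col not in table.columns:
            raise FormatError(f"{path}: missing column {col}")
    if "T_K" not in meta:
        raise FormatError(f"{path}: missing metadata T_K")
    df = table[["frequency_Hz", "eps_loss"]].astype(float)
    df = df.sort_values("frequency_Hz")
    return LossSpectrum(
        temperature=float(meta["T_K"]),
        frequency=df["frequency_Hz"].to_numpy(),
        eps_loss=df["eps_loss"].to_numpy(),
    )


def write_loss_spectrum(spec: LossSpectrum, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# T_K={spec.temperature!r}\n")
        fh.write("frequency_Hz,eps_loss\n")
        for f, e in zip(spec.frequency, spec.eps_loss):
            fh.write(f"{float(f)!r},{float(e)!r}\n")


__all__ = [
    "FormatError",
    "ValidationError",
    "Thermogram",
    "LossSpectrum",
    "RunConfig",
    "read_thermogram",
    "write_thermogram",
    "read_loss_spectrum",
    "write_loss_spectrum",
    "replace",
]
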