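"""Synthetic driving inputs: weather, stem water potential, phloem sugar.

The model needs four hourly inputs over the season: air temperature, relative
humidity, stem xylem water potential and stem phloem sucrose concentration.
This module synthesizes them from a compact configuration:

* seasonal envelopes of daily extrema (T_max, T_min, H_max, H_min) and of the
  daily transpiration total are second-order Fourier series in calendar day;
* within a day, temperature follows a sine-exponential curve (sinusoidal rise
  from the minimum at sunrise, exponential decay after sunset) with the day
  length computed from latitude and date; humidity is antiphase to
  temperature between its own extrema;
* transpiration is a smooth daytime pulse whose 24 h integral equals the
  envelope's daily total, and stem water potential follows
  Ψ_x = P_soil − Tr / L_soil_stem;
* phloem concentration tracks the diurnal temperature pattern between fixed
  extrema (defaults 9% and 17%), optionally lowered by a crop-load offset.

The default Fourier coefficients are illustrative: they are hand-set to give
a Southern-Hemisphere season of realistic magnitude (late-autumn harvest
about 7 °C cooler than mid-summer, transpiration several-fold lower), not a
fit to any weather record.  Alternatively, hourly samples can be read from a
CSV table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, model_validator

_OMEGA = 2.0 * math.pi / 365.0


class EnvironmentConfigError(ValueError):
    pass


class EnvironmentConfig(BaseModel):
    """Configuration of the synthetic environment generator."""

    model_config = ConfigDict(extra="forbid")

    latitude: float = -37.8            # degrees; negative = Southern Hemisphere
    bloom_doy: int = 325               # calendar day of full bloom (21 Nov)

    # Fourier envelopes [a0, a1, b1, a2, b2] on calendar day, order 2
    tmax_fourier: Sequence[float] = (18.0, 4.6407, 1.2263, 0.4348, 0.2470)   # °C
    tmin_fourier: Sequence[float] = (9.5, 3.6739, 0.9708, 0.2609, 0.1482)    # °C
    hmax_fourier: Sequence[float] = (0.95, -0.0195, -0.0046, 0.0, 0.0)       # fraction
    hmin_fourier: Sequence[float] = (0.55, -0.0584, -0.0139, 0.0, 0.0)       # fraction
    tr_total_fourier: Sequence[float] = (100.0, 82.19, 21.71, 4.348, 2.470)  # L/day

    # diurnal sine-exponential shape constants
    lag_a: float = 1.8                 # h, lag of T_max after solar noon
    night_b: float = 2.2               # dimensionless night decay constant

    P_soil: float = -1.0               # bar, well-watered soil
    L_soil_stem: float = 0.001         # L s^-1 bar^-1, soil-to-stem conductance

    C_min: float = 0.09                # g/g, daily phloem concentration minimum
    C_max: float = 0.17                # g/g, daily phloem concentration maximum

    # input-pattern perturbations: additive shifts of the daily extrema
    t_min_offset: float = 0.0
    t_max_offset: float = 0.0
    h_min_offset: float = 0.0
    h_max_offset: float = 0.0
    psi_min_offset: float = 0.0
    psi_max_offset: float = 0.0
    cp_min_offset: float = 0.0
    cp_max_offset: float = 0.0

    @model_validator(mode="after")
    def _check(self):
        if not self.C_min < self.C_max:
            raise ValueError("require C_min < C_max")
        if self.L_soil_stem <= 0:
            raise ValueError("L_soil_stem must be > 0")
        for name in ("tmax_fourier", "tmin_fourier", "hmax_fourier",
                     "hmin_fourier", "tr_total_fourier"):
            if len(getattr(self, name)) != 5:
                raise ValueError(f"{name} needs 5 coefficients [a0,a1,b1,a2,b2]")
        return self


@dataclass
class EnvironmentSample:
    """The driving inputs at one instant."""

    t: float       # DAFB, decimal
    T: float       # air temperature (°C)
    H_a: float     # relative humidity (fraction)
    Tr: float      # vine transpiration (L s^-1)
    psi_x: float   # stem xylem water potential (bar)
    C_p: float     # stem phloem sugar concentration (g/g)


def _fourier(coef: Sequence[float], doy: float) -> float:
    a0, a1, b1, a2, b2 = coef
    x = _OMEGA * doy
    return (a0 + a1 * math.cos(x) + b1 * math.sin(x)
            + a2 * math.cos(2 * x) + b2 * math.sin(2 * x))


def day_length(latitude: float, doy: float) -> float:
    """Astronomical day length (h) from latitude (deg) and calendar day."""
    decl = math.radians(-23.45 * math.cos(_OMEGA * (doy + 10.0)))
    lat = math.radians(latitude)
    x = -math.tan(lat) * math.tan(decl)
    x = min(1.0, max(-1.0, x))
    return 24.0 * math.acos(x) / math.pi


class SyntheticEnvironment:
    """Deterministic hourly environment built from an :class:`EnvironmentConfig`.

    ``crop_offset`` lowers the phloem sucrose concentration uniformly
    (0.01 g/g emulates a high crop load).
    """

    def __init__(self, config: EnvironmentConfig | None = None, crop_offset: float = 0.0):
        self.config = config or EnvironmentConfig()
        self.crop_offset = crop_offset

    # -- daily scaffolding -------------------------------------------------

    def doy(self, day: float) -> int:
        return int(math.floor(self.config.bloom_doy + day)) % 365

    def envelopes(self, day: float) -> dict[str, float]:
        """Daily extrema and solar geometry for the day containing ``day``."""
        cfg = self.config
        d = self.doy(day)
        DL = day_length(cfg.latitude, d)
        tmax = _fourier(cfg.tmax_fourier, d) + cfg.t_max_offset
        tmin = _fourier(cfg.tmin_fourier, d) + cfg.t_min_offset
        hmax = min(_fourier(cfg.hmax_fourier, d) + cfg.h_max_offset, 1.0)
        hmin = max(_fourier(cfg.hmin_fourier, d) + cfg.h_min_offset, 0.0)
        tr_total = max(_fourier(cfg.tr_total_fourier, d), 0.0)
        return {
            "doy": d, "day_length": DL,
            "sunrise": 12.0 - DL / 2.0, "sunset": 12.0 + DL / 2.0,
            "t_max": tmax, "t_min": min(tmin, tmax - 0.1),
            "h_max": max(hmax, hmin + 1e-6), "h_min": hmin,
            "tr_total": tr_total,
        }

    # -- diurnal curves ----------------------------------------------------

    def _temperature_shape(self, env: dict[str, float], hour: float) -> float:
        """Normalized diurnal temperature position in [0, 1] (0 at T_min)."""
        cfg = self.config
        sr, ss, DL = env["sunrise"], env["sunset"], env["day_length"]
        if sr <= hour <= ss:
            return math.sin(math.pi * (hour - sr) / (DL + 2.0 * cfg.lag_a))
        # night: exponential decay from the sunset value to 0 at sunrise
        n = hour - ss if hour > ss else hour + 24.0 - ss
        N = 24.0 - DL
        shape_ss = math.sin(math.pi * DL / (DL + 2.0 * cfg.lag_a))
        eb = math.exp(-cfg.night_b)
        return shape_ss * (math.exp(-cfg.night_b * n / N) - eb) / (1.0 - eb)

    def diurnal_temperature(self, day: float, hour: float) -> float:
        env = self.envelopes(day)
        shape = self._temperature_shape(env, hour)
        return env["t_min"] + (env["t_max"] - env["t_min"]) * shape

    def diurnal_humidity(self, day: float, hour: float) -> float:
        """Relative humidity, antiphase to temperature between its extrema."""
        env = self.envelopes(day)
        shape = self._temperature_shape(env, hour)
        h = env["h_max"] - (env["h_max"] - env["h_min"]) * shape
        return min(max(h, 0.0), 1.0)

    def transpiration(self, day: float, hour: float) -> float:
        """Vine transpiration (L s⁻¹): daytime sin² pulse, zero at night."""
        env = self.envelopes(day)
        sr, ss, DL = env["sunrise"], env["sunset"], env["day_length"]
        if not sr <= hour <= ss or DL <= 0:
            return 0.0
        shape = math.sin(math.pi * (hour - sr) / DL) ** 2
        # integral of sin^2 over the day is DL/2 hours = DL*1800 seconds
        return env["tr_total"] * shape / (DL * 1800.0)

    def stem_water_potential(self, day: float, hour: float) -> float:
        """Ψ_x = P_soil − Tr/L_soil_stem, with optional extrema offsets."""
        cfg = self.config
        env = self.envelopes(day)
        psi_max = cfg.P_soil + cfg.psi_max_offset
        tr_peak = env["tr_total"] / (env["day_length"] * 1800.0)
        psi_min = cfg.P_soil - tr_peak / cfg.L_soil_stem + cfg.psi_min_offset
        sr, ss, DL = env["sunrise"], env["sunset"], env["day_length"]
        if not sr <= hour <= ss or DL <= 0:
            return psi_max
        shape = math.sin(math.pi * (hour - sr) / DL) ** 2
        return psi_max + (psi_min - psi_max) * shape

    def phloem_concentration(self, day: float, hour: float) -> float:
        """Stem phloem sucrose (g/g) tracking the diurnal temperature pattern."""
        cfg = self.config
        env = self.envelopes(day)
        shape = self._temperature_shape(env, hour)
        c_min = cfg.C_min + cfg.cp_min_offset
        c_max = cfg.C_max + cfg.cp_max_offset
        c = c_min + (c_max - c_min) * shape - self.crop_offset
        return max(c, 0.0)

    # -- composition -------------------------------------------------------

    def sample(self, t: float) -> EnvironmentSample:
        """All driving inputs at decimal DAFB ``t``."""
        day = math.floor(t)
        hour = (t - day) * 24.0
        return EnvironmentSample(
            t=t,
            T=self.diurnal_temperature(day, hour),
            H_a=self.diurnal_humidity(day, hour),
            Tr=self.transpiration(day, hour),
            psi_x=self.stem_water_potential(day, hour),
            C_p=self.phloem_concentration(day, hour),
        )

    def to_frame(self, t_start: float, t_end: float, step_h: float = 1.0) -> pd.DataFrame:
        """Hourly (or finer) table of the generated series."""
        times = np.arange(t_start, t_end + 1e-9, step_h / 24.0)
        rows = [self.sample(float(t)) for t in times]
        return pd.DataFrame(
            {
                "t": [r.t for r in rows],
                "T": [r.T for r in rows],
                "H_a": [r.H_a for r in rows],
                "Tr": [r.Tr for r in rows],
                "psi_x": [r.psi_x for r in rows],
                "C_p": [r.C_p for r in rows],
            }
        )


REQUIRED_COLUMNS = ("t", "T", "H_a", "Tr", "psi_x", "C_p")


class TabulatedEnvironment:
    """Environment driven by a user-supplied hourly table (linear interpolation)."""

    def __init__(self, frame: pd.DataFrame):
        missing = [c for c in REQUIRED_COLUMNS if c not in frame.columns]
        if missing:
            raise EnvironmentConfigError(f"environment table missing columns {missing}")
        t = frame["t"].to_numpy(float)
        if len(t) < 2:
            raise EnvironmentConfigError("environment table needs at least two rows")
        dt = np.diff(t)
        if not (dt > 0).all():
            row = int(np.argmin(dt > 0)) + 2  # 1-based data row after the header
            raise EnvironmentConfigError(f"non-monotone time at data row {row}")
        bad = ~((frame["H_a"] >= 0) & (frame["H_a"] <= 1))
        if bad.any():
            row = int(np.argmax(bad.to_numpy())) + 2
            raise EnvironmentConfigError(f"humidity outside [0, 1] at data row {row}")
        if (frame["Tr"] < 0).any():
            raise EnvironmentConfigError("negative transpiration in environment table")
        self.frame = frame.reset_index(drop=True)
        self._t = t
        self._cols = {c: frame[c].to_numpy(float) for c in REQUIRED_COLUMNS[1:]}

    def sample(self, t: float) -> EnvironmentSample:
        vals = {c: float(np.interp(t, self._t, v)) for c, v in self._cols.items()}
        return EnvironmentSample(t=t, **{
            "T": vals["T"], "H_a": vals["H_a"], "Tr": vals["Tr"],
            "psi_x": vals["psi_x"], "C_p": vals["C_p"],
        })

    @classmethod
    def from_csv(cls, path: str | Path) -> "TabulatedEnvironment":
        return cls(pd.read_csv(path))


# -- module-level convenience wrappers ------------------------------------

def diurnal_temperature(day: float, hour: float, cfg: EnvironmentConfig) -> float:
    return SyntheticEnvironment(cfg).diurnal_temperature(day, hour)


def diurnal_humidity(day: float, hour: float, cfg: EnvironmentConfig) -> float:
    return SyntheticEnvironment(cfg).diurnal_humidity(day, hour)


def transpiration(day: float, hour: float, cfg: EnvironmentConfig) -> float:
    return SyntheticEnvironment(cfg).transpiration(day, hour)


def stem_water_potential(Tr: float, cfg: EnvironmentConfig) -> float:
    """Ψ_x from an instantaneous transpiration rate (Eq.-of-state form)."""
    return cfg.P_soil - Tr / cfg.L_soil_stem


def phloem_concentration(day: float, hour: float, crop_offset: float, cfg: EnvironmentConfig) -> float:
    return SyntheticEnvironment(cfg, crop_offset=crop_offset).phloem_concentration(day, hour)
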