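"""Fruit state, derived quantities, quality outputs and trajectories."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import pandas as pd

from . import starch
from .biophysics import osmotic_pressure
from .development import fruit_surface_area
from .params import ParameterSet


@dataclass
class FruitState:
    """ODE state of the berry at one instant.

    t is decimal days after full bloom (DAFB); w water (g), s total dry
    matter (g), u starch (g), P_f turgor (bar).  Turgor may transiently be
    negative early in the season.
    """

    t: float
    w: float
    s: float
    u: float
    P_f: float

    def validate(self) -> None:
        import math

        if not self.w > 0:
            raise ValueError(f"water mass must be positive (w={self.w})")
        if not self.s > 0:
            raise ValueError(f"dry mass must be positive (s={self.s})")
        if not 0 <= self.u <= self.s:
            raise ValueError(f"starch must lie in [0, s] (u={self.u}, s={self.s})")
        if not math.isfinite(self.P_f):
            raise ValueError("turgor must be finite")


@dataclass
class DerivedFruitQuantities:
    """Quantities computed from a state: composition, potentials, geometry."""

    o: float        # structural dry matter (g)
    s_s: float      # soluble solids (g)
    Z: float        # soluble fraction of dry matter
    C_f: float      # sugar mass fraction of the juice (g/g)
    pi_f: float     # fruit osmotic pressure (bar)
    psi_f: float    # fruit water potential P_f - pi_f (bar)
    V: float        # volume (cm^3)
    A_f: float      # surface area (cm^2)


@dataclass
class QualityOutputs:
    FW: float             # fresh weight w + s (g)
    DW: float             # dry weight s (g)
    DM_pct: float         # dry matter, % of fresh weight
    SS_pct: float         # soluble solids, % of juice mass
    ST_pct: float         # starch, % of dry weight
    diameter_rel: float   # FW^(1/3), relative diameter units


def derive_quantities(state: FruitState, params: ParameterSet, T: float) -> DerivedFruitQuantities:
    """Compute composition, osmotic/water potentials, volume and area at temperature T (°C)."""
    opt = params.options
    o = starch.other_dry_matter(
        state.s, state.w, state.u, params.starch,
        form=opt.structural_form, cap_base=opt.cap_base,
    )
    s_s = starch.soluble_solids_mass(state.s, o, state.u)
    Z = starch.soluble_fraction(s_s, state.s)
    C_f = s_s / (state.w + s_s)
    pi_f = osmotic_pressure(C_f, params.solutes.pi_fO, T, params.constants)
    FW = state.w + state.s
    return DerivedFruitQuantities(
        o=o,
        s_s=s_s,
        Z=Z,
        C_f=C_f,
        pi_f=pi_f,
        psi_f=state.P_f - pi_f,
        V=FW / params.constants.density,
        A_f=fruit_surface_area(FW, params.area),
    )


def quality_outputs(state: FruitState, derived: DerivedFruitQuantities) -> QualityOutputs:
    """Commercial quality attributes; SS% is on a juice-mass (water + solubles) base."""
    FW = state.w + state.s
    juice = state.w + derived.s_s
    return QualityOutputs(
        FW=FW,
        DW=state.s,
        DM_pct=100.0 * state.s / FW,
        SS_pct=100.0 * derived.s_s / juice if juice > 0 else 0.0,
        ST_pct=100.0 * state.u / state.s,
        diameter_rel=FW ** (1.0 / 3.0),
    )


@dataclass
class Trajectory:
    """Time-indexed record of a simulation: states, fluxes, diagnostics."""

    frame: pd.DataFrame
    metadata: dict[str, Any] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.frame)

    def at_day(self, day: float) -> pd.Series:
        """Row nearest to the requested day."""
        idx = (self.frame["t"] - day).abs().idxmin()
        return self.frame.loc[idx]

    def to_csv(self, path: str | Path) -> None:
        path = Path(path)
        self.frame.to_csv(path, index=False)
        path.with_suffix(path.suffix + ".meta.json").write_text(
            json.dumps(self.metadata, indent=2, default=str)
        )

    @classmethod
    def from_csv(cls, path: str | Path) -> "Trajectory":
        path = Path(path)
        frame = pd.read_csv(path)
        meta_path = path.with_suffix(path.suffix + ".meta.json")
        metadata = json.loads(meta_path.read_text()) if meta_path.exists() else {}
        return cls(frame=frame, metadata=metadata)
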