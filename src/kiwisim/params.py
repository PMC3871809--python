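"""Parameter registry: grouped model constants with units and validation.

Every constant of the berry model lives in a :class:`ParameterSet`, grouped by
sub-model.  The shipped default file (``data/default_params.yaml``) is the
single source of the base values; :func:`load_parameters` merges a user source
(mapping or YAML/JSON file) over those defaults and validates the result.
"""

from __future__ import annotations

import json
from importlib import resources
from pathlib import Path
from typing import Any, Literal, Mapping

import yaml
from pydantic import BaseModel, ConfigDict, model_validator


class ParameterError(ValueError):
    """Raised when a parameter source is malformed or out of range."""


class _Group(BaseModel):
    model_config = ConfigDict(extra="forbid")


class InitialValues(_Group):
    w0: float
    s0: float
    u0: float
    Pf0: float

    @model_validator(mode="after")
    def _check(self):
        if self.w0 <= 0 or self.s0 <= 0:
            raise ValueError("initial water and dry mass must be positive")
        if not 0 <= self.u0 <= self.s0:
            raise ValueError("initial starch must lie in [0, s0]")
        return self


class OtherSolutes(_Group):
    pi_pO: float
    pi_fO: float

    @model_validator(mode="after")
    def _check(self):
        if self.pi_pO < 0 or self.pi_fO < 0:
            raise ValueError("baseline osmotic pressures must be >= 0")
        return self


class CellExpansion(_Group):
    Y: float
    d1: float
    d2: float
    phi1: float
    phi2: float
    phi_k: float
    epsilon: float

    @model_validator(mode="after")
    def _check(self):
        if not self.d1 < self.d2:
            raise ValueError("require d1 < d2")
        if not self.phi1 > self.phi2 > 0:
            raise ValueError("require phi1 > phi2 > 0")
        if self.epsilon <= 0 or self.phi_k < 0 or self.Y < 0:
            raise ValueError("epsilon > 0, phi_k >= 0, Y >= 0 required")
        return self


class ActiveUptake(_Group):
    Km: float
    nu1: float
    Q10_nu: float

    @model_validator(mode="after")
    def _check(self):
        if self.Km <= 0 or self.nu1 < 0 or self.Q10_nu <= 0:
            raise ValueError("Km > 0, nu1 >= 0, Q10_nu > 0 required")
        return self


class Membrane(_Group):
    sigma_p: float
    sigma_x: float
    a_x: float
    a_p: float
    L_x: float
    L_p: float
    p_s: float

    @model_validator(mode="after")
    def _check(self):
        for name in ("sigma_p", "sigma_x"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"reflection coefficient {name}={v} outside [0, 1]")
        for name in ("a_x", "a_p", "L_x", "L_p", "p_s"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        return self


class SkinPermeance(_Group):
    rho0: float
    rho_inf: float
    k_rho: float
    t_rho: float

    @model_validator(mode="after")
    def _check(self):
        if not self.rho0 > self.rho_inf > 0:
            raise ValueError("require rho0 > rho_inf > 0")
        if self.k_rho < 0:
            raise ValueError("k_rho must be >= 0")
        return self


class PedicelConductance(_Group):
    L1x: float
    L2x: float
    k1x: float
    k2x: float
    t1: float
    t2: float
    Lp_inf: float
    k1p: float

    @model_validator(mode="after")
    def _check(self):
        for name in ("L1x", "L2x", "k1x", "k2x", "Lp_inf", "k1p"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        return self


class StarchParams(_Group):
    A_o: float
    k_o: float
    s_b: float
    k_s1: float
    t_r: float
    t_h: float
    k_u: float

    @model_validator(mode="after")
    def _check(self):
        for name in ("A_o", "k_o", "s_b", "k_s1", "t_r", "t_h", "k_u"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not self.t_h < self.t_r:
            raise ValueError("require t_h < t_r")
        return self


class Respiration(_Group):
    q_m: float
    q_g: float
    Q10_r: float

    @model_validator(mode="after")
    def _check(self):
        if self.q_m < 0 or self.q_g < 0 or self.Q10_r <= 0:
            raise ValueError("q_m, q_g >= 0 and Q10_r > 0 required")
        return self


class PhysicalConstants(_Group):
    R_g: float
    M_s: float
    M_w: float
    H_f: float
    rho_sol: float
    density: float

    @model_validator(mode="after")
    def _check(self):
        if not 0 < self.H_f <= 1:
            raise ValueError("H_f must lie in (0, 1]")
        for name in ("R_g", "M_s", "M_w", "rho_sol", "density"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        return self


class SurfaceArea(_Group):
    gamma: float
    eta: float

    @model_validator(mode="after")
    def _check(self):
        if self.gamma <= 0 or self.eta <= 0:
            raise ValueError("gamma, eta must be > 0")
        return self


class ModelOptions(_Group):
    structural_form: Literal["proportion", "saturating"] = "proportion"
    cap_base: Literal["fresh", "juice"] = "fresh"
    pedicel_sugar_conc: Literal["downstream", "mean"] = "mean"
    sensitivity_average: Literal["half_difference", "abs_mean"] = "half_difference"


class ParameterSet(_Group):
    """All model constants, grouped by sub-model."""

    initial: InitialValues
    solutes: OtherSolutes
    expansion: CellExpansion
    uptake: ActiveUptake
    membrane: Membrane
    skin: SkinPermeance
    pedicel: PedicelConductance
    starch: StarchParams
    respiration: Respiration
    constants: PhysicalConstants
    area: SurfaceArea
    options: ModelOptions

    def to_dict(self) -> dict[str, Any]:
        return self.model_dump()

    def with_overrides(self, overrides: Mapping[str, Any]) -> "ParameterSet":
        """New set with ``{"group.field": value}``-style overrides applied."""
        data = self.to_dict()
        for key, value in overrides.items():
            group, _, field = key.partition(".")
            if not field or group not in data or field not in data[group]:
                raise ParameterError(f"unknown parameter {key!r}")
            data[group][field] = value
        return load_parameters(data, use_defaults=False)

    def get(self, key: str) -> Any:
        group, _, field = key.partition(".")
        try:
            return getattr(getattr(self, group), field)
        except AttributeError as exc:
            raise ParameterError(f"unknown parameter {key!r}") from exc


#: Units registry, keyed "group.field".  Used for documentation and to
#: cross-check optional ``units:`` annotations in user parameter files.
UNITS: dict[str, str] = {
    "initial.w0": "g", "initial.s0": "g", "initial.u0": "g", "initial.Pf0": "bar",
    "solutes.pi_pO": "bar", "solutes.pi_fO": "bar",
    "expansion.Y": "bar", "expansion.d1": "DAFB", "expansion.d2": "DAFB",
    "expansion.phi1": "bar^-1 h^-1", "expansion.phi2": "bar^-1 h^-1",
    "expansion.phi_k": "d^-1", "expansion.epsilon": "bar",
    "uptake.Km": "g/g", "uptake.nu1": "h^-1", "uptake.Q10_nu": "1",
    "membrane.sigma_p": "1", "membrane.sigma_x": "1",
    "membrane.a_x": "1", "membrane.a_p": "1",
    "membrane.L_x": "g cm^-2 bar^-1 h^-1", "membrane.L_p": "g cm^-2 bar^-1 h^-1",
    "membrane.p_s": "cm h^-1",
    "skin.rho0": "cm h^-1", "skin.rho_inf": "cm h^-1",
    "skin.k_rho": "d^-1", "skin.t_rho": "DAFB",
    "pedicel.L1x": "g h^-1 bar^-1", "pedicel.L2x": "g h^-1 bar^-1",
    "pedicel.k1x": "d^-1", "pedicel.k2x": "d^-1",
    "pedicel.t1": "DAFB", "pedicel.t2": "DAFB",
    "pedicel.Lp_inf": "g h^-1 bar^-1", "pedicel.k1p": "d^-1",
    "starch.A_o": "1", "starch.k_o": "g^-1", "starch.s_b": "%",
    "starch.k_s1": "d^-1", "starch.t_r": "DAFB", "starch.t_h": "d",
    "starch.k_u": "d^-1",
    "respiration.q_m": "g g^-1 h^-1", "respiration.q_g": "g/g",
    "respiration.Q10_r": "1",
    "constants.R_g": "cm^3 bar mol^-1 K^-1", "constants.M_s": "g mol^-1",
    "constants.M_w": "g mol^-1", "constants.H_f": "1",
    "constants.rho_sol": "g cm^-3", "constants.density": "g cm^-3",
    "area.gamma": "cm^2 g^-eta", "area.eta": "1",
}


def default_parameter_dict() -> dict[str, Any]:
    """The shipped base-value parameter file as a nested dict."""
    text = resources.files("kiwisim.data").joinpath("default_params.yaml").read_text()
    return yaml.safe_load(text)


def _deep_merge(base: dict, override: Mapping) -> dict:
    out = dict(base)
    for key, value in override.items():
        if key in out and isinstance(out[key], dict) and isinstance(value, Mapping):
            out[key] = _deep_merge(out[key], value)
        else:
            out[key] = value
    return out


def _check_units(annotations: Mapping[str, str]) -> None:
    for key, unit in annotations.items():
        if key not in UNITS:
            raise ParameterError(f"units given for unknown parameter {key!r}")
        if unit != UNITS[key]:
            raise ParameterError(
                f"unit mismatch for {key!r}: file says {unit!r}, registry says {UNITS[key]!r}"
            )


def load_parameters(
    source: Mapping[str, Any] | str | Path | None = None,
    *,
    use_defaults: bool = True,
) -> ParameterSet:
    """Build a validated :class:`ParameterSet`.

    Parameters
    ----------
    source
        ``None`` (defaults only), a nested mapping, or a path to a YAML/JSON
        file.  Missing fields fall back to the shipped defaults; unknown keys
        are rejected.  An optional top-level ``units`` mapping
        (``{"group.field": "unit"}``) is cross-checked against the registry.
    use_defaults
        When false, ``source`` must provide every field (used for round-trips).
    """
    if isinstance(source, (str, Path)):
        path = Path(source)
        text = path.read_text()
        data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        if not isinstance(data, Mapping):
            raise ParameterError(f"parameter file {path} does not hold a mapping")
        source = data
    merged: dict[str, Any] = dict(source) if source else {}
    units = merged.pop("units", None)
    if units:
        _check_units(units)
    if use_defaults:
        merged = _deep_merge(default_parameter_dict(), merged)
    try:
        return ParameterSet.model_validate(merged)
    except Exception as exc:  # pydantic ValidationError -> domain error
        raise ParameterError(str(exc)) from exc
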