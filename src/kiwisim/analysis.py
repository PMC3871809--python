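"""Analysis procedures: one-at-a-time sensitivity and diurnal-growth comparison.

Sensitivity follows the crop-model convention: each parameter (or the daily
extrema of a driving input) is perturbed up and down around the base run and
the signed half-difference of the harvest-day quality outputs is reported.
The diurnal comparison converts continuously logged fruit diameters (LVDT
series) to fractional fresh weight via the cube law and aligns them with a
simulated trajectory at an anchor day.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .environment import EnvironmentConfig
from .params import ParameterSet, load_parameters
from .simulator import SimulationConfig, Trajectory, simulate

QUALITY_COLUMNS = ("FW", "DW", "DM_pct", "SS_pct", "ST_pct")

#: environment-input targets: name -> EnvironmentConfig extrema-offset field
ENV_TARGETS = {
    "env.cp_min": "cp_min_offset", "env.cp_max": "cp_max_offset",
    "env.t_min": "t_min_offset", "env.t_max": "t_max_offset",
    "env.psi_min": "psi_min_offset", "env.psi_max": "psi_max_offset",
    "env.h_min": "h_min_offset", "env.h_max": "h_max_offset",
}


class SensitivityError(ValueError):
    pass


@dataclass
class SensitivitySpec:
    """One perturbation: a parameter key ("group.field") or input ("env.*")."""

    target: str
    delta: float                  # absolute shift, or fraction when relative
    relative: bool = False
    evaluation_day: float = 170.0

    def __post_init__(self):
        if self.delta == 0:
            raise SensitivityError("delta must be nonzero")


@dataclass
class SensitivityResult:
    target: str
    base_value: float | None      # None for input patterns (offsets around 0)
    delta: float                  # the absolute perturbation applied
    changes: dict[str, float] = field(default_factory=dict)

    def as_row(self) -> dict[str, float]:
        row = {"target": self.target, "base_value": self.base_value, "delta": self.delta}
        row.update(self.changes)
        return row


def _outputs_at(traj: Trajectory, day: float) -> dict[str, float]:
    row = traj.at_day(day)
    return {c: float(row[c]) for c in QUALITY_COLUMNS}


def _run(cfg: SimulationConfig, params: ParameterSet, env_cfg: EnvironmentConfig) -> Trajectory:
    return simulate(cfg, params=params, env_config=env_cfg)


def sensitivity_run(
    spec: SensitivitySpec,
    cfg: SimulationConfig | None = None,
    params: ParameterSet | None = None,
    env_config: EnvironmentConfig | None = None,
) -> SensitivityResult:
    """Run base ± delta and summarize the change on the evaluation day.

    With the default ``half_difference`` convention the reported change for
    each output X is (X(+δ) − X(−δ))/2; the ``abs_mean`` alternative reports
    the mean of |ΔX| for the two runs, signed by the +δ direction.
    """
    cfg = cfg or SimulationConfig()
    params = params or load_parameters()
    env_config = env_config or EnvironmentConfig()
    if cfg.t_end < spec.evaluation_day:
        cfg = cfg.model_copy(update={"t_end": spec.evaluation_day})

    if spec.target in ENV_TARGETS:
        off_field = ENV_TARGETS[spec.target]
        if spec.relative:
            raise SensitivityError("input-pattern perturbations must be absolute")
        base_value = None
        delta = spec.delta

        def perturbed(sign: float) -> Trajectory:
            env = env_config.model_copy(update={off_field: sign * delta})
            return _run(cfg, params, env)

    else:
        base_value = float(params.get(spec.target))
        delta = spec.delta * base_value if spec.relative else spec.delta

        def perturbed(sign: float) -> Trajectory:
            p = params.with_overrides({spec.target: base_value + sign * delta})
            return _run(cfg, p, env_config)

    up = _outputs_at(perturbed(+1.0), spec.evaluation_day)
    down = _outputs_at(perturbed(-1.0), spec.evaluation_day)

    changes = {}
    if params.options.sensitivity_average == "half_difference":
        for c in QUALITY_COLUMNS:
            changes[c] = (up[c] - down[c]) / 2.0
    else:
        base = _outputs_at(_run(cfg, params, env_config), spec.evaluation_day)
        for c in QUALITY_COLUMNS:
            mag = (abs(up[c] - base[c]) + abs(down[c] - base[c])) / 2.0
            changes[c] = mag if up[c] >= down[c] else -mag
    return SensitivityResult(target=spec.target, base_value=base_value,
                             delta=delta, changes=changes)


def sensitivity_table(
    specs: Sequence[SensitivitySpec],
    cfg: SimulationConfig | None = None,
    params: ParameterSet | None = None,
    env_config: EnvironmentConfig | None = None,
) -> pd.DataFrame:
    """Batch of :func:`sensitivity_run` rows in a quality-output table."""
    rows = [
        sensitivity_run(s, cfg=cfg, params=params, env_config=env_config).as_row()
        for s in specs
    ]
    return pd.DataFrame(rows)


def default_input_specs() -> list[SensitivitySpec]:
    """The standard input-pattern perturbations (extrema of the four inputs)."""
    return [
        SensitivitySpec("env.cp_min", 0.02), SensitivitySpec("env.cp_max", 0.02),
        SensitivitySpec("env.t_min", 2.0), SensitivitySpec("env.t_max", 2.0),
        SensitivitySpec("env.psi_min", 2.0), SensitivitySpec("env.psi_max", 0.5),
        SensitivitySpec("env.h_min", 0.1), SensitivitySpec("env.h_max", 0.03),
    ]


def default_parameter_specs() -> list[SensitivitySpec]:
    """Standard ±20% (or noted exceptions) parameter perturbations."""
    pct20 = [
        "initial.w0", "initial.s0", "solutes.pi_pO", "solutes.pi_fO",
        "expansion.d1", "expansion.d2", "expansion.phi1", "expansion.phi2",
        "expansion.phi_k", "expansion.epsilon", "uptake.Km", "uptake.nu1",
        "membrane.a_x", "membrane.a_p", "skin.rho0", "skin.k_rho",
        "skin.rho_inf", "pedicel.t1", "pedicel.t2", "pedicel.L1x",
        "pedicel.L2x", "pedicel.k1x", "pedicel.k2x", "pedicel.Lp_inf",
        "pedicel.k1p", "initial.u0",
        "starch.A_o", "starch.k_o", "starch.s_b", "starch.k_s1", "starch.t_h",
        "starch.k_u",
    ]
    specs = [SensitivitySpec(t, 0.20, relative=True) for t in pct20]
    specs += [
        SensitivitySpec("initial.Pf0", 1.00, relative=True),
        SensitivitySpec("expansion.Y", 0.25, relative=True),
        SensitivitySpec("uptake.Q10_nu", 0.50, relative=True),
        SensitivitySpec("membrane.sigma_p", 0.05, relative=True),
        SensitivitySpec("membrane.p_s", 0.50, relative=True),
        SensitivitySpec("skin.t_rho", 0.22, relative=True),
        SensitivitySpec("starch.t_r", 0.06, relative=True),
    ]
    return specs


# ---------------------------------------------------------------------------
# Elasticity ablation


def elasticity_ablation(
    traj: Trajectory,
    params: ParameterSet | None = None,
    env_config: EnvironmentConfig | None = None,
    window: tuple[float, float] = (55.0, 60.0),
    start_day: float = 50.0,
    end_day: float = 62.0,
    calibrate: bool = True,
) -> dict[str, float]:
    """Compare diurnal fresh-weight oscillations with and without elasticity.

    Restarts a rigid-wall (pure Lockhart) run from the elastic trajectory's
    state at ``start_day``.  With ``calibrate`` a scalar on wall extensibility
    (the compensating refit) is secant-adjusted so both variants reach the
    same fresh weight at ``end_day``; the reversible diurnal swing is then
    compared on detrended per-day amplitudes over ``window``.
    """
    from .simulator import SimulationConfig, simulate_rigid
    from .state import FruitState

    params = params or load_parameters()
    env_config = env_config or EnvironmentConfig()
    row = traj.at_day(start_day)
    init = FruitState(t=float(row["t"]), w=float(row["w"]), s=float(row["s"]),
                      u=float(row["u"]), P_f=float(row["P_f"]))
    cfg = SimulationConfig(t_start=float(row["t"]), t_end=end_day)
    fw_target = float(traj.at_day(end_day)["FW"])
    fw_start = float(row["FW"])

    def run(scale: float) -> Trajectory:
        return simulate_rigid(cfg, params=params, env_config=env_config,
                              initial=init, phi_scale=scale)

    scale = 1.0
    rigid = run(scale)
    if calibrate:
        # secant iteration on the growth over the comparison span
        for _ in range(2):
            grown = float(rigid.at_day(end_day)["FW"]) - fw_start
            want = fw_target - fw_start
            if grown <= 0 or abs(grown - want) / max(want, 1e-9) < 0.01:
                break
            scale *= want / grown
            rigid = run(scale)

    t_el = traj.frame["t"].to_numpy(float)
    t_ri = rigid.frame["t"].to_numpy(float)
    amp_elastic = detrended_daily_amplitude(t_el, traj.frame["FW"].to_numpy(float), *window)
    amp_rigid = detrended_daily_amplitude(t_ri, rigid.frame["FW"].to_numpy(float), *window)
    return {
        "amplitude_elastic": amp_elastic,
        "amplitude_rigid": amp_rigid,
        "phi_scale": scale,
        "fw_elastic_end": fw_target,
        "fw_rigid_end": float(rigid.at_day(end_day)["FW"]),
    }


# ---------------------------------------------------------------------------
# LVDT diurnal-growth comparison


@dataclass
class DiameterSeries:
    """Continuously logged fruit diameters (mm) against decimal DAFB."""

    t: np.ndarray
    diameter: np.ndarray
    label: str = "lvdt"

    def __post_init__(self):
        self.t = np.asarray(self.t, float)
        self.diameter = np.asarray(self.diameter, float)
        if self.t.ndim != 1 or self.t.shape != self.diameter.shape:
            raise ValueError("time and diameter must be 1-D and equal length")
        if not (np.diff(self.t) > 0).all():
            raise ValueError("time stamps must be strictly increasing")
        if not (self.diameter > 0).all():
            raise ValueError("diameters must be positive")

    @classmethod
    def from_csv(cls, path, label: str = "lvdt") -> "DiameterSeries":
        frame = pd.read_csv(path)
        for col in ("t", "diameter_mm"):
            if col not in frame.columns:
                raise ValueError(f"LVDT CSV missing column {col!r}")
        return cls(frame["t"].to_numpy(), frame["diameter_mm"].to_numpy(), label=label)


def lvdt_fractional_weight(d: DiameterSeries) -> np.ndarray:
    """Fractional fresh weight (d/d₀)³ — fresh weight scales with diameter cubed."""
    return (d.diameter / d.diameter[0]) ** 3


def detrended_daily_amplitude(t: np.ndarray, x: np.ndarray,
                              day_start: float, day_end: float) -> float:
    """Mean per-day peak-to-trough of x after removing each day's linear trend.

    Separates the reversible diurnal swing from net growth within the day.
    """
    t = np.asarray(t, float)
    x = np.asarray(x, float)
    amps = []
    for d0 in np.arange(math.floor(day_start), day_end):
        m = (t >= d0) & (t < d0 + 1)
        if m.sum() < 4:
            continue
        tt, xx = t[m], x[m]
        coef = np.polyfit(tt, xx, 1)
        resid = xx - np.polyval(coef, tt)
        amps.append(resid.max() - resid.min())
    if not amps:
        raise ValueError("window contains no full day of samples")
    return float(np.mean(amps))


def compare_window(
    traj: Trajectory,
    d: DiameterSeries,
    anchor_day: float,
    window: tuple[float, float] = (55.0, 60.0),
) -> pd.DataFrame:
    """Align an LVDT-derived fresh-weight series with a simulated trajectory.

    The LVDT fractional weights are scaled so both series are equal at the
    anchor day; the returned table carries both series on the LVDT time grid
    plus per-day diurnal amplitude statistics in ``DataFrame.attrs``.
    """
    t_model = traj.frame["t"].to_numpy(float)
    fw_model = traj.frame["FW"].to_numpy(float)
    lo, hi = window
    for name, tt in (("model", t_model), ("lvdt", d.t)):
        if tt.min() > lo or tt.max() < hi or not (tt.min() <= anchor_day <= tt.max()):
            raise ValueError(f"{name} series does not cover the comparison window")

    frac = lvdt_fractional_weight(d)
    frac_anchor = float(np.interp(anchor_day, d.t, frac))
    fw_anchor = float(np.interp(anchor_day, t_model, fw_model))
    fw_lvdt = frac * (fw_anchor / frac_anchor)
    fw_model_on_lvdt = np.interp(d.t, t_model, fw_model)

    out = pd.DataFrame({"t": d.t, "FW_lvdt": fw_lvdt, "FW_model": fw_model_on_lvdt})
    amp_lvdt = detrended_daily_amplitude(d.t, fw_lvdt, lo, hi)
    amp_model = detrended_daily_amplitude(t_model, fw_model, lo, hi)
    out.attrs["amplitude_lvdt"] = amp_lvdt
    out.attrs["amplitude_model"] = amp_model
    out.attrs["amplitude_ratio"] = amp_model / amp_lvdt if amp_lvdt else float("nan")
    out.attrs["anchor_day"] = anchor_day
    return out
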