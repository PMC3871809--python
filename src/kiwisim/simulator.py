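"""Fixed-step RK4 season simulator with the per-stage pedicel solve.

The four-state ODE (water w, dry matter s, starch u, turgor P_f) is
integrated with the classical fourth-order Runge–Kutta scheme at a fixed
half-hour default step.  The pedicel conservation system is algebraic and is
re-solved at every RK4 stage (a semi-explicit DAE treatment): turgor can
change quickly within the hour, and a per-step solve would lag the fluxes.

Cumulative flux integrals are accumulated with the same RK4 stage weights as
the state update, so water and dry-matter book-keeping is exact to rounding.

A rigid-wall (pure Lockhart, no elastic term) variant is provided for the
elasticity-ablation comparison and as the ε→∞ reference: there turgor is not
a state but solves, at every instant, the algebraic balance between net
volumetric inflow and plastic expansion.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal

import pandas as pd
from pydantic import BaseModel, ConfigDict
from scipy.optimize import brentq

from . import __version__ as _pkg_version
from . import biophysics, development, starch
from .environment import EnvironmentConfig, EnvironmentSample, SyntheticEnvironment
from .params import ParameterSet, load_parameters
from .pedicel import PedicelSolution, solve_fruit_end, stem_state
from .state import FruitState, Trajectory, derive_quantities, quality_outputs


class SimulationError(RuntimeError):
    """Integration failure; carries the last valid state for diagnosis."""

    def __init__(self, message: str, last_state: FruitState | None = None):
        super().__init__(message)
        self.last_state = last_state


class SimulationConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    t_start: float = 0.0          # DAFB
    t_end: float = 170.0          # DAFB
    step: float = 0.5             # h
    cadence: float = 1.0          # h, output interval (multiple of step)
    scenario: Literal["low", "high", "custom"] = "low"
    crop_offset: float = 0.0      # g/g, used when scenario == "custom"
    seed: int = 0                 # reserved for stochastic weather options

    def offset(self) -> float:
        if self.scenario == "low":
            return 0.0
        if self.scenario == "high":
            return 0.01
        return self.crop_offset


@dataclass
class StageEval:
    """Everything evaluated at one (state, time) point."""

    dw: float
    ds: float
    du: float
    dPf: float
    fluxes: biophysics.FluxSet
    ped: PedicelSolution
    env: EnvironmentSample


#: fluxes accumulated with RK4 weights, in this order
FLUX_NAMES = ("U_x", "U_p", "U_a", "U_m", "U_d", "T_f", "R_f")


class KiwiBerryModel:
    """Derivative field of the berry ODE for a given parameter set and environment."""

    def __init__(self, params: ParameterSet, env, *,
                 phi_scale: float = 1.0, membrane_scale: float = 1.0):
        self.params = params
        self.env = env
        # scaling hooks for the elasticity-ablation refit
        self.phi_scale = phi_scale
        self.membrane_scale = membrane_scale
        # worst conservation residuals over every accepted pedicel solve
        self.max_residual_mass = 0.0
        self.max_residual_sugar = 0.0

    def evaluate(self, t: float, w: float, s: float, u: float, P_f: float) -> StageEval:
        p = self.params
        env = self.env.sample(t)
        st = FruitState(t=t, w=w, s=s, u=u, P_f=P_f)
        der = derive_quantities(st, p, env.T)
        A_f = der.A_f * self.membrane_scale

        stem = stem_state(env.psi_x, env.C_p, env.T, p)
        nu_m = development.max_active_uptake(s, env.T, p.uptake)
        sol = solve_fruit_end(
            stem, t=t, T=env.T,
            P_f=P_f, pi_f=der.pi_f, psi_f=der.psi_f, C_f=der.C_f,
            A_f=A_f, nu_m=nu_m,
            L_x_ped=development.pedicel_xylem_conductance(t, p.pedicel),
            L_p_ped=development.pedicel_phloem_conductance(t, p.pedicel),
            params=p,
        )
        self.max_residual_mass = max(self.max_residual_mass, abs(sol.residual_mass))
        self.max_residual_sugar = max(self.max_residual_sugar, abs(sol.residual_sugar))

        rho = development.skin_permeance(t, p.skin)
        T_f = biophysics.transpiration_flux(der.A_f, rho, env.T, env.H_a, p.constants)

        dw = sol.U_x + sol.U_p - T_f
        sugar_in = sol.U_a + sol.U_m + sol.U_d
        ds = biophysics.net_dry_matter_rate(sugar_in, s, env.T, p.respiration)
        R_f = sugar_in - ds
        du = starch.starch_rate(der.s_s, u, t, p.starch) / 24.0  # d^-1 -> h^-1

        phi = development.wall_extensibility(t, p.expansion) * self.phi_scale
        dV = (dw + ds) / p.constants.density
        dPf = biophysics.turgor_rate(P_f, der.V, dV, phi, p.expansion.Y, p.expansion.epsilon)

        fluxes = biophysics.FluxSet(
            U_x=sol.U_x, U_p=sol.U_p, U_a=sol.U_a, U_m=sol.U_m, U_d=sol.U_d,
            T_f=T_f, R_f=R_f,
        )
        return StageEval(dw=dw, ds=ds, du=du, dPf=dPf, fluxes=fluxes, ped=sol, env=env)


def rk4_step(model: KiwiBerryModel, state: FruitState, dt_h: float):
    """One classical RK4 step of size ``dt_h`` hours.

    Returns ``(new_state, weighted_fluxes)`` where the flux tuple carries the
    RK4-weighted averages of (U_x, U_p, U_a, U_m, U_d, T_f, R_f) over the
    step, i.e. the same quadrature that advanced the state.
    """
    t, w, s, u, P = state.t, state.w, state.s, state.u, state.P_f
    dt_d = dt_h / 24.0

    k1 = model.evaluate(t, w, s, u, P)
    k2 = model.evaluate(t + dt_d / 2, w + dt_h / 2 * k1.dw, s + dt_h / 2 * k1.ds,
                        u + dt_h / 2 * k1.du, P + dt_h / 2 * k1.dPf)
    k3 = model.evaluate(t + dt_d / 2, w + dt_h / 2 * k2.dw, s + dt_h / 2 * k2.ds,
                        u + dt_h / 2 * k2.du, P + dt_h / 2 * k2.dPf)
    k4 = model.evaluate(t + dt_d, w + dt_h * k3.dw, s + dt_h * k3.ds,
                        u + dt_h * k3.du, P + dt_h * k3.dPf)

    def comb(a, b, c, d):
        return (a + 2.0 * b + 2.0 * c + d) / 6.0

    new = FruitState(
        t=t + dt_d,
        w=w + dt_h * comb(k1.dw, k2.dw, k3.dw, k4.dw),
        s=s + dt_h * comb(k1.ds, k2.ds, k3.ds, k4.ds),
        u=u + dt_h * comb(k1.du, k2.du, k3.du, k4.du),
        P_f=P + dt_h * comb(k1.dPf, k2.dPf, k3.dPf, k4.dPf),
    )
    weighted = tuple(
        comb(getattr(k1.fluxes, n), getattr(k2.fluxes, n),
             getattr(k3.fluxes, n), getattr(k4.fluxes, n))
        for n in FLUX_NAMES
    )
    return new, weighted


def _record(model: KiwiBerryModel, state: FruitState, cum: dict[str, float]) -> dict[str, float]:
    ev = model.evaluate(state.t, state.w, state.s, state.u, state.P_f)
    p = model.params
    der = derive_quantities(state, p, ev.env.T)
    q = quality_outputs(state, der)
    row = {
        "t": state.t, "w": state.w, "s": state.s, "u": state.u, "P_f": state.P_f,
        "o": der.o, "s_s": der.s_s, "Z": der.Z, "C_f": der.C_f,
        "pi_f": der.pi_f, "psi_f": der.psi_f, "V": der.V, "A_f": der.A_f,
        "FW": q.FW, "DW": q.DW, "DM_pct": q.DM_pct, "SS_pct": q.SS_pct,
        "ST_pct": q.ST_pct, "diameter_rel": q.diameter_rel,
        "U_x": ev.fluxes.U_x, "U_p": ev.fluxes.U_p, "U_a": ev.fluxes.U_a,
        "U_m": ev.fluxes.U_m, "U_d": ev.fluxes.U_d, "T_f": ev.fluxes.T_f,
        "R_f": ev.fluxes.R_f,
        "F_p": ev.ped.F_p, "F_x": ev.ped.F_x, "S_ped": ev.ped.S_ped,
        "psi_fruit_end": ev.ped.psi_fruit_end,
        "C_p_fruit_end": ev.ped.C_p_fruit_end,
        "residual_mass": ev.ped.residual_mass,
        "residual_sugar": ev.ped.residual_sugar,
        "T": ev.env.T, "H_a": ev.env.H_a, "Tr": ev.env.Tr,
        "psi_x": ev.env.psi_x, "C_p": ev.env.C_p,
    }
    row.update({f"cum_{n}": cum[n] for n in FLUX_NAMES})
    row["max_residual_mass"] = model.max_residual_mass
    row["max_residual_sugar"] = model.max_residual_sugar
    return row


def simulate(
    cfg: SimulationConfig | None = None,
    params: ParameterSet | None = None,
    env=None,
    env_config: EnvironmentConfig | None = None,
    initial: FruitState | None = None,
) -> Trajectory:
    """Run a full simulation and return a :class:`Trajectory`.

    ``env`` may be any object with a ``sample(t)`` method; by default a
    :class:`SyntheticEnvironment` is built from ``env_config`` with the
    scenario's crop-load offset.
    """
    cfg = cfg or SimulationConfig()
    params = params or load_parameters()
    if env is None:
        env = SyntheticEnvironment(env_config or EnvironmentConfig(),
                                   crop_offset=cfg.offset())
    model = KiwiBerryModel(params, env)

    if cfg.step <= 0 or cfg.t_start >= cfg.t_end:
        raise ValueError("require step > 0 and t_start < t_end")
    n_sub = max(int(round(cfg.cadence / cfg.step)), 1)

    ini = params.initial
    state = initial or FruitState(t=cfg.t_start, w=ini.w0, s=ini.s0, u=ini.u0, P_f=ini.Pf0)
    state.validate()

    cum = {n: 0.0 for n in FLUX_NAMES}
    rows = [_record(model, state, cum)]

    n_steps = int(round((cfg.t_end - cfg.t_start) * 24.0 / cfg.step))
    for i in range(n_steps):
        try:
            state_new, weighted = rk4_step(model, state, cfg.step)
        except Exception as exc:
            raise SimulationError(f"step failed at t={state.t:.4f}: {exc}", state) from exc
        for n, f in zip(FLUX_NAMES, weighted):
            cum[n] += f * cfg.step
        if not all(map(math.isfinite, (state_new.w, state_new.s, state_new.u, state_new.P_f))):
            raise SimulationError(f"non-finite state at t={state_new.t:.4f}", state)
        if state_new.w < 1e-6 or state_new.s < 1e-6:
            raise SimulationError(f"state floored at t={state_new.t:.4f}", state)
        state = state_new
        if (i + 1) % n_sub == 0 or i == n_steps - 1:
            rows.append(_record(model, state, cum))

    frame = pd.DataFrame(rows)
    meta = {
        "package": "kiwisim", "version": _pkg_version,
        "config": cfg.model_dump(),
        "parameters": params.to_dict(),
        "environment": getattr(env, "config", None).model_dump()
        if getattr(env, "config", None) is not None else "external",
        "crop_offset": getattr(env, "crop_offset", cfg.offset()),
    }
    return Trajectory(frame=frame, metadata=meta)


def run_scenarios(
    cfg: SimulationConfig | None = None,
    scenarios: dict[str, float] | None = None,
    params: ParameterSet | None = None,
    env_config: EnvironmentConfig | None = None,
) -> dict[str, Trajectory]:
    """Batch runs differing only in the phloem crop-load offset."""
    cfg = cfg or SimulationConfig()
    scenarios = scenarios if scenarios is not None else {"low": 0.0, "high": 0.01}
    out = {}
    for name, offset in scenarios.items():
        c = cfg.model_copy(update={"scenario": "custom", "crop_offset": offset})
        out[name] = simulate(c, params=params, env_config=env_config)
    return out


# ---------------------------------------------------------------------------
# Rigid-wall (pure Lockhart) variant


def _rigid_turgor(model: KiwiBerryModel, t: float, w: float, s: float, u: float) -> float:
    """Turgor solving net volumetric inflow = plastic expansion at (t, state)."""
    p = model.params

    def g(P: float) -> float:
        ev = model.evaluate(t, w, s, u, P)
        V = (w + s) / p.constants.density
        phi = development.wall_extensibility(t, p.expansion) * model.phi_scale
        return (ev.dw + ev.ds) / p.constants.density / V - phi * max(P - p.expansion.Y, 0.0)

    lo, hi = -20.0, 60.0
    glo, ghi = g(lo), g(hi)
    tries = 0
    while glo * ghi > 0 and tries < 6:
        lo -= 40.0
        hi += 40.0
        glo, ghi = g(lo), g(hi)
        tries += 1
    if glo * ghi > 0:
        raise SimulationError(f"rigid turgor balance not bracketed at t={t:.3f}")
    return brentq(g, lo, hi, xtol=1e-10)


def simulate_rigid(
    cfg: SimulationConfig | None = None,
    params: ParameterSet | None = None,
    env=None,
    env_config: EnvironmentConfig | None = None,
    initial: FruitState | None = None,
    *,
    phi_scale: float = 1.0,
    membrane_scale: float = 1.0,
) -> Trajectory:
    """Pure-Lockhart season: no elastic term, turgor is algebraic.

    ``phi_scale`` and ``membrane_scale`` scale wall extensibility and the
    membrane exchange area; they implement the compensating refit used when
    comparing the rigid model against the elastic one.
    """
    cfg = cfg or SimulationConfig()
    params = params or load_parameters()
    if env is None:
        env = SyntheticEnvironment(env_config or EnvironmentConfig(),
                                   crop_offset=cfg.offset())
    model = KiwiBerryModel(params, env, phi_scale=phi_scale, membrane_scale=membrane_scale)

    ini = params.initial
    if initial is None:
        state = FruitState(t=cfg.t_start, w=ini.w0, s=ini.s0, u=ini.u0, P_f=ini.Pf0)
    else:
        state = FruitState(**vars(initial))
    state.P_f = _rigid_turgor(model, state.t, state.w, state.s, state.u)

    dt = cfg.step
    dt_d = dt / 24.0
    n_sub = max(int(round(cfg.cadence / cfg.step)), 1)
    rows = []

    def record(st: FruitState):
        ev = model.evaluate(st.t, st.w, st.s, st.u, st.P_f)
        der = derive_quantities(st, params, ev.env.T)
        q = quality_outputs(st, der)
        rows.append({
            "t": st.t, "w": st.w, "s": st.s, "u": st.u, "P_f": st.P_f,
            "FW": q.FW, "DW": q.DW, "DM_pct": q.DM_pct, "SS_pct": q.SS_pct,
            "ST_pct": q.ST_pct,
        })

    record(state)
    n_steps = int(round((cfg.t_end - cfg.t_start) * 24.0 / dt))
    for i in range(n_steps):
        t, w, s, u = state.t, state.w, state.s, state.u

        def f(tt, ww, ss, uu):
            P = _rigid_turgor(model, tt, ww, ss, uu)
            ev = model.evaluate(tt, ww, ss, uu, P)
            return ev.dw, ev.ds, ev.du, P

        d1 = f(t, w, s, u)
        d2 = f(t + dt_d / 2, w + dt / 2 * d1[0], s + dt / 2 * d1[1], u + dt / 2 * d1[2])
        d3 = f(t + dt_d / 2, w + dt / 2 * d2[0], s + dt / 2 * d2[1], u + dt / 2 * d2[2])
        d4 = f(t + dt_d, w + dt * d3[0], s + dt * d3[1], u + dt * d3[2])
        comb = lambda j: (d1[j] + 2 * d2[j] + 2 * d3[j] + d4[j]) / 6.0
        state = FruitState(t=t + dt_d, w=w + dt * comb(0), s=s + dt * comb(1),
                           u=u + dt * comb(2), P_f=0.0)
        state.P_f = _rigid_turgor(model, state.t, state.w, state.s, state.u)
        if (i + 1) % n_sub == 0 or i == n_steps - 1:
            record(state)

    meta = {"package": "kiwisim", "version": _pkg_version, "variant": "rigid-lockhart",
            "config": cfg.model_dump(), "phi_scale": phi_scale,
            "membrane_scale": membrane_scale}
    return Trajectory(frame=pd.DataFrame(rows), metadata=meta)
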