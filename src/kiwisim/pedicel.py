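"""Pedicel/receptacle algebraic solver.

The pedicel is a resistive conduit with no storage: at every instant the
water carried by its xylem and phloem must equal the fruit's membrane water
uptake, and the sucrose carried by the phloem must equal the fruit's sugar
uptake.  Given the stem-end vasculature state and the fruit state, the two
conservation laws determine the fruit-end xylem water potential Ψ' and the
fruit-end phloem sugar concentration C_p'.

Closure: the fruit-end phloem is taken to be in local water-potential
equilibrium with the fruit-end xylem, P_p' − π_p'(C_p') = Ψ', mirroring the
stem-end construction P_p = Ψ_x + π_p.  With that closure the mass balance
is linear in Ψ' for a given C_p', leaving one scalar root-finding problem in
C_p' for the sugar balance, solved by bracketed Brent iteration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy.optimize import brentq

from .biophysics import osmotic_pressure
from .params import ParameterSet


class PedicelSolverError(RuntimeError):
    """Raised when the fruit-end system cannot be bracketed or solved."""


@dataclass
class StemState:
    """Vasculature at the stem end of the pedicel."""

    psi_x: float   # stem xylem water potential (bar)
    C_p: float     # stem phloem sugar concentration (g/g)
    P_p: float     # stem phloem turgor (bar); local equilibrium psi_x + pi_p
    pi_p: float    # stem phloem osmotic pressure (bar)


def stem_state(psi_x: float, C_p: float, T: float, params: ParameterSet) -> StemState:
    """Build the stem-end state from potential, concentration and temperature."""
    pi_p = osmotic_pressure(C_p, params.solutes.pi_pO, T, params.constants)
    return StemState(psi_x=psi_x, C_p=C_p, P_p=psi_x + pi_p, pi_p=pi_p)


@dataclass
class PedicelSolution:
    """Accepted fruit-end state with fluxes and conservation residuals."""

    psi_fruit_end: float       # shared fruit-end xylem/apoplast potential (bar)
    C_p_fruit_end: float       # fruit-end phloem concentration (g/g)
    P_p_fruit_end: float       # fruit-end phloem turgor (bar)
    pi_p_fruit_end: float      # fruit-end phloem osmotic pressure (bar)
    F_p: float                 # pedicel phloem mass flow (g/h)
    F_x: float                 # pedicel xylem mass flow (g/h)
    S_ped: float               # pedicel sucrose flux (g/h)
    U_x: float                 # fruit water uptake, xylem membrane (g/h)
    U_p: float                 # fruit water uptake, phloem membrane (g/h)
    U_a: float                 # active sugar uptake (g/h)
    U_m: float                 # advective sugar uptake (g/h)
    U_d: float                 # diffusive sugar uptake (g/h)
    residual_mass: float       # F_p + F_x − U_x − U_p (g/h)
    residual_sugar: float      # S_ped − U_a − U_m − U_d (g/h)
    iterations: int = 0
    #: True when C_p' fell outside [0, C_p] (possible when the pedicel
    #: phloem is nearly non-conducting early in the season); flagged, not fatal
    out_of_range: bool = False


def pedicel_phloem_flow(P_p: float, P_p_fruit_end: float, L_p_ped: float) -> float:
    """Pressure-driven mass flow through the pedicel phloem (g h⁻¹)."""
    return L_p_ped * (P_p - P_p_fruit_end)


def pedicel_xylem_flow(psi_x: float, psi_fruit_end: float, L_x_ped: float) -> float:
    """Tension-driven flow through the pedicel xylem (g h⁻¹)."""
    return L_x_ped * (psi_x - psi_fruit_end)


def pedicel_sugar_flux(F_p: float, C_p_fruit_end: float) -> float:
    """Advective sucrose flux through the pedicel phloem (g h⁻¹)."""
    return F_p * C_p_fruit_end


def solve_fruit_end(
    stem: StemState,
    *,
    t: float | None = None,
    T: float = 20.0,
    P_f: float,
    pi_f: float,
    psi_f: float,
    C_f: float,
    A_f: float,
    nu_m: float,
    L_x_ped: float,
    L_p_ped: float,
    params: ParameterSet,
    xtol: float = 1e-14,
    maxiter: int = 200,
) -> PedicelSolution:
    """Solve the two pedicel conservation equations for (Ψ', C_p').

    ``t`` is accepted for logging only; conductances must already be
    evaluated at the current time.  Raises :class:`PedicelSolverError` when
    the sugar balance cannot be bracketed on the admissible concentration
    interval.
    """
    m = params.membrane
    con = params.constants
    pi_pO = params.solutes.pi_pO
    sugar_mean = params.options.pedicel_sugar_conc == "mean"

    kx = m.a_x * A_f * m.L_x          # xylem membrane conductance (g/h/bar)
    kp = m.a_p * A_f * m.L_p          # phloem membrane conductance
    # van 't Hoff slope at the ambient temperature: fruit-end osmotic
    # pressure is pi_p' = vh * C_p' + pi_pO, matching the stem construction
    vh = con.R_g * (T + 273.15) * con.rho_sol / con.M_s
    sigma = m.sigma_p
    Km = params.uptake.Km

    denom = L_p_ped + L_x_ped + kx + kp

    if denom == 0.0 or (kx == 0.0 and kp == 0.0 and L_p_ped == 0.0):
        # Severed or inert system: no flows; fruit-end mirrors the stem.
        return PedicelSolution(
            psi_fruit_end=stem.psi_x, C_p_fruit_end=stem.C_p,
            P_p_fruit_end=stem.psi_x + stem.pi_p, pi_p_fruit_end=stem.pi_p,
            F_p=0.0, F_x=0.0, S_ped=0.0,
            U_x=0.0, U_p=0.0, U_a=0.0, U_m=0.0, U_d=0.0,
            residual_mass=0.0, residual_sugar=0.0, iterations=0,
        )

    def system(C: float):
        """Fluxes at candidate fruit-end concentration C, with Ψ' eliminated."""
        pi_pp = vh * C + pi_pO
        # mass balance, linear in psi':
        rhs = (
            L_p_ped * (stem.P_p - pi_pp)
            + L_x_ped * stem.psi_x
            + kx * psi_f
            - kp * ((1.0 - sigma) * pi_pp - P_f + sigma * pi_f)
        )
        psi = rhs / denom
        P_pp = psi + pi_pp
        F_p = L_p_ped * (stem.P_p - P_pp)
        F_x = L_x_ped * (stem.psi_x - psi)
        U_x = kx * (psi - psi_f)
        U_p = kp * (P_pp - P_f - sigma * (pi_pp - pi_f))
        U_a = nu_m * C / (Km + C)
        return psi, pi_pp, P_pp, F_p, F_x, U_x, U_p, U_a

    n_eval = 0

    def residual(C: float) -> float:
        nonlocal n_eval
        n_eval += 1
        psi, pi_pp, P_pp, F_p, F_x, U_x, U_p, U_a = system(C)
        U_m = (1.0 - sigma) * 0.5 * (C + C_f) * U_p
        U_d = m.p_s * m.a_p * A_f * (C - C_f)
        conc = 0.5 * (stem.C_p + C) if sugar_mean else C
        return F_p * conc - (U_a + U_m + U_d)

    if A_f == 0.0:
        # No uptake surface: zero fruit fluxes; C_p' = C_p by convention and
        # Ψ' balances the (idle) pedicel flows.
        C = stem.C_p
        psi, pi_pp, P_pp, F_p, F_x, U_x, U_p, U_a = system(C)
        return PedicelSolution(
            psi_fruit_end=psi, C_p_fruit_end=C, P_p_fruit_end=P_pp,
            pi_p_fruit_end=pi_pp,
            F_p=F_p, F_x=F_x, S_ped=pedicel_sugar_flux(F_p, C),
            U_x=0.0, U_p=0.0, U_a=0.0, U_m=0.0, U_d=0.0,
            residual_mass=F_p + F_x, residual_sugar=F_p * C, iterations=0,
        )

    lo, hi = 0.0, max(1.5 * max(stem.C_p, C_f), 1e-3)
    f_lo = residual(lo)
    f_hi = residual(hi)
    if f_lo < 0.0:
        # No non-negative root: the balance closes at a (small) negative
        # concentration.  The residual has a pole at C = -Km where active
        # uptake diverges, so a sign change exists in (-Km, 0).
        hi, f_hi = lo, f_lo
        for frac in (0.125, 0.25, 0.5, 0.75, 0.95, 0.999):
            lo = -Km * frac
            f_lo = residual(lo)
            if f_lo * f_hi <= 0:
                break
    else:
        tries = 0
        while f_lo * f_hi > 0 and hi < 0.95 and tries < 8:
            hi = min(hi * 2.0, 0.95)
            f_hi = residual(hi)
            tries += 1
    if f_lo * f_hi > 0:
        raise PedicelSolverError(
            f"sugar balance not bracketed on [{lo:.3g}, {hi:.3g}] at t={t}: "
            f"g({lo:.3g})={f_lo:.3e}, g({hi:.3g})={f_hi:.3e}"
        )
    if f_lo == 0.0:
        C = lo
    elif f_hi == 0.0:
        C = hi
    else:
        C = brentq(residual, lo, hi, xtol=xtol, maxiter=maxiter)

    psi, pi_pp, P_pp, F_p, F_x, U_x, U_p, U_a = system(C)
    U_m = (1.0 - sigma) * 0.5 * (C + C_f) * U_p
    U_d = m.p_s * m.a_p * A_f * (C - C_f)
    conc = 0.5 * (stem.C_p + C) if sugar_mean else C
    S_ped = F_p * conc
    sol = PedicelSolution(
        psi_fruit_end=psi, C_p_fruit_end=C, P_p_fruit_end=P_pp,
        pi_p_fruit_end=pi_pp,
        F_p=F_p, F_x=F_x, S_ped=S_ped,
        U_x=U_x, U_p=U_p, U_a=U_a, U_m=U_m, U_d=U_d,
        residual_mass=F_p + F_x - U_x - U_p,
        residual_sugar=S_ped - (U_a + U_m + U_d),
        iterations=n_eval,
        out_of_range=not 0.0 <= C <= stem.C_p,
    )
    if not math.isfinite(sol.residual_sugar):
        raise PedicelSolverError(f"non-finite pedicel solution at t={t}")
    return sol
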