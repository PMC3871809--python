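"""Prescribed developmental trajectories of model coefficients.

Cell-wall extensibility, maximal active uptake, pedicel axial conductances,
skin permeance and the surface-area allometry all change with fruit age or
size according to fixed functional forms; this module holds those forms as
pure functions of time (DAFB), dry mass, or fresh weight.
"""

from __future__ import annotations

import math

from .params import (
    ActiveUptake,
    CellExpansion,
    PedicelConductance,
    SkinPermeance,
    SurfaceArea,
)


def _logistic(x: float) -> float:
    # overflow-safe logistic
    if x >= 0:
        return 1.0 / (1.0 + math.exp(-x))
    e = math.exp(x)
    return e / (1.0 + e)


def wall_extensibility(t: float, p: CellExpansion) -> float:
    """Cell-wall extensibility φ(t) in bar⁻¹ h⁻¹.

    ln φ is piecewise linear: plateau φ1 through the cell-division phase
    (t ≤ d1), log-linear transition to φ2 at d2, then a slow log decline at
    rate φ_k.  Continuous everywhere.
    """
    if t <= p.d1:
        return p.phi1
    ln1, ln2 = math.log(p.phi1), math.log(p.phi2)
    if t <= p.d2:
        frac = (t - p.d1) / (p.d2 - p.d1)
        return math.exp(ln1 + frac * (ln2 - ln1))
    return math.exp(ln2 - p.phi_k * (t - p.d2))


def max_active_uptake(s: float, T: float, p: ActiveUptake) -> float:
    """Maximal active sugar uptake ν_m = ν1·s·Q10^((T−20)/10) in g h⁻¹."""
    return p.nu1 * s * p.Q10_nu ** ((T - 20.0) / 10.0)


def pedicel_xylem_conductance(t: float, p: PedicelConductance) -> float:
    """Pedicel xylem axial conductance in g h⁻¹ bar⁻¹.

    Double-logistic shape: rises from near L2x to a maximum around
    40–55 DAFB, then declines to the late-season plateau L2x.
    """
    rise = _logistic(p.k1x * (t - p.t1))
    fall = 1.0 - _logistic(p.k2x * (t - p.t2))
    return p.L2x + (p.L1x - p.L2x) * rise * fall


def pedicel_phloem_conductance(t: float, p: PedicelConductance) -> float:
    """Pedicel phloem axial conductance in g h⁻¹ bar⁻¹.

    Grows in proportion to the xylem conductance early on (same rise rate)
    but never breaks down: a single logistic saturating at Lp_inf.
    """
    return p.Lp_inf * _logistic(p.k1p * (t - p.t1))


def skin_permeance(t: float, p: SkinPermeance) -> float:
    """Skin permeance ρ(t) to water vapour in cm h⁻¹ (non-increasing)."""
    if t < p.t_rho:
        return p.rho0
    return p.rho_inf + (p.rho0 - p.rho_inf) * math.exp(-p.k_rho * (t - p.t_rho))


def fruit_surface_area(FW: float, p: SurfaceArea) -> float:
    """Fruit surface area A_f = γ·FW^η in cm² (FW in g)."""
    if FW <= 0:
        raise ValueError("surface area requires FW > 0")
    return p.gamma * FW ** p.eta
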