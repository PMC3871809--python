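"""Single-compartment fruit biophysics: potentials, fluxes, derivatives.

The berry is one well-mixed compartment behind a composite membrane whose
area grows with fruit surface area.  Water enters from the fruit-end xylem
(water-potential difference) and phloem (pressure difference corrected by a
reflection coefficient); sugar enters by a parallel combination of active
(Michaelis–Menten) uptake, mass flow and diffusion; water leaves by skin
transpiration and dry matter by respiration.  Growth follows the
Lockhart/Ortega law with an elastic modulus, so turgor is a third state
variable alongside water and dry mass.

Internal rate unit is per hour throughout; the starch sub-model's per-day
rates are converted at the assembly boundary only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .params import Membrane, PhysicalConstants, Respiration


@dataclass
class FluxSet:
    """All instantaneous fluxes (g h⁻¹) at one evaluation."""

    U_x: float   # water from fruit-end xylem
    U_p: float   # water from fruit-end phloem
    U_a: float   # active sugar uptake
    U_m: float   # advective (mass-flow) sugar uptake
    U_d: float   # diffusive sugar uptake
    T_f: float   # transpiration loss
    R_f: float   # respiratory dry-matter loss

    @property
    def water_in(self) -> float:
        return self.U_x + self.U_p - self.T_f

    @property
    def sugar_in(self) -> float:
        return self.U_a + self.U_m + self.U_d


def osmotic_pressure(C: float, pi_other: float, T: float, con: PhysicalConstants) -> float:
    """Van 't Hoff osmotic pressure (bar) of a sugar mass fraction C plus a baseline.

    C is g solute per g solution; the solution density con.rho_sol converts
    it to a molar concentration of sucrose equivalents.
    """
    return con.R_g * (T + 273.15) * (C * con.rho_sol / con.M_s) + pi_other


def saturation_vapour_pressure(T: float) -> float:
    """Saturation vapour pressure over water (bar); Buck equation, 0–40 °C."""
    return 6.1121e-3 * math.exp(17.502 * T / (240.97 + T))


def transpiration_flux(
    A_f: float, rho: float, T: float, H_a: float, con: PhysicalConstants
) -> float:
    """Skin transpiration (g h⁻¹) from the internal/ambient humidity gap."""
    c_sat = con.M_w * saturation_vapour_pressure(T) / (con.R_g * (T + 273.15))
    return max(A_f * rho * c_sat * (con.H_f - H_a), 0.0)


def xylem_uptake(psi_x_fruit_end: float, psi_f: float, A_f: float, m: Membrane) -> float:
    """Water uptake across the xylem membrane (g h⁻¹); sign carries direction."""
    return m.a_x * A_f * m.L_x * (psi_x_fruit_end - psi_f)


def phloem_water_uptake(
    P_p: float, pi_p: float, P_f: float, pi_f: float, A_f: float, m: Membrane
) -> float:
    """Water uptake across the phloem membrane (g h⁻¹), reflection-corrected."""
    return m.a_p * A_f * m.L_p * (P_p - P_f - m.sigma_p * (pi_p - pi_f))


def sugar_uptake(
    C_p: float,
    C_f: float,
    U_p: float,
    nu_m: float,
    A_f: float,
    m: Membrane,
    Km: float,
) -> tuple[float, float, float]:
    """Active, advective and diffusive sugar uptake (g h⁻¹).

    Active uptake saturates in the fruit-end phloem concentration C_p;
    advection rides the phloem water flux at the mean membrane concentration;
    diffusion follows the concentration difference.
    """
    U_a = nu_m * C_p / (Km + C_p)
    U_m = (1.0 - m.sigma_p) * 0.5 * (C_p + C_f) * U_p
    U_d = m.p_s * m.a_p * A_f * (C_p - C_f)
    return U_a, U_m, U_d


def maintenance_respiration(s: float, T: float, q: Respiration) -> float:
    """Maintenance component of respiration (g h⁻¹) at temperature T (°C)."""
    return q.q_m * q.Q10_r ** ((T - 20.0) / 10.0) * s


def respiration(s: float, T: float, ds_dt_gross: float, q: Respiration) -> float:
    """Total respiratory dry-matter loss: maintenance + growth components."""
    return maintenance_respiration(s, T, q) + q.q_g * max(ds_dt_gross, 0.0)


def net_dry_matter_rate(sugar_in: float, s: float, T: float, q: Respiration) -> float:
    """Net ds/dt (g h⁻¹) with growth respiration resolved implicitly.

    Growth respiration is proportional to net growth, so when uptake exceeds
    maintenance, ds/dt = (sugar_in − maintenance)/(1 + q_g); otherwise there
    is no growth component and ds/dt = sugar_in − maintenance.
    """
    maint = maintenance_respiration(s, T, q)
    if sugar_in > maint:
        return (sugar_in - maint) / (1.0 + q.q_g)
    return sugar_in - maint


def turgor_rate(
    P_f: float,
    V: float,
    dV_dt: float,
    phi: float,
    Y: float,
    epsilon: float,
) -> float:
    """Ortega turgor dynamics: dP_f/dt = ε·[(1/V)·dV/dt − φ·max(P_f − Y, 0)].

    The plastic (irreversible) term only engages above the yield threshold;
    shrinkage is carried entirely by the elastic term.
    """
    plastic = phi * max(P_f - Y, 0.0)
    return epsilon * (dV_dt / V - plastic)
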