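"""Pedicel solver: conservation, oracle agreement, limits, continuity.

The independent oracle re-solves the fruit-end system by brute-force 2-D
grid refinement over (Ψ', C_p'), minimizing the sum of squared conservation
residuals — sharing no code path with the closed-form elimination + Brent
iteration used by the solver.
"""

import numpy as np
import pytest

from kiwisim import biophysics as bio
from kiwisim import development as dev
from kiwisim.environment import SyntheticEnvironment
from kiwisim.fixtures import random_states
from kiwisim.params import load_parameters
from kiwisim.pedicel import (
    pedicel_phloem_flow,
    pedicel_sugar_flux,
    pedicel_xylem_flow,
    solve_fruit_end,
    stem_state,
)
from kiwisim.state import derive_quantities

PARAMS = load_parameters()


def test_elementary_flow_relations():
    assert pedicel_phloem_flow(5.0, 5.0, 0.016) == 0.0
    assert pedicel_phloem_flow(6.0, 4.0, 0.016) == pytest.approx(0.032)
    assert pedicel_phloem_flow(4.0, 6.0, 0.016) == pytest.approx(-0.032)
    assert pedicel_xylem_flow(-1.0, -6.0, 0.09) == pytest.approx(0.45)
    assert pedicel_xylem_flow(-6.0, -1.0, 0.09) == pytest.approx(-0.45)
    assert pedicel_sugar_flux(0.0, 0.12) == 0.0
    assert pedicel_sugar_flux(0.032, 0.0) == 0.0
    assert pedicel_sugar_flux(0.032, 0.12) == pytest.approx(0.00384)


def _solve_for_state(st, env, params, scale=1.0):
    e = env.sample(st.t)
    der = derive_quantities(st, params, e.T)
    stem = stem_state(e.psi_x, e.C_p, e.T, params)
    nu_m = dev.max_active_uptake(st.s, e.T, params.uptake)
    sol = solve_fruit_end(
        stem, t=st.t, T=e.T,
        P_f=st.P_f, pi_f=der.pi_f, psi_f=der.psi_f, C_f=der.C_f,
        A_f=der.A_f, nu_m=nu_m,
        L_x_ped=dev.pedicel_xylem_conductance(st.t, params.pedicel) * scale,
        L_p_ped=dev.pedicel_phloem_conductance(st.t, params.pedicel) * scale,
        params=params,
    )
    return sol, der, stem, e, nu_m


def grid_search_oracle(st, env, params, inner_rounds=12, outer_rounds=12, n=41):
    """Brute-force minimizer of squared residuals over (Ψ', C_p').

    Nested grid refinement: for each candidate C the best Ψ is located by a
    dense refined scan (vectorized), then the same refinement runs over C on
    the residual envelope.  No closed-form elimination, no root bracketing.
    """
    e = env.sample(st.t)
    der = derive_quantities(st, params, e.T)
    stem = stem_state(e.psi_x, e.C_p, e.T, params)
    nu_m = dev.max_active_uptake(st.s, e.T, params.uptake)
    m, con = params.membrane, params.constants
    Lx = dev.pedicel_xylem_conductance(st.t, params.pedicel)
    Lp = dev.pedicel_phloem_conductance(st.t, params.pedicel)
    vh = con.R_g * (e.T + 273.15) * con.rho_sol / con.M_s
    mean_conv = params.options.pedicel_sugar_conc == "mean"
    kx = m.a_x * der.A_f * m.L_x
    kp = m.a_p * der.A_f * m.L_p

    def sq(psi, C):
        """Sum of squared residuals; psi may be a numpy array."""
        pi_pp = vh * C + params.solutes.pi_pO
        P_pp = psi + pi_pp
        F_p = Lp * (stem.P_p - P_pp)
        F_x = Lx * (stem.psi_x - psi)
        U_x = kx * (psi - der.psi_f)
        U_p = kp * (P_pp - st.P_f - m.sigma_p * (pi_pp - der.pi_f))
        U_a = nu_m * C / (params.uptake.Km + C)
        U_m = (1.0 - m.sigma_p) * 0.5 * (C + der.C_f) * U_p
        U_d = m.p_s * m.a_p * der.A_f * (C - der.C_f)
        conc = 0.5 * (stem.C_p + C) if mean_conv else C
        r1 = F_p + F_x - U_x - U_p
        r2 = F_p * conc - (U_a + U_m + U_d)
        return r1 * r1 + r2 * r2

    def best_psi(C):
        lo, hi = e.psi_x - 25.0, e.psi_x + 25.0
        for _ in range(inner_rounds):
            ps = np.linspace(lo, hi, n)
            v = sq(ps, C)
            i = int(np.argmin(v))
            lo, hi = ps[max(i - 1, 0)], ps[min(i + 1, n - 1)]
        return ps[i], float(v[i])

    c_lo, c_hi = -0.45 * params.uptake.Km, 0.5
    for _ in range(outer_rounds):
        cs = np.linspace(c_lo, c_hi, n)
        vals = [best_psi(c) for c in cs]
        j = int(np.argmin([v for _, v in vals]))
        c_lo, c_hi = cs[max(j - 1, 0)], cs[min(j + 1, n - 1)]
    return vals[j][0], float(cs[j])


class TestSolverContracts:
    def test_residuals_at_machine_level(self, synthetic_env):
        st = random_states(1, seed=5)[0]
        sol, *_ = _solve_for_state(st, synthetic_env, PARAMS)
        assert abs(sol.residual_mass) <= 1e-9
        assert abs(sol.residual_sugar) <= 1e-9

    def test_oracle_agreement_on_sampled_states(self, synthetic_env):
        """Spot check (the acceptance suite covers 100 states)."""
        for st in random_states(5, seed=11):
            sol, *_ = _solve_for_state(st, synthetic_env, PARAMS)
            psi_o, c_o = grid_search_oracle(st, synthetic_env, PARAMS)
            assert sol.psi_fruit_end == pytest.approx(psi_o, abs=1e-4)
            assert sol.C_p_fruit_end == pytest.approx(c_o, abs=1e-4)

    def test_continuity_in_stem_potential(self, synthetic_env):
        """1e-6 bar perturbation of Ψ_x moves Ψ' by O(1e-6): no branch jumps."""
        for st in random_states(10, seed=3):
            e = synthetic_env.sample(st.t)
            der = derive_quantities(st, PARAMS, e.T)
            nu_m = dev.max_active_uptake(st.s, e.T, PARAMS.uptake)
            kwargs = dict(
                t=st.t, T=e.T, P_f=st.P_f, pi_f=der.pi_f, psi_f=der.psi_f,
                C_f=der.C_f, A_f=der.A_f, nu_m=nu_m,
                L_x_ped=dev.pedicel_xylem_conductance(st.t, PARAMS.pedicel),
                L_p_ped=dev.pedicel_phloem_conductance(st.t, PARAMS.pedicel),
                params=PARAMS,
            )
            s0 = solve_fruit_end(stem_state(e.psi_x, e.C_p, e.T, PARAMS), **kwargs)
            s1 = solve_fruit_end(stem_state(e.psi_x + 1e-6, e.C_p, e.T, PARAMS), **kwargs)
            assert abs(s1.psi_fruit_end - s0.psi_fruit_end) < 1e-4

    def test_monotone_sugar_flux_in_stem_concentration(self, synthetic_env):
        for st in random_states(5, seed=7):
            e = synthetic_env.sample(st.t)
            der = derive_quantities(st, PARAMS, e.T)
            nu_m = dev.max_active_uptake(st.s, e.T, PARAMS.uptake)
            kwargs = dict(
                t=st.t, T=e.T, P_f=st.P_f, pi_f=der.pi_f, psi_f=der.psi_f,
                C_f=der.C_f, A_f=der.A_f, nu_m=nu_m,
                L_x_ped=dev.pedicel_xylem_conductance(st.t, PARAMS.pedicel),
                L_p_ped=dev.pedicel_phloem_conductance(st.t, PARAMS.pedicel),
                params=PARAMS,
            )
            fluxes = [
                solve_fruit_end(stem_state(e.psi_x, cp, e.T, PARAMS), **kwargs).S_ped
                for cp in (0.09, 0.13, 0.17)
            ]
            assert fluxes[0] <= fluxes[1] + 1e-12 <= fluxes[2] + 2e-12


class TestLimits:
    def test_zero_resistance_recovers_stem_conditions(self, synthetic_env):
        st = random_states(1, seed=21)[0]
        sol, der, stem, e, nu_m = _solve_for_state(st, synthetic_env, PARAMS, scale=1e6)
        assert sol.psi_fruit_end == pytest.approx(stem.psi_x, abs=1e-4)
        assert sol.C_p_fruit_end == pytest.approx(stem.C_p, abs=1e-4)

    def test_degenerate_no_uptake_surface(self, synthetic_env):
        st = random_states(1, seed=2)[0]
        e = synthetic_env.sample(st.t)
        der = derive_quantities(st, PARAMS, e.T)
        stem = stem_state(e.psi_x, e.C_p, e.T, PARAMS)
        sol = solve_fruit_end(
            stem, t=st.t, T=e.T, P_f=st.P_f, pi_f=der.pi_f, psi_f=der.psi_f,
            C_f=der.C_f, A_f=0.0, nu_m=0.0,
            L_x_ped=0.05, L_p_ped=0.01, params=PARAMS,
        )
        assert sol.C_p_fruit_end == stem.C_p
        assert sol.U_x == sol.U_p == sol.U_a == 0.0

    def test_severed_pedicel_and_inert_membrane(self, synthetic_env):
        st = random_states(1, seed=4)[0]
        e = synthetic_env.sample(st.t)
        der = derive_quantities(st, PARAMS, e.T)
        p0 = PARAMS.with_overrides(
            {"membrane.a_x": 0.0, "membrane.a_p": 0.0, "membrane.p_s": 0.0}
        )
        stem = stem_state(e.psi_x, e.C_p, e.T, p0)
        sol = solve_fruit_end(
            stem, t=st.t, T=e.T, P_f=st.P_f, pi_f=der.pi_f, psi_f=der.psi_f,
            C_f=der.C_f, A_f=der.A_f, nu_m=0.0,
            L_x_ped=0.0, L_p_ped=0.0, params=p0,
        )
        assert sol.F_p == sol.F_x == sol.S_ped == 0.0
        assert sol.C_p_fruit_end == stem.C_p
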