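"""Starch / soluble-solids partition and dynamics.

Fruit dry matter ``s`` is split into structural matter ``o`` (cell walls,
membranes), soluble solids ``s_s`` (osmotically active sugars) and starch
``u`` (osmotically inert storage).  Starch is synthesized from soluble solids
at a rate coefficient ``k_s(t)`` that declines to zero at the cutoff time
``t_r``, and is hydrolysed back at the constant rate ``k_u`` — the late-season
hydrolysis is what drives the harvest rise in soluble solids.

All functions are pure; rates are per day (the simulator converts to the
internal per-hour convention at its assembly boundary).
"""

from __future__ import annotations

import logging
import math

from .params import StarchParams

logger = logging.getLogger(__name__)


def other_dry_matter(
    s: float,
    w: float,
    u: float,
    p: StarchParams,
    *,
    form: str = "proportion",
    cap_base: str = "fresh",
) -> float:
    """Structural ("other") dry matter ``o`` in grams.

    The structural mass is an exponentially reducing proportion of dry
    weight, capped early in the season so that a basal soluble-solids
    requirement (``s_b`` percent) plus ``o`` and starch never exceed ``s``.

    ``form="saturating"`` selects the alternative ``A_o*(1 - exp(-k_o*s))``
    reading (A_o in grams); ``cap_base="juice"`` computes the basal soluble
    requirement on juice mass instead of fresh weight.
    """
    if s <= 0:
        return 0.0
    if form == "proportion":
        o = p.A_o * s * math.exp(-p.k_o * s)
    elif form == "saturating":
        o = p.A_o * (1.0 - math.exp(-p.k_o * s))
    else:
        raise ValueError(f"unknown structural form {form!r}")
    fb = p.s_b / 100.0
    if cap_base == "fresh":
        basal = fb * (w + s)
    elif cap_base == "juice":
        # smallest s_s with s_s/(w + s_s) >= s_b/100
        basal = fb * w / (1.0 - fb)
    else:
        raise ValueError(f"unknown cap base {cap_base!r}")
    cap = s - u - basal
    return max(min(o, cap), 0.0)


def soluble_solids_mass(s: float, o: float, u: float) -> float:
    """Soluble solids ``s_s = s - o - u``, floored at zero with a warning."""
    s_s = s - o - u
    if s_s < 0:
        logger.warning(
            "soluble solids floored at 0 (s=%.6g, o=%.6g, u=%.6g): inconsistent state",
            s, o, u,
        )
        return 0.0
    return s_s


def starch_synthesis_rate(t: float, p: StarchParams) -> float:
    """Synthesis rate coefficient ``k_s(t)`` in d⁻¹.

    Declines from near ``k_s1`` slowly at first, then faster, reaching zero
    at ``t_r``; at ``t_r - t_h`` it equals ``(1 - 1/e)`` ≈ 63% of maximum.
    """
    if t >= p.t_r:
        return 0.0
    return p.k_s1 * (1.0 - math.exp(-(p.t_r - t) / p.t_h))


def starch_rate(s_s: float, u: float, t: float, p: StarchParams) -> float:
    """Net starch rate ``du/dt = k_s(t)·s_s − k_u·u`` in g d⁻¹."""
    return starch_synthesis_rate(t, p) * s_s - p.k_u * u


def soluble_fraction(s_s: float, s: float) -> float:
    """Proportion ``Z = s_s / s`` of dry matter in soluble form."""
    if s <= 0:
        raise ValueError("soluble fraction undefined for zero dry matter")
    return s_s / s
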