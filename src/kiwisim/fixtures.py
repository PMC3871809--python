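"""Deterministic generators for test and demonstration inputs.

Everything the test-suite consumes is generated here from a seed: synthetic
weather tables, synthetic LVDT diameter logs, random-but-valid fruit states
for property tests, and a five-day "toy season" for quick runs.  Same seed,
same bytes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from .analysis import DiameterSeries
from .environment import EnvironmentConfig, SyntheticEnvironment
from .simulator import SimulationConfig, Trajectory, simulate
from .state import FruitState


@dataclass
class FixtureSpec:
    kind: str                     # weather | lvdt | states | toy-season
    seed: int
    options: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self):
        if self.kind not in ("weather", "lvdt", "states", "toy-season"):
            raise ValueError(f"unknown fixture kind {self.kind!r}")


def weather_frame(t_start: float = 0.0, t_end: float = 5.0, step_h: float = 1.0,
                  config: EnvironmentConfig | None = None) -> pd.DataFrame:
    """Synthetic hourly weather table (deterministic; no noise)."""
    return SyntheticEnvironment(config or EnvironmentConfig()).to_frame(t_start, t_end, step_h)


def random_states(n: int, seed: int) -> list[FruitState]:
    """Seeded valid fruit states spanning the season's plausible envelope."""
    rng = np.random.default_rng(seed)
    states = []
    for _ in range(n):
        t = float(rng.uniform(0.0, 170.0))
        w = float(rng.uniform(2.0, 120.0))
        s = float(rng.uniform(0.3, 18.0))
        u = float(rng.uniform(0.0, 0.8) * s)
        P_f = float(rng.uniform(-1.0, 15.0))
        st = FruitState(t=t, w=w, s=s, u=u, P_f=P_f)
        st.validate()
        states.append(st)
    return states


def synthetic_lvdt(
    seed: int,
    t_start: float = 54.0,
    t_end: float = 61.0,
    step_h: float = 1.0 / 6.0,         # 10-minute cadence
    d0_mm: float = 40.0,
    growth_mm_per_day: float = 0.35,
    diurnal_mm: float = 0.12,
    noise: float = 2e-4,
    traj: Trajectory | None = None,
) -> DiameterSeries:
    """Synthetic LVDT diameter log (a constructed stand-in, not field data).

    Either derives diameters from a supplied trajectory via the cube law, or
    builds a smooth growth + diurnal-shrink curve; multiplicative white noise
    of relative amplitude ``noise`` is applied with the mandatory seed.
    """
    rng = np.random.default_rng(seed)
    t = np.arange(t_start, t_end + 1e-9, step_h / 24.0)
    if traj is not None:
        fw = np.interp(t, traj.frame["t"], traj.frame["FW"])
        d = d0_mm * (fw / fw[0]) ** (1.0 / 3.0)
    else:
        # daytime shrink, night recovery: minimum near mid-afternoon
        hour = (t - np.floor(t)) * 24.0
        diurnal = -diurnal_mm * 0.5 * (1.0 - np.cos(2.0 * np.pi * (hour - 4.0) / 24.0))
        d = d0_mm + growth_mm_per_day * (t - t_start) + diurnal
    d = d * (1.0 + noise * rng.standard_normal(t.size))
    return DiameterSeries(t=t, diameter=d, label=f"synthetic-lvdt-seed{seed}")


def toy_season(seed: int = 0, days: float = 5.0) -> Trajectory:
    """Five-day simulation from the default initial state (fast smoke input)."""
    cfg = SimulationConfig(t_start=0.0, t_end=days, seed=seed)
    return simulate(cfg)


def generate(spec: FixtureSpec, out_dir: str | Path | None = None):
    """Produce the fixture; when ``out_dir`` is given, also write CSV files.

    Files begin with a comment-free header row; the seed is recorded in the
    file name for provenance.
    """
    if spec.kind == "weather":
        obj = weather_frame(**spec.options)
        frames = {"weather": obj}
    elif spec.kind == "lvdt":
        series = synthetic_lvdt(seed=spec.seed, **spec.options)
        obj = series
        frames = {"lvdt": pd.DataFrame({"t": series.t, "diameter_mm": series.diameter})}
    elif spec.kind == "states":
        states = random_states(spec.options.get("n", 100), spec.seed)
        obj = states
        frames = {"states": pd.DataFrame([vars(s) for s in states])}
    else:  # toy-season
        traj = toy_season(seed=spec.seed, **spec.options)
        obj = traj
        frames = {"toy_season": traj.frame}

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for name, frame in frames.items():
            frame.to_csv(out_dir / f"{name}_seed{spec.seed}.csv", index=False)
    return obj
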