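"""In-silico reaction knockouts: zero one rate constant and quantify
the growth reduction versus control.

Setting a rate constant to zero removes the corresponding molecular
interaction from the network, emulating a perfectly specific inhibitor.
The basal HIF1α machinery is excluded from the eligible set: HIF1α is
ubiquitous in all cells, so a drug hitting its basal production (the
Hill term parameterized by k8, k9, k12) or its oxygen-dependent
degradation (k7) could not be tumor-specific. Every other constant,
including the degradation kd and basal growth v1, may be knocked out.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import PARAM_NAMES, CellLineProfile, Environment, volume_from_diameter
from .simulate import SimulationError, Trajectory, simulate

__all__ = ["EXCLUDED_PARAMS", "ELIGIBLE_PARAMS", "KnockoutResult",
           "KnockoutExclusionError", "knockout_run",
           "growth_reduction_table", "paired_knockout_contrast"]

#: Basal HIF1α production (Hill triple) and oxygen-dependent degradation.
EXCLUDED_PARAMS = ("k7", "k8", "k9", "k12")
ELIGIBLE_PARAMS = tuple(n for n in PARAM_NAMES if n not in EXCLUDED_PARAMS)


class KnockoutExclusionError(ValueError):
    """Requested knockout is in the excluded (non-targetable) set."""


@dataclass
class KnockoutResult:
    """Outcome of zeroing one rate constant (or none, for control)."""

    parameter: str | None         # None = control
    cell_line: str
    trajectory: Trajectory
    final_diameter: float         # um
    final_volume: float           # um^3
    pct_reduction_diameter: float  # 100*(1 - gd/gd_control)
    volume_ratio_vs_control: float
    diameter_growth: float        # final - initial diameter, um
    volume_growth: float          # final - initial volume, um^3


def _grid(horizon: float) -> np.ndarray:
    return np.linspace(0.0, horizon, max(int(horizon) + 1, 2))


def knockout_run(profile: CellLineProfile, param: str | None, *,
                 horizon: float = 960.0, env: Environment | None = None,
                 rtol: float = 1e-8, atol: float = 1e-10) -> KnockoutResult:
    """Simulate with the named constant set to 0 and compare to the
    control run (``param=None`` returns the control itself)."""
    if param is not None:
        if param in EXCLUDED_PARAMS:
            raise KnockoutExclusionError(
                f"{param} parameterizes the basal production or oxygen-"
                "dependent degradation of HIF1a, which is ubiquitous in "
                "all cells and therefore excluded from in-silico "
                f"knockouts (excluded set: {EXCLUDED_PARAMS})")
        if param not in ELIGIBLE_PARAMS:
            raise KeyError(f"unknown rate constant {param!r}")
    t_grid = _grid(horizon)
    control = simulate(profile, env, t_grid, rtol=rtol, atol=atol)
    if param is None:
        traj = control
    else:
        ko = profile.with_params(profile.params.with_values(**{param: 0.0}))
        traj = simulate(ko, env, t_grid, rtol=rtol, atol=atol)
    gd0 = profile.initial.gd
    gd_c = float(control.gd[-1])
    gd_f = float(traj.gd[-1])
    vol_c = volume_from_diameter(gd_c)
    vol_f = volume_from_diameter(gd_f)
    vol_0 = volume_from_diameter(gd0)
    return KnockoutResult(
        parameter=param,
        cell_line=profile.name,
        trajectory=traj,
        final_diameter=gd_f,
        final_volume=vol_f,
        pct_reduction_diameter=100.0 * (1.0 - gd_f / gd_c),
        volume_ratio_vs_control=vol_f / vol_c,
        diameter_growth=gd_f - gd0,
        volume_growth=vol_f - vol_0,
    )


def growth_reduction_table(profile: CellLineProfile, *,
                           horizon: float = 960.0,
                           env: Environment | None = None,
                           params=ELIGIBLE_PARAMS,
                           rtol: float = 1e-8, atol: float = 1e-10
                           ) -> pd.DataFrame:
    """One knockout per eligible constant plus the control row, ranked
    by percent diameter reduction (control first)."""
    rows = []
    control = knockout_run(profile, None, horizon=horizon, env=env,
                           rtol=rtol, atol=atol)
    for res in [control] + [
            _safe_run(profile, p, horizon, env, rtol, atol) for p in params]:
        if isinstance(res, dict):
            rows.append(res)
            continue
        rows.append({
            "parameter": "control" if res.parameter is None else res.parameter,
            "final_gd_um": res.final_diameter,
            "final_volume_um3": res.final_volume,
            "pct_reduction_diameter": res.pct_reduction_diameter,
            "volume_ratio_vs_control": res.volume_ratio_vs_control,
            "diameter_growth_um": res.diameter_growth,
            "volume_growth_um3": res.volume_growth,
            "failed": False,
        })
    df = pd.DataFrame(rows)
    body = df[df["parameter"] != "control"].sort_values(
        "pct_reduction_diameter", ascending=False)
    return pd.concat([df[df["parameter"] == "control"], body],
                     ignore_index=True)


def _safe_run(profile, param, horizon, env, rtol, atol):
    try:
        return knockout_run(profile, param, horizon=horizon, env=env,
                            rtol=rtol, atol=atol)
    except SimulationError as exc:
        return {"parameter": param, "final_gd_um": float("nan"),
                "final_volume_um3": float("nan"),
                "pct_reduction_diameter": float("nan"),
                "volume_ratio_vs_control": float("nan"),
                "diameter_growth_um": float("nan"),
                "volume_growth_um3": float("nan"),
                "failed": True, "message": str(exc)}


def paired_knockout_contrast(profile: CellLineProfile, param_a: str = "k10",
                             param_b: str = "k6", *,
                             horizon: float = 960.0,
                             env: Environment | None = None) -> dict:
    """Growth under knockout A relative to knockout B.

    Returns both the diameter-growth and volume-growth ratios
    (growth = final − initial, so the shared initial size cancels).
    """
    a = knockout_run(profile, param_a, horizon=horizon, env=env)
    b = knockout_run(profile, param_b, horizon=horizon, env=env)
    return {
        "param_a": param_a,
        "param_b": param_b,
        "diameter_growth_ratio": a.diameter_growth / b.diameter_growth,
        "volume_growth_ratio": a.volume_growth / b.volume_growth,
        "final_volume_ratio": a.final_volume / b.final_volume,
        "result_a": a,
        "result_b": b,
    }
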