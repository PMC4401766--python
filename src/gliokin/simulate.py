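"""Time integration of the kinetic model and steady-state summaries.

The four ODEs are integrated with an adaptive, stiffness-switching
solver (LSODA by default) at tight tolerances (rtol 1e-8, atol 1e-10).
Free IGFI is reconstructed algebraically from the conserved total at
every output point, so ligand conservation holds by construction;
what the solver must (and does) preserve is that the bound complex
stays within [0, total].

Steady state of the molecular species is assessed by a relative-rate
criterion over the trailing 10% of the time grid: species X is
converged when |dX/dt|·t_final / max(|X|, ε) < rel_tol throughout the
window. The diameter grows without bound whenever v1 > 0 and is
reported but never flagged converged in that regime.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .model import (
    SPECIES_NAMES,
    CellLineProfile,
    Environment,
    ModelState,
    SingularDenominatorError,
    volume_from_diameter,
)

__all__ = ["Trajectory", "SteadyStateSummary", "SimulationError",
           "simulate", "steady_state", "hypoxia_response"]

#: Negative excursions smaller than this are clipped to zero.
_NEG_CLIP = 1e-9


class SimulationError(RuntimeError):
    """The ODE solver failed; carries the failure time and last state."""

    def __init__(self, message: str, t_fail: float | None = None,
                 last_state: np.ndarray | None = None):
        super().__init__(message)
        self.t_fail = t_fail
        self.last_state = last_state


def _make_rhs(params, o2: float, igfi_total: float,
              strict_printed_dissociation: bool):
    """Closure over plain floats for a fast solver callback.

    Mirrors the rate functions in :mod:`gliokin.model` exactly (tested
    to 1e-12); kept separate only to avoid per-step dataclass
    construction.
    """
    k1, k2, k3, k4, k5 = params.k1, params.k2, params.k3, params.k4, params.k5
    k6, k7, k8, k9, k10 = params.k6, params.k7, params.k8, params.k9, params.k10
    k11, k12, kd, v1 = params.k11, params.k12, params.kd, params.v1
    k_diss = k3 if strict_printed_dissociation else k4

    def rhs(t, y):
        b = y[0] if y[0] > 0.0 else 0.0
        c = y[1] if y[1] > 0.0 else 0.0
        h = y[2] if y[2] > 0.0 else 0.0
        i = igfi_total - c
        if i < 0.0:
            i = 0.0
        db = k1 * b * i * (1.0 - k2 * b) - k3 * i * b + k4 * c - kd * b + k5 * h
        denom = k12 + k9 * h
        if denom != 0.0:
            hill = k8 * h / denom
        elif k8 * h == 0.0:
            hill = 0.0
        else:
            raise SingularDenominatorError(
                f"Hill denominator k12 + k9*H = 0 at H={h}")
        dc = k3 * i * b - k_diss * c - kd * c
        dh = k6 * i - k7 * o2 * h + hill + k10 * b
        dgd = v1 + k11 * h
        return (db, dc, dh, dgd)

    return rhs


@dataclass
class Trajectory:
    """Solution of one simulation on an explicit time grid.

    ``states`` has one row per time point with columns in
    :data:`~gliokin.model.SPECIES_NAMES` order.
    """

    times: np.ndarray
    states: np.ndarray
    profile: CellLineProfile
    environment: Environment

    @property
    def igfbp2(self) -> np.ndarray:
        return self.states[:, 0]

    @property
    def complex(self) -> np.ndarray:
        return self.states[:, 1]

    @property
    def hif1a(self) -> np.ndarray:
        return self.states[:, 2]

    @property
    def gd(self) -> np.ndarray:
        return self.states[:, 3]

    @property
    def igfi_free(self) -> np.ndarray:
        return self.environment.igfi_total_effective - self.complex

    @property
    def volume(self) -> np.ndarray:
        return volume_from_diameter(self.gd)

    def final_state(self) -> ModelState:
        return ModelState.from_array(self.states[-1])

    def to_frame(self) -> pd.DataFrame:
        """Tabular view with the canonical export column names."""
        return pd.DataFrame({
            "time_hr": self.times,
            "igfi_free_nM": self.igfi_free,
            "igfbp2_nM": self.igfbp2,
            "complex_nM": self.complex,
            "hif1a_uM": self.hif1a,
            "gd_um": self.gd,
            "volume_um3": self.volume,
        })


@dataclass
class SteadyStateSummary:
    """Per-species steady values with convergence flags.

    ``values`` are the final-time values; ``converged[name]`` is True
    when the relative-rate criterion held over the trailing window;
    ``time_to_steady[name]`` is the earliest grid time from which the
    criterion holds through the end (NaN when never)."""

    values: dict[str, float]
    converged: dict[str, bool]
    time_to_steady: dict[str, float]
    rel_tol: float = 1e-4
    window_fraction: float = 0.1
    extras: dict = field(default_factory=dict)


def simulate(profile: CellLineProfile,
             env: Environment | None = None,
             t_grid: np.ndarray | None = None,
             *,
             rtol: float = 1e-8,
             atol: float = 1e-10,
             method: str = "LSODA",
             strict_printed_dissociation: bool = False) -> Trajectory:
    """Integrate the model under a constant environment.

    Parameters
    ----------
    profile
        Cell-line parameterization (constants + initial state).
    env
        Environment override; defaults to the profile's own.
    t_grid
        Strictly increasing output grid in hours starting at 0;
        defaults to an hourly grid over ``env.duration``.
    """
    env = env if env is not None else profile.environment
    if t_grid is None:
        t_grid = np.arange(0.0, float(env.duration) + 0.5, 1.0)
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid.ndim != 1 or len(t_grid) < 2:
        raise ValueError("t_grid must be 1-D with at least 2 points")
    if np.any(np.diff(t_grid) <= 0):
        raise ValueError("t_grid must be strictly increasing")
    if t_grid[0] != 0.0:
        raise ValueError("t_grid must start at 0 (the initial state)")

    y0 = profile.initial.as_array()
    rhs = _make_rhs(profile.params, env.o2_percent,
                    env.igfi_total_effective, strict_printed_dissociation)
    sol = solve_ivp(rhs, (t_grid[0], t_grid[-1]), y0, method=method,
                    t_eval=t_grid, rtol=rtol, atol=atol)
    if not sol.success:
        t_fail = float(sol.t[-1]) if sol.t.size else t_grid[0]
        last = sol.y[:, -1] if sol.y.size else y0
        raise SimulationError(
            f"ODE solver failed at t={t_fail:.6g} hr: {sol.message}",
            t_fail=t_fail, last_state=last,
        )
    y = sol.y.T.copy()
    y[0] = y0  # the t=0 row is the initial state exactly, not solver output
    # Clip infinitesimal negative excursions; anything larger is a real
    # solver failure and should surface.
    tiny_neg = (y < 0.0) & (y > -_NEG_CLIP)
    y[tiny_neg] = 0.0
    if np.any(y < 0.0):
        worst = float(y.min())
        raise SimulationError(
            f"trajectory went negative beyond clip tolerance (min {worst:g})"
        )
    return Trajectory(times=t_grid, states=y, profile=profile,
                      environment=env)


def steady_state(traj: Trajectory, rel_tol: float = 1e-4,
                 window_fraction: float = 0.1) -> SteadyStateSummary:
    """Assess per-species convergence of a trajectory.

    Requires at least 10 grid points. Rates are re-evaluated from the
    model equations at the stored states.
    """
    if len(traj.times) < 10:
        raise ValueError("trajectory must have at least 10 points")
    rhs = _make_rhs(traj.profile.params, traj.environment.o2_percent,
                    traj.environment.igfi_total_effective, False)
    t_final = float(traj.times[-1])
    n = len(traj.times)
    derivs = np.array([rhs(t, y) for t, y in zip(traj.times, traj.states)])
    eps = 1e-12
    # Dimensionless slowness metric per point and species.
    metric = (np.abs(derivs) * t_final
              / np.maximum(np.abs(traj.states), eps))
    ok = metric < rel_tol

    values: dict[str, float] = {}
    converged: dict[str, bool] = {}
    tts: dict[str, float] = {}
    n_window = max(2, int(np.ceil(window_fraction * n)))
    for j, name in enumerate(SPECIES_NAMES):
        values[name] = float(traj.states[-1, j])
        converged[name] = bool(ok[-n_window:, j].all())
        holds_through_end = np.flip(np.logical_and.accumulate(
            np.flip(ok[:, j])))
        idx = np.nonzero(holds_through_end)[0]
        tts[name] = float(traj.times[idx[0]]) if idx.size else float("nan")
    values["igfi_free"] = float(traj.igfi_free[-1])
    return SteadyStateSummary(values=values, converged=converged,
                              time_to_steady=tts, rel_tol=rel_tol,
                              window_fraction=window_fraction)


def hypoxia_response(profile: CellLineProfile,
                     o2_levels,
                     *,
                     control_o2: float = 21.0,
                     duration: float = 2000.0,
                     baseline: str = "control-steady",
                     rel_tol: float = 1e-4,
                     rtol: float = 1e-8,
                     atol: float = 1e-10) -> pd.DataFrame:
    """Steady species values and fold-changes across oxygen levels.

    Each level is simulated to ``duration`` hours and summarized by
    :func:`steady_state`. Fold-changes are relative to the steady
    values at ``control_o2`` (``baseline="control-steady"``, the
    default) or to the profile's initial values
    (``baseline="initial"``).
    """
    o2_levels = list(np.atleast_1d(o2_levels).astype(float))
    if baseline not in ("control-steady", "initial"):
        raise ValueError("baseline must be 'control-steady' or 'initial'")

    species = ("hif1a", "igfbp2", "complex", "igfi_free")

    def steady_at(o2: float) -> SteadyStateSummary:
        env = Environment(o2_percent=o2, igfi_total=profile.environment.igfi_total,
                          duration=duration,
                          added_igfi=profile.environment.added_igfi)
        traj = simulate(profile, env, rtol=rtol, atol=atol)
        return steady_state(traj, rel_tol=rel_tol)

    if baseline == "control-steady":
        ref = steady_at(control_o2).values
    else:
        init = profile.initial
        ref = {"hif1a": init.hif1a, "igfbp2": init.igfbp2,
               "complex": init.complex,
               "igfi_free": init.igfi_free(
                   profile.environment.igfi_total_effective)}

    rows = []
    for o2 in o2_levels:
        ss = steady_at(o2)
        row: dict[str, float] = {"o2_percent": o2}
        for sp in species:
            row[sp] = ss.values[sp]
            row[f"{sp}_fold"] = ss.values[sp] / ref[sp]
        row["species_converged"] = all(
            ss.converged[s] for s in ("igfbp2", "complex", "hif1a"))
        rows.append(row)
    return pd.DataFrame(rows)
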