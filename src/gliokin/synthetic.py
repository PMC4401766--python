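"""Synthetic datasets with the structure of the experiments the model
is calibrated against.

Three experiment designs are emulated:

* spheroid diameters from a hanging-drop assay, measured on days
  1, 4, 5 and 6 and averaged over ~20 droplets (``in_vitro``);
* xenograft tumor volumes recorded daily over 40 days and averaged
  over 10 animals (``in_vivo``);
* an IGFBP2 concentration time course after adding 0 or 100 nM ligand
  at t=0, and a steady-state HIF1α-versus-O₂ curve reported as relative
  expression normalized to its maximum.

Noise defaults to multiplicative lognormal at 5% relative sd: the real
measurement error law is not recoverable from published means, so this
is an explicit modelling choice favouring positivity and scale
invariance. With ``sd=0`` every generator reproduces the noiseless
simulation exactly at the design points.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np

from .model import CellLineProfile, Environment
from .fitting import ObservationSeries
from .simulate import simulate

__all__ = ["NoiseModel", "gen_growth_series", "gen_igfbp2_timecourse",
           "gen_hif1a_o2_curve", "IN_VITRO_TIMES_HR", "IN_VIVO_TIMES_HR"]

#: Measurement days 1, 4, 5, 6 of the hanging-drop assay, in hours.
IN_VITRO_TIMES_HR = np.array([24.0, 96.0, 120.0, 144.0])
#: Daily marks over the 40-day xenograft study, in hours.
IN_VIVO_TIMES_HR = np.arange(0.0, 961.0, 24.0)


@dataclass(frozen=True)
class NoiseModel:
    """Measurement-noise law applied per replicate draw.

    ``kind="lognormal"`` multiplies each true value by exp(sd·z) with
    z ~ N(0,1) (median-unbiased, always positive); ``kind="gaussian"``
    adds sd·z in absolute units and clips negatives to zero with a
    warning. ``sd=0`` reproduces the model output exactly.
    """

    kind: str = "lognormal"
    sd: float = 0.05

    def __post_init__(self) -> None:
        if self.kind not in ("lognormal", "gaussian"):
            raise ValueError("kind must be 'lognormal' or 'gaussian'")
        if self.sd < 0:
            raise ValueError("sd must be >= 0")

    def apply(self, values: np.ndarray, rng: np.random.Generator,
              size: tuple | None = None) -> np.ndarray:
        """Noisy draws; ``size`` may prepend replicate axes."""
        values = np.asarray(values, dtype=float)
        shape = values.shape if size is None else size + values.shape
        if self.sd == 0:
            return np.broadcast_to(values, shape).copy()
        z = rng.standard_normal(shape)
        if self.kind == "lognormal":
            return values * np.exp(self.sd * z)
        out = values + self.sd * z
        n_neg = int(np.sum(out < 0))
        if n_neg:
            warnings.warn(f"clipped {n_neg} negative gaussian draws to 0",
                          stacklevel=2)
            out = np.maximum(out, 0.0)
        return out


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def gen_growth_series(profile: CellLineProfile, design: str = "in_vitro",
                      noise: NoiseModel = NoiseModel(), *,
                      seed=0, n_replicates: int | None = None,
                      rtol: float = 1e-8, atol: float = 1e-10
                      ) -> ObservationSeries:
    """Replicate-averaged growth data for one experiment design.

    ``in_vitro`` yields spheroid diameters (μm) at the day marks,
    averaged over 20 droplets by default; ``in_vivo`` yields tumor
    volumes (μm³) on a daily 40-day grid, averaged over 10 animals.
    """
    if design == "in_vitro":
        times = IN_VITRO_TIMES_HR
        observable = "diameter_um"
        n_rep = 20 if n_replicates is None else n_replicates
    elif design == "in_vivo":
        times = IN_VIVO_TIMES_HR
        observable = "volume_um3"
        n_rep = 10 if n_replicates is None else n_replicates
    else:
        raise ValueError("design must be 'in_vitro' or 'in_vivo'")
    rng = _rng(seed)
    t_grid = np.unique(np.concatenate([[0.0], times]))
    traj = simulate(profile, None, t_grid, rtol=rtol, atol=atol)
    pos = np.searchsorted(t_grid, times)
    truth = traj.gd[pos] if observable == "diameter_um" \
        else traj.volume[pos]
    draws = noise.apply(truth, rng, size=(n_rep,))
    env = profile.environment
    return ObservationSeries(
        observable=observable, coords=times, values=draws.mean(axis=0),
        env_overrides={"o2_percent": env.o2_percent,
                       "igfi_total": env.igfi_total,
                       "added_igfi": env.added_igfi},
        metadata={"generator": "gen_growth_series", "design": design,
                  "profile": profile.name, "n_replicates": n_rep,
                  "noise_kind": noise.kind, "noise_sd": noise.sd,
                  "seed": None if isinstance(seed, np.random.Generator)
                  else int(seed)},
    )


def gen_igfbp2_timecourse(profile: CellLineProfile, added_igfi: float = 0.0,
                          t_grid=None, noise: NoiseModel = NoiseModel(), *,
                          seed=0, rtol: float = 1e-8, atol: float = 1e-10
                          ) -> ObservationSeries:
    """IGFBP2 (nM) over time after a t=0 ligand bolus of ``added_igfi``
    nM (0–48 hr at 6-hr intervals by default)."""
    if added_igfi < 0:
        raise ValueError("added_igfi must be >= 0")
    times = np.arange(0.0, 48.1, 6.0) if t_grid is None \
        else np.asarray(t_grid, dtype=float)
    rng = _rng(seed)
    env = replace(profile.environment, added_igfi=added_igfi,
                  duration=float(times[-1]))
    grid = np.unique(np.concatenate([[0.0], times]))
    traj = simulate(profile, env, grid, rtol=rtol, atol=atol)
    pos = np.searchsorted(grid, times)
    values = noise.apply(traj.igfbp2[pos], rng)
    return ObservationSeries(
        observable="igfbp2_nM", coords=times, values=values,
        # embed the generating conditions so a fit replays them
        env_overrides={"added_igfi": added_igfi,
                       "o2_percent": env.o2_percent,
                       "igfi_total": env.igfi_total},
        metadata={"generator": "gen_igfbp2_timecourse",
                  "profile": profile.name, "added_igfi_nM": added_igfi,
                  "noise_kind": noise.kind, "noise_sd": noise.sd,
                  "seed": None if isinstance(seed, np.random.Generator)
                  else int(seed)},
    )


def gen_hif1a_o2_curve(profile: CellLineProfile, o2_grid=None,
                       noise: NoiseModel = NoiseModel(), *,
                       seed=0, steady_duration: float = 500.0,
                       rtol: float = 1e-8, atol: float = 1e-10
                       ) -> ObservationSeries:
    """Steady-state HIF1α versus O₂ as relative expression (normalized
    to the curve maximum before noise is applied)."""
    o2 = np.linspace(2.0, 21.0, 8) if o2_grid is None \
        else np.asarray(o2_grid, dtype=float)
    if np.any(o2 < 2.0) or np.any(o2 > 21.0):
        raise ValueError("o2_grid must lie within [2, 21]")
    rng = _rng(seed)
    steady = np.empty_like(o2)
    for i, level in enumerate(o2):
        env = replace(profile.environment, o2_percent=float(level),
                      duration=steady_duration)
        t_grid = np.array([0.0, steady_duration / 2.0, steady_duration])
        traj = simulate(profile, env, t_grid, rtol=rtol, atol=atol)
        steady[i] = traj.hif1a[-1]
    rel = steady / steady.max()
    values = noise.apply(rel, rng)
    return ObservationSeries(
        observable="hif1a_vs_o2", coords=o2, values=values,
        metadata={"generator": "gen_hif1a_o2_curve",
                  "profile": profile.name,
                  "steady_duration_hr": steady_duration,
                  "noise_kind": noise.kind, "noise_sd": noise.sd,
                  "seed": None if isinstance(seed, np.random.Generator)
                  else int(seed)},
    )
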