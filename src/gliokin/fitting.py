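"""Parameter estimation against observed time series.

The estimation scheme mirrors common practice for small kinetic models:
a seeded real-coded genetic algorithm searches log10-parameter space
globally within bounds (the fitted constants span five orders of
magnitude, so log space is the natural metric), and the best individual
is refined with a Nelder–Mead simplex. The refinement can only improve
the objective: if the simplex ends worse, the GA optimum is kept.

The objective is a weighted sum over observation series of the residual
sum of squares normalized by each series' total sum of squares about
its mean, which makes series with heterogeneous units (diameters in μm,
volumes in μm³, concentrations in nM, relative expression)
commensurable. Relative-expression observables (``hif1a_rel``,
``hif1a_vs_o2``) are matched through a per-evaluation least-squares
scale factor, since such data determine the model concentration only up
to a multiplicative constant.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import minimize

from .model import (
    PARAM_NAMES,
    CellLineProfile,
    Environment,
    KineticParameters,
)
from .simulate import SimulationError, simulate

__all__ = ["OBSERVABLES", "ObservationSeries", "GAConfig", "FitResult",
           "r_squared", "predict_series", "objective", "fit"]

OBSERVABLES = ("diameter_um", "volume_um3", "igfbp2_nM", "hif1a_rel",
               "hif1a_vs_o2")

#: Observables fitted through a free multiplicative scale factor.
_SCALED = ("hif1a_rel", "hif1a_vs_o2")

_PENALTY = 1e12


@dataclass(frozen=True)
class ObservationSeries:
    """One observed dataset: an observable sampled on a coordinate grid.

    ``coords`` are hours for time-course observables and oxygen
    percentages for ``hif1a_vs_o2``. ``env_overrides`` may set
    ``o2_percent``, ``added_igfi`` or ``duration`` for the simulation
    that predicts this series.
    """

    observable: str
    coords: np.ndarray
    values: np.ndarray
    weight: float = 1.0
    env_overrides: dict = field(default_factory=dict)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.observable not in OBSERVABLES:
            raise ValueError(
                f"observable must be one of {OBSERVABLES}, "
                f"got {self.observable!r}")
        object.__setattr__(self, "coords",
                           np.asarray(self.coords, dtype=float))
        object.__setattr__(self, "values",
                           np.asarray(self.values, dtype=float))
        if self.coords.shape != self.values.shape or self.coords.ndim != 1:
            raise ValueError("coords and values must be equal-length 1-D")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("values must be finite")
        if self.weight < 0:
            raise ValueError("weight must be >= 0")


def r_squared(observed, predicted) -> float:
    """Coefficient of determination 1 − SS_res/SS_tot."""
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.size < 2:
        raise ValueError("need at least 2 points")
    ss_tot = float(np.sum((obs - obs.mean()) ** 2))
    if ss_tot == 0.0:
        raise ValueError(
            "observed values have zero variance; R^2 is undefined")
    ss_res = float(np.sum((obs - pred) ** 2))
    return 1.0 - ss_res / ss_tot


def _series_env(profile: CellLineProfile,
                series: ObservationSeries) -> Environment:
    base = profile.environment
    over = dict(series.env_overrides)
    return Environment(
        o2_percent=float(over.get("o2_percent", base.o2_percent)),
        igfi_total=float(over.get("igfi_total", base.igfi_total)),
        duration=float(over.get("duration", base.duration)),
        added_igfi=float(over.get("added_igfi", base.added_igfi)),
    )


def predict_series(profile: CellLineProfile, series: ObservationSeries, *,
                   rtol: float = 1e-8, atol: float = 1e-10,
                   steady_duration: float = 500.0) -> np.ndarray:
    """Model prediction at the series' coordinates (unscaled for
    relative-expression observables)."""
    env = _series_env(profile, series)
    if series.observable == "hif1a_vs_o2":
        out = np.empty_like(series.coords)
        for i, o2 in enumerate(series.coords):
            env_i = replace(env, o2_percent=float(o2),
                            duration=steady_duration)
            t_grid = np.array([0.0, steady_duration / 2.0, steady_duration])
            traj = simulate(profile, env_i, t_grid, rtol=rtol, atol=atol)
            out[i] = traj.hif1a[-1]
        return out
    times = series.coords
    t_grid = np.unique(np.concatenate([[0.0], times]))
    traj = simulate(profile, env, t_grid, rtol=rtol, atol=atol)
    pos = np.searchsorted(t_grid, times)
    if series.observable == "diameter_um":
        return traj.gd[pos]
    if series.observable == "volume_um3":
        return traj.volume[pos]
    if series.observable == "igfbp2_nM":
        return traj.igfbp2[pos]
    if series.observable == "hif1a_rel":
        return traj.hif1a[pos]
    raise AssertionError(series.observable)


def _scaled_sse(series: ObservationSeries, predicted: np.ndarray
                ) -> tuple[float, float]:
    """(SSE, scale): optimal least-squares scale for relative
    observables, identity scale otherwise."""
    obs = series.values
    if series.observable in _SCALED:
        denom = float(np.dot(predicted, predicted))
        alpha = float(np.dot(obs, predicted)) / denom if denom > 0 else 0.0
        resid = obs - alpha * predicted
        return float(np.dot(resid, resid)), alpha
    resid = obs - predicted
    return float(np.dot(resid, resid)), 1.0


def objective(params: KineticParameters, series_list,
              profile: CellLineProfile, *,
              rtol: float = 1e-8, atol: float = 1e-10) -> float:
    """Weighted variance-normalized SSE over all series (deterministic;
    solver failures contribute a large finite penalty)."""
    prof = profile.with_params(params)
    total = 0.0
    for s in series_list:
        ss_tot = float(np.sum((s.values - s.values.mean()) ** 2))
        norm = ss_tot if ss_tot > 0 else 1.0
        try:
            pred = predict_series(prof, s, rtol=rtol, atol=atol)
            sse, _ = _scaled_sse(s, pred)
            total += s.weight * sse / norm
        except (SimulationError, ValueError):
            total += s.weight * _PENALTY
    return total


@dataclass(frozen=True)
class GAConfig:
    """Genetic-algorithm hyperparameters (all conventional defaults)."""

    population_size: int = 50
    generations: int = 200
    tournament_size: int = 2
    crossover_prob: float = 0.9
    crossover_eta: float = 15.0   # SBX distribution index
    mutation_eta: float = 20.0    # polynomial-mutation index
    mutation_prob: float | None = None  # default 1/n_genes
    elitism: int = 1


@dataclass
class FitResult:
    """Fitted parameters with provenance for exact replay."""

    params: KineticParameters
    free_params: tuple[str, ...]
    objective_value: float
    ga_best_objective: float
    per_series: list[dict]
    ga_config: GAConfig
    seed: int
    bounds: dict[str, tuple[float, float]]
    convergence: list[tuple[int, float]]
    n_evaluations: int


def _sbx(rng, a, b, lo, hi, eta, prob):
    """Simulated-binary crossover on gene vectors (per-gene)."""
    c1, c2 = a.copy(), b.copy()
    do = rng.random(a.shape) < 0.5
    if rng.random() < prob:
        u = rng.random(a.shape)
        beta = np.where(u <= 0.5,
                        (2.0 * u) ** (1.0 / (eta + 1.0)),
                        (1.0 / (2.0 * (1.0 - u))) ** (1.0 / (eta + 1.0)))
        mean = 0.5 * (a + b)
        diff = 0.5 * np.abs(a - b)
        c1 = np.where(do, mean - beta * diff, a)
        c2 = np.where(do, mean + beta * diff, b)
    return np.clip(c1, lo, hi), np.clip(c2, lo, hi)


def _poly_mutation(rng, x, lo, hi, eta, prob):
    y = x.copy()
    span = hi - lo
    for j in range(len(x)):
        if rng.random() < prob and span[j] > 0:
            u = rng.random()
            if u < 0.5:
                delta = (2.0 * u) ** (1.0 / (eta + 1.0)) - 1.0
            else:
                delta = 1.0 - (2.0 * (1.0 - u)) ** (1.0 / (eta + 1.0))
            y[j] = np.clip(x[j] + delta * span[j], lo[j], hi[j])
    return y


def fit(series_list, free_params, bounds: dict[str, tuple[float, float]],
        *, profile: CellLineProfile, seed: int,
        ga_config: GAConfig = GAConfig(), refine: bool = True,
        refine_fatol: float = 1e-10, refine_maxfev: int = 5000,
        rtol: float = 1e-8, atol: float = 1e-10) -> FitResult:
    """Estimate the named constants by GA + simplex refinement.

    ``bounds`` maps each free parameter to a positive (lo, hi) search
    interval; the search runs in log10 space. ``seed`` is mandatory and
    makes the whole fit bit-reproducible.
    """
    free_params = tuple(free_params)
    if not free_params:
        raise ValueError("free_params must not be empty")
    for name in free_params:
        if name not in PARAM_NAMES:
            raise KeyError(f"unknown rate constant {name!r}")
        lo, hi = bounds[name]
        if lo <= 0 or hi <= lo:
            raise ValueError(
                f"bounds for {name} must satisfy 0 < lo < hi, "
                f"got ({lo}, {hi})")
    rng = np.random.default_rng(seed)
    lo = np.array([math.log10(bounds[n][0]) for n in free_params])
    hi = np.array([math.log10(bounds[n][1]) for n in free_params])
    n_genes = len(free_params)
    cfg = ga_config
    mut_prob = cfg.mutation_prob if cfg.mutation_prob is not None \
        else 1.0 / n_genes

    n_evals = 0

    def evaluate(genes: np.ndarray) -> float:
        nonlocal n_evals
        n_evals += 1
        if np.any(genes < lo - 1e-12) or np.any(genes > hi + 1e-12):
            return _PENALTY * (1.0 + float(np.sum(
                np.maximum(lo - genes, 0) + np.maximum(genes - hi, 0))))
        params = profile.params.with_values(
            **{n: 10.0 ** g for n, g in zip(free_params, genes)})
        return objective(params, series_list, profile, rtol=rtol, atol=atol)

    pop = lo + (hi - lo) * rng.random((cfg.population_size, n_genes))
    fitness = np.array([evaluate(ind) for ind in pop])
    convergence: list[tuple[int, float]] = [(0, float(fitness.min()))]

    for gen in range(1, cfg.generations + 1):
        order = np.argsort(fitness)
        elite = pop[order[:cfg.elitism]].copy()
        children = []
        while len(children) < cfg.population_size - cfg.elitism:
            idx = rng.integers(0, cfg.population_size,
                               size=(2, cfg.tournament_size))
            p1 = pop[idx[0][np.argmin(fitness[idx[0]])]]
            p2 = pop[idx[1][np.argmin(fitness[idx[1]])]]
            c1, c2 = _sbx(rng, p1, p2, lo, hi, cfg.crossover_eta,
                          cfg.crossover_prob)
            children.append(_poly_mutation(rng, c1, lo, hi,
                                           cfg.mutation_eta, mut_prob))
            if len(children) < cfg.population_size - cfg.elitism:
                children.append(_poly_mutation(rng, c2, lo, hi,
                                               cfg.mutation_eta, mut_prob))
        pop = np.vstack([elite, np.array(children)])
        fitness = np.array([evaluate(ind) for ind in pop])
        convergence.append((gen, float(fitness.min())))

    best_idx = int(np.argmin(fitness))
    best_genes = pop[best_idx].copy()
    ga_best = float(fitness[best_idx])

    final_genes, final_obj = best_genes, ga_best
    if refine:
        res = minimize(evaluate, best_genes, method="Nelder-Mead",
                       options={"fatol": refine_fatol, "xatol": 1e-10,
                                "maxfev": refine_maxfev})
        if res.fun <= ga_best:      # refinement never worsens the result
            final_genes, final_obj = np.clip(res.x, lo, hi), float(res.fun)

    fitted = profile.params.with_values(
        **{n: 10.0 ** g for n, g in zip(free_params, final_genes)})
    prof = profile.with_params(fitted)
    per_series = []
    for s in series_list:
        try:
            pred = predict_series(prof, s, rtol=rtol, atol=atol)
            sse, scale = _scaled_sse(s, pred)
            r2 = r_squared(s.values, scale * pred)
        except (SimulationError, ValueError):
            sse, scale, r2 = float("nan"), float("nan"), float("nan")
        per_series.append({"observable": s.observable, "sse": sse,
                           "r_squared": r2, "scale": scale,
                           "weight": s.weight})
    return FitResult(params=fitted, free_params=free_params,
                     objective_value=final_obj, ga_best_objective=ga_best,
                     per_series=per_series, ga_config=cfg, seed=int(seed),
                     bounds={n: tuple(bounds[n]) for n in free_params},
                     convergence=convergence, n_evaluations=n_evals)
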