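"""Local and global sensitivity analysis of glioblastoma growth.

Local analysis perturbs one rate constant at a time by a multiplying
factor in [0.1, 10] and summarizes the effect on the final tumor
diameter with a normalized sensitivity index

    SI = |GD_n − GD_o| / (C · T · Δk)        [hr⁻¹]

where GD_n / GD_o are the perturbed / reference final diameters, T the
simulation horizon in hours, Δk the multiplying factor and C a shared
diameter normalizer. C is defined as the maximum final diameter across
the whole sweep being summarized (including the reference run) by
default; a "control" normalizer (C = GD_o) is available. Note the
index is bounded above by 1/(T·Δk) whenever C ≥ max(GD_n, GD_o).

Global analysis draws a Latin-Hypercube design over all rate constants
(log-uniform over 0.1×–10× of fitted values by default), simulates the
final diameter for each sample, and attributes influence by partial
correlation (values-based or rank-based/PRCC, with two independent
computation routes) and by PCA of the standardized design + response.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import qmc, rankdata
from sklearn.decomposition import PCA

from .model import PARAM_NAMES, SPECIES_NAMES, CellLineProfile, Environment, KineticParameters
from .simulate import SimulationError, simulate

__all__ = [
    "SWEEP_PARAMS",
    "SensitivityRecord",
    "LhsDesign",
    "sensitivity_index",
    "local_sweep",
    "sensitivity_table",
    "initial_condition_sweep",
    "lhs_sample",
    "factor_ranges",
    "run_lhs_growth",
    "partial_correlation",
    "pca_summary",
]

#: The 13 constants of the single-constant sweep. k12 only rescales the
#: basal Hill denominator jointly with k9 and is excluded from the
#: canonical sweep set (it is still a valid argument to local_sweep).
SWEEP_PARAMS = tuple(n for n in PARAM_NAMES if n != "k12")


@dataclass(frozen=True)
class SensitivityRecord:
    """One (parameter, factor) perturbation result."""

    parameter: str
    factor: float
    gd_n: float          # perturbed final diameter, um
    gd_o: float          # reference final diameter, um
    normalizer: float    # C, um
    horizon: float       # T, hr
    index: float         # hr^-1
    failed: bool = False
    message: str = ""


def sensitivity_index(gd_n: float, gd_o: float, c: float, t: float,
                      dk: float) -> float:
    """Normalized sensitivity index |gd_n − gd_o| / (c·t·dk), hr⁻¹."""
    if c <= 0 or t <= 0 or dk <= 0:
        raise ValueError(
            f"normalizer, horizon and factor must be > 0 "
            f"(got c={c}, t={t}, dk={dk})"
        )
    return abs(gd_n - gd_o) / (c * t * dk)


def _final_gd(profile: CellLineProfile, horizon: float,
              env: Environment | None, rtol: float, atol: float) -> float:
    env = env if env is not None else profile.environment
    t_grid = np.linspace(0.0, horizon, max(int(horizon) + 1, 2))
    traj = simulate(profile, env, t_grid, rtol=rtol, atol=atol)
    return float(traj.gd[-1])


def local_sweep(profile: CellLineProfile, param: str,
                factors=(0.1, 10.0), *, horizon: float = 960.0,
                env: Environment | None = None,
                normalizer: str = "sweep-max",
                rtol: float = 1e-8, atol: float = 1e-10
                ) -> list[SensitivityRecord]:
    """Perturb one rate constant by each factor, all else fixed.

    Simulation failures are recorded per-factor (``failed=True``) and
    the sweep continues.
    """
    if param not in PARAM_NAMES:
        raise KeyError(f"unknown rate constant {param!r}")
    if normalizer not in ("sweep-max", "control"):
        raise ValueError("normalizer must be 'sweep-max' or 'control'")
    gd_o = _final_gd(profile, horizon, env, rtol, atol)
    runs: list[tuple[float, float, bool, str]] = []
    for f in factors:
        if f <= 0:
            raise ValueError(f"factors must be > 0, got {f}")
        try:
            gd_n = _final_gd(
                profile.with_params(profile.params.scaled(param, f)),
                horizon, env, rtol, atol)
            runs.append((float(f), gd_n, False, ""))
        except SimulationError as exc:
            runs.append((float(f), float("nan"), True, str(exc)))
    finals = [gd for _, gd, bad, _ in runs if not bad]
    c = max(finals + [gd_o]) if normalizer == "sweep-max" else gd_o
    out = []
    for f, gd_n, bad, msg in runs:
        idx = float("nan") if bad else sensitivity_index(gd_n, gd_o, c,
                                                         horizon, f)
        out.append(SensitivityRecord(parameter=param, factor=f, gd_n=gd_n,
                                     gd_o=gd_o, normalizer=c,
                                     horizon=horizon, index=idx,
                                     failed=bad, message=msg))
    return out


def sensitivity_table(profile: CellLineProfile, *,
                      params=SWEEP_PARAMS, factor: float = 10.0,
                      horizon: float = 960.0,
                      env: Environment | None = None,
                      normalizer: str = "sweep-max",
                      rtol: float = 1e-8, atol: float = 1e-10
                      ) -> pd.DataFrame:
    """One-factor sweep over every constant, sharing a single
    normalizer C across the whole set; sorted by descending index."""
    gd_o = _final_gd(profile, horizon, env, rtol, atol)
    rows = []
    for name in params:
        try:
            gd_n = _final_gd(
                profile.with_params(profile.params.scaled(name, factor)),
                horizon, env, rtol, atol)
            rows.append({"parameter": name, "factor": factor, "gd_n": gd_n,
                         "gd_o": gd_o, "failed": False})
        except SimulationError as exc:
            rows.append({"parameter": name, "factor": factor,
                         "gd_n": float("nan"), "gd_o": gd_o, "failed": True,
                         "message": str(exc)})
    df = pd.DataFrame(rows)
    finals = df.loc[~df["failed"], "gd_n"].tolist()
    c = max(finals + [gd_o]) if normalizer == "sweep-max" else gd_o
    df["normalizer"] = c
    df["horizon"] = horizon
    df["index"] = [
        float("nan") if bad else sensitivity_index(gd_n, gd_o, c, horizon,
                                                   factor)
        for gd_n, bad in zip(df["gd_n"], df["failed"])
    ]
    return df.sort_values("index", ascending=False, ignore_index=True)


def initial_condition_sweep(profile: CellLineProfile,
                            factors=(0.1, 10.0),
                            o2_levels=(2.0, 21.0), *,
                            horizon: float = 960.0,
                            rtol: float = 1e-8, atol: float = 1e-10
                            ) -> pd.DataFrame:
    """Vary each initial species by each factor (one at a time) and the
    oxygen level, reporting final species values and diameter.

    The control row (all factors 1, control O2) comes first.
    """
    for f in factors:
        if not (0.1 <= f <= 10.0):
            raise ValueError(f"factors must lie in [0.1, 10], got {f}")
    base_env = profile.environment
    rows = []

    def run(varied: str, factor: float, o2: float, prof: CellLineProfile):
        env = Environment(o2_percent=o2, igfi_total=base_env.igfi_total,
                          duration=horizon, added_igfi=base_env.added_igfi)
        t_grid = np.linspace(0.0, horizon, max(int(horizon) + 1, 2))
        traj = simulate(prof, env, t_grid, rtol=rtol, atol=atol)
        row = {"varied": varied, "factor": factor, "o2_percent": o2}
        for j, sp in enumerate(SPECIES_NAMES):
            row[f"final_{sp}"] = float(traj.states[-1, j])
        row["final_igfi_free"] = float(traj.igfi_free[-1])
        rows.append(row)

    run("control", 1.0, base_env.o2_percent, profile)
    for sp in SPECIES_NAMES:
        for f in factors:
            run(sp, f, base_env.o2_percent,
                profile.with_initial(profile.initial.scaled(sp, f)))
    for o2 in o2_levels:
        run("o2_percent", o2 / base_env.o2_percent, o2, profile)
    return pd.DataFrame(rows)


@dataclass
class LhsDesign:
    """A Latin-Hypercube sample over named parameter ranges.

    ``samples`` holds absolute parameter values, one row per sample;
    per dimension there is exactly one sample in each of ``n_samples``
    equal-probability strata (equal log-width strata for the default
    log-uniform scale)."""

    names: tuple[str, ...]
    ranges: dict[str, tuple[float, float]]
    scale: str
    seed: int
    samples: np.ndarray
    n_samples: int = field(init=False)

    def __post_init__(self) -> None:
        self.n_samples = self.samples.shape[0]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.samples, columns=list(self.names))


def factor_ranges(params: KineticParameters, lo: float = 0.1,
                  hi: float = 10.0, names=PARAM_NAMES
                  ) -> dict[str, tuple[float, float]]:
    """Per-parameter (lo×, hi×) ranges around fitted values."""
    return {n: (getattr(params, n) * lo, getattr(params, n) * hi)
            for n in names}


def lhs_sample(n: int, ranges: dict[str, tuple[float, float]],
               scale: str = "log", seed: int | None = None) -> LhsDesign:
    """Draw a seeded Latin-Hypercube design over the given ranges."""
    if n < 2:
        raise ValueError(f"need n >= 2 samples, got {n}")
    if scale not in ("log", "linear"):
        raise ValueError("scale must be 'log' or 'linear'")
    names = tuple(ranges)
    lo = np.array([ranges[k][0] for k in names], dtype=float)
    hi = np.array([ranges[k][1] for k in names], dtype=float)
    if np.any(lo < 0) or np.any(hi < lo):
        raise ValueError("ranges must satisfy 0 <= lo <= hi")
    degenerate = hi == lo
    if np.any(degenerate):
        warnings.warn(
            "degenerate range(s) (lo == hi) produce constant column(s): "
            + ", ".join(np.array(names)[degenerate]), stacklevel=2)
    if scale == "log" and np.any(lo <= 0):
        raise ValueError("log scale requires strictly positive lower bounds")
    sampler = qmc.LatinHypercube(d=len(names), seed=seed)
    u = sampler.random(n)
    if scale == "log":
        x = 10.0 ** (np.log10(lo) + (np.log10(hi) - np.log10(lo)) * u)
    else:
        x = lo + (hi - lo) * u
    x[:, degenerate] = lo[degenerate]
    return LhsDesign(names=names, ranges=dict(ranges), scale=scale,
                     seed=-1 if seed is None else int(seed), samples=x)


def run_lhs_growth(profile: CellLineProfile, design: LhsDesign, *,
                   horizon: float = 960.0, env: Environment | None = None,
                   rtol: float = 1e-8, atol: float = 1e-10) -> np.ndarray:
    """Final diameter for every design row (NaN where the solver
    failed)."""
    base = profile.params.as_dict()
    y = np.empty(design.n_samples)
    for i in range(design.n_samples):
        vals = dict(base)
        vals.update(dict(zip(design.names, design.samples[i])))
        prof = profile.with_params(KineticParameters.from_mapping(vals))
        try:
            y[i] = _final_gd(prof, horizon, env, rtol, atol)
        except SimulationError:
            y[i] = float("nan")
    return y


def _residual_partial_corr(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Partial correlation of each column of X with y, adjusting for
    all remaining columns by least-squares residualization."""
    n, d = X.shape
    out = np.empty(d)
    ones = np.ones((n, 1))
    for j in range(d):
        Z = np.column_stack([ones, np.delete(X, j, axis=1)])
        rx = X[:, j] - Z @ np.linalg.lstsq(Z, X[:, j], rcond=None)[0]
        ry = y - Z @ np.linalg.lstsq(Z, y, rcond=None)[0]
        out[j] = np.corrcoef(rx, ry)[0, 1]
    return out


def _precision_partial_corr(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Same coefficients from the inverse of the joint correlation
    matrix (independent route used for cross-validation)."""
    M = np.column_stack([X, y])
    R = np.corrcoef(M, rowvar=False)
    try:
        P = np.linalg.inv(R)
    except np.linalg.LinAlgError as exc:
        raise ValueError(
            "singular correlation matrix; partial correlation is "
            "undefined (collinear or constant columns?)"
        ) from exc
    d = X.shape[1]
    return np.array([-P[j, d] / np.sqrt(P[j, j] * P[d, d])
                     for j in range(d)])


def partial_correlation(design, response, *, method: str = "values",
                        engine: str = "residual") -> pd.Series:
    """Per-parameter partial correlation with the response.

    Parameters
    ----------
    design
        :class:`LhsDesign`, DataFrame, or (n, d) array.
    response
        Length-n response vector (e.g. final diameters).
    method
        ``"values"`` uses the values as given; ``"ranks"`` rank-
        transforms every column first (PRCC).
    engine
        ``"residual"`` (regression residualization) or ``"precision"``
        (inverse correlation matrix); the two agree to numerical
        precision and exist as independent cross-checks.
    """
    if isinstance(design, LhsDesign):
        names = list(design.names)
        X = design.samples
    elif isinstance(design, pd.DataFrame):
        names = list(design.columns)
        X = design.to_numpy(dtype=float)
    else:
        X = np.asarray(design, dtype=float)
        names = [f"x{j}" for j in range(X.shape[1])]
    y = np.asarray(response, dtype=float)
    ok = np.isfinite(X).all(axis=1) & np.isfinite(y)
    X, y = X[ok], y[ok]
    n, d = X.shape
    if n <= d + 2:
        raise ValueError(
            f"need more samples than parameters + 2 (n={n}, d={d})")
    if method not in ("values", "ranks"):
        raise ValueError("method must be 'values' or 'ranks'")
    if method == "ranks":
        X = np.apply_along_axis(rankdata, 0, X)
        y = rankdata(y)
    if engine == "residual":
        coef = _residual_partial_corr(X, y)
    elif engine == "precision":
        coef = _precision_partial_corr(X, y)
    else:
        raise ValueError("engine must be 'residual' or 'precision'")
    return pd.Series(coef, index=names, name="partial_correlation")


@dataclass
class PcaSummary:
    """PCA of the standardized (log-scaled) design, optionally with the
    response appended as an extra column."""

    columns: list[str]
    loadings: np.ndarray              # (n_components, n_columns), rows orthonormal
    explained_variance_ratio: np.ndarray
    scores: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        idx = [f"PC{i + 1}" for i in range(self.loadings.shape[0])]
        df = pd.DataFrame(self.loadings, index=idx, columns=self.columns)
        df.insert(0, "explained_variance_ratio",
                  self.explained_variance_ratio)
        return df


def pca_summary(design, response=None, *, log_params: bool = True,
                n_components: int | None = None) -> PcaSummary:
    """Standardized-variable PCA of the design (log10 by default)
    with the response appended when given."""
    if isinstance(design, LhsDesign):
        names = list(design.names)
        X = design.samples
    elif isinstance(design, pd.DataFrame):
        names = list(design.columns)
        X = design.to_numpy(dtype=float)
    else:
        X = np.asarray(design, dtype=float)
        names = [f"x{j}" for j in range(X.shape[1])]
    cols = np.log10(X) if log_params else X.copy()
    if response is not None:
        y = np.asarray(response, dtype=float).reshape(-1, 1)
        cols = np.column_stack([cols, y])
        names = names + ["response"]
    ok = np.isfinite(cols).all(axis=1)
    cols = cols[ok]
    std = cols.std(axis=0, ddof=0)
    std[std == 0] = 1.0
    Z = (cols - cols.mean(axis=0)) / std
    pca = PCA(n_components=n_components)
    scores = pca.fit_transform(Z)
    return PcaSummary(columns=names, loadings=pca.components_,
                      explained_variance_ratio=pca.explained_variance_ratio_,
                      scores=scores)
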