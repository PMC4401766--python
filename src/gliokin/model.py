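"""Core kinetic model of insulin signalling coupled to glioblastoma growth.

The model tracks four dynamic quantities — IGFBP2 (nM), the bound
IGFI–IGFBP2 complex (nM), HIF1α (μM) and the glioblastoma spheroid/tumor
diameter (μm) — under a constant oxygen tension. Free IGFI is not
integrated: the total ligand pool is conserved and partitioned between
free and bound forms, so the free concentration is recovered
algebraically at every instant.

Rate laws
---------
With B = [IGFBP2], I = [IGFI]_free, C = [complex], H = [HIF1α],
GD = diameter and O2 the oxygen level in percent:

    I      = I_total − C                                  (conservation)
    dB/dt  = k1·B·I·(1 − k2·B) − k3·I·B + k4·C − kd·B + k5·H
    dC/dt  = k3·I·B − k4·C − kd·C
    dH/dt  = k6·I − k7·O2·H + k8·H/(k12 + k9·H) + k10·B
    dGD/dt = v1 + k11·H

IGFBP2 production is logistic in B (capacity 1/k2) and proportional to
free ligand; HIF1α is produced basally through a Hill term that is
independent of oxygen, produced by IGFI and IGFBP2 inputs, and degraded
in proportion to oxygen; tumor diameter grows at a basal
glucose-dependent rate plus a HIF1α-proportional rate.

All species enter the rate laws as the numeric values in their native
units (nM, μM, μm) with no conversion factors — the fitted constants
absorb the unit bridging. The oxygen level is the percent number
(2–21), not a fraction.

Note on the complex dissociation flux: internal consistency between the
IGFBP2 and complex balances requires the dissociation flux leaving the
complex pool to equal the +k4·C flux entering the IGFBP2 pool, so k4 is
used by default. A ``strict_printed_dissociation`` toggle substitutes k3
for users who want the alternative (inconsistent) convention in which
the complex balance uses the binding constant for dissociation.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, fields, replace

import numpy as np

__all__ = [
    "PARAM_NAMES",
    "SPECIES_NAMES",
    "ConservationError",
    "SingularDenominatorError",
    "KineticParameters",
    "ModelState",
    "Environment",
    "CellLineProfile",
    "free_igfi",
    "digfbp2_dt",
    "dcomplex_dt",
    "dhif1a_dt",
    "dgd_dt",
    "rates",
    "volume_from_diameter",
    "diameter_from_volume",
]

#: Canonical ordering of the 14 rate constants.
PARAM_NAMES = (
    "k1", "k2", "k3", "k4", "k5", "k6", "k7", "k8", "k9", "k10",
    "k11", "k12", "kd", "v1",
)

#: Canonical ordering of the dynamic state variables.
SPECIES_NAMES = ("igfbp2", "complex", "hif1a", "gd")


class ConservationError(ValueError):
    """Bound complex exceeds the conserved total ligand pool."""


class SingularDenominatorError(ZeroDivisionError):
    """The Hill denominator k12 + k9·H evaluated to zero."""


@dataclass(frozen=True)
class KineticParameters:
    """The 14 rate constants of the model.

    Units follow the fitted parameter table: k1, k3 in hr⁻¹·nM⁻¹; k2 in
    nM⁻¹; k4, k5, k7, k8, k10, kd in hr⁻¹; k6 in nM⁻¹; k9 in μM⁻¹;
    k11, v1 in μm·hr⁻¹; k12 dimensionless. All must be non-negative.
    """

    k1: float   # IGFBP2 production
    k2: float   # logistic capacity factor of IGFBP2 production
    k3: float   # IGFI + IGFBP2 binding
    k4: float   # complex dissociation
    k5: float   # HIF1α → IGFBP2 promotion
    k6: float   # IGFI → HIF1α production
    k7: float   # O2-dependent HIF1α degradation
    k8: float   # basal HIF1α production (Hill numerator rate)
    k9: float   # Hill denominator coefficient
    k10: float  # IGFBP2 → HIF1α promotion
    k11: float  # HIF1α-driven diameter growth
    k12: float  # Hill denominator constant
    kd: float   # IGFBP2 / complex degradation
    v1: float   # basal glucose-dependent diameter growth

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not math.isfinite(v) or v < 0:
                raise ValueError(
                    f"rate constant {f.name} must be finite and >= 0, got {v!r}"
                )

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in PARAM_NAMES], dtype=float)

    def as_dict(self) -> dict[str, float]:
        return {n: getattr(self, n) for n in PARAM_NAMES}

    def with_values(self, **updates: float) -> "KineticParameters":
        """Copy with the named constants replaced."""
        return replace(self, **updates)

    def scaled(self, name: str, factor: float) -> "KineticParameters":
        """Copy with one constant multiplied by ``factor``."""
        if name not in PARAM_NAMES:
            raise KeyError(f"unknown rate constant {name!r}")
        return replace(self, **{name: getattr(self, name) * factor})

    @classmethod
    def from_mapping(cls, mapping: dict[str, float]) -> "KineticParameters":
        missing = [n for n in PARAM_NAMES if n not in mapping]
        if missing:
            raise KeyError(f"missing rate constant(s): {', '.join(missing)}")
        return cls(**{n: float(mapping[n]) for n in PARAM_NAMES})


@dataclass(frozen=True)
class ModelState:
    """Instantaneous values of the four dynamic variables.

    ``igfbp2`` and ``complex`` in nM, ``hif1a`` in μM, ``gd`` (diameter)
    in μm. Free IGFI is derived, not stored: see :meth:`igfi_free`.
    """

    igfbp2: float
    complex: float
    hif1a: float
    gd: float

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not math.isfinite(v) or v < 0:
                raise ValueError(
                    f"state variable {f.name} must be finite and >= 0, got {v!r}"
                )

    def as_array(self) -> np.ndarray:
        return np.array([self.igfbp2, self.complex, self.hif1a, self.gd])

    @classmethod
    def from_array(cls, y: np.ndarray) -> "ModelState":
        return cls(igfbp2=float(y[0]), complex=float(y[1]),
                   hif1a=float(y[2]), gd=float(y[3]))

    def igfi_free(self, igfi_total: float) -> float:
        """Free IGFI by conservation of the total ligand pool."""
        return free_igfi(igfi_total, self.complex)

    def scaled(self, name: str, factor: float) -> "ModelState":
        if name not in SPECIES_NAMES:
            raise KeyError(f"unknown state variable {name!r}")
        return replace(self, **{name: getattr(self, name) * factor})


@dataclass(frozen=True)
class Environment:
    """Constant external conditions for one simulation.

    ``o2_percent`` is the oxygen level as a percent number (the
    physiological range is 2–21; values outside it trigger a warning,
    not an error). ``igfi_total`` (nM) is the conserved ligand pool;
    ``added_igfi`` (nM) is an extra bolus added to the pool at t=0, used
    to emulate ligand-addition time-course experiments. ``duration`` is
    the default simulation span in hours.
    """

    o2_percent: float = 21.0
    igfi_total: float = 95.1
    duration: float = 960.0
    added_igfi: float = 0.0

    def __post_init__(self) -> None:
        if not (2.0 <= self.o2_percent <= 21.0):
            warnings.warn(
                f"o2_percent={self.o2_percent} is outside the calibrated "
                "range [2, 21]", stacklevel=2,
            )
        if self.duration <= 0:
            raise ValueError(f"duration must be > 0, got {self.duration}")
        if self.igfi_total < 0 or self.added_igfi < 0:
            raise ValueError("igfi_total and added_igfi must be >= 0")

    @property
    def igfi_total_effective(self) -> float:
        """Conserved ligand pool including any t=0 bolus."""
        return self.igfi_total + self.added_igfi


@dataclass(frozen=True)
class CellLineProfile:
    """Named bundle of rate constants, initial state and environment.

    The two bundled cell lines differ only in initial diameter and the
    growth constants v1 and k11: LN229 (strongly insulin-dependent
    growth) versus U87 (weakly insulin-dependent growth).
    """

    name: str
    params: KineticParameters
    initial: ModelState
    environment: Environment = Environment()

    def with_params(self, params: KineticParameters) -> "CellLineProfile":
        return replace(self, params=params)

    def with_initial(self, initial: ModelState) -> "CellLineProfile":
        return replace(self, initial=initial)

    def with_environment(self, environment: Environment) -> "CellLineProfile":
        return replace(self, environment=environment)


def free_igfi(igfi_total: float, complex_: float) -> float:
    """Free IGFI concentration (nM) by mass conservation.

    Raises :class:`ConservationError` if the bound complex exceeds the
    total pool.
    """
    if complex_ > igfi_total:
        raise ConservationError(
            f"bound complex ({complex_} nM) exceeds total IGFI "
            f"({igfi_total} nM); conservation violated"
        )
    return igfi_total - complex_


def digfbp2_dt(state: ModelState, env: Environment,
               p: KineticParameters) -> float:
    """Net IGFBP2 rate (nM/hr): logistic ligand-driven production minus
    binding, plus complex dissociation, minus degradation, plus
    HIF1α-driven promotion."""
    b = state.igfbp2
    i = state.igfi_free(env.igfi_total_effective)
    return (p.k1 * b * i * (1.0 - p.k2 * b)
            - p.k3 * i * b
            + p.k4 * state.complex
            - p.kd * b
            + p.k5 * state.hif1a)


def dcomplex_dt(state: ModelState, env: Environment, p: KineticParameters,
                strict_printed_dissociation: bool = False) -> float:
    """Net complex rate (nM/hr): binding minus dissociation minus
    degradation. ``strict_printed_dissociation`` uses k3 instead of k4
    for the dissociation flux (see module docstring)."""
    i = state.igfi_free(env.igfi_total_effective)
    k_diss = p.k3 if strict_printed_dissociation else p.k4
    return (p.k3 * i * state.igfbp2
            - k_diss * state.complex
            - p.kd * state.complex)


def dhif1a_dt(state: ModelState, env: Environment,
              p: KineticParameters) -> float:
    """Net HIF1α rate (μM/hr): IGFI-driven production, oxygen-dependent
    degradation, oxygen-independent basal (Hill) production and
    IGFBP2-driven promotion."""
    h = state.hif1a
    denom = p.k12 + p.k9 * h
    if denom != 0.0:
        hill = p.k8 * h / denom
    elif p.k8 * h == 0.0:
        hill = 0.0  # vanishing numerator: the basal term is absent
    else:
        raise SingularDenominatorError(
            f"Hill denominator k12 + k9*H = 0 at H={h}"
        )
    i = state.igfi_free(env.igfi_total_effective)
    return (p.k6 * i
            - p.k7 * env.o2_percent * h
            + hill
            + p.k10 * state.igfbp2)


def dgd_dt(state: ModelState, p: KineticParameters) -> float:
    """Diameter growth rate (μm/hr): basal plus HIF1α-proportional."""
    return p.v1 + p.k11 * state.hif1a


def rates(state: ModelState, env: Environment, p: KineticParameters,
          strict_printed_dissociation: bool = False) -> np.ndarray:
    """All four net rates in :data:`SPECIES_NAMES` order."""
    return np.array([
        digfbp2_dt(state, env, p),
        dcomplex_dt(state, env, p, strict_printed_dissociation),
        dhif1a_dt(state, env, p),
        dgd_dt(state, p),
    ])


def volume_from_diameter(gd: float) -> float:
    """Spheroid volume (μm³) of a sphere with diameter ``gd`` (μm)."""
    gd = np.asarray(gd, dtype=float)
    if np.any(gd < 0):
        raise ValueError(f"diameter must be >= 0, got {gd}")
    out = (4.0 / 3.0) * np.pi * (gd / 2.0) ** 3
    return float(out) if out.ndim == 0 else out


def diameter_from_volume(volume: float) -> float:
    """Inverse of :func:`volume_from_diameter`."""
    volume = np.asarray(volume, dtype=float)
    if np.any(volume < 0):
        raise ValueError(f"volume must be >= 0, got {volume}")
    out = 2.0 * (volume * 3.0 / (4.0 * np.pi)) ** (1.0 / 3.0)
    return float(out) if out.ndim == 0 else out
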