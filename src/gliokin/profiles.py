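"""Bundled cell-line parameterizations and flat config-file I/O.

Two glioblastoma cell lines ship with the package:

* ``U87`` — spheroid line whose growth is weakly dependent on insulin
  signalling (high basal growth v1, low HIF1α-driven growth k11;
  initial diameter 170 μm from hanging-drop spheroids).
* ``LN229`` — xenograft line strongly dependent on insulin signalling
  (low v1, high k11; initial diameter 3200 μm from tumor volumes).

All other constants and initial concentrations are shared between the
two lines. Profiles serialize to a flat key:value YAML mapping; the
loader validates that every required field is present.
"""

from __future__ import annotations

import dataclasses
import os

import yaml

from .model import (
    PARAM_NAMES,
    CellLineProfile,
    Environment,
    KineticParameters,
    ModelState,
)

__all__ = ["U87", "LN229", "BUNDLED", "get_profile", "load_profile",
           "save_profile", "ProfileError"]


class ProfileError(ValueError):
    """A profile config file is missing or malformed."""


_SHARED = dict(
    k1=0.0452,    # IGFBP2 production, hr^-1 nM^-1
    k2=0.0004,    # logistic capacity factor, nM^-1
    k3=0.0002,    # IGFI-IGFBP2 binding, hr^-1 nM^-1
    k4=0.0007,    # complex dissociation, hr^-1
    k5=9.5495,    # HIF1a -> IGFBP2 promotion
    k6=0.0001,    # IGFI -> HIF1a production
    k7=0.1176,    # O2-dependent HIF1a degradation, hr^-1 per percent O2
    k8=0.01057,   # basal HIF1a Hill rate, hr^-1
    k9=0.0241,    # Hill denominator coefficient, uM^-1
    k10=0.0002,   # IGFBP2 -> HIF1a promotion, hr^-1
    k12=21.0,     # Hill denominator constant, dimensionless
    kd=3.92702,   # IGFBP2/complex degradation, hr^-1
)

_INITIAL_SHARED = dict(igfbp2=3.68, complex=2.6, hif1a=1.0)

# Total IGFI = free (92.5 nM) + bound complex (2.6 nM).
_ENV = Environment(o2_percent=21.0, igfi_total=95.1, duration=960.0,
                   added_igfi=0.0)

U87 = CellLineProfile(
    name="U87",
    params=KineticParameters(v1=2.601, k11=21.6, **_SHARED),
    initial=ModelState(gd=170.0, **_INITIAL_SHARED),
    environment=_ENV,
)

LN229 = CellLineProfile(
    name="LN229",
    params=KineticParameters(v1=0.5779, k11=179.55, **_SHARED),
    initial=ModelState(gd=3200.0, **_INITIAL_SHARED),
    environment=_ENV,
)

BUNDLED: dict[str, CellLineProfile] = {"U87": U87, "LN229": LN229}

_STATE_KEYS = {
    "igfbp2_nM": "igfbp2",
    "complex_nM": "complex",
    "hif1a_uM": "hif1a",
    "gd_um": "gd",
}
_ENV_KEYS = {
    "o2_percent": "o2_percent",
    "igfi_total_nM": "igfi_total",
    "duration_hr": "duration",
    "added_igfi_nM": "added_igfi",
}


def get_profile(name: str) -> CellLineProfile:
    """Return a bundled profile by cell-line name."""
    try:
        return BUNDLED[name]
    except KeyError:
        raise ProfileError(
            f"unknown bundled profile {name!r}; available: "
            f"{sorted(BUNDLED)}"
        ) from None


def load_profile(path_or_name: str | os.PathLike) -> CellLineProfile:
    """Load a profile: a bundled name (``"U87"``/``"LN229"``) or a path
    to a flat key:value YAML config."""
    s = os.fspath(path_or_name)
    if s in BUNDLED:
        return BUNDLED[s]
    if not os.path.exists(s):
        raise ProfileError(
            f"{s!r} is neither a bundled profile name nor an existing file"
        )
    with open(s) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ProfileError(f"profile file {s!r} must be a flat key:value map")
    required = (["name"] + list(PARAM_NAMES) + list(_STATE_KEYS)
                + list(_ENV_KEYS))
    missing = [k for k in required if k not in raw]
    if missing:
        raise ProfileError(
            f"profile file {s!r} is missing required field(s): "
            f"{', '.join(missing)}"
        )
    params = KineticParameters.from_mapping(
        {n: float(raw[n]) for n in PARAM_NAMES})
    initial = ModelState(**{v: float(raw[k]) for k, v in _STATE_KEYS.items()})
    env = Environment(**{v: float(raw[k]) for k, v in _ENV_KEYS.items()})
    return CellLineProfile(name=str(raw["name"]), params=params,
                           initial=initial, environment=env)


def save_profile(profile: CellLineProfile, path: str | os.PathLike) -> None:
    """Write a profile as a flat key:value YAML config (lossless
    round-trip with :func:`load_profile`)."""
    flat: dict[str, object] = {"name": profile.name}
    flat.update(profile.params.as_dict())
    for key, attr in _STATE_KEYS.items():
        flat[key] = getattr(profile.initial, attr)
    for key, attr in _ENV_KEYS.items():
        flat[key] = getattr(profile.environment, attr)
    with open(path, "w") as fh:
        yaml.safe_dump(flat, fh, sort_keys=False)


def _as_dict(profile: CellLineProfile) -> dict:
    """JSON-friendly nested dict (used in run manifests)."""
    return {
        "name": profile.name,
        "params": profile.params.as_dict(),
        "initial": dataclasses.asdict(profile.initial),
        "environment": dataclasses.asdict(profile.environment),
    }
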