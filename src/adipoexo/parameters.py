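"""Model parameters: rate constants, compartment volumes and the measurement scale.

The kinetic model has 20 rate constants (units s^-1, composed with the
concentration unit of each mass-action partner), two physical volumes
(pipette and cell, in litres) and one measurement scaling constant
``kscale`` that maps the net exocytosis rate of the model onto the
measured capacitance rate (fF/s).  The published optimal set is exposed
as :data:`TABLE1`; the published search ranges as :data:`DEFAULT_BOUNDS`.

Rate constants are expressed per *second*; experiment time grids
throughout the package are in *minutes* (the unit of the recordings),
and the conversion happens once inside the simulator.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, fields, replace
from pathlib import Path

import numpy as np

__all__ = [
    "ModelParameters",
    "TABLE1",
    "DEFAULT_BOUNDS",
    "RATE_NAMES",
    "PARAM_NAMES",
]

#: The 20 free rate constants, in canonical order.
RATE_NAMES = (
    "krel", "kexo", "kCaATP", "kcAMP", "kCa2", "kATP2", "kEndo",
    "kCacAMP", "km", "kdegcAMP", "kremCa", "kdegATP", "kDiffcAMP",
    "kDiffCa", "kDiffATP", "kB", "kCL", "k1", "k2", "k3",
)

#: All searched parameters: rate constants followed by the two volumes.
PARAM_NAMES = RATE_NAMES + ("Vpip", "Vcell")

_RATE_RANGE = (1e-4, 1e4)
_VPIP_RANGE = (2e-5, 6e-5)      # 20-60 ul
_VCELL_RANGE = (8.6e-15, 171.7e-15)  # 8.6-171.7 fl

#: Search ranges used for parameter estimation.
DEFAULT_BOUNDS: dict[str, tuple[float, float]] = {
    **{name: _RATE_RANGE for name in RATE_NAMES},
    "Vpip": _VPIP_RANGE,
    "Vcell": _VCELL_RANGE,
}


@dataclass(frozen=True)
class ModelParameters:
    """Full parameter set of the exocytosis model.

    All rate constants must be strictly positive and inside the search
    range [1e-4, 1e4]; the volumes inside their physical ranges; the
    measurement scale ``kscale`` (fF/s per model rate unit) must be
    non-negative.  Instances are immutable; use :meth:`with_values` to
    derive modified copies.
    """

    krel: float
    kexo: float
    kCaATP: float
    kcAMP: float
    kCa2: float
    kATP2: float
    kEndo: float
    kCacAMP: float
    km: float
    kdegcAMP: float
    kremCa: float
    kdegATP: float
    kDiffcAMP: float
    kDiffCa: float
    kDiffATP: float
    kB: float
    kCL: float
    k1: float
    k2: float
    k3: float
    Vpip: float
    Vcell: float
    kscale: float = 1.0

    def __post_init__(self) -> None:
        for name in PARAM_NAMES:
            value = getattr(self, name)
            if not np.isfinite(value) or value <= 0.0:
                raise ValueError(f"parameter {name!r} must be strictly positive, got {value!r}")
        if not np.isfinite(self.kscale) or self.kscale < 0.0:
            raise ValueError(f"kscale must be non-negative, got {self.kscale!r}")

    # -- array / mapping views -------------------------------------------------

    def to_array(self) -> np.ndarray:
        """The 22 searched parameters as a float array in canonical order."""
        return np.array([getattr(self, n) for n in PARAM_NAMES], dtype=float)

    @classmethod
    def from_array(cls, values: np.ndarray, kscale: float = 1.0) -> "ModelParameters":
        values = np.asarray(values, dtype=float)
        if values.shape != (len(PARAM_NAMES),):
            raise ValueError(f"expected {len(PARAM_NAMES)} parameter values, got shape {values.shape}")
        return cls(**dict(zip(PARAM_NAMES, values)), kscale=kscale)

    def to_dict(self) -> dict[str, float]:
        return {f.name: float(getattr(self, f.name)) for f in fields(self)}

    def with_values(self, **updates: float) -> "ModelParameters":
        return replace(self, **updates)

    # -- bounds ----------------------------------------------------------------

    def within_bounds(self, bounds: dict[str, tuple[float, float]] | None = None) -> bool:
        """True if every searched parameter lies inside its (closed) range."""
        bounds = DEFAULT_BOUNDS if bounds is None else bounds
        return all(
            bounds[n][0] <= getattr(self, n) <= bounds[n][1] for n in PARAM_NAMES
        )

    # -- serialization ---------------------------------------------------------

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "ModelParameters":
        data = json.loads(Path(path).read_text())
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown parameter keys in {path}: {sorted(unknown)}")
        return cls(**data)


#: Published optimal parameter set (rate constants per second, volumes in litres).
TABLE1 = ModelParameters(
    krel=3.7356e-4,
    kexo=2.3764e-2,
    kCaATP=6.5771e1,
    kcAMP=5.9263e-2,
    kCa2=2.4300e-4,
    kATP2=2.2347e-2,
    kEndo=5.8257e2,
    kCacAMP=1.7826e1,
    km=7.2790e-3,
    kdegcAMP=3.3182e-4,
    kremCa=1.2482e-2,
    kdegATP=1.9718e3,
    kDiffcAMP=2.0835e-2,
    kDiffCa=4.4218e-2,
    kDiffATP=3.4721,
    kB=3.9240,
    kCL=5.6875e-3,
    k1=2.2070e-3,
    k2=2.4024e-2,
    k3=1.0046e-4,
    Vpip=2.1168e-5,
    Vcell=1.3990e-13,
    kscale=4.0,
)
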