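"""The 14-state kinetic model of adrenergically stimulated adiponectin exocytosis.

The model couples three subsystems:

* **Receptor cycling** — inactive (B), active (Bact) and desensitized
  (Bde) beta3-adrenergic receptors.  Epinephrine (EPI) or the selective
  agonist CL 316243 (CL) drive activation; the total receptor amount is
  conserved.
* **Intracellular mediators** — cAMP (produced downstream of Bact,
  degraded, and exchanged with the patch pipette), free Ca2+ and ATP
  (pipette exchange plus removal/degradation).  Pipette exchange is
  first-order diffusion gated by the binary ``pip`` flag, and flux into
  the pipette is scaled by the volume ratio Vcell/Vpip.
* **Vesicle trafficking** — a constant reserve pool (Res) feeds the
  releasable pool (Rel) under Ca2+/ATP control; cAMP triggers fusion of
  releasable vesicles with the plasma membrane pool (PM), from which
  vesicles are exocytosed or recycled; endocytosis is driven by the
  product of cAMP and Ca2+.

The measured quantity is the capacitance rate
``y_hat = kscale * (vExo - vEndo)`` in fF/s.

Units: rate constants are per second, cAMP/ATP in mM, Ca2+/EPI/CL in uM,
pool sizes in arbitrary units.  Time grids at the API are in minutes
(the unit of the recordings and figure axes).

The default initial condition uses a total receptor complement of 100
a.u. and pools Res = 4000, Rel = 1000 a.u.  These scales are part of the
model specification: together with the published rate constants they
place the stimulated response in the regime where exocytosis peaks
around two minutes, partial receptor knockdown is buffered
sub-proportionally, and Ca2+-dependent replenishment visibly sustains
the releasable pool (see docs/methods.md for the calibration rationale).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.integrate import ODEintWarning, odeint

from . import _kernels
from ._kernels import N_STATES, STATE_NAMES
from .parameters import ModelParameters
from .protocols import Protocol

__all__ = [
    "ModelState",
    "Trajectory",
    "SimulationError",
    "STATE_NAMES",
    "RECEPTOR_TOTAL",
    "RESERVE_POOL",
    "RELEASABLE_POOL",
    "derivatives",
    "initial_state",
    "simulate",
    "measurement",
]

#: Total beta3AR complement of an unperturbed cell (a.u.).
RECEPTOR_TOTAL = 100.0
#: Reserve vesicle pool size (a.u.); constant during a recording.
RESERVE_POOL = 4000.0
#: Initial releasable vesicle pool size (a.u.).
RELEASABLE_POOL = 1000.0

#: Negative values beyond this magnitude are treated as integrator failure.
_NEGATIVITY_TOLERANCE = 1e-9
#: Relative drift allowed in the conserved receptor total.
_CONSERVATION_TOLERANCE = 1e-6


class SimulationError(RuntimeError):
    """Integration failed or produced an invalid trajectory.

    Carries the offending parameter set so that estimation can map the
    failure to an infinite cost.
    """

    def __init__(self, message: str, params: ModelParameters | None = None):
        super().__init__(message)
        self.params = params


@dataclass(frozen=True)
class ModelState:
    """A snapshot of the 14 dynamic states."""

    B: float = 0.0
    Bact: float = 0.0
    Bde: float = 0.0
    cAMP: float = 0.0
    Ca: float = 0.0
    ATP: float = 0.0
    pipcAMP: float = 0.0
    pipCa: float = 0.0
    pipATP: float = 0.0
    Res: float = 0.0
    Rel: float = 0.0
    PM: float = 0.0
    Endo: float = 0.0
    Adiponectin: float = 0.0

    def to_array(self) -> np.ndarray:
        return np.array([getattr(self, name) for name in STATE_NAMES], dtype=float)

    @classmethod
    def from_array(cls, values: np.ndarray) -> "ModelState":
        values = np.asarray(values, dtype=float)
        if values.shape != (N_STATES,):
            raise ValueError(f"expected {N_STATES} state values, got shape {values.shape}")
        return cls(**dict(zip(STATE_NAMES, values)))

    @property
    def receptor_total(self) -> float:
        return self.B + self.Bact + self.Bde


@dataclass(frozen=True)
class Trajectory:
    """A simulated time course.

    ``times`` are in minutes with ``times[0] == 0``; ``states`` has one
    row per time point.  The derived fluxes (per second) are stored at
    simulation time: ``vExo = kexo*PM``, ``vEndo = kEndo*Endo``, the
    reserve-to-releasable transport ``vRes_Rel`` and the fusion rate
    ``vRel_PM``.
    """

    times: np.ndarray
    states: np.ndarray
    vExo: np.ndarray
    vEndo: np.ndarray
    vRes_Rel: np.ndarray
    vRel_PM: np.ndarray
    params: ModelParameters
    protocol: Protocol

    def state(self, name: str) -> np.ndarray:
        """Time series of one named state."""
        return self.states[:, STATE_NAMES.index(name)]

    def state_at(self, index: int) -> ModelState:
        return ModelState.from_array(self.states[index])

    @property
    def net_rate(self) -> np.ndarray:
        """Model-unit net exocytosis rate vExo - vEndo (before scaling)."""
        return self.vExo - self.vEndo

    def to_frame(self, kscale: float | None = None) -> pd.DataFrame:
        kscale = self.params.kscale if kscale is None else kscale
        frame = pd.DataFrame(self.states, columns=list(STATE_NAMES))
        frame.insert(0, "time_min", self.times)
        frame["vExo"] = self.vExo
        frame["vEndo"] = self.vEndo
        frame["y_hat"] = kscale * self.net_rate
        return frame

    def to_csv(self, path, kscale: float | None = None) -> None:
        self.to_frame(kscale=kscale).to_csv(path, index=False)


def initial_state(protocol: Protocol, receptor_total: float = RECEPTOR_TOTAL) -> ModelState:
    """Initial condition for a protocol.

    The cell starts at rest: all receptors inactive (scaled down by the
    knockdown fraction), mediator concentrations at their basal values
    (states measure the increase over basal, hence zero), pools at their
    resting sizes, and the pipette pre-loaded with its filling solution
    (irrelevant when ``pip = 0``).
    """
    kd = protocol.knockdown_fraction
    if not 0.0 <= kd <= 1.0:
        raise ValueError(f"knockdown_fraction must lie in [0, 1], got {kd!r}")
    return ModelState.from_array(_initial_array(protocol, receptor_total))


def _initial_array(protocol: Protocol, receptor_total: float) -> np.ndarray:
    state = np.zeros(N_STATES)
    state[0] = receptor_total * (1.0 - protocol.knockdown_fraction)
    if protocol.pip:
        state[6] = protocol.pipette_cAMP
        state[7] = protocol.pipette_Ca
        state[8] = protocol.pipette_ATP
    state[9] = RESERVE_POOL
    state[10] = RELEASABLE_POOL
    return state


def derivatives(state: ModelState, params: ModelParameters, protocol: Protocol) -> ModelState:
    """Right-hand side of the ODE system (per second), as a ModelState."""
    y = state.to_array()
    if np.any(y < 0):
        bad = [STATE_NAMES[i] for i in np.flatnonzero(y < 0)]
        raise ValueError(f"negative state components: {bad}")
    if protocol.pip not in (0, 1):
        raise ValueError(f"pip must be binary, got {protocol.pip!r}")
    dy = _kernels.rhs(y, 0.0, params.to_array(), protocol.EPI, protocol.CL,
                      float(protocol.pip))
    return ModelState.from_array(dy)


def simulate(
    params: ModelParameters,
    protocol: Protocol,
    times: np.ndarray,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> Trajectory:
    """Integrate the model over a strictly increasing time grid (minutes).

    Uses LSODA (stiff/non-stiff switching) with the analytic Jacobian;
    the ATP degradation rate makes the system stiff.  The trajectory is
    checked for receptor conservation and non-negativity; tiny negative
    solver noise (magnitude below 1e-9) is clipped to zero.
    """
    times = np.asarray(times, dtype=float)
    if times.ndim != 1 or times.size < 2:
        raise ValueError("times must be a 1-D grid with at least two points")
    if times[0] != 0.0:
        raise ValueError("times must start at 0")
    if np.any(np.diff(times) <= 0):
        raise ValueError("times must be strictly increasing")
    if protocol.pip not in (0, 1):
        raise ValueError(f"pip must be binary, got {protocol.pip!r}")

    y0 = _initial_array(protocol, RECEPTOR_TOTAL)
    k = params.to_array()
    args = (k, float(protocol.EPI), float(protocol.CL), float(protocol.pip))
    try:
        with warnings.catch_warnings():
            # failures are detected via the solver message and raised below
            warnings.simplefilter("ignore", ODEintWarning)
            states, info = odeint(
                _kernels.rhs, y0, times * 60.0, args=args, Dfun=_kernels.jacobian,
                rtol=rtol, atol=atol, mxstep=500_000, full_output=True,
            )
    except Exception as exc:  # pragma: no cover - solver-internal failures
        raise SimulationError(f"integration failed: {exc}", params) from exc
    if info["message"] != "Integration successful.":
        raise SimulationError(f"integration failed: {info['message']}", params)
    if not np.all(np.isfinite(states)):
        raise SimulationError("integration produced non-finite states", params)

    if np.any(states < -_NEGATIVITY_TOLERANCE):
        worst = float(states.min())
        raise SimulationError(f"state went negative ({worst:.3e})", params)
    states = np.clip(states, 0.0, None)

    total0 = y0[0] + y0[1] + y0[2]
    totals = states[:, 0] + states[:, 1] + states[:, 2]
    if total0 > 0 and np.max(np.abs(totals - total0)) > _CONSERVATION_TOLERANCE * total0:
        raise SimulationError("receptor conservation violated beyond tolerance", params)

    mm = states[:, 4] / (params.km + states[:, 4])
    return Trajectory(
        times=times,
        states=states,
        vExo=params.kexo * states[:, 11],
        vEndo=params.kEndo * states[:, 12],
        vRes_Rel=mm * (params.kCa2 + params.kATP2 * states[:, 5]) * states[:, 9],
        vRel_PM=states[:, 3] * (params.kcAMP + mm * states[:, 5] * params.kCaATP) * states[:, 10],
        params=params,
        protocol=protocol,
    )


def measurement(trajectory: Trajectory, kscale: float | None = None) -> np.ndarray:
    """Measured capacitance rate y_hat = kscale * (vExo - vEndo), in fF/s."""
    kscale = trajectory.params.kscale if kscale is None else kscale
    if kscale < 0:
        raise ValueError(f"kscale must be non-negative, got {kscale!r}")
    return kscale * trajectory.net_rate
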