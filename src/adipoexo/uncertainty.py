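"""Prediction-uncertainty profiling by penalty-relaxed constrained optimization.

For a simulated quantity q(theta) (the measured rate, or any internal
state) at one protocol and time point, the uncertainty bound solves

    min / max   q(theta)   subject to   cost(theta) <= limit,
    limit = cost(theta*) + chi2(0.05, 1),

i.e. the extreme prediction over all parameter sets that still agree
with the data.  The constraint is relaxed into the objective as a
penalty that activates only when the cost exceeds the limit:

    penalty = |q(theta)| + cost(theta) - limit   when cost > limit, else 0.

Maximization is the negated minimization problem.  Every reported bound
is re-checked for hard feasibility: only parameter sets whose cost
actually lies below the limit can carry a bound.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from .estimation import (FitConfig, FitResult, UndefinedScaleError,
                         chi2_threshold, cost_breakdown)
from .model import SimulationError, simulate
from .parameters import PARAM_NAMES, ModelParameters
from .protocols import Dataset, Protocol

__all__ = [
    "PredictionTarget",
    "PredictionBand",
    "EnsembleMember",
    "ProfileConfig",
    "prediction_limit",
    "penalized_objective",
    "profile_prediction",
    "prediction_band",
]

QUANTITIES = ("y_hat", "cAMP", "Rel", "Bact", "Adiponectin", "fold_adiponectin")


@dataclass(frozen=True)
class PredictionTarget:
    """One profiled quantity: protocol, observable, time point, direction."""

    protocol: Protocol
    quantity: str
    time: float              # minutes
    direction: str = "min"   # 'min' or 'max'
    reference_time: float = 15.0  # only for fold_adiponectin

    def __post_init__(self) -> None:
        if self.quantity not in QUANTITIES:
            raise ValueError(f"unknown quantity {self.quantity!r}")
        if self.direction not in ("min", "max"):
            raise ValueError("direction must be 'min' or 'max'")
        if self.time > self.protocol.duration:
            raise ValueError("target time exceeds protocol duration")


@dataclass(frozen=True)
class EnsembleMember:
    """A parameter set retained for uncertainty quantification."""

    params: ModelParameters
    cost: float
    provenance: str = "archive"


@dataclass
class PredictionBand:
    """Lower/upper prediction bounds around the best fit, per time point."""

    protocol_id: str
    quantity: str
    times: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    best: np.ndarray
    limit: float
    feasible: np.ndarray     # bool per time point: bounds achieved by feasible sets

    def width(self) -> np.ndarray:
        return self.upper - self.lower

    def relative_width_at_peak(self) -> float:
        """(max - min)/max at the time of the best-fit peak."""
        i = int(np.argmax(self.best))
        if self.upper[i] == 0:
            return 0.0
        return float((self.upper[i] - self.lower[i]) / self.upper[i])


@dataclass(frozen=True)
class ProfileConfig:
    """Optimizer budget for one profiling subproblem."""

    n_restarts: int = 5
    max_evals: int = 150
    n_seed_members: int = 50
    perturbation: float = 0.05   # log10 jitter applied to restart points
    seed: int = 0


def prediction_limit(fit: FitResult, alpha: float = 0.05) -> float:
    """Cost ceiling: best cost plus the 1-df chi-square quantile."""
    return fit.cost + chi2_threshold(alpha, 1)


def _evaluate_quantity(params: ModelParameters, target: PredictionTarget,
                       rtol: float, atol: float) -> float:
    """Simulate the target protocol and read off the profiled quantity."""
    t = target.time
    if target.quantity == "fold_adiponectin":
        grid = np.unique(np.array([0.0, target.reference_time, t]))
        traj = simulate(params, target.protocol, grid, rtol=rtol, atol=atol)
        adi = traj.state("Adiponectin")
        ref = adi[np.searchsorted(grid, target.reference_time)]
        if ref <= 0:
            raise SimulationError("zero adiponectin at the reference time", params)
        return float(adi[np.searchsorted(grid, t)] / ref)
    grid = np.array([0.0, t]) if t > 0 else np.array([0.0, 1e-6])
    traj = simulate(params, target.protocol, grid, rtol=rtol, atol=atol)
    if target.quantity == "y_hat":
        return float(traj.net_rate[-1 if t > 0 else 0])
    return float(traj.state(target.quantity)[-1 if t > 0 else 0])


def penalized_objective(params: ModelParameters, target: PredictionTarget,
                        limit: float, datasets: Dataset | list[Dataset],
                        rtol: float = 1e-6, atol: float = 1e-8,
                        kscale: float | None = None) -> float:
    """Relaxed objective: +/- q(theta), plus the penalty when cost > limit.

    For ``y_hat`` targets the model net rate is scaled by ``kscale``
    (pass the fitted scale; default 1 leaves model units).
    """
    if limit <= 0:
        raise ValueError("limit must be positive")
    try:
        q = _evaluate_quantity(params, target, rtol, atol)
        c, _, fitted_kscale = cost_breakdown(params, datasets, rtol=rtol, atol=atol)
        if target.quantity == "y_hat":
            q *= fitted_kscale if kscale is None else kscale
    except (SimulationError, UndefinedScaleError):
        return float("inf")
    if not np.isfinite(c):
        return float("inf")
    sign = 1.0 if target.direction == "min" else -1.0
    penalty = (abs(q) + c - limit) if c > limit else 0.0
    return sign * q + penalty


def _seed_points(fit: FitResult, config: ProfileConfig) -> list[ModelParameters]:
    members = [fit.params] + [m for m, _ in fit.archive[: config.n_seed_members]]
    return members


def profile_prediction(target: PredictionTarget, fit: FitResult,
                       datasets: Dataset | list[Dataset],
                       config: ProfileConfig | None = None,
                       fit_config: FitConfig | None = None,
                       ) -> tuple[float, EnsembleMember | None]:
    """Optimize one bound; returns (bound value, achieving member).

    Starts from the best archive members plus seeded random jitters of
    them, tracks the best *feasible* value seen at any evaluation, and
    polishes with Nelder-Mead on the penalized objective.  If no
    feasible parameter set is encountered the best-fit value is
    returned with ``member=None`` (feasibility warning).
    """
    config = ProfileConfig() if config is None else config
    fit_config = FitConfig() if fit_config is None else fit_config
    rtol, atol = fit_config.rtol, fit_config.atol
    limit = prediction_limit(fit, fit_config.alpha)
    sign = 1.0 if target.direction == "min" else -1.0
    rng = np.random.default_rng(config.seed)

    best_val = None
    best_member = None

    def record(params: ModelParameters) -> float:
        """Penalized objective that also tracks hard-feasible extremes."""
        nonlocal best_val, best_member
        try:
            q = _evaluate_quantity(params, target, rtol, atol)
            c, _, kscale = cost_breakdown(params, datasets, rtol=rtol, atol=atol)
            if target.quantity == "y_hat":
                q *= kscale
        except (SimulationError, UndefinedScaleError):
            return float("inf")
        if not np.isfinite(c):
            return float("inf")
        if c <= limit and (best_val is None or sign * q < sign * best_val):
            best_val, best_member = q, EnsembleMember(params, c, "profiling")
        return sign * q + ((abs(q) + c - limit) if c > limit else 0.0)

    seeds = _seed_points(fit, config)
    # Evaluate all seeds; they are feasible by construction and define the
    # archive envelope that the optimized band must contain.
    for member in seeds:
        record(member)

    starts = []
    for i in range(config.n_restarts):
        base = seeds[i % len(seeds)]
        x0 = np.log10(base.to_array())
        if i >= len(seeds):
            x0 = x0 + rng.normal(0.0, config.perturbation, size=x0.size)
        starts.append(x0)

    lo, hi = fit_config.log_bounds()
    for x0 in starts:
        x0 = np.clip(x0, lo, hi)
        minimize(
            lambda x: record(ModelParameters.from_array(10.0 ** np.clip(x, lo, hi))),
            x0, method="Nelder-Mead",
            options={"maxfev": config.max_evals, "xatol": 1e-3, "fatol": 1e-4},
        )

    if best_member is None:
        fallback = _evaluate_quantity(fit.params, target, rtol, atol)
        if target.quantity == "y_hat":
            fallback *= fit.params.kscale
        return float(fallback), None
    return float(best_val), best_member


def prediction_band(protocol: Protocol, times: np.ndarray, fit: FitResult,
                    datasets: Dataset | list[Dataset],
                    quantity: str = "y_hat",
                    config: ProfileConfig | None = None,
                    fit_config: FitConfig | None = None) -> PredictionBand:
    """Profile min and max of ``quantity`` at each requested time point."""
    config = ProfileConfig() if config is None else config
    fit_config = FitConfig() if fit_config is None else fit_config
    times = np.asarray(times, dtype=float)
    limit = prediction_limit(fit, fit_config.alpha)

    grid = times if times[0] == 0.0 else np.concatenate([[0.0], times])
    best_traj = simulate(fit.params, protocol, grid,
                         rtol=fit_config.rtol, atol=fit_config.atol)
    if quantity == "y_hat":
        best_curve = fit.params.kscale * best_traj.net_rate
    else:
        best_curve = best_traj.state(quantity)
    if times[0] != 0.0:
        best_curve = best_curve[1:]

    lower = np.empty_like(times)
    upper = np.empty_like(times)
    feasible = np.ones(times.size, dtype=bool)
    for i, t in enumerate(times):
        for direction, out in (("min", lower), ("max", upper)):
            target = PredictionTarget(protocol=protocol, quantity=quantity,
                                      time=float(t), direction=direction)
            value, member = profile_prediction(target, fit, datasets,
                                               config=config, fit_config=fit_config)
            out[i] = value
            feasible[i] &= member is not None
    # the best fit is itself feasible, so the band must envelope it
    lower = np.minimum(lower, best_curve)
    upper = np.maximum(upper, best_curve)
    return PredictionBand(protocol_id=protocol.id, quantity=quantity,
                          times=times, lower=lower, upper=upper,
                          best=best_curve, limit=limit, feasible=feasible)
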