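"""Parameter estimation: weighted least-squares cost, chi-square model test,
peak-timing constraints and the multi-start fitting pipeline.

The objective is the SEM-weighted sum of squared residuals over all
estimation datasets,

    cost(theta) = sum_{t,e} ((y_{t,e} - y_hat_{t,e}(theta)) / SEM_{t,e})^2,

compared against the upper 5% chi-square quantile with degrees of
freedom equal to the number of data points minus one (one degree is
consumed by the measurement scale).  The scale ``kscale`` is not a
search dimension: for any candidate rate-constant set it has a closed
form weighted least-squares solution, which is profiled out inside
every cost evaluation.

Search runs in log10 space over the published bounds (the rate
constants span eight decades).  A seeded Sobol screen generates
candidate start points; each selected start is refined with a bounded
trust-region least-squares solver.  Parameter sets whose stimulated
exocytosis peak falls outside the configured window are rejected
outright, mirroring the prior-knowledge constraint on peak timing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.optimize import least_squares
from scipy.stats import qmc

from .model import SimulationError, Trajectory, simulate
from .parameters import DEFAULT_BOUNDS, PARAM_NAMES, ModelParameters
from .protocols import Dataset

__all__ = [
    "FitConfig",
    "FitResult",
    "UndefinedScaleError",
    "fit_kscale",
    "cost",
    "cost_breakdown",
    "chi2_threshold",
    "passes_chi2",
    "peak_constraint_ok",
    "estimate_parameters",
]


class UndefinedScaleError(ValueError):
    """The measurement scale cannot be fitted (model rate is zero everywhere)."""


@dataclass(frozen=True)
class FitConfig:
    """Settings for the estimation pipeline.

    ``n_starts`` local refinements are launched from the best of
    ``n_candidates`` Sobol-screened points.  ``max_nfev`` bounds the
    residual evaluations per refinement (0 disables local refinement).
    Integration during fitting uses the (slightly relaxed) tolerances
    below; final reporting re-simulates at the model defaults.
    """

    bounds: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_BOUNDS))
    n_starts: int = 24
    n_candidates: int = 4096
    seed: int = 0
    rtol: float = 1e-6
    atol: float = 1e-8
    peak_window: tuple[float, float] = (1.0, 4.0)
    alpha: float = 0.05
    max_nfev: int = 300
    n_polish: int = 2
    polish_sigma: float = 0.2
    n_intensify: int = 8
    archive_size: int = 200

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")
        for name, (lo, hi) in self.bounds.items():
            if not (np.isfinite(lo) and np.isfinite(hi) and 0 < lo < hi):
                raise ValueError(f"invalid bounds for {name!r}: ({lo}, {hi})")

    def log_bounds(self) -> tuple[np.ndarray, np.ndarray]:
        lo = np.log10([self.bounds[n][0] for n in PARAM_NAMES])
        hi = np.log10([self.bounds[n][1] for n in PARAM_NAMES])
        return lo, hi


@dataclass
class FitResult:
    """Outcome of :func:`estimate_parameters`."""

    params: ModelParameters          # best set found, kscale fitted
    cost: float
    per_condition: dict[str, float]
    n_datapoints: int
    threshold: float
    passed: bool
    archive: list[tuple[ModelParameters, float]]   # feasible sets below threshold
    start_costs: list[float]         # final cost of each refinement start
    seed: int


# ---------------------------------------------------------------------------
# cost machinery
# ---------------------------------------------------------------------------

def fit_kscale(sim_rates: np.ndarray, means: np.ndarray, sems: np.ndarray) -> float:
    """Closed-form weighted least-squares measurement scale.

    Minimizes sum(((y - kscale*s)/SEM)^2) over kscale, where ``s`` is
    the per-observation model net rate; negative solutions are clamped
    to zero (the scale is physically non-negative).
    """
    s = np.asarray(sim_rates, float)
    y = np.asarray(means, float)
    w = 1.0 / np.asarray(sems, float) ** 2
    denom = np.sum(w * s * s)
    if denom == 0.0:
        raise UndefinedScaleError("all simulated rates are zero; kscale undefined")
    return max(0.0, float(np.sum(w * y * s) / denom))


def _estimation_datasets(datasets: Dataset | list[Dataset]) -> list[Dataset]:
    if isinstance(datasets, Dataset):
        datasets = [datasets]
    used = [d for d in datasets if d.role == "estimation"]
    if not used:
        raise ValueError("no estimation-role dataset supplied")
    return used


def _collect(params: ModelParameters, datasets: list[Dataset],
             rtol: float, atol: float):
    """Simulate every condition at its observation times.

    Returns (labels, sim_rates, means, sems) aligned per observation,
    or raises SimulationError.
    """
    labels, rates, means, sems = [], [], [], []
    for dataset in datasets:
        for cid in dataset.condition_ids:
            obs = [o for o in dataset.sorted_observations() if o.condition_id == cid]
            if not obs:
                continue
            times = np.array([o.time for o in obs])
            grid = times if times[0] == 0.0 else np.concatenate([[0.0], times])
            traj = simulate(params, dataset.protocols[cid], grid, rtol=rtol, atol=atol)
            net = traj.net_rate if times[0] == 0.0 else traj.net_rate[1:]
            labels.extend([cid] * len(obs))
            rates.extend(net.tolist())
            means.extend([o.mean for o in obs])
            sems.extend([o.sem for o in obs])
    return (np.array(labels), np.array(rates), np.array(means), np.array(sems))


def residuals(params: ModelParameters, datasets: Dataset | list[Dataset],
              rtol: float = 1e-6, atol: float = 1e-8) -> np.ndarray:
    """SEM-weighted residual vector with kscale profiled out."""
    used = _estimation_datasets(datasets)
    _, s, y, sem = _collect(params, used, rtol, atol)
    kscale = fit_kscale(s, y, sem)
    return (y - kscale * s) / sem


def cost(params: ModelParameters, datasets: Dataset | list[Dataset],
         rtol: float = 1e-6, atol: float = 1e-8) -> float:
    """Total weighted sum of squares; +inf on simulation failure."""
    try:
        r = residuals(params, datasets, rtol=rtol, atol=atol)
    except (SimulationError, UndefinedScaleError):
        return float("inf")
    return float(np.sum(r * r))


def cost_breakdown(params: ModelParameters, datasets: Dataset | list[Dataset],
                   rtol: float = 1e-6, atol: float = 1e-8
                   ) -> tuple[float, dict[str, float], float]:
    """(total cost, per-condition cost, fitted kscale)."""
    used = _estimation_datasets(datasets)
    labels, s, y, sem = _collect(params, used, rtol, atol)
    kscale = fit_kscale(s, y, sem)
    r2 = ((y - kscale * s) / sem) ** 2
    per = {cid: float(r2[labels == cid].sum()) for cid in np.unique(labels)}
    return float(r2.sum()), per, kscale


# ---------------------------------------------------------------------------
# chi-square test
# ---------------------------------------------------------------------------

def chi2_threshold(alpha: float, df: int) -> float:
    """Upper-alpha quantile of the chi-square distribution."""
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    if df < 1:
        raise ValueError("df must be >= 1")
    return float(stats.chi2.isf(alpha, df))


def passes_chi2(cost_value: float, n_datapoints: int,
                alpha: float = 0.05) -> tuple[bool, float]:
    """Chi-square model test at ``n_datapoints - 1`` degrees of freedom.

    One degree of freedom is consumed by the profiled measurement scale.
    The model is accepted iff cost < threshold (strict).
    """
    if n_datapoints < 2:
        raise ValueError("need at least 2 datapoints")
    threshold = chi2_threshold(alpha, n_datapoints - 1)
    return bool(cost_value < threshold), threshold


# ---------------------------------------------------------------------------
# peak-timing constraint
# ---------------------------------------------------------------------------

def peak_constraint_ok(trajectory: Trajectory, protocol=None,
                       window: tuple[float, float] = (1.0, 4.0)) -> bool:
    """True iff the exocytosis-rate peak falls inside ``window`` (minutes).

    The constraint encodes prior knowledge that extracellularly
    stimulated cells peak near two minutes; it is vacuously true for
    protocols without an adrenergic stimulus.
    """
    protocol = trajectory.protocol if protocol is None else protocol
    if not protocol.has_ec_stimulus:
        return True
    peak_time = trajectory.times[int(np.argmax(trajectory.net_rate))]
    return window[0] <= peak_time <= window[1]


def _constraints_ok(params: ModelParameters, datasets: list[Dataset],
                    config: FitConfig) -> bool:
    """Peak-window check on a 0.1-min grid for every stimulated condition."""
    grid = np.arange(0.0, 12.0 + 1e-9, 0.1)
    for dataset, cid in _ec_conditions(datasets):
        proto = dataset.protocols[cid]
        try:
            traj = simulate(params, proto, grid, rtol=config.rtol, atol=config.atol)
        except SimulationError:
            return False
        if not peak_constraint_ok(traj, proto, config.peak_window):
            return False
    return True


# ---------------------------------------------------------------------------
# multi-start estimation
# ---------------------------------------------------------------------------

def _params_from_log(x: np.ndarray) -> ModelParameters:
    return ModelParameters.from_array(10.0 ** np.asarray(x))


def _ec_conditions(datasets: list[Dataset]) -> list[tuple[Dataset, str]]:
    return [(d, cid) for d in datasets for cid in d.condition_ids
            if d.protocols[cid].has_ec_stimulus]


def estimate_parameters(datasets: Dataset | list[Dataset],
                        config: FitConfig | None = None) -> FitResult:
    """Multi-start global search with local trust-region refinement.

    Stage 1 screens a seeded Sobol sample of log-space candidates by
    cost and flags those whose stimulated exocytosis peak already falls
    inside the configured window.  Stage 2 refines ``n_starts`` starts
    along two complementary routes: peak-feasible starts are refined
    directly on the barrier-augmented residuals, while the best
    unconstrained starts are refined on the plain weighted residuals
    first and then "repaired" by a barrier refinement (the observation
    grids are too sparse to see a transient spike before the first
    post-zero time point, so unconstrained refinement alone is drawn
    into spurious early-spike optima).  The hinge barrier requires the
    response outside the peak window to stay below 97% of the in-window
    maximum.  Each start is polished by ``n_polish`` perturbation
    restarts, and ``n_intensify`` further restarts iterate around the
    incumbent.  Parameter sets violating the hard peak window are never
    returned as the optimum.

    Deterministic for a fixed ``config.seed``.  Every evaluated set
    that respects bounds and constraint and lands below the chi-square
    threshold is archived for later prediction profiling.
    """
    config = FitConfig() if config is None else config
    used = _estimation_datasets(datasets)
    n_obs = sum(len(d) for d in used)
    _, threshold = passes_chi2(0.0, n_obs, config.alpha)
    lo, hi = config.log_bounds()
    rng = np.random.default_rng(config.seed)

    ec = _ec_conditions(used)
    all_sems = [o.sem for d in used for o in d.observations]
    sem_scale = float(np.median(all_sems))
    w0, w1 = config.peak_window
    barrier_grid = np.round(np.arange(0.0, 12.0 + 1e-9, 0.1), 6)
    in_window = (barrier_grid >= w0) & (barrier_grid <= w1)
    n_pen = len(ec) * int((~in_window).sum())
    # The barrier demands a 3% clearance between the response outside the
    # window and its in-window maximum; the generating model satisfies
    # that with margin, while refined fits cannot park the peak on the
    # window edge.
    barrier_margin = 0.97
    barrier_weight = 10.0

    def eval_cost(x: np.ndarray) -> float:
        return cost(_params_from_log(x), used, rtol=config.rtol, atol=config.atol)

    def res_augmented(x: np.ndarray) -> np.ndarray:
        """Weighted residuals plus the peak-window hinge barrier."""
        try:
            params = _params_from_log(x)
            _, s, y, sem = _collect(params, used, config.rtol, config.atol)
            kscale = fit_kscale(s, y, sem)
            r = (y - kscale * s) / sem
            penalties = []
            for dataset, cid in ec:
                traj = simulate(params, dataset.protocols[cid], barrier_grid,
                                rtol=config.rtol, atol=config.atol)
                y_bar = kscale * traj.net_rate
                ceiling = barrier_margin * float(np.max(y_bar[in_window]))
                penalties.extend(
                    barrier_weight *
                    np.maximum(0.0, y_bar[~in_window] - ceiling) / sem_scale)
            return np.concatenate([r, penalties])
        except (SimulationError, UndefinedScaleError):
            return np.full(n_obs + n_pen, 1e6)

    def res_data(x: np.ndarray) -> np.ndarray:
        try:
            return residuals(_params_from_log(x), used,
                             rtol=config.rtol, atol=config.atol)
        except (SimulationError, UndefinedScaleError):
            return np.full(n_obs, 1e6)

    def trf(fn, x0: np.ndarray):
        return least_squares(fn, x0, bounds=(lo, hi), method="trf",
                             max_nfev=config.max_nfev, xtol=1e-10, ftol=1e-10,
                             x_scale="jac")

    # Stage 1: seeded Sobol screen; every candidate gets a cost, feasible
    # candidates (per the coarse peak check) are tracked separately.
    sampler = qmc.Sobol(d=len(PARAM_NAMES), scramble=True,
                        rng=np.random.default_rng(config.seed))
    candidates = qmc.scale(sampler.random(config.n_candidates), lo, hi)
    screen = np.array([eval_cost(x) for x in candidates])
    cost_order = np.argsort(screen, kind="stable")
    feasible_idx = [i for i, x in enumerate(candidates)
                    if np.isfinite(screen[i])
                    and _constraints_ok(_params_from_log(x), used, config)]
    feasible_order = sorted(feasible_idx, key=lambda i: screen[i])

    prearchive: list[tuple[np.ndarray, float]] = []
    best_x, best_cost = None, float("inf")
    start_costs: list[float] = []
    polish_sigmas = (config.polish_sigma, 2.5 * config.polish_sigma)

    def submit(x: np.ndarray) -> float:
        """Score a refined point; track archive and the feasible incumbent."""
        nonlocal best_x, best_cost
        c = eval_cost(x)
        if np.isfinite(c) and c < threshold:
            prearchive.append((x, c))
        if c < best_cost and _constraints_ok(_params_from_log(x), used, config):
            best_x, best_cost = x, c
        return c

    def polish(x_best: np.ndarray, aug_best: float) -> np.ndarray:
        for j in range(config.n_polish):
            sigma = polish_sigmas[j % len(polish_sigmas)]
            x_p = np.clip(x_best + rng.normal(0.0, sigma, x_best.size), lo, hi)
            sol = trf(res_augmented, x_p)
            if 2.0 * sol.cost < aug_best:
                x_best, aug_best = sol.x, 2.0 * sol.cost
        return x_best

    # Stage 2a: barrier refinement from peak-feasible starts (the deeper
    # minima almost always come from this route, so it gets most starts).
    n_feas = min(len(feasible_order), max(3 * config.n_starts // 4, 1))
    for idx in feasible_order[:n_feas]:
        submit(candidates[idx])  # refinement can only improve on the start
        if config.max_nfev == 0:
            start_costs.append(float(screen[idx]))
            continue
        sol = trf(res_augmented, candidates[idx])
        x_fin = polish(sol.x, 2.0 * sol.cost)
        start_costs.append(submit(x_fin))

    # Stage 2b: unconstrained refinement from the best-cost starts, then a
    # barrier "repair" step that pushes the peak into the window.
    n_unc = min(config.n_starts - n_feas, len(cost_order))
    for idx in cost_order[:n_unc]:
        if not np.isfinite(screen[idx]):
            continue
        submit(candidates[idx])
        if config.max_nfev == 0:
            start_costs.append(float(screen[idx]))
            continue
        sol = trf(res_data, candidates[idx])
        repaired = trf(res_augmented, sol.x)
        x_fin = polish(repaired.x, 2.0 * repaired.cost)
        start_costs.append(submit(x_fin))

    # Stage 3: intensification around the incumbent (iterated local search).
    if best_x is not None and config.max_nfev > 0:
        ladder = (0.5 * config.polish_sigma, 1.5 * config.polish_sigma,
                  3.0 * config.polish_sigma)
        incumbent = best_x
        for j in range(config.n_intensify):
            x_p = np.clip(incumbent + rng.normal(0.0, ladder[j % len(ladder)],
                                                 incumbent.size), lo, hi)
            sol = trf(res_augmented, x_p)
            submit(sol.x)
            incumbent = best_x

    # sub-threshold screened candidates also qualify for the archive
    prearchive.extend((candidates[i], float(screen[i])) for i in feasible_idx
                      if screen[i] < threshold)

    archive: list[tuple[ModelParameters, float]] = []
    seen: set[bytes] = set()
    for x, c in sorted(prearchive, key=lambda item: item[1]):
        key = np.round(x, 3).tobytes()
        if key in seen:
            continue
        seen.add(key)
        params = _params_from_log(x)
        if _constraints_ok(params, used, config):
            archive.append((params, c))
        if len(archive) >= config.archive_size:
            break

    if best_x is None:
        # No feasible set: report the bounds midpoint with infinite cost.
        mid = _params_from_log((lo + hi) / 2.0)
        return FitResult(params=mid, cost=float("inf"), per_condition={},
                         n_datapoints=n_obs, threshold=threshold, passed=False,
                         archive=[], start_costs=start_costs, seed=config.seed)

    total, per, kscale = cost_breakdown(_params_from_log(best_x), used,
                                        rtol=config.rtol, atol=config.atol)
    best = _params_from_log(best_x).with_values(kscale=kscale)
    return FitResult(params=best, cost=total, per_condition=per,
                     n_datapoints=n_obs, threshold=threshold,
                     passed=total < threshold, archive=archive,
                     start_costs=start_costs, seed=config.seed)
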