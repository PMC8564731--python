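"""Synthetic patch-clamp-like datasets for testing the analysis pipeline.

No public repository of the original capacitance recordings exists, so
the estimation, uncertainty and prediction stages are exercised against
generated data with the same statistical structure the analysis
assumes: sparse time courses (a handful of points over 0-12 min), a
known generating parameter set, Gaussian replicate noise whose standard
deviation is a fixed fraction of the trace maximum, and SEM = sd/sqrt(n)
with replicate counts in the published range (4-15 cells per point).

Because the SEM recorded for each point is the *known* noise standard
error (not a sample estimate), each standardized residual of the
generating model is exactly standard normal and the expected cost at
the true parameters equals the number of data points - the calibration
property the chi-square model test relies on.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .estimation import (FitConfig, FitResult, cost, estimate_parameters,
                         passes_chi2)
from .model import simulate
from .parameters import TABLE1, ModelParameters
from .protocols import Dataset, Observation, Protocol, builtin_protocols
from .uncertainty import ProfileConfig, prediction_band

__all__ = [
    "NoiseSpec",
    "TruthRecord",
    "RecoveryConfig",
    "RecoveryReport",
    "generate_dataset",
    "recovery_experiment",
]

DEFAULT_TIMES = np.array([0.0, 2.0, 4.0, 6.0, 8.0, 10.0, 12.0])


@dataclass(frozen=True)
class NoiseSpec:
    """Replicate structure of the generated observations.

    ``noise_fraction`` scales the per-replicate Gaussian noise sd as a
    fraction of the condition's maximal absolute measured rate;
    replicate counts are drawn uniformly from ``n_range`` per point.
    """

    n_range: tuple[int, int] = (4, 15)
    noise_fraction: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_range[0] < 2 or self.n_range[1] < self.n_range[0]:
            raise ValueError(f"invalid replicate range {self.n_range!r}")
        if self.noise_fraction <= 0:
            raise ValueError("noise fraction must be positive")


@dataclass
class TruthRecord:
    """Noise-free traces and the generating parameters."""

    params: ModelParameters
    times: dict[str, np.ndarray]
    y_true: dict[str, np.ndarray]    # fF/s, kscale applied


@dataclass(frozen=True)
class RecoveryConfig:
    """End-to-end harness settings: generate, fit, profile."""

    params_true: ModelParameters = TABLE1
    protocols: tuple[Protocol, ...] = tuple(builtin_protocols())
    times: tuple[float, ...] = tuple(DEFAULT_TIMES)
    noise: NoiseSpec = NoiseSpec()
    fit: FitConfig = field(default_factory=FitConfig)
    band_times: tuple[float, ...] = ()   # empty: skip band coverage
    band_protocol_id: str | None = None
    profile: ProfileConfig = ProfileConfig()
    seed: int = 0


@dataclass
class RecoveryReport:
    """Outcome of a generate-fit-profile round trip."""

    fit: FitResult
    truth: TruthRecord
    dataset: Dataset
    chi2_pass: bool
    cost_true: float
    fraction_within_3sem: float
    band_coverage: float | None       # fraction of profiled points covering truth


def generate_dataset(params_true: ModelParameters,
                     protocols: list[Protocol] | tuple[Protocol, ...] | None = None,
                     times: np.ndarray | None = None,
                     noise: NoiseSpec | None = None,
                     role: str = "estimation") -> tuple[Dataset, TruthRecord]:
    """Simulate each protocol, add replicate noise, record mean/SEM/n.

    For each condition the noise-free measured rate ``y_true(t)`` is
    simulated with ``params_true`` (including its kscale); per point,
    ``n`` replicates ``y_true + eps`` are drawn with
    ``eps ~ N(0, sd^2)``, ``sd = noise_fraction * max|y_true|`` over the
    trace, and the observation records the sample mean with the known
    ``SEM = sd/sqrt(n)``.
    """
    protocols = list(builtin_protocols()) if protocols is None else list(protocols)
    times = DEFAULT_TIMES if times is None else np.asarray(times, dtype=float)
    noise = NoiseSpec() if noise is None else noise
    rng = np.random.default_rng(noise.seed)

    observations: list[Observation] = []
    truth_times: dict[str, np.ndarray] = {}
    truth_y: dict[str, np.ndarray] = {}
    for proto in sorted(protocols, key=lambda p: p.id):
        grid = times if times[0] == 0.0 else np.concatenate([[0.0], times])
        traj = simulate(params_true, proto, grid)
        y_true = params_true.kscale * traj.net_rate
        if times[0] != 0.0:
            y_true = y_true[1:]
        truth_times[proto.id] = times.copy()
        truth_y[proto.id] = y_true
        sd = noise.noise_fraction * np.max(np.abs(y_true))
        if sd == 0.0:
            sd = noise.noise_fraction  # flat-zero trace: unit-scale floor
        for t, y in zip(times, y_true):
            n = int(rng.integers(noise.n_range[0], noise.n_range[1] + 1))
            replicates = y + rng.normal(0.0, sd, size=n)
            observations.append(Observation(
                condition_id=proto.id, time=float(t),
                mean=float(replicates.mean()), sem=float(sd / np.sqrt(n)), n=n,
            ))
    dataset = Dataset(protocols={p.id: p for p in protocols},
                      observations=observations, role=role)
    record = TruthRecord(params=params_true, times=truth_times, y_true=truth_y)
    return dataset, record


def recovery_experiment(config: RecoveryConfig | None = None) -> RecoveryReport:
    """Generate a dataset, refit the model, and score the recovery.

    Reports the chi-square verdict of the refit, the fraction of
    observation points where the refit prediction lies within 3 SEM of
    the noise-free truth, and (when band times are configured) the
    fraction of profiled points whose prediction band covers the truth.
    """
    config = RecoveryConfig() if config is None else config
    noise = NoiseSpec(n_range=config.noise.n_range,
                      noise_fraction=config.noise.noise_fraction,
                      seed=config.seed)
    dataset, truth = generate_dataset(config.params_true, config.protocols,
                                      np.asarray(config.times), noise)
    fit_config = FitConfig(**{**config.fit.__dict__, "seed": config.seed})
    fit = estimate_parameters(dataset, fit_config)

    cost_true = cost(config.params_true, dataset)
    chi2_pass, _ = passes_chi2(fit.cost, len(dataset), fit_config.alpha)

    # prediction vs noise-free truth, in SEM units
    within = 0
    total = 0
    sem_by_key = {(o.condition_id, o.time): o.sem for o in dataset.observations}
    for cid, times in truth.times.items():
        grid = times if times[0] == 0.0 else np.concatenate([[0.0], times])
        traj = simulate(fit.params, dataset.protocols[cid], grid)
        y_fit = fit.params.kscale * traj.net_rate
        if times[0] != 0.0:
            y_fit = y_fit[1:]
        for t, yt, yf in zip(times, truth.y_true[cid], y_fit):
            total += 1
            if abs(yf - yt) <= 3.0 * sem_by_key[(cid, float(t))]:
                within += 1
    fraction = within / total if total else float("nan")

    band_coverage = None
    if config.band_times and config.band_protocol_id:
        proto = dataset.protocols[config.band_protocol_id]
        band_times = np.asarray(config.band_times, dtype=float)
        band = prediction_band(proto, band_times, fit, dataset,
                               config=config.profile, fit_config=fit_config)
        t_truth = truth.times[proto.id]
        y_truth = truth.y_true[proto.id]
        covered = 0
        for t, lo, hi in zip(band.times, band.lower, band.upper):
            yt = float(np.interp(t, t_truth, y_truth))
            if lo - 1e-9 <= yt <= hi + 1e-9:
                covered += 1
        band_coverage = covered / band.times.size

    return RecoveryReport(fit=fit, truth=truth, dataset=dataset,
                          chi2_pass=chi2_pass, cost_true=cost_true,
                          fraction_within_3sem=fraction,
                          band_coverage=band_coverage)
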