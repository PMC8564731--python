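"""Cost function, kscale profiling, chi-square test and constraint logic."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import adipoexo as ax
from adipoexo.estimation import UndefinedScaleError, fit_kscale, residuals
from adipoexo.protocols import Dataset, Observation, Protocol


# ---------------------------------------------------------------------------
# kscale profiling
# ---------------------------------------------------------------------------

def test_kscale_exact_weighted_least_squares():
    assert fit_kscale([1, 2], [2, 4], [1, 1]) == pytest.approx(2.0)
    # hand-evaluated closed form with unequal SEMs:
    # (2*1/1 + 4*2/4) / (1/1 + 4/4) = 4/2 = 2
    assert fit_kscale([1, 2], [2, 4], [1, 2]) == pytest.approx(2.0)


def test_kscale_clamped_to_zero_and_degenerate_input():
    assert fit_kscale([1.0], [-3.0], [1.0]) == 0.0
    with pytest.raises(UndefinedScaleError):
        fit_kscale([0.0, 0.0], [1.0, 2.0], [1.0, 1.0])


@settings(deadline=None, max_examples=50)
@given(st.integers(2, 8), st.integers(0, 1000))
def test_kscale_beats_grid_search_oracle(n, seed):
    rng = np.random.default_rng(seed)
    s = rng.normal(0, 1, n)
    if np.all(s == 0):
        s[0] = 1.0
    y = rng.normal(0, 2, n)
    sem = rng.uniform(0.2, 2.0, n)
    k_star = fit_kscale(s, y, sem)

    def sse(k):
        return float(np.sum(((y - k * s) / sem) ** 2))

    grid = np.linspace(0.0, max(1.0, 3 * abs(k_star)), 20001)
    k_grid = grid[np.argmin([sse(k) for k in grid])]
    assert sse(k_star) <= sse(k_grid) + 1e-6


# ---------------------------------------------------------------------------
# cost
# ---------------------------------------------------------------------------

def _dataset_with(observations, protocols):
    return Dataset(protocols=protocols, observations=observations)


def test_cost_is_zero_for_a_perfect_fit(table1, protocols):
    proto = protocols["CL1_ATP3"]
    times = np.array([2.0, 6.0, 12.0])
    traj = ax.simulate(table1, proto, np.concatenate([[0.0], times]))
    y = 2.5 * traj.net_rate[1:]
    obs = [Observation(proto.id, t, m, 0.4, 5) for t, m in zip(times, y)]
    dataset = _dataset_with(obs, {proto.id: proto})
    assert ax.cost(table1, dataset, rtol=1e-8, atol=1e-10) == pytest.approx(0.0, abs=1e-8)


def test_cost_matches_hand_computed_sum(table1, protocols):
    # three-point fixture: cost = sum(((y - kscale*s)/sem)^2) with kscale
    # fixed by the closed form; verified against a by-hand evaluation
    proto = protocols["CL1_ATP3"]
    times = np.array([2.0, 6.0, 12.0])
    traj = ax.simulate(table1, proto, np.concatenate([[0.0], times]),
                       rtol=1e-6, atol=1e-8)
    s = traj.net_rate[1:]
    y = np.array([10.0, 5.0, 1.0])
    sem = np.array([2.0, 1.0, 0.5])
    kscale = fit_kscale(s, y, sem)
    expected = float(np.sum(((y - kscale * s) / sem) ** 2))
    obs = [Observation(proto.id, t, m, e, 5) for t, m, e in zip(times, y, sem)]
    dataset = _dataset_with(obs, {proto.id: proto})
    assert ax.cost(table1, dataset) == pytest.approx(expected, rel=1e-9)
    total, per, k = ax.cost_breakdown(table1, dataset)
    assert total == pytest.approx(expected, rel=1e-9)
    assert per[proto.id] == pytest.approx(expected, rel=1e-9)
    assert k == pytest.approx(kscale)


def test_doubling_all_sems_divides_cost_by_four(table1, protocols):
    proto = protocols["CTRL_cAMP_ATP"]
    times = np.array([2.0, 6.0, 12.0])
    obs = [Observation(proto.id, t, m, 0.8, 5) for t, m in zip(times, [4.0, 2.0, 1.0])]
    wide = [Observation(proto.id, o.time, o.mean, 2 * o.sem, o.n) for o in obs]
    d1 = _dataset_with(obs, {proto.id: proto})
    d2 = _dataset_with(wide, {proto.id: proto})
    assert ax.cost(table1, d2) == pytest.approx(ax.cost(table1, d1) / 4.0, rel=1e-9)


def test_cost_invariant_under_condition_relabelling_and_reordering(table1, small_dataset):
    dataset, _ = small_dataset
    base = ax.cost(table1, dataset)
    shuffled = Dataset(protocols=dict(dataset.protocols),
                       observations=list(reversed(dataset.observations)))
    assert ax.cost(table1, shuffled) == pytest.approx(base, rel=1e-12)
    renamed_protocols = {}
    renamed_obs = []
    for cid, proto in dataset.protocols.items():
        new = f"z_{cid}"
        renamed_protocols[new] = Protocol(**{**proto.to_dict(), "id": new})
    for o in dataset.observations:
        renamed_obs.append(Observation(f"z_{o.condition_id}", o.time, o.mean, o.sem, o.n))
    renamed = Dataset(protocols=renamed_protocols, observations=renamed_obs)
    assert ax.cost(table1, renamed) == pytest.approx(base, rel=1e-12)


def test_validation_role_datasets_are_excluded_from_the_cost(table1, small_dataset):
    dataset, _ = small_dataset
    val = Dataset(protocols=dict(dataset.protocols),
                  observations=list(dataset.observations), role="validation")
    assert ax.cost(table1, [dataset, val]) == pytest.approx(
        ax.cost(table1, dataset), rel=1e-12)
    with pytest.raises(ValueError, match="estimation"):
        ax.cost(table1, val) != ax.cost(table1, val)  # no estimation data at all


# ---------------------------------------------------------------------------
# chi-square test
# ---------------------------------------------------------------------------

def test_chi2_threshold_published_and_oracle_values():
    assert ax.chi2_threshold(0.05, 24) == pytest.approx(36.4, abs=0.05)
    assert ax.chi2_threshold(0.05, 6) == pytest.approx(12.6, abs=0.05)
    assert ax.chi2_threshold(0.05, 1) == pytest.approx(3.841, abs=5e-4)
    with pytest.raises(ValueError):
        ax.chi2_threshold(0.0, 5)
    with pytest.raises(ValueError):
        ax.chi2_threshold(0.05, 0)


def test_passes_chi2_uses_n_minus_one_df_and_strict_inequality():
    ok, thr = ax.passes_chi2(28.4, 25)
    assert ok and thr == pytest.approx(36.4, abs=0.05)
    ok, thr = ax.passes_chi2(12.1, 7)
    assert ok and thr == pytest.approx(12.6, abs=0.05)
    at_limit, thr = ax.passes_chi2(ax.chi2_threshold(0.05, 9), 10)
    assert not at_limit


# ---------------------------------------------------------------------------
# peak constraint
# ---------------------------------------------------------------------------

def test_peak_constraint_on_simulated_trajectories(table1, protocols):
    grid = np.linspace(0, 12, 241)
    traj = ax.simulate(table1, protocols["CL1_ATP3"], grid)
    assert ax.peak_constraint_ok(traj, window=(1.0, 4.0))
    assert not ax.peak_constraint_ok(traj, window=(5.0, 8.0))
    # no extracellular stimulus: vacuously satisfied regardless of shape
    quiet = ax.simulate(table1, protocols["CTRL_cAMP_ATP"], grid)
    assert ax.peak_constraint_ok(quiet, window=(5.0, 8.0))


# ---------------------------------------------------------------------------
# estimation pipeline
# ---------------------------------------------------------------------------

def test_fit_result_contract(small_fit, small_dataset, small_fit_config):
    dataset, _ = small_dataset
    fit = small_fit
    assert fit.n_datapoints == len(dataset)
    assert fit.passed == (fit.cost < fit.threshold)
    assert fit.params.within_bounds(small_fit_config.bounds)
    for params, archived_cost in fit.archive:
        assert params.within_bounds(small_fit_config.bounds)
        assert archived_cost >= fit.cost - 1e-9
        assert archived_cost < fit.threshold


def test_estimation_is_deterministic_given_seed(small_dataset):
    dataset, _ = small_dataset
    config = ax.FitConfig(n_candidates=128, n_starts=1, max_nfev=40,
                          n_polish=0, seed=3)
    a = ax.estimate_parameters(dataset, config)
    b = ax.estimate_parameters(dataset, config)
    assert a.params == b.params
    assert a.cost == b.cost
    assert a.start_costs == b.start_costs


def test_local_refinement_never_hurts(small_dataset):
    dataset, _ = small_dataset
    screen_only = ax.FitConfig(n_candidates=128, n_starts=2, max_nfev=0, seed=5)
    refined = ax.FitConfig(n_candidates=128, n_starts=2, max_nfev=100,
                           n_polish=0, seed=5)
    a = ax.estimate_parameters(dataset, screen_only)
    b = ax.estimate_parameters(dataset, refined)
    assert b.cost <= a.cost + 1e-9
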