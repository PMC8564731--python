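"""Unit and property tests of the ODE core: derivatives, invariants, oracles."""

import numpy as np
import pytest

import adipoexo as ax
from adipoexo import _kernels
from adipoexo.model import (RECEPTOR_TOTAL, RELEASABLE_POOL, RESERVE_POOL,
                            ModelState, initial_state)
from adipoexo.protocols import Protocol


def minutes(*vals):
    return np.asarray(vals, dtype=float)


# ---------------------------------------------------------------------------
# derivatives
# ---------------------------------------------------------------------------

def test_zero_state_without_stimulus_has_zero_derivatives(table1):
    proto = Protocol(id="rest", pip=0)
    deriv = ax.derivatives(ModelState(), table1, proto)
    assert all(getattr(deriv, n) == 0.0 for n in ax.model.STATE_NAMES)


def test_receptor_activation_term_matches_direct_substitution(table1):
    # B = 1, everything else 0, EPI = 5: d(B)/dt = -5*kB, d(Bact)/dt = +5*kB
    proto = Protocol(id="epi", pip=0, EPI=5.0)
    deriv = ax.derivatives(ModelState(B=1.0), table1, proto)
    assert deriv.B == pytest.approx(-5.0 * table1.kB, rel=1e-12)
    assert deriv.Bact == pytest.approx(5.0 * table1.kB, rel=1e-12)
    assert deriv.Bde == 0.0
    assert deriv.Rel == deriv.PM == deriv.Adiponectin == 0.0


def test_cl_stimulus_is_weighted_by_kcl(table1):
    proto = Protocol(id="cl", pip=0, CL=2.0)
    deriv = ax.derivatives(ModelState(B=1.0), table1, proto)
    assert deriv.Bact == pytest.approx(2.0 * table1.kCL * table1.kB, rel=1e-12)


def test_pipette_flux_conserves_volume_weighted_mass(table1):
    # d/dt(Vcell*cAMP + Vpip*pipcAMP) = 0 when production and degradation
    # are absent: the cell flux and pipette flux cancel after scaling.
    proto = Protocol(id="pip", pip=1)
    state = ModelState(cAMP=1.0, pipcAMP=0.0)
    deriv = ax.derivatives(state, table1, proto)
    # remove the degradation contribution analytically
    d_camp = deriv.cAMP + table1.kdegcAMP * state.cAMP
    assert table1.Vcell * d_camp + table1.Vpip * deriv.pipcAMP == pytest.approx(0.0, abs=1e-18)


def test_negative_state_is_rejected(table1):
    proto = Protocol(id="x", pip=0)
    with pytest.raises(ValueError, match="negative"):
        ax.derivatives(ModelState(Ca=-1e-3), table1, proto)


def test_analytic_jacobian_matches_finite_differences(table1):
    rng = np.random.default_rng(0)
    y = np.abs(rng.normal(1.0, 1.0, 14))
    k = table1.to_array()
    J = _kernels.jacobian(y, 0.0, k, 5.0, 1.0, 1.0)
    for j in range(14):
        h = 1e-7 * max(1.0, abs(y[j]))
        e = np.zeros(14)
        e[j] = h
        col = (_kernels.rhs(y + e, 0.0, k, 5.0, 1.0, 1.0)
               - _kernels.rhs(y - e, 0.0, k, 5.0, 1.0, 1.0)) / (2 * h)
        assert np.allclose(J[:, j], col, rtol=1e-5, atol=1e-6 * max(1.0, np.abs(col).max()))


# ---------------------------------------------------------------------------
# initial conditions
# ---------------------------------------------------------------------------

def test_initial_state_loads_pipette_and_scales_receptors():
    proto = Protocol(id="atp", pipette_ATP=3.0, knockdown_fraction=0.3)
    state = initial_state(proto)
    assert state.pipATP == 3.0
    assert state.ATP == 0.0
    assert state.B == pytest.approx(0.7 * RECEPTOR_TOTAL)
    assert state.Bact == state.Bde == 0.0


def test_initial_state_without_pipette_has_empty_pipette_states():
    proto = Protocol(id="bath", pip=0, EPI=5.0)
    state = initial_state(proto)
    assert state.pipcAMP == state.pipCa == state.pipATP == 0.0
    assert state.Res == RESERVE_POOL
    assert state.Rel == RELEASABLE_POOL
    assert state.PM == state.Endo == state.Adiponectin == 0.0


# ---------------------------------------------------------------------------
# simulation invariants
# ---------------------------------------------------------------------------

def test_no_stimulus_means_no_measured_signal(table1):
    proto = Protocol(id="quiet", pip=1, pipette_ATP=3.0, duration=30.0)
    traj = ax.simulate(table1, proto, minutes(0, 5, 10, 20, 30))
    assert np.all(ax.measurement(traj) == 0.0)
    assert np.all(traj.state("Adiponectin") == 0.0)


def test_receptor_total_is_conserved_along_trajectories(table1, protocols):
    for proto in protocols.values():
        traj = ax.simulate(table1, proto, np.linspace(0, 12, 25))
        totals = traj.state("B") + traj.state("Bact") + traj.state("Bde")
        assert np.max(np.abs(totals - RECEPTOR_TOTAL)) < 1e-6 * RECEPTOR_TOTAL


def test_no_exocytosis_without_camp(table1):
    # Ca and ATP alone cannot trigger fusion: cAMP gates vRel_PM.
    proto = Protocol(id="ca_atp", pipette_Ca=1.5, pipette_ATP=3.0, duration=30.0)
    traj = ax.simulate(table1, proto, np.linspace(0, 30, 61))
    # zero up to solver noise far below the integration tolerance
    assert np.all(traj.state("cAMP") < 1e-15)
    assert np.all(traj.vRel_PM < 1e-12)
    assert np.all(traj.state("Adiponectin") < 1e-9)


def test_releasable_pool_depletion_halts_exocytosis(table1):
    # without Ca there is no replenishment: Rel is non-increasing and the
    # measured rate decays towards zero after the peak
    proto = Protocol(id="cl", CL=1.0, pipette_ATP=3.0, duration=60.0)
    traj = ax.simulate(table1, proto, np.linspace(0, 60, 121))
    rel = traj.state("Rel")
    assert np.all(np.diff(rel) <= 1e-9 * rel[0])
    y = traj.net_rate
    assert y[-1] < 0.01 * y.max()


def test_simulation_requires_grid_starting_at_zero(table1, protocols):
    with pytest.raises(ValueError, match="start at 0"):
        ax.simulate(table1, protocols["CL1_ATP3"], minutes(1, 2, 3))
    with pytest.raises(ValueError, match="increasing"):
        ax.simulate(table1, protocols["CL1_ATP3"], minutes(0, 2, 2))


def test_pipette_only_camp_step_matches_closed_form(table1):
    # With production and degradation switched off in the kernel and the
    # cell-to-pipette volume ratio negligible, the cAMP equation is linear:
    # cAMP(t) = pipcAMP0 * (1 - exp(-kDiffcAMP * t)).
    from scipy.integrate import odeint

    k = table1.to_array()
    k[[9, 19]] = 0.0          # kdegcAMP, k3
    y0 = np.zeros(14)
    y0[6] = 0.1               # pipette cAMP, mM
    t_sec = np.linspace(0.0, 600.0, 21)
    sol = odeint(_kernels.rhs, y0, t_sec, args=(k, 0.0, 0.0, 1.0),
                 Dfun=_kernels.jacobian, rtol=1e-10, atol=1e-12)
    expected = 0.1 * (1.0 - np.exp(-table1.kDiffcAMP * t_sec))
    # Vcell/Vpip ~ 7e-9, so pipette depletion is negligible but nonzero
    assert np.allclose(sol[:, 3], expected, rtol=1e-5, atol=1e-12)


def test_adaptive_integration_matches_fixed_step_rk4(table1):
    # explicit RK4 oracle on an ATP-free protocol (the stiff ATP mode stays
    # at zero, so an explicit method with a small step is stable)
    proto = Protocol(id="epi_only", EPI=5.0, duration=2.0)
    times = minutes(0.0, 1.0, 2.0)
    traj = ax.simulate(table1, proto, times)

    k = table1.to_array()
    args = (k, 5.0, 0.0, 1.0)
    y = ax.initial_state(proto).to_array()
    h = 1e-4 * 60.0  # 1e-4 min, in seconds
    out = [y.copy()]
    t = 0.0
    for step in range(int(round(2.0 / 1e-4))):
        k1 = _kernels.rhs(y, t, *args)
        k2 = _kernels.rhs(y + 0.5 * h * k1, t + 0.5 * h, *args)
        k3 = _kernels.rhs(y + 0.5 * h * k2, t + 0.5 * h, *args)
        k4 = _kernels.rhs(y + h * k3, t + h, *args)
        y = y + h / 6.0 * (k1 + 2 * k2 + 2 * k3 + k4)
        t += h
        if (step + 1) % 10_000 == 0:
            out.append(y.copy())
    oracle = np.array(out)
    scale = np.abs(oracle).max(axis=0) + 1e-12
    assert np.allclose(traj.states / scale, oracle / scale, atol=1e-4)


def test_knockdown_scales_receptor_linear_subsystem_exactly(table1):
    # Bact(t) and cAMP(t) are linear in the initial receptor amount when
    # the pipette contains no cAMP.
    base = Protocol(id="epi", EPI=5.0, pipette_ATP=3.0, duration=12.0)
    times = np.linspace(0, 12, 13)
    ref = ax.simulate(table1, base, times)
    for alpha in (0.7, 0.4):
        kd = Protocol(**{**base.to_dict(), "knockdown_fraction": 1 - alpha})
        traj = ax.simulate(table1, kd, times)
        for name in ("Bact", "cAMP"):
            a, b = traj.state(name), alpha * ref.state(name)
            scale = np.abs(b).max()
            assert np.allclose(a, b, atol=1e-6 * scale, rtol=1e-6)


def test_measurement_is_scaled_net_rate(table1):
    proto = Protocol(id="cl", CL=1.0, pipette_ATP=3.0)
    traj = ax.simulate(table1, proto, np.linspace(0, 12, 13))
    np.testing.assert_allclose(ax.measurement(traj, kscale=3.0),
                               3.0 * (traj.vExo - traj.vEndo))
    assert np.all(ax.measurement(traj, kscale=0.0) == 0.0)
    with pytest.raises(ValueError):
        ax.measurement(traj, kscale=-1.0)


def test_trajectory_frame_exports_all_states(table1, protocols):
    traj = ax.simulate(table1, protocols["EPI5_ATP3"], minutes(0, 6, 12))
    frame = traj.to_frame()
    assert list(frame.columns[:2]) == ["time_min", "B"]
    assert {"vExo", "vEndo", "y_hat"} <= set(frame.columns)
    np.testing.assert_allclose(frame["y_hat"].to_numpy(),
                               table1.kscale * traj.net_rate)
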