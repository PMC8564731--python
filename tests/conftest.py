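"""Shared fixtures: parameter sets, protocols, synthetic fixtures and fits."""

import numpy as np
import pytest

import adipoexo as ax


@pytest.fixture(scope="session")
def table1():
    return ax.TABLE1


@pytest.fixture(scope="session")
def protocols():
    return {p.id: p for p in ax.builtin_protocols()}


@pytest.fixture(scope="session")
def small_dataset():
    """Two-condition synthetic dataset used by estimation/uncertainty tests."""
    dataset, truth = ax.generate_dataset(
        ax.TABLE1,
        protocols=[ax.get_protocol("CL1_ATP3"), ax.get_protocol("CTRL_cAMP_ATP")],
        times=np.array([0.0, 2.0, 6.0, 12.0]),
        noise=ax.NoiseSpec(seed=11),
    )
    return dataset, truth


@pytest.fixture(scope="session")
def small_fit_config():
    return ax.FitConfig(n_candidates=512, n_starts=4, max_nfev=150,
                        n_polish=1, seed=11)


@pytest.fixture(scope="session")
def small_fit(small_dataset, small_fit_config):
    """A cheap but real fit of the small synthetic dataset."""
    dataset, _ = small_dataset
    return ax.estimate_parameters(dataset, small_fit_config)


@pytest.fixture(scope="session")
def recovery_report():
    """Full generate-fit round trip at the default study conditions."""
    return ax.recovery_experiment(ax.RecoveryConfig(seed=1))
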