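"""Shared fixtures: replicate ensembles reused across the suite.

The forward-simulation ensembles are the expensive part of the suite, so
each scenario is simulated once per session and shared by every test that
needs it.  Scenario parameters are the study conditions (selection scheme
(0.05, 0.1, 0.2), mu = 2.5e-9, burn-in 1000, epoch 1500, theta -> N via
4*N*mu); only the replicate count (200) is desk-scale.
"""

from __future__ import annotations

import numpy as np
import pytest

from softsweep import wf_sim

ENSEMBLE_REPLICATES = 200
BASE_SEED = 20100617


def make_ensemble(
    theta: float, rho: float = 0.15, seed: int = BASE_SEED,
    replicates: int = ENSEMBLE_REPLICATES,
) -> list[wf_sim.RunSummary]:
    cfg = wf_sim.ScenarioConfig(theta=theta, rho_cM_per_Mbp=rho, seed=seed)
    return wf_sim.run_ensemble(cfg, replicates)


@pytest.fixture(scope="session")
def ensemble_theta001():
    """theta = 0.01 (N = 1e6), the mutation-limited regime."""
    return make_ensemble(0.01)


@pytest.fixture(scope="session")
def ensemble_theta01():
    """theta = 0.1 (N = 1e7), intermediate regime."""
    return make_ensemble(0.1)


@pytest.fixture(scope="session")
def ensemble_theta1():
    """theta = 1 (N = 1e8), the mutation-rich regime."""
    return make_ensemble(1.0)


@pytest.fixture(scope="session")
def ensemble_theta1_rho0():
    """theta = 1 with recombination off: soft sweeps from recurrent mutation."""
    return make_ensemble(1.0, rho=0.0, seed=BASE_SEED + 1)


@pytest.fixture(scope="session")
def balance_runs():
    """Long burn-ins at N = 1e4, theta = 0.01, for mutation-selection balance.

    Six replicates of a 30,000-generation burn-in; the late-window resistant
    frequency and the occupancy fraction are compared with the deterministic
    and diffusion expectations.
    """
    runs = []
    for r in range(6):
        cfg = wf_sim.ScenarioConfig(
            N=10_000, mu=2.5e-7, burn_in=30_000, epoch=0, seed=BASE_SEED + 2
        )
        runs.append(wf_sim.run_scenario(cfg, wf_sim.replicate_rng(BASE_SEED + 2, r)))
    return runs


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
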