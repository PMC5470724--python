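"""Shared fixtures: parameter sets, conditions, and the session-scoped
stochastic runs that several test modules compare against analytics."""

from __future__ import annotations

import numpy as np
import pytest

from myo1c import (CycleParameters, Conditions, RateSet, table1_parameters,
                   SimulationConfig, gillespie_run, strongly_bound_dwells,
                   ExperimentDesign, generate_events)
from myo1c.inference import bin_events, joint_fit, DEFAULT_FIT_CONDITIONS


@pytest.fixture(scope="session")
def table1() -> CycleParameters:
    return table1_parameters()


@pytest.fixture()
def phys() -> Conditions:
    return Conditions.physiological(actin=100.0)


def random_rateset(rng: np.random.Generator,
                   lo: float = 0.01, hi: float = 10.0) -> RateSet:
    """A fully connected random rate set (log-uniform magnitudes)."""
    names = ("w12", "w15", "w21", "w23", "w32",
             "w34", "w43", "w45", "w51", "w54")
    return RateSet(**{n: float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
                      for n in names})


def random_balanced_system(rng: np.random.Generator):
    """Random (params, conditions) pair with the ATP-release rate balanced."""
    params = CycleParameters(
        dx1=rng.uniform(2.0, 8.0), dx2=rng.uniform(0.5, 4.0),
        delta1=rng.uniform(0.0, 1.0), delta2=rng.uniform(0.0, 1.0),
        xi=rng.uniform(2.0, 20.0), omega_off=rng.uniform(1e-3, 1.0),
        w23_0=np.exp(rng.uniform(-2, 3)), w32_hat=np.exp(rng.uniform(-9, 0)),
        w34_0=np.exp(rng.uniform(-2, 3)), w43_hat=np.exp(rng.uniform(-3, 2)),
        w45_hat=np.exp(rng.uniform(-3, 2)), w51_0=np.exp(rng.uniform(-1, 5)),
        w21=np.exp(rng.uniform(-1, 5)), w12_hat=np.exp(rng.uniform(-3, 2)),
        w15_hat=np.exp(rng.uniform(-5, 0))).rebalanced()
    cond = Conditions(
        atp=np.exp(rng.uniform(0, 8)), adp=np.exp(rng.uniform(-2, 6)),
        pi=np.exp(rng.uniform(-2, 8)), actin=np.exp(rng.uniform(0, 8)),
        force=rng.uniform(-6.0, 6.0))
    return params, cond


@pytest.fixture(scope="session")
def single_head_clamp(table1):
    """Long single-head isometric-clamp run at 2 pN, saturating ATP.

    Returns (conditions, trajectory, strongly-bound dwell times); about
    10^4 completed strong-state sojourns.
    """
    cond = DEFAULT_FIT_CONDITIONS["atp5000"].with_force(2.0)
    cfg = SimulationConfig(N=1, params=table1, conditions=cond,
                           mode="force_clamp", t_max=35000.0, seed=42)
    traj = gillespie_run(cfg)
    return cond, traj, strongly_bound_dwells(traj)


@pytest.fixture(scope="session")
def ensemble30(table1):
    """30 coupled heads at kappa = 0.5 pN/nm and high actin (10 mM).

    Dict mapping external force (pN) to the trajectory.
    """
    out = {}
    for F, seed in ((2.0, 7), (6.0, 8)):
        cond = Conditions.physiological(actin=10000.0).with_force(F)
        cfg = SimulationConfig(N=30, params=table1, conditions=cond,
                               mode="force_clamp", t_max=20.0, burn_in=2.0,
                               seed=seed)
        out[F] = gillespie_run(cfg)
    return out


@pytest.fixture(scope="session")
def recovery_fit(table1):
    """End-to-end synthetic round trip: generate -> bin -> joint fit.

    500 events per condition from the packaged truth, 20-start CI-weighted
    joint fit.  Returns (truth, events, binned, fit result).
    """
    design = ExperimentDesign(events_per_condition=500)
    events = generate_events(design, table1, seed=0)
    binned = bin_events(events)
    result = joint_fit(binned, DEFAULT_FIT_CONDITIONS, base=table1,
                       n_starts=20, seed=0)
    return table1, events, binned, result
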