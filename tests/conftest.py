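"""Shared fixtures.

The 1000-day evolution runs are the expensive part of the suite; they are
computed once per session here and shared between the property tests and the
acceptance tests.
"""

import numpy as np
import pytest

import phagewave as pw


@pytest.fixture(scope="session")
def baseline_run():
    """Full 1000-day baseline-preset run (stable regime, xi=0.002)."""
    cfg = pw.load_config("baseline")
    traj = pw.simulate_evolution(cfg.build_evo_params(), cfg.build_initial_spec(), 1000.0)
    return traj


@pytest.fixture(scope="session")
def baseline_series(baseline_run):
    return baseline_run.scalar_series()


@pytest.fixture(scope="session")
def baseline_run_fine():
    """Baseline run on the doubled grid (n=8000), for the refinement check."""
    cfg = pw.load_config({"grid": {"n": 8000}})
    traj = pw.simulate_evolution(cfg.build_evo_params(), cfg.build_initial_spec(), 1000.0)
    return traj


@pytest.fixture(scope="session")
def enriched_run():
    """Full 1000-day enriched-preset run (oscillatory regime, xi=0.02).

    Snapshots every day: the S-recovery spikes of the deep predator-prey
    cycles are only ~1-2 days wide (period 14-19 days), so the default 5-day
    cadence undersamples their amplitude.
    """
    cfg = pw.load_config("enriched")
    traj = pw.simulate_evolution(
        cfg.build_evo_params(), cfg.build_initial_spec(), 1000.0,
        np.arange(0.0, 1001.0, 1.0),
    )
    return traj


@pytest.fixture(scope="session")
def enriched_series(enriched_run):
    return enriched_run.scalar_series()


@pytest.fixture(scope="session")
def ode_oracle_pair():
    """Dispersion-free single-variant run vs the three-population ODE model.

    With q = 0 and all initial phage mass on one interior grid node, the
    phenotype-space system collapses exactly onto the ODE model with
    k = k(r0): the trapezoid weight of an interior node is dr, so scaling the
    nodal density by 1/dr makes every coupling term identical.  The pair
    exercises the full solver stack on both sides.
    """
    r0 = 1.0
    t_end = 300.0
    out_times = np.arange(0.0, t_end + 1e-9, 5.0)
    cfg = pw.load_config(
        {"model": {"q": 0.0}, "solver": {"rtol": 1e-8, "atol": 1e-12}}
    )
    params = cfg.build_evo_params()
    grid = params.grid
    j = int(np.argmin(np.abs(grid.nodes - r0)))
    assert 0 < j < grid.n - 1
    P0 = 1.0
    p = np.zeros(grid.n)
    p[j] = P0 / grid.dr
    state0 = pw.EvoState(S=params.C, i=np.zeros(grid.n), p=p)
    traj = pw.simulate_evolution(params, state0, t_end, out_times)

    bk = cfg.build_bk_params(at_r=float(grid.nodes[j]))
    table = pw.simulate_ode(bk, (bk.C, 0.0, P0), t_end, out_times, rtol=1e-10, atol=1e-13)
    return traj, table
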