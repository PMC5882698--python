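"""The phenotype-space evolution model: right-hand side, initial state, solver."""

import numpy as np
import pytest

import phagewave as pw
from phagewave.evolution_sim import (
    EvoParams,
    EvoState,
    InitialConditionSpec,
    evo_rhs,
    initial_state,
    simulate_evolution,
)
from phagewave.phenotype_space import LinearKLandscape, build_grid

LS = LinearKLandscape(xi=0.002, lam=3.0, mu=20.0, b=149.254)


def make_params(n=200, r_end=10.0, q=1e-6, **kw):
    return EvoParams(alpha=1.5, C=100.0, q=q, landscape=LS, grid=build_grid(r_end, n), **kw)


class TestEvoRhs:
    def test_uninfected_logistic_growth(self):
        params = make_params()
        n = params.grid.n
        state = EvoState(S=40.0, i=np.zeros(n), p=np.zeros(n))
        d = evo_rhs(params, state)
        assert d.S == pytest.approx(1.5 * 40.0 * (1 - 40.0 / 100.0), rel=1e-12)
        assert np.all(d.i == 0) and np.all(d.p == 0)

    def test_shape_mismatch_rejected(self):
        params = make_params()
        state = EvoState(S=1.0, i=np.zeros(7), p=np.zeros(params.grid.n))
        with pytest.raises(ValueError, match="shape"):
            evo_rhs(params, state)

    def test_single_node_reduces_to_ode_rates(self):
        """q=0, point support: nodal rates times dr equal the ODE rates."""
        params = make_params(q=0.0)
        grid = params.grid
        j = 60
        S0, I0, P0 = 55.0, 3.0, 40.0
        i = np.zeros(grid.n)
        p = np.zeros(grid.n)
        i[j] = I0 / grid.dr
        p[j] = P0 / grid.dr
        d = evo_rhs(params, EvoState(S=S0, i=i, p=p))
        bk = pw.BKParams(alpha=1.5, C=100.0, k=0.002 * grid.nodes[j], lam=3.0, b=149.254, mu=20.0)
        ref = pw.ode_rhs(bk, (S0, I0, P0))
        assert d.S == pytest.approx(ref[0], rel=1e-12)
        assert d.i[j] * grid.dr == pytest.approx(ref[1], rel=1e-12)
        assert d.p[j] * grid.dr == pytest.approx(ref[2], rel=1e-12)

    def test_derivative_nonnegative_where_field_vanishes(self):
        params = make_params()
        rng = np.random.default_rng(0)
        n = params.grid.n
        i = rng.random(n)
        p = rng.random(n)
        j = 77
        i[j] = p[j] = 0.0
        d = evo_rhs(params, EvoState(S=50.0, i=i, p=p))
        assert d.i[j] >= 0
        assert d.p[j] >= 0


class TestInitialState:
    def test_pulse_mass_normalized_exactly(self):
        params = make_params(n=400)
        spec = InitialConditionSpec(center=1.0, width=0.05, total_phage=2.5)
        s = initial_state(spec, params)
        assert params.grid.integrate(s.p) == pytest.approx(2.5, rel=1e-12)

    def test_all_bacteria_susceptible(self):
        params = make_params()
        s = initial_state(InitialConditionSpec(), params)
        assert s.S == params.C
        assert np.all(s.i == 0)

    def test_pulse_peaks_at_requested_center(self):
        params = make_params(n=2000)
        s = initial_state(InitialConditionSpec(center=1.0, width=0.05), params)
        peak = params.grid.nodes[np.argmax(s.p)]
        assert abs(peak - 1.0) <= params.grid.dr / 2 + 1e-12

    def test_truncated_pulse_warns(self):
        params = make_params(n=200, r_end=10.0)
        with pytest.warns(UserWarning, match="truncated"):
            initial_state(InitialConditionSpec(center=0.02, width=0.1), params)

    @pytest.mark.parametrize("field_name", ["center", "width", "total_phage"])
    def test_invalid_spec_rejected(self, field_name):
        with pytest.raises(ValueError):
            InitialConditionSpec(**{field_name: -1.0})


class TestSimulateEvolution:
    def test_ode_reduction_oracle(self, ode_oracle_pair):
        """q=0 point-support run tracks the three-population ODE within 0.1%."""
        traj, table = ode_oracle_pair
        grid = traj.params.grid
        S_pde = np.array([s.S for s in traj.states])
        I_pde = np.array([grid.integrate(s.i) for s in traj.states])
        P_pde = np.array([grid.integrate(s.p) for s in traj.states])
        for pde, ode in ((S_pde, table["S"]), (I_pde, table["I"]), (P_pde, table["P"])):
            ode = np.asarray(ode)
            denom = np.maximum(np.abs(ode), 1e-3 * np.abs(ode).max())
            assert np.max(np.abs(pde - ode) / denom) < 1e-3

    def test_nonnegative_and_boundary_clean_short_run(self):
        params = make_params(n=400, r_end=10.0)
        traj = simulate_evolution(params, InitialConditionSpec(), 50.0, np.arange(0, 51, 5.0))
        for s in traj.states:
            assert s.S >= 0
            assert s.i.min() >= -10 * params.atol
            assert s.p.min() >= -10 * params.atol

    def test_invalid_out_times_rejected(self):
        params = make_params()
        with pytest.raises(ValueError):
            simulate_evolution(params, InitialConditionSpec(), 10.0, [0.0, 5.0, 5.0])

    def test_wave_hitting_wall_warns(self):
        # tiny domain: the pulse sits in the outer 5% of the grid immediately
        params = make_params(n=64, r_end=1.1)
        with pytest.warns(UserWarning, match="boundary"):
            simulate_evolution(params, InitialConditionSpec(), 5.0, [0.0, 5.0])


class TestTrajectorySeries:
    def test_series_columns_and_monotone_time(self, baseline_series):
        assert list(baseline_series.columns) == [
            "t", "S", "I_total", "P_total", "mean_k", "mean_R0", "wave_pos",
        ]
        assert np.all(np.diff(baseline_series["t"]) > 0)

    def test_initial_row_reflects_seed_pulse(self, baseline_series):
        row = baseline_series.iloc[0]
        assert row["S"] == pytest.approx(100.0)
        assert row["I_total"] == 0.0
        assert row["P_total"] == pytest.approx(1.0, rel=1e-9)
        assert row["mean_k"] == pytest.approx(0.002, rel=5e-3)
        assert row["wave_pos"] == pytest.approx(1.0, rel=5e-3)

    def test_total_densities_evolve_continuously(self, baseline_series):
        """No solver glitches: snapshot-to-snapshot changes follow the local trend.

        After the initial invasion transient the totals vary smoothly, so each
        5-day increment should stay within 10x its neighbouring increments.
        """
        late = baseline_series[baseline_series["t"] >= 50.0]
        for col in ("I_total", "P_total"):
            v = late[col].to_numpy()
            steps = np.abs(np.diff(v))
            floor = 1e-6 * np.abs(v).max()
            neighbor = np.maximum(steps[:-2], steps[2:]) + floor
            assert np.all(steps[1:-1] <= 10 * neighbor)
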