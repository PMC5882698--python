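"""Unit tests of the three-population ODE model: equilibria, stability, Hopf scan."""

import numpy as np
import pytest

from phagewave.model_core import (
    BKParams,
    basic_reproduction_number,
    equilibria,
    hopf_threshold,
    jacobian,
    ode_rhs,
    simulate_ode,
)

BASELINE = dict(alpha=1.5, C=100.0, k=0.002, lam=3.0, b=149.254, mu=20.0)


@pytest.fixture
def params():
    return BKParams(**BASELINE)


class TestParams:
    @pytest.mark.parametrize("name", ["alpha", "C", "k", "lam", "b", "mu"])
    def test_nonpositive_rejected(self, name):
        bad = dict(BASELINE)
        bad[name] = -1.0
        with pytest.raises(ValueError, match=name):
            BKParams(**bad)

    def test_burst_size_below_one_warns_but_constructs(self):
        with pytest.warns(UserWarning, match="burst size"):
            p = BKParams(**{**BASELINE, "b": 0.5})
        assert basic_reproduction_number(p) < 0


class TestRhsAndR0:
    def test_origin_and_phage_free_are_equilibria(self, params):
        assert np.allclose(ode_rhs(params, (0, 0, 0)), 0)
        assert np.allclose(ode_rhs(params, (params.C, 0, 0)), 0)

    def test_nonfinite_state_rejected(self, params):
        with pytest.raises(ValueError):
            ode_rhs(params, (np.nan, 0, 0))

    @pytest.mark.parametrize(
        "overrides, expected",
        [
            ({}, 1.48254),  # baseline landscape slope at r=1
            ({"k": 0.02}, 14.8254),  # enriched slope at r=1
        ],
    )
    def test_r0_closed_form(self, overrides, expected):
        p = BKParams(**{**BASELINE, **overrides})
        assert basic_reproduction_number(p) == pytest.approx(expected, rel=1e-12)

    def test_r0_zero_at_unit_burst_size(self):
        with pytest.warns(UserWarning):
            p = BKParams(**{**BASELINE, "b": 1.0})
        assert basic_reproduction_number(p) == 0.0


class TestEquilibria:
    def test_trivial_states_always_present(self, params):
        eq = equilibria(params)
        assert eq.E0 == (0.0, 0.0, 0.0)
        assert eq.Ef == (params.C, 0.0, 0.0)

    def test_positive_equilibrium_annihilates_rhs(self, params):
        eq = equilibria(params)
        assert eq.Eplus is not None
        assert all(x > 0 for x in eq.Eplus)
        residual = ode_rhs(params, eq.Eplus)
        scale = max(abs(t) for t in (params.alpha * eq.Eplus[0], params.mu * eq.Eplus[2]))
        assert np.max(np.abs(residual)) < 1e-9 * scale

    def test_absent_below_threshold(self):
        # choose k so that R0 = 0.5
        k = 0.5 * BASELINE["mu"] / ((BASELINE["b"] - 1) * BASELINE["C"])
        eq = equilibria(BKParams(**{**BASELINE, "k": k}))
        assert eq.R0 == pytest.approx(0.5)
        assert eq.Eplus is None

    def test_saddle_node_merge_with_phage_free_state(self):
        """As R0 -> 1+ the positive equilibrium collapses onto (C, 0, 0)."""
        C, mu, b = BASELINE["C"], BASELINE["mu"], BASELINE["b"]
        k_at = lambda R0: R0 * mu / ((b - 1) * C)
        eq1 = equilibria(BKParams(**{**BASELINE, "k": k_at(1.0)}))
        assert eq1.Eplus is None  # boundary: E+ has merged into Ef
        eq = equilibria(BKParams(**{**BASELINE, "k": k_at(1.0 + 1e-6)}))
        S, I, P = eq.Eplus
        assert S == pytest.approx(C, rel=1e-5)
        assert I == pytest.approx(0.0, abs=1e-4)
        assert P == pytest.approx(0.0, abs=1e-3)


class TestJacobian:
    def test_origin_eigenvalues(self, params):
        eig = np.sort(np.linalg.eigvals(jacobian(params, (0, 0, 0))).real)
        assert eig == pytest.approx([-params.mu, -params.lam, params.alpha])

    def test_matches_finite_differences(self, params):
        rng = np.random.default_rng(42)
        h = 1e-6
        for _ in range(20):
            state = rng.uniform(0.1, 200.0, size=3)
            J = jacobian(params, state)
            J_fd = np.empty((3, 3))
            for j in range(3):
                dp = state.copy()
                dm = state.copy()
                dp[j] += h
                dm[j] -= h
                J_fd[:, j] = (ode_rhs(params, dp) - ode_rhs(params, dm)) / (2 * h)
            assert np.allclose(J, J_fd, rtol=1e-5, atol=1e-5 * np.abs(J).max())

    def test_phage_free_state_stable_below_threshold(self):
        k = 0.5 * BASELINE["mu"] / ((BASELINE["b"] - 1) * BASELINE["C"])
        p = BKParams(**{**BASELINE, "k": k})
        eig = np.linalg.eigvals(jacobian(p, (p.C, 0.0, 0.0)))
        assert np.all(eig.real < 0)


class TestHopfThreshold:
    def test_threshold_inside_reference_slope_range(self, params):
        kc = hopf_threshold(params, "k", 0.002, 0.02)
        assert kc is not None and 0.002 < kc < 0.02

    def test_sign_dichotomy_around_threshold(self, params):
        kc = hopf_threshold(params, "k", 0.002, 0.02)

        def abscissa(k):
            p = params.with_(k=k)
            return np.max(np.linalg.eigvals(jacobian(p, equilibria(p).Eplus)).real)

        assert abscissa(0.99 * kc) < 0
        assert abscissa(1.01 * kc) > 0
        # the reported threshold itself sits on the crossing
        scale = abs(abscissa(0.99 * kc)) + abs(abscissa(1.01 * kc))
        assert abs(abscissa(kc)) < 10 * scale

    def test_no_crossing_returns_none(self, params):
        assert hopf_threshold(params, "k", 0.002, 0.004) is None

    def test_unknown_parameter_rejected(self, params):
        with pytest.raises(ValueError, match="unknown parameter"):
            hopf_threshold(params, "beta", 0.1, 1.0)

    def test_no_positive_equilibrium_anywhere_is_diagnosed(self, params):
        with pytest.raises(ValueError, match="E\\+ exists nowhere"):
            hopf_threshold(params, "k", 1e-6, 5e-5)  # R0 < 0.75 throughout


class TestSimulateOde:
    def test_equilibrium_initial_condition_stays_put(self, params):
        eq = equilibria(params)
        table = simulate_ode(params, eq.Eplus, 200.0, out_times=np.linspace(0, 200, 81))
        final = table[["S", "I", "P"]].to_numpy()
        assert np.allclose(final, np.array(eq.Eplus), rtol=1e-6, atol=1e-6)

    def test_phage_extinction_below_threshold(self):
        k = 0.8 * BASELINE["mu"] / ((BASELINE["b"] - 1) * BASELINE["C"])
        p = BKParams(**{**BASELINE, "k": k})
        table = simulate_ode(p, (p.C / 2, 1.0, 1.0), 500.0)
        assert table["P"].iloc[-1] < 1e-6
        assert table["S"].iloc[-1] == pytest.approx(p.C, rel=1e-3)

    def test_sustained_oscillations_beyond_threshold(self, params):
        from scipy.signal import find_peaks

        p = params.with_(k=0.02)
        table = simulate_ode(p, (p.C, 1.0, 1.0), 1000.0, out_times=np.linspace(0, 1000, 4001))
        S = table["S"].to_numpy()
        half = S[S.size // 2 :]
        peaks, _ = find_peaks(half, prominence=0.05 * (half.max() - half.min()))
        assert peaks.size >= 3
        amplitudes = half[peaks]
        assert amplitudes.min() > 0.8 * amplitudes.max()

    def test_negative_initial_state_rejected(self, params):
        with pytest.raises(ValueError):
            simulate_ode(params, (-1.0, 0.0, 0.0), 10.0)

    def test_trajectories_stay_nonnegative(self, params):
        table = simulate_ode(params, (params.C, 0.0, 1.0), 300.0)
        assert (table[["S", "I", "P"]].to_numpy() >= 0).all()
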