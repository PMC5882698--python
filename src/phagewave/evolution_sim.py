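"""Method-of-lines simulation of phage evolution in phenotype space.

The model couples a scalar susceptible population ``S(t)`` to two density
fields over the phenotype coordinate: infected bacteria ``i(r, t)`` and free
phage ``p(r, t)``::

    dS/dt      = alpha*S*(1 - (S + Int[i])/C) - S * Int[k(r) p(r,t)]
    di/dt(r)   = k(r) p(r,t) S - lam(r) i(r,t) + q * Lap i(r,t)
    dp/dt(r)   = -k(r) p(r,t) S - mu(r) p(r,t) + b(r) lam(r) i(r,t)

where ``Int[.]`` is the integral over phenotype space (composite trapezoid
on the grid) and ``Lap`` the dispersion (mutation) operator.  Spatial
discretization turns this into a stiff ODE system of dimension ``2n + 1``.

The state vector is interleaved, ``y = [i_1, p_1, ..., i_n, p_n, S]``, so
that the Jacobian is banded (bandwidth 2) in the field block with a single
dense border row/column for ``S``.  Newton systems of the implicit time
stepper are solved in O(n) by a banded LU plus a rank-one bordering step.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import lapack

from ._stepper import SolverError, integrate_trbdf2
from .phenotype_space import FitnessLandscape, Grid, dispersion_operator

__all__ = [
    "EvoParams",
    "InitialConditionSpec",
    "EvoState",
    "EvoTrajectory",
    "evo_rhs",
    "initial_state",
    "simulate_evolution",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True, eq=False)
class EvoParams:
    """Ecological parameters, landscape, grid and solver settings for one run."""

    alpha: float
    C: float
    q: float
    landscape: FitnessLandscape
    grid: Grid
    bc: str = "no-flux"
    rtol: float = 1e-6
    atol: float = 1e-9

    def __post_init__(self):
        if self.alpha <= 0 or self.C <= 0:
            raise ValueError("alpha and C must be > 0")
        if self.q < 0:
            raise ValueError("dispersion coefficient q must be >= 0")


@dataclass(frozen=True)
class InitialConditionSpec:
    """Initial phage pulse: Gaussian in phenotype space.

    center      : phenotype coordinate of the pulse
    width       : standard deviation of the pulse
    total_phage : integral of p(r, 0) over the grid (virions/ml)
    """

    center: float = 1.0
    width: float = 0.05
    total_phage: float = 1.0

    def __post_init__(self):
        if self.width <= 0 or self.total_phage <= 0 or self.center <= 0:
            raise ValueError("center, width and total_phage must be > 0")


@dataclass(frozen=True, eq=False)
class EvoState:
    """Scalar susceptible density plus the two phenotype-space fields."""

    S: float
    i: np.ndarray
    p: np.ndarray


@dataclass(frozen=True, eq=False)
class EvoTrajectory:
    """Snapshots of an evolution run at strictly increasing output times."""

    times: np.ndarray
    states: list[EvoState]
    params: EvoParams
    stats: dict = field(default_factory=dict)

    def field_matrix(self, which: str) -> np.ndarray:
        """Stack one field over time: shape (n_times, n_nodes)."""
        if which not in ("i", "p"):
            raise ValueError("which must be 'i' or 'p'")
        return np.stack([getattr(s, which) for s in self.states])

    def scalar_series(self) -> "pandas.DataFrame":
        """Derived scalar time series; see :mod:`phagewave.observables`."""
        from .observables import trajectory_summary

        return trajectory_summary(self)


class _ArrowheadBandedSolver:
    """Newton linear algebra for the interleaved MOL system.

    The iteration matrix ``M = I - c*J`` splits into a pentadiagonal block
    over the fields, a border column (coupling to ``S``), a border row (the
    quadrature row of ``dS/dt``) and a corner scalar.  ``M x = b`` is solved
    by block elimination:  factor the banded block once per matrix, pre-solve
    the border column, then each right-hand side costs one banded
    back-substitution and a scalar Schur complement.
    """

    KL = KU = 2

    def __init__(self, model: "_MOLModel"):
        self.m = model

    def factor(self, t: float, y: np.ndarray, c: float):
        m = self.m
        n = m.n
        nn = 2 * n
        i = y[0:nn:2]
        p = y[1:nn:2]
        S = y[-1]
        kp = m.k * p
        kl, ku = self.KL, self.KU
        ab = np.zeros((2 * kl + ku + 1, nn))
        # J block diagonals (interleaved ordering: i_j -> 2j, p_j -> 2j+1)
        diag = np.empty(nn)
        diag[0::2] = -m.lam + m.lap_diag
        diag[1::2] = -m.k * S - m.mu
        sup1 = np.zeros(nn - 1)
        sup1[0::2] = m.k * S  # d(di_j)/d(p_j)
        sub1 = np.zeros(nn - 1)
        sub1[0::2] = m.b * m.lam  # d(dp_j)/d(i_j)
        sup2 = np.zeros(nn - 2)
        sup2[0::2] = m.lap_upper  # d(di_j)/d(i_{j+1})
        sub2 = np.zeros(nn - 2)
        sub2[0::2] = m.lap_lower  # d(di_j)/d(i_{j-1})
        ab[kl + ku, :] = 1.0 - c * diag
        ab[kl + ku - 1, 1:] = -c * sup1
        ab[kl + ku - 2, 2:] = -c * sup2
        ab[kl + ku + 1, :-1] = -c * sub1
        ab[kl + ku + 2, :-2] = -c * sub2
        lu, piv, info = lapack.dgbtrf(ab, kl, ku)
        if info != 0:
            raise RuntimeError(f"banded LU factorization failed (info={info})")
        # border column: d(field rows)/dS
        u = np.empty(nn)
        u[0::2] = kp
        u[1::2] = -kp
        # border row: d(dS/dt)/d(fields)
        v = np.empty(nn)
        v[0::2] = -m.alpha * S / m.C * m.w
        v[1::2] = -S * m.k * m.w
        a_corner = m.alpha * (1.0 - (2.0 * S + m.w @ i) / m.C) - m.w @ kp
        col = -c * u
        row = -c * v
        corner = 1.0 - c * a_corner
        xc, info = lapack.dgbtrs(lu, kl, ku, col[:, None], piv)
        if info != 0:
            raise RuntimeError("banded back-substitution failed")
        xc = xc[:, 0]
        denom = corner - row @ xc
        if denom == 0.0 or not np.isfinite(denom):
            raise RuntimeError("singular bordered system")
        return (lu, piv, row, xc, denom)

    def solve(self, fac, b: np.ndarray) -> np.ndarray:
        lu, piv, row, xc, denom = fac
        xb, info = lapack.dgbtrs(lu, self.KL, self.KU, b[:-1][:, None], piv)
        if info != 0:
            raise RuntimeError("banded back-substitution failed")
        xb = xb[:, 0]
        xs = (b[-1] - row @ xb) / denom
        out = np.empty(b.size)
        out[:-1] = xb - xs * xc
        out[-1] = xs
        return out


class _MOLModel:
    """Precomputed arrays and the right-hand side of the interleaved system."""

    def __init__(self, params: EvoParams):
        g = params.grid
        self.n = g.n
        self.alpha = params.alpha
        self.C = params.C
        k, lam, mu, b = params.landscape.traits(g.nodes)
        self.k, self.lam, self.mu, self.b = k, lam, mu, b
        self.w = g.trapezoid_weights
        L = dispersion_operator(g, params.q, bc=params.bc).tocsr()
        # the operator is tridiagonal by construction; keep its three bands
        n = g.n
        dense_bands = L.todia()
        offsets = list(dense_bands.offsets)
        data = dense_bands.data

        def band(off):
            if off not in offsets:
                return np.zeros(n + (0 if off == 0 else -1))
            row = data[offsets.index(off)]
            if off == 0:
                return row.copy()
            if off == 1:
                return row[1:].copy()
            return row[:-1].copy()

        self.lap_diag = band(0)
        self.lap_upper = band(1)  # coupling of node j to j+1, length n-1
        self.lap_lower = band(-1)  # coupling of node j to j-1, length n-1

    def pack(self, state: EvoState) -> np.ndarray:
        y = np.empty(2 * self.n + 1)
        y[0 : 2 * self.n : 2] = state.i
        y[1 : 2 * self.n : 2] = state.p
        y[-1] = state.S
        return y

    def unpack(self, y: np.ndarray) -> EvoState:
        return EvoState(S=float(y[-1]), i=y[0 : 2 * self.n : 2].copy(), p=y[1 : 2 * self.n : 2].copy())

    def rhs(self, t: float, y: np.ndarray) -> np.ndarray:
        n = self.n
        nn = 2 * n
        i = y[0:nn:2]
        p = y[1:nn:2]
        S = y[-1]
        kp = self.k * p
        di = kp * S - self.lam * i + self.lap_diag * i
        di[:-1] += self.lap_upper * i[1:]
        di[1:] += self.lap_lower * i[:-1]
        dp = -kp * S - self.mu * p + self.b * self.lam * i
        dS = self.alpha * S * (1.0 - (S + self.w @ i) / self.C) - S * (self.w @ kp)
        out = np.empty(nn + 1)
        out[0:nn:2] = di
        out[1:nn:2] = dp
        out[-1] = dS
        return out


def evo_rhs(params: EvoParams, state: EvoState, t: float = 0.0) -> EvoState:
    """Time derivative of an :class:`EvoState` (same layout as the state)."""
    n = params.grid.n
    for name in ("i", "p"):
        f = getattr(state, name)
        if np.shape(f) != (n,):
            raise ValueError(f"field {name!r} has shape {np.shape(f)}, grid has {n} nodes")
    model = _MOLModel(params)
    dy = model.rhs(t, model.pack(state))
    return model.unpack(dy)


def initial_state(spec: InitialConditionSpec, params: EvoParams) -> EvoState:
    """All bacteria susceptible (S = C, i = 0) plus a narrow phage pulse.

    The Gaussian pulse is rescaled so its trapezoid integral over the grid
    equals ``total_phage`` exactly.
    """
    g = params.grid
    z = (g.nodes - spec.center) / spec.width
    p = np.exp(-0.5 * z**2)
    raw_mass = g.integrate(p)
    if raw_mass <= 0:
        raise ValueError("initial pulse has no mass on the grid; widen it or move the center")
    # mass lost to truncation by the domain ends, relative to the full Gaussian
    full_mass = spec.width * np.sqrt(2.0 * np.pi)
    if raw_mass < 0.99 * full_mass:
        warnings.warn(
            f"initial pulse truncated by the grid: {100 * (1 - raw_mass / full_mass):.1f}% "
            "of its mass falls outside (0, r_end]",
            stacklevel=2,
        )
    p *= spec.total_phage / raw_mass
    return EvoState(S=float(params.C), i=np.zeros(g.n), p=p)


def simulate_evolution(
    params: EvoParams,
    spec_or_state,
    t_end: float,
    out_times=None,
    first_step: float = 1e-4,
) -> EvoTrajectory:
    """Integrate the phenotype-space model and return snapshots.

    ``spec_or_state`` may be an :class:`InitialConditionSpec` or a prepared
    :class:`EvoState`.  Snapshots are taken at ``out_times`` (default: every
    5 days).  A warning is issued if more than 0.1% of the infected or phage
    mass sits in the outermost 5% of the grid at any output time (the
    travelling wave has reached the wall and the truncation is no longer
    innocuous).
    """
    if not t_end > 0:
        raise ValueError("t_end must be positive")
    if out_times is None:
        out_times = np.arange(0.0, t_end + 1e-9, 5.0)
    out_times = np.asarray(out_times, dtype=float)
    if np.any(np.diff(out_times) <= 0):
        raise ValueError("out_times must be strictly increasing")

    model = _MOLModel(params)
    if isinstance(spec_or_state, InitialConditionSpec):
        state0 = initial_state(spec_or_state, params)
    else:
        state0 = spec_or_state
    y0 = model.pack(state0)

    checkpoints = np.linspace(0.0, t_end, 11)[1:]
    next_cp = [0]

    def progress(t):
        while next_cp[0] < checkpoints.size and t >= checkpoints[next_cp[0]]:
            logger.info("simulate_evolution: reached t=%.1f of %.1f days", t, t_end)
            next_cp[0] += 1

    solver = _ArrowheadBandedSolver(model)

    # Population densities are non-negative in the exact flow; clip the
    # (error-level) undershoots so the bilinear infection term cannot amplify
    # sign-indefinite noise through the deep oscillation troughs.  S = 0 is an
    # absorbing state of the logistic term that the exact flow never reaches
    # (its true minima, exp(-Int[k P]), merely fall below the solver's
    # resolution), so S is kept at a floor of one absolute-tolerance unit
    # instead of being allowed to stick at zero.
    s_floor = params.atol

    def project(y):
        if y.min() >= 0.0 and y[-1] >= s_floor:
            return y
        out = np.maximum(y, 0.0)
        out[-1] = max(out[-1], s_floor)
        return out

    try:
        res = integrate_trbdf2(
            model.rhs,
            solver,
            y0,
            (0.0, float(t_end)),
            out_times,
            rtol=params.rtol,
            atol=params.atol,
            first_step=first_step,
            progress=progress,
            project=project,
        )
    except SolverError as err:
        raise RuntimeError(
            f"evolution solver failed; last good time t={err.last_t:.6g} days"
        ) from err
    logger.info(
        "simulate_evolution: %d steps, %d rejected, %d factorizations, %d rhs calls",
        res.n_steps,
        res.n_rejected,
        res.n_factorizations,
        res.n_rhs,
    )

    states = [model.unpack(row) for row in res.y]
    # negativity diagnostic (solver works on the unconstrained system)
    min_val = min(min(s.i.min(), s.p.min(), s.S) for s in states)
    if min_val < -100.0 * params.atol:
        warnings.warn(
            f"snapshots undershoot zero by {-min_val:.3g}; consider tightening tolerances",
            stacklevel=2,
        )
    # wall-contact diagnostic
    edge = max(1, int(0.05 * params.grid.n))
    w = params.grid.trapezoid_weights
    for t_out, s in zip(res.t, states):
        for name in ("i", "p"):
            f = getattr(s, name)
            total = float(w @ np.abs(f))
            if total > 0 and float(w[-edge:] @ np.abs(f[-edge:])) > 1e-3 * total:
                warnings.warn(
                    f"more than 0.1% of the {name}-mass is in the outermost 5% of the "
                    f"grid at t={t_out:.1f}; the wave has reached the boundary",
                    stacklevel=2,
                )
                break
        else:
            continue
        break

    stats = dict(
        n_steps=res.n_steps,
        n_rejected=res.n_rejected,
        n_factorizations=res.n_factorizations,
        n_rhs=res.n_rhs,
    )
    return EvoTrajectory(times=res.t, states=states, params=params, stats=stats)
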