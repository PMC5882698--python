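"""Lytic phage-bacteria dynamics: the Beretta-Kuang ODE model.

Three well-mixed populations interact in an aquatic environment: susceptible
bacteria ``S`` grow logistically (rate ``alpha``, carrying capacity ``C``)
and are infected by free phage ``P`` at bilinear rate ``k*S*P``; infected
bacteria ``I`` do not reproduce and lyse at rate ``lam``, each releasing on
average ``b`` virions; free phage decay at rate ``mu`` and are also lost by
adsorption to susceptible cells::

    dS/dt = alpha*S*(1 - (S + I)/C) - k*S*P
    dI/dt = k*S*P - lam*I
    dP/dt = b*lam*I - k*S*P - mu*P

The dynamics is organized by the phage's basic reproduction number
``R0 = (b - 1)*k*C/mu``: for ``R0 <= 1`` the phage-free state ``(C, 0, 0)``
is globally stable; at ``R0 = 1`` a saddle-node bifurcation creates a
positive equilibrium ``E+``, which itself loses stability through a
supercritical Hopf bifurcation at larger ``R0`` (the paradox of enrichment),
giving rise to self-sustained predator-prey oscillations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

__all__ = [
    "BKParams",
    "EquilibriumSet",
    "ode_rhs",
    "basic_reproduction_number",
    "equilibria",
    "jacobian",
    "hopf_threshold",
    "simulate_ode",
]

_PARAM_NAMES = ("alpha", "C", "k", "lam", "b", "mu")


@dataclass(frozen=True)
class BKParams:
    """Parameters of the ODE model.

    alpha : per-capita bacterial growth rate (1/day)
    C     : carrying capacity (cells/ml)
    k     : infection (adsorption) rate constant (ml/(cell*day))
    lam   : lysis rate of infected cells (1/day)
    b     : mean burst size (dimensionless)
    mu    : free-phage decay rate (1/day)
    """

    alpha: float
    C: float
    k: float
    lam: float
    b: float
    mu: float

    def __post_init__(self):
        for name in _PARAM_NAMES:
            value = getattr(self, name)
            if not np.isfinite(value) or value <= 0:
                raise ValueError(f"parameter {name!r} must be finite and > 0, got {value}")
        if self.b <= 1:
            warnings.warn(
                "burst size b <= 1 gives a non-positive basic reproduction "
                "number; the phage cannot persist",
                stacklevel=2,
            )

    def with_(self, **kwargs) -> "BKParams":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class EquilibriumSet:
    """The model's equilibria: origin, phage-free state, and (if R0 > 1) E+."""

    E0: tuple[float, float, float]
    Ef: tuple[float, float, float]
    Eplus: tuple[float, float, float] | None
    R0: float


def _as_state(state) -> np.ndarray:
    arr = np.asarray(state, dtype=float)
    if arr.shape != (3,):
        raise ValueError(f"state must have 3 components (S, I, P), got shape {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise ValueError("state components must be finite")
    return arr


def ode_rhs(params: BKParams, state) -> np.ndarray:
    """Time derivative (dS/dt, dI/dt, dP/dt) at ``state = (S, I, P)``."""
    S, I, P = _as_state(state)
    infection = params.k * S * P
    dS = params.alpha * S * (1.0 - (S + I) / params.C) - infection
    dI = infection - params.lam * I
    dP = params.b * params.lam * I - infection - params.mu * P
    return np.array([dS, dI, dP])


def basic_reproduction_number(params: BKParams) -> float:
    """``R0 = (b - 1)*k*C/mu``: secondary infections per phage at S = C."""
    return (params.b - 1.0) * params.k * params.C / params.mu


def equilibria(params: BKParams) -> EquilibriumSet:
    """All equilibria of the model.

    ``E+`` has coordinates ``S+ = C/R0``, ``I+ = alpha*C/(lam*R0 + alpha) *
    (R0 - 1)/R0`` and ``P+ = lam*R0*I+/(k*C)``; it exists exactly when
    ``R0 > 1`` (at ``R0 = 1`` it merges with the phage-free state in a
    saddle-node bifurcation).
    """
    R0 = basic_reproduction_number(params)
    E0 = (0.0, 0.0, 0.0)
    Ef = (params.C, 0.0, 0.0)
    if R0 > 1.0:
        S = params.C / R0
        I = params.alpha * params.C / (params.lam * R0 + params.alpha) * (R0 - 1.0) / R0
        P = params.lam * R0 * I / (params.k * params.C)
        Eplus = (S, I, P)
    else:
        Eplus = None
    return EquilibriumSet(E0=E0, Ef=Ef, Eplus=Eplus, R0=R0)


def jacobian(params: BKParams, state) -> np.ndarray:
    """Exact Jacobian of :func:`ode_rhs` with respect to (S, I, P)."""
    S, I, P = _as_state(state)
    a, C, k, lam, b, mu = (
        params.alpha,
        params.C,
        params.k,
        params.lam,
        params.b,
        params.mu,
    )
    return np.array(
        [
            [a * (1.0 - (2.0 * S + I) / C) - k * P, -a * S / C, -k * S],
            [k * P, -lam, k * S],
            [-k * P, b * lam, -k * S - mu],
        ]
    )


def _max_real_eig_at_eplus(params: BKParams) -> float | None:
    eq = equilibria(params)
    if eq.Eplus is None:
        return None
    eig = np.linalg.eigvals(jacobian(params, eq.Eplus))
    return float(np.max(eig.real))


def hopf_threshold(
    params: BKParams,
    vary: str,
    lo: float,
    hi: float,
    tol: float = 1e-10,
) -> float | None:
    """Critical value of one parameter at which E+ loses stability.

    Scans ``vary`` in ``[lo, hi]`` for a sign change of the largest real part
    of the Jacobian eigenvalues at E+, then bisects to ``tol``.  Returns
    ``None`` if the spectral abscissa does not change sign on the interval
    (restricted to the sub-interval where E+ exists).
    """
    if vary not in _PARAM_NAMES:
        raise ValueError(f"unknown parameter {vary!r}; expected one of {_PARAM_NAMES}")
    if not lo < hi:
        raise ValueError("require lo < hi")

    def abscissa(value: float) -> float | None:
        return _max_real_eig_at_eplus(params.with_(**{vary: value}))

    # restrict to where E+ exists
    samples = np.linspace(lo, hi, 201)
    values = [(v, abscissa(v)) for v in samples]
    values = [(v, a) for v, a in values if a is not None]
    if not values:
        raise ValueError(
            f"E+ exists nowhere on [{lo}, {hi}] for parameter {vary!r} (R0 <= 1 throughout)"
        )
    bracket = None
    for (v0, a0), (v1, a1) in zip(values, values[1:]):
        if np.sign(a0) != np.sign(a1):
            bracket = (v0, v1)
            break
    if bracket is None:
        return None
    return float(brentq(abscissa, *bracket, xtol=tol))


def simulate_ode(
    params: BKParams,
    init,
    t_end: float,
    out_times=None,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    method: str = "LSODA",
):
    """Integrate the ODE model; returns a pandas DataFrame ``t, S, I, P``.

    Uses an adaptive stiff-capable solver.  The large relaxation cycles pass
    through very low infection levels, hence the tight default absolute
    tolerance.  Output components are clipped at zero; an undershoot beyond
    ``100*atol`` triggers a warning instead of being silently hidden.
    """
    import pandas as pd

    init = _as_state(init)
    if np.any(init < 0):
        raise ValueError("initial state must be non-negative")
    if not t_end > 0:
        raise ValueError("t_end must be positive")
    if out_times is None:
        out_times = np.linspace(0.0, t_end, 401)
    out_times = np.asarray(out_times, dtype=float)

    sol = solve_ivp(
        lambda t, y: ode_rhs(params, y),
        (0.0, t_end),
        init,
        method=method,
        t_eval=out_times,
        jac=lambda t, y: jacobian(params, y),
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:
        last_t = sol.t[-1] if sol.t.size else 0.0
        raise RuntimeError(f"ODE solver failed at t={last_t:.6g}: {sol.message}")
    y = sol.y.T
    undershoot = y.min()
    if undershoot < -100.0 * atol:
        warnings.warn(
            f"trajectory undershoots zero by {-undershoot:.3g}; "
            "consider tightening solver tolerances",
            stacklevel=2,
        )
    y = np.clip(y, 0.0, None)
    return pd.DataFrame({"t": sol.t, "S": y[:, 0], "I": y[:, 1], "P": y[:, 2]})
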