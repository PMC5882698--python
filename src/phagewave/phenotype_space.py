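"""Fitness landscapes, phenotype grid, and the mutation (dispersion) operator.

Viral variants are indexed by a one-dimensional phenotype coordinate ``r``
(dimensionless).  A fitness landscape assigns each variant its four
phenotypic traits: infection rate ``k(r)``, lysis rate ``lam(r)``, phage
decay rate ``mu(r)`` and burst size ``b(r)``.  Small random mutations are
modelled as diffusion of density through phenotype space with a small,
variant-independent dispersion coefficient ``q``.

The truncated interval ``(0, r_end]`` is discretized uniformly; the discrete
Laplacian is the standard second-order central difference.  Two boundary
closures are provided:

``"robin"``
    The condition ``q * d(field)/dn = field`` (outward normal derivative) at
    both ends, eliminated through first-order ghost nodes.  Note that at the
    right end this orientation feeds the boundary node at rate ``~1/dr``
    (continuum rate ``~1/q``): any nonzero density there grows explosively,
    so this closure is only usable while the solution stays away from the
    boundary.  See the methods note for discussion.

``"no-flux"``
    Homogeneous Neumann closure (reflecting ends).  With ``q ~ 1e-6`` and a
    pulse far from the boundary the interior solution is indistinguishable
    from the Robin one; this is the closure the shipped presets use.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy import sparse

__all__ = [
    "FitnessLandscape",
    "LinearKLandscape",
    "TabulatedLandscape",
    "Grid",
    "build_grid",
    "variant_r0",
    "dispersion_operator",
]

MIN_NODES = 16


@dataclass(frozen=True)
class FitnessLandscape:
    """Trait functions of a 1-D phenotype coordinate; all must be positive on (0, r_end]."""

    k_of_r: Callable[[np.ndarray], np.ndarray]
    lam_of_r: Callable[[np.ndarray], np.ndarray]
    mu_of_r: Callable[[np.ndarray], np.ndarray]
    b_of_r: Callable[[np.ndarray], np.ndarray]

    def traits(self, r: np.ndarray):
        """Evaluate (k, lam, mu, b) on an array of coordinates."""
        r = np.asarray(r, dtype=float)
        shape = np.shape(r)
        vals = tuple(np.broadcast_to(f(r), shape).astype(float) for f in
                     (self.k_of_r, self.lam_of_r, self.mu_of_r, self.b_of_r))
        for name, v in zip(("k", "lam", "mu", "b"), vals):
            if np.any(v <= 0) or not np.all(np.isfinite(v)):
                raise ValueError(f"landscape trait {name}(r) must be finite and > 0")
        return vals


def LinearKLandscape(xi: float, lam: float, mu: float, b: float) -> FitnessLandscape:
    """Landscape with ``k(r) = xi*r`` and constant ``lam, mu, b``.

    The Darwinian fitness ``R0(r) = (b-1)*C*xi*r/mu`` then grows linearly in
    the phenotype coordinate, which makes directional selection transparent.
    """
    if xi <= 0:
        raise ValueError("landscape slope xi must be > 0")
    for name, v in (("lam", lam), ("mu", mu), ("b", b)):
        if v <= 0:
            raise ValueError(f"landscape constant {name} must be > 0")
    ls = FitnessLandscape(
        k_of_r=lambda r: xi * np.asarray(r, dtype=float),
        lam_of_r=lambda r: np.full_like(np.asarray(r, dtype=float), lam),
        mu_of_r=lambda r: np.full_like(np.asarray(r, dtype=float), mu),
        b_of_r=lambda r: np.full_like(np.asarray(r, dtype=float), b),
    )
    object.__setattr__(ls, "xi", xi)
    return ls


def TabulatedLandscape(tables: dict[str, np.ndarray]) -> FitnessLandscape:
    """Landscape from per-trait ``(r, value)`` tables, linearly interpolated.

    ``tables`` maps each of ``"k", "lam", "mu", "b"`` to a two-column array.
    """
    interps = {}
    for name in ("k", "lam", "mu", "b"):
        if name not in tables:
            raise ValueError(f"tabulated landscape is missing trait {name!r}")
        tab = np.asarray(tables[name], dtype=float)
        if tab.ndim != 2 or tab.shape[1] != 2 or tab.shape[0] < 2:
            raise ValueError(f"trait table {name!r} must have shape (>=2, 2)")
        r, v = tab[:, 0], tab[:, 1]
        if np.any(np.diff(r) <= 0):
            raise ValueError(f"trait table {name!r} must have increasing r")
        interps[name] = (r, v)

    def make(name):
        r, v = interps[name]
        return lambda x: np.interp(np.asarray(x, dtype=float), r, v)

    return FitnessLandscape(
        k_of_r=make("k"), lam_of_r=make("lam"), mu_of_r=make("mu"), b_of_r=make("b")
    )


@dataclass(frozen=True, eq=False)
class Grid:
    """Uniform discretization of the truncated phenotype interval (0, r_end]."""

    r_end: float
    n: int
    nodes: np.ndarray = field(repr=False)
    dr: float

    @property
    def trapezoid_weights(self) -> np.ndarray:
        """Composite-trapezoid quadrature weights over the node range."""
        w = np.full(self.n, self.dr)
        w[0] = w[-1] = 0.5 * self.dr
        return w

    def integrate(self, values: np.ndarray) -> float:
        """Composite trapezoid integral of a nodal field."""
        values = np.asarray(values, dtype=float)
        if values.shape[-1] != self.n:
            raise ValueError(f"field has {values.shape[-1]} nodes, grid has {self.n}")
        return float(np.trapezoid(values, dx=self.dr))


def build_grid(r_end: float, n: int) -> Grid:
    """Uniform grid with node ``j`` at ``j*dr`` (j = 1..n), ``dr = r_end/n``."""
    if not r_end > 0:
        raise ValueError("r_end must be > 0")
    if int(n) != n or n < MIN_NODES:
        raise ValueError(f"need at least {MIN_NODES} nodes, got {n}")
    n = int(n)
    dr = r_end / n
    nodes = dr * np.arange(1, n + 1)
    return Grid(r_end=float(r_end), n=n, nodes=nodes, dr=dr)


def variant_r0(landscape: FitnessLandscape, r, C: float):
    """Variant-specific basic reproduction number ``R0(r) = (b(r)-1)*C*k(r)/mu(r)``.

    This is the natural measure of a variant's Darwinian fitness: the number
    of secondary infections its phage achieve in a fully susceptible
    population at carrying capacity.
    """
    r_arr = np.asarray(r, dtype=float)
    if np.any(r_arr <= 0):
        raise ValueError("phenotype coordinate r must be > 0")
    k, _, mu, b = landscape.traits(r_arr)
    out = (b - 1.0) * C * k / mu
    return float(out) if np.isscalar(r) or np.shape(r) == () else out


def dispersion_operator(grid: Grid, q: float, bc: str = "robin") -> sparse.csr_matrix:
    """Sparse matrix of the mutation operator ``q * Laplacian`` on grid fields.

    Interior rows are the central second difference scaled by ``q``; boundary
    rows encode the requested closure (see module docstring).  For ``q = 0``
    the operator degenerates to the zero map and the boundary nodes are left
    uncoupled (the printed Robin condition then reduces to field = 0 at the
    ends, which holds trivially for a pulse away from the boundary).
    """
    if q < 0:
        raise ValueError("dispersion coefficient q must be >= 0")
    if bc not in ("robin", "no-flux"):
        raise ValueError(f"unknown boundary condition {bc!r}; expected 'robin' or 'no-flux'")
    n, dr = grid.n, grid.dr
    if q == 0.0:
        return sparse.csr_matrix((n, n))
    lower = np.ones(n - 1)
    main = np.full(n, -2.0)
    upper = np.ones(n - 1)
    L = sparse.diags([lower, main, upper], [-1, 0, 1], format="lil")
    # ghost-node elimination at both ends
    if bc == "no-flux":
        # ghost = boundary value: q*(u_ghost - 2u_0 + u_1)/dr^2 -> q*(u_1 - u_0)/dr^2
        L[0, 0] = -1.0
        L[-1, -1] = -1.0
        op = (q / dr**2) * L.tocsr()
    else:
        # printed Robin form, outward normal: q*(u_ghost - u_end)/dr = u_end
        # => u_ghost = u_end*(1 + dr/q); second difference at the boundary row
        # becomes q*(u_neighbor - u_end)/dr^2 + u_end/dr
        L[0, 0] = -1.0
        L[-1, -1] = -1.0
        op = (q / dr**2) * L.tocsr() + sparse.diags(
            np.r_[1.0 / dr, np.zeros(n - 2), 1.0 / dr]
        )
    return op.tocsr()
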