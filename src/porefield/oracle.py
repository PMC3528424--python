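"""Independent numerical electrostatics oracles.

Two routes that do not share code with the analytic engine beyond the
potential definition they are checked against:

* ``numeric_gradient_field`` recovers E = |-grad V| from the pair potential
  by second-order central differences, validating the hand-derived gradient
  in the closed-form field expression.
* ``fd_laplace_solve`` solves the 2-D Laplace equation with successive
  over-relaxation (SOR) for a single pair, with Dirichlet data +/- V_AB/2
  on nodes inside the conductor circles, validating that the analytic
  potential is the solution of the boundary-value problem it claims to
  solve.  The outer boundary ring carries the analytic potential so the
  comparison isolates interior accuracy (a validation choice, not a physics
  claim).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from numba import njit

from .field import pair_potential
from .geometry import Layout, PairGeometry, pair_geometries

__all__ = ["RelaxationGrid", "ConvergenceError", "numeric_gradient_field", "fd_laplace_solve"]

SOR_OMEGA = 1.9
SOR_TOL = 1e-8  # volts, max absolute node update per sweep
SOR_MAX_ITERS = 50_000


class ConvergenceError(RuntimeError):
    """SOR failed to reach the tolerance within the iteration budget."""


@dataclass(frozen=True)
class RelaxationGrid:
    """Converged SOR solution on an n x n node grid spanning the tissue square.

    Nodes are corner-inclusive: ``x_i = -L/2 + i * L/(n-1)``; ``fixed``
    marks Dirichlet nodes (electrode interiors and the outer ring), which
    retain their values at every iteration.  ``potential[r, c]`` follows the
    field-map orientation (row 0 = max y).
    """

    n: int
    potential: np.ndarray  # (n, n) volts
    fixed: np.ndarray  # (n, n) bool
    residual: float  # volts
    iterations: int

    def nodes(self, extent: float) -> tuple[np.ndarray, np.ndarray]:
        xs = np.linspace(-extent / 2, extent / 2, self.n)
        ys = xs[::-1].copy()
        return np.meshgrid(xs, ys)


def numeric_gradient_field(x: float, y: float, pair: PairGeometry, h: float | None = None) -> float:
    """Field magnitude from a central-difference gradient of the potential.

    Second-order in the step ``h`` (default 1e-6 * d_AB); converges to the
    closed-form field as h -> 0.
    """
    if h is None:
        h = 1e-6 * pair.d_ab
    if not (h > 0):
        raise ValueError(f"step must be positive, got {h}")
    dvdx = (pair_potential(x + h, y, pair) - pair_potential(x - h, y, pair)) / (2 * h)
    dvdy = (pair_potential(x, y + h, pair) - pair_potential(x, y - h, pair)) / (2 * h)
    return math.hypot(dvdx, dvdy)


@njit(cache=True)
def _sor_sweep(v, fixed, omega, tol, max_iters):  # pragma: no cover - numba kernel
    n = v.shape[0]
    for it in range(max_iters):
        delta = 0.0
        for r in range(1, n - 1):
            for c in range(1, n - 1):
                if fixed[r, c]:
                    continue
                new = 0.25 * (v[r - 1, c] + v[r + 1, c] + v[r, c - 1] + v[r, c + 1])
                upd = omega * (new - v[r, c])
                v[r, c] += upd
                a = abs(upd)
                if a > delta:
                    delta = a
        if delta <= tol:
            return delta, it + 1
    return delta, max_iters


def fd_laplace_solve(
    layout: Layout,
    n: int = 200,
    *,
    omega: float = SOR_OMEGA,
    tol: float = SOR_TOL,
    max_iters: int = SOR_MAX_ITERS,
) -> RelaxationGrid:
    """Finite-difference Laplace solution for a single-pair layout.

    Dirichlet values: +V_AB/2 on nodes of the anode disk, -V_AB/2 on the
    cathode disk, the analytic pair potential on the outer boundary ring.
    Deterministic row-major SOR sweeps until the largest node update falls
    below ``tol``.

    The discrete conductor disk is the node set within ``rho0 + h/2`` of
    the center (h = grid spacing): a Dirichlet node constrains the
    discrete solution only at the node itself, so the effective
    (capacitance-equivalent) boundary of the bare node set {r <= rho0}
    sits about half a spacing INSIDE the physical surface, biasing the
    whole exterior solution by O(h).  Padding by half a cell centers the
    staircase boundary on the true circle and restores O(h^2)-like
    agreement with the continuum solution.
    """
    pairs = pair_geometries(layout)
    if len(pairs) != 1:
        raise ValueError(f"relaxation oracle requires a single-pair layout, got {len(pairs)} pairs")
    if n < 100:
        raise ValueError(f"grid size must be >= 100, got {n}")
    pair = pairs[0]
    L = layout.tissue_side
    xs = np.linspace(-L / 2, L / 2, n)
    ys = xs[::-1].copy()
    xg, yg = np.meshgrid(xs, ys)

    v = np.zeros((n, n))
    fixed = np.zeros((n, n), dtype=bool)
    h = L / (n - 1)
    r_disk = layout.electrode_radius + h / 2  # half-cell padding, see docstring
    a, c = pair.anode, pair.cathode
    in_anode = (xg - a.x) ** 2 + (yg - a.y) ** 2 <= r_disk**2
    in_cathode = (xg - c.x) ** 2 + (yg - c.y) ** 2 <= r_disk**2
    v[in_anode] = +pair.voltage / 2
    v[in_cathode] = -pair.voltage / 2
    fixed |= in_anode | in_cathode

    ring = np.zeros((n, n), dtype=bool)
    ring[0, :] = ring[-1, :] = ring[:, 0] = ring[:, -1] = True
    ring &= ~fixed
    v[ring] = pair_potential(xg[ring], yg[ring], pair)
    fixed |= ring

    residual, iters = _sor_sweep(v, fixed, omega, tol, max_iters)
    if residual > tol:
        raise ConvergenceError(
            f"SOR did not converge in {max_iters} sweeps (residual {residual:.3e} V > {tol:.1e} V)"
        )
    return RelaxationGrid(n=n, potential=v, fixed=fixed, residual=residual, iterations=iters)
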