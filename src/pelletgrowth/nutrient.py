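"""Quasi-steady nutrient boundary-value problem and analytic oracles.

In the quasi-steady limit the nutrient profile satisfies, inside the
sphere of dimensionless radius ``S``,

    laplacian(B) = f(B) * n,      f(B) = B / (kappa + B)  (B > 0),

with ``B = 1`` at the pellet surface and zero flux at the centre.  On
the front-fixed coordinate ``y = r/S`` this becomes

    B'' + (2/y) B' = S^2 f(B) n   on (0, 1),   B'(0) = 0,  B(1) = 1,

with the centre handled through the symmetric limit
``laplacian(B) -> 3 B''`` at ``y = 0``.

When the pellet is large enough the nutrient is exhausted before it
reaches the centre and a "dead core" forms in which both consumption
and matrix production cease.  The closed-form solutions implemented at
the bottom of this module (saturated consumption with and without a
core, and the small-B linear limit) are deliberately independent of the
finite-difference path and serve as verification oracles.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import get_lapack_funcs
from scipy.optimize import brentq

from .params import RadialGrid, kinetics_f

__all__ = [
    "BvpSolution",
    "ConvergenceError",
    "solve_nutrient",
    "analytic_no_core",
    "analytic_dead_core_radius",
    "analytic_linear",
]

#: Radius threshold sqrt(6) above which a dead core exists in the
#: saturated-consumption limit.
CORE_THRESHOLD = np.sqrt(6.0)


class ConvergenceError(RuntimeError):
    """Nonlinear nutrient solve failed to reach tolerance."""

    def __init__(self, message: str, residual: float):
        super().__init__(message)
        self.residual = residual


@dataclass
class BvpSolution:
    """Converged nutrient profile with solver diagnostics."""

    B: np.ndarray
    iterations: int
    residual: float


def _assemble_laplacian(grid: RadialGrid, S: float):
    """Conservative three-point stencil for the spherical Laplacian in
    mapped coordinates, scaled so row i reads  (Lap B)_i  =  rhs_i."""
    y, dy, N = grid.y, grid.dy, grid.N
    yh_lo = (y - dy / 2) ** 2
    yh_hi = (y + dy / 2) ** 2
    lower = np.zeros(N)
    diag = np.zeros(N)
    upper = np.zeros(N)
    i = np.arange(1, N - 1)
    a = yh_lo[i] / (y[i] ** 2 * dy * dy)
    c = yh_hi[i] / (y[i] ** 2 * dy * dy)
    lower[i] = a
    upper[i] = c
    diag[i] = -(a + c)
    # centre: symmetric limit laplacian -> 3 B'' with ghost B[-1] = B[1]
    diag[0] = -6.0 / dy**2
    upper[0] = 6.0 / dy**2
    return lower, diag, upper


def _residual(B, lower, diag, upper, source_coef, kappa):
    """Max-norm residual of the nonlinear discrete system (Dirichlet row
    excluded; it is satisfied exactly)."""
    N = len(B)
    r = np.empty(N - 1)
    lap0 = diag[0] * B[0] + upper[0] * B[1]
    r[0] = lap0 - source_coef[0] * kinetics_f(B[0], kappa)
    i = np.arange(1, N - 1)
    lap = lower[i] * B[i - 1] + diag[i] * B[i] + upper[i] * B[i + 1]
    r[1:] = lap - source_coef[i] * kinetics_f(B[i], kappa)
    return float(np.max(np.abs(r)))


_gtsv = get_lapack_funcs(("gtsv",), (np.empty(0, dtype=np.float64),))[0]


def _solve_tridiag(lower, diag, upper, rhs):
    # direct LAPACK tridiagonal solve; the wrapper overhead of
    # solve_banded is measurable in the time-stepping loop
    _, _, _, x, info = _gtsv(lower[1:], diag, upper[:-1], rhs)
    if info != 0:
        raise np.linalg.LinAlgError(f"tridiagonal solve failed (info={info})")
    return x


def solve_nutrient(
    n: np.ndarray,
    S: float,
    kappa: float,
    grid: RadialGrid,
    tol: float = 1e-9,
    max_iter: int = 200,
    B0: np.ndarray | None = None,
    newton_threshold: float = 1e-3,
) -> BvpSolution:
    """Solve the quasi-steady nutrient problem for a given cell profile.

    The nonlinearity is handled by Picard iteration with the Michaelis-
    Menten denominator lagged, ``f(B) ~ B / (kappa + B_old)``, which
    keeps every iterate inside ``[0, 1]`` (the linearised operator is an
    M-matrix), followed by Newton steps once the residual drops below
    ``newton_threshold``.  A Newton step that increases the residual is
    discarded in favour of a Picard step, so the iteration is globally
    robust across the near-degenerate dead-core regime.

    Parameters
    ----------
    n : ndarray
        Cell volume fraction per node, in ``[0, 1]``.
    S : float
        Dimensionless pellet radius (positive).
    kappa : float
        Michaelis constant (positive).
    grid : RadialGrid
        Mapped radial grid.
    tol : float
        Convergence tolerance on the max-norm of the discrete residual.
    B0 : ndarray, optional
        Warm-start profile (for example the previous time step).

    Returns
    -------
    BvpSolution

    Raises
    ------
    ConvergenceError
        If the residual does not reach ``tol`` within ``max_iter``
        iterations; the exception carries the last residual.
    ValueError
        On negative ``n`` or nonpositive ``S``, ``kappa`` or ``tol``.
    """
    n = np.asarray(n, dtype=float)
    if len(n) != grid.N:
        raise ValueError(f"n has {len(n)} entries for a grid of {grid.N} nodes")
    if np.any(n < 0):
        raise ValueError("cell fraction n must be nonnegative")
    if S <= 0:
        raise ValueError(f"S must be positive, got {S}")
    if tol <= 0:
        raise ValueError(f"tol must be positive, got {tol}")
    if kappa <= 0:
        raise ValueError(f"kappa must be positive, got {kappa}")

    N = grid.N
    lower, diag, upper = _assemble_laplacian(grid, S)
    source_coef = S * S * n  # multiplies f(B)

    B = np.ones(N) if B0 is None else np.clip(np.asarray(B0, dtype=float), 0.0, 1.0)
    res = _residual(B, lower, diag, upper, source_coef, kappa)
    if res < tol:
        return BvpSolution(B=B, iterations=0, residual=res)

    for it in range(1, max_iter + 1):
        if res < newton_threshold:
            B_try = _newton_step(B, lower, diag, upper, source_coef, kappa)
            res_try = _residual(B_try, lower, diag, upper, source_coef, kappa)
            if res_try < res:
                B, res = B_try, res_try
                if res < tol:
                    return BvpSolution(B=B, iterations=it, residual=res)
                continue
        B = _picard_step(B, lower, diag, upper, source_coef, kappa)
        res = _residual(B, lower, diag, upper, source_coef, kappa)
        if res < tol:
            return BvpSolution(B=B, iterations=it, residual=res)

    raise ConvergenceError(
        f"nutrient solve did not reach tol={tol:.1e} in {max_iter} iterations "
        f"(last residual {res:.3e})",
        residual=res,
    )


def _picard_step(B, lower, diag, upper, source_coef, kappa):
    """One lagged-denominator Picard sweep: solve the linear M-matrix
    system  Lap B - [S^2 n/(kappa+B_old)] B = 0  with B(1)=1."""
    coef = source_coef / (kappa + np.maximum(B, 0.0))
    d = diag - coef
    lo = lower.copy()
    up = upper.copy()
    rhs = np.zeros(len(B))
    d[-1] = 1.0
    lo[-1] = 0.0
    rhs[-1] = 1.0
    return _solve_tridiag(lo, d, up, rhs)


def _newton_step(B, lower, diag, upper, source_coef, kappa):
    """One Newton step on the full nonlinear system."""
    N = len(B)
    Bp = np.maximum(B, 0.0)
    fprime = np.where(B > 0, kappa / (kappa + Bp) ** 2, 0.0)
    d = diag - source_coef * fprime
    lo = lower.copy()
    up = upper.copy()
    rhs = np.empty(N)
    rhs[0] = -(diag[0] * B[0] + upper[0] * B[1] - source_coef[0] * kinetics_f(B[0], kappa))
    i = np.arange(1, N - 1)
    lap = lower[i] * B[i - 1] + diag[i] * B[i] + upper[i] * B[i + 1]
    rhs[1:-1] = -(lap - source_coef[i] * kinetics_f(B[i], kappa))
    d[-1] = 1.0
    lo[-1] = 0.0
    rhs[-1] = 0.0
    delta = _solve_tridiag(lo, d, up, rhs)
    return B + delta


# ---------------------------------------------------------------------------
# Closed-form oracles (independent of the finite-difference solver)


def analytic_no_core(r, S: float):
    """Saturated-consumption profile without a dead core.

    Closed form of ``laplacian(B) = 1`` in a sphere of radius ``S`` with
    ``B(S) = 1`` and symmetry at the centre:  ``B = 1 - (S^2 - r^2)/6``.
    Valid while the centre value stays nonnegative, i.e. ``S <= sqrt(6)``.
    This is the ``kappa -> 0`` limit of the model with ``n = 1``.
    """
    r = np.asarray(r, dtype=float)
    if S > CORE_THRESHOLD:
        raise ValueError(
            f"S = {S} exceeds sqrt(6): a dead core exists, use the dead-core oracle"
        )
    if np.any(r < 0) or np.any(r > S):
        raise ValueError("r must lie in [0, S]")
    out = 1.0 - (S * S - r * r) / 6.0
    return float(out) if out.ndim == 0 else out


def analytic_dead_core_radius(S: float, tol: float = 1e-10) -> float:
    """Dead-core radius for saturated consumption in a sphere.

    For ``S >= sqrt(6)`` the nutrient vanishes on ``r <= a`` with both
    ``B(a) = 0`` and ``B'(a) = 0``; solving ``laplacian(B) = 1`` on the
    shell ``a < r < S`` with ``B(S) = 1`` gives the core radius as the
    unique root in ``[0, S)`` of

        S^2/6 + a^3/(3S) - a^2/2 = 1.

    The left-hand side is strictly decreasing in ``a`` on ``(0, S)``, so
    bracketed root finding is reliable.
    """
    if S < CORE_THRESHOLD:
        raise ValueError(f"S = {S} below sqrt(6): no dead core exists")

    def g(a: float) -> float:
        return S * S / 6.0 + a**3 / (3.0 * S) - a * a / 2.0 - 1.0

    if g(0.0) <= tol:  # S == sqrt(6) up to round-off: core is born at the centre
        return 0.0
    return float(brentq(g, 0.0, S, xtol=tol))


def analytic_linear(r, S: float, kappa: float):
    """Small-nutrient (linear-consumption) profile.

    For ``B << kappa`` the kinetics reduce to ``B/kappa`` and the profile
    is ``B(r) = S sinh(r/sqrt(kappa)) / (r sinh(S/sqrt(kappa)))`` with the
    finite centre limit ``S / (sqrt(kappa) sinh(S/sqrt(kappa)))``.  Also
    the exact solution of the model for any ``B`` when consumption is
    replaced by its linearisation, which makes it a 2%-level oracle for
    large ``kappa``.
    """
    if kappa <= 0:
        raise ValueError(f"kappa must be positive, got {kappa}")
    r = np.asarray(r, dtype=float)
    if np.any(r < 0) or np.any(r > S):
        raise ValueError("r must lie in [0, S]")
    rk = np.sqrt(kappa)
    denom = np.sinh(S / rk)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(
            r > 0,
            S * np.sinh(r / rk) / (np.where(r > 0, r, 1.0) * denom),
            S / (rk * denom),
        )
    return float(out) if out.ndim == 0 else out
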