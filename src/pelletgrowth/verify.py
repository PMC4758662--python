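"""Built-in verification suite: analytic oracles and scheme diagnostics.

Collects the checks a release must pass into one runnable report:
closed-form nutrient profiles, dead-core location, grid convergence
order, cell-volume conservation and the volume-fraction closure.  Used
by ``pelletgrowth verify`` and importable for tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nutrient import (
    analytic_dead_core_radius,
    analytic_linear,
    analytic_no_core,
    solve_nutrient,
)
from .params import ModelParameters, RadialGrid
from .transport import SolverConfig, cell_volume_integral, initial_state, run_to

__all__ = ["CheckResult", "run_all"]


@dataclass
class CheckResult:
    name: str
    measured: float
    tolerance: float
    passed: bool
    detail: str = ""


def _check(name, measured, tolerance, detail=""):
    return CheckResult(name, float(measured), float(tolerance), bool(measured <= tolerance), detail)


def check_no_core_oracle(N: int = 400) -> CheckResult:
    """Saturated consumption without a core: max error vs closed form."""
    grid = RadialGrid(N)
    S = 2.0
    sol = solve_nutrient(np.ones(N), S, 1e-4, grid)
    exact = analytic_no_core(grid.y * S, S)
    err = np.max(np.abs(sol.B - exact))
    return _check("nutrient_no_core_max_error", err, 1e-3, f"S=2, kappa=1e-4, N={N}")


def check_linear_oracle(N: int = 400) -> CheckResult:
    """Large-kappa (linear consumption) limit: max relative error."""
    grid = RadialGrid(N)
    S, kappa = 2.0, 50.0
    sol = solve_nutrient(np.ones(N), S, kappa, grid)
    exact = analytic_linear(grid.y * S, S, kappa)
    err = np.max(np.abs(sol.B - exact) / exact)
    return _check("nutrient_linear_max_rel_error", err, 0.02, f"S=2, kappa=50, N={N}")


def check_dead_core(N: int = 400, S: float = 6.0) -> CheckResult:
    """Numerical dead-core edge vs the analytic core radius."""
    grid = RadialGrid(N)
    kappa = 1e-4
    sol = solve_nutrient(np.ones(N), S, kappa, grid, max_iter=2000)
    a_exact = analytic_dead_core_radius(S)
    inside = np.where(sol.B < 10 * kappa)[0]
    a_num = grid.y[inside[-1]] * S if len(inside) else 0.0
    cell = S * grid.dy
    return _check(
        "dead_core_radius_error_cells",
        abs(a_num - a_exact) / cell,
        2.0,
        f"numeric {a_num:.4f} vs analytic {a_exact:.4f}, cell {cell:.4f}",
    )


def check_grid_convergence() -> CheckResult:
    """Second-order convergence of the nutrient solver (doubling N).

    Uses a tiny kappa so the saturated closed form is exact to ~1e-9 and
    the measured error is pure discretization; the tolerance is held at
    1e-8 because the residual round-off floor grows as 1/dy^2.
    """
    S = 2.0
    errs = []
    for N in (400, 800, 1600):
        grid = RadialGrid(N)
        sol = solve_nutrient(np.ones(N), S, 1e-9, grid, tol=1e-8, max_iter=800)
        errs.append(np.max(np.abs(sol.B - analytic_no_core(grid.y * S, S))))
    slopes = [np.log2(errs[i] / errs[i + 1]) for i in range(2)]
    slope = float(np.mean(slopes))
    ok = 1.7 <= slope <= 2.3
    return CheckResult(
        "nutrient_convergence_order",
        slope,
        2.3,
        ok,
        f"errors {[f'{e:.2e}' for e in errs]}, want order in [1.7, 2.3]",
    )


def check_conservation(
    t_end: float = 0.5, N: int = 400, dt: float = 1e-3
) -> CheckResult:
    """Relative cell-volume drift over a short growth run at sigma0=6."""
    params = ModelParameters(kappa=0.3, sigma0=6.0)
    grid = RadialGrid(N)
    config = SolverConfig(dt=dt)
    state0 = initial_state(params, grid, config)
    M0 = cell_volume_integral(state0.n, state0.S, grid)
    final = run_to(state0, t_end, params, grid, config)[-1]
    drift = abs(cell_volume_integral(final.n, final.S, grid) / M0 - 1)
    return _check("cell_volume_rel_drift", drift, 1e-3, f"t_end={t_end}, N={N}, dt={dt}")


def check_closure(t_end: float = 0.25, N: int = 200, dt: float = 2e-3) -> CheckResult:
    """Volume-fraction closure |n + p - 1| along a short run."""
    params = ModelParameters(kappa=0.3, sigma0=6.0)
    grid = RadialGrid(N)
    config = SolverConfig(dt=dt)
    final = run_to(initial_state(params, grid, config), t_end, params, grid, config)[-1]
    dev = np.max(np.abs(final.n + final.p - 1.0))
    return _check("closure_max_dev", dev, 1e-10, f"t_end={t_end}")


def run_all(N: int = 400) -> list[CheckResult]:
    """Run the whole suite; any failure means the build is not releasable."""
    return [
        check_no_core_oracle(N),
        check_linear_oracle(N),
        check_dead_core(N),
        check_grid_convergence(),
        check_conservation(),
        check_closure(),
    ]
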