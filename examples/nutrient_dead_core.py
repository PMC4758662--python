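"""Nutrient penetration and the dead core.

Solves the quasi-steady nutrient profile for a fully cellular pellet at
several sizes and compares the numerically starved region with the
closed-form dead-core radius (saturated-consumption limit). Pellets
beyond sqrt(6) diffusion lengths cannot supply their centre.
"""

import numpy as np

from pelletgrowth import (
    RadialGrid,
    analytic_dead_core_radius,
    solve_nutrient,
)

grid = RadialGrid(400)
kappa = 1e-4  # near-saturated consumption

print("S/L    B(centre)    numeric core    analytic core")
for S in (2.0, 3.0, 6.0):
    sol = solve_nutrient(np.ones(grid.N), S, kappa, grid, max_iter=2000)
    starved = np.where(sol.B < 10 * kappa)[0]
    a_num = grid.y[starved[-1]] * S if len(starved) else 0.0
    a_exact = analytic_dead_core_radius(S) if S >= np.sqrt(6) else 0.0
    print(f"{S:3.0f}    {sol.B[0]:9.2e}    {a_num:12.3f}    {a_exact:13.3f}")

print(
    "\nA sigma0 = 2 pellet keeps B > 0 everywhere; at sigma0 = 3 and 6 a"
    "\ncentral dead core appears and grows, matching the analytic radius"
    "\n(root of S^2/6 + a^3/(3S) - a^2/2 = 1) to within the grid spacing."
)
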