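"""Forward-simulate a cartilage cell pellet at the fitted parameters.

A sigma0 = 6 pellet (84 um initial radius, 14 um nutrient diffusion
length) is grown to day 28. The printed table shows the pellet radius
and the proteoglycan fraction at the centre and the surface: matrix
accumulates almost exclusively at the periphery because the centre is
nutrient-starved from the start of culture.
"""

import numpy as np

from pelletgrowth import (
    DimensionalScales,
    ModelParameters,
    RadialGrid,
    SolverConfig,
    bin_profile,
    days_to_model_time,
    initial_state,
    run_to,
)

params = ModelParameters(kappa=0.3, sigma0=6.0)
scales = DimensionalScales()  # S0 = 84 um, L = 14 um, beta = 0.23 / day
grid = RadialGrid(200)
config = SolverConfig(dt=2e-3)

days = (7, 14, 21, 28)
checkpoints = [days_to_model_time(d, scales) for d in days]
states = run_to(
    initial_state(params, grid, config),
    checkpoints[-1], params, grid, config, checkpoints=checkpoints,
)

print("day   radius_um   p(centre)   p(surface)")
for day, st in zip(days, states):
    print(f"{day:3d}   {st.S * scales.L_um:9.1f}   {st.p[0]:9.4f}   {st.p[-1]:10.4f}")

rings = bin_profile(states[-1].p, grid, n_rings=6)
print("\nday-28 ring-binned proteoglycan fractions (centre -> surface):")
print("  " + "  ".join(f"{v:.3f}" for v in rings.values))
print(
    "\nThe outer rings approach the 0.7-0.9 fractions seen in stained"
    "\nsections at late culture, while the centre stays nearly matrix-free."
)
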