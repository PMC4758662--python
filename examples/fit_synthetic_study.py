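"""Parameter estimation from a synthetic histology study.

Generates noisy ring measurements (3 replicate pellets x 8 sections,
5% section-to-section noise) at the fitted parameter point, re-fits
(sigma0, kappa, beta) on the day-21/28 ring means, and profiles the
objective in kappa. The initial size sigma0 is recovered well; kappa is
only weakly constrained on its small side, which is why the original
data fit could not pin it down.
"""

import numpy as np

from pelletgrowth import (
    DimensionalScales,
    ModelParameters,
    fit,
    generate,
    profile_identifiability,
)

truth = {"sigma0": 6.0, "kappa": 0.3, "beta_per_day": 0.23}
params = ModelParameters(kappa=truth["kappa"], sigma0=truth["sigma0"])
scales = DimensionalScales(beta_per_day=truth["beta_per_day"])

dataset = generate(params, scales, noise_sd=0.05, n_replicates=3,
                   sections_per_replicate=8, seed=42)
print(f"dataset: {len(dataset.data)} ring measurements, days {dataset.days}")

result = fit(dataset, n_starts=2, seed=0, maxfev=100)
print("\nfitted parameters (truth in brackets):")
for name, value in result.estimates.items():
    print(f"  {name:13s} = {value:7.4f}   [{truth[name]}]")
print(f"  loss = {result.loss:.2e} after {result.n_evaluations} simulations")

profile = profile_identifiability(
    dataset, "kappa", np.geomspace(0.03, 3, 7),
    fixed={"sigma0": truth["sigma0"], "beta_per_day": truth["beta_per_day"]},
)
print("\nkappa identifiability profile (loss along a two-decade grid):")
for _, row in profile.iterrows():
    print(f"  kappa = {row['value']:6.3f}   loss = {row['loss']:.4f}")
print(
    "\nLosses barely move below kappa ~ 0.3 (weakly identified there) but"
    "\nclimb for large kappa, where the kinetics become effectively linear."
)
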