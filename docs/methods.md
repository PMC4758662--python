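# Methods

## Model and assumptions

The pellet is a sphere of dimensionless radius S(t) made of two
incompressible volume fractions — cells n(r, t) and proteoglycan matrix
p(r, t), n + p = 1 — plus a diffusing nutrient B(r, t) normalised by its
concentration in the stirred medium. The model deliberately omits cell
proliferation and death (pellet cultures are past their proliferative
phase by the first harvest), treats collagen as inert background, and
lets cells and matrix share one velocity field u = (v, 0, 0).

Consumption and production share one saturating rate law,
f(B) = B/(κ + B) for B > 0 and 0 otherwise; the Heaviside cutoff
encodes that matrix cannot degrade back into nutrient. The quasi-steady
limit ξ = 0 is assumed throughout: nutrient transport equilibrates
instantaneously on the matrix-production time scale, so B solves the
elliptic problem ∇²B = f(B)·n at every instant with B = 1 at the surface
and symmetry at the centre. `ModelParameters` rejects ξ ≠ 0; the full
hyperbolic–parabolic system is out of scope.

Matrix production creates volume, ∇·u = f(B)·n, which both dilutes the
cell fraction and moves the boundary through the kinematic condition
dS/dt = v(S). With p closed algebraically as 1 − n, the model state is
(n, B, S).

### Parameters

| symbol | meaning | default | unit |
|---|---|---|---|
| κ (`kappa`) | Michaelis constant / medium concentration | 0.3 | — |
| Σ₀ (`sigma0`) | initial radius / diffusion length | 6 | — |
| L (`L_um`) | nutrient diffusion length | 14 | µm |
| S₀ (`S0_um`) | initial pellet radius | 84 | µm |
| β (`beta_per_day`) | matrix production rate constant | 0.23 | day⁻¹ |

Defaults are the values that fit day-21/28 pellet measurements. Σ₀ and
S₀/L are cross-checked to 10⁻¹² relative whenever both are supplied.

**The β unit.** The source literature prints β with the unit s⁻¹, which
would saturate a pellet with matrix within minutes and is irreconcilable
with 28-day culture dynamics. This package interprets β = 0.23 **per
day**, giving dimensionless times t̃ = β·days ∈ [1.61, 6.44] for days
7–28 and model behaviour on the observed time scale. Because the
quasi-steady reduction leaves matrix production as the only rate, the
dimensionless time unit is 1/β and `days_to_model_time` is simply
β·days. The unit lives in one configurable field (`beta_per_day`), so a
user who disagrees can override it; the choice is flagged here rather
than silently corrected.

## Numerics

### Front-fixing map

The moving domain is mapped to the unit interval by y = r/S(t) (the same
normalised radius the experimental profiles are plotted on). All fields
live on one uniform y-grid; `RadialGrid(N)` with N = 400 nodes is the
production default, N = 80–200 the reduced budgets (below).

### Nutrient solve

The mapped equation B″ + (2/y)B′ = S² f(B) n is discretised with the
conservative three-point stencil ((y²B′)′/y²); the centre uses the
symmetric limit ∇²B → 3B″. The nonlinear system is solved by Picard
iteration with a lagged Michaelis denominator — the linearised operator
is an M-matrix, so every iterate stays in [0, 1] — switching to Newton
steps once the residual falls below 10⁻³, with fallback to Picard
whenever a Newton step fails to reduce the residual. Dead cores need no
explicit interface tracking: B is clamped to max(B, 0) inside the
kinetics, and the discrete solution decays exponentially into the core.

Default residual tolerance 10⁻⁹ (max norm of the discrete equations).
The operator entries scale as 2/Δy² ≈ 3·10⁵ at N = 400, so the residual
round-off floor is a few 10⁻¹⁰; 10⁻⁹ sits ~6 orders below the
truncation error while remaining reachable in double precision. Warm
starts from the previous time step make the per-step cost one or two
Newton iterations.

Verification oracles (independent closed forms, in `nutrient.py` and
exercised by `pelletgrowth verify`): the saturated no-core profile
1 − (S² − r²)/6; the dead-core radius as the bracketed root of
S²/6 + a³/(3S) − a²/2 = 1 (unique: the left side is strictly decreasing
in a); and the linear-consumption sinh profile for B ≪ κ. Measured at
N = 400: no-core error 1.5·10⁻⁴, sinh relative error 2.6·10⁻⁴,
dead-core edge within 1.5 cells of a = 4.4451 for S = 6. The observed
convergence order is ≈1.85 (the centre stencil is locally first-order;
the global error is still dominated by the second-order interior).

### Transport and the moving boundary

The cell-conservation law is advanced by a finite-volume scheme on the
mapped grid: nodes act as cell centres (half cells at y = 0 and 1), and
one backward-Euler step solves

    g_i (1 + 3Δt·Ṡ/S) n_i^{new} + (Δt) Δ_faces[ y_f² c_f n_up ] = g_i n_i^{old}

where g_i = (y_hi³ − y_lo³)/3 is the exact cell volume in the y²dy
measure, c_f = (v_f − y_f Ṡ)/S the characteristic speed at the face,
n_up the first-order upwind value, and the (1 + 3Δt·Ṡ/S) factor the
implicit geometric dilution the front-fixing map introduces. Face
velocities come from the cumulative midpoint sum of the production
integral y² f(B) n, and Ṡ = v(1) from the total. Two exact discrete
identities motivate this construction over the nonconservative
characteristic form:

* **conservation** — the flux vanishes identically at both ends (c = 0
  at y = 0 and, by the kinematic condition, at y = 1), so total cell
  volume S³·Σ g_i n_i changes only through the O((Δt·Ṡ/S)²)-per-step
  mismatch between (1 + x)³ and 1/(1 + 3x); measured drift over a full
  day-28 run at Σ₀ = 6 is 1·10⁻⁴ relative (N = 400, Δt = 10⁻³), halving
  with Δt;
* **boundedness** — plugging n ≡ 1 into a row yields g_i + Δt·s_i ≥ g_i
  because the face-velocity sums telescope exactly against the
  production integral, so the constant 1 is a discrete supersolution and
  the M-matrix comparison principle keeps n in [0, 1] with no limiter.
  The explicit −f·n² dilution appears implicitly through the flux
  divergence; a single saturated step reproduces n ≈ 1 − Δt and
  S ≈ Σ₀(1 + Δt/3) to O(Δt²).

p is closed algebraically as 1 − n (exact to round-off). A debug mode
(`track_independent_p`) integrates p by its own conservation law
∂p/∂t + ∇·(u p) = f·n with the same implicit operator; because the
production source exactly equals the advection defect of the constant
profile, the independently integrated p agrees with 1 − n to ~10⁻¹⁴ —
a strong internal consistency check.

A step whose relative cell-volume drift exceeds `step_mass_tol`
(default 10⁻⁴) is halved and retried up to `max_halvings` times. The
output velocity field uses cumulative Simpson quadrature (exact for the
saturated v = r/3 case); the stepping itself uses the midpoint face sums
for which the identities above are exact.

Defaults: Δt = 10⁻³ dimensionless (≈6.4·10³ steps per 28-day run),
checkpoints at the day-equivalents {7, 14, 21, 28}.

### Ring binning

A stained central section through a spherically symmetric pellet is a
disc whose in-plane radius equals the 3D radius, so the experimental
per-ring area fractions correspond to weighting the radial profile by y
("section-area", the default); a y² "shell-volume" weighting is provided
for sensitivity analysis since the study protocol does not say whether
area fractions were volume-corrected. Profiles are treated as piecewise
linear and the ring averages evaluated exactly (two-point Gauss per
sub-segment, splitting grid cells at ring edges), so ring means
recombine to the whole-disc mean to round-off. Ring counts 5 and 6
match the sectioning protocol; other counts require an explicit
override.

## Synthetic measurements

`generate` emulates the structure of the study's readout: harvests at
days 7/14/21/28, 3 replicate pellets, 4–14 central sections each
(default 8), 5–6 rings. Each section is the model's ring-mean vector
plus independent truncated-Gaussian noise on the fraction scale
(default SD 0.05; a moment-matched Beta option exists). The true
section-to-section variance of the study is not reported, so the noise
SD is an explicit generator parameter, not an estimate. Truncation bias
is negligible (< 0.005) for ring means in [0.2, 0.8] and grows toward
the 0/1 boundaries — tests restrict mean-recovery claims to the
interior accordingly.

What the generator does **not** emulate: sectioning artefacts (tearing,
off-centre sections), stain-separation error, collagen, or the early
activation-controlled regime. The model is known not to reproduce
day-7/14 measurements, where matrix deposition appears to be governed by
cellular activation spreading rather than nutrient supply; an optional
`early_centre_shift` distorts the early-day means so fitting experiments
can demonstrate why those timepoints are excluded. Passing tests on
synthetic data therefore shows the estimation machinery is correct under
the model's own assumptions — not that the model describes early-stage
biology.

## Fitting

The historical data fit was informal; this package makes it explicit:
sum of squared differences between model ring values and per-ring means
pooled over all replicate sections, by default over days 21 and 28 only,
minimised over (Σ₀, κ, β) by Nelder–Mead (the objective is only
piecewise smooth through the simulator) with κ and β searched in log
scale and a deterministic multi-start (default 5; box Σ₀ ∈ [2, 12],
κ ∈ [0.01, 10], β ∈ [0.05, 0.6] per day). Failed simulations return a
large finite penalty so the simplex can retreat. β is identified by the
change between the two timepoints; Σ₀ by the profile shape.

Objective evaluations run at a reduced budget (N = 80, Δt = 10⁻²,
nutrient tolerance 10⁻⁸): ring values at this resolution differ from an
N = 200, Δt = 2·10⁻³ reference by at most ~0.005, under half the
standard error of a ring mean at the default noise level (0.05/√24 ≈
0.010), so the optimisation surface is unaffected at the precision the
data support. The recovery study (`experiments.recovery_study`) uses 2
starts × 100 evaluations per seed; recovered Σ₀ lands within 10 % of
truth in 10/10 seeds (median error ~3 %).

κ is weakly identified, but **one-sidedly**: on a two-decade profile
grid the loss is nearly flat for κ ≤ 0.3 (range ≈ 5 % of the Σ₀-profile
range) yet rises steeply for κ ≳ 1, where the kinetics become
effectively linear in B and change the spatial shape of the late-time
profile in a way no rescaling of β can absorb. `kappa_flatness` reports
the full-grid range ratio (measured ≈ 0.28 against a Σ₀ ∈ [3, 12]
profile); analyses that treat κ as interchangeable over the whole range
[0.03, 3] overstate the insensitivity.

## Known limitations

* First-order accuracy in time and in the upwind advection; the
  conservation and regime results above quote the resolutions they were
  measured at.
* The ξ = 0 reduction removes early-time nutrient transients entirely.
* One matrix species, no collagen dynamics, no cell proliferation or
  death, no mechanics — by design, to isolate the nutrient-limitation
  mechanism.
* The nondimensionalisation (definition of L in terms of the diffusion
  and consumption constants, and of the time unit) is reconstructed
  from the structure of the equations; only the combinations L, κ, β
  enter the implementation.
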