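# Methods

## Model

The batch culture is described by dynamic flux balance analysis: the
intracellular network is at pseudo-steady state (`S v = 0`, `S` stored
metabolites × reactions so the identity holds literally for column flux
vectors), while boundary species accumulate according to
`dx_i/dt = v_i x_0`, with `x_0` the biomass concentration (gDCW/L) and `v`
specific exchange rates (mmol gDCW⁻¹ h⁻¹). Unlike classical dynamic FBA, no
instantaneous cellular objective is imposed: the flux trajectory itself is
the optimization variable, so the result is an upper bound on what any
regulatory program could achieve, not a prediction of wild-type behaviour.

### Mode reduction

Any steady-state flux is a nonnegative combination of elementary flux modes,
so the feasible boundary behaviour per mol of glucose is the convex hull of
the modes' yield vectors. Modes are enumerated by the double-description
method on the reversibility-split network (bit-set support minimality test
per constraint pass, adequate up to roughly 10⁵ modes; larger sets can be
imported from an external enumerator and are validated against the network
before use), normalized by glucose uptake, projected onto the boundary
species, de-duplicated, reduced to hull vertices (Qhull, with an affine-
subspace fallback for degenerate clouds) and finally to the Pareto-optimal
subset under the production senses an optimal solution can exploit —
maximize biomass, excess ATP and product yields, minimize oxygen-uptake
magnitude; other byproducts are ignored. Glucose is implicit (−1 in every
mode) and excess ATP is a mode coordinate through the non-growth ATP demand
reaction, which is what lets the maintenance constraint act on mode mixes.
Tolerances: nullspace residual 1e-9, duplicate merge 1e-9, hull membership
1e-8 — tighter than the NLP solver tolerance so reduction error cannot
cascade into the optimization.

### Kinetic bounds

Glucose uptake is bounded by a Han–Levenspiel law (Monod in glucose times
`(1 − x_n/C*_n)^{a_n}` product-inhibition terms). Parameters for the
succinate producer: v_max −11.47 mmol gDCW⁻¹ h⁻¹, K_s 11.27 mM, critical
concentrations 860.4 (glucose, exponent 0.603), 385.7 (succinate), 235.3
(formate), 538.8 mM (acetate), all other exponents 1. Above a critical
concentration the base turns negative and a fractional power is undefined;
the bound is clamped to zero (the law is only valid below C*). The ATP
demand flux is bounded below by the non-growth maintenance (4.7 mmol gDCW⁻¹
h⁻¹ anaerobic succinate producer; 8.39 with oxygen uptake bounded at −18.2
for the aerobic preset, which reuses the same uptake law because no
substrate-inhibition model of its own is available). Uptake fluxes are
negative throughout; "minimum" bounds are the most negative admissible
values.

## Optimal control transcription

Time is split into `N_K` finite elements divided as evenly as possible over
`N_F` stages; per stage the mode-fraction vector `y_l` is constant (fixed
relative enzyme allocation) and per collocation point the total activity
`a_jk` scales all modes together, so the state dynamics inside element `j`
read `dx/dτ = h_l a_jk x_{0jk} (Rᵀ y_l)`. States are degree-`N_D` Lagrange
polynomials on the right-endpoint Radau nodes plus an interpolation-only
node at 0 (no collocation constraint there); Radau collocation is used for
its stiff decay, which matters as glucose runs out. The NLP variables are
`X (N_X, N_K, N_D+1)`, `Y (N_F, N_R)`, `A (N_K, N_D+1)` and `h (N_F)`;
constraints are the collocated dynamics, inter-element continuity, unit
mode-fraction sums, the kinetic bounds evaluated at every collocation state
(ATP: `a·(yᵀR)_atp ≥` maintenance; oxygen analogously), pairwise step-ratio
bounds `h_l ≤ 10 h_m`, and a residual-glucose cap `x_glc(t_f) ≤ 0.2
x_glc(0)` that rules out the trivial fast-quit solution. Variable bounds
0 < X < 1000, 0 ≤ Y ≤ 1, 0 < A < 1000 (a finite stand-in for the open upper
bound), 0.1 < h < 30, with strict inequalities realized as closed bounds
with a 1e-9 interior margin. The objective is the productivity
`(x_p(t_f) − x_p(0)) / Σ_j h_{stage(j)}`, the denominator summing each
element's stage step length.

Numerical choices:

- **Scaling.** mM states are scaled by 100, biomass by 1 g/L, activity and
  step lengths by 10, and the productivity objective by 10, before handing
  the problem to the solver.
- **Static-state elimination.** Boundary species that no retained mode can
  move (e.g. pyruvate once Pareto reduction discards all pyruvate-secreting
  modes) are held at their initial value instead of being carried as NLP
  states; keeping them produces rows of degenerate equality constraints
  pinned against variable bounds, which stalls the SQP line search.
- **Solver.** SLSQP (scipy) with finite-difference derivatives, trust-region
  free; a solution is accepted when the scaled constraint violation is below
  1e-5. The transcription is solver-agnostic; an interior-point solver could
  be substituted without touching the constraint functions.
- **Multistart.** The NLP is nonconvex, so each solve runs a deterministic
  start family: uniform mode fractions, a growth-early/product-late
  heuristic (mass concentrated on the best-scoring mode per stage), and
  Dirichlet perturbations from fixed seeds (11, 17, 23). Every start is made
  consistent by forward-simulating its policy with the ODE integrator and
  sampling states and activities onto the collocation grid; the element
  length is set so the horizon reaches 80% glucose consumption.
- **Smoothing.** Inside the NLP the inhibition base is clipped at 1e-9
  rather than 0 to keep the uptake bound differentiable near C*.
- **Stage sweeps** warm-start each stage count from the previous solution
  embedded into the refined stage structure (in addition to the fresh
  multistart), which preserves the feasible-set nesting of stage counts in
  the reported optima.

## Pareto surface

The maximum productivity `P_max` is solved first; the frontier then
maximizes yield — product formed over glucose consumed, exactly that
quotient, not product over initial glucose — under the equality
`(x_p(t_f) − x_p(0)) − α P_max Σ h = 0`, sweeping α from 1 downward with
each solve warm-started from its neighbour (continuation degrades gracefully
from the productivity optimum; the sweep direction is a package choice). At
α = 0 the equality pins net product formation to zero, which is structurally
infeasible whenever every mode co-produces product; such endpoint failures
are reported with their status but not counted toward the >20%
failure-fraction abort. Mass-unit conversions use 180.16 g/mol glucose and
118.09 g/mol succinate.

## Validation oracles

Two independent routes check the transcription. A forward simulator
integrates multi-stage strategies (piecewise-constant mode fractions;
activity either riding the uptake bound, constant, or an arbitrary profile)
with LSODA at rtol 1e-8, flooring depleted species at zero and flagging any
instant at which the ATP maintenance cannot be met — feasibility screening,
not reallocation, so the oracle bounds rather than imitates the NLP. A
brute-force search grids the per-stage mode simplex and the switch time
(horizon adapted from a pilot run to 2.5× the uniform-mix 80%-consumption
time), picks the productivity-optimal endpoint along each trajectory among
the prefix-feasible instants consuming ≥80% of the glucose, and polishes the
best few grid points with Nelder–Mead. Re-simulating a solved collocation
policy (per-stage fractions, interpolated activity) through the integrator
reproduces final states to within 1% of each species' trajectory range on
all packaged problems.

## Packaged networks and study conditions

The *A. succinogenes* fixture is a deliberately lumped ~22-reaction
core-carbon network — EMP glycolysis to PEP, PEP carboxykinase (ATP-forming)
into the reductive malate/fumarate/succinate branch, pyruvate-formate lyase
and pyruvate dehydrogenase at the pyruvate node, acetate kinase, an
oxidative citrate → 2-oxoglutarate → succinate route, a single NAD(H) pool,
and a lumped biomass reaction (1 flux unit ≡ 1 gDCW) — not a genome-scale
reconstruction. The method only needs the boundary yield polytope, and the
fixture reproduces its two anchors exactly: the stoichiometric succinate
maximum 12/7 ≈ 1.71 mol/mol (CO2-fixing reductive flux redox-balanced by the
oxidative branch) and a biomass yield of 0.044 gDCW per mmol glucose, to
which the growth-ATP coefficient is calibrated by bisection on the growth LP
at an uptake of 9.5 mmol gDCW⁻¹ h⁻¹ with maintenance enforced (the measured
yield was obtained under maintenance, so calibration operates under the same
condition). Mode counts of genome-scale reconstructions (thousands of modes)
are not reproduced by this fixture and are not claimed. Balance checking in
the fixtures tracks carbon, with cofactor pairs assigned zero carbon so
conserved moieties cancel; H/O bookkeeping is not meaningful for lumped
steps.

Toy problems define the validation conditions: `growth_vs_product` has two
boundary modes (biomass 0.04 gDCW/mmol, product 0.2, ATP 1.0; versus
product 1.5, ATP 0.5 per glucose), Monod uptake v_max −10, K_s 1 mM, product
inhibition C* 800 mM, maintenance 2.0, inoculum 0.05 gDCW/L in 100 mM
glucose — rates and yields in the range of anaerobic fermentations so the
batch runs 10–20 h. `aerobic_shift` adds an oxygen-consuming high-growth
mode (biomass 0.08, ATP 2.0, O2 −1.5) under an oxygen supply bound of −10,
emulating the aerobic-growth-then-anaerobic-production strategy. Default
initial conditions for fixture runs (0.05 gDCW/L, 500 mM glucose) are
configuration, not claims; the test problems use 100 mM for shorter
horizons. The suite's discretizations (6 elements, degree 3) are chosen as
the coarsest grids at which the solver-vs-oracle and re-simulation checks
hold; production runs default to 20 elements and degree 5.

## What the tests do and do not show

The synthetic problems have smooth kinetics, a single substrate, perfectly
known yields and no biological regulation, lag phases, pH dynamics or
product export limits. Passing the suite shows that the transcription,
reduction and continuation machinery compute the dynamic optimum of the
stated model to the stated tolerances — it does not validate the model
against fermentation data beyond the calibrated anchors above, and computed
maxima are upper bounds that real strains need not attain.

## Known limitations

- SLSQP with finite differences limits practical problem size to a few
  thousand variables; exact-derivative interior-point solving would scale
  further.
- The brute-force oracle covers at most 4 modes and 2 stages (grid growth).
- Local optimality only: the multistart is a heuristic, not a certificate.
- Titer does not enter any objective; fed-batch operation and multiple
  substrates are out of scope.
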