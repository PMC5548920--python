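# Methods

`relfit` estimates kinetic parameters of ODE models of cell-signalling
pathways from relative (arbitrary-unit) time-course data, and instruments the
estimation well enough to compare scaling schemes, objective functions and
optimisation algorithms against each other. This note records the models and
procedures it implements, the defaults and why they were chosen, and what the
synthetic benchmarks do and do not demonstrate.

## Model and observation layer

A model is `dx/dt = f(x, θ)` with named states and parameters, initial state
`x₀(θ)`, and output functions `y = g(x)` mapping states to observables.
Models are declared as arithmetic expressions (`+ - * / ^`, parentheses,
identifiers); the right-hand side is differentiated symbolically at build
time, so the state Jacobian `∂f/∂x`, the parameter Jacobian `∂f/∂θ` and the
output gradients are exact. Experimental conditions are override maps
(parameter values or initial states, e.g. a stimulus dose or a knocked-down
pool size) applied to copies; the base problem is immutable.

Integration uses LSODA (stiff/non-stiff switching) through scipy's low
overhead `odeint` interface with the analytic state Jacobian. Default
tolerances are rtol 1e-8 / atol 1e-10, configurable per problem; the
synthetic benchmark problems set 1e-7/1e-9, trading a little accuracy for
roughly double the throughput (the sensitivity-vs-finite-difference agreement
stays two orders of magnitude inside its acceptance margin at that setting).
Output times are always exactly the measurement times of the condition —
residuals never interpolate.

Forward sensitivities `∂x/∂θ_k` come from the augmented system of dimension
`n_states · (p + 1)`: `dS/dt = (∂f/∂x) S + ∂f/∂θ_free`, with
`S(0) = ∂x₀/∂θ_free` and zero rows for condition-overridden initial states.
The sensitivity right-hand side is built from the symbolic Jacobians, never
from internal finite differences — otherwise the sensitivity-equation (SE)
vs finite-difference (FD) comparison the package exists for would be
measuring a finite-difference method against itself.

## Scaling schemes: DNS and SF

Relative assays (immunoblots, multiplexed ELISA, RT-qPCR) report values on an
arbitrary intensity scale that is only comparable within one replicate. The
standard laboratory normalisation divides each value by a reference — the
average, the maximum, or a designated reference point of that observable in
that replicate: `ỹ_i = ŷ_i / ŷ_ref`. The normalisation group is
(observable, replicate), pooling conditions and times; replicates are fitted
individually after normalisation rather than averaged, preserving the
per-replicate semantics of the normalisation. An alternative convention
normalises within condition; the pooled grouping is the package default and
the one the synthetic benchmarks assume.

Both objective families compare the model against the data *after* the
dataset's own normalisation directive (directive `none` keeps raw values).
They differ in how the simulation reaches that scale:

* **DNS** (data-driven normalisation of simulations): the simulated
  observable is divided by the *same* aggregate — mean, max, or selected
  point — computed over the simulated values at exactly the (condition,
  time) points that defined the data reference for that group. No extra
  parameters; the reference depends on θ and must be recomputed after every
  simulation. A non-positive simulated reference marks the parameter set
  infeasible and maps to a finite penalty (1e10) rather than an exception,
  so derivative-free optimisers can step back out.
* **SF** (scaling factors): one estimated multiplier α_j > 0 per observable
  scales the simulation, `ỹ_i ≈ α_j y_i(θ)`. With J observables this adds J
  search dimensions. α is treated as a genuine search variable (not profiled
  out analytically), matching how such factors behave in estimate ensembles.

Using the same data scale for both schemes makes their least-squares values
directly comparable, which the convergence summaries rely on.

## Objectives

* **LS**: sum of squared residuals `Σ (ỹ_i − μ_i)²`, where μ_i is the
  DNS-normalised or α-scaled simulated value.
* **LL**: negative Gaussian log-likelihood with a two-parameter error model
  `σ_i = s_a + s_b·|μ_i|` (absolute plus proportional noise):
  `Σ [ (ỹ_i − μ_i)²/(2σ_i²) + ln σ_i ]`, additive constant dropped. s_a and
  s_b are estimated jointly with θ. The prediction, not the datum, enters σ
  — weighting noise by itself biases fits toward low-signal points. In the
  s_b = 0 limit with σ fixed, LL is an affine function of LS (same
  minimiser), and minimising over s_a at fixed residuals recovers the usual
  ML variance, s_a* = rms(r); both properties are tested.

For the least-squares optimiser the LL objective is expressed through an
extended residual vector `[(ỹ−μ)/σ, sqrt(2 ln σ + C)]` with C = 60, whose
sum of squares equals `2·NLL + n·C` — an affine transform with identical
minimiser; C keeps the root real for σ down to the 1e-6 search bound.

The free-parameter vector is laid out `[kinetic | α_j… (SF) | s_a, s_b
(LL)]` in declaration order. All searched quantities are positive and are
searched in log10 space; kinetic bounds default to ±3 decades around the
nominal value, nuisance bounds to [1e-6, 1e6].

## Evaluation accounting

Two counting conventions are maintained side by side, because their
disagreement is exactly what makes evaluation counts a misleading proxy for
compute time when gradients come from sensitivity equations:

* `objective_calls` — actual objective/residual evaluations; an SE Jacobian
  counts as **one** call (one augmented-system solve), an FD Jacobian as the
  **p + 1** calls it actually performs.
* `fd_equivalent_evals` — charges p + 1 per gradient *regardless* of how it
  was computed: the cost an FD gradient would have had. For FD runs the two
  columns coincide; for SE runs the first is systematically smaller even
  when wall-clock time is not, since one augmented solve costs far more than
  one plain solve.

Wall time is measured with a monotonic clock around each objective/gradient
call, independently of either count. Every optimiser emits the same trace
records (elapsed seconds, both counts, best objective so far), so
convergence can be summarised per time cutoff (median/quartiles across runs)
or per evaluation count.

## Optimisers

All three searches operate in log10 parameter space within box bounds and
are deterministic given a seed.

**LevMar (SE/FD variants) with Latin-hypercube restarts.** Starts are
log-uniform Latin hypercube samples (exactly one per stratum per dimension).
Each start runs a damped least-squares descent; the two variants differ only
in where the residual Jacobian comes from: sensitivity equations, or forward
differences of the residual vector with a noise-aware relative step of 1e-4
(≈ sqrt of the solver tolerance — residuals carry integration error of order
rtol, so much smaller steps are noise-dominated; oracle comparisons against
the sensitivity Jacobian use 1e-6 explicitly). The inner solver is
scipy's bounded trust-region-reflective least squares with Jacobian column
scaling (`x_scale='jac'`, the Moré convention). A classic fixed-schedule
multiplicative-damping LM was implemented first and retired: on the
benchmark cascades in log space it either crawled along curved valleys
(thousands of iterations stuck around 1e-3) or converged to shallow
stationary points, where the trust-region solver from identical starts
reaches machine-precision minima; column scaling alone changed terminal
objectives by eight orders of magnitude. Termination: relative objective
change, step norm, gradient stationarity, per-start iteration cap, or the
global evaluation/time budget.

**GLSDC** (genetic local search with diversity control) never requests a
gradient. Cycles alternate (i) real-coded genetic generations — the
population sorted by fitness is filtered so every retained elite is at least
δ = 0.1 away from the others in box-normalised coordinates, offspring are
produced by BLX-0.5 crossover with per-coordinate mutation at rate 1/p, and
offspring landing within δ of a retained elite are replaced by fresh uniform
samples — with (ii) Powell refinement of the top three mutually distinct
individuals. The incumbent best carries its conjugate direction set across
cycles: restarting Powell with the previous direction set lets it follow
curved valleys that defeat a fresh axis-aligned set (observed: 2e-12 vs a
1e-6 stall from the same point and budget). Powell's box bounds are enforced
by a quadratic penalty outside the box rather than scipy's bounded line
search, which is markedly less precise near an optimum. Population defaults
to min(10p, 200). These internals are a faithful-in-spirit reconstruction of
the published hybrid's outline (its exact hyper-parameters are not public);
ties in elite selection break by index, so runs are reproducible.

## Practical identifiability

Two complementary tools:

* **Ensemble PCA.** Per-parameter estimates across independent runs are
  normalised as `log2(θ_ij / min_j θ_ij)` (a value of 1 = two-fold above the
  smallest estimate; the printed formula normalises by the per-parameter
  minimum — a best-objective-run baseline is available as an option).
  Columns are centred but not rescaled (the log2 transform is the scaling
  step; whether the original convention centred is not documented — centring
  is the default here). PCA is scoped to the free kinetic parameters;
  scaling-factor and error-model columns are dropped. The **degree of
  practical non-identifiability** is the number of principal components with
  variance strictly greater than 1. This measures estimate dispersion, not
  sloppiness (relative anisotropy of directions): a system can be uniformly
  variable — hence not sloppy — and still unidentifiable.
* **Fisher-information bound at an optimum.** From the residual Jacobian J
  in log10 coordinates, a parameter is *practically identifiable at
  tolerance f* given fit quality ‖r‖ ≤ ρ if its worst-case displacement over
  `{δ : ‖Jδ‖ ≤ ρ}`, which is `ρ·sqrt(Σ_k V_ik²/s_k²)` from the SVD, stays
  below log10(f). This operationalises "which parameters did a perfect fit
  actually pin down", and is how the recovery tests decide which parameters
  must match the ground truth.

A synthetic-cloud generator provides ground truth for the PCA pipeline:
k latent directions embedded orthonormally in log2 space (exactly orthogonal
mean-zero latent columns scaled to the spread of a uniform of width
`spread`) plus isotropic noise in the complement, exponentiated to positive
estimates. For spread 4 and noise sd 0.05 the spectrum is k eigenvalues at
≈1.33 against a floor of 0.0025, so the recovered degree equals k exactly.

## Synthetic benchmark problems

Real calibration problems of this kind (pseudophosphatase/ERK and
EGF/HRG-driven ERK pathway models with 25-49 species) are not
redistributable at package scale,
so the generator emulates their *experimental design* rather than their
equations: a phosphorylation cascade of n tiers (Michaelis–Menten activation
by the upstream active form, saturable deactivation, optional negative
feedback from the last tier onto tier-1 activation), two conditions, a small
number of observables formed as sums of active forms, uniform time grids,
per-(observable, replicate) arbitrary-unit gains drawn log-uniformly from
[10, 3000] (emulating densitometry counts against ~unit model
concentrations), and measurement noise matching the LL error model,
`ŷ = gain·(y + (s_a + s_b|y|)·ε)`, with default (s_a, s_b) = (0.02, 0.1) in
simulation units. All randomness flows from one seed through named
substreams (truth, gains, noise, embedding).

Presets mirror the shapes such problems take in practice (observables ×
free kinetic parameters; data points):

| preset | tiers | obs | free | points | conditions | feedback |
|---|---|---|---|---|---|---|
| `styx-like` | 3 | 1 | 10 | 38 | control + knock-down (T1 → 0.3) | no |
| `egfhrg-small` | 8 | 8 | 10 | 112 | high/low dose | yes |
| `egfhrg-large` | 15 | 8 | 74 | 112 | high/low dose | yes |

Design choices worth recording. Truth values are drawn from moderately
saturating ranges (km, kmd ∈ [0.2, 0.8] against unit pools): weak saturation
makes each tier's kact/km enter only as a ratio — structurally
unidentifiable — while the chosen regime keeps the smallest Jacobian
singular values around 1e-3–1e-2 in log10 space, i.e. genuinely partially
non-identifiable, like the real problems. The `styx-like` preset omits the
feedback loop and pairs a control with a knock-down condition (scaled tier-1
pool), which both matches the design of single-observable knock-down
experiments and removes the main source of landscape multimodality; the
8-observable presets keep the feedback. Free parameters are taken from a
fixed priority order (rate constants, feedback strength, then Michaelis
constants, then basal rates) so that preset shapes are reproducible.

What passing the round-trip tests shows — and does not. Noiseless data with
arbitrary gains give DNS-LS exactly zero at the truth (scale invariance of
the shared normalisation), multistart LevMar reaches < 1e-8 and recovers
the identifiable subset within 1%, and the PCA degree pipeline is exact on
constructed clouds. None of this demonstrates performance on real data:
the cascades are far smaller than real pathway models (3–15 states vs
25–49 species), the noise model is exactly the one the LL objective
assumes, time grids are uniform, and replicate gains are pure multipliers
with no background, censoring or loading-control structure.

## Experiment runner

A grid of (algorithm × scaling × objective) cells runs `n_runs` independent
seeded optimisations per cell (per-run seed = base seed + run index;
n = 96 is the conventional full-scale ensemble size, configurable). Artifacts per cell: estimates
table, per-run traces, convergence summary at configured time cutoffs,
PCA identifiability report; a JSON manifest records seeds, versions and the
timing methodology, and `metrics.csv` sets per-call counts, fd-equivalent
counts and wall seconds side by side. A failed cell is recorded and skipped,
never fatal. Plots are deliberately out of scope: CSV tables are the
contract.

## Known limitations

* The LL error-model form (σ = s_a + s_b|μ|, Gaussian) is an assumption;
  the exact error-model formulation used by existing estimation pipelines
  is rarely printed in full, so this form is declared rather than inherited.
* GLSDC hyper-parameters are reconstructions from the algorithm's
  published outline; its original internals are not public.
* The degree-of-nonidentifiability rule (variance > 1, strict) is sharp at
  the boundary by construction; variances near 1 flip the count.
* Desk-scale problem sizes: the heavy end-to-end runs use 8 starts or a few
  ×10⁴ objective evaluations and minutes of CPU, not the multi-hour 96-run
  cluster ensembles such comparisons use at full scale; directional claims (e.g.
  DNS converging faster than SF) are reported as monitored benchmarks, not
  asserted, at this scale.
* The single-observable cascade landscape is multimodal: besides the truth
  basin it contains secondary near-perfect-fit pockets (objectives down to
  ~3e-8 on noiseless data with one parameter hundreds-fold off). From eight
  ±3-decade Latin-hypercube starts, each LM variant enters the truth basin
  in roughly 40% of seed/design combinations, and derivative-free descent
  (Powell, hence GLSDC's local phase) was never observed to enter it at
  this budget — gradient flow, not local polish, is what finds that basin.
  Ground-truth recovery results should therefore be read per-run, best-of-
  ensemble, exactly as the estimate-ensemble identifiability analysis
  assumes.
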