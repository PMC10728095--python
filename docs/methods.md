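# Methods

## Model

The system is a three-compartment ODE model of a solid tumor under CTL
attack. Two tumor phenotypes, high-antigen (N) and low-antigen (M), share a
logistic growth law with joint carrying capacity K; the model treats the
phenotypes identically up to their parameter values, so every statement
about N has an M mirror (this symmetry is enforced by a property test).
CTLs (T) are recruited at a constant rate μ, proliferate in response to each
antigen class with Michaelis saturation (α_nt, α_mt; half-saturation κ₂),
die at rate δ_t, and are lost through contact with tumor cells (δ_n, δ_m).

Killing happens through two mechanisms with distinct kinetics:

- **fast (perforin/granzyme)** — contact killing within minutes, modelled as
  mass action: per-target hazard δ_f·T. Engaged with probability p₁ (N
  cells) or p₂ (M cells).
- **slow (FasL/death receptor)** — requires sustained conjugation, modelled
  as a Beddington–DeAngelis functional response
  δ_s·κ₁T / (κ₀ + κ₁T + N + M): linear in T when effectors are scarce,
  saturating at the maximum rate δ_s as effectors accumulate (κ₁ sets how
  quickly), and diluted by total tumor bulk, since a finite effector pool is
  shared over all targets. Engaged with the complementary probability.

The probabilities interpolate linearly: the per-capita tumor death rate is
p·fast + (1−p)·slow, so p = 0 and p = 1 recover the pure mechanisms.

The tumor-interference term in the slow response is what allows a large
tumor to outgrow a slow-killing immune response while a fast-killing one
still controls it; without it the model predicts stable microscopic dormancy
at the baseline parameterization instead of the escape-with-relapse behavior
that the killing-mechanism contrast is about. The fast mechanism is left as
pure mass action: per-conjugation killing that completes in minutes is far
from effector saturation at the cell densities the model visits.

PD-1/PD-L1 suppression multiplies both kill terms (and only them) by
F = 1/(1 + P·L/k_TQ) with P = ρ_p·T the total PD-1 and
L = ρ_l·(T + ε_c·(N+M)) the total PD-L1; ε_c is the tumor:T-cell PD-L1
expression ratio. T-cell proliferation is not suppressed: the checkpoint's
documented proximal effect is on cytotoxic activity. Ideal blockade sets
F ≡ 1. The anti-PD-1 binding rate μ_PA is carried in the parameter set for
completeness but drives nothing — blockade is idealized, not
pharmacokinetic.

## Units, thresholds and the detection-limit clamp

Cell counts convert to volume at 10⁶ cells/mm³, the standard solid-tumor
convention; it places the 5·10⁹-cell carrying capacity at 5000 mm³. Tumors
below 0.1 mm³ are not detectable by imaging, so integration stops when total
tumor volume first reaches 0.1 mm³: the reported volume is held at exactly
0.1 mm³ afterwards, the composition is frozen at its value when the limit
was reached, and T relaxes to its tumor-free homeostatic level μ/δ_t in
closed form (dT/dt = μ − δ_t·T; tumor-stimulation terms are dropped because
the tumor is at the detection limit). A trajectory that reached the limit is
classified as *clinical elimination* — the tumor became undetectable; this
is the only way a clamped readout can be eliminated, since the reported
volume never falls below the clamp. Unclamped readouts classify by volume:
dormancy on [0.1, 500] mm³ (boundaries included), escape above. Steady-state
analysis uses the parallel bifurcation thresholds: elimination means no
tumor cells at all, dormancy a persistent tumor below 500 mm³, escape at or
above it. The two vocabularies are kept separate in the API
(`ClinicalLabel` vs `SteadyOutcome`).

An inoculum already below 0.1 mm³ clamps at t = 0 (handled, not rejected).

## Parameters and defaults

Baseline values and admissible ranges are the published mouse
parameterization (`ParameterSet.baseline()`, `ParameterSet.range_of`).
Reference points: tumor proliferation 0.337/day; K = 5·10⁹ cells; fast-kill
coefficients 2.5·10⁻⁷ /cell/day; maximum slow-kill rate 4/day with
κ₀ = 2·10⁷ cells and κ₁ = 0.5; recruitment μ = 2·10⁴ cells/day with death
δ_t = 0.0412/day (homeostatic T ≈ 4.85·10⁵ cells); p₁ = 0.92, p₂ = 0.33
(high-antigen cells usually die fast, low-antigen cells usually slowly);
k_TQ = 1.296·10⁻⁹ μM².

The standard inoculum for single runs and response grids is 1 mm³ at 50/50
composition with **T(0) = 0**: the tumor is implanted into a site with no
pre-existing infiltrate and effectors arrive through recruitment. Starting
instead at immune homeostasis (T(0) = μ/δ_t) puts ~0.5 effectors per tumor
cell in place on day 0 and flips the baseline blockade outcome from
escape-with-relapse to clinical elimination; the infiltration-limited start
is the biologically sensible default for xenograft-style questions and is a
one-argument override (`default_initial_state(..., T0=...)`).

## Numerics

- **Integration**: LSODA (stiffness-switching) with rtol 10⁻⁸ and atol 10⁻²
  cells — the state spans ten orders of magnitude, so accuracy rides on the
  relative tolerance. The clamp is a terminal event on total tumor cells;
  requested readout days are included in `t_eval` exactly, so no
  interpolation error enters day-25/150 values. Tests check that readouts
  are invariant to a 10× tolerance tightening and to the sampling
  resolution.
- **Equilibria**: each invariant branch ({N=M=0}, {M=0}, {N=0}, interior) is
  solved separately by multistart Powell-hybrid root finding on the
  per-capita equations in log coordinates (positivity built in, trivial
  roots removed), with log-uniform starts over [1, 10K] and deduplication at
  10⁻⁶ relative distance. The tumor-free equilibrium (0, 0, μ/δ_t) and its
  eigenvalues are closed-form. Stability uses central finite-difference
  Jacobians (eigenvalue tolerance 10⁻⁸/day; anything between is marginal).
  Residuals must satisfy max|f| ≤ 10⁻⁶·max(1, ‖state‖).
- **Degenerate symmetry**: on the p₁ = p₂ diagonal with otherwise symmetric
  parameters the phenotypes are interchangeable and attractors pick up a
  neutral direction (marginal stability). Classification then raises and the
  bifurcation sweep falls back to long-run simulation from a grid of initial
  conditions; the fallback is recorded per grid point.
- **p2 threshold**: bisection to 10⁻³ on the day-25 blocked:active volume
  ratio, after a coarse monotonicity check of the reduction curve (a
  non-monotone profile aborts with a pointer to the grid scan).

## Virtual cohort

One virtual mouse = one Latin-hypercube draw (scipy's `LatinHypercube`,
which places exactly one sample per equal-probability stratum per dimension)
of all 23 model parameters plus two initial conditions. Sampling is uniform
on every published range: plain uniform LHS is the standard companion of
PRCC and makes the stratification interpretable on the parameter's natural
scale. The initial tumor is fixed at 1 mm³ (the standard inoculum); the
initial low-antigen fraction is uniform on [0, 1]; the initial
effector:tumor ratio is log-uniform on [0.1, 10], the usual
effector-to-target window of cytotoxicity assays, so the cohort spans
poorly infiltrated (1:10) to heavily infiltrated (10:1) tumors
symmetrically in log space. All three choices are plain fields of
`CohortSpec` and trivially overridden.

Each mouse is integrated under both checkpoint modes from identical initial
conditions; day-25 and day-150 volume, composition and clinical label are
recorded. Failed integrations are flagged and excluded from probabilities
(more than 1% failures aborts the run — that indicates solver
misconfiguration, not isolated stiffness; in practice the failure count is
zero). Binned outcome rates use equal-width bins on the parameter's sampling
scale; outcome-conditioned summaries report median, quartiles and a
Gaussian-KDE sketch on a fixed 128-point grid, omitting labels with fewer
than 10 mice.

With these defaults the cohort reproduces the expected short-horizon
pattern: under an active checkpoint no mice are clinically eliminated by
day 25 (≈20% dormant, ≈80% escaped), while ideal blockade eliminates
≈16–20% by day 25 with ≈40% escaped, and elimination probability rises
monotonically with antigen-driven CTL proliferation (α_nt) and recruitment
(μ).

## Global sensitivity

`global_sensitivity` pairs the cohort sampler with partial rank correlation
coefficients: all columns are rank-transformed, each input's ranks and the
output's ranks are residualized on all other inputs by least squares, and
the residual correlation is the PRCC (robust to singular designs; a constant
or fully collinear column reports NaN and ranks last). Significance uses the
t approximation with n − 2 − (d − 1) degrees of freedom and
Benjamini–Hochberg control at FDR 0.05 across inputs. Default n = 2000,
seed recorded in the report. The headline contrast: with the checkpoint
active, day-25 volume answers only to tumor-intrinsic rates (α_n, α_m, K);
with it blocked, p₁, p₂, α_nt, α_mt and μ all become significant, while
μ_PA and the checkpoint-engagement parameters (ρ_p, ρ_l, ε_c, k_TQ) stay at
noise level, as they must.

## Reproducibility

Every stochastic stage takes an explicit seed; the CLI derives per-stage
substreams from one global seed via `SeedSequence` with fixed stage offsets,
so adding a stage never perturbs another's stream and reruns are
byte-identical. Artifacts are CSV/JSON with a manifest embedding the
resolved configuration, seed and package version.

## Known limitations

- **Oscillatory attractors.** Parts of the sampled parameter space support
  stable limit cycles (tumor volume oscillating through the dormancy range).
  Equilibrium enumeration cannot represent them; the steady-state
  consistency test detects and exempts them, and the sweep's simulation
  fallback reports what long runs actually do. Formal continuation/Hopf
  detection is out of scope.
- **Discrete extinction.** The continuum model lets a tumor regrow from
  arbitrarily small positive mass. Trajectories that drive the tumor below
  one cell are treated as eliminated where simulation and equilibrium
  analysis are compared — a fraction of a cell cannot relapse — even if the
  tumor-free state is formally unstable.
- **Long-horizon blockade outcomes are turnover-sensitive.** Whether a
  tumor controlled at day 25 is eliminated or relapses by day 150 hinges on
  how long CTL pressure persists, which the sampled T-cell death rate δ_t
  (uniform up to 0.5/day, i.e. half-lives down to 1.4 days) largely
  decides. Under these study conditions relapse dominates late outcomes;
  restricting δ_t to slower, effector-memory-like turnover (≤ 0.05/day)
  roughly triples late elimination. Day-150 cohort fractions should be read
  with this sensitivity in mind.
- No pharmacokinetics (blockade is all-or-none), no spatial structure, no
  stochastic demography; measurement noise on volumes is not modelled.
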