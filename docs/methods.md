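# Methods

## The model-reduction problem

The generalized Lotka–Volterra (GLV) equations describe concentrations
x ∈ R^S of S interacting species,

    dx/dt = diag(x) (r + A x),

with growth rates r (1/time) and interaction rates A (1/(concentration·time)).
In practice one often works with a *partial* model that keeps only s < S
species of interest: the leading s×s block of A and the first s growth rates.
The omitted S² − s² interaction terms and S − s growth rates bias the partial
model — its equilibrium and transients drift away from the full ("detailed")
system's. `glvenrich` studies whether that bias can be absorbed by a sparse
*embedded discrepancy operator*: a correction inside the ODE rather than a
post-hoc adjustment of its outputs,

    dx/dt = P(x) + diag(x) δ0 + diag(|dx/dt|) δ1 ,

with only 2s new parameters, constrained by sign information (all entries of
δ0, δ1 ≤ 0, because every interaction in the model class is competitive).

## Random model class

Detailed models are sampled so that A is symmetric, entrywise strictly
negative and strictly diagonally dominant, hence negative definite, hence
every interior equilibrium −A⁻¹r is stable:

1. off-diagonal magnitudes B_ij ~ logN(0, σ_B²), symmetrized, i < j;
2. diagonal magnitudes C_ii = logN(0, σ_C²) + Σ_{k≠i} B_ki — a lognormal
   slack *added to* the off-diagonal row sum, which is what forces strict
   dominance (the sum is a deterministic floor, not a location shift);
3. A = −(B + C), r = max_i C_ii · 1 (one shared positive growth rate).

logN(0, σ²) means the underlying normal has mean 0 and variance σ².
Column versus row sums in step 2 are interchangeable because B is symmetric.
Principal submatrices inherit symmetry, negativity and strict dominance, so
every partial model of a generated detailed model is itself stable.
Defaults σ_B² = σ_C² = 1, S = 10, s = 4 match the package's reference study
conditions.

## The enriched system and its resolution

Because |dx/dt| appears on the right-hand side, the enriched system is
implicit in the derivative, but it decouples componentwise. With
g_i = P_i(x) + δ_i0 x_i,

    dx_i/dt = g_i / (1 − δ_i1)  if g_i > 0,
    dx_i/dt = g_i / (1 + δ_i1)  if g_i < 0,
    dx_i/dt = 0                 if g_i = 0.

For −1 < δ_i1 ≤ 0 both denominators are positive, the derivative keeps the
sign of g_i, and this is the unique consistent solution (plugging back
reproduces g_i + δ_i1|dx_i/dt| exactly; the property tests verify this to
1e−12). At δ_i1 ≤ −1 the descending branch has no consistent solution, so
the model is undefined; calibration assigns such proposals zero posterior
mass even though the nominal prior box U(−100, 0) contains them. The g_i = 0
tie-break (derivative zero) is the unique consistent choice.

δ0 shifts the equilibrium to −A⁻¹(r + δ0). In the scalar and uncoupled
(diagonal-A) cases a nonpositive δ0 can only shrink the equilibrium; in
coupled systems the inverse of an all-negative symmetric A has positive
off-diagonal entries, so depressing one species can *raise* a competitor's
equilibrium (competitive release) — the suite documents both behaviours.
Meanwhile δ1 rescales the speed of approach on each fixed-derivative-sign regime
(factor 1/(1−δ_i1) ascending, 1/(1+δ_i1) descending) without moving the
equilibrium. On any interval where the derivative signs are constant the
enriched trajectory therefore coincides with a smooth GLV system whose rates
are scaled by those factors; the suite checks this equivalence numerically,
and a finite-difference diagnostic confirms empirically that derivative
signs stop changing well before the end of each run.

## Observations

Observations are taken from detailed-model trajectories of the s retained
species: T instants uniformly spaced on (0, t_final] (t = 0 is excluded
because the initial condition is known), across n_φ initial-condition
scenarios whose entries are i.i.d. logN(0, 1). The first n_φc scenarios form
the calibration split, the rest the validation split. Measurement noise is
additive N(0, σ_ε²) with σ_ε² = 0.001 known; noise is not truncated at zero,
keeping the data model identical to the Gaussian likelihood. A scenario
prescribes initial values only for the retained species; the unretained
S − s initial values are drawn from the same lognormal stream and stored
with the scenario so runs are reproducible.

## Calibration

The 2s parameters carry independent U(−100, 0) priors (restricted by the
δ1 > −1 solvability constraint). The likelihood compares observations with
the noiseless enriched trajectory started from each calibration scenario's
retained-species initial condition, under the known noise variance.
Sampling uses an in-house delayed-rejection adaptive Metropolis (DRAM)
scheme: Gaussian random-walk proposals whose covariance adapts to
(2.38²/d)·cov(history) after a warm-up, plus one delayed-rejection stage at
0.2× scale whenever the first proposal is rejected. Defaults: start at all
δ = −0.1, adaptation from iteration 1000 refreshed every 50, 50% burn-in.
The sampler is validated against a correlated-Gaussian oracle and by
prior recovery with the likelihood switched off; effective sample size and
split-R̂ come from `arviz`.

All calibration scenarios are integrated as one stacked ODE system per
proposal — exact, since the enriched right-hand side couples nothing across
trajectories — which cuts solver overhead several-fold. Simulation defaults
are LSODA with rtol 1e−8/atol 1e−10 (equilibria must be resolved well below
the 1e−8 nonnegativity guard); calibration uses RK45 with rtol 1e−6 (and the
heavy resampling studies rtol 1e−5), ample against residuals measured on a
noise scale of ~0.03. GLV dynamics preserve nonnegativity analytically, so
trajectories are never clipped; a dip below −1e−8 raises an error instead.

## Validation: γ-values

For each observation y*, γ(y*) is the posterior-predictive probability of
outcomes *less likely* than y*: γ = P(p(Y) ≤ p(y*)) for Y drawn from the
predictive density. Draws take θ from the chain with replacement, push it
through the enriched ODE, and add measurement noise; the density is a
1-D Gaussian KDE with Silverman bandwidth. Only the ordering of density
values matters, so γ is invariant under monotone rescaling of the estimate
and only mildly bandwidth-sensitive (checked at ±50%). KDE fitting is capped
at 4000 draws (fitting is quadratic in the sample size) while the tail
probability is still evaluated over every draw. Default 2000 draws per
observation put the γ standard error near 0.01 at the τ = 0.05 operating
point; a zero-variance draw set defines γ as 1 at the point mass and 0
elsewhere. The summary f_γ(τ) is the fraction of γ-values below τ, reported
per split; when the fitted class truly generated the data, γ is
asymptotically uniform and f_γ(τ) → τ.

## Study defaults and problem sizes

* **Proof of concept** (S = 2, s = 1, fixed A = [[−3, −1], [−1, −2]],
  r = [5, 3]): 3 calibration scenarios, T = 10, σ_ε² = 0.001, 30k-iteration
  chain. The observation horizon is t_final = 3 here: δ1 multiplies |dx/dt|
  and is therefore informed only by transient data, and this system
  equilibrates by t ≈ 1.5; sampling a longer window leaves δ1 at its prior.
  The acceptance-test variant runs 15k iterations.
* **Single realization / ensemble** (random models): t_final = 10,
  n_φc = n_φv = 3, T = 10; desk-scale defaults of 10k-iteration chains,
  200 predictive trajectories, n_M = 10 realizations (the CLI's
  `--full-scale` flag restores n_M = 100 with 50k chains).
* **Self-consistency control**: data generated from an enriched model with
  known parameters (S = 3, s = 2, 12 scenarios), one 10k chain; f_γ is
  required to sit within 3 binomial standard errors of τ on each split.
* **Recovery study**: 20 replicates of enriched-truth data (s = 1, 3
  scenarios, t_final = 3), 4k-iteration chains; each 95% credible interval
  must cover its true parameter in ≥ 18 of 20 replicates.

## What the synthetic data does and does not emulate

The generator reproduces the structural features the method relies on —
competitive, symmetric, diagonally dominant interactions; stable equilibria;
scenario-to-scenario variability; additive homoscedastic noise. It does not
emulate cooperative or asymmetric interactions, limit cycles or chaos,
heteroscedastic or multiplicative measurement error, irregular sampling, or
model-form error beyond species omission. Passing tests therefore show that
the discrepancy operator captures *reduction* error in well-behaved
competitive systems, not that it corrects arbitrary model misspecification.

## Known limitations

* Stability of the enriched system under sign-changing derivatives rests on
  an empirical diagnostic, not a proof.
* δ1 is weakly identified when observations sit near equilibrium; its
  posterior then reverts toward the (restricted) prior.
* The ensemble driver at desk scale (n_M = 10, short chains) tracks the
  qualitative trend of f_γ with α = s/S, not publication-scale curves.
* σ_ε² is treated as known; misspecifying it would distort both the
  posterior and the γ-values.
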