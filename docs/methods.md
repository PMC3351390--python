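# Methods

## Path models and their algebra

A model is a directed/bidirected graph over the five observed variables
(mb, BMR, MMR, T_b, R_max), analyzed standardized.  Directed edges carry
path coefficients collected in B (`B[t, s]` = coefficient of s → t);
exogenous variances, endogenous error variances and bidirectional-edge
covariances live in Ψ.  The implied covariance is the observed-variable
reduced form Σ(θ) = (I−B)⁻¹ Ψ (I−B)⁻ᵀ.  Conventions, each of which is needed
to reproduce the degrees of freedom printed in the published selection
table:

* Every model keeps the full 5×5 matrix; a variable untouched by any edge
  (T_b in the thermogenic-capacity models) has its covariances fixed at 0,
  so its sample correlations count toward misfit.
* Exogenous variances are fixed at 1 (correlation-matrix analysis), except
  that an endpoint of a bidirectional edge with no incoming directed edge
  keeps a free variance: it is a dependent variable of the structural
  equations, and fixing it would miscount the parental-care model VIII
  (df 9 instead of the published 8).
* The BMR–MMR link b3 is, by default, an equality-constrained reciprocal
  pair of directed edges (the literal reading of the structural equations);
  `b3="covariance"` switches it to a Ψ off-diagonal.  Both use one free
  parameter, so df is identical.
* The BMR–R_max link b5 is always a covariance (the parental-care
  hypothesis makes it explicitly correlational), including in the combined
  models that write it inside two structural equations.  This convention
  reproduces the printed df for models IX–XII.
* Degrees of freedom: df = p(p+1)/2 − t with t = (one parameter per
  equality group or ungrouped directed edge) + (one per bidirectional
  edge) + (one per free variance).

Under these rules the encoded zoo reproduces the published df column for
models I–VI and VIII–XII.  The published table prints "Model VII" twice
(df 8 and df 6) and model VIII never; the df-8 row matches VIII's structure,
and VII itself counts to df 7 under the covariance-b5 convention (it would
count to 6 only if b5 were two unconstrained reciprocal coefficients).  Both
models are implemented from their structural equations; no attempt is made
to decide which printed row is which.

### A feasibility note on the published coefficients

The published fitted equations give b1 = 0.96, b2 = 0.95, b3 = 0.05.  Under
the reciprocal-b3 reading the reduced-form standardized mb → MMR coefficient
is (b1 + b3·b2)/(1 − b3²) ≈ 1.010 > 1, which leaves no positive error
variance for MMR: these values cannot generate standardized data under that
reading.  Under the covariance reading they are feasible (error variances
0.098 and 0.078).  The trait generator therefore uses the covariance
reading.  Similarly, the published R_max coefficient of 1.27 for the winning
model is impossible on the standardized scale of a single-predictor
equation (1.27² > 1) and is inconsistent with the published r² of 0.18; the
generator uses b4 = 0.42, which reproduces r² ≈ 0.18.  The fitting engine
itself reports whatever the data imply and reconciles nothing.

## Estimation

F(θ) = ln|Σ(θ)| + tr(SΣ(θ)⁻¹) − ln|S| − p is minimized by L-BFGS-B from an
OLS-informed start (per-equation regressions on S; equality groups take the
mean of their members' estimates) plus seeded random restarts (default 10).
A non-positive-definite Σ during search is handled by a large penalty.
Convergence is judged substantively: optimizer success, an exact fit
(F ≤ 1e−8), or a flat numerical gradient.  Error variances are not
constrained; a negative fitted value (Heywood case) is flagged, never
hidden.  Standard errors are the square roots of the diagonal of the inverse
numerical Hessian of (n−1)/2·F at the optimum; Wald tests use the two-sided
normal reference with no small-sample correction.  χ² = (n−1)·F_min,
BIC = χ² − df·ln(n) and RMSEA with the (n−1) denominator were chosen because
they reproduce the published table's arithmetic at n = 17 (an n-denominator
RMSEA does not).  r² per dependent variable is 1 − (error variance)/(implied
variance).

The bootstrap resamples species rows with replacement after a canonical sort
by species name (so intervals are invariant to input row order given the
seed), refits with a cheap options profile, drops failed replicates, and
reports percentile intervals — defaults 1999 replicates at 95%, since the
source analysis names neither.  A run with more than half its replicates
failed is flagged unreliable.

Model ranking sorts by BIC ascending with ties broken by larger df, then
model id.  Mixed sample sizes are an error.

## Phylogenetic signal

The tree covariance V has V[i,j] = shared root-to-tip path length (computed
from tip depths and patristic distances).  Blomberg's K is the observed
MSE₀/MSE ratio around the GLS phylogenetic mean divided by its Brownian
expectation (tr(V) − n/(1ᵀV⁻¹1))/(n−1); K = 1 exactly on a star tree and
averages 1 under Brownian motion.  Pagel's λ rescales V's off-diagonals,
with the Gaussian likelihood profiled analytically over the mean and σ² and
maximized over λ ∈ [0,1] by bounded scalar search (tolerance 1e−6, endpoints
checked explicitly).  Polytomies need no resolution; a singular V (zero
terminal branches) gets a documented ridge of 1e−8·mean(diag) with a
warning.  K has no randomization p-value by default.  The "no signal, no
correction" decision is exposed as `correction_advised` with explicit
user-policy thresholds (default 0.5 for both statistics) and is never
applied automatically.  An R/phytools cross-check on the same inputs is part
of the test suite as an independent oracle.

## R_max estimation

Two published readings of "spline the time series" are implemented as named
strategies.  `low_density_spline` (default, matching the R-function concept):
pair each per-capita rate ln(N_{t+1}/N_t)/Δt with its starting density,
smooth with a cubic smoothing spline, evaluate at the minimum observed
density.  `max_smoothed_rate`: smooth ln N(t) and take the maximum
derivative.  The smoothing penalty is chosen by generalized cross-validation
by default; `smoothing=0` gives the interpolating reading.  Densities are
normalized by their maximum before smoothing, making the estimate invariant
to rescaling abundance; near-duplicate densities (an equilibrated series) are
averaged into one knot, and if GCV is still ill-posed the estimator falls
back to interpolation.  A constant series returns 0.

## Synthetic data

The generator emulates a 17-species comparative study: a Yule tree (tips
extended past the final speciation by the next waiting time, keeping V
nonsingular), traits drawn from the reduced-form multivariate normal of a
chosen model with error variances solved for unit implied variances, and
per-species stochastic Ricker censuses (σ = 0.1, T = 30, K = 100) whose
growth rates are tied to the species' R_max trait.  Phylogenetic structure
is injected per trait as √λ·(standardized Brownian draw) +
√(1−λ)·(standardized model draw) — a deliberately simple mixture that trades
cross-trait correlation for autocorrelation, adequate for testing signal
detection but not a joint phylogenetic model.  The generator produces
standardized traits only: passing tests demonstrate recovery of structure,
not realism of allometric units, measurement error, or the literature
heterogeneity of real trait compilations.

## Problem sizes and numerical choices

Calibration checks use sizes chosen to make sampling error small relative to
the asserted tolerances while keeping the default test run quick: Monte-Carlo
covariance oracles at 1–2×10⁵ draws with 3.5-SE bands; coefficient recovery
at n = 5000 within 3 SE; K calibration over 1000 Brownian replicates;
λ recovery over 500 (tests) or 200 (acceptance script) replicates;
model-selection consistency over 100 replicates of n = 200 (50 in the
script) fitted without restarts or standard errors, since only BIC ranks
matter; bootstrap coverage over 30 outer replicates of 199 draws; R_max
recovery over 200 seeded series.  Seeds are fixed everywhere; every
public sampler takes an explicit seed and is deterministic given it.

## Known limitations

Observed variables only — no latent constructs, mean structures, multi-group
fits, GLS/WLS estimators, or missing-data handling.  The λ search is bounded
to [0,1] (no over-dispersion λ > 1).  Tree inference is out of scope: trees
are consumed as Newick input.  At n = 17 the ML χ² reference and Wald tests
are asymptotic approximations; the bootstrap is the more defensible
uncertainty statement at that size, and model ranks fluctuate across draws —
as the examples deliberately show.
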