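# endopath

Causal path-model comparison for the origin of endothermy — and a general
toolkit for small-sample structural equation modeling on species trait
correlations.

## The scientific problem

Why did birds and mammals evolve costly, continuous endothermy?  The
competing verbal hypotheses make different causal claims about which
physiological trait natural selection acted on:

* **Thermoregulatory, higher body temperature:** selection favoured higher
  body temperature (T_b), so T_b should predict fitness.
* **Thermoregulatory, thermogenic capacity:** selection favoured the capacity
  to generate heat in the cold, i.e. maximum metabolic rate (MMR) should
  predict fitness.
* **Parental care:** basal metabolic rate (BMR) rose as a by-product of
  selection for parental care, so BMR and fitness should be *correlated*
  (mediated by unmeasured variables) rather than causally linked.

`endopath` formalizes these as twelve candidate path models over five
observed, standardized species-level variables — body mass (mb), BMR, MMR,
T_b, and the intrinsic population growth rate R_max as a global fitness proxy
— and asks which model the comparative data support.  Each model is a set of
structural equations; for example the thermogenic-capacity model (zoo id VI)
is

```
R_max = b4·MMR        BMR = b2·mb + b3·MMR        MMR = b1·mb + b3·BMR
```

with the BMR–MMR link b3 either an equality-constrained reciprocal pair
(default) or a free covariance, and the parental-care link b5 always a
covariance (double-headed arrow).

## The statistics

* **Covariance-structure ML** (`endopath.sem`): a model with coefficient
  matrix B and (co)variance matrix Ψ implies
  Σ(θ) = (I−B)⁻¹ Ψ (I−B)⁻ᵀ.  Fitting minimizes the ML discrepancy
  F(θ) = ln|Σ| + tr(SΣ⁻¹) − ln|S| − p against the sample correlation matrix
  S.  Then χ² = (n−1)·F_min with df = p(p+1)/2 − (free parameters),
  BIC = χ² − df·ln(n) (lower is better), and
  RMSEA = √(max(χ²−df, 0)/(df·(n−1))).  Wald tests come from the inverse
  Hessian; percentile bootstrap intervals over species resamples back them up
  at small n.
* **Phylogenetic signal** (`endopath.phylo`): Blomberg's K and Pagel's λ
  against the Brownian-motion covariance V of a user-supplied Newick tree,
  to check whether species values can be treated as independent.
* **R_max from census data** (`endopath.rmax`): per-capita growth rates
  ln(N_{t+1}/N_t)/Δt smoothed against density with a cubic spline and read
  off at the lowest observed density — the low-density limit of the
  R-function.
* **Ground-truth generators** (`endopath.simulate`): Yule trees,
  model-implied trait tables (optionally with Brownian structure mixed in),
  and stochastic Ricker abundance series, for calibration and recovery tests.

## Worked example

```sh
python examples/fit_model_zoo.py
```

simulates 17 species from the thermogenic-capacity model and fits all twelve
candidates:

```
model_id   chi2  df     p     BIC  RMSEA  r2_R_max
      VI  3.106   8 0.928 -19.559  0.000     0.214
     VII  2.794   7 0.903 -17.038  0.000     0.214
       V  3.002   7 0.885 -16.830  0.000     0.219
       I  3.106   7 0.875 -16.726  0.000     0.213
    ...
Best model by BIC: VI

Fitted structural equations of the best model:
Model VI:
  BMR = 0.539 mb (P = 0.000) +0.353 MMR (P = 0.000)
  MMR = 0.643 mb (P = 0.000) +0.353 BMR (P = 0.000)
  R_max = 0.463 MMR (P = 0.037)
```

The generating model wins: its χ² is small relative to its 8 degrees of
freedom (P = 0.93, the model cannot be rejected), RMSEA is 0, and its BIC
beats every rival; MMR explains about 21% of the variance in R_max in this
draw.  At n = 17 this outcome is seed-dependent — the same script with
another seed can crown a neighbouring model, which is exactly the
small-sample uncertainty the bootstrap intervals are there to expose.

Other examples: `examples/phylogenetic_signal.py` (K/λ screen with a
correction advisory), `examples/estimate_rmax.py` (spline R_max from a
Ricker census), `examples/run_pipeline.py` (the full pipeline: preparation,
signal screen, twelve fits, bootstrap of the winner, reproducibility
manifest).

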