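# Methods

## Model

Replicated count surveys: `S` sites, `T` visits, counts `y_it`.  The
population at each site is closed over the survey window, abundance
`N_i` is an i.i.d. draw from a mixing distribution, and conditional on
`N_i` the visit counts are independent `Binomial(N_i, p)` with a common
per-individual detection probability `p`.  Mixing families:

| family  | abundance law                  | free parameters |
|---------|--------------------------------|-----------------|
| poisson | `Poisson(λ)`                   | λ, p            |
| negbin  | gamma-mixed Poisson (NB-2): gamma shape `a`, rate `b = a/λ` | λ, a, p |
| zip     | point mass ψ at 0, else `Poisson(λ)` | λ, ψ, p   |

λ is the mean of the mixing distribution in the Poisson and NB families, so
abundance estimates are directly comparable across them.  The NB-2 variance
is `λ + λ²/a`; the coefficient of variation of the Poisson mean is `1/√a`,
and the Poisson model is the `a → ∞` limit.  The ZIP's per-site pmf is
`ψ·1{y = 0} + (1−ψ)·(Poisson pmf)`; its functional form is not uniquely
dictated by the modelling framework, and this standard
point-mass-at-zero-abundance parameterization is the package's choice.
With a single visit only the product `pλ` is estimable; `fit` then reports
the product and flags the parameters non-identifiable.

## Exact multivariate likelihoods

Classify each individual by the subset `s ⊆ {1..T}` of visits on which it
was seen.  Under Poisson abundance the latent subset counts `n_s` are
independent Poisson with rates `θ_s = λ w_s`, `w_s = p^|s| (1−p)^(T−|s|)`,
and the observed vector is `y_t = Σ_{s ∋ t} n_s`.  The site pmf is the sum
over all non-negative integer configurations `(n_s)` consistent with `y` of
the product of Poisson masses; for gamma mixing the same sum with weight
`[Π_s w_s^{n_s}/n_s!] · Γ(a+M)/Γ(a) · b^a/(b+W)^{a+M}` where `M = Σ n_s`
and `W = 1 − (1−p)^T`.  These are *identical* to the classical truncated
likelihood in the `K → ∞` limit but involve no truncation constant.

Configuration enumeration is depth-first over the subsets in a canonical
order (size ascending, then lexicographic), carrying per-occasion remaining
budgets; the feasible range for `n_s` is 0..min of its members' budgets and
branches die as soon as an occasion with positive budget loses coverage.
Guards: `T ≤ 10` (the latent dimension is `2^T − 1`) and a cap of 5e6
configurations.  An independent brute-force box-scan oracle validates the
enumeration in the tests.

All pmfs are computed in log space with log-sum-exp across configurations
(`Γ(a+M)` and the factorials overflow quickly otherwise).  A per-dataset
cache enumerates configurations once per *unique* count row and evaluates
the likelihood for new parameters with dense linear algebra plus a
segmented log-sum-exp, which is what makes iterative maximization cheap —
the cost is independent of λ, unlike the truncated sum.

## Truncated formulation and the choice of K

The classical bounded-sum likelihood is provided both as an oracle for the
exact forms and because the bias induced by a too-small fixed `K` is itself
a phenomenon the package demonstrates.  In auto mode `K` is the smallest
integer whose upper-tail mixing probability is below `epsilon`
(default 1e-5, configurable), floored at the maximum observed count,
refreshed from the current λ at every objective evaluation during
optimization, and hard-capped at 1e6.  The tail rule uses the fitted
family's own cdf (Poisson, NB, or ZIP).  The truncation error of the
*dataset* log-likelihood scales like `S·epsilon`, so comparisons demanding
absolute error `δ` should set `epsilon ≲ δ/S` (the equivalence tests use
1e-12).

## Moments and diagnostics

With `m1` the grand mean count, `m2` the mean squared count and `m11` the
equal-weighted mean of the `T(T−1)/2` pairwise cross-products:

- `D1 = m11 − m1²`, the intraclass covariance (pooled centring is correct
  because all visits share the expectation `pμ`).  `D1 ≤ 0` predicts an
  infinite Poisson abundance MLE.
- `D2 = m1 − m2 + m11 = m1·p̂`.  `D2 ≤ 0` means the moment estimate of `p`
  is non-positive and the moment estimate of abundance infinite; this is
  the operative diagnostic for the negative-binomial family.  The
  complementary bound `p̂ ≤ 1` is `m11 ≤ m2`, a Cauchy–Schwarz consequence
  with no diagnostic content.

Moment estimators: `p̂ = D2/m1`, `μ̂ = λ̂ = m1/p̂`, implied mixing variance
`σ̂² = m11/p̂² − μ̂ − μ̂²`, gamma shape `â = μ̂²/σ̂²`.  Validity requires
`D1 > 0`, `D2 > 0` and `σ̂² > 0`; the three conditions are reported as
separate flags (`σ̂² ≤ 0` with the others positive is Poisson-compatible
data, not a failure of the abundance estimate).  A correlation-based
Poisson estimator is also provided: for Poisson mixing the population
correlation between visits equals `p` exactly, so `p̂` is the mean pairwise
sample correlation (population denominators, for consistency with the raw
moments) and `λ̂ = m1/p̂`.

**Exact signs.**  Both diagnostics have genuine point masses at zero — all
counts zero for `D1`; only-0/1 counts with no within-site repeat detection
for `D2` — and there the floating-point difference of the sample moments is
pure sign noise (~1e-16, because the three moments have different
denominators).  Signs are therefore computed in exact integer arithmetic by
clearing denominators.  Prediction flags treat a tie as triggering (a tied
diagnostic corresponds to an infinite moment estimate), while the
sign-classification experiments count only strict negatives and put ties in
the mixed category: a tie is evidence for neither sign, and in the sparse
scenarios the `D2 = 0` atom is large enough to dominate the "both
negative" cell if miscounted.

## Fitting and boundary detection

Maximization is over transformed parameters (`log λ`, `logit p`, `log a`,
`logit ψ`; transforms clipped at ±35) by Nelder–Mead simplex, started from
the moment estimates when valid and otherwise from the generic start
`p = 0.5, λ = m1/0.5, a = 1`.  A moment start whose λ̂ already exceeds the
operational infinity threshold also falls back — starting beyond the
threshold would prejudge the boundary verdict.

Two stopping rules:

- `strict` (default): simplex parameter spread *and* function spread below
  `tol` (1e-8).  On the boundary ridge the parameter spread never
  collapses, so the search runs to the iteration cap and the climb is
  detected.
- `ftol`: function-spread-only stopping at relative tolerance `√eps` with
  10% initial simplex steps — the stock behavior of general-purpose simplex
  optimizers.  On a flat ridge it halts early at a finite abundance.  The
  Monte-Carlo study runners use this mode because the frequency of
  *operationally* infinite estimates is itself shaped by that stopping
  behavior; with strict stopping essentially every flat-ridge fit reaches
  the threshold.

`boundary_infinite` is declared when λ̂ exceeds the operational infinity
threshold (default 1e3 — any large cutoff separates the two modes of the
strongly bimodal λ̂ sampling distribution; configurable) or the iteration
cap (default 500) is reached while the λ trace over the last 50 iterations
is still climbing monotonically (1% jitter allowance).  Because the
likelihood surface can hold an interior optimum alongside the boundary
ridge, a moment-started fit that lands on the boundary is cross-checked
with a second run from the generic start and the higher-likelihood solution
is kept; without this, profile checks showed ridge endpoints with *lower*
log-likelihood than the interior optimum being reported as infinite.
Non-converged, non-boundary fits get up to 3 jittered restarts.
`profile_lambda` maximizes the remaining parameters over a λ grid for
direct inspection of flatness.

## Synthetic data and the simulation studies

The generator draws `N_i` from the mixing distribution (gamma-Poisson for
NB, so non-integer shapes are exact) and thins binomially — the hierarchical
route, which is exactly the model, so passing recovery tests shows
correctness of estimator and likelihood code, not robustness to model
violation.  Real surveys violate several assumptions the generator encodes:
constant `p` across individuals, sites and visits; closure; independence
between sites; no covariates.  Results here say nothing about those.

Randomness is counter-based: `default_rng(SeedSequence(root_seed,
spawn_key=(scenario_index, replicate)))`, so scenarios are reproducible in
any execution order.

Study grids (defaults, overridable): the Poisson diagnostic study runs
λ ∈ {2, 5, 10} × p ∈ {0.10, 0.25} × T ∈ {2, 3, 4} at S = 20 sites, 1000
replicates; EPN is the proportion of replicates with `D1 ≤ 0` and EPD the
proportion whose Poisson MLE is operationally infinite.  The
negative-binomial study adds shape a ∈ {1.25, 5.00} and uses T ∈ {2, 3},
classifying replicates by the strict signs of (D1, D2) and fitting the NB
model to the both-negative replicates (and to a random subsample of the
both-positive ones, whose per-scenario size caps the fitting cost; the
subsample is drawn from a stream separate from the replicate seeds).  The
fixed-K experiment fits the truncated likelihood with K ∈ {100, 200, 400}
on λ = 2, p = 0.1, T = 2 data and summarizes the upper mode of λ̂
(estimates above 10× the true abundance); the design-subsampling workflow
recomputes `D1` over random site/visit subsets of a single dataset.

The acceptance script runs the five Poisson cells and two NB cells at 1000
replicates and the 24-scenario NB grid at 250 replicates (every
both-negative replicate fitted); these sizes keep the whole script under a
minute while leaving Monte-Carlo standard errors of a few percent, and the
test suite uses the same or smaller sizes for the same reason.

## Known limitations

- No covariates on λ or p, no unbalanced designs, no missing visits.
- No standard errors or confidence intervals for either MOM or ML
  estimates.
- The operational infinity threshold is a convention; any value separating
  the interior mode from the boundary pile-up gives the same verdicts, but
  the reported λ̂ on a flagged fit is meaningless beyond "large".
- Enumeration cost grows quickly with `T` and with large counts at `T ≥ 4`;
  the truncated formulation with auto-K is the practical choice there.
- The `ftol` stopping mode intentionally reproduces premature-termination
  behavior of stock optimizers; use the default `strict` mode when the
  goal is the best attainable optimum rather than study replication.
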