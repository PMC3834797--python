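# Methods

## Model

The data are right-censored survival records `(x_i, y_i, δ_i)`:
`x_i ∈ {0,1}^m` a vector of binary dysregulation items obtained from
continuous features, `y_i ≥ 0` an observed time, `δ_i = 1` when the event
was observed and 0 when follow-up ended first. The hazard follows Cox's
proportional model, `h(t | x) = h_0(t) · exp(βᵀ z(x))`, where the covariate
vector `z(x)` indexes **itemsets**: `z_t(x) = 1` iff the sample carries every
item of the conjunction `t`. The baseline hazard `h_0` cancels from the
partial likelihood and is never estimated. Estimation is L1-penalized
partial-likelihood maximization,

```
β(λ) = argmin  −ℓ(β) + λ‖β‖₁ ,
```

with the covariate index ranging over all itemsets up to `max_order`
(default 3; reported expression-survival interactions rarely involve more
genes, and the order cap bounds the lattice search). The penalized optimum
is characterized by the subgradient conditions: writing
`c(t) = ∂ℓ/∂β_t = Σ_i w_i x_{t,i}`,

* `c(t) = sign(β_t) · λ` for active itemsets,
* `|c(t)| ≤ λ` for inactive ones.

The per-sample weights have martingale-residual form,
`w_i = δ_i − Σ_{risk terms containing i} m_r π_{r,i}`, with `π_{r,i}` the
sample's share of the risk-set mass `Σ_k a_{r,k} e^{η_k}` under the current
linear predictor η. Because `c(t)` is a *linear sum of the indicator over
samples*, KKT screening over the exponential covariate space becomes
weighted itemset mining.

### Tie handling

The partial likelihood is built from a "risk term" decomposition (one term
per distinct event time under Breslow's rule, multiplicity = number of tied
events; Efron's progressive down-weighting is available by flag and
decomposes the same way). Breslow is the default: it is the simplest rule
consistent with plain risk-set sums, and the path derivations stay exact
under it. A subject censored exactly at an event time remains in that risk
set (standard convention).

## Path following

From `λ_max = max_t |c(t)|` at β = 0 (found by the same branch-and-bound
search as the miner, on the null-model weights) the engine repeats:

1. **Step length.** With the active set fixed, differentiating the KKT
   equalities gives `H_A (dβ_A/dλ) = s_A` (`H_A` the active-set Hessian of
   ℓ, `s_A` the sign vector; a just-entered zero coefficient takes the sign
   of its gradient). Candidate events are
   * removals: `d = β_j / (dβ_j/dλ)`, the linearized zero crossings;
   * entries: the roots of `c(t; λ−d) = ±(λ−d)` under the first-order
     expansion `c(t; λ−d) = c(t) − d·c′(t)`, where
     `c′(t) = Σ_i v_i x_{t,i}` with `v` the Hessian contracted with the
     per-sample direction `g = X_A dβ_A/dλ`. Each side is the minimization
     of `(p₀ + Σ p_i x_{t,i}) / (q₀ + Σ q_i x_{t,i})` over the lattice
     (`p₀ = λ, p = ∓w, q₀ = 1, q = ∓v`) — an unconstrained fractional 0–1
     program solved exactly (below). Ties resolve toward removals first,
     then by fewest items / lexicographic order.
2. **Predict.** `β_pred = β + (λ_next − λ) dβ/dλ` (λ on its natural scale;
   a singular `H_A` falls back to the warm start, with a ridge-stabilized
   direction for the step search).
3. **Correct.** Proximal Newton on the active columns: the smooth part is
   replaced by its local quadratic model, the L1-penalized quadratic is
   solved exactly by cyclic soft-thresholding (producing exact zeros), with
   an Armijo backtracking line search on the true penalized objective.
   Convergence is declared on the KKT residual (default 1e-9), not on
   objective decrease, so every recorded state carries an explicit
   optimality certificate. Active sets stay small, so full Newton is cheap.
4. **Update the active set.** Mine all itemsets with
   `|c(t)| ≥ λ − slack` (admission slack 1e-7 absolute — float-noise
   protection that also lets the linearized step converge onto an event
   from below, since its error shrinks quadratically), add the missing
   ones, re-fit, remove previously active coordinates whose coefficient is
   exactly zero, and repeat until stable (at most 20 inner loops).

Two boundary rules keep the loop deterministic and correct, and are shared
verbatim by the tests' independent expansion-path oracle:

* an itemset **removed** at this λ is not re-admitted within the same
  update (it sits exactly on the penalty boundary and would oscillate);
* an itemset **admitted** during this update is exempt from zero-removal
  there — at its own entry event its optimal coefficient is exactly zero
  and only becomes non-null as λ decreases further. Removing it would
  defer the event past its true location (verified by brute-force KKT
  checking during development).

Consequently a state recorded exactly at an entry event shows the entrant
with a (numerically) zero coefficient; strictly below the event it is
non-null.

Termination: `max_active` itemsets (default 50), `λ ≤ 0.01·λ_max`, or 200
recorded events — sparse models are the only useful region, so the full
path to λ = 0 is never needed. A relative minimum step (1e-10·λ) guarantees
progress; identical inputs give bit-identical traces.

Indicator-identical itemsets (e.g. a pattern and a superset with the same
supporting samples) make the penalized problem non-unique; `canonicalize`
keeps the representative with fewest items (ties lexicographic), both in
mining output and, implicitly, in the entry-candidate tie-breaks.

## Lattice searches

Items are visited in descending-support order (stable by index), the
standard heuristic that maximizes early pruning; each DFS node scores all
its extensions with one row-sliced matrix-vector product.

**Threshold mining** (signed weights). Plain weighted support is not
anti-monotone when weights are signed; the bound
`Σ_i max(w_i, 0) x_{t,i}` is, since supersets only shrink the support. A
branch (including its root) is pruned when the bound falls below the
threshold, so no qualifying itemset is ever lost. The negative side is the
same search on `−w`.

**Fractional 0–1 minimization.** Only itemsets with positive denominator
and value above a small floor are candidates (zero numerator = an itemset
already on the boundary). Two sound prunes against the running minimum
`curmin`:

* *fast bound* — from the branch's partial sums `P⁻ = Σ max(−p_i,0)` and
  `Q⁺ = Σ max(q_i,0)` over the support: every superset has numerator
  `≥ p₀ − P⁻` and denominator `≤ q₀ + Q⁺`; when the minimal numerator is
  non-negative the branch's ratios are all `≥ (p₀−P⁻)/(q₀+Q⁺)`. A branch
  whose maximal denominator is non-positive holds no candidate at all.
* *tight bound* (optional, shallow depths, off by default) — the
  parametric check `min over sub-supports of (N − curmin·D) ≥ 0`,
  separable per sample, certifying no superset beats `curmin`. It is
  sharper but costs an extra pass per node, so the fast bound is the
  default.

Both prunes use a strict relative margin (1e-12) so exact-value ties are
still visited and the canonical tie-break (fewest items, lexicographic) is
deterministic. Pruned and exhaustive searches return identical optima —
asserted by enumeration on hundreds of random instances in the tests.

## Binarization

`up.f` = value > μ + θσ, `dn.f` = value < μ − θσ, per feature; θ defaults
to 1.5, σ uses ddof = 1 (population σ available by flag), inequalities are
strict, constant features yield nothing, and items carried by fewer than 2
samples are dropped (a single-sample pattern can only overfit). Optional
per-feature z-scoring stands in for cross-array normalization; full
microarray normalization is out of scope. One consequence of the θσ rule
worth keeping in mind: by the one-sided Chebyshev inequality no
distribution can place more than `1/(1+θ²)` of its mass beyond μ + θσ —
at θ = 1.5 an item can never cover more than ~31% of samples.

## The resampling screen

After holding out a 25% test subset once, each of `n_iterations` (default
100) iterations draws a 95% subsample of the training data without
replacement, follows the path, and collects every multi-item itemset that
appears in any state. An itemset is kept when the unpenalized fit
{constituent single items + itemset indicator} beats the nested fit
{constituent single items} in a likelihood-ratio test with 1 df at
α = 0.05 — the most direct reading of "significantly improved over the
linear model". Aggregation counts an itemset once per iteration; itemsets
recurring in at least `min_occurrences` iterations (default 4) are ranked
by training-set logrank p (pattern carriers vs non-carriers; degenerate
groupings report p = 1), flagged by Bonferroni with
`m = number of distinct candidates reaching aggregation` (the hypothesis
family is larger than the reported list), and finally evaluated by logrank
on the untouched test subset. Per-iteration RNG streams are derived from
the master seed by index, so runs are reproducible bit-for-bit and an
interrupted run resumes from its iteration log.

## Synthetic cohorts

The generator emulates the *shape* of an expression-profiling survival
study: Gaussian features (optionally block-correlated), binarized by the
same μ ± θσ rule, exponential survival times with
`h_i = h₀·exp(Σ planted β · itemset indicator)` (Weibull by shape flag),
and independent exponential censoring whose rate is calibrated by root
finding so the expected censored fraction matches the target (achieved
rates land within ±5 points at n ≥ 500). Planted effects are defined on
the *binarized* items, so ground truth lives exactly in the search space.

Block correlation alone cannot give a multi-item pattern useful support at
θ = 1.5 (two 6.7% tails co-occur in well under 1% of samples even at
ρ = 0.8). Planted effects therefore support a **carrier subpopulation**: a
fraction of samples has every member feature displaced deep into the
binarization tail — a molecular subtype jointly dysregulating a small
module — plus an optional **singleton fraction** of samples dysregulated in
one member feature only, which dilutes the marginal associations so that
the conjunction, not its margins, carries the survival signal. The
displacement is a deep bimodal split (12σ, within-carrier sd 0.25) rather
than a mild shift because the dysregulated mass (26% per feature in the
demo scenario) sits near the Chebyshev ceiling above, where a mild shift
would inflate σ and push the cutoff into the carrier mode.

The canonical demo (`interaction_demo_spec`): 300 samples, 25 features,
one pattern `up.g000 * up.g001` with log-hazard 1.0, carrier fraction
0.12, singleton fraction 0.14, 30% censoring. What this cohort does *not*
emulate: realistic microarray noise, batch effects, missing values, and —
importantly — realistic dimensionality (tens of features, not tens of
thousands). Passing tests on it demonstrate the machinery, not field
performance.

### Power of the recovery study, and two known red results

Two simulation studies in `tests/test_acceptance.py` are asserted at
targets the above conditions cannot meet; they are left failing rather than
weakened, because the analysis is informative:

* **Planted-pair recovery** (target ≥ 90% of 20 seeds; measured ~70%). The
  gate is the nested LR filter: at log-hazard 1.0 on ~213-sample
  subsamples its noncentrality is ~5–6 — *for every feasible prevalence
  design*, because the pattern indicator is logically nested in its items
  and per-item prevalence is Chebyshev-capped, so an exhaustive scan over
  (pattern prevalence, singleton dilution) with idealized two-point items
  plateaus at median χ² ≈ 6–7 (power ≈ 0.70 at α = 0.05, against the
  ≈ 0.93 per-seed rate the target requires). Subsample draws share 95% of
  the data, so repeated iterations cannot rescue cohorts whose
  training-set LR p lands high. Recovery at this effect size is intrinsically
  a two-in-three proposition.
* **Randomized-label negative control** (target ≥ 95% of runs with zero
  Bonferroni-significant candidates; measured ~80%). At desk-scale
  dimensionality a permuted cohort's strongest chance patterns are stable
  across overlapping subsamples: they recur, pass the occurrence filter,
  and the correction family `m` (aggregated candidates, 1–9 here) badly
  undercounts the ~1200-pattern lattice each path searched, so 0.05/m is
  lenient. With tens of thousands of probes the spurious pool is so large
  that each iteration surfaces different patterns and recurrence filtering
  works as intended; that regime is out of reach at this scale (raising
  the cohort to 100 features makes concentration *worse*, not better).

The screen protocol used by these studies is the standard one scaled for
runtime: 25 iterations with the occurrence threshold scaled
proportionally (4/100 → 1/25), path search restricted to pairs with
`max_active` 12, 40 events, and λ down to 0.05·λ_max. Problem sizes
elsewhere: oracle equivalence uses 50 fixtures of 30–60 samples and ≤ 12
items at order ≤ 3; pruning and mining soundness use 500 random instances
each; null calibration uses 500 replicates at n = 150.

## Numerical choices

* Linear predictors are centered by their maximum before exponentiation
  (overflow guard, mathematically neutral).
* Unpenalized fits clip coefficients at |β| ≤ 15 as a monotone-likelihood
  (separation) guard; a fit ending on the bound is flagged unconverged.
* The corrector's quadratic subproblem adds a 1e-10-scaled ridge; the
  predictor's linear solve falls back to a ridge-stabilized system when
  the active Hessian is singular (duplicate-indicator active sets are
  already prevented by canonicalization).
* Coordinate-descent zeros are exact, so removal detection needs no
  threshold; the independent oracle (L-BFGS-B on the positive/negative
  split plus a sign-fixed Newton polish) uses 1e-8.
* KS-uniformity, type-I-error and calibration tests run at fixed seeds;
  all stochastic assertions are deterministic given the suite.

## Limitations

Single survival outcome; no elastic-net or group penalties, no stratified
or time-varying Cox models, no competing risks; approximate (grid) paths
are deliberately excluded — events are located by the exact fractional
search. The negative-control behavior of the screen depends on input
dimensionality as analyzed above. Mining cost grows with item count and
with λ descending; the order cap and `max_active` keep the default
configuration interactive.
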