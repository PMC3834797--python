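# combocox

Discovering **combinatorial interactions in survival data**: which *pairs or
triples* of dysregulated genes — not just single genes — are associated with
patient survival?

Expression profiles are first dichotomized into items: `up.<gene>` flags
samples whose expression exceeds μ + θσ and `dn.<gene>` those below μ − θσ
(θ = 1.5 by default). An *itemset* is a conjunction of such items, e.g.
`dn.BBC3 * dn.KIAA0882` ("BBC3 *and* KIAA0882 both under-expressed"), and its
indicator column is a candidate covariate for a Cox proportional hazards
model of survival time. The model is the L1-penalized partial likelihood over
**all** itemsets up to a maximum order:

```
min over β of   −ℓ(β | D) + λ Σ_t |β_t| ,        t ranging over itemsets,
```

where ℓ is the Cox log partial likelihood of the right-censored data
D = (x_i, y_i, δ_i). The covariate space is exponentially large, but the
package follows the **regularization path** — the sequence of λ values at
which itemsets enter or leave the active set — without ever materializing it:

* the KKT conditions reduce "which itemsets must enter at penalty λ" to
  finding all itemsets whose *weighted support* Σ_i w_i x_{t,i} crosses ±λ,
  a weighted frequent-itemset mining problem solved by a pruned depth-first
  search (the per-sample weights w_i are martingale-residual-form gradients
  of the partial likelihood);
* the next event λ is the minimum of linear-fractional functions over the
  itemset lattice — an unconstrained fractional 0–1 program solved exactly
  by branch and bound;
* between events the active coefficients are tracked by a
  predictor–corrector scheme (linear extrapolation along dβ/dλ, then a
  proximal-Newton re-fit).

On top of the path engine, a **resampling screen** runs the path repeatedly
on subsamples of the training data, keeps itemsets that beat their
constituent single items in a nested likelihood-ratio test, filters by
recurrence across iterations, ranks candidates by logrank p-value with
Bonferroni correction, and validates survivors on a held-out test subset.

Everything is certifiable: on small inputs the engine's entire trace is
reproduced by an independent dense L1 Cox path on the explicitly expanded
all-itemsets design matrix, and brute-force lattice enumeration confirms the
KKT certificate at every recorded state (see `tests/`).

## Worked example

```python
import combocox as cx

# a synthetic 300-patient cohort: a two-gene pattern (up.g000 & up.g001)
# carried by a 12% subpopulation raises the log hazard by 1.0
expr, data, truth = cx.generate(cx.interaction_demo_spec(seed=0))

res = cx.PatternCoxPath(data, max_order=2).fit(max_active=8,
                                               lambda_min_ratio=0.1)
print(f"lambda_max = {res.lambda_max:.3f}")
print(res.summary().head(6).to_string(index=False))
```

```
lambda_max = 21.019
   lambda action           itemset  order  support  active_size
21.019353    add up.g000 * up.g001      2       41            1
 9.312259    add           up.g010      1       21            2
 8.590047    add           dn.g014      1       18            3
 8.111909    add           dn.g016      1       19            4
 6.552324    add           up.g005      1       20            5
 5.910429    add           up.g024      1       22            6
```

The planted pair is the first covariate to enter the path (at λ_max = 21.0,
more than twice the score of the strongest noise item), carried by 41 of the
300 samples. The resampling screen then quantifies how reliably it recurs:

```python
screen = cx.InteractionScreen(
    data,
    cx.ScreenConfig(n_iterations=25, min_occurrences=1, seed=0),
    cx.PathConfig(max_order=2, max_active=12, max_events=40,
                  lambda_min_ratio=0.05),
)
sres = screen.fit()
print(sres.summary().head(4).to_string(index=False))
print("correction factor m =", sres.m_bonferroni)
```

```
 Gene combination  LR test P-value  Logrank P-value  No. of occurrences  Test logrank P-value  Bonferroni significant
up.g000 * up.g001         0.000009     5.721352e-08                  25              0.042384                    True
up.g007 * up.g014         0.000521     3.268490e-02                  21              1.000000                   False
up.g000 * dn.g020         0.002821     5.952394e-02                   4              1.000000                   False
up.g001 * up.g013         0.022545     4.208055e-01                   1              0.570315                   False
correction factor m = 4
```

The planted interaction appears in **all 25** subsample runs, its training
logrank p-value (6·10⁻⁸) is Bonferroni-significant at 0.05/m, and it remains
significant (p = 0.042) on the held-out 25% test subset that never touched
selection. The noise combinations either fail the correction or collapse in
test. Such recovery depends on the nested LR filter's power — at a log-hazard
of 1.0 with a ~13% pattern it succeeds on roughly two out of three cohorts
(see `docs/methods.md` for the power analysis).

The same pipeline runs from the shell:

```bash
combocox simulate --n-samples 300 --planted "up.g000*up.g001:1.0:0.12" \
    --seed 0 --out cohort/
combocox path   --items cohort/items.tsv --survival cohort/survival.tsv \
    --max-order 2 --out pathrun/
combocox screen --items cohort/items.tsv --survival cohort/survival.tsv \
    --iterations 100 --out screenrun/
```

## Layout

| module | contents |
| --- | --- |
| `combocox.survival` | partial likelihood, derivatives, penalized fitter, KM / logrank / LR tests |
| `combocox.binarize` | μ ± θσ dichotomization |
| `combocox.patterns` | itemsets, activation weights, weighted-support mining |
| `combocox.path` | the predictor–corrector path engine and fractional step search |
| `combocox.screen` | the resampling interaction screen |
| `combocox.simulate` | synthetic cohorts with planted effects |
| `combocox.model` | `PatternCoxPath` / `InteractionScreen` front end |
| `combocox.io`, `combocox.cli` | tabular formats and the `combocox` command |
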