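# combatkit

Empirical Bayes batch correction for gene-expression matrices — original
(mean/variance), **mean-only**, and **reference-batch** adjustment — together
with **moment-based diagnostics** that tell you which of the three a dataset
actually needs, and simulation harnesses for evaluating all of it.

It is aimed at anyone combining log-scale expression data (microarray or
log-transformed RNA-seq) across processing batches, labs, or platforms:
batch effects shift per-gene means and rescale per-gene variances, confound
biological contrasts, and — under pooled correction — make every sample's
adjusted values depend on which other batches happen to be on hand ("set
bias"), which is fatal for frozen biomarkers.

## The model

For gene *g*, batch *i*, sample *j*, log expression is modeled as

```
Y_ijg = α_g + X_ij β_g + γ_ig + δ_ig ε_ijg ,    ε_ijg ~ N(0, σ_g²)
```

with additive (γ) and multiplicative (δ) batch effects. After per-gene OLS,
the data are standardized,

```
Z_ijg = (Y_ijg − α̂_g − X_ij β̂_g) / σ̂_g ,
```

and each batch's per-gene effects (γ̂_ig = batch mean of Z, δ̂²_ig = batch
variance of Z) are shrunk toward batch-level priors fitted across genes —
γ_ig ~ N(γ̄_i, τ̄²_i) and δ²_ig ~ InverseGamma(λ_i, θ_i) by the method of
moments — via the usual iterated conditional posterior means. The shrunken
effects are then removed:

* **original** — `Y* = σ̂ (Z − γ*) / δ* + α̂ + Xβ̂` (mean and variance);
* **mean-only** — `Y* = σ̂ (Z − γ*) + α̂ + Xβ̂` (δ* ≡ 1; within-batch
  variances are preserved to the last bit of rounding);
* **reference** — α̂, σ̂ come from a designated reference batch, all other
  batches are adjusted to its profile, and the reference batch is returned
  **bit-identical**, so previously adjusted data never change when new
  batches arrive.

The diagnostics estimate four moments (mean, variance, skewness, excess
kurtosis) of Z either per **sample** (over genes) or per **(gene, batch)**
cell (over samples) and compare them across batches with a one-way F-test
plus a *robust* variant, `F_r = F / max(1, M/n₀)`, that counteracts the
p-value collapse when the number of moment estimates M is huge.

## Worked example

Simulate a two-batch, two-condition study whose batches differ only in the
mean, diagnose it, and correct it:

```bash
combatkit simulate --kind de --batch-effect mean_only --seed 42 --out-dir demo
combatkit diagnose --expression demo/expression.tsv --metadata demo/metadata.tsv \
    --batch-col batch --covariate-col group --after-mode mean_only --out-dir demo
```

prints

```
[None] recommendation: mean-only
[Mean-only] recommendation: no adjustment indicated
```

and `demo/diagnostics.json` holds the full grid. Before adjustment the
robust mean tests reject decisively while the variance tests do not
(sample-level / gene-level robust p-values: mean 0.0000 / 0.0000, variance
0.0606 / 0.5109) — so only the additive batch effect is real and mean-only
correction suffices. After mean-only correction the mean p-values rise to
1.0000 at both levels and the variance cells are untouched (0.0518 /
0.5109): the batch effect is gone and nothing else was disturbed.

From Python the same thing is three calls:

```python
from combatkit import read_expression, read_metadata, batch_diagnostics, combat

Y = read_expression("demo/expression.tsv")
design = read_metadata("demo/metadata.tsv", batch_col="batch",
                       covariate_cols=["group"], sample_ids=Y.sample_ids)
print(batch_diagnostics(Y, design).recommendation)   # "mean-only"
adjusted = combat(Y, design, mode="mean_only").adjusted
```

The pathway-signature benchmark (a clean 200×6 perturbation experiment
combined with a noisy 200×600 patient-like cohort; accuracy = k-means
recovery of the 100 signature genes):

```bash
combatkit benchmark --seed 1 --n-seeds 5 --out-dir bench
```

```
            batch1  batch2  combined
unadjusted   1.000   0.513     0.547
original     0.533   0.552     0.535
reference    1.000   0.761     0.762
```

Unadjusted, the small clean batch separates the signature perfectly but the
combined data do not (the noisy cohort dominates every distance). Pooled
original-mode adjustment *destroys* the clean batch (1.000 → 0.533) by
inflating its variance toward the cohort's, while reference-batch
adjustment keeps it intact by construction and recovers most of the signal
in the combined data. That asymmetry is the case for reference-batch
correction in biomarker workflows.

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes the six benchmark accuracies above from scratch — 20 fresh
generator seeds, both adjustment modes run with the pathway-activation
covariate, k-means scoring of batch 1 and of the combined matrix — and
writes one JSON entry per cell (values in percent).

## Layout

| module | contents |
| --- | --- |
| `combatkit.model` | `ExpressionMatrix`, `StudyDesign`, design matrices, OLS fit, standardization |
| `combatkit.adjust` | batch-effect estimation, EB hyperpriors/posteriors, the three `combat` modes |
| `combatkit.diagnostics` | moment tables, standard/robust F-tests, `batch_diagnostics` report |
| `combatkit.simulate` | pathway and DE study generators, k-means scoring, type-I/power harness |
| `combatkit.io` / `combatkit.cli` | TSV/CSV I/O, id-matched metadata, `combatkit` command |

See `docs/methods.md` for estimators, conventions, numerical choices, and
known limitations.
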