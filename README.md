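# knockboost

FDR-controlled variable selection for tabular biomedical data (wide
omics-style matrices included) by combining **model-X knockoffs** with
**gradient-boosted decision trees** and **SHAP** feature attributions.

## The problem

Given an *n × p* design matrix *X* and a response *y* (continuous, binary,
or multi-class), we want the subset of columns that genuinely influence *y*
while controlling the expected fraction of false selections — the false
discovery rate (FDR) — at a nominal level *q*. Classical filters built on
the Lasso handle linear effects; boosted trees capture nonlinear and
interaction effects, but their importance scores alone offer no error
control. The knockoff filter supplies that control for any learner, as long
as the importance statistic treats a feature and its synthetic "knockoff"
copy symmetrically.

## The method

1. **Knockoff construction.** Estimate the feature correlation matrix Σ
   (Ledoit–Wolf shrinkage toward the identity when *n ≤ p*), choose a
   non-negative vector *s* with `2Σ − diag(s) ⪰ 0` (equicorrelated
   `s_j = min(1, 2λ_min(Σ))` by default, a coordinate-ascent SDP solver
   optionally), and sample second-order Gaussian knockoffs from
   `K | X ~ N(X − XΣ⁻¹diag(s), 2diag(s) − diag(s)Σ⁻¹diag(s))`, so that
   `cov([X K]) ≈ [[Σ, Σ−diag(s)], [Σ−diag(s), Σ]]`.
2. **Importance.** Fit LightGBM (or XGBoost) on the augmented *n × 2p*
   matrix `[X K]` and compute tree-exact SHAP attributions φ_ij on the
   raw-score scale; aggregate `Z_j = mean_i |φ_ij|` over instances (and sum
   over classes for multi-class models).
3. **Filter.** Form the antisymmetric pair statistic `W_j = Z_j − Z_{j+p}`
   (flip-sign valid: swapping a feature with its knockoff negates `W_j`),
   find the knockoff+ threshold
   `τ = min{t > 0 : (1 + #{W_j ≤ −t}) / max(1, #{W_j ≥ t}) ≤ q}`,
   and select `Ŝ = {j : W_j ≥ τ}`.

The Lasso regularization-path entry statistic (`Z_j = sup{λ : β̂_j(λ) ≠ 0}`)
is included as the classical comparator, and a simulation harness reproduces
block-Gaussian studies (10×10 AR(1) blocks, ρ = 0.1) with linear, logistic,
multinomial, and nonlinear response models, reporting mean/sd of the false
discovery proportion (FDP) and power over repeated runs.

## Worked example

```python
import knockboost as kb

# a linear-regression scenario: p = 200 features in AR(1) blocks,
# the first ten carry coefficient 2, the rest are null
scen = kb.SimulationScenario(kind="lin_reg", n=500, p=200)
x = kb.draw_design(scen, seed=1)
y = kb.gen_response(scen, x, seed=1)

result = kb.run_pipeline(x, y, q=0.1, seed=1)
print("selected:", result.selected)
print("threshold:", round(result.threshold, 4))
fdp, power = kb.fdp_and_power(result.selected, scen.true_support)
print(f"fdp={fdp:.3f} power={power:.3f}")
```

prints

```
selected: [0, 1, 2, 3, 4, 5, 6, 7, 8, 9]
threshold: 0.7112
fdp=0.000 power=1.000
```

All ten planted signals are recovered (power 1.0), nothing else passes the
knockoff+ threshold (FDP 0), and the threshold is the smallest |W| at which
the estimated false-discovery ratio drops below q = 0.1. Note that with the
`+1` numerator offset the filter is all-or-nothing near `1/q` discoveries:
at q = 0.1 it can only ever return ≥ 10 features or none.

The same pipeline runs from the shell on CSV/TSV inputs:

```bash
knockboost select --x expr.csv --y labels.csv --task binary --q 0.1 \
    --seed 1 --out selection.json
knockboost simulate --scenario lin_reg --n 500 --p 1000 --reps 20 \
    --q 0.1 --seed 1 --out study/
```

`select` writes a JSON report (1-based selected indices, W vector,
threshold, full resolved config); `simulate` writes a tidy per-repetition
CSV plus a JSON summary (`fdr_mean`, `fdr_sd`, `power_mean`).

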