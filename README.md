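# netpred

Stable prediction models from correlated omics data via network-guided
group penalization.

## The problem

Omics matrices (metabolomics, transcriptomics, glycomics, …) are
high-dimensional (p ≫ n) and strongly block-correlated: features organize
into modules driven by shared biology.  Standard regularized regression
handles the dimensionality but not the correlation — the lasso picks one
feature at random out of each correlated block, so re-running the analysis
on a resampled dataset selects a different feature with a different effect
size.  `netpred` builds prediction models that are stable under resampling
by making the correlation structure part of the model:

1. **Network construction** — estimate a weighted feature–feature network
   from the training data: soft-thresholded correlation (WGCNA style,
   a_ij = |cor|^β), ridge-penalized partial correlations sparsified against
   an empirical null (Efron central matching + Benjamini–Hochberg), or a
   graphical lasso with AIC-selected penalty.
2. **Module detection** — topological-overlap dissimilarity
   (TOM_ij = (Σ_u a_iu a_uj + a_ij)/(min(k_i,k_j) + 1 − a_ij)),
   average-linkage clustering, and a dynamic tree cut.
3. **Group-penalized prediction** — the modules G_1…G_L enter a linear
   model through hub selection + ridge, the group lasso
   (λ Σ_l √p_l ‖β_l‖₂), the sparse group lasso (mixing an ℓ1 term with
   weight α), or adaptive group ridge (group-specific penalties
   λ_l = λ'_l λ); lasso, ridge and elastic net are the ungrouped baselines.

Because every estimation step can overfit, the *whole* pipeline is wrapped
in double (nested) cross-validation: networks, modules and all tuning
parameters are re-estimated inside each outer training fold, and predictive
ability is reported as

    Q² = 1 − Σᵢ (yᵢ − pᵢ)² / Σᵢ (yᵢ − p0ᵢ)²,

the cross-validated fraction of variance explained relative to the
training-fold-mean predictor p0.

A hub-model simulator generates data with exactly this structure — k
feature modules, each with one hub feature (hub–member correlation ρ_m,
member–member ρ_m²), one uncorrelated module, and an outcome loading on
eigen-subspaces of the feature correlation — with full ground truth for
module recovery and coefficient estimation studies.

See `docs/methods.md` for the models, defaults, and numerical choices.

## Worked example

```python
import netpred as nps

# scenario "a": outcome on the dominant eigen-subspace; n=50, p=200, k=4
scn = nps.SimScenario(n_samples=50, n_features=200, n_modules=4,
                      scenario="a", seed=3)
X, y, truth = nps.simulate_dataset(scn)

# double CV of WGCNA -> TOM clustering -> group lasso
cfg = nps.PipelineConfig(network="wgcna", model="grplasso")
report = nps.double_cv(X, y, cfg, outer_k=10, seed=11)
stab = nps.selection_stability(report)
print(f"Q2 = {report.q2:.3f}")
print("modules per fold:", [f["n_modules"] for f in report.per_fold])
print(f"selected at least once: {stab.at_least_once}, "
      f"in all folds: {stab.always_selected}")
```

prints

```
Q2 = 0.922
modules per fold: [2, 2, 2, 2, 2, 2, 2, 2, 2, 2]
selected at least once: 72, in all folds: 52
```

The two detected modules are the strongly correlated blocks (hub
correlations .9 and .7); the group lasso keeps them as whole groups in
most folds — 52 of the 72 features ever selected are selected in *all*
ten folds, the stability the pipeline is designed for — and the
cross-validated Q² of 0.92 approaches the simulated signal ceiling (the
outcome's population R² is calibrated to 0.95).  An ordinary lasso on the
same data selects fewer, arbitrary representatives of each block with much
higher fold-to-fold churn.

The same pipeline is available from the shell:

```bash
netpred simulate --scenario a --p 200 --k 4 --n 50 --seed 3 --out sim/
netpred network  --method wgcna --in sim/X.csv --out net.tsv
netpred cluster  --net net.tsv --x sim/X.csv --out modules.tsv
netpred cv       --x sim/X.csv --y sim/y.csv --config cv.yaml --out cv/
```

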