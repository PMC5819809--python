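# Methods

`netpred` builds prediction models for a continuous outcome from a
high-dimensional omics matrix in three steps — network estimation, module
detection, group-penalized regression — and evaluates the whole procedure by
double (nested) cross-validation.  This note records the models, the
numerical choices, and the places where the design was genuinely open.

## Step 1 — network estimation

Given a training matrix **X** (n samples × p features, column-standardized),
three estimators of a weighted adjacency A = [a_ij], a_ij ∈ [0, 1], zero
diagonal:

**Soft-thresholded correlation (WGCNA style).**
a_ij = |cor(x_i, x_j)|^β with an unsigned convention.  The soft-threshold
power can be chosen by the scale-free topology criterion: connectivities
k_i = Σ_j a_ij are binned (10 equal-width bins), log10(frequency) is
regressed on log10(mean bin connectivity), and the smallest power whose R²
reaches 0.8 is kept (the R² is negated when the slope is positive; if no
power reaches the target the best one wins).  `scale_free_fit` also reports
γ̂ = −slope, the implied exponent of P(k) ∝ k^−γ.

*Caveat and default.*  Hub-model block-correlated data — the structure this
package's simulator generates, and a reasonable cartoon of metabolomics —
is **not** scale-free: the criterion's R² only rises once the power is so
large (≥14) that every edge outside the strongest module is crushed to
zero, after which no other module can ever be detected.  The pipeline
therefore defaults to the conventional unsigned-network power 6
(`PipelineConfig.powers=(6,)`); passing a grid enables the scale-free
search.

**Ridge-penalized partial correlations.**
S′ = S + λI is inverted and scaled to partial correlations
R̂ = −scale(S′⁻¹).  λ is chosen from a log-spaced grid (20 points,
10⁻³…10) by maximizing held-out Gaussian log-likelihood
log det Θ − tr(S_test Θ) over 5 internal folds.  Each off-diagonal r_ij is
Fisher-transformed, z = ½ log((1+r)/(1−r)) (clipped at ±6), and tested
against an **empirical null** estimated by central matching: a quadratic in
z is fitted by Poisson regression to the counts of a 120-bin histogram
restricted to the central 50 % of the histogram range, and the implied
normal gives (μ₀, σ₀).  (The central window is defined on the histogram
*range*, not the interquartile range: with only ±0.67 σ of data the
curvature of the quadratic is so poorly determined that the σ₀ estimate on
5 000 genuinely null z-values varies from 0.79 to 1.83 across seeds;
the range-based window gives 1.00 ± 0.02.)  Two-sided p-values from that
null are Benjamini–Hochberg corrected at FDR 0.05; non-significant entries
are zeroed and edge weights are |r_ij|.

**Graphical lasso.**
Θ̂ maximizes log det Θ − tr(SΘ) − λ‖Θ‖₁ (scikit-learn's solver,
off-diagonal penalty).  λ is selected from a log grid (default 6 points,
0.15…0.8) by minimizing AIC = n·tr(SΘ) − log det Θ + 2E, where E counts
nonzero strictly-upper-triangular entries of Θ (the diagonal is never zero,
so including it could only shift the AIC by a constant).  Penalties at
which the solver fails (the hub-model correlation matrix with n < p is
severely ill-conditioned at small λ) are dropped with a warning.  Θ̂ is
symmetrized by triangle averaging and converted to partial correlations
r_ij = −Θ_ij/√(Θ_ii Θ_jj); weights are |r_ij|.

Edge weights entering clustering are always absolute values, because the
topological overlap below requires nonnegative weights in [0, 1]; signs are
retained in the `PrecisionFit` for reporting.

## Step 2 — module detection

The topological overlap matrix

    TOM_ij = (Σ_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 − a_ij)

measures shared neighborhoods; dissTOM = 1 − TOM feeds average-linkage
(UPGMA) hierarchical clustering.

The dendrogram is cut by a simplified dynamic-hybrid rule.  TOM
dissimilarities concentrate most merge heights immediately below the
dendrogram top (for soft-thresholded networks more than half of all merges
can sit at height ≈ 1), so no pre-set cut height is reliable.  Instead, 40
candidate heights between the 5th-percentile merge height (controlled by
`deep_split`; level 2 = 5 %) and the top are scanned and the cut retaining
the most clusters of size ≥ `min_size` (default 20) is kept, ties going to
the higher cut.  Undersized clusters are dissolved; each dissolved feature
joins the retained cluster with the smallest average dissimilarity,
provided that distance does not exceed the cluster's own maximal internal
merge height, otherwise it stays unassigned (label 0).  Re-assignment
iterates to a fixed point; clusters are renumbered by decreasing size.  A
dendrogram with no height spread (empty network) leaves everything
unassigned.  Downstream, unassigned features form one extra group, so
uncorrelated variables still enter the prediction model.

Partition quality against a known reference module is scored by matching
the estimated cluster with the largest overlap (ties → smaller label):
TPR = |matched ∩ reference| / |reference|, FNR = 1 − TPR,
FPR = |matched \ reference| / (p − |reference|).

## Step 3 — prediction models

All fits column-standardize X and center y on the training data (the
intercept is unpenalized and equals the training mean); coefficients live
on the standardized scale and predictions apply the stored training
means/scales.

* **Hubs + ridge**: per module, the feature(s) with the largest count of
  nonzero within-module edges (all ties kept); ridge on the hub columns.
* **Group lasso**: ‖y − Xβ‖² + λ Σ_l √p_l ‖β_l‖₂, solved by block
  coordinate descent with *exact* block minimization — each block
  subproblem reduces, through the group's SVD, to a one-dimensional
  monotone root find solved by safeguarded Newton.  The λ path has 50 log
  points from λ_max (the KKT bound 2‖X_lᵀy‖/√p_l maximized over groups)
  down three decades, warm-started.
* **Sparse group lasso**: adds α λ‖β‖₁ against (1−α) λ Σ √p_l ‖β_l‖₂;
  block proximal gradient with the exact composite prox (coordinate
  soft-threshold, then group shrinkage); α ∈ {0.1, 0.5, 0.9} in the study
  grid.  α = 0 and α = 1 reduce to group lasso and lasso.
* **Adaptive group ridge**: ‖y − Xβ‖² + Σ_l λ_l ‖β_l‖², λ_l = λ′_l·λ,
  solved in closed form ((XᵀX + Λ)⁻¹Xᵀy, or the n×n dual when p > n).
  λ is tuned with all multipliers at 1; multipliers are then set by moment
  matching, λ′_l ∝ p_l / Σ_{q∈G_l}(β̂_q² + v̂ar_q) (sandwich variance,
  σ̂² = RSS/n), normalized to geometric mean 1 and clamped to
  [10⁻², 10²]; finally the global λ is re-tuned at the estimated
  multipliers.  The default is a **single** multiplier update: iterating
  the recipe to a fixed point has a runaway mode in which the signal
  group's penalty collapses, the fit interpolates, σ̂² → 0 and the
  remaining multipliers diverge (observed within six iterations on the
  simulator's own data).  With `max_iter` > 1 updates are damped (factor
  0.5 on the log scale); `max_iter = 0` reproduces ordinary ridge exactly.
* **Baselines**: lasso (‖y − Xβ‖² + λ‖β‖₁), ridge (+λ‖β‖²) and elastic
  net (coordinate-descent convention, mixing 0.5), via scikit-learn's path
  solvers; the convention makes singleton-group group lasso and lasso
  coincide at the same λ.

**Tuning.**  Every predictive penalty is tuned by inner 10-fold
cross-validated squared error with the one-standard-error rule (largest λ
within one SE of the minimum).  Plain argmin is unstable when the error
curve is flat: under a permuted outcome it picks arbitrarily small λ and
the double-CV Q² drops to −0.3; the 1-SE rule keeps the null Q² near zero
and leaves strong-signal fits unchanged (≈ .91 either way on scenario-a
data).  Tuning-path solver tolerance is 1e-5; the final fit at the chosen
λ uses 1e-7 (maximum coefficient change per sweep).

## Double cross-validation and Q²

The outer loop (default 10 folds, seeded, shuffled) measures prediction
only: network, clustering, and every tuning parameter are re-estimated
inside each training fold.  With p_i the held-out prediction for sample i
and p0_i the training-fold mean,

    Q² = 1 − Σ(y_i − p_i)² / Σ(y_i − p0_i)²,

the cross-validated fraction of variance explained (0 for the naive
predictor, 1 for perfect prediction, negative when worse than naive).
Selection stability counts, per feature, in how many outer folds its
coefficient is nonzero (|β| > 1e-8 — ridge-type models therefore select
everything, and are reported separately); summary counts are
"selected in all folds", "selected at least once", and their ratio.

## Simulator

Σ is block-diagonal under a hub observation model: module m (size p/k) has
one hub feature with correlation ρ_m to each member, member–member
correlation ρ_m², and the last module is the identity (uncorrelated
variables).  Defaults: ρ = (.9, .7, .5, 0) for k = 4 and
(.9, .8, .7, .6, .5, .4, .3, 0) for k = 8 — decreasing within-module
correlation plus one noise block.  A symmetric uniform perturbation
(half-width 0.05 by default) is added off-diagonal, the matrix is projected
to the nearest positive-definite matrix by eigenvalue clipping at 1e-6, and
the diagonal is renormalized to 1.  Rows of X are i.i.d. N(0, Σ).

The outcome loads on eigen-subspaces of Σ: with eigenvectors u_1 ≥ … ≥ u_p
(by eigenvalue; ties broken by index), scenario **a** sets β ∝ u_1,
**b** β ∝ u_4, **c** β ∝ u_1 + u_4, and y = Xβ + ε, ε ~ N(0, 1).  The
coefficient magnitude is calibrated **once**: it is chosen so the
population R² of the scenario-a component X u_1 equals 0.95, and that same
magnitude is reused unchanged for scenarios b and c — their weaker signal
is a consequence of the spectrum, not a separate dial.

What the simulator does *not* emulate: real metabolite/transcript marginal
distributions (log-normality, heavy tails, missingness), outcome
nonlinearity, and batch structure.  Passing tests therefore demonstrate
correctness of the machinery and behavior under a Gaussian hub-model
cartoon, not performance on real omics data.

## Problem sizes used in the shipped analyses

The replicated study in `scripts/acceptance.py` and the heavier tests use
the study's default dimensions (n = 50, p = 200, k = 4, 10 outer folds)
with 6–10 Monte-Carlo replicates per cell, a deliberate package choice
that keeps each summary's Monte-Carlo standard error small relative to the
differences of interest while remaining runnable on a laptop; the
graphical-lasso branch dominates the cost.  `double_cv` refuses the
graphical lasso above a configurable feature ceiling (default 2000).

## Known limitations

* The dynamic tree cut is a simplified re-implementation; it reproduces the
  qualitative behavior (few large modules from correlation networks, giant
  or empty partitions from over-shrunk partial-correlation networks) but
  not every heuristic of the reference algorithm, and module counts are
  sensitive to `min_size` and the candidate-cut grid.
* The adaptive group ridge multiplier scheme is a deliberately conservative
  stand-in for empirical-Bayes group-penalty estimation (single
  moment-matching update by default; see above).
* Only continuous outcomes and non-overlapping groups are supported.
* The graphical lasso inherits scikit-learn's solver fragility on
  ill-conditioned n < p correlation matrices; affected penalties are
  dropped from the grid rather than repaired.
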