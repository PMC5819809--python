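"""Double (nested) cross-validation of the full three-step pipeline.

The outer folds measure prediction only: inside each training fold the
network is estimated, modules are cut, and every tuning parameter is chosen
by inner cross-validation, so held-out samples never influence any part of
the fitted model.  Predictive ability is summarized by

    Q2 = 1 - sum (y_i - p_i)^2 / sum (y_i - p0_i)^2,

where p_i is the prediction for sample i from the fold where it was held
out and p0_i the naive prediction (the training-fold mean of y).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import KFold

from netpred import grouppred, network as netmod
from netpred.modules import ModulePartition, cut_modules, topological_overlap

NETWORK_METHODS = ("wgcna", "ggm_ridge", "glasso", "apriori", "none")
MODEL_METHODS = ("hubs", "grplasso", "sgl", "agr", "lasso", "ridge", "enet")
GROUPED_MODELS = ("hubs", "grplasso", "sgl", "agr")


@dataclass
class PipelineConfig:
    """One network + clustering + model combination.

    ``network='apriori'`` uses a supplied true partition and skips network
    estimation; ``network='none'`` is for the ungrouped baselines.
    """

    network: str = "wgcna"
    model: str = "grplasso"
    name: str | None = None
    alpha: float = 0.5
    min_size: int = 20
    deep_split: int = 2
    # hub-model data is not scale-free, so the scale-free search degenerates
    # to extreme powers; the pipeline defaults to the canonical unsigned
    # power 6 and only searches when given a larger grid
    powers: tuple = (6,)
    r2_target: float = 0.8
    ridge_grid: tuple = netmod.DEFAULT_RIDGE_GRID
    glasso_grid: tuple = netmod.DEFAULT_GLASSO_GRID
    fdr_level: float = 0.05
    inner_folds: int = 10
    lambda_grid: tuple | None = None
    glasso_p_ceiling: int = 2000

    def __post_init__(self):
        if self.network not in NETWORK_METHODS:
            raise ValueError(f"unknown network method {self.network!r}")
        if self.model not in MODEL_METHODS:
            raise ValueError(f"unknown model {self.model!r}")
        if self.model in GROUPED_MODELS and self.network == "none":
            raise ValueError(f"model {self.model!r} needs a network/partition")
        if self.name is None:
            self.name = (self.model if self.network == "none"
                         else f"{self.network}+{self.model}")


@dataclass
class CVReport:
    outer_folds: int
    predictions: np.ndarray
    naive_predictions: np.ndarray
    per_fold: list
    q2: float
    seed: int = 0


@dataclass
class StabilitySummary:
    always_selected: int
    at_least_once: int
    proportion: float
    per_feature_frequency: np.ndarray
    per_feature_mean_coef: np.ndarray


def q_squared(y, predictions, naive_predictions) -> float:
    """Cross-validated fraction of variance explained (1 - SSE/SSE0)."""
    y = np.asarray(y, dtype=float)
    p = np.asarray(predictions, dtype=float)
    p0 = np.asarray(naive_predictions, dtype=float)
    if not (y.size == p.size == p0.size):
        raise ValueError("length mismatch")
    denom = ((y - p0) ** 2).sum()
    if denom < 1e-300:
        raise ValueError("constant outcome: naive SSE is zero")
    return float(1.0 - ((y - p) ** 2).sum() / denom)


def _build_partition(Xtr, config: PipelineConfig, apriori_labels=None):
    """Network + clustering inside one training fold.

    Returns (labels, fold_meta).
    """
    meta = {"network": config.network}
    if config.network == "apriori":
        if apriori_labels is None:
            raise ValueError("apriori network requires apriori_labels")
        labels = np.asarray(apriori_labels, dtype=int)
        meta["n_modules"] = int(labels.max(initial=0))
        return labels, meta, None
    if config.network == "wgcna":
        sft = netmod.pick_soft_threshold(Xtr, config.powers, config.r2_target)
        net = netmod.pearson_adjacency(Xtr, sft.power)
        meta.update(power=sft.power,
                    scale_free_r2=sft.r2_by_power[sft.power],
                    gamma_hat=sft.gamma_hat)
    elif config.network == "ggm_ridge":
        net, fit, _ = netmod.ggm_ridge_network(Xtr, config.ridge_grid,
                                               config.fdr_level)
        meta.update(ridge_lambda=fit.lam)
    else:  # glasso
        net, fit = netmod.glasso_network(Xtr, config.glasso_grid)
        meta.update(glasso_lambda=fit.lam, aic=fit.aic,
                    n_edges=fit.n_nonzero)
    part = cut_modules(topological_overlap(net), config.min_size,
                       config.deep_split)
    meta["n_modules"] = part.n_modules
    return part.labels, meta, net


def _fit_model(Xtr, ytr, labels, net, config: PipelineConfig, seed: int):
    kw = dict(lambda_grid=config.lambda_grid,
              inner_folds=config.inner_folds, seed=seed)
    if config.model == "grplasso":
        return grouppred.fit_group_lasso(
            Xtr, ytr, ModulePartition.from_labels(labels), **kw)
    if config.model == "sgl":
        return grouppred.fit_sparse_group_lasso(
            Xtr, ytr, ModulePartition.from_labels(labels),
            alpha=config.alpha, **kw)
    if config.model == "agr":
        return grouppred.fit_adaptive_group_ridge(
            Xtr, ytr, ModulePartition.from_labels(labels), **kw)
    if config.model == "hubs":
        if net is None:
            raise ValueError("hub selection requires an estimated network")
        hubs = grouppred.select_hubs(net,
                                     ModulePartition.from_labels(labels))
        if not hubs.hubs:
            raise ValueError("no hubs selectable")
        return grouppred.fit_hub_ridge(Xtr, ytr, hubs, **kw)
    return grouppred.fit_baseline(Xtr, ytr, config.model,
                                  lambda_grid=config.lambda_grid,
                                  alpha=config.alpha,
                                  inner_folds=config.inner_folds, seed=seed)


def double_cv(X, y, config: PipelineConfig, outer_k: int = 10, seed: int = 0,
              apriori_labels=None) -> CVReport:
    """Nested cross-validation of network -> modules -> model.

    All estimation happens on the training portion of each outer fold; the
    held-out samples are only touched for prediction.  Fold assignment and
    every inner tuning split derive deterministically from ``seed``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if outer_k < 2:
        raise ValueError("outer_k must be >= 2")
    if n < 2 * outer_k:
        raise ValueError("need at least 2 samples per outer fold")
    if config.network == "glasso" and p > config.glasso_p_ceiling:
        raise ValueError(
            f"graphical lasso refused for p={p} > ceiling "
            f"{config.glasso_p_ceiling}; raise glasso_p_ceiling to override")

    kf = KFold(n_splits=outer_k, shuffle=True, random_state=seed)
    predictions = np.full(n, np.nan)
    naive = np.full(n, np.nan)
    per_fold = []
    for fold_id, (tr, te) in enumerate(kf.split(X)):
        Xtr, ytr = X[tr], y[tr]
        fold_seed = (seed * 1000003 + fold_id) % (2 ** 31)
        if config.network == "none":
            labels, meta, net = (np.zeros(p, dtype=int),
                                 {"network": "none", "n_modules": 0}, None)
        else:
            labels, meta, net = _build_partition(Xtr, config, apriori_labels)
        model = _fit_model(Xtr, ytr, labels, net, config, fold_seed)
        predictions[te] = grouppred.predict(model, X[te])
        naive[te] = ytr.mean()
        meta.update(fold=fold_id, model=config.model, lam=model.lam,
                    alpha=model.alpha,
                    module_labels=labels.copy(),
                    coef=model.coef.copy(),
                    selected=set(model.selected.tolist()))
        per_fold.append(meta)
    q2 = q_squared(y, predictions, naive)
    return CVReport(outer_folds=outer_k, predictions=predictions,
                    naive_predictions=naive, per_fold=per_fold, q2=q2,
                    seed=seed)


def selection_stability(report: CVReport) -> StabilitySummary:
    """Selection counts across outer folds and per-feature mean coefficients
    (zeros included), the quantity shown in per-feature coefficient
    boxplots."""
    coefs = np.vstack([f["coef"] for f in report.per_fold])
    freq = (np.abs(coefs) > grouppred.SELECT_TOL).sum(axis=0)
    always = int((freq == report.outer_folds).sum())
    once = int((freq > 0).sum())
    prop = always / once if once else 0.0
    return StabilitySummary(always_selected=always, at_least_once=once,
                            proportion=float(prop),
                            per_feature_frequency=freq,
                            per_feature_mean_coef=coefs.mean(axis=0))


def replicate_tables(scenarios, configs, M: int, seed: int = 0,
                     outer_k: int = 10, reference_modules=(1,),
                     verbose: bool = False):
    """Aggregate a replicated simulation into summary tables.

    Per scenario x config cell: mean and Monte-Carlo standard error of Q2,
    mean/min/max cluster count, and mean TPR/FNR/FPR for the reference
    modules.  Returns (summary DataFrame, per-replicate DataFrame).
    """
    from netpred import simdata

    res = simdata.run_simulation(scenarios, M, configs, seed=seed,
                                 outer_k=outer_k,
                                 reference_modules=reference_modules,
                                 verbose=verbose)
    rep = res["replicates"]
    group_cols = ["scenario", "n", "p", "k", "config"]
    rows = []
    for key, df in rep.groupby(group_cols):
        m = len(df)
        row = dict(zip(group_cols, key))
        row["M"] = m
        row["q2_mean"] = df["q2"].mean()
        row["q2_se"] = df["q2"].std(ddof=1) / np.sqrt(m) if m > 1 else 0.0
        row["clusters_mean"] = df["clusters_mean"].mean()
        row["clusters_se"] = (df["clusters_mean"].std(ddof=1) / np.sqrt(m)
                              if m > 1 else 0.0)
        row["clusters_min"] = int(df["clusters_min"].min())
        row["clusters_max"] = int(df["clusters_max"].max())
        for col in df.columns:
            if col.startswith(("tpr_", "fnr_", "fpr_")):
                row[col + "_mean"] = df[col].mean()
                row[col + "_se"] = (df[col].std(ddof=1) / np.sqrt(m)
                                    if m > 1 else 0.0)
        rows.append(row)
    import pandas as pd
    return pd.DataFrame(rows), rep
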