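"""Weighted feature-feature network estimation.

Three estimators are provided, all returning a :class:`WeightedNetwork`
whose entries lie in [0, 1] with zero diagonal:

* :func:`pearson_adjacency` / :func:`pick_soft_threshold` — soft-thresholded
  absolute Pearson correlation (WGCNA style), with the power chosen by the
  scale-free topology criterion;
* :func:`ggm_ridge_network` — ridge-penalized partial correlations,
  sparsified by testing Fisher-transformed entries against an empirical null
  estimated by Efron's central matching;
* :func:`glasso_network` — graphical-lasso precision matrix with the penalty
  chosen by AIC; edge weights are absolute partial correlations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.covariance import graphical_lasso as _sk_glasso
from sklearn.exceptions import ConvergenceWarning
from sklearn.model_selection import KFold
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests

DEFAULT_POWER_GRID = (1, 2, 3, 4, 5, 6, 7, 8, 9, 10, 12, 14, 16, 18, 20)
DEFAULT_RIDGE_GRID = tuple(np.geomspace(1e-3, 10.0, 20))
DEFAULT_GLASSO_GRID = tuple(np.geomspace(0.15, 0.8, 6))

_Z_CLIP = 6.0


@dataclass
class WeightedNetwork:
    """Symmetric nonnegative edge-weight matrix with per-node connectivity."""

    weights: np.ndarray
    method: str
    params: dict = field(default_factory=dict)

    def __post_init__(self):
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValueError("weights must be a square matrix")
        if not np.allclose(w, w.T, atol=1e-10):
            raise ValueError("weights must be symmetric")
        w = (w + w.T) / 2.0
        if w.min() < -1e-12 or w.max() > 1 + 1e-12:
            raise ValueError("weights must lie in [0, 1]")
        np.fill_diagonal(w, 0.0)
        self.weights = np.clip(w, 0.0, 1.0)

    @property
    def connectivity(self) -> np.ndarray:
        return self.weights.sum(axis=1)

    @property
    def n_features(self) -> int:
        return self.weights.shape[0]


@dataclass
class SoftThresholdFit:
    power: int
    r2_by_power: dict
    gamma_hat: float


@dataclass
class PrecisionFit:
    sample_cov: np.ndarray
    lam: float
    precision: np.ndarray
    partial_corr: np.ndarray
    loglik: float = np.nan
    aic: float = np.nan
    n_nonzero: int = 0


@dataclass
class EmpiricalNullTest:
    z_values: np.ndarray
    null_mean: float
    null_sd: float
    p_values: np.ndarray
    q_values: np.ndarray


def _standardize_columns(X):
    X = np.asarray(X, dtype=float)
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    zero = sd < 1e-12
    if zero.any():
        warnings.warn(f"{int(zero.sum())} zero-variance feature(s); "
                      "their correlations are set to 0")
    sd_safe = np.where(zero, 1.0, sd)
    return (X - mu) / sd_safe, zero


def _safe_corr(X):
    """Pearson correlation with zero-variance columns mapped to 0 rows."""
    Xs, zero = _standardize_columns(X)
    n = Xs.shape[0]
    C = Xs.T @ Xs / n
    C[zero, :] = 0.0
    C[:, zero] = 0.0
    np.fill_diagonal(C, 1.0)
    return np.clip(C, -1.0, 1.0)


def pearson_adjacency(X, power: int = 6) -> WeightedNetwork:
    """Unsigned WGCNA adjacency a_ij = |cor(x_i, x_j)|**power."""
    if power < 1:
        raise ValueError("power must be >= 1")
    X = np.asarray(X, dtype=float)
    if X.shape[0] < 3:
        raise ValueError("need at least 3 samples")
    A = np.abs(_safe_corr(X)) ** power
    np.fill_diagonal(A, 0.0)
    return WeightedNetwork(A, method="wgcna", params={"power": int(power)})


def scale_free_fit(connectivity, nbins: int = 10):
    """Goodness of fit of P(k) ~ k^-gamma on binned connectivities.

    Bins the observed connectivities into ``nbins`` equal-width bins,
    regresses log10(frequency) on log10(mean bin connectivity) and returns
    ``(r2_signed, gamma_hat)`` where the R2 is negated when the slope is
    positive (a rising degree distribution is *anti* scale-free).
    """
    k = np.asarray(connectivity, dtype=float)
    if np.ptp(k) < 1e-12:
        raise ValueError("degenerate degree distribution")
    edges = np.linspace(k.min(), k.max(), nbins + 1)
    idx = np.clip(np.digitize(k, edges[1:-1]), 0, nbins - 1)
    xs, ys = [], []
    for b in range(nbins):
        mask = idx == b
        if not mask.any():
            continue
        mean_k = k[mask].mean()
        if mean_k <= 0:
            continue
        xs.append(np.log10(mean_k))
        ys.append(np.log10(mask.sum() / k.size))
    if len(xs) < 2:
        raise ValueError("degenerate degree distribution")
    res = stats.linregress(xs, ys)
    r2 = res.rvalue ** 2
    if res.slope > 0:
        r2 = -r2
    return float(r2), float(-res.slope)


def pick_soft_threshold(X, powers=DEFAULT_POWER_GRID,
                        r2_target: float = 0.8) -> SoftThresholdFit:
    """Choose the soft-threshold power by the scale-free topology criterion.

    Returns the smallest power whose binned log-log degree fit reaches
    ``r2_target``; if none does, the power maximizing the (signed) R2.
    """
    powers = [int(p) for p in powers]
    if not powers:
        raise ValueError("empty power grid")
    C = np.abs(_safe_corr(np.asarray(X, dtype=float)))
    np.fill_diagonal(C, 0.0)
    r2_by_power, gamma_by_power = {}, {}
    for pw in powers:
        k = (C ** pw).sum(axis=1)
        r2, gamma = scale_free_fit(k)
        r2_by_power[pw] = r2
        gamma_by_power[pw] = gamma
    chosen = None
    for pw in sorted(powers):
        if r2_by_power[pw] >= r2_target:
            chosen = pw
            break
    if chosen is None:
        chosen = max(sorted(powers), key=lambda pw: r2_by_power[pw])
    return SoftThresholdFit(power=chosen, r2_by_power=r2_by_power,
                            gamma_hat=gamma_by_power[chosen])


def _partial_corr_from_precision(theta):
    d = np.sqrt(np.clip(np.diag(theta), 1e-300, None))
    R = -theta / np.outer(d, d)
    R = (R + R.T) / 2.0
    np.fill_diagonal(R, 1.0)
    return np.clip(R, -1.0, 1.0)


def empirical_null(z_values, nbins: int = 120, central: float = 0.5):
    """Estimate the null mean/sd of z-statistics by Efron's central matching.

    A quadratic in z is fitted by Poisson regression to the histogram counts
    in the central ``central`` fraction of the histogram's range (120
    equal-width bins by default); the implied normal density gives the null
    parameters.  Falls back to the mean/sd of the central window when the
    quadratic is not concave.
    """
    z = np.asarray(z_values, dtype=float)
    if z.size < 10:
        return float(np.mean(z)), float(max(np.std(z), 1e-8))
    counts, edges = np.histogram(z, bins=nbins)
    centers = (edges[:-1] + edges[1:]) / 2.0
    mid = (edges[0] + edges[-1]) / 2.0
    half = central * (edges[-1] - edges[0]) / 2.0
    lo, hi = mid - half, mid + half
    keep = (centers >= lo) & (centers <= hi)
    zc = z[(z >= lo) & (z <= hi)]
    fallback = (float(np.mean(zc)), float(max(np.std(zc), 1e-8)))
    if keep.sum() < 5:
        return fallback
    Xd = np.column_stack([np.ones(keep.sum()), centers[keep],
                          centers[keep] ** 2])
    try:
        fit = sm.GLM(counts[keep], Xd, family=sm.families.Poisson()).fit()
        b1, b2 = fit.params[1], fit.params[2]
    except Exception:
        return fallback
    if b2 >= -1e-12:
        return fallback
    sd = float(np.sqrt(-1.0 / (2.0 * b2)))
    mean = float(b1 * sd * sd)
    return mean, sd


def ggm_ridge_network(X, lambda_grid=DEFAULT_RIDGE_GRID,
                      fdr_level: float = 0.05, cv_folds: int = 5,
                      random_state: int = 0):
    """Ridge-penalized partial-correlation network with empirical-null edges.

    The ridge penalty is chosen from ``lambda_grid`` by maximizing held-out
    Gaussian log-likelihood over ``cv_folds`` internal folds.  Partial
    correlations are ``-scale((S + lambda I)^-1)``; each off-diagonal entry
    is Fisher-transformed and tested against the central-matching empirical
    null; entries not significant after Benjamini-Hochberg control at
    ``fdr_level`` are zeroed.  Edge weights are absolute surviving partial
    correlations.
    """
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if p < 2:
        raise ValueError("need at least 2 features")
    lambda_grid = [float(l) for l in lambda_grid]
    if any(l <= 0 for l in lambda_grid):
        raise ValueError("ridge lambda values must be > 0")

    Xs, _ = _standardize_columns(X)
    kf = KFold(n_splits=min(cv_folds, n), shuffle=True,
               random_state=random_state)
    scores = np.zeros(len(lambda_grid))
    for tr, te in kf.split(Xs):
        S_tr = np.cov(Xs[tr], rowvar=False, bias=True)
        S_te = np.cov(Xs[te], rowvar=False, bias=True)
        for j, lam in enumerate(lambda_grid):
            theta = np.linalg.inv(S_tr + lam * np.eye(p))
            sign, logdet = np.linalg.slogdet(theta)
            scores[j] += logdet - np.trace(S_te @ theta)
    lam = lambda_grid[int(np.argmax(scores))]

    S = np.cov(Xs, rowvar=False, bias=True)
    theta = np.linalg.inv(S + lam * np.eye(p))
    R = _partial_corr_from_precision(theta)

    iu = np.triu_indices(p, 1)
    r = R[iu]
    with np.errstate(divide="ignore"):
        z = np.arctanh(np.clip(r, -1 + 1e-16, 1 - 1e-16))
    if np.any(np.abs(z) > _Z_CLIP):
        warnings.warn("|partial correlation| near 1; Fisher z clipped at +-6")
        z = np.clip(z, -_Z_CLIP, _Z_CLIP)

    null_mean, null_sd = empirical_null(z)
    pvals = 2.0 * stats.norm.sf(np.abs(z - null_mean) / null_sd)
    reject, qvals, _, _ = multipletests(pvals, alpha=fdr_level,
                                        method="fdr_bh")[:4]

    W = np.zeros((p, p))
    W[iu] = np.where(reject, np.abs(r), 0.0)
    W = W + W.T
    net = WeightedNetwork(W, method="ggm_ridge",
                          params={"lambda": lam, "fdr_level": fdr_level,
                                  "null_mean": null_mean,
                                  "null_sd": null_sd})
    fit = PrecisionFit(sample_cov=S, lam=lam, precision=theta,
                       partial_corr=R)
    test = EmpiricalNullTest(z_values=z, null_mean=null_mean,
                             null_sd=null_sd, p_values=pvals,
                             q_values=qvals)
    return net, fit, test


def glasso_aic(S, theta, n: int, tol: float = 1e-8) -> float:
    """AIC = n * tr(S Theta) - log det(Theta) + 2E, with E the number of
    nonzero strictly-upper-triangular entries of Theta."""
    sign, logdet = np.linalg.slogdet(theta)
    if sign <= 0:
        return np.inf
    E = int((np.abs(theta[np.triu_indices(theta.shape[0], 1)]) > tol).sum())
    return float(n * np.trace(S @ theta) - logdet + 2 * E)


def glasso_network(X, lambda_grid=DEFAULT_GLASSO_GRID, max_iter: int = 50,
                   tol: float = 1e-2):
    """Graphical-lasso partial-correlation network with AIC model selection.

    Each penalty in ``lambda_grid`` is fitted by the graphical lasso
    (off-diagonal L1 penalty on the precision matrix); penalties at which
    the solver fails to converge are dropped with a warning.  The penalty
    minimizing AIC is kept; the precision matrix is symmetrized by averaging
    its triangles and converted to partial correlations.
    """
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if n < 3:
        raise ValueError("need at least 3 samples")
    lambda_grid = [float(l) for l in lambda_grid]
    if any(l < 0 for l in lambda_grid):
        raise ValueError("lasso lambda values must be >= 0")

    S = _safe_corr(X)
    best = None
    for lam in lambda_grid:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("error", ConvergenceWarning)
                if lam < 1e-12:
                    theta = np.linalg.inv(S)
                else:
                    _, theta = _sk_glasso(S, alpha=lam, max_iter=max_iter,
                                          tol=tol)
        except (FloatingPointError, np.linalg.LinAlgError,
                ConvergenceWarning, ValueError) as exc:
            warnings.warn(f"graphical lasso failed at lambda={lam:.4g} "
                          f"({type(exc).__name__}); dropped")
            continue
        aic = glasso_aic(S, theta, n)
        if best is None or aic < best[0]:
            best = (aic, lam, theta)
    if best is None:
        raise RuntimeError("graphical lasso failed at every lambda")

    aic, lam, theta = best
    theta = (theta + theta.T) / 2.0
    R = _partial_corr_from_precision(theta)
    W = np.abs(R)
    np.fill_diagonal(W, 0.0)
    # solver tolerance leaves tiny nonzeros; treat them as absent edges
    W[W < 1e-8] = 0.0
    E = int((np.abs(theta[np.triu_indices(p, 1)]) > 1e-8).sum())
    sign, logdet = np.linalg.slogdet(theta)
    loglik = float(logdet - np.trace(S @ theta))
    net = WeightedNetwork(W, method="ggm_lasso",
                          params={"lambda": lam, "aic": aic})
    fit = PrecisionFit(sample_cov=S, lam=lam, precision=theta,
                       partial_corr=R, loglik=loglik, aic=aic, n_nonzero=E)
    return net, fit
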