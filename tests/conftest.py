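import numpy as np
import pytest

import netpred as nps


@pytest.fixture(scope="session")
def hub_dataset():
    """One scenario-a dataset at the study's default size (n=50, p=200)."""
    scn = nps.SimScenario(n_samples=50, n_features=200, n_modules=4,
                          scenario="a", seed=42)
    X, y, truth = nps.simulate_dataset(scn)
    return X, y, truth


@pytest.fixture()
def small_regression():
    """Random 30x8 instance with 3 groups (n > p: unique optima)."""
    rng = np.random.default_rng(5)
    X = rng.standard_normal((30, 8))
    beta = np.array([1.0, -0.5, 0.0, 0.0, 2.0, 0.0, 0.0, 0.3])
    y = X @ beta + rng.normal(0, 0.5, 30)
    labels = np.array([1, 1, 1, 2, 2, 2, 3, 3])
    return X, y, labels


def fista(Xs, yc, prox, lipschitz, n_iter=20000, tol=1e-12):
    """Generic accelerated proximal-gradient reference solver.

    Minimizes ||y - X b||^2 + P(b) where ``prox(v, step)`` is the proximal
    operator of P.  Used as an independent oracle for the coordinate-descent
    and block-descent solvers in the package.
    """
    p = Xs.shape[1]
    b = np.zeros(p)
    z = b.copy()
    tk = 1.0
    L = 2.0 * lipschitz
    for _ in range(n_iter):
        grad = -2.0 * (Xs.T @ (yc - Xs @ z))
        b_new = prox(z - grad / L, 1.0 / L)
        tk_new = (1.0 + np.sqrt(1.0 + 4.0 * tk * tk)) / 2.0
        z = b_new + ((tk - 1.0) / tk_new) * (b_new - b)
        if np.abs(b_new - b).max() < tol:
            b = b_new
            break
        b, tk = b_new, tk_new
    return b


def group_prox(labels, lam, alpha=0.0):
    """Proximal operator of the (sparse) group lasso penalty."""
    labels = np.asarray(labels)

    def prox(v, step):
        out = np.empty_like(v)
        for l in np.unique(labels):
            idx = np.flatnonzero(labels == l)
            w = np.sqrt(idx.size)
            u = v[idx]
            u = np.sign(u) * np.maximum(np.abs(u) - step * alpha * lam, 0.0)
            nu = np.linalg.norm(u)
            t2 = step * (1.0 - alpha) * lam * w
            out[idx] = np.zeros_like(u) if nu <= t2 else (1 - t2 / nu) * u
        return out
    return prox
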