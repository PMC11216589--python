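"""Independently coded reference implementations used as test oracles.

These deliberately avoid the package's code paths and scikit-learn: PLS is
a from-scratch NIPALS power iteration, PCA a brute-force eigendecomposition
of the sample covariance, and the cross-validation bookkeeping is written
out longhand.  They are slow and only meant for tiny fixtures.
"""

from __future__ import annotations

import numpy as np


def nipals_pls(X, Y, n_components, tol=1e-13, max_iter=5000):
    """NIPALS PLS2 with centered X and Y (no variance scaling).

    Returns a predictor closure.  Mode-A deflation with regression of Y on
    the X scores, matching the textbook algorithm.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    x_mean, y_mean = X.mean(axis=0), Y.mean(axis=0)
    Xr, Yr = X - x_mean, Y - y_mean
    n, p = Xr.shape
    q = Yr.shape[1]
    W = np.zeros((p, n_components))
    P = np.zeros((p, n_components))
    Q = np.zeros((q, n_components))
    for a in range(n_components):
        # start from the Y column with largest variance
        u = Yr[:, np.argmax(Yr.var(axis=0))].copy()
        w_old = None
        for _ in range(max_iter):
            w = Xr.T @ u
            nw = np.linalg.norm(w)
            if nw < 1e-300:
                break
            w /= nw
            t = Xr @ w
            c = Yr.T @ t / (t @ t)
            u = Yr @ c / (c @ c)
            if w_old is not None and np.linalg.norm(w - w_old) < tol:
                break
            w_old = w
        t = Xr @ w
        tt = t @ t
        p_load = Xr.T @ t / tt
        q_load = Yr.T @ t / tt
        Xr = Xr - np.outer(t, p_load)
        Yr = Yr - np.outer(t, q_load)
        W[:, a], P[:, a], Q[:, a] = w, p_load, q_load
    coef = W @ np.linalg.pinv(P.T @ W) @ Q.T

    def predict(Xnew):
        return (np.asarray(Xnew, dtype=float) - x_mean) @ coef + y_mean

    return predict


def pearson(a, b):
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    a = a - a.mean()
    b = b - b.mean()
    denom = np.sqrt((a**2).sum() * (b**2).sum())
    if denom < 1e-14:
        return float("nan")
    return float((a * b).sum() / denom)


def reference_scores(X_train, X_other, Y_train, Y_other, n_folds, n_components,
                     n_repetitions, seed):
    """Longhand cross-validated scoring of one layer.

    Reproduces the contract: per repetition, stimuli are permuted with
    default_rng(seed + r) and split into n_folds near-equal folds; per fold
    a PLS is fitted on the complement; training-domain score pools held-out
    predictions across folds; other-domain score correlates fold-averaged
    predictions.  Returns (id-like scores, other scores), each
    (n_repetitions, n_sites).
    """
    n_train, n_sites = Y_train.shape
    r_train = np.zeros((n_repetitions, n_sites))
    r_other = np.zeros((n_repetitions, n_sites))
    for rep in range(n_repetitions):
        rng = np.random.default_rng(seed + rep)
        order = rng.permutation(n_train)
        folds = np.array_split(order, n_folds)
        held_out = np.zeros_like(Y_train)
        other_sum = np.zeros_like(Y_other)
        for test_idx in folds:
            mask = np.ones(n_train, dtype=bool)
            mask[test_idx] = False
            m = min(n_components, int(mask.sum()) - 1, X_train.shape[1])
            predictor = nipals_pls(X_train[mask], Y_train[mask], m)
            held_out[np.sort(test_idx)] = predictor(X_train[np.sort(test_idx)])
            other_sum += predictor(X_other)
        other_avg = other_sum / n_folds
        for j in range(n_sites):
            r_train[rep, j] = pearson(held_out[:, j], Y_train[:, j])
            r_other[rep, j] = pearson(other_avg[:, j], Y_other[:, j])
    return r_train, r_other


def brute_force_pca(X):
    """Eigendecomposition of the sample covariance, eigenvalues descending."""
    X = np.asarray(X, dtype=float)
    Xc = X - X.mean(axis=0)
    cov = Xc.T @ Xc / (X.shape[0] - 1)
    vals, vecs = np.linalg.eigh(cov)
    order = np.argsort(vals)[::-1]
    return vals[order], vecs[:, order]
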