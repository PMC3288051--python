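"""Independent reference implementations used as test oracles.

These deliberately avoid the package's correlation-matrix code path: the PLS
iteration below works in score space, column by column, the way the algorithm
is written on paper, and the OLS solves use raw normal equations.
"""

from __future__ import annotations

import numpy as np


def naive_two_block_plspm(X, block1, block2, tol=1e-10, max_iter=2000):
    """Score-space centroid/mode-A PLS path fit for two blocks.

    Returns (beta, loadings) with the sum-of-loadings >= 0 sign convention
    per block; ``block1``/``block2`` are column index lists into ``X``.
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    Z = (X - X.mean(0)) / X.std(0, ddof=1)
    blocks = [np.asarray(block1), np.asarray(block2)]
    W = [np.ones(len(b)) for b in blocks]

    def block_scores(W):
        out = []
        for b, w in zip(blocks, W):
            s = Z[:, b] @ w
            out.append(s / s.std(ddof=1))
        return out

    for _ in range(max_iter):
        s1, s2 = block_scores(W)
        c = np.corrcoef(s1, s2)[0, 1]
        inner = [np.sign(c) * s2, np.sign(c) * s1]
        W_new = []
        for b, z in zip(blocks, inner):
            w = Z[:, b].T @ z / (n - 1)
            s = Z[:, b] @ w
            W_new.append(w / s.std(ddof=1))
        # compare in the projective sense (signs are unidentified mid-stream)
        diffs = []
        for w_old, w_new in zip(W, W_new):
            diffs.append(min(np.abs(w_new - w_old).max(),
                             np.abs(w_new + w_old).max()))
        W = [w if np.abs(w - o).max() <= np.abs(w + o).max() else -w
             for w, o in zip(W_new, W)]
        if max(diffs) < tol:
            break

    s1, s2 = block_scores(W)
    scores = [s1, s2]
    loadings = np.empty(X.shape[1])
    signs = []
    for k, b in enumerate(blocks):
        lam = np.array([np.corrcoef(Z[:, j], scores[k])[0, 1] for j in b])
        sgn = 1.0 if lam.sum() >= 0 else -1.0
        loadings[b] = sgn * lam
        signs.append(sgn)
    beta = signs[0] * signs[1] * np.corrcoef(s1, s2)[0, 1]
    return float(beta), loadings


def ols_solve(X, y):
    """Slope vector from raw normal equations (intercept prepended)."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    A = np.column_stack([np.ones(len(y)), X])
    return np.linalg.solve(A.T @ A, A.T @ y)


def ols_slope_inference(x, y):
    """Slope, SE, two-sided t-test p for simple regression y ~ 1 + x."""
    from scipy import stats

    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(y)
    A = np.column_stack([np.ones(n), x])
    coef = np.linalg.solve(A.T @ A, A.T @ y)
    resid = y - A @ coef
    s2 = resid @ resid / (n - 2)
    cov = s2 * np.linalg.inv(A.T @ A)
    se = np.sqrt(cov[1, 1])
    t = coef[1] / se
    p = 2 * stats.t.sf(abs(t), n - 2)
    return float(coef[1]), float(se), float(p)
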