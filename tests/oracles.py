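"""Independent reference implementations used only to cross-check results.

These deliberately avoid the code paths (and, where possible, the libraries)
used by the package: AUC by brute-force pair counting / the Mann-Whitney U
statistic computed from first principles, logistic regression by a hand-written
IRLS loop, and the Welch t-test from its closed form.
"""

from __future__ import annotations

import numpy as np


def brute_force_auc(pos_scores, neg_scores) -> float:
    """P(random positive > random negative), ties scoring 1/2."""
    total = 0.0
    for p in pos_scores:
        for n in neg_scores:
            if p > n:
                total += 1.0
            elif p == n:
                total += 0.5
    return total / (len(pos_scores) * len(neg_scores))


def mann_whitney_auc(y, scores) -> float:
    """AUC via the U statistic computed from midranks, no scipy."""
    y = np.asarray(y, dtype=bool)
    s = np.asarray(scores, dtype=float)
    order = np.argsort(s, kind="mergesort")
    ranks = np.empty(s.size, dtype=float)
    sorted_s = s[order]
    i = 0
    while i < s.size:
        j = i
        while j + 1 < s.size and sorted_s[j + 1] == sorted_s[i]:
            j += 1
        ranks[order[i:j + 1]] = 0.5 * (i + j) + 1.0  # average of 1-based ranks
        i = j + 1
    n1 = int(y.sum())
    n0 = y.size - n1
    u = ranks[y].sum() - n1 * (n1 + 1) / 2.0
    return u / (n1 * n0)


def irls_logistic(X, y, ridge: float, max_iter: int = 200,
                  tol: float = 1e-12) -> tuple[np.ndarray, float]:
    """Ridge-penalized logistic regression by iteratively reweighted least
    squares; the intercept is unpenalized. Returns (coef, intercept)."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, d = X.shape
    Z = np.hstack([np.ones((n, 1)), X])
    beta = np.zeros(d + 1)
    P = np.eye(d + 1) * ridge
    P[0, 0] = 0.0
    for _ in range(max_iter):
        eta = Z @ beta
        p = 1.0 / (1.0 + np.exp(-eta))
        grad = Z.T @ (p - y) + P @ beta
        W = p * (1.0 - p)
        H = (Z * W[:, None]).T @ Z + P
        step = np.linalg.solve(H, grad)
        beta -= step
        if np.max(np.abs(grad)) < tol:
            break
    return beta[1:], float(beta[0])


def welch_t(a, b) -> tuple[float, float]:
    """Closed-form Welch statistic and Welch-Satterthwaite df (t, df)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    va, vb = a.var(ddof=1) / a.size, b.var(ddof=1) / b.size
    t = (a.mean() - b.mean()) / np.sqrt(va + vb)
    df = (va + vb) ** 2 / (va**2 / (a.size - 1) + vb**2 / (b.size - 1))
    return float(t), float(df)
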