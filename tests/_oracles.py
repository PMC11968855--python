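"""Independent oracles used by the test suite.

These deliberately use different algorithms from the package code paths
they check (normal equations, pairwise enumeration, proximal gradient).
"""

from __future__ import annotations

import numpy as np


def ols_oracle(design: np.ndarray, y: np.ndarray, coef_index: int):
    """(beta, se, t) for one coefficient by explicit normal equations."""
    dtd = design.T @ design
    dtd_inv = np.linalg.inv(dtd)
    coef = dtd_inv @ design.T @ y
    resid = y - design @ coef
    df = design.shape[0] - design.shape[1]
    sigma2 = float(resid @ resid) / df
    se = np.sqrt(dtd_inv[coef_index, coef_index] * sigma2)
    return float(coef[coef_index]), float(se), df


def roc_auc_pairs(labels: np.ndarray, score: np.ndarray) -> float:
    """O(n^2) enumeration of case-control pairs with half credit for ties."""
    pos = score[np.asarray(labels, dtype=bool)]
    neg = score[~np.asarray(labels, dtype=bool)]
    wins = 0.0
    for a in pos:
        for b in neg:
            if a > b:
                wins += 1.0
            elif a == b:
                wins += 0.5
    return wins / (len(pos) * len(neg))


def pr_auc_threshold_sweep(labels: np.ndarray, score: np.ndarray) -> float:
    """Threshold-by-threshold PR area: sum precision * recall increments."""
    labels = np.asarray(labels, dtype=bool)
    score = np.asarray(score, dtype=float)
    n_pos = labels.sum()
    area = 0.0
    prev_recall = 0.0
    for thr in sorted(set(score), reverse=True):
        called = score >= thr
        tp = (called & labels).sum()
        precision = tp / called.sum()
        recall = tp / n_pos
        area += (recall - prev_recall) * precision
        prev_recall = recall
    return float(area)


def elastic_net_objective(x, y, beta, lam, alpha):
    """(1/2n)||y - Xb||^2 + lam * (alpha ||b||_1 + (1-alpha)/2 ||b||^2)."""
    n = len(y)
    resid = y - x @ beta
    return (
        0.5 * float(resid @ resid) / n
        + lam * (alpha * np.abs(beta).sum() + 0.5 * (1 - alpha) * float(beta @ beta))
    )


def elastic_net_fista(x, y, lam, alpha, n_iter=20000, tol=1e-12):
    """Accelerated proximal-gradient solver for the elastic-net objective."""
    n, p = x.shape
    lip = np.linalg.norm(x, ord=2) ** 2 / n + lam * (1 - alpha)
    beta = np.zeros(p)
    z = beta.copy()
    t = 1.0
    obj_prev = np.inf
    for _ in range(n_iter):
        grad = -(x.T @ (y - x @ z)) / n + lam * (1 - alpha) * z
        u = z - grad / lip
        thr = lam * alpha / lip
        beta_new = np.sign(u) * np.maximum(np.abs(u) - thr, 0.0)
        t_new = 0.5 * (1 + np.sqrt(1 + 4 * t * t))
        z = beta_new + (t - 1) / t_new * (beta_new - beta)
        beta, t = beta_new, t_new
        obj = elastic_net_objective(x, y, beta, lam, alpha)
        if abs(obj_prev - obj) < tol * max(1.0, abs(obj)):
            break
        obj_prev = obj
    return beta


def elastic_net_kkt_violation(x, y, beta, lam, alpha):
    """Max KKT violation of the elastic-net stationarity conditions."""
    n = len(y)
    grad = -(x.T @ (y - x @ beta)) / n + lam * (1 - alpha) * beta
    viol = np.where(
        beta == 0.0,
        np.maximum(np.abs(grad) - lam * alpha, 0.0),
        np.abs(grad + lam * alpha * np.sign(beta)),
    )
    return float(viol.max())


def ridge_solution(x, y, lam):
    p = x.shape[1]
    return np.linalg.solve(x.T @ x + lam * np.eye(p), x.T @ y)
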