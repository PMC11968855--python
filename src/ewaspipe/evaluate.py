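"""Benchmarking of smoking scores against self-report.

Incremental R^2 compares nested least-squares fits (age + sex vs
age + sex + score).  ROC-AUC uses the rank statistic
P(score_case > score_control) + 0.5 P(tie); PR-AUC integrates the
precision-recall curve step-wise over thresholds at the observed scores,
with precision at recall 0 anchored to the highest-score threshold.
Contrasts are pairwise one-vs-one over smoking categories.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "incremental_r2",
    "roc_auc",
    "pr_auc",
    "correlations",
    "evaluation_report",
]

CONTRASTS = (
    ("current", "never"),
    ("current", "former"),
    ("former", "never"),
)


def _r2(design: np.ndarray, y: np.ndarray) -> float:
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ coef
    tss = ((y - y.mean()) ** 2).sum()
    if tss == 0:
        raise ValueError("response has zero variance")
    return 1.0 - (resid**2).sum() / tss


def incremental_r2(y, score, age, sex) -> float:
    """R^2(y ~ age + sex + score) - R^2(y ~ age + sex)."""
    y = np.asarray(y, dtype=float)
    if len(y) <= 4:
        raise ValueError("need more than 4 samples")
    sex01 = pd.Series(sex).astype(str).map(
        {"F": 0.0, "M": 1.0, "0": 0.0, "1": 1.0}
    ).to_numpy()
    null = np.column_stack([np.ones(len(y)), np.asarray(age, float), sex01])
    full = np.column_stack([null, np.asarray(score, float)])
    if np.linalg.matrix_rank(null) < null.shape[1]:
        raise ValueError("collinear covariates in null model")
    return _r2(full, y) - _r2(null, y)


def roc_auc(labels, score) -> float:
    """Probability a random positive outranks a random negative (ties 1/2)."""
    labels = np.asarray(labels).astype(bool)
    score = np.asarray(score, dtype=float)
    n_pos = int(labels.sum())
    n_neg = int((~labels).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    ranks = stats.rankdata(score)  # average ranks handle ties
    return float((ranks[labels].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def pr_auc(labels, score) -> float:
    """Step-wise area under the precision-recall curve at observed thresholds."""
    labels = np.asarray(labels).astype(bool)
    score = np.asarray(score, dtype=float)
    n_pos = int(labels.sum())
    if n_pos == 0:
        raise ValueError("positive class absent")
    order = np.argsort(-score, kind="mergesort")
    sorted_labels = labels[order]
    sorted_scores = score[order]
    tp = np.cumsum(sorted_labels)
    fp = np.cumsum(~sorted_labels)
    # evaluate at the last index of each distinct threshold
    distinct = np.r_[sorted_scores[1:] != sorted_scores[:-1], True]
    tp = tp[distinct]
    fp = fp[distinct]
    precision = tp / (tp + fp)
    recall = tp / n_pos
    prev_recall = np.r_[0.0, recall[:-1]]
    return float(((recall - prev_recall) * precision).sum())


def correlations(y, score) -> tuple[float, float]:
    """(Pearson r, Spearman r with average ranks for ties)."""
    y = np.asarray(y, dtype=float)
    score = np.asarray(score, dtype=float)
    if len(y) < 3:
        raise ValueError("need at least 3 samples")
    if np.ptp(y) == 0 or np.ptp(score) == 0:
        raise ValueError("zero variance input")
    pearson = stats.pearsonr(y, score).statistic
    spearman = stats.spearmanr(y, score).statistic
    return float(pearson), float(spearman)


def evaluation_report(
    status,
    y,
    score,
    age,
    sex,
) -> dict:
    """All metrics for a cohort: incremental R^2, correlations, per-contrast AUCs."""
    status = pd.Series(status).astype(str)
    score = np.asarray(score, dtype=float)
    report: dict = {
        "incremental_r2": incremental_r2(y, score, age, sex),
    }
    pearson, spearman = correlations(y, score)
    report["pearson_r"] = pearson
    report["spearman_r"] = spearman
    for pos, neg in CONTRASTS:
        sel = status.isin((pos, neg)).to_numpy()
        key = f"{pos}_vs_{neg}"
        labels = (status[sel] == pos).to_numpy()
        if labels.any() and not labels.all():
            report[f"auc_{key}"] = roc_auc(labels, score[sel])
            report[f"prauc_{key}"] = pr_auc(labels, score[sel])
            report[f"n_{key}"] = int(sel.sum())
        else:
            report[f"auc_{key}"] = float("nan")
            report[f"prauc_{key}"] = float("nan")
            report[f"n_{key}"] = int(sel.sum())
    return report
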