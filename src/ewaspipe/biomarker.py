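"""Elastic-net methylation score of cumulative smoking, plus a single-site score.

Training minimizes (1/2n)||y - Xb||^2 + lambda [alpha ||b||_1 +
(1 - alpha)/2 ||b||^2] with alpha fixed (0.5 by default) and lambda chosen
to minimize mean squared prediction error over seeded k-fold
cross-validation on a log-spaced path from lambda_max down four decades.
Predictors are standardized internally for the penalty; stored weights
apply to raw beta values so the model projects onto new cohorts, with
training-mean imputation for absent sites.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import ElasticNet, enet_path

from ._rng import rng_for

logger = logging.getLogger(__name__)

__all__ = [
    "BiomarkerModel",
    "prefilter_sites",
    "train_elastic_net",
    "score",
    "train_single_site",
]


@dataclass
class BiomarkerModel:
    """Sparse linear methylation score on raw beta values."""

    intercept: float
    weights: pd.Series  # site_id -> coefficient, non-zero entries only
    training_means: pd.Series  # site_id -> mean methylation in training data
    alpha: float
    lambda_selected: float
    n_train: int
    n_features_prefilter: int
    cv_lambda_path: np.ndarray | None = field(default=None, repr=False)
    cv_mse: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must be in [0, 1]")
        missing = self.weights.index.difference(self.training_means.index)
        if len(missing):
            raise ValueError("every weighted site needs a stored training mean")

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("site_id\tweight\ttraining_mean\n")
            fh.write(f"(intercept)\t{float(self.intercept)!r}\t0\n")
            for sid in self.weights.index:
                fh.write(
                    f"{sid}\t{float(self.weights[sid])!r}\t"
                    f"{float(self.training_means[sid])!r}\n"
                )

    @classmethod
    def from_tsv(cls, path, alpha: float = 0.5) -> "BiomarkerModel":
        df = pd.read_csv(path, sep="\t", float_precision="round_trip")
        inter = df[df["site_id"] == "(intercept)"]
        intercept = float(inter["weight"].iloc[0]) if len(inter) else 0.0
        body = df[df["site_id"] != "(intercept)"]
        return cls(
            intercept=intercept,
            weights=pd.Series(body["weight"].to_numpy(float), index=body["site_id"]),
            training_means=pd.Series(
                body["training_mean"].to_numpy(float), index=body["site_id"]
            ),
            alpha=alpha,
            lambda_selected=float("nan"),
            n_train=0,
            n_features_prefilter=len(body),
        )


def prefilter_sites(methylation: pd.DataFrame, allowed: list[str]) -> pd.DataFrame:
    """Restrict columns to the intersection with an allowed-site list."""
    if not len(allowed):
        raise ValueError("allowed site list is empty")
    shared = methylation.columns.intersection(pd.Index(allowed))
    if shared.empty:
        raise ValueError("no overlap between matrix sites and allowed list")
    logger.info("prefilter: %d of %d sites retained", len(shared), methylation.shape[1])
    return methylation[shared]


def _lambda_path(x_std: np.ndarray, y_c: np.ndarray, alpha: float,
                 n_lambda: int, decades: float) -> np.ndarray:
    n = len(y_c)
    lam_max = np.abs(x_std.T @ y_c).max() / (n * max(alpha, 1e-3))
    return np.geomspace(lam_max, lam_max * 10.0 ** (-decades), n_lambda)


def train_elastic_net(
    methylation: pd.DataFrame,
    y: np.ndarray | pd.Series,
    alpha: float = 0.5,
    n_folds: int = 10,
    seed: int = 0,
    n_lambda: int = 100,
    path_decades: float = 4.0,
    standardize: bool = True,
    lambda_override: float | None = None,
) -> BiomarkerModel:
    """Fit the cross-validated elastic net and package the model.

    Folds come from a seeded permutation, so the selected lambda and the
    weights are reproducible for a given seed.  ``lambda_override`` skips
    CV and fits at the given penalty (used by limit-case tests).
    """
    y = np.asarray(y, dtype=float)
    n, p = methylation.shape
    if n < n_folds:
        raise ValueError("need at least as many samples as folds")
    if np.ptp(y) == 0:
        raise ValueError("constant response: nothing to fit")
    x_raw = methylation.to_numpy(dtype=float)
    if not np.isfinite(x_raw).all():
        raise ValueError("non-finite methylation values")

    x_mean = x_raw.mean(axis=0)
    x_sd = x_raw.std(axis=0) if standardize else np.ones(p)
    x_sd = np.where(x_sd == 0, 1.0, x_sd)
    x_std = (x_raw - x_mean) / x_sd
    y_mean = y.mean()
    y_c = y - y_mean

    if lambda_override is not None:
        lam = float(lambda_override)
        path = np.array([lam])
        cv_mse = None
    else:
        path = _lambda_path(x_std, y_c, alpha, n_lambda, path_decades)
        rng = rng_for(seed, "elastic_net_folds")
        fold = rng.permutation(n) % n_folds
        mse = np.zeros((n_folds, len(path)))
        for f in range(n_folds):
            tr = fold != f
            va = ~tr
            xt = x_std[tr]
            xt_mean = xt.mean(axis=0)
            yt_mean = y_c[tr].mean()
            # fold fits only rank lambdas; moderate tolerance is enough
            _, coefs, _ = enet_path(
                xt - xt_mean, y_c[tr] - yt_mean,
                l1_ratio=alpha, alphas=path, tol=1e-4, max_iter=2000,
            )
            pred = (x_std[va] - xt_mean) @ coefs + yt_mean
            mse[f] = ((pred - y_c[va, None]) ** 2).mean(axis=0)
        cv_mse = mse.mean(axis=0)
        # minimum CV error; prefer the sparser (larger) lambda on exact ties
        lam = float(path[np.argmin(cv_mse)])

    model = ElasticNet(
        alpha=max(lam, 1e-12), l1_ratio=alpha, fit_intercept=False,
        tol=1e-10, max_iter=100_000,
    )
    model.fit(x_std, y_c)
    w_std = model.coef_

    w_raw = w_std / x_sd
    nz = np.flatnonzero(w_raw != 0.0)
    weights = pd.Series(w_raw[nz], index=methylation.columns[nz])
    intercept = float(y_mean - (x_mean[nz] * w_raw[nz]).sum())
    logger.info("elastic net: lambda=%.6g, %d non-zero of %d sites", lam, len(nz), p)
    return BiomarkerModel(
        intercept=intercept,
        weights=weights,
        training_means=pd.Series(x_mean[nz], index=methylation.columns[nz]),
        alpha=alpha,
        lambda_selected=lam,
        n_train=n,
        n_features_prefilter=p,
        cv_lambda_path=path,
        cv_mse=cv_mse,
    )


def score(
    model: BiomarkerModel,
    methylation: pd.DataFrame,
    missing_policy: str = "train_mean",
    strict: bool = False,
) -> pd.Series:
    """Project the score onto a cohort; absent sites take their training mean."""
    if missing_policy != "train_mean":
        raise ValueError("only the train_mean missing policy is implemented")
    present = model.weights.index.intersection(methylation.columns)
    absent = model.weights.index.difference(methylation.columns)
    if len(model.weights):
        frac_absent = len(absent) / len(model.weights)
        if frac_absent > 0.5:
            msg = (f"{len(absent)}/{len(model.weights)} weighted sites absent "
                   f"from the cohort")
            if strict:
                raise ValueError(msg)
            logger.warning(msg)
        elif len(absent):
            logger.info("imputing %d absent weighted sites with training means",
                        len(absent))
    values = methylation[present].to_numpy(dtype=float)
    # per-sample NaNs also fall back to the training mean
    means = model.training_means[present].to_numpy()
    values = np.where(np.isnan(values), means, values)
    total = model.intercept + values @ model.weights[present].to_numpy()
    if len(absent):
        total = total + (model.weights[absent] * model.training_means[absent]).sum()
    return pd.Series(total, index=methylation.index, name="score")


def train_single_site(
    m: np.ndarray | pd.Series, y: np.ndarray | pd.Series, site_id: str = "cg05575921"
) -> BiomarkerModel:
    """Least-squares slope/intercept for a one-CpG score, in model form."""
    m = np.asarray(m, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.ptp(m) == 0:
        raise ValueError("site does not vary")
    fit = stats.linregress(m, y)
    return BiomarkerModel(
        intercept=float(fit.intercept),
        weights=pd.Series({site_id: float(fit.slope)}),
        training_means=pd.Series({site_id: float(m.mean())}),
        alpha=0.0,
        lambda_selected=0.0,
        n_train=len(m),
        n_features_prefilter=1,
    )
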