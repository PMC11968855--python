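"""Bayesian penalized linear-regression EWAS.

Per-CpG effects carry a five-component prior: a discrete spike at the
origin plus four Gaussian slabs whose variances are fixed fractions
(0.001, 0.01, 0.1, 1.0 by default) of a common, sampled effect-size scale.
A single-chain Gibbs sampler sweeps the CpGs, sampling each component
indicator from its 5-way categorical full conditional (effect marginalized
analytically per component, log-space with max subtraction), then the
effect given the indicator, then the mixture proportions (Dirichlet) and
the two variances (scaled inverse chi-square).  The residual vector is
updated incrementally.

Inputs must be column-standardized; posterior inclusion probabilities,
posterior mean effects and per-sample variance-explained draws are
returned in a :class:`PosteriorSummary`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

__all__ = [
    "MixturePrior",
    "ChainConfig",
    "PosteriorSummary",
    "run_gibbs",
    "variance_explained",
    "call_significant",
]


@dataclass
class MixturePrior:
    """Spike + Gaussian-slab mixture prior and variance hyperpriors.

    ``slab_variance_fractions`` multiply the sampled common scale sigma2_beta.
    ``dirichlet_concentration`` has 5 entries ordered (spike, slab1..slab4).
    Set an ``update_*`` flag False to hold the corresponding parameter at its
    ``init`` value (used by the conjugate/ridge oracles).
    """

    slab_variance_fractions: tuple[float, ...] = (0.001, 0.01, 0.1, 1.0)
    dirichlet_concentration: tuple[float, ...] = (1.0, 1.0, 1.0, 1.0, 1.0)
    nu_beta: float = 4.0
    s2_beta: float = 0.01
    nu_e: float = 4.0
    s2_e: float = 1.0
    pi_init: tuple[float, ...] | None = None
    sigma2_beta_init: float | None = None
    sigma2_e_init: float | None = None
    update_pi: bool = True
    update_sigma2_beta: bool = True
    update_sigma2_e: bool = True

    def __post_init__(self) -> None:
        fracs = np.asarray(self.slab_variance_fractions, dtype=float)
        if (fracs <= 0).any() or (np.diff(fracs) <= 0).any():
            raise ValueError("slab variance fractions must be positive, strictly increasing")
        conc = np.asarray(self.dirichlet_concentration, dtype=float)
        if len(conc) != len(fracs) + 1 or (conc <= 0).any():
            raise ValueError("dirichlet_concentration needs K+1 positive entries")
        if self.pi_init is not None:
            pi = np.asarray(self.pi_init, dtype=float)
            if len(pi) != len(fracs) + 1 or (pi < 0).any() or not np.isclose(pi.sum(), 1.0):
                raise ValueError("pi_init must be a length-K+1 probability vector")


@dataclass
class ChainConfig:
    """Gibbs chain settings; retained draws = floor(post_burn / thin)."""

    burn_in: int = 5000
    post_burn_iterations: int = 10000
    thin: int = 5
    seed: int = 0
    random_scan: bool = False

    def __post_init__(self) -> None:
        if self.burn_in < 0 or self.post_burn_iterations < 1 or self.thin < 1:
            raise ValueError("invalid chain configuration")

    @property
    def n_retained(self) -> int:
        return self.post_burn_iterations // self.thin


@dataclass
class PosteriorSummary:
    pip: np.ndarray  # per-CpG inclusion probability
    post_mean: np.ndarray  # per-CpG posterior mean effect
    component_prob: np.ndarray  # per-CpG mean component occupancy (p, K+1)
    v_samples: np.ndarray  # variance-explained draws
    sigma2_beta_samples: np.ndarray
    sigma2_e_samples: np.ndarray
    pi_samples: np.ndarray  # (retained, K+1)
    n_retained: int
    cpg_ids: list[str] = field(default_factory=list)
    # final-state diagnostics for residual-conservation checks
    final_beta: np.ndarray | None = None
    final_residual: np.ndarray | None = None


@njit(cache=True)
def _gibbs_kernel(X, y, cvar, conc, nu_b, s2b0, nu_e, s2e0,
                  burn_in, post_iters, thin, seed,
                  update_pi, update_s2b, update_s2e,
                  pi_init, s2b_init, s2e_init, random_scan):
    n, p = X.shape
    K = cvar.shape[0]
    np.random.seed(seed)

    beta = np.zeros(p)
    comp = np.zeros(p, dtype=np.int64)
    r = y.copy()
    pi = pi_init.copy()
    s2b = s2b_init
    s2e = s2e_init

    xx = np.empty(p)
    for j in range(p):
        col = X[:, j]
        xx[j] = np.dot(col, col)

    mean_y = 0.0
    for i in range(n):
        mean_y += y[i]
    mean_y /= n
    var_y = 0.0
    for i in range(n):
        var_y += (y[i] - mean_y) ** 2
    var_y /= n

    n_ret = post_iters // thin
    pip_count = np.zeros(p)
    beta_sum = np.zeros(p)
    comp_count = np.zeros((p, K + 1))
    v_samples = np.empty(n_ret)
    s2b_samples = np.empty(n_ret)
    s2e_samples = np.empty(n_ret)
    pi_samples = np.empty((n_ret, K + 1))

    order = np.arange(p)
    logw = np.empty(K + 1)
    w = np.empty(K + 1)
    ridx = 0
    total = burn_in + post_iters

    for it in range(total):
        if random_scan:
            for jj in range(p - 1, 0, -1):
                swap = np.random.randint(0, jj + 1)
                tmp = order[jj]
                order[jj] = order[swap]
                order[swap] = tmp
        for jj in range(p):
            j = order[jj]
            bj = beta[j]
            col = X[:, j]
            rhs = np.dot(col, r) + xx[j] * bj
            if pi[0] > 0.0:
                logw[0] = np.log(pi[0])
            else:
                logw[0] = -np.inf
            for k in range(1, K + 1):
                if pi[k] > 0.0:
                    v = cvar[k - 1] * s2b
                    d = xx[j] + s2e / v
                    logw[k] = (np.log(pi[k])
                               - 0.5 * np.log(v * xx[j] / s2e + 1.0)
                               + rhs * rhs / (2.0 * s2e * d))
                else:
                    logw[k] = -np.inf
            m = logw[0]
            for k in range(1, K + 1):
                if logw[k] > m:
                    m = logw[k]
            sw = 0.0
            for k in range(K + 1):
                w[k] = np.exp(logw[k] - m)
                sw += w[k]
            u = np.random.random() * sw
            pick = 0
            acc = 0.0
            for k in range(K + 1):
                acc += w[k]
                if u <= acc:
                    pick = k
                    break
            if pick == 0:
                newb = 0.0
            else:
                v = cvar[pick - 1] * s2b
                d = xx[j] + s2e / v
                mean_b = rhs / d
                sd_b = np.sqrt(s2e / d)
                newb = mean_b + sd_b * np.random.normal()
            comp[j] = pick
            diff = bj - newb
            if diff != 0.0:
                for i in range(n):
                    r[i] += col[i] * diff
            beta[j] = newb

        if update_pi:
            sw = 0.0
            for k in range(K + 1):
                cnt = 0.0
                for j in range(p):
                    if comp[j] == k:
                        cnt += 1.0
                w[k] = np.random.gamma(conc[k] + cnt, 1.0)
                sw += w[k]
            for k in range(K + 1):
                pi[k] = w[k] / sw

        if update_s2b:
            m_nz = 0.0
            ssq = 0.0
            for j in range(p):
                if comp[j] > 0:
                    m_nz += 1.0
                    ssq += beta[j] * beta[j] / cvar[comp[j] - 1]
            df = nu_b + m_nz
            chi = 2.0 * np.random.gamma(df / 2.0, 1.0)
            s2b = (nu_b * s2b0 + ssq) / chi
            if s2b < 1e-12:
                s2b = 1e-12

        if update_s2e:
            rss = 0.0
            for i in range(n):
                rss += r[i] * r[i]
            df = nu_e + n
            chi = 2.0 * np.random.gamma(df / 2.0, 1.0)
            s2e = (nu_e * s2e0 + rss) / chi
            if s2e < 1e-12:
                s2e = 1e-12

        if it >= burn_in:
            t = it - burn_in + 1
            if t % thin == 0 and ridx < n_ret:
                gm = 0.0
                for i in range(n):
                    gm += y[i] - r[i]
                gm /= n
                gv = 0.0
                for i in range(n):
                    gv += (y[i] - r[i] - gm) ** 2
                gv /= n
                v_samples[ridx] = gv / var_y if var_y > 0 else 0.0
                s2b_samples[ridx] = s2b
                s2e_samples[ridx] = s2e
                for k in range(K + 1):
                    pi_samples[ridx, k] = pi[k]
                for j in range(p):
                    beta_sum[j] += beta[j]
                    comp_count[j, comp[j]] += 1.0
                    if comp[j] > 0:
                        pip_count[j] += 1.0
                ridx += 1

    return (pip_count, beta_sum, comp_count, v_samples, s2b_samples,
            s2e_samples, pi_samples, ridx, beta, r)


def run_gibbs(
    X: np.ndarray,
    y: np.ndarray,
    prior: MixturePrior | None = None,
    chain: ChainConfig | None = None,
    cpg_ids: list[str] | None = None,
    standardization_tol: float = 1e-3,
) -> PosteriorSummary:
    """Run the Gibbs sampler on standardized inputs.

    ``X`` (n, p) and ``y`` (n,) must be column-standardized (population
    mean 0, variance 1 within ``standardization_tol``); this is a contract
    of the model, enforced here.
    """
    prior = prior or MixturePrior()
    chain = chain or ChainConfig()
    X = np.asfortranarray(np.asarray(X, dtype=np.float64))  # column sweeps
    y = np.asarray(y, dtype=np.float64)
    if X.ndim != 2 or y.ndim != 1 or X.shape[0] != y.shape[0]:
        raise ValueError("X must be (n, p) and y (n,) with matching n")
    if not np.isfinite(X).all() or not np.isfinite(y).all():
        raise ValueError("non-finite values in inputs")
    tol = standardization_tol
    if abs(y.mean()) > tol or abs(y.std() - 1.0) > tol:
        raise ValueError("y is not standardized (mean 0, variance 1)")
    col_mean = X.mean(axis=0)
    col_sd = X.std(axis=0)
    if np.abs(col_mean).max() > tol or np.abs(col_sd - 1.0).max() > tol:
        raise ValueError("columns of X are not standardized")

    K = len(prior.slab_variance_fractions)
    pi_init = (np.asarray(prior.pi_init, dtype=float)
               if prior.pi_init is not None
               else np.asarray(prior.dirichlet_concentration, dtype=float)
               / sum(prior.dirichlet_concentration))
    s2b_init = float(prior.sigma2_beta_init
                     if prior.sigma2_beta_init is not None else prior.s2_beta)
    s2e_init = float(prior.sigma2_e_init
                     if prior.sigma2_e_init is not None else prior.s2_e)

    out = _gibbs_kernel(
        X, y,
        np.asarray(prior.slab_variance_fractions, dtype=float),
        np.asarray(prior.dirichlet_concentration, dtype=float),
        float(prior.nu_beta), float(prior.s2_beta),
        float(prior.nu_e), float(prior.s2_e),
        int(chain.burn_in), int(chain.post_burn_iterations), int(chain.thin),
        int(chain.seed) & 0x7FFFFFFF,
        prior.update_pi, prior.update_sigma2_beta, prior.update_sigma2_e,
        pi_init, s2b_init, s2e_init, chain.random_scan,
    )
    (pip_count, beta_sum, comp_count, v_samples, s2b_samples,
     s2e_samples, pi_samples, n_ret, final_beta, final_resid) = out
    if n_ret != chain.n_retained:  # pragma: no cover - kernel invariant
        raise RuntimeError("retained-sample bookkeeping mismatch")
    if not (np.isfinite(v_samples).all() and np.isfinite(s2e_samples).all()):
        raise RuntimeError("non-finite draws in chain; check inputs and prior")
    return PosteriorSummary(
        pip=pip_count / n_ret,
        post_mean=beta_sum / n_ret,
        component_prob=comp_count / n_ret,
        v_samples=v_samples,
        sigma2_beta_samples=s2b_samples,
        sigma2_e_samples=s2e_samples,
        pi_samples=pi_samples,
        n_retained=int(n_ret),
        cpg_ids=list(cpg_ids) if cpg_ids is not None else
        [f"cpg{j + 1:06d}" for j in range(X.shape[1])],
        final_beta=final_beta,
        final_residual=final_resid,
    )


def variance_explained(summary: PosteriorSummary, level: float = 0.95):
    """Posterior mean and equal-tailed credible interval of var(Xb)/var(y)."""
    v = np.asarray(summary.v_samples, dtype=float)
    if v.size < 2:
        raise ValueError("need at least 2 retained samples")
    if not 0.0 < level < 1.0:
        raise ValueError("level must be in (0, 1)")
    a = (1.0 - level) / 2.0
    lower, upper = np.percentile(v, [100 * a, 100 * (1 - a)])
    return float(v.mean()), float(lower), float(upper)


def call_significant(
    pips: np.ndarray,
    cpg_ids: list[str] | None = None,
    thresholds: tuple[float, ...] = (0.80, 0.95),
) -> dict[float, list[str]]:
    """Tiered CpG lists at strict PIP thresholds (pip > t)."""
    pips = np.asarray(pips, dtype=float)
    if pips.size and ((pips < 0).any() or (pips > 1).any()):
        raise ValueError("PIPs must lie in [0, 1]")
    ids = (list(cpg_ids) if cpg_ids is not None
           else [f"cpg{j + 1:06d}" for j in range(pips.size)])
    return {
        float(t): [ids[j] for j in np.flatnonzero(pips > t)]
        for t in thresholds
    }
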