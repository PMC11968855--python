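"""Synthetic cohorts with the statistical structure the pipeline assumes.

The restricted-access cohort data are replaced by generators that emulate
their structure: sparse per-CpG effects from a spike + multi-scale Gaussian
mixture on methylation, a zero-inflated pack-years phenotype with
never/former/current categories, overdispersed sequencing read depths for
two platforms, and Hardy-Weinberg genotypes with a polygenic phenotype.

All generators are deterministic given their seed; each operation draws
from its own derived RNG stream (see :mod:`ewaspipe._rng`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._rng import rng_for
from .seqfilters import CoverageTable

__all__ = [
    "SimulationConfig",
    "TruthRecord",
    "simulate_methylation_cohort",
    "simulate_smoking_phenotype",
    "simulate_coverage",
    "simulate_genotypes",
]


def _popvar(x: np.ndarray) -> float:
    return float(np.var(x))  # population (1/n) variance throughout


@dataclass
class SimulationConfig:
    """Knobs for the methylation-cohort generator.

    ``slab_variances`` are the four mixture scale fractions of a common
    effect-size scale; ``slab_proportions`` + ``spike_fraction`` must sum
    to one.  ``n_causal`` pins the number of non-null CpGs exactly
    (otherwise component labels are drawn per CpG).
    """

    n_individuals: int = 500
    n_cpgs: int = 1000
    spike_fraction: float = 0.95
    slab_variances: tuple[float, float, float, float] = (0.001, 0.01, 0.1, 1.0)
    slab_proportions: tuple[float, float, float, float] = (0.025, 0.015, 0.007, 0.003)
    target_h2: float = 0.5
    covariate_effects: dict = field(
        default_factory=lambda: {"age": 0.1, "sex": 0.1, "batch": 0.05}
    )
    never_smoker_fraction: float = 0.5
    seed: int = 0
    n_causal: int | None = None
    ar1_rho: float = 0.0
    n_batches: int = 3
    # draw a fresh population under the same per-CpG ground truth (for
    # score-transfer experiments); None reuses the master seed
    population_seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_individuals < 1 or self.n_cpgs < 1:
            raise ValueError("n_individuals and n_cpgs must be >= 1")
        if not 0.0 <= self.target_h2 < 1.0:
            raise ValueError("target_h2 must be in [0, 1)")
        total = self.spike_fraction + sum(self.slab_proportions)
        if not np.isclose(total, 1.0, atol=1e-8):
            raise ValueError(
                f"spike_fraction + slab_proportions must sum to 1 (got {total})"
            )
        if min(self.slab_proportions) < 0 or not 0 <= self.spike_fraction <= 1:
            raise ValueError("mixture proportions must be non-negative")
        if any(v <= 0 for v in self.slab_variances):
            raise ValueError("slab variances must be positive")
        if self.n_causal is not None and self.n_causal > self.n_cpgs:
            raise ValueError("n_causal exceeds n_cpgs")
        if not -1.0 < self.ar1_rho < 1.0:
            raise ValueError("ar1_rho must be in (-1, 1)")


@dataclass
class TruthRecord:
    """Ground truth emitted next to a simulated dataset."""

    effects: np.ndarray  # per-feature true effect
    components: np.ndarray  # 0 = null, 1..4 = slab index
    realized_h2: float
    score: np.ndarray  # per-individual true signal part

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"effect": self.effects, "component": self.components})


def simulate_methylation_cohort(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, TruthRecord]:
    """Simulate a beta-value matrix, phenotype table and truth record.

    Baseline methylation is generated on the M-value (logit) scale and
    squashed through the logistic map so stored values lie in [0, 1].
    Effects act linearly on the column-standardized stored matrix, so the
    truth record's bookkeeping (``realized_h2`` = var(score)/var(trait))
    holds exactly for the emitted data.
    """
    cfg = config
    # site-level truth and individual-level draws use separate streams so a
    # second population can be generated under identical ground truth
    rng_site = rng_for(cfg.seed, "cohort")
    rng_ind = rng_for(
        cfg.population_seed if cfg.population_seed is not None else cfg.seed,
        "cohort_individuals",
    )
    n, p = cfg.n_individuals, cfg.n_cpgs

    mu = rng_site.uniform(-1.5, 1.5, size=p)

    age = rng_ind.uniform(25.0, 75.0, size=n)
    sex = rng_ind.choice(["F", "M"], size=n)
    batch = rng_ind.choice([f"b{i + 1}" for i in range(cfg.n_batches)], size=n)

    z = rng_ind.standard_normal((n, p))
    if cfg.ar1_rho != 0.0:
        rho = cfg.ar1_rho
        for j in range(1, p):
            z[:, j] = rho * z[:, j - 1] + np.sqrt(1.0 - rho * rho) * z[:, j]
    mvals = mu[None, :] + z
    beta_matrix = 1.0 / (1.0 + np.exp(-mvals))

    # column-standardized view used to define the true linear signal
    x = beta_matrix - beta_matrix.mean(axis=0)
    sd = x.std(axis=0)
    sd[sd == 0] = 1.0
    x /= sd

    components = np.zeros(p, dtype=np.int64)
    effects = np.zeros(p)
    if cfg.target_h2 > 0.0:
        props = np.asarray(cfg.slab_proportions, dtype=float)
        if cfg.n_causal is not None:
            causal = rng_site.choice(p, size=cfg.n_causal, replace=False)
            labels = rng_site.choice(4, size=cfg.n_causal, p=props / props.sum()) + 1
            components[causal] = labels
        else:
            probs = np.concatenate([[cfg.spike_fraction], props])
            components = rng_site.choice(5, size=p, p=probs / probs.sum())
        nz = components > 0
        if nz.any():
            scales = np.asarray(cfg.slab_variances)[components[nz] - 1]
            effects[nz] = rng_site.standard_normal(nz.sum()) * np.sqrt(scales)

    score = x @ effects
    sv = _popvar(score)
    if cfg.target_h2 > 0.0 and sv > 0.0:
        scale = np.sqrt(cfg.target_h2 / sv)
        effects *= scale
        score *= scale
    else:
        effects[:] = 0.0
        components[:] = 0
        score[:] = 0.0

    eff = cfg.covariate_effects
    age_std = (age - age.mean()) / (age.std() or 1.0)
    sex01 = (sex == "M").astype(float)
    sex_std = (sex01 - sex01.mean()) / (sex01.std() or 1.0)
    batch_codes = pd.Categorical(batch).codes.astype(float)
    batch_std = (batch_codes - batch_codes.mean()) / (batch_codes.std() or 1.0)
    cov_part = (
        eff.get("age", 0.0) * age_std
        + eff.get("sex", 0.0) * sex_std
        + eff.get("batch", 0.0) * batch_std
    )
    noise = rng_ind.standard_normal(n) * np.sqrt(max(1.0 - cfg.target_h2, 0.0))
    trait = cov_part + score + noise

    realized = _popvar(score) / _popvar(trait) if _popvar(trait) > 0 else 0.0

    sample_ids = [f"S{i + 1:05d}" for i in range(n)]
    cpg_ids = [f"cpg{j + 1:06d}" for j in range(p)]
    methylation = pd.DataFrame(beta_matrix, index=pd.Index(sample_ids, name="sample_id"),
                               columns=cpg_ids)
    phenotypes = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "trait": trait,
            "age": age,
            "sex": sex,
            "batch": batch,
        }
    )
    truth = TruthRecord(
        effects=effects, components=components, realized_h2=float(realized), score=score
    )
    return methylation, phenotypes, truth


def simulate_smoking_phenotype(
    n: int,
    never_fraction: float,
    seed: int,
    corruption_rate: float = 0.0,
    former_fraction_of_smokers: float = 0.5,
) -> pd.DataFrame:
    """Simulate a smoking questionnaire table with derived pack years.

    Categories are assigned first (never => zero pack years and no
    start/stop ages); current/former smokers get consistent start/stop ages
    and a right-skewed cigarettes-per-day distribution, so pack years are
    zero-inflated and approximately log-normal among ever smokers.  With
    ``corruption_rate`` > 0 a random subset of records is made internally
    inconsistent (for exercising record QC).
    """
    if not 0.0 <= never_fraction <= 1.0:
        raise ValueError("never_fraction must be in [0, 1]")
    if not 0.0 <= corruption_rate <= 1.0:
        raise ValueError("corruption_rate must be in [0, 1]")
    rng = rng_for(seed, "smoking_phenotype")

    u = rng.random(n)
    status = np.where(
        u < never_fraction,
        "never",
        np.where(
            u < never_fraction + (1 - never_fraction) * former_fraction_of_smokers,
            "former",
            "current",
        ),
    )
    current_age = rng.uniform(30.0, 75.0, size=n)
    sex = rng.choice(["F", "M"], size=n)
    batch = rng.choice(["b1", "b2", "b3"], size=n)

    cigs = np.zeros(n)
    started = np.full(n, np.nan)
    stopped = np.full(n, np.nan)
    ever = status != "never"
    n_ever = int(ever.sum())
    if n_ever:
        cigs[ever] = np.round(np.exp(rng.normal(2.6, 0.5, size=n_ever)) / 2.0) * 2.0
        cigs[ever] = np.clip(cigs[ever], 1.0, 80.0)
        started[ever] = np.round(
            np.clip(rng.uniform(14.0, 25.0, size=n_ever), 14.0, current_age[ever] - 1.0)
        )
    former = status == "former"
    if former.any():
        span = current_age[former] - started[former]
        stopped[former] = np.round(started[former] + rng.uniform(1.0, 1.0 + span))
        stopped[former] = np.minimum(stopped[former], np.floor(current_age[former]))
        stopped[former] = np.maximum(stopped[former], started[former] + 1.0)

    years = np.zeros(n)
    years[former] = stopped[former] - started[former]
    current = status == "current"
    years[current] = current_age[current] - started[current]
    pack_years = years * cigs / 20.0

    table = pd.DataFrame(
        {
            "sample_id": [f"S{i + 1:05d}" for i in range(n)],
            "smoking_status": status,
            "cigs_per_day": cigs,
            "age_started": started,
            "age_stopped": stopped,
            "current_age": current_age,
            "sex": sex,
            "batch": batch,
            "pack_years": pack_years,
        }
    )

    if corruption_rate > 0.0:
        corrupt = rng.random(n) < corruption_rate
        for i in np.flatnonzero(corrupt):
            st = table.at[i, "smoking_status"]
            if st == "never":
                table.at[i, "cigs_per_day"] = 10.0  # never smoker reporting use
            elif st == "former":
                table.at[i, "age_stopped"] = table.at[i, "age_started"] - 2.0
            else:
                table.at[i, "age_stopped"] = table.at[i, "current_age"] - 1.0
        table.attrs["n_corrupted"] = int(corrupt.sum())
    else:
        table.attrs["n_corrupted"] = 0
    return table


def simulate_coverage(
    n_samples: int,
    n_sites: int,
    platform: str,
    mean_depth: float,
    seed: int,
    dispersion: float = 2.0,
    n_effect_sites: int = 0,
    effect_shift: float = 0.3,
    n_cases: int | None = None,
) -> tuple[CoverageTable, TruthRecord]:
    """Simulate per-site, per-sample read counts for a sequencing platform.

    Total reads are negative binomial with mean ``mean_depth`` times a
    per-site log-normal depth factor (``dispersion`` is the NB shape k;
    var = mu + mu^2/k).  Methylated reads are binomial given a per-site true
    fraction; the first ``n_cases`` samples are cases, with the true
    fraction shifted by ``effect_shift`` at ``n_effect_sites`` designated
    sites.
    """
    if platform not in {"short_read_panel", "long_read"}:
        raise ValueError("platform must be short_read_panel or long_read")
    if mean_depth <= 0:
        raise ValueError("mean_depth must be positive")
    rng = rng_for(seed, "coverage")
    if n_cases is None:
        n_cases = n_samples // 2

    starts = 1000 + 2 * np.sort(rng.choice(1_000_000, size=n_sites, replace=False))
    sites = pd.DataFrame({"chrom": "chr1", "start": starts, "end": starts + 2})

    base_frac = rng.beta(0.4, 0.4, size=n_sites)
    effect_sites = rng.choice(n_sites, size=n_effect_sites, replace=False) if n_effect_sites else np.array([], dtype=int)
    shift_sign = rng.choice([-1.0, 1.0], size=n_effect_sites)
    frac = np.tile(base_frac[:, None], (1, n_samples))
    for k, j in enumerate(effect_sites):
        shifted = np.clip(base_frac[j] + shift_sign[k] * effect_shift, 0.01, 0.99)
        frac[j, :n_cases] = shifted

    depth_factor = np.exp(rng.normal(0.0, 0.3, size=n_sites))
    mu = mean_depth * depth_factor[:, None] * np.ones((1, n_samples))
    k = dispersion
    p_nb = k / (k + mu)
    total = rng.negative_binomial(k, p_nb)
    meth = rng.binomial(total, frac)

    samples = [f"case{i + 1:03d}" for i in range(n_cases)] + [
        f"ctrl{i + 1:03d}" for i in range(n_samples - n_cases)
    ]
    table = CoverageTable(sites=sites, samples=samples, meth=meth, total=total)

    effects = np.zeros(n_sites)
    components = np.zeros(n_sites, dtype=np.int64)
    if n_effect_sites:
        effects[effect_sites] = shift_sign * effect_shift
        components[effect_sites] = 1
    group = np.array([1.0] * n_cases + [0.0] * (n_samples - n_cases))
    truth = TruthRecord(effects=effects, components=components, realized_h2=0.0, score=group)
    return table, truth


def simulate_genotypes(
    n_individuals: int,
    n_snps: int,
    maf_range: tuple[float, float],
    h2_snp: float,
    n_causal: int,
    seed: int,
) -> tuple[pd.DataFrame, pd.DataFrame, TruthRecord]:
    """Simulate Hardy-Weinberg dosages and a polygenic phenotype."""
    lo, hi = maf_range
    if not (0.0 < lo <= hi <= 0.5):
        raise ValueError("maf_range must satisfy 0 < lo <= hi <= 0.5")
    if not 0.0 <= h2_snp < 1.0:
        raise ValueError("h2_snp must be in [0, 1)")
    if n_causal > n_snps:
        raise ValueError("n_causal exceeds n_snps")
    rng = rng_for(seed, "genotypes")

    freq = rng.uniform(lo, hi, size=n_snps)
    dosages = rng.binomial(2, freq, size=(n_individuals, n_snps)).astype(np.int8)

    x = dosages.astype(float)
    x -= x.mean(axis=0)
    sd = x.std(axis=0)
    sd[sd == 0] = 1.0
    x /= sd

    effects = np.zeros(n_snps)
    components = np.zeros(n_snps, dtype=np.int64)
    score = np.zeros(n_individuals)
    if h2_snp > 0.0 and n_causal > 0:
        causal = rng.choice(n_snps, size=n_causal, replace=False)
        effects[causal] = rng.standard_normal(n_causal)
        components[causal] = 1
        score = x @ effects
        sv = _popvar(score)
        if sv > 0:
            scale = np.sqrt(h2_snp / sv)
            effects *= scale
            score *= scale
        else:
            effects[:] = 0.0
            components[:] = 0
    noise = rng.standard_normal(n_individuals) * np.sqrt(1.0 - h2_snp)
    trait = score + noise

    sample_ids = [f"S{i + 1:05d}" for i in range(n_individuals)]
    snp_ids = [f"rs{j + 1:07d}" for j in range(n_snps)]
    geno = pd.DataFrame(dosages, index=pd.Index(sample_ids, name="sample_id"), columns=snp_ids)
    geno.attrs["chrom"] = ["chr1"] * n_snps
    geno.attrs["pos"] = list(range(10_000, 10_000 + 100 * n_snps, 100))
    pheno = pd.DataFrame({"sample_id": sample_ids, "trait": trait})
    truth = TruthRecord(
        effects=effects,
        components=components,
        realized_h2=float(_popvar(score) / _popvar(trait)) if _popvar(trait) > 0 else 0.0,
        score=score,
    )
    return geno, pheno, truth
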