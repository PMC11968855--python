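import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from ewaspipe import synthetic


def standardize(a: np.ndarray) -> np.ndarray:
    a = np.asarray(a, dtype=float)
    return (a - a.mean(axis=0)) / a.std(axis=0)


@pytest.fixture(scope="session")
def small_cohort():
    cfg = synthetic.SimulationConfig(
        n_individuals=300, n_cpgs=400, target_h2=0.4, seed=11, n_causal=12,
        covariate_effects={},
    )
    return synthetic.simulate_methylation_cohort(cfg)


@pytest.fixture()
def questionnaire():
    return synthetic.simulate_smoking_phenotype(n=500, never_fraction=0.5, seed=7)


@pytest.fixture()
def clean_questionnaire(questionnaire):
    from ewaspipe import phenotype as phen

    mask, _ = phen.flag_inconsistent_records(questionnaire)
    return questionnaire[~mask].reset_index(drop=True)


def make_coverage(total: np.ndarray, meth: np.ndarray | None = None,
                  chrom: str = "chr1") -> "synthetic.CoverageTable":
    from ewaspipe.seqfilters import CoverageTable

    total = np.asarray(total, dtype=np.int64)
    if meth is None:
        meth = total // 2
    n_sites, n_samples = total.shape
    starts = np.arange(100, 100 + 10 * n_sites, 10)
    sites = pd.DataFrame({"chrom": chrom, "start": starts, "end": starts + 2})
    samples = [f"s{i + 1:03d}" for i in range(n_samples)]
    return CoverageTable(sites=sites, samples=samples, meth=np.asarray(meth, np.int64),
                         total=total)
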