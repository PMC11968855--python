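"""Smoking phenotype construction and methylation pre-processing.

Pack years are years of smoking times cigarettes per day over twenty, with
never smokers fixed at zero.  Records whose questionnaire fields contradict
each other are flagged and excluded rather than repaired.  The analysis
phenotype is ln(pack years + 1), residualized on age and sex, and scaled to
mean 0 / variance 1 (population variance).  Methylation columns are
residualized on age, sex and batch and standardized the same way.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "compute_pack_years",
    "flag_inconsistent_records",
    "transform_phenotype",
    "residualize_methylation",
    "encode_smoking_ordinal",
]

_STATUSES = ("never", "former", "current")

FLAG_NEVER_REPORTS_SMOKING = "never_reports_smoking"
FLAG_STOP_BEFORE_START = "stop_not_after_start"
FLAG_START_AFTER_CURRENT = "start_after_current_age"
FLAG_CURRENT_WITH_STOP = "current_with_stop_age"
FLAG_INCOMPLETE = "incomplete_record"


def compute_pack_years(table: pd.DataFrame) -> pd.Series:
    """Derive pack years per record: years smoked x cigs/day / 20.

    Years smoked are ``age_stopped - age_started`` for former smokers and
    ``current_age - age_started`` for current smokers; never smokers get 0.
    Records with negative smoking duration or missing required fields yield
    NaN here and are caught by :func:`flag_inconsistent_records`.
    """
    status = table["smoking_status"]
    bad = ~status.isin(_STATUSES)
    if bad.any():
        raise ValueError(f"unknown smoking status values: {sorted(status[bad].unique())}")
    years = pd.Series(np.nan, index=table.index)
    former = status == "former"
    current = status == "current"
    years[former] = table.loc[former, "age_stopped"] - table.loc[former, "age_started"]
    years[current] = table.loc[current, "current_age"] - table.loc[current, "age_started"]
    years[years < 0] = np.nan  # routed to record flagging, never clipped
    pack_years = years * table["cigs_per_day"] / 20.0
    pack_years[status == "never"] = 0.0
    return pack_years


def flag_inconsistent_records(table: pd.DataFrame) -> tuple[pd.Series, pd.Series]:
    """Cross-reference status against the other questionnaire fields.

    Returns a boolean exclusion mask and a comma-joined reason string per
    record.  Flags: never smokers reporting cigarettes or start/stop ages;
    stop age not after start age; start age above current age; current
    smokers with a stop age; smokers with missing required fields.
    """
    status = table["smoking_status"]
    cigs = table["cigs_per_day"]
    started = table["age_started"]
    stopped = table["age_stopped"]
    current_age = table["current_age"]

    reasons: dict[str, pd.Series] = {}
    never = status == "never"
    reasons[FLAG_NEVER_REPORTS_SMOKING] = never & (
        (cigs.fillna(0) > 0) | started.notna() | stopped.notna()
    )
    both = started.notna() & stopped.notna()
    reasons[FLAG_STOP_BEFORE_START] = both & (stopped <= started)
    reasons[FLAG_START_AFTER_CURRENT] = started.notna() & (started > current_age)
    reasons[FLAG_CURRENT_WITH_STOP] = (status == "current") & stopped.notna()
    ever = status.isin(("former", "current"))
    reasons[FLAG_INCOMPLETE] = ever & (
        cigs.isna() | started.isna() | ((status == "former") & stopped.isna())
    )

    mask = pd.Series(False, index=table.index)
    labels = pd.Series("", index=table.index)
    for name, hit in reasons.items():
        mask |= hit
        labels[hit] = labels[hit].where(labels[hit] == "", labels[hit] + ",") + name
    n = int(mask.sum())
    if n:
        logger.info("flagged %d/%d inconsistent records", n, len(table))
    return mask, labels


def _standardize(values: np.ndarray) -> np.ndarray:
    sd = values.std()  # population variance by construction
    if sd == 0:
        raise ValueError("constant phenotype after transform: nothing to analyze")
    return (values - values.mean()) / sd


def _design(age: np.ndarray, sex: np.ndarray) -> np.ndarray:
    sex01 = _sex_indicator(sex)
    return np.column_stack([np.ones(len(age)), np.asarray(age, dtype=float), sex01])


def _sex_indicator(sex) -> np.ndarray:
    s = pd.Series(sex).astype(str)
    mapping = {"F": 0.0, "M": 1.0, "0": 0.0, "1": 1.0}
    bad = ~s.isin(mapping)
    if bad.any():
        raise ValueError(f"unrecognized sex labels: {sorted(s[bad].unique())}")
    return s.map(mapping).to_numpy()


def transform_phenotype(
    pack_years: np.ndarray | pd.Series,
    age: np.ndarray | pd.Series,
    sex: np.ndarray | pd.Series,
) -> np.ndarray:
    """ln(pack years + 1), residualized on age and sex, standardized."""
    y = np.log1p(np.asarray(pack_years, dtype=float))
    if len(y) < 3:
        raise ValueError("need at least 3 samples")
    if not np.isfinite(y).all():
        raise ValueError("non-finite pack years")
    d = _design(np.asarray(age, dtype=float), sex)
    # drop constant covariate columns (keep intercept) so the fit is full rank
    keep = [0] + [j for j in (1, 2) if np.ptp(d[:, j]) > 0]
    d = d[:, keep]
    coef, *_ = np.linalg.lstsq(d, y, rcond=None)
    resid = y - d @ coef
    return _standardize(resid)


def residualize_methylation(
    methylation: pd.DataFrame,
    age: np.ndarray | pd.Series,
    sex: np.ndarray | pd.Series,
    batch: np.ndarray | pd.Series | None = None,
) -> pd.DataFrame:
    """Residualize each CpG column on age, sex (+ batch dummies); standardize.

    Batch enters as full dummy coding against the first category in sorted
    order.  Columns with zero residual variance are dropped with a logged
    warning.  Raises if the covariate design is rank deficient.
    """
    n = len(methylation)
    cols = [np.ones(n), np.asarray(age, dtype=float), _sex_indicator(sex)]
    if batch is not None:
        cats = sorted(pd.Series(batch).astype(str).unique())
        for level in cats[1:]:
            cols.append((pd.Series(batch).astype(str) == level).to_numpy(float))
    design = np.column_stack(cols)
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError("covariate design is rank deficient")
    values = methylation.to_numpy(dtype=float)
    coef, *_ = np.linalg.lstsq(design, values, rcond=None)
    resid = values - design @ coef
    sd = resid.std(axis=0)
    keep = sd > 1e-12
    if not keep.all():
        dropped = list(methylation.columns[~keep])
        logger.warning("dropping %d zero-residual-variance CpGs: %s",
                       len(dropped), dropped[:10])
    resid = resid[:, keep]
    resid = (resid - resid.mean(axis=0)) / resid.std(axis=0)
    return pd.DataFrame(resid, index=methylation.index, columns=methylation.columns[keep])


def encode_smoking_ordinal(status) -> np.ndarray:
    """never -> 0, former -> 1, current -> 2."""
    s = pd.Series(status).astype(str)
    mapping = {"never": 0, "former": 1, "current": 2}
    bad = ~s.isin(mapping)
    if bad.any():
        raise ValueError(f"unknown smoking status: {sorted(s[bad].unique())}")
    return s.map(mapping).to_numpy(dtype=np.int64)
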