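"""Heavy-smoker case selection and age/sex-matched never-smoker controls.

Cases are the top pack-years current smokers within each sex.  Controls are
matched greedily within sex by nearest age, processing cases with the
fewest eligible controls first, each control used at most once, with a
hard age window (default < 365 days).  ``validate_pairs`` re-checks the
published contract on any pairing, whatever produced it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = ["MatchResult", "select_cases", "match_controls", "validate_pairs"]

DAYS_PER_YEAR = 365.25


@dataclass
class MatchResult:
    pairs: pd.DataFrame  # case_id, control_id, age_difference_days, sex
    unmatched: list[str]


def select_cases(phenotypes: pd.DataFrame, n_per_sex: int) -> list[str]:
    """Top ``n_per_sex`` current smokers by pack years within each sex.

    Ties break lexicographically on sample id.  Raises if either sex has a
    shortfall, naming the sex and the gap.
    """
    current = phenotypes[phenotypes["smoking_status"] == "current"]
    chosen: list[str] = []
    for sex_label, grp in current.groupby("sex"):
        ranked = grp.sort_values(
            ["pack_years", "sample_id"], ascending=[False, True], kind="mergesort"
        )
        if len(ranked) < n_per_sex:
            raise ValueError(
                f"insufficient current smokers of sex {sex_label!r}: "
                f"need {n_per_sex}, have {len(ranked)}"
            )
        chosen.extend(ranked["sample_id"].head(n_per_sex))
    if not chosen:
        raise ValueError("no current smokers available")
    return sorted(chosen)


def match_controls(
    cases: pd.DataFrame,
    pool: pd.DataFrame,
    max_age_diff_days: float = 365.0,
) -> MatchResult:
    """Greedy scarcity-first nearest-age matching within sex.

    ``cases`` and ``pool`` need sample_id, sex and age (years).  Cases with
    no in-window control are reported unmatched, never raised.
    """
    if pool.empty:
        raise ValueError("control pool is empty")
    window_years = max_age_diff_days / DAYS_PER_YEAR

    pool_by_sex = {
        s: grp.sort_values("sample_id").reset_index(drop=True)
        for s, grp in pool.groupby("sex")
    }
    used: set[str] = set()

    def eligible(case_row) -> pd.DataFrame:
        grp = pool_by_sex.get(case_row.sex)
        if grp is None:
            return pd.DataFrame(columns=pool.columns)
        diff = (grp["age"] - case_row.age).abs()
        ok = (diff < window_years) & ~grp["sample_id"].isin(used)
        return grp[ok]

    case_rows = list(cases.sort_values("sample_id").itertuples(index=False))
    # scarcity-first: fewest eligible controls matched first, id tie-break
    scored = sorted(case_rows, key=lambda c: (len(eligible(c)), c.sample_id))

    pairs = []
    unmatched: list[str] = []
    for case in scored:
        cand = eligible(case)
        if cand.empty:
            unmatched.append(case.sample_id)
            continue
        diff = (cand["age"] - case.age).abs()
        best = cand.loc[
            diff.sort_values(kind="mergesort").index
        ].iloc[0]  # nearest age; stable sort breaks ties on sample id order
        used.add(best["sample_id"])
        pairs.append(
            (
                case.sample_id,
                best["sample_id"],
                abs(best["age"] - case.age) * DAYS_PER_YEAR,
                case.sex,
            )
        )
    pairs_df = pd.DataFrame(
        pairs, columns=["case_id", "control_id", "age_difference_days", "sex"]
    ).sort_values("case_id").reset_index(drop=True)
    if unmatched:
        logger.info("%d cases unmatched within the age window", len(unmatched))
    return MatchResult(pairs=pairs_df, unmatched=sorted(unmatched))


def validate_pairs(
    pairs: pd.DataFrame,
    phenotypes: pd.DataFrame,
    max_age_diff_days: float = 365.0,
) -> tuple[bool, pd.DataFrame, pd.DataFrame]:
    """Re-check every pair against the matching contract.

    Returns (all_ok, violations, surviving_pairs).  Violating pairs (age
    gap >= threshold or sex mismatch) are excluded from the survivors and
    logged.  Unknown sample ids raise.
    """
    info = phenotypes.set_index("sample_id")
    missing = [
        sid
        for sid in pd.concat([pairs["case_id"], pairs["control_id"]])
        if sid not in info.index
    ]
    if missing:
        raise KeyError(f"unknown sample ids in pairs: {sorted(set(missing))}")

    rows = []
    for tup in pairs.itertuples(index=False):
        case = info.loc[tup.case_id]
        ctrl = info.loc[tup.control_id]
        gap_days = abs(float(case["age"]) - float(ctrl["age"])) * DAYS_PER_YEAR
        reasons = []
        if gap_days >= max_age_diff_days:
            reasons.append("age_gap")
        if case["sex"] != ctrl["sex"]:
            reasons.append("sex_mismatch")
        rows.append((tup.case_id, tup.control_id, gap_days, ",".join(reasons)))
    checked = pd.DataFrame(
        rows, columns=["case_id", "control_id", "age_gap_days", "violation"]
    )
    violations = checked[checked["violation"] != ""].reset_index(drop=True)
    ok = violations.empty
    survivors = pairs[~pairs["case_id"].isin(violations["case_id"])].reset_index(drop=True)
    if not ok:
        logger.warning("excluding %d pairs violating the matching contract", len(violations))
    return ok, violations, survivors
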