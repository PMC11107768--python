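"""Eligibility rules and Dx / No-Dx stratification.

A child is eligible for a condition in a period if it has at least 365
cumulative enrolled days intersecting the period, at least one encounter
(any visit type, including virtual) in the period, and an age that falls in
the condition's [min_age, max_age] window at some point during the period.
Eligible children are partitioned into the Dx stratum (at least one
encounter in the period carrying a qualifying code) and the No-Dx stratum.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .codesets import CodeSet, match_codes
from .cohort import CohortTable, age_years
from .config import ICD10_TRANSITION, Period

OVERALL = "overall"


@dataclass(frozen=True)
class StratumCount:
    """One row of the population/sample bookkeeping table: a condition ×
    stratum cell with its population size and (optionally) chart-review
    sample and confirmed-case counts."""

    condition: str
    stratum: str  # "Dx" or "No-Dx"
    period: str = OVERALL
    N: int = 0
    n_sampled: int = 0
    n_confirmed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.n_confirmed <= self.n_sampled <= max(self.N, self.n_sampled)):
            raise ValueError(
                f"{self.condition}/{self.stratum}/{self.period}: need "
                f"n_confirmed <= n_sampled and nonnegative counts"
            )
        if self.N < 0:
            raise ValueError("N must be nonnegative")


def strata_frame(strata: "list[StratumCount] | pd.DataFrame") -> pd.DataFrame:
    """Normalize a list of StratumCount (or an equivalent frame) to a frame."""
    if isinstance(strata, pd.DataFrame):
        df = strata.copy()
        if "period" not in df:
            df["period"] = OVERALL
        for col in ("n_sampled", "n_confirmed"):
            if col not in df:
                df[col] = 0
        return df
    return pd.DataFrame([vars(s) for s in strata])


def _enrolled_days(enrollment: pd.DataFrame, period: Period) -> pd.Series:
    """Cumulative enrolled days per child intersecting the period."""
    start = pd.Timestamp(period.start)
    end = pd.Timestamp(period.end)
    lo = enrollment["start"].clip(lower=start)
    hi = enrollment["end"].clip(upper=end)
    days = (hi - lo).dt.days + 1
    days = days.clip(lower=0)
    return days.groupby(enrollment["child_id"]).sum()


def eligible_children(
    cohort: CohortTable,
    codeset: CodeSet,
    period: Period,
    min_enrolled_days: int = 365,
) -> set[int]:
    """Child ids meeting the enrollment, visit, and age rules for *codeset*
    in *period*."""
    days = _enrolled_days(cohort.enrollment, period)
    enrolled = set(days.index[days >= min_enrolled_days])

    enc = cohort.encounters
    in_period = (enc["date"] >= pd.Timestamp(period.start)) & (
        enc["date"] <= pd.Timestamp(period.end)
    )
    visited = set(enc.loc[in_period, "child_id"])

    ch = cohort.children
    if len(ch) == 0:
        return set()
    age_end = age_years(np.full(len(ch), pd.Timestamp(period.end)), ch["birth_date"])
    age_start = age_years(np.full(len(ch), pd.Timestamp(period.start)), ch["birth_date"])
    # age range during the period is [age_start, age_end]; it intersects the
    # window iff it reaches min_age by period end and started at most max_age
    in_age = (age_end >= codeset.min_age_years) & (age_start <= codeset.max_age_years)
    aged = set(ch.loc[in_age, "child_id"])

    return enrolled & visited & aged


def _coded_children(cohort: CohortTable, codeset: CodeSet, period: Period) -> set[int]:
    enc = cohort.encounters
    coded = enc[enc["code"].notna() & (enc["code"] != "")]
    if len(coded) == 0:
        return set()
    in_period = (coded["date"] >= pd.Timestamp(period.start)) & (
        coded["date"] <= pd.Timestamp(period.end)
    )
    coded = coded[in_period]
    systems = pd.Series(
        np.where(coded["date"] < pd.Timestamp(ICD10_TRANSITION), "icd9", "icd10"),
        index=coded.index,
    )
    hit = match_codes(coded["code"], codeset, systems)
    return set(coded.loc[hit, "child_id"])


def stratum_membership(
    cohort: CohortTable,
    codesets: dict[str, CodeSet],
    periods: list[Period],
    min_enrolled_days: int = 365,
) -> pd.DataFrame:
    """Per-period stratum membership: one row per (condition, period,
    stratum, child_id), with Dx meaning at least one qualifying coded
    encounter while eligible in that period."""
    rows = []
    for cond, cs in codesets.items():
        for period in periods:
            elig = eligible_children(cohort, cs, period, min_enrolled_days)
            if not elig:
                continue
            dx = _coded_children(cohort, cs, period) & elig
            nodx = elig - dx
            for stratum, ids in (("Dx", dx), ("No-Dx", nodx)):
                if ids:
                    rows.append(
                        pd.DataFrame(
                            {
                                "condition": cond,
                                "period": period.label,
                                "stratum": stratum,
                                "child_id": sorted(ids),
                            }
                        )
                    )
    if not rows:
        return pd.DataFrame(columns=["condition", "period", "stratum", "child_id"])
    return pd.concat(rows, ignore_index=True)


def stratify(
    cohort: CohortTable,
    codesets: dict[str, CodeSet],
    periods: list[Period],
    min_enrolled_days: int = 365,
) -> list[StratumCount]:
    """Population stratum counts per condition × period, plus 'overall'
    rows in which each child counts once (Dx overall if Dx in any period)."""
    member = stratum_membership(cohort, codesets, periods, min_enrolled_days)
    counts: list[StratumCount] = []
    for cond in codesets:
        sub = member[member["condition"] == cond]
        for period in periods:
            per = sub[sub["period"] == period.label]
            for stratum in ("Dx", "No-Dx"):
                n = int((per["stratum"] == stratum).sum())
                counts.append(StratumCount(cond, stratum, period.label, N=n))
        dx_overall = set(sub.loc[sub["stratum"] == "Dx", "child_id"])
        elig_overall = set(sub["child_id"])
        counts.append(StratumCount(cond, "Dx", OVERALL, N=len(dx_overall)))
        counts.append(StratumCount(cond, "No-Dx", OVERALL, N=len(elig_overall - dx_overall)))
    return counts
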