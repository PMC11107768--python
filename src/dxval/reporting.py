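"""Cohort-characteristics reporting and Markdown table rendering."""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .cohort import CohortTable, age_years

logger = logging.getLogger(__name__)

AGE_BANDS = ["2-5", "6-11", "12-17"]
CHARACTERISTICS = ["age_band", "sex", "race_ethnicity", "income_band", "insurance"]


def _age_band(ages: np.ndarray) -> pd.Categorical:
    return pd.cut(
        ages, bins=[2, 6, 12, 18], right=False, labels=AGE_BANDS, include_lowest=True
    )


def characteristics_table(
    cohort: CohortTable,
    sample: pd.DataFrame | None = None,
    reference: pd.DataFrame | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Frequency table of cohort characteristics, split into chart-reviewed
    vs non-reviewed children plus the full cohort, with an optional
    externally supplied reference distribution column.

    Ages are evaluated at one uniformly chosen clinical visit per child
    (seeded); children without encounters, or outside the 2-17 bands at
    that visit, are excluded from the age block with a logged count.

    ``reference`` is passed through untouched: a frame with columns
    (characteristic, category, percent).
    """
    ch = cohort.children.copy()
    rng = np.random.default_rng(seed)

    enc = cohort.encounters
    n_enc = enc.groupby("child_id")["date"].count()
    no_visit = set(ch["child_id"]) - set(n_enc.index)
    if no_visit:
        logger.info("characteristics_table: %d children with no encounters excluded "
                    "from the age block", len(no_visit))
    picks = enc.sort_values(["child_id", "date"]).groupby("child_id").sample(
        n=1, random_state=rng.integers(2**31)
    )
    ch = ch.merge(
        picks[["child_id", "date"]].rename(columns={"date": "index_visit"}),
        on="child_id", how="left",
    )
    has_visit = ch["index_visit"].notna()
    ages = np.full(len(ch), np.nan)
    if has_visit.any():
        ages[has_visit.to_numpy()] = age_years(
            ch.loc[has_visit, "index_visit"], ch.loc[has_visit, "birth_date"]
        )
    ch["age_band"] = _age_band(ages)
    out_of_band = int(has_visit.sum() - ch["age_band"].notna().sum())
    if out_of_band:
        logger.info("characteristics_table: %d children outside the 2-17 age bands "
                    "at the index visit excluded from the age block", out_of_band)

    if sample is not None and len(sample):
        reviewed_ids = set(sample.loc[sample.get("active", True), "child_id"])
    else:
        reviewed_ids = set()
    ch["reviewed"] = ch["child_id"].isin(reviewed_ids)

    blocks = []
    for char in CHARACTERISTICS:
        col = ch[char]
        categories = (
            list(col.cat.categories) if isinstance(col.dtype, pd.CategoricalDtype)
            else sorted(col.dropna().unique())
        )
        for cat in categories:
            in_cat = col == cat
            row = {"characteristic": char, "category": cat}
            for label, mask in (
                ("reviewed", ch["reviewed"]),
                ("not_reviewed", ~ch["reviewed"]),
                ("total", pd.Series(True, index=ch.index)),
            ):
                denom = int((col.notna() & mask).sum())
                n = int((in_cat & mask).sum())
                row[f"{label}_n"] = n
                row[f"{label}_pct"] = 100.0 * n / denom if denom else float("nan")
            blocks.append(row)
    table = pd.DataFrame(blocks)

    if reference is not None:
        ref = reference.rename(columns={"percent": "reference_pct"})
        table = table.merge(
            ref[["characteristic", "category", "reference_pct"]],
            on=["characteristic", "category"], how="left",
        )
    return table


def to_markdown(df: pd.DataFrame, floatfmt: str = ".1f") -> str:
    """Minimal GitHub-style Markdown rendering of a frame."""
    def fmt(v) -> str:
        if isinstance(v, float):
            if np.isnan(v):
                return ""
            return format(v, floatfmt)
        return str(v)

    headers = [str(c) for c in df.columns]
    lines = ["| " + " | ".join(headers) + " |",
             "|" + "|".join("---" for _ in headers) + "|"]
    for _, row in df.iterrows():
        lines.append("| " + " | ".join(fmt(v) for v in row) + " |")
    return "\n".join(lines) + "\n"
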