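"""Stratified chart-review sampling, blocked-record replacement, the
dual-abstraction reliability subsample, normalized sampling weights, and
the design-margin calculator.

The verification design samples a fixed number of children per condition ×
period × stratum cell (default 40, i.e. 120 per stratum over three periods)
and estimates population-level accuracy with normalized per-record weights

    W_ij = N_ij / (n_ij * N_i),

where N_ij is the population size of stratum j of condition i, n_ij the
number sampled there, and N_i the condition's total study population.  The
sampled weights then sum to one within each condition.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .strata import OVERALL, StratumCount, strata_frame

SAMPLE_COLUMNS = [
    "condition", "period", "stratum", "child_id", "replacement_generation", "active",
]


@dataclass(frozen=True)
class SamplingWeights:
    """Per condition × stratum normalized record weights."""

    table: pd.DataFrame  # columns: condition, stratum, W

    def get(self, condition: str, stratum: str) -> float:
        t = self.table
        row = t[(t["condition"] == condition) & (t["stratum"] == stratum)]
        if len(row) != 1:
            raise KeyError(f"no weight for ({condition!r}, {stratum!r})")
        return float(row["W"].iloc[0])

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def draw_sample(
    membership: pd.DataFrame, per_cell: int, seed: int
) -> pd.DataFrame:
    """Simple random sample without replacement of *per_cell* children per
    condition × period × stratum cell.

    No child is sampled twice for the same condition (across periods or
    strata); a cell too small to fill raises with the offending cell named.
    """
    if per_cell < 0:
        raise ValueError("per_cell must be nonnegative")
    rng = np.random.default_rng(seed)
    out = []
    if per_cell == 0 or len(membership) == 0:
        return pd.DataFrame(columns=SAMPLE_COLUMNS)
    cells = membership.sort_values(["condition", "period", "stratum", "child_id"])
    taken_by_condition: dict[str, set[int]] = {}
    for (cond, period, stratum), grp in cells.groupby(
        ["condition", "period", "stratum"], sort=True
    ):
        taken = taken_by_condition.setdefault(cond, set())
        pool = grp.loc[~grp["child_id"].isin(taken), "child_id"].to_numpy()
        if pool.size < per_cell:
            raise ValueError(
                f"stratum cell ({cond}, {period}, {stratum}) has only "
                f"{pool.size} available children, needs {per_cell}"
            )
        chosen = rng.choice(pool, size=per_cell, replace=False)
        taken.update(int(c) for c in chosen)
        out.append(
            pd.DataFrame(
                {
                    "condition": cond,
                    "period": period,
                    "stratum": stratum,
                    "child_id": np.sort(chosen),
                    "replacement_generation": 0,
                    "active": True,
                }
            )
        )
    return pd.concat(out, ignore_index=True)


def replace_blocked(
    sample: pd.DataFrame,
    review: pd.DataFrame,
    membership: pd.DataFrame,
    seed: int,
) -> pd.DataFrame:
    """Retire active blocked records and append same-cell replacement rows.

    One replacement generation: each active record whose review outcome is
    ``blocked`` is deactivated and a never-sampled child from the same
    condition × period × stratum is appended with its generation
    incremented.  Callers re-review the appended rows and repeat until no
    active record is blocked (see ``pipeline.review_with_replacement``).
    A cell with no children left raises, reporting the shortfall.
    """
    key = ["condition", "period", "stratum", "child_id"]
    merged = sample.merge(
        review[key + ["outcome"]], on=key, how="left", validate="1:1"
    )
    blocked = merged["active"] & (merged["outcome"] == "blocked")
    if not blocked.any():
        return sample.copy()

    rng = np.random.default_rng(seed)
    out = sample.copy()
    out.loc[blocked.to_numpy(), "active"] = False
    new_rows = []
    for (cond, period, stratum), grp in merged[blocked].groupby(
        ["condition", "period", "stratum"], sort=True
    ):
        need = len(grp)
        ever = set(
            out.loc[out["condition"] == cond, "child_id"]
        )  # never reuse a child within a condition, active or not
        cell = membership[
            (membership["condition"] == cond)
            & (membership["period"] == period)
            & (membership["stratum"] == stratum)
        ]
        pool = cell.loc[~cell["child_id"].isin(ever), "child_id"].to_numpy()
        if pool.size < need:
            raise ValueError(
                f"stratum cell ({cond}, {period}, {stratum}) exhausted: "
                f"{need} replacements needed, {pool.size} children left"
            )
        chosen = rng.choice(np.sort(pool), size=need, replace=False)
        new_rows.append(
            pd.DataFrame(
                {
                    "condition": cond,
                    "period": period,
                    "stratum": stratum,
                    "child_id": np.sort(chosen),
                    "replacement_generation": grp["replacement_generation"].to_numpy() + 1,
                    "active": True,
                }
            )
        )
    return pd.concat([out] + new_rows, ignore_index=True)


def select_reliability_subsample(
    sample: pd.DataFrame,
    total: int = 180,
    per_abstractor: int = 90,
    per_condition: int = 36,
    seed: int = 0,
) -> pd.DataFrame:
    """Draw the dual-abstraction subsample: *total* records balanced across
    conditions (*per_condition* each), balanced Dx/No-Dx within condition,
    and split evenly between two reabstracting abstractors."""
    if total == 0:
        return pd.DataFrame(columns=SAMPLE_COLUMNS + ["second_abstractor"])
    active = sample[sample["active"]]
    conditions = sorted(active["condition"].unique())
    if per_condition * len(conditions) != total:
        raise ValueError(
            f"inconsistent design: {per_condition} per condition x "
            f"{len(conditions)} conditions != total {total}"
        )
    if 2 * per_abstractor != total:
        raise ValueError(
            f"inconsistent design: 2 abstractors x {per_abstractor} != total {total}"
        )
    if per_condition % 2:
        raise ValueError("per_condition must be even to balance Dx/No-Dx")
    per_cell = per_condition // 2
    rng = np.random.default_rng(seed)
    picks = []
    for cond in conditions:
        for stratum in ("Dx", "No-Dx"):
            cell = active[
                (active["condition"] == cond) & (active["stratum"] == stratum)
            ].sort_values(["period", "child_id"])
            if len(cell) < per_cell:
                raise ValueError(
                    f"({cond}, {stratum}): {len(cell)} active records, "
                    f"need {per_cell} for the reliability subsample"
                )
            idx = rng.choice(len(cell), size=per_cell, replace=False)
            picks.append(cell.iloc[np.sort(idx)])
    subset = pd.concat(picks, ignore_index=True)
    abstractor = np.tile([1, 2], total // 2 + 1)[:total]
    subset["second_abstractor"] = rng.permutation(abstractor)
    return subset


def compute_weights(
    strata: "list[StratumCount] | pd.DataFrame", period: str = OVERALL
) -> SamplingWeights:
    """Normalized sampling weights W_ij = N_ij / (n_ij * N_i) for the given
    period's rows (default the overall rows).

    Within each condition the sampled records' weights sum to exactly 1:
    sum_j n_ij * W_ij = sum_j N_ij / N_i = 1.
    """
    df = strata_frame(strata)
    df = df[df["period"] == period]
    rows = []
    for cond, grp in df.groupby("condition", sort=True):
        strata_present = set(grp["stratum"])
        if strata_present != {"Dx", "No-Dx"}:
            raise ValueError(
                f"{cond}: need exactly the Dx and No-Dx strata, got {sorted(strata_present)}"
            )
        n_total = int(grp["N"].sum())
        if n_total <= 0:
            raise ValueError(f"{cond}: empty study population")
        for _, row in grp.iterrows():
            if row["n_sampled"] <= 0:
                raise ValueError(
                    f"{cond}/{row['stratum']}: n_sampled must be positive to form weights"
                )
            rows.append(
                {
                    "condition": cond,
                    "stratum": row["stratum"],
                    "W": float(row["N"]) / (float(row["n_sampled"]) * n_total),
                }
            )
    return SamplingWeights(pd.DataFrame(rows))


def attach_sample_counts(
    strata: "list[StratumCount] | pd.DataFrame",
    sample: pd.DataFrame,
    review: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Fill n_sampled (active records) and n_confirmed (adjudicated yes)
    into a stratum-count frame, per period and overall."""
    df = strata_frame(strata).copy()
    active = sample[sample["active"]].copy()
    if review is not None:
        key = ["condition", "period", "stratum", "child_id"]
        active = active.merge(review[key + ["adjudicated"]], on=key, how="left")
    for i, row in df.iterrows():
        if row["period"] == OVERALL:
            sel = (active["condition"] == row["condition"]) & (
                active["stratum"] == row["stratum"]
            )
        else:
            sel = (
                (active["condition"] == row["condition"])
                & (active["stratum"] == row["stratum"])
                & (active["period"] == row["period"])
            )
        df.loc[i, "n_sampled"] = int(sel.sum())
        if review is not None:
            df.loc[i, "n_confirmed"] = int((active.loc[sel, "adjudicated"] == "yes").sum())
    return df


def one_sided_margin(p: float, n: int, confidence: float = 0.90) -> float:
    """One-sided normal-approximation margin z_c * sqrt(p(1-p)/n) for a
    proportion estimated from n records."""
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p must be in [0, 1], got {p}")
    if n < 1:
        raise ValueError("n must be at least 1")
    if not 0.0 < confidence < 1.0:
        raise ValueError("confidence must be in (0, 1)")
    z = stats.norm.ppf(confidence)
    return float(z * np.sqrt(p * (1.0 - p) / n))
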