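"""Synthetic EHR cohort and chart-review generator.

The generator emulates a pediatric validation-study population with known
ground truth so the whole sampling/weighting/metrics pipeline can run and be
checked with no access to real records.

Generative model
----------------
* Stratum membership comes first: each condition's Dx stratum is hit at
  exactly the requested size, and the latent true case status is then drawn
  conditional on stratum (``ppv_true`` for Dx children,
  ``one_minus_npv_true`` for No-Dx children).
* Eligibility differences between conditions are realized through age:
  condition eligibility is nested by the code set's minimum age, so a
  config may request smaller totals for higher-minimum-age conditions
  (e.g. ADHD at 5 years) and the generator assigns birth dates that place
  the surplus children below that condition's age window.
* Each child belongs to exactly one study period: enrollment and all
  encounters fall inside it, so per-period strata partition the overall
  strata, matching designs that report period columns summing to the
  overall stratum.
* Chart review: "blocked notes" and "insufficient notes" are per-child
  chart properties drawn at the configured rates; otherwise an abstractor
  reads the true status and flips it independently with
  ``abstractor_error_rate``.  A designated reliability subsample receives a
  second, independent reading; disagreements are adjudicated to the truth
  (expert adjudication), single readings stand as abstracted.
"""

from __future__ import annotations

import datetime as dt

import numpy as np
import pandas as pd

from .codesets import REPRESENTATIVE_CODES, CodeSet, default_code_sets
from .cohort import (
    CHILD_COLUMNS,
    ENCOUNTER_COLUMNS,
    ENROLLMENT_COLUMNS,
    TRUTH_COLUMNS,
    CohortTable,
)
from .config import ICD10_TRANSITION, SimulationConfig

DEFAULT_DEMOGRAPHICS: dict[str, dict[str, float]] = {
    "sex": {"female": 0.489, "male": 0.511},
    "race_ethnicity": {
        "nh_white": 0.245,
        "nh_black": 0.079,
        "hispanic": 0.516,
        "asian_pi": 0.100,
        "other_unknown": 0.060,
    },
    "income_band": {
        "<30k": 0.026,
        "30k-49k": 0.211,
        "50k-69k": 0.267,
        "70k-89k": 0.211,
        ">=90k": 0.284,
        "missing": 0.001,
    },
    "insurance": {
        "medicaid": 0.234,
        "commercial": 0.719,
        "private": 0.041,
        "other": 0.006,
    },
}

VISIT_TYPES = ("office", "virtual", "ED", "hospital")
VISIT_TYPE_P = (0.66, 0.20, 0.10, 0.04)

REVIEW_COLUMNS = [
    "condition", "period", "stratum", "child_id", "replacement_generation",
    "outcome", "outcome_2", "second_abstractor", "adjudicated",
]

# RNG stream tags; child-level chart properties must be stable across
# repeated review calls (replacement redraws see the same chart).
_STREAM_BLOCKED = 1001
_STREAM_INSUFFICIENT = 1002
_STREAM_ABSTRACTION = 1003


def _years_before(d: dt.date, years: int) -> dt.date:
    try:
        return d.replace(year=d.year - years)
    except ValueError:  # Feb 29
        return d.replace(year=d.year - years, day=28)


def _allocate(n: int, shares: list[float]) -> list[int]:
    """Largest-remainder integer allocation of n across shares."""
    raw = [n * s for s in shares]
    base = [int(x) for x in raw]
    short = n - sum(base)
    order = sorted(range(len(shares)), key=lambda i: raw[i] - base[i], reverse=True)
    for i in order[:short]:
        base[i] += 1
    return base


def _day(d: dt.date) -> np.int64:
    return np.int64(pd.Timestamp(d).value // 86_400_000_000_000)


def _to_dates(days: np.ndarray) -> pd.Series:
    return pd.Series(pd.to_datetime(days * 86_400_000_000_000))


def _nested_levels(
    config: SimulationConfig, codesets: dict[str, CodeSet]
) -> tuple[list[int], list[int], dict[str, int]]:
    """Min-age levels (ascending), eligible-pool totals per level (must be
    non-increasing), and each condition's level index."""
    min_age = {
        c: (codesets[c].min_age_years if c in codesets else 2) for c in config.conditions
    }
    levels = sorted(set(min_age.values()))
    totals: list[int] = []
    for a in levels:
        conds = [c for c in config.conditions if min_age[c] == a]
        tots = {config.conditions[c].n_total for c in conds}
        if len(tots) > 1:
            raise ValueError(
                f"conditions with min_age {a} must share one eligible total, got "
                + ", ".join(f"{c}={config.conditions[c].n_total}" for c in conds)
            )
        totals.append(tots.pop())
    for (a1, t1), (a2, t2) in zip(zip(levels, totals), zip(levels[1:], totals[1:])):
        if t2 > t1:
            raise ValueError(
                f"eligible total for min_age {a2} ({t2}) exceeds total for "
                f"min_age {a1} ({t1}); eligibility is nested by age"
            )
    cond_level = {c: levels.index(min_age[c]) for c in config.conditions}
    return levels, totals, cond_level


def _representative_code(condition: str, system: str, codesets: dict[str, CodeSet]) -> str:
    code = REPRESENTATIVE_CODES.get((condition, system))
    if code is not None:
        return code
    pats = codesets[condition].patterns(system) if condition in codesets else ()
    if not pats:
        raise ValueError(f"no {system} code pattern available for condition {condition!r}")
    return pats[0]


def simulate_population(
    config: SimulationConfig, codesets: dict[str, CodeSet] | None = None
) -> CohortTable:
    """Generate a cohort whose per-condition Dx / No-Dx strata have exactly
    the configured sizes.

    Deterministic for a fixed config (including seed).  Overall stratum
    sizes are exact; the split across periods follows ``config.shares``
    by largest-remainder allocation, so period Dx counts are exact as well.
    """
    codesets = codesets if codesets is not None else default_code_sets()
    levels, totals, cond_level = _nested_levels(config, codesets)
    n = totals[0]
    rng = np.random.default_rng(config.seed)

    if n == 0:
        empty = CohortTable(
            children=pd.DataFrame(columns=CHILD_COLUMNS),
            enrollment=pd.DataFrame(columns=ENROLLMENT_COLUMNS),
            encounters=pd.DataFrame(columns=ENCOUNTER_COLUMNS),
            truth=pd.DataFrame(columns=TRUTH_COLUMNS),
        )
        return empty

    periods = config.periods
    shares = config.shares
    n_levels = len(levels)

    # Children [0, totals[k]) form the eligible pool of level k: ids are
    # ordered oldest band first so every pool is a prefix.
    band = np.empty(n, dtype=np.int64)  # index into levels
    bounds = totals + [0]
    for k in range(n_levels):
        band[bounds[k + 1]: bounds[k]] = k

    # Period assignment: exact largest-remainder split within each band.
    period_idx = np.empty(n, dtype=np.int64)
    for k in range(n_levels):
        lo, hi = bounds[k + 1], bounds[k]
        counts = _allocate(hi - lo, shares)
        pos = lo
        for p_i, cnt in enumerate(counts):
            period_idx[pos: pos + cnt] = p_i
            pos += cnt

    # Birth dates: band k children are, at their period's end, at least
    # levels[k] but younger than levels[k+1] (top band: at most 17).
    birth_days = np.empty(n, dtype=np.int64)
    for k in range(n_levels):
        upper = levels[k + 1] if k + 1 < n_levels else 18
        for p_i, period in enumerate(periods):
            mask = (band == k) & (period_idx == p_i)
            m = int(mask.sum())
            if m == 0:
                continue
            lo_day = _day(_years_before(period.end, upper)) + 1
            hi_day = _day(_years_before(period.end, levels[k]))
            birth_days[mask] = rng.integers(lo_day, hi_day + 1, size=m)

    # Demographics.
    child_id = np.arange(n, dtype=np.int64)
    demo_cols = {}
    for field, dist in DEFAULT_DEMOGRAPHICS.items():
        labels = list(dist)
        p = np.asarray(list(dist.values()), dtype=float)
        demo_cols[field] = rng.choice(labels, size=n, p=p / p.sum())

    period_labels = np.asarray([p.label for p in periods])
    children = pd.DataFrame(
        {
            "child_id": child_id,
            "birth_date": _to_dates(birth_days).values,
            "sex": demo_cols["sex"],
            "race_ethnicity": demo_cols["race_ethnicity"],
            "income_band": demo_cols["income_band"],
            "insurance": demo_cols["insurance"],
            "period": period_labels[period_idx],
        }
    )

    # Enrollment: the full assigned period (satisfies the 1-year rule).
    start_days = np.asarray([_day(p.start) for p in periods])[period_idx]
    end_days = np.asarray([_day(p.end) for p in periods])[period_idx]
    enrollment = pd.DataFrame(
        {
            "child_id": child_id,
            "start": _to_dates(start_days).values,
            "end": _to_dates(end_days).values,
        }
    )

    # Visit-date window: within the assigned period, not before the second
    # birthday (charts of infants carry no study-relevant visits here).
    second_bday = birth_days + 731
    visit_lo = np.maximum(start_days, np.where(second_bday <= end_days, second_bday, birth_days))
    visit_hi = end_days

    n_enc = 1 + rng.poisson(0.8, size=n)
    rows = np.repeat(np.arange(n), n_enc)
    u = rng.random(rows.size)
    enc_days = visit_lo[rows] + np.floor(u * (visit_hi[rows] - visit_lo[rows] + 1)).astype(np.int64)
    enc_frames = [
        pd.DataFrame(
            {
                "child_id": child_id[rows],
                "date": _to_dates(enc_days).values,
                "visit_type": rng.choice(VISIT_TYPES, size=rows.size, p=VISIT_TYPE_P),
                "code": pd.array([pd.NA] * rows.size, dtype="string"),
            }
        )
    ]

    # Dx assignment and latent truth, condition by condition.
    truth_frames = []
    transition_day = _day(ICD10_TRANSITION)
    for cond, spec in config.conditions.items():
        k = cond_level[cond]
        pool_size = totals[k]
        dx_mask = np.zeros(pool_size, dtype=bool)
        n_dx_per_period = _allocate(spec.n_dx, shares)
        for p_i, n_dx_p in enumerate(n_dx_per_period):
            pool_p = np.flatnonzero(period_idx[:pool_size] == p_i)
            if n_dx_p > pool_p.size:
                raise ValueError(
                    f"{cond}: requested {n_dx_p} Dx children in period "
                    f"{periods[p_i].label!r} but the eligible pool there has {pool_p.size}"
                )
            chosen = rng.choice(pool_p, size=n_dx_p, replace=False)
            dx_mask[chosen] = True
        dx_ids = np.flatnonzero(dx_mask)

        if dx_ids.size:
            code_days = visit_lo[dx_ids] + np.floor(
                rng.random(dx_ids.size) * (visit_hi[dx_ids] - visit_lo[dx_ids] + 1)
            ).astype(np.int64)
            systems = np.where(code_days < transition_day, "icd9", "icd10")
            codes = np.array(
                [
                    _representative_code(cond, "icd9", codesets),
                    _representative_code(cond, "icd10", codesets),
                ]
            )[(systems == "icd10").astype(int)]
            enc_frames.append(
                pd.DataFrame(
                    {
                        "child_id": child_id[dx_ids],
                        "date": _to_dates(code_days).values,
                        "visit_type": rng.choice(VISIT_TYPES, size=dx_ids.size, p=VISIT_TYPE_P),
                        "code": pd.array(codes, dtype="string"),
                    }
                )
            )

        true_status = np.empty(pool_size, dtype=bool)
        true_status[dx_mask] = rng.random(int(dx_mask.sum())) < spec.ppv_true
        true_status[~dx_mask] = rng.random(int((~dx_mask).sum())) < spec.one_minus_npv_true
        truth_frames.append(
            pd.DataFrame(
                {
                    "child_id": child_id[:pool_size],
                    "condition": cond,
                    "period": period_labels[period_idx[:pool_size]],
                    "stratum": np.where(dx_mask, "Dx", "No-Dx"),
                    "true_status": true_status,
                }
            )
        )

    encounters = pd.concat(enc_frames, ignore_index=True)
    encounters = encounters.sort_values(["child_id", "date"], kind="stable").reset_index(drop=True)
    truth = pd.concat(truth_frames, ignore_index=True)
    return CohortTable(children, enrollment, encounters, truth)


def _child_property(seed: int, stream: int, n: int) -> np.ndarray:
    return np.random.default_rng([seed, stream]).random(n)


def simulate_chart_review(
    cohort: CohortTable,
    sample: pd.DataFrame,
    config: SimulationConfig,
    reliability: pd.DataFrame | None = None,
    nonce: int = 0,
) -> pd.DataFrame:
    """Simulate abstraction outcomes for the sampled records.

    Each record receives one of four outcomes: ``yes`` / ``no`` (the latent
    truth flipped independently per abstractor with
    ``abstractor_error_rate``), ``blocked`` or ``insufficient`` (per-child
    chart properties at the configured rates).  Rows of *reliability* (a
    subset of the sample with a ``second_abstractor`` column) get a second
    independent reading; on disagreement the adjudicated call is the truth.

    ``nonce`` distinguishes abstraction randomness between successive calls
    (e.g. replacement generations) under one config seed.
    """
    required = {"condition", "period", "stratum", "child_id"}
    if not required.issubset(sample.columns):
        raise ValueError(f"sample must have columns {sorted(required)}")
    rows = sample.copy()
    if "replacement_generation" not in rows:
        rows["replacement_generation"] = 0

    truth = cohort.truth[["child_id", "condition", "true_status"]]
    merged = rows.merge(truth, on=["child_id", "condition"], how="left", validate="m:1")
    missing = merged.loc[merged["true_status"].isna(), "child_id"]
    if len(missing):
        raise KeyError(
            f"sampled child_ids missing from cohort truth table: {sorted(set(missing))[:10]}"
        )

    n_pool = int(cohort.children["child_id"].max()) + 1 if len(cohort.children) else 0
    blocked_u = _child_property(config.seed, _STREAM_BLOCKED, n_pool)
    insufficient_u = _child_property(config.seed, _STREAM_INSUFFICIENT, n_pool)
    cid = merged["child_id"].to_numpy()
    blocked = blocked_u[cid] < config.blocked_rate
    insufficient = (~blocked) & (insufficient_u[cid] < config.insufficient_rate)

    rngf = np.random.default_rng([config.seed, _STREAM_ABSTRACTION, nonce])
    m = len(merged)
    flip1 = rngf.random(m) < config.abstractor_error_rate
    flip2 = rngf.random(m) < config.abstractor_error_rate

    truth_arr = merged["true_status"].to_numpy(dtype=bool)
    read1 = np.where(truth_arr ^ flip1, "yes", "no")
    read2 = np.where(truth_arr ^ flip2, "yes", "no")

    outcome = np.where(blocked, "blocked", np.where(insufficient, "insufficient", read1))

    if reliability is not None and len(reliability):
        key = ["condition", "child_id"]
        rel = reliability[key + ["second_abstractor"]]
        merged = merged.merge(rel, on=key, how="left", validate="m:1")
        dual = merged["second_abstractor"].notna().to_numpy()
    else:
        merged["second_abstractor"] = pd.NA
        dual = np.zeros(m, dtype=bool)

    readable = ~(blocked | insufficient)
    outcome_2 = np.where(
        dual & readable, read2, np.where(dual & ~readable, outcome, "")
    )
    truth_read = np.where(truth_arr, "yes", "no")
    adjudicated = np.where(
        readable,
        np.where(dual & (read1 != read2), truth_read, read1),
        "",
    )

    out = merged[
        ["condition", "period", "stratum", "child_id", "replacement_generation"]
    ].copy()
    out["outcome"] = outcome
    out["outcome_2"] = pd.array(
        [v if v else pd.NA for v in outcome_2], dtype="string"
    )
    out["second_abstractor"] = merged["second_abstractor"]
    out["adjudicated"] = pd.array([v if v else pd.NA for v in adjudicated], dtype="string")
    return out.reset_index(drop=True)
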