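"""Weighted diagnostic-accuracy metrics and interrater agreement.

Under verification sampling stratified on the code (Dx / No-Dx), population
sensitivity and specificity require the normalized sampling weights, while
PPV and NPV are within-stratum proportions and hence weight-free:

    sensitivity = TP*W_dx / (TP*W_dx + FN*W_nodx)
    specificity = TN*W_nodx / (TN*W_nodx + FP*W_dx)
    PPV = TP / (TP + FP)          NPV = TN / (TN + FN)
    F = 2*sens*PPV / (sens + PPV) J = sens + spec - 1

TP/FP are tallied in the Dx stratum (gold standard yes/no) and FN/TN in the
No-Dx stratum.  All results are reported as percents rounded half-up to one
decimal; metrics with an empty denominator propagate as NaN (undefined),
never as 0 or 100.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from scipy import stats

from .sampling import SamplingWeights
from .strata import OVERALL

logger = logging.getLogger(__name__)

METRICS = ("sensitivity", "specificity", "ppv", "npv", "f_score", "youden_j")
CI_METHODS = ("stratified-bootstrap", "logit-normal")


def round_percent(proportion: float, digits: int = 1) -> float:
    """Half-up rounding of a proportion onto the percent scale."""
    if proportion is None or (isinstance(proportion, float) and math.isnan(proportion)):
        return float("nan")
    q = Decimal(10) ** -digits
    return float(Decimal(repr(proportion * 100.0)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ConfusionSummary:
    """Gold-standard confusion cells for one condition (and period scope)."""

    condition: str
    period: str = OVERALL
    tp: int = 0
    fp: int = 0
    tn: int = 0
    fn: int = 0

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be nonnegative")

    @property
    def n_dx(self) -> int:
        return self.tp + self.fp

    @property
    def n_nodx(self) -> int:
        return self.tn + self.fn


@dataclass(frozen=True)
class KappaResult:
    kappa: float
    observed_agreement: float
    expected_agreement: float
    n_pairs: int


@dataclass(frozen=True)
class WeightedPerformance:
    """One reporting row: the six statistics as percents (1 decimal), with
    optional CIs, plus the unrounded proportions in ``raw``."""

    condition: str
    period: str
    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    f_score: float
    youden_j: float
    raw: dict = field(default_factory=dict)
    ci: dict = field(default_factory=dict)
    ci_method: str | None = None


def confusion_counts(
    review: pd.DataFrame,
    condition: str,
    period: str = OVERALL,
) -> ConfusionSummary:
    """Tally TP/FP/TN/FN for *condition* from adjudicated review records.

    Active Dx-stratum records with gold standard "yes" are TP and "no" FP;
    No-Dx records with "yes" are FN (missed cases) and "no" TN.  Records
    whose outcome is ``insufficient`` are excluded; any other active record
    without an adjudicated yes/no raises, listing the offenders.
    """
    rows = review[review["condition"] == condition]
    if "active" in rows.columns:
        rows = rows[rows["active"]]
    if period != OVERALL:
        rows = rows[rows["period"] == period]
    rows = rows[rows["outcome"] != "insufficient"]
    bad = rows[~rows["adjudicated"].isin(["yes", "no"])]
    if len(bad):
        ids = bad["child_id"].tolist()[:10]
        raise ValueError(
            f"{condition}: {len(bad)} active records lack an adjudicated "
            f"yes/no outcome (e.g. child_ids {ids}); replace or exclude them first"
        )
    dx = rows[rows["stratum"] == "Dx"]
    nodx = rows[rows["stratum"] == "No-Dx"]
    return ConfusionSummary(
        condition=condition,
        period=period,
        tp=int((dx["adjudicated"] == "yes").sum()),
        fp=int((dx["adjudicated"] == "no").sum()),
        tn=int((nodx["adjudicated"] == "no").sum()),
        fn=int((nodx["adjudicated"] == "yes").sum()),
    )


def _raw_metrics(conf: ConfusionSummary, w_dx: float, w_nodx: float) -> dict:
    tp, fp, tn, fn = conf.tp, conf.fp, conf.tn, conf.fn
    nan = float("nan")

    pos_mass = tp * w_dx + fn * w_nodx
    sens = tp * w_dx / pos_mass if pos_mass > 0 else nan
    neg_mass = tn * w_nodx + fp * w_dx
    spec = tn * w_nodx / neg_mass if neg_mass > 0 else nan
    ppv = tp / (tp + fp) if tp + fp > 0 else nan
    npv = tn / (tn + fn) if tn + fn > 0 else nan
    f = 2 * sens * ppv / (sens + ppv) if sens + ppv > 0 else nan
    j = sens + spec - 1.0
    return {
        "sensitivity": sens,
        "specificity": spec,
        "ppv": ppv,
        "npv": npv,
        "f_score": f,
        "youden_j": j,
    }


def weighted_performance(
    conf: ConfusionSummary,
    weights: SamplingWeights,
    ci_method: str | None = None,
    ci_level: float = 0.95,
    n_boot: int = 1000,
    seed: int = 0,
) -> WeightedPerformance:
    """All six statistics for one confusion summary, on the percent scale.

    With ``ci_method`` set, attaches per-metric confidence intervals (see
    :func:`confidence_interval`).
    """
    w_dx = weights.get(conf.condition, "Dx")
    w_nodx = weights.get(conf.condition, "No-Dx")
    raw = _raw_metrics(conf, w_dx, w_nodx)
    ci: dict = {}
    if ci_method is not None:
        for m in METRICS:
            ci[m] = confidence_interval(
                m, conf, weights, method=ci_method, level=ci_level,
                n_boot=n_boot, seed=seed,
            )
    return WeightedPerformance(
        condition=conf.condition,
        period=conf.period,
        sensitivity=round_percent(raw["sensitivity"]),
        specificity=round_percent(raw["specificity"]),
        ppv=round_percent(raw["ppv"]),
        npv=round_percent(raw["npv"]),
        f_score=round_percent(raw["f_score"]),
        youden_j=round_percent(raw["youden_j"]),
        raw=raw,
        ci=ci,
        ci_method=ci_method,
    )


def cohens_kappa(ratings_a, ratings_b) -> KappaResult:
    """Unweighted Cohen's kappa for two raters' binary (yes/no) readings.

    Pairs where either reading is not a binary yes/no (blocked or
    insufficient charts) are dropped with a logged count.
    """
    a = pd.Series(ratings_a).astype("string")
    b = pd.Series(ratings_b).astype("string").set_axis(a.index)
    usable = a.isin(["yes", "no"]) & b.isin(["yes", "no"])
    n_dropped = int((~usable).sum())
    if n_dropped:
        logger.info("cohens_kappa: dropped %d non-binary pairs", n_dropped)
    a, b = a[usable], b[usable]
    n = len(a)
    if n == 0:
        raise ValueError("no usable yes/no pairs for kappa")
    p_o = float((a == b).mean())
    p_yes_a = float((a == "yes").mean())
    p_yes_b = float((b == "yes").mean())
    p_e = p_yes_a * p_yes_b + (1 - p_yes_a) * (1 - p_yes_b)
    kappa = 1.0 if p_e == 1.0 else (p_o - p_e) / (1.0 - p_e)
    return KappaResult(kappa=kappa, observed_agreement=p_o, expected_agreement=p_e, n_pairs=n)


def _metric_from_counts(
    metric: str, tp, fp, tn, fn, w_dx: float, w_nodx: float
):
    """Vectorized raw metric over (arrays of) confusion counts."""
    tp, fp, tn, fn = (np.asarray(x, dtype=float) for x in (tp, fp, tn, fn))
    with np.errstate(invalid="ignore", divide="ignore"):
        sens = tp * w_dx / (tp * w_dx + fn * w_nodx)
        spec = tn * w_nodx / (tn * w_nodx + fp * w_dx)
        if metric == "sensitivity":
            return sens
        if metric == "specificity":
            return spec
        if metric == "ppv":
            return tp / (tp + fp)
        if metric == "npv":
            return tn / (tn + fn)
        if metric == "f_score":
            ppv = tp / (tp + fp)
            return 2 * sens * ppv / (sens + ppv)
        if metric == "youden_j":
            return sens + spec - 1.0
    raise ValueError(f"unknown metric {metric!r}; expected one of {METRICS}")


def confidence_interval(
    metric: str,
    conf: ConfusionSummary,
    weights: SamplingWeights,
    method: str = "stratified-bootstrap",
    level: float = 0.95,
    n_boot: int = 1000,
    seed: int = 0,
) -> tuple[float, float]:
    """CI for one metric, on the percent scale, clamped to [0, 100].

    ``stratified-bootstrap`` (default): resample records with replacement
    within each stratum — equivalently redraw the confirmed counts from
    binomials at the observed rates — recompute the weighted metric, and
    take percentile bounds.  Degenerate cells (no errors observed) produce
    an interval touching the boundary.

    ``logit-normal``: delta-method normal interval on the logit scale,
    back-transformed; available for the four proportion metrics only.
    """
    if metric not in METRICS:
        raise ValueError(f"unknown metric {metric!r}; expected one of {METRICS}")
    if not 0.0 < level < 1.0:
        raise ValueError("level must be in (0, 1)")
    w_dx = weights.get(conf.condition, "Dx")
    w_nodx = weights.get(conf.condition, "No-Dx")

    if method == "stratified-bootstrap":
        rng = np.random.default_rng(seed)
        n_dx, n_nodx = conf.n_dx, conf.n_nodx
        tp_b = rng.binomial(n_dx, conf.tp / n_dx, size=n_boot) if n_dx else np.zeros(n_boot)
        tn_b = rng.binomial(n_nodx, conf.tn / n_nodx, size=n_boot) if n_nodx else np.zeros(n_boot)
        vals = _metric_from_counts(
            metric, tp_b, n_dx - tp_b, tn_b, n_nodx - tn_b, w_dx, w_nodx
        )
        vals = vals[~np.isnan(vals)]
        if vals.size == 0:
            return (float("nan"), float("nan"))
        alpha = (1.0 - level) / 2.0
        lo, hi = np.percentile(vals, [100 * alpha, 100 * (1 - alpha)])
        return (
            float(np.clip(lo * 100.0, 0.0, 100.0)),
            float(np.clip(hi * 100.0, 0.0, 100.0)),
        )

    if method == "logit-normal":
        point = float(
            _metric_from_counts(metric, conf.tp, conf.fp, conf.tn, conf.fn, w_dx, w_nodx)
        )
        if metric in ("f_score", "youden_j"):
            raise ValueError(f"logit-normal interval not defined for {metric!r}")
        if math.isnan(point):
            return (float("nan"), float("nan"))
        if point in (0.0, 1.0):  # degenerate: no variability on the logit scale
            return (point * 100.0, point * 100.0)
        if metric == "ppv":
            var = 1.0 / conf.tp + 1.0 / conf.fp
        elif metric == "npv":
            var = 1.0 / conf.tn + 1.0 / conf.fn
        elif metric == "sensitivity":
            # two independent binomial "success" counts enter the odds
            var = (1.0 / conf.tp - 1.0 / conf.n_dx) + (1.0 / conf.fn - 1.0 / conf.n_nodx)
        else:  # specificity
            var = (1.0 / conf.tn - 1.0 / conf.n_nodx) + (1.0 / conf.fp - 1.0 / conf.n_dx)
        z = stats.norm.ppf(1.0 - (1.0 - level) / 2.0)
        logit = math.log(point / (1.0 - point))
        lo = 1.0 / (1.0 + math.exp(-(logit - z * math.sqrt(var))))
        hi = 1.0 / (1.0 + math.exp(-(logit + z * math.sqrt(var))))
        return (lo * 100.0, hi * 100.0)

    raise ValueError(f"unknown method {method!r}; expected one of {CI_METHODS}")


def performance_frame(results: list[WeightedPerformance]) -> pd.DataFrame:
    """Tidy frame of reporting rows (condition × period × six statistics)."""
    rows = []
    for r in results:
        row = {
            "condition": r.condition,
            "period": r.period,
            **{m: getattr(r, m) for m in METRICS},
        }
        for m, (lo, hi) in r.ci.items():
            row[f"{m}_ci_low"] = round(lo, 1)
            row[f"{m}_ci_high"] = round(hi, 1)
        rows.append(row)
    return pd.DataFrame(rows)
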