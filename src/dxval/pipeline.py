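"""End-to-end validation pipeline and run manifests.

``run_pipeline`` wires the stages together:

    simulate -> stratify -> draw sample -> chart review (with blocked-record
    replacement) -> reliability subsample & kappa -> weights -> weighted
    metrics -> characteristics table -> Markdown/CSV report + JSON manifest

Re-running from a manifest reproduces every output byte-identically.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .codesets import CodeSet, default_code_sets
from .cohort import CohortTable
from .config import SimulationConfig
from .metrics import (
    ConfusionSummary,
    KappaResult,
    WeightedPerformance,
    cohens_kappa,
    confusion_counts,
    performance_frame,
    weighted_performance,
)
from .reporting import characteristics_table, to_markdown
from .sampling import (
    attach_sample_counts,
    compute_weights,
    draw_sample,
    replace_blocked,
    select_reliability_subsample,
)
from .simulate import simulate_chart_review, simulate_population
from .strata import OVERALL, strata_frame, stratify, stratum_membership

logger = logging.getLogger(__name__)

MAX_REPLACEMENT_GENERATIONS = 50


@dataclass
class PipelineResult:
    cohort: CohortTable
    membership: pd.DataFrame
    strata: pd.DataFrame
    sample: pd.DataFrame
    review: pd.DataFrame
    weights: pd.DataFrame | None
    metrics: pd.DataFrame
    characteristics: pd.DataFrame
    kappa: KappaResult | None
    manifest: dict = field(default_factory=dict)


def review_with_replacement(
    cohort: CohortTable,
    sample: pd.DataFrame,
    membership: pd.DataFrame,
    config: SimulationConfig,
    reliability: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate review, replacing blocked records with same-stratum redraws
    until every active record is readable.  Returns (sample, review)."""
    reviews = []
    current = sample
    pending = sample
    for generation in range(MAX_REPLACEMENT_GENERATIONS):
        rev = simulate_chart_review(
            cohort, pending, config, reliability=reliability, nonce=generation
        )
        reviews.append(rev)
        review_all = pd.concat(reviews, ignore_index=True)
        replaced = replace_blocked(
            current, review_all, membership, seed=np.random.default_rng(
                [config.seed, 500, generation]
            ).integers(2**31),
        )
        n_new = len(replaced) - len(current)
        if n_new == 0:
            review_all = review_all.merge(
                current[["condition", "period", "stratum", "child_id", "active"]],
                on=["condition", "period", "stratum", "child_id"], how="left",
            )
            review_all["active"] = review_all["active"].fillna(False)
            return current, review_all
        logger.info("replacement generation %d: %d blocked records replaced",
                    generation + 1, n_new)
        pending = replaced.iloc[len(current):]
        current = replaced
    raise RuntimeError("blocked-record replacement did not converge")


def run_pipeline(
    config: SimulationConfig,
    out_dir: str | Path | None = None,
    per_cell: int = 40,
    codesets: dict[str, CodeSet] | None = None,
    reliability_total: int = 180,
    ci_method: str | None = "stratified-bootstrap",
    n_boot: int = 1000,
    reference: pd.DataFrame | None = None,
) -> PipelineResult:
    """Execute the whole validation study on a simulated cohort.

    With ``per_cell=0`` an empty report is produced (warning logged).
    All stage outputs are written under ``out_dir`` when given, together
    with a JSON manifest sufficient to reproduce the run.
    """
    codesets = codesets if codesets is not None else default_code_sets()
    codesets = {c: codesets[c] for c in config.conditions}

    cohort = simulate_population(config, codesets)
    member = stratum_membership(cohort, codesets, config.periods)
    strata_counts = stratify(cohort, codesets, config.periods)

    if per_cell == 0 or cohort.n_children == 0:
        logger.warning("empty design (per_cell=%d, n_children=%d): empty report",
                       per_cell, cohort.n_children)
        result = PipelineResult(
            cohort=cohort, membership=member, strata=strata_frame(strata_counts),
            sample=pd.DataFrame(), review=pd.DataFrame(), weights=None,
            metrics=pd.DataFrame(), characteristics=characteristics_table(cohort, None, reference, seed=config.seed),
            kappa=None, manifest=_manifest(config, per_cell, reliability_total, ci_method, n_boot),
        )
        if out_dir is not None:
            _write_outputs(result, Path(out_dir))
        return result

    sample = draw_sample(member, per_cell, seed=np.random.default_rng([config.seed, 200]).integers(2**31))

    n_active = int(sample["active"].sum())
    rel_total = reliability_total if reliability_total <= n_active else 0
    reliability = (
        select_reliability_subsample(
            sample, total=rel_total,
            per_abstractor=rel_total // 2,
            per_condition=rel_total // len(config.conditions) if rel_total else 0,
            seed=np.random.default_rng([config.seed, 300]).integers(2**31),
        )
        if rel_total
        else None
    )

    sample, review = review_with_replacement(cohort, sample, member, config, reliability)
    logger.info("final sample: %d active records, %d replacements",
                int(sample["active"].sum()),
                int((sample["replacement_generation"] > 0).sum()))

    kappa: KappaResult | None = None
    if reliability is not None:
        dual = review[review["second_abstractor"].notna() & review["active"]]
        if len(dual):
            kappa = cohens_kappa(dual["outcome"], dual["outcome_2"])

    strata_counts = attach_sample_counts(strata_counts, sample, review)
    weights = compute_weights(strata_counts, period=OVERALL)

    results: list[WeightedPerformance] = []
    for cond in config.conditions:
        conf = confusion_counts(review, cond, period=OVERALL)
        results.append(
            weighted_performance(
                conf, weights, ci_method=ci_method, n_boot=n_boot,
                seed=np.random.default_rng([config.seed, 400]).integers(2**31),
            )
        )
    metrics_df = performance_frame(results)
    chars = characteristics_table(cohort, sample, reference, seed=config.seed)

    result = PipelineResult(
        cohort=cohort, membership=member, strata=strata_counts, sample=sample,
        review=review, weights=weights.table, metrics=metrics_df,
        characteristics=chars, kappa=kappa,
        manifest=_manifest(config, per_cell, reliability_total, ci_method, n_boot),
    )
    if out_dir is not None:
        _write_outputs(result, Path(out_dir))
    return result


def _manifest(config, per_cell, reliability_total, ci_method, n_boot) -> dict:
    cfg = json.loads(config.model_dump_json())
    blob = json.dumps(cfg, sort_keys=True).encode()
    return {
        "dxval_version": __version__,
        "numpy_version": np.__version__,
        "pandas_version": pd.__version__,
        "config": cfg,
        "config_sha256": hashlib.sha256(blob).hexdigest(),
        "per_cell": per_cell,
        "reliability_total": reliability_total,
        "ci_method": ci_method,
        "n_boot": n_boot,
        "seed": config.seed,
    }


def _write_outputs(result: PipelineResult, out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    result.cohort.write_csv(out / "cohort")
    result.membership.to_csv(out / "stratum_membership.csv", index=False)
    strata_frame(result.strata).to_csv(out / "strata.csv", index=False)
    result.sample.to_csv(out / "sample.csv", index=False)
    result.review.to_csv(out / "review.csv", index=False)
    if result.weights is not None:
        result.weights.to_csv(out / "weights.csv", index=False)
    result.metrics.to_csv(out / "metrics.csv", index=False)
    result.characteristics.to_csv(out / "characteristics.csv", index=False)
    (out / "manifest.json").write_text(json.dumps(result.manifest, indent=2, sort_keys=True))

    parts = ["# Validation report\n"]
    if result.kappa is not None:
        parts.append(
            f"Interrater reliability: kappa = {result.kappa.kappa:.4f} "
            f"(observed agreement {result.kappa.observed_agreement:.4f}, "
            f"n = {result.kappa.n_pairs})\n"
        )
    if len(result.metrics):
        parts.append("## Weighted performance (overall)\n")
        parts.append(to_markdown(result.metrics))
    if len(result.characteristics):
        parts.append("\n## Cohort characteristics\n")
        parts.append(to_markdown(result.characteristics))
    (out / "report.md").write_text("".join(parts))


def run_from_manifest(path: str | Path, out_dir: str | Path | None = None) -> PipelineResult:
    """Re-execute a run exactly as recorded in its manifest."""
    data = json.loads(Path(path).read_text())
    config = SimulationConfig.model_validate(data["config"])
    return run_pipeline(
        config,
        out_dir=out_dir,
        per_cell=data["per_cell"],
        reliability_total=data["reliability_total"],
        ci_method=data["ci_method"],
        n_boot=data["n_boot"],
    )
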