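"""In-memory container for EHR-style cohort extracts.

A :class:`CohortTable` bundles four tidy tables: children (demographics),
enrollment spans, encounters (with optional diagnosis codes), and the
per-condition latent truth table.  For simulated cohorts the truth table is
the generative ground truth; for imported real extracts it holds the
adjudicated chart-review determinations where known.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

CHILD_COLUMNS = [
    "child_id", "birth_date", "sex", "race_ethnicity", "income_band",
    "insurance", "period",
]
ENROLLMENT_COLUMNS = ["child_id", "start", "end"]
ENCOUNTER_COLUMNS = ["child_id", "date", "visit_type", "code"]
TRUTH_COLUMNS = ["child_id", "condition", "period", "stratum", "true_status"]


@dataclass
class CohortTable:
    """Four aligned tables keyed by integer ``child_id``."""

    children: pd.DataFrame
    enrollment: pd.DataFrame
    encounters: pd.DataFrame
    truth: pd.DataFrame

    def __post_init__(self) -> None:
        ids = self.children["child_id"]
        if ids.duplicated().any():
            dup = ids[ids.duplicated()].head().tolist()
            raise ValueError(f"duplicate child_ids, e.g. {dup}")

    @property
    def n_children(self) -> int:
        return len(self.children)

    # ---- IO ---------------------------------------------------------
    def write_csv(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.children.to_csv(out / "children.csv", index=False)
        self.enrollment.to_csv(out / "enrollment.csv", index=False)
        self.encounters.to_csv(out / "encounters.csv", index=False)
        self.truth.to_csv(out / "truth.csv", index=False)

    @classmethod
    def read_csv(cls, in_dir: str | Path) -> "CohortTable":
        d = Path(in_dir)
        children = pd.read_csv(d / "children.csv", parse_dates=["birth_date"])
        enrollment = pd.read_csv(d / "enrollment.csv", parse_dates=["start", "end"])
        encounters = pd.read_csv(
            d / "encounters.csv", parse_dates=["date"], dtype={"code": "string"}
        )
        truth = pd.read_csv(d / "truth.csv")
        truth["true_status"] = truth["true_status"].astype(bool)
        return cls(children, enrollment, encounters, truth)


def age_years(on: pd.Series | np.ndarray, birth: pd.Series | np.ndarray) -> np.ndarray:
    """Completed years of age on date ``on`` (vectorized; birthday counts)."""
    on = pd.DatetimeIndex(np.asarray(on, dtype="datetime64[ns]"))
    birth = pd.DatetimeIndex(np.asarray(birth, dtype="datetime64[ns]"))
    before_birthday = (np.asarray(on.month) * 100 + np.asarray(on.day)) < (
        np.asarray(birth.month) * 100 + np.asarray(birth.day)
    )
    return np.asarray(on.year) - np.asarray(birth.year) - before_birthday.astype(int)
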