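"""Simulation configuration for synthetic EHR validation cohorts.

A :class:`SimulationConfig` describes the generative study conditions: the
per-condition Dx / No-Dx stratum sizes, the latent coding-accuracy
probabilities, the study periods, and the chart-review nuisance rates
(blocked notes, insufficient notes, abstractor error).
"""

from __future__ import annotations

import datetime as dt
import json
from pathlib import Path
from typing import Optional

import yaml
from pydantic import BaseModel, Field, NonNegativeInt, field_validator, model_validator

#: US transition date from ICD-9-CM to ICD-10-CM coding.
ICD10_TRANSITION = dt.date(2015, 10, 1)


class Period(BaseModel):
    """A study time window with an inclusive [start, end] date range."""

    label: str
    start: dt.date
    end: dt.date

    @model_validator(mode="after")
    def _ordered(self) -> "Period":
        if self.end < self.start:
            raise ValueError(f"period {self.label!r}: end {self.end} before start {self.start}")
        return self

    @property
    def coding_system(self) -> str:
        """Coding system in force for the whole period ('icd9' or 'icd10')."""
        return "icd9" if self.end < ICD10_TRANSITION else "icd10"


class ConditionSpec(BaseModel):
    """Generative parameters for one condition.

    ``ppv_true`` is the probability that a child in the Dx stratum (has a
    qualifying code) is a true case; ``one_minus_npv_true`` the probability
    that a No-Dx child is a true case.  These are the latent coding-accuracy
    dials the validation pipeline is meant to recover.
    """

    n_dx: NonNegativeInt
    n_nodx: NonNegativeInt
    ppv_true: float = Field(ge=0.0, le=1.0)
    one_minus_npv_true: float = Field(ge=0.0, le=1.0)

    @property
    def n_total(self) -> int:
        return self.n_dx + self.n_nodx


class SimulationConfig(BaseModel):
    """Full generative description of a synthetic validation cohort."""

    conditions: dict[str, ConditionSpec]
    periods: list[Period]
    period_shares: Optional[list[float]] = None
    blocked_rate: float = Field(default=0.03, ge=0.0, le=1.0)
    insufficient_rate: float = Field(default=0.0, ge=0.0, le=1.0)
    abstractor_error_rate: float = Field(default=0.0125, ge=0.0, le=1.0)
    seed: int = 0

    @field_validator("conditions")
    @classmethod
    def _nonempty(cls, v: dict[str, ConditionSpec]) -> dict[str, ConditionSpec]:
        if not v:
            raise ValueError("conditions: at least one condition required")
        return v

    @model_validator(mode="after")
    def _check(self) -> "SimulationConfig":
        if not self.periods:
            raise ValueError("periods: at least one period required")
        for a, b in zip(self.periods, self.periods[1:]):
            if b.start <= a.end:
                raise ValueError(
                    f"periods: {b.label!r} overlaps or precedes {a.label!r}"
                )
        if self.period_shares is not None:
            if len(self.period_shares) != len(self.periods):
                raise ValueError("period_shares: length must match periods")
            if any(s < 0 for s in self.period_shares):
                raise ValueError("period_shares: negative share")
            tot = sum(self.period_shares)
            if abs(tot - 1.0) > 1e-9:
                raise ValueError(f"period_shares: must sum to 1, got {tot}")
        return self

    @property
    def shares(self) -> list[float]:
        if self.period_shares is not None:
            return list(self.period_shares)
        k = len(self.periods)
        return [1.0 / k] * k

    # ---- round-trip -------------------------------------------------
    def to_file(self, path: str | Path) -> None:
        path = Path(path)
        data = json.loads(self.model_dump_json())
        if path.suffix in (".yml", ".yaml"):
            path.write_text(yaml.safe_dump(data, sort_keys=False))
        else:
            path.write_text(json.dumps(data, indent=2))

    @classmethod
    def from_file(cls, path: str | Path) -> "SimulationConfig":
        path = Path(path)
        text = path.read_text()
        data = yaml.safe_load(text) if path.suffix in (".yml", ".yaml") else json.loads(text)
        return cls.model_validate(data)


def default_periods() -> list[Period]:
    """The three study windows: pre-pandemic ICD-9, pre-pandemic ICD-10,
    and post-pandemic ICD-10."""
    return [
        Period(label="2012-2014", start=dt.date(2012, 1, 1), end=dt.date(2014, 12, 31)),
        Period(label="2017-2019", start=dt.date(2017, 1, 1), end=dt.date(2019, 12, 31)),
        Period(label="2021-2022", start=dt.date(2021, 1, 1), end=dt.date(2022, 12, 31)),
    ]


def default_study_config(seed: int = 0) -> SimulationConfig:
    """Full-scale study conditions: the published stratum sizes of a large
    integrated-health-system pediatric cohort and near-perfect coding
    accuracy (chart-confirmed fractions on the order of 119/120 .. 120/120
    per stratum).

    This is a ~2.3M-child cohort; scale the counts down (keeping the Dx :
    No-Dx ratio) for interactive use.
    """
    c = ConditionSpec
    return SimulationConfig(
        conditions={
            "DBD": c(n_dx=41351, n_nodx=2110254, ppv_true=120 / 120, one_minus_npv_true=0 / 120),
            "anxiety": c(n_dx=120484, n_nodx=2031121, ppv_true=120 / 120, one_minus_npv_true=1 / 120),
            "ASD": c(n_dx=47441, n_nodx=2236490, ppv_true=119 / 120, one_minus_npv_true=0 / 120),
            "MDD": c(n_dx=43919, n_nodx=2107686, ppv_true=119 / 120, one_minus_npv_true=0 / 120),
            "ADHD": c(n_dx=108717, n_nodx=1768413, ppv_true=119 / 120, one_minus_npv_true=0 / 120),
        },
        periods=default_periods(),
        blocked_rate=0.03,
        insufficient_rate=0.0,
        abstractor_error_rate=0.0125,
        seed=seed,
    )
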