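"""Condition code sets and ICD code matching.

A :class:`CodeSet` holds prefix patterns for ICD-9-CM and ICD-10-CM plus the
condition's eligible age window.  Matching is prefix-based: a 3-character
category pattern matches every subcode beneath it.  Comparison is
case-insensitive and ignores the decimal point, so ``"F84"`` matches
``"F84.0"`` and ``"31401"`` matches the pattern ``"314"``.

The shipped default sets are editable package defaults for five pediatric
mental, emotional, and behavioral conditions; production users should load
their own curated lists (:func:`read_code_sets` / :func:`write_code_sets`).
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

SYSTEMS = ("icd9", "icd10")


def normalize_code(code: str) -> str:
    """Canonical form used for matching: uppercase, no decimal point."""
    return code.replace(".", "").strip().upper()


@dataclass(frozen=True)
class CodeSet:
    """Diagnosis-code definition of one condition.

    Parameters
    ----------
    condition
        Condition label (e.g. ``"ADHD"``).
    icd9_codes, icd10_codes
        Prefix patterns under each coding system.
    min_age_years, max_age_years
        Inclusive age window (completed years) for cohort eligibility.
    """

    condition: str
    icd9_codes: tuple[str, ...] = ()
    icd10_codes: tuple[str, ...] = ()
    min_age_years: int = 2
    max_age_years: int = 17

    def patterns(self, coding_system: str) -> tuple[str, ...]:
        if coding_system == "icd9":
            return self.icd9_codes
        if coding_system == "icd10":
            return self.icd10_codes
        raise ValueError(f"unknown coding_system {coding_system!r}; expected one of {SYSTEMS}")


def classify_code(code: str, codeset: CodeSet, coding_system: str) -> bool:
    """True iff *code* belongs to *codeset* under *coding_system*.

    Prefix semantics: the code matches if its normalized form starts with
    any normalized pattern of the set.
    """
    if not code or not code.strip():
        raise ValueError("code must be non-empty")
    norm = normalize_code(code)
    return any(norm.startswith(normalize_code(p)) for p in codeset.patterns(coding_system))


def match_codes(codes: pd.Series, codeset: CodeSet, coding_systems: pd.Series) -> pd.Series:
    """Vectorized :func:`classify_code` over aligned code / system series.

    Empty or missing codes match nothing (they raise in the scalar API but
    are routine in encounter tables, where most visits carry no study code).
    """
    norm = codes.fillna("").map(normalize_code)
    out = pd.Series(False, index=codes.index)
    for system in SYSTEMS:
        mask = (coding_systems == system) & (norm != "")
        if not mask.any():
            continue
        hit = pd.Series(False, index=codes.index[mask])
        sub = norm[mask]
        for pat in codeset.patterns(system):
            hit |= sub.str.startswith(normalize_code(pat))
        out.loc[mask] = hit
    return out


# Package defaults; deliberately coarse category-level prefixes.
_DEFAULTS = [
    CodeSet("ASD", icd9_codes=("299",), icd10_codes=("F84",), min_age_years=2),
    CodeSet("ADHD", icd9_codes=("314",), icd10_codes=("F90",), min_age_years=5),
    CodeSet("DBD", icd9_codes=("312", "313.81"), icd10_codes=("F91",), min_age_years=3),
    CodeSet(
        "anxiety",
        icd9_codes=("300.0", "300.2", "300.3", "309.21"),
        icd10_codes=("F40", "F41", "F93.0"),
        min_age_years=3,
    ),
    CodeSet(
        "MDD",
        icd9_codes=("296.2", "296.3", "300.4", "311"),
        icd10_codes=("F32", "F33", "F34.1"),
        min_age_years=3,
    ),
]


def default_code_sets() -> dict[str, CodeSet]:
    """Editable default code sets for the five study conditions."""
    return {cs.condition: cs for cs in _DEFAULTS}


#: A representative concrete billable code per condition and system, used by
#: the simulator when stamping qualifying diagnoses onto encounters.
REPRESENTATIVE_CODES = {
    ("ASD", "icd9"): "299.00",
    ("ASD", "icd10"): "F84.0",
    ("ADHD", "icd9"): "314.01",
    ("ADHD", "icd10"): "F90.0",
    ("DBD", "icd9"): "312.9",
    ("DBD", "icd10"): "F91.9",
    ("anxiety", "icd9"): "300.00",
    ("anxiety", "icd10"): "F41.1",
    ("MDD", "icd9"): "296.20",
    ("MDD", "icd10"): "F32.9",
}


# ---- IO --------------------------------------------------------------

_COLUMNS = ["condition", "system", "pattern", "min_age", "max_age"]


def write_code_sets(codesets: dict[str, CodeSet], path: str | Path) -> None:
    """Write code sets as JSON (mapping) or CSV (long table)."""
    path = Path(path)
    if path.suffix == ".json":
        data = {
            name: {
                "icd9_codes": list(cs.icd9_codes),
                "icd10_codes": list(cs.icd10_codes),
                "min_age_years": cs.min_age_years,
                "max_age_years": cs.max_age_years,
            }
            for name, cs in codesets.items()
        }
        path.write_text(json.dumps(data, indent=2))
        return
    with path.open("w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(_COLUMNS)
        for name, cs in codesets.items():
            for system in SYSTEMS:
                for pat in cs.patterns(system):
                    w.writerow([name, system, pat, cs.min_age_years, cs.max_age_years])


def read_code_sets(path: str | Path) -> dict[str, CodeSet]:
    path = Path(path)
    if path.suffix == ".json":
        data = json.loads(path.read_text())
        return {
            name: CodeSet(
                condition=name,
                icd9_codes=tuple(d.get("icd9_codes", ())),
                icd10_codes=tuple(d.get("icd10_codes", ())),
                min_age_years=int(d.get("min_age_years", 2)),
                max_age_years=int(d.get("max_age_years", 17)),
            )
            for name, d in data.items()
        }
    df = pd.read_csv(path)
    out: dict[str, CodeSet] = {}
    for name, grp in df.groupby("condition", sort=False):
        icd9 = tuple(grp.loc[grp["system"] == "icd9", "pattern"].astype(str))
        icd10 = tuple(grp.loc[grp["system"] == "icd10", "pattern"].astype(str))
        out[str(name)] = CodeSet(
            condition=str(name),
            icd9_codes=icd9,
            icd10_codes=icd10,
            min_age_years=int(grp["min_age"].iloc[0]),
            max_age_years=int(grp["max_age"].iloc[0]),
        )
    return out
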