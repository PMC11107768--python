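import datetime as dt

import pandas as pd
import pytest

import dxval as dv


@pytest.fixture
def one_period() -> dv.Period:
    return dv.Period(label="2017-2019", start=dt.date(2017, 1, 1), end=dt.date(2019, 12, 31))


@pytest.fixture
def make_config(one_period):
    """Factory for small one-condition configs used across tests."""

    def _make(
        n_dx=50,
        n_nodx=450,
        ppv_true=0.9,
        one_minus_npv_true=0.0,
        condition="anxiety",
        seed=0,
        periods=None,
        **kw,
    ) -> dv.SimulationConfig:
        return dv.SimulationConfig(
            conditions={
                condition: dv.ConditionSpec(
                    n_dx=n_dx,
                    n_nodx=n_nodx,
                    ppv_true=ppv_true,
                    one_minus_npv_true=one_minus_npv_true,
                )
            },
            periods=periods or [one_period],
            seed=seed,
            **kw,
        )

    return _make


@pytest.fixture
def handmade_cohort(one_period) -> dv.CohortTable:
    """Five children with hand-chosen eligibility edge cases.

    * child 0: age 10, enrolled all period, one office visit, ADHD code
    * child 1: enrolled, no encounters at all
    * child 2: age 2 during the period (ASD-eligible, ADHD-ineligible)
    * child 3: enrolled only 100 days
    * child 4: age 10, eligible, no code
    """
    mk = pd.Timestamp
    children = pd.DataFrame(
        {
            "child_id": [0, 1, 2, 3, 4],
            "birth_date": [mk("2008-06-15"), mk("2008-06-15"), mk("2016-11-20"),
                           mk("2008-06-15"), mk("2009-03-01")],
            "sex": ["female"] * 5,
            "race_ethnicity": ["hispanic"] * 5,
            "income_band": ["50k-69k"] * 5,
            "insurance": ["commercial"] * 5,
            "period": [one_period.label] * 5,
        }
    )
    enrollment = pd.DataFrame(
        {
            "child_id": [0, 1, 2, 3, 4],
            "start": [mk("2017-01-01")] * 3 + [mk("2019-06-01"), mk("2017-01-01")],
            "end": [mk("2019-12-31")] * 3 + [mk("2019-09-08"), mk("2019-12-31")],
        }
    )
    encounters = pd.DataFrame(
        {
            "child_id": [0, 0, 2, 3, 4],
            "date": [mk("2018-03-01"), mk("2018-07-15"), mk("2019-06-01"),
                     mk("2019-07-01"), mk("2018-01-10")],
            "visit_type": ["office", "office", "office", "office", "virtual"],
            "code": pd.array(["F90.0", pd.NA, "F84.0", "F90.1", pd.NA], dtype="string"),
        }
    )
    truth = pd.DataFrame(
        {
            "child_id": [0, 1, 2, 3, 4],
            "condition": ["ADHD"] * 5,
            "period": [one_period.label] * 5,
            "stratum": ["Dx", "No-Dx", "No-Dx", "Dx", "No-Dx"],
            "true_status": [True, False, False, True, False],
        }
    )
    return dv.CohortTable(children, enrollment, encounters, truth)
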