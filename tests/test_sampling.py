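"""Stratified sampling, replacement, reliability subsample, weights."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import dxval as dv

SETS = dv.default_code_sets()


def make_membership(cells: dict[tuple[str, str, str], int]) -> pd.DataFrame:
    rows = []
    next_id = 0
    for (cond, period, stratum), n in cells.items():
        ids = range(next_id, next_id + n)
        next_id += n
        rows.append(pd.DataFrame({"condition": cond, "period": period,
                                  "stratum": stratum, "child_id": list(ids)}))
    return pd.concat(rows, ignore_index=True)


class TestDrawSample:
    def test_full_design_has_1200_records(self):
        cells = {
            (c, p, s): 500
            for c in ("ASD", "ADHD", "DBD", "anxiety", "MDD")
            for p in ("2012-2014", "2017-2019", "2021-2022")
            for s in ("Dx", "No-Dx")
        }
        sample = dv.draw_sample(make_membership(cells), per_cell=40, seed=0)
        assert len(sample) == 1200
        assert sample["active"].all()
        sizes = sample.groupby(["condition", "period", "stratum"]).size()
        assert (sizes == 40).all()

    def test_per_cell_zero_is_empty(self):
        member = make_membership({("a", "p", "Dx"): 10})
        assert len(dv.draw_sample(member, 0, seed=0)) == 0

    def test_whole_stratum_selected_when_exact(self):
        member = make_membership({("a", "p", "Dx"): 7, ("a", "p", "No-Dx"): 9})
        sample = dv.draw_sample(member, per_cell=7, seed=3)
        dx = sample[sample["stratum"] == "Dx"]
        assert set(dx["child_id"]) == set(member[member["stratum"] == "Dx"]["child_id"])

    def test_undersized_cell_raises_with_cell_name(self):
        member = make_membership({("ADHD", "p", "Dx"): 5, ("ADHD", "p", "No-Dx"): 50})
        with pytest.raises(ValueError, match=r"ADHD.*Dx"):
            dv.draw_sample(member, per_cell=10, seed=0)

    def test_seed_determinism(self):
        member = make_membership({("a", "p", "Dx"): 100, ("a", "p", "No-Dx"): 100})
        s1 = dv.draw_sample(member, 20, seed=5)
        s2 = dv.draw_sample(member, 20, seed=5)
        s3 = dv.draw_sample(member, 20, seed=6)
        pd.testing.assert_frame_equal(s1, s2)
        assert not s1["child_id"].equals(s3["child_id"])

    def test_no_child_twice_per_condition(self):
        # same children present in every period's membership
        rows = []
        for p in ("p1", "p2", "p3"):
            rows.append(pd.DataFrame({"condition": "a", "period": p,
                                      "stratum": "Dx", "child_id": range(30)}))
            rows.append(pd.DataFrame({"condition": "a", "period": p,
                                      "stratum": "No-Dx", "child_id": range(30, 60)}))
        member = pd.concat(rows, ignore_index=True)
        sample = dv.draw_sample(member, per_cell=8, seed=1)
        assert not sample.duplicated(["condition", "child_id"]).any()


class TestReplaceBlocked:
    @staticmethod
    def _review(sample: pd.DataFrame, blocked_ids: set[int]) -> pd.DataFrame:
        review = sample[["condition", "period", "stratum", "child_id",
                         "replacement_generation"]].copy()
        review["outcome"] = np.where(review["child_id"].isin(list(blocked_ids)),
                                     "blocked", "yes")
        review["adjudicated"] = np.where(review["outcome"] == "yes", "yes", pd.NA)
        return review

    def test_no_blocked_returns_unchanged(self):
        member = make_membership({("a", "p", "Dx"): 20, ("a", "p", "No-Dx"): 20})
        sample = dv.draw_sample(member, 5, seed=0)
        out = dv.replace_blocked(sample, self._review(sample, set()), member, seed=1)
        pd.testing.assert_frame_equal(out, sample)

    def test_replacements_same_cell_and_fresh(self):
        member = make_membership({("a", "p", "Dx"): 20, ("a", "p", "No-Dx"): 20})
        sample = dv.draw_sample(member, 5, seed=0)
        blocked = set(sample["child_id"].iloc[:3])
        out = dv.replace_blocked(sample, self._review(sample, blocked), member, seed=1)
        assert len(out) == len(sample) + 3
        assert int(out["active"].sum()) == len(sample)
        new = out.iloc[len(sample):]
        assert (new["replacement_generation"] == 1).all()
        assert not out.duplicated(["condition", "child_id"]).any()
        # replacements land in the cells that lost records
        lost = sample[sample["child_id"].isin(list(blocked))]
        assert (new.groupby(["period", "stratum"]).size()
                == lost.groupby(["period", "stratum"]).size()).all()

    def test_exhausted_cell_raises(self):
        member = make_membership({("a", "p", "Dx"): 5, ("a", "p", "No-Dx"): 5})
        sample = dv.draw_sample(member, 5, seed=0)
        blocked = set(sample[sample["stratum"] == "Dx"]["child_id"].iloc[:2])
        with pytest.raises(ValueError, match="exhausted"):
            dv.replace_blocked(sample, self._review(sample, blocked), member, seed=1)


class TestReliabilitySubsample:
    def _sample(self, n_per_cell=120):
        cells = {
            (c, "p", s): 500
            for c in ("ASD", "ADHD", "DBD", "anxiety", "MDD")
            for s in ("Dx", "No-Dx")
        }
        return dv.draw_sample(make_membership(cells), n_per_cell, seed=0)

    def test_default_design(self):
        sub = dv.select_reliability_subsample(self._sample(), seed=2)
        assert len(sub) == 180
        assert (sub.groupby("condition").size() == 36).all()
        assert (sub.groupby(["condition", "stratum"]).size() == 18).all()
        assert (sub.groupby("second_abstractor").size() == 90).all()

    def test_zero_total_empty(self):
        sub = dv.select_reliability_subsample(self._sample(), total=0,
                                              per_abstractor=0, per_condition=0)
        assert len(sub) == 0

    def test_inconsistent_counts_raise(self):
        with pytest.raises(ValueError, match="inconsistent"):
            dv.select_reliability_subsample(self._sample(), total=180,
                                            per_abstractor=90, per_condition=40)
        with pytest.raises(ValueError, match="inconsistent"):
            dv.select_reliability_subsample(self._sample(), total=180,
                                            per_abstractor=80, per_condition=36)


class TestWeights:
    def test_published_style_weight(self):
        strata = [
            dv.StratumCount("anxiety", "Dx", N=120484, n_sampled=120),
            dv.StratumCount("anxiety", "No-Dx", N=2031121, n_sampled=120),
        ]
        w = dv.compute_weights(strata)
        assert w.get("anxiety", "Dx") == pytest.approx(0.0004666439, abs=5e-11)
        assert w.get("anxiety", "No-Dx") == pytest.approx(0.0078666894, abs=5e-11)

    def test_equal_strata_symmetry(self):
        strata = [
            dv.StratumCount("c", "Dx", N=500, n_sampled=10),
            dv.StratumCount("c", "No-Dx", N=500, n_sampled=10),
        ]
        w = dv.compute_weights(strata)
        assert w.get("c", "Dx") == w.get("c", "No-Dx") == pytest.approx(1 / 20)

    def test_hand_arithmetic(self):
        strata = [
            dv.StratumCount("c", "Dx", N=100, n_sampled=10),
            dv.StratumCount("c", "No-Dx", N=900, n_sampled=10),
        ]
        w = dv.compute_weights(strata)
        assert w.get("c", "Dx") == pytest.approx(0.01)
        assert w.get("c", "No-Dx") == pytest.approx(0.09)
        assert 10 * w.get("c", "Dx") + 10 * w.get("c", "No-Dx") == pytest.approx(1.0)

    def test_zero_sampled_raises(self):
        strata = [
            dv.StratumCount("c", "Dx", N=100, n_sampled=0),
            dv.StratumCount("c", "No-Dx", N=900, n_sampled=10),
        ]
        with pytest.raises(ValueError, match="n_sampled"):
            dv.compute_weights(strata)

    def test_missing_stratum_raises(self):
        with pytest.raises(ValueError, match="No-Dx"):
            dv.compute_weights([dv.StratumCount("c", "Dx", N=10, n_sampled=5)])

    @settings(max_examples=200, deadline=None)
    @given(
        n_dx=st.integers(1, 10**7),
        n_nodx=st.integers(1, 10**7),
        s_dx=st.integers(1, 500),
        s_nodx=st.integers(1, 500),
    )
    def test_normalization_property(self, n_dx, n_nodx, s_dx, s_nodx):
        """Sampled weights sum to 1 per condition for any configuration."""
        w = dv.compute_weights([
            dv.StratumCount("c", "Dx", N=n_dx, n_sampled=min(s_dx, n_dx)),
            dv.StratumCount("c", "No-Dx", N=n_nodx, n_sampled=min(s_nodx, n_nodx)),
        ])
        total = (min(s_dx, n_dx) * w.get("c", "Dx")
                 + min(s_nodx, n_nodx) * w.get("c", "No-Dx"))
        assert total == pytest.approx(1.0, abs=1e-12)

    @settings(max_examples=100, deadline=None)
    @given(n_dx=st.integers(1, 10**6), n_nodx=st.integers(1, 10**6),
           n_samp=st.integers(1, 200))
    def test_weighted_prevalence_identity(self, n_dx, n_nodx, n_samp):
        """Sum of Dx-sampled weights equals the population Dx share exactly."""
        s = min(n_samp, n_dx, n_nodx)
        w = dv.compute_weights([
            dv.StratumCount("c", "Dx", N=n_dx, n_sampled=s),
            dv.StratumCount("c", "No-Dx", N=n_nodx, n_sampled=s),
        ])
        assert s * w.get("c", "Dx") == pytest.approx(n_dx / (n_dx + n_nodx), rel=1e-12)


class TestMargin:
    def test_vanishing_with_n(self):
        assert dv.one_sided_margin(0.5, 10**12) < 1e-5

    def test_design_margin_values(self):
        assert dv.one_sided_margin(0.85, 120, 0.90) == pytest.approx(0.0418, abs=5e-5)
        assert dv.one_sided_margin(0.85, 120, 0.95) == pytest.approx(0.0536, abs=5e-5)

    def test_out_of_range_p(self):
        with pytest.raises(ValueError):
            dv.one_sided_margin(1.2, 100)
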