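import numpy as np
import pandas as pd
import pytest

from mhq.reliability import (
    ConsistencyPairSpec,
    _largest_remainder,
    across_sample_anova,
    age_band,
    draw_matched_samples,
    element_mean_correlation,
    gap_stratum,
    internal_consistency,
    pair_retests,
    test_retest_stats,
)
from mhq.instrument import SLEEP_SUFFICIENCY_RECODE


class TestMatchedSamples:
    def _cohort(self, n, strata_values, seed=0):
        rng = np.random.default_rng(seed)
        return pd.DataFrame(
            {
                "stratum": rng.choice(strata_values, size=n),
                "value": rng.normal(size=n),
            }
        )

    def test_single_stratum_disjoint_split(self):
        df = self._cohort(8, ["only"])
        out = draw_matched_samples(df, k=2, size=4, strata_columns=("stratum",))
        assert all(len(s) == 4 for s in out.samples)
        assert set(out.samples[0]).isdisjoint(out.samples[1])

    def test_infeasible_size_rejected(self):
        df = self._cohort(10, ["only"])
        with pytest.raises(ValueError, match="exceeds cohort size"):
            draw_matched_samples(df, k=4, size=3, strata_columns=("stratum",))

    def test_two_strata_proportional_allocation(self):
        # 50/50 cohort, sample size 10: exactly 5 + 5 per sample
        df = pd.DataFrame({"stratum": ["a"] * 50 + ["b"] * 50, "value": 0.0})
        out = draw_matched_samples(df, k=4, size=10, strata_columns=("stratum",),
                                   seed=1)
        for idx in out.samples:
            counts = df.loc[idx, "stratum"].value_counts()
            assert counts["a"] == 5 and counts["b"] == 5

    def test_union_has_no_duplicates(self):
        df = self._cohort(200, ["a", "b", "c"], seed=2)
        out = draw_matched_samples(df, k=3, size=40, strata_columns=("stratum",),
                                   seed=3)
        union = np.concatenate(out.samples)
        assert len(union) == len(set(union)) == 120

    def test_reproducible_under_seed(self):
        df = self._cohort(100, ["a", "b"], seed=4)
        a = draw_matched_samples(df, k=2, size=20, strata_columns=("stratum",), seed=9)
        b = draw_matched_samples(df, k=2, size=20, strata_columns=("stratum",), seed=9)
        for x, y in zip(a.samples, b.samples):
            assert np.array_equal(x, y)

    def test_deficient_cell_reported(self):
        df = pd.DataFrame({"stratum": ["a"] * 99 + ["b"], "value": 0.0})
        with pytest.raises(ValueError, match="infeasible cell"):
            draw_matched_samples(df, k=4, size=25, strata_columns=("stratum",))

    def test_largest_remainder_sums_exactly(self):
        for total in (7, 10, 33):
            alloc = _largest_remainder(np.array([0.5, 0.3, 0.2]), total)
            assert alloc.sum() == total

    def test_age_bands(self):
        bands = age_band(pd.Series([18, 24, 25, 64, 65, 85]))
        assert bands.tolist() == ["18-24", "18-24", "25-34", "55-64", "65+", "65+"]


class TestAnova:
    def test_identical_samples_give_f_zero(self):
        sample = pd.DataFrame({"v": [1.0, 2.0, 3.0, 4.0]})
        res = across_sample_anova([sample, sample.copy(), sample.copy()], "v")
        assert res.f_statistic == pytest.approx(0.0, abs=1e-12)

    def test_separated_samples_give_tiny_p(self):
        rng = np.random.default_rng(0)
        a = pd.DataFrame({"v": rng.normal(0, 0.01, 50)})
        b = pd.DataFrame({"v": rng.normal(10, 0.01, 50)})
        res = across_sample_anova([a, b], "v")
        assert res.p_value < 1e-12

    def test_matches_textbook_two_pass_anova(self):
        rng = np.random.default_rng(1)
        frames = [pd.DataFrame({"v": rng.normal(0, 1, 30)}) for _ in range(4)]
        res = across_sample_anova(frames, "v")
        # hand-rolled oracle
        groups = [f["v"].to_numpy() for f in frames]
        grand = np.concatenate(groups).mean()
        ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
        ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
        df_b = len(groups) - 1
        df_w = sum(len(g) for g in groups) - len(groups)
        f = (ss_between / df_b) / (ss_within / df_w)
        assert res.f_statistic == pytest.approx(f)

    def test_degenerate_constant_data_flagged(self):
        a = pd.DataFrame({"v": [2.0, 2.0, 2.0]})
        res = across_sample_anova([a, a.copy()], "v")
        assert res.degenerate and res.p_value == 1.0


class TestElementMeanCorrelation:
    def test_identical_samples_r_one(self, bank, small_cohort):
        df = small_cohort.data
        table = element_mean_correlation([df, df.copy()], bank)
        assert table["r"].iloc[0] == pytest.approx(1.0)

    def test_four_samples_give_six_pairs(self, bank, small_cohort):
        df = small_cohort.data
        quarters = [df.iloc[i::4] for i in range(4)]
        table = element_mean_correlation(quarters, bank)
        assert len(table) == 6
        assert (table["r"] > 0.8).all()  # same population, high agreement


def _attempts(rows):
    df = pd.DataFrame(rows, columns=["respondent_id", "attempt_day"])
    df["x"] = np.arange(len(df), dtype=float)
    return df


class TestPairRetests:
    def test_same_and_next_day_retakes_excluded(self):
        pairs = pair_retests(_attempts([("a", 0), ("a", 0), ("b", 5), ("b", 6)]))
        assert len(pairs) == 0

    def test_three_day_gap_included_with_stratum(self):
        pairs = pair_retests(_attempts([("a", 0), ("a", 3)]))
        assert len(pairs) == 1
        assert pairs.gap_days[0] == 3
        assert pairs.strata[0] == "3-7"

    def test_earliest_qualifying_retake_wins(self):
        pairs = pair_retests(_attempts([("a", 0), ("a", 1), ("a", 40), ("a", 90)]))
        assert len(pairs) == 1
        assert pairs.gap_days[0] == 40
        assert pairs.strata[0] == "31-60"

    def test_each_id_contributes_at_most_one_pair(self):
        df = _attempts([("a", 0), ("a", 10), ("a", 20), ("b", 0), ("b", 30)])
        pairs = pair_retests(df)
        assert len(pairs) == 2
        assert sorted(pairs.first["respondent_id"]) == ["a", "b"]
        assert (pairs.gap_days >= 3).all()

    def test_gap_strata_boundaries(self):
        assert gap_stratum(2) is None
        assert gap_stratum(3) == "3-7"
        assert gap_stratum(8) == "8-30"
        assert gap_stratum(120) == "61-120"
        assert gap_stratum(450) == "121-450"
        assert gap_stratum(451) is None


class TestRetestStats:
    def test_identical_attempts_give_r_one(self, bank, small_cohort):
        df = small_cohort.data.head(100).copy()
        second = df.copy()
        second["attempt_day"] = df["attempt_day"] + 10
        pairs = pair_retests(pd.concat([df, second], ignore_index=True))
        stats = test_retest_stats(pairs, bank)
        assert stats.score_r == pytest.approx(1.0)
        assert stats.element_r == pytest.approx(1.0)

    def test_reflected_ratings_give_element_r_minus_one(self, bank, small_cohort):
        df = small_cohort.data.head(50).copy()
        second = df.copy()
        second["attempt_day"] = df["attempt_day"] + 10
        for eid in bank.element_ids:
            second[eid] = 10 - second[eid]
        pairs = pair_retests(pd.concat([df, second], ignore_index=True))
        stats = test_retest_stats(pairs, bank)
        assert stats.element_r == pytest.approx(-1.0, abs=1e-9)

    def test_sparse_strata_reported_absent(self, bank, small_cohort):
        df = small_cohort.data.head(10).copy()
        second = df.copy()
        second["attempt_day"] = df["attempt_day"] + 5  # all pairs in 3-7
        pairs = pair_retests(pd.concat([df, second], ignore_index=True))
        stats = test_retest_stats(pairs, bank)
        table = stats.by_stratum.set_index("stratum")
        assert table.loc["3-7", "n"] == 10
        assert np.isnan(table.loc["121-450", "score_r"])


class TestInternalConsistency:
    def test_item_against_itself_r_one(self, small_cohort):
        spec = ConsistencyPairSpec("self", "memory", "memory")
        table = internal_consistency(small_cohort.data, [spec])
        assert table["r"].iloc[0] == pytest.approx(1.0)

    def test_independent_items_near_zero(self):
        rng = np.random.default_rng(8)
        df = pd.DataFrame({"a": rng.integers(1, 10, 5000),
                           "b": rng.integers(1, 10, 5000)})
        table = internal_consistency(df, [ConsistencyPairSpec("ab", "a", "b")])
        assert abs(table["r"].iloc[0]) < 0.05

    def test_recode_applied_to_categorical_item(self):
        df = pd.DataFrame(
            {
                "sleep_quality": [1, 3, 5, 7],
                "sleep_sufficiency": ["hardly ever", "some of the time",
                                      "most of the time", "all the time"],
            }
        )
        spec = ConsistencyPairSpec("sleep", "sleep_quality", "sleep_sufficiency",
                                   recode_b=SLEEP_SUFFICIENCY_RECODE)
        table = internal_consistency(df, [spec])
        assert table["r"].iloc[0] == pytest.approx(1.0)  # both strictly increasing

    def test_degenerate_variance_flagged(self):
        df = pd.DataFrame({"a": [5, 5, 5, 5], "b": [1, 2, 3, 4]})
        table = internal_consistency(df, [ConsistencyPairSpec("ab", "a", "b")])
        assert table["degenerate"].iloc[0]
        assert np.isnan(table["r"].iloc[0])

    def test_order_invariance(self, small_cohort):
        df = small_cohort.data
        shuffled = df.sample(frac=1, random_state=1)
        a = internal_consistency(df)
        b = internal_consistency(shuffled)
        assert np.allclose(a["r"], b["r"])
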