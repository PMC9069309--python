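import numpy as np
import pandas as pd
import pytest
from pydantic import ValidationError

from mhq.instrument import validate_roster
from mhq.reliability import internal_consistency, pair_retests
from mhq.scoring import score_roster
from mhq.simulate import (
    GeneratorConfig,
    TraitModel,
    default_config,
    generate_cohort,
    generate_probes,
    generate_productivity,
    generate_retests,
    load_config,
    save_config,
)


class TestConfig:
    def test_invalid_configs_itemized(self):
        with pytest.raises(ValidationError):
            GeneratorConfig(n=-1)
        with pytest.raises(ValidationError):
            GeneratorConfig(trait=TraitModel(weights=[0.5, 0.4]))
        with pytest.raises(ValidationError):
            GeneratorConfig(retest={"stability": 1.5})
        with pytest.raises(ValidationError):
            GeneratorConfig(response={"loading": 0.9,
                                      "group_loadings": {"sleep": 0.9}})

    def test_yaml_round_trip(self, tmp_path):
        config = default_config(n=42, seed=9)
        path = tmp_path / "c.yaml"
        save_config(config, path)
        assert load_config(path) == config

    def test_trait_is_standardized(self):
        rng = np.random.default_rng(0)
        from mhq.simulate import _draw_trait

        draws = _draw_trait(TraitModel(), 200_000, rng)
        assert abs(draws.mean()) < 0.01
        assert abs(draws.std() - 1.0) < 0.01


class TestGenerateCohort:
    def test_empty_cohort(self, bank):
        roster = generate_cohort(default_config(n=0, seed=1), bank)
        assert len(roster) == 0

    def test_same_seed_identical(self, bank):
        a = generate_cohort(default_config(n=500, seed=42), bank)
        b = generate_cohort(default_config(n=500, seed=42), bank)
        pd.testing.assert_frame_equal(a.data, b.data)
        pd.testing.assert_frame_equal(a.latent, b.latent)

    def test_different_seed_differs(self, bank):
        a = generate_cohort(default_config(n=500, seed=42), bank)
        b = generate_cohort(default_config(n=500, seed=43), bank)
        assert not a.data[bank.element_ids].equals(b.data[bank.element_ids])

    def test_records_are_valid(self, bank, small_cohort):
        assert validate_roster(small_cohort.data, bank).all()

    def test_healthy_pole_limit_scores_200(self, bank):
        # push the trait far into the healthy pole: best possible record
        config = default_config(
            n=50, seed=2,
            trait={"weights": [1.0], "means": [0.0], "sds": [1.0]},
        )
        roster = generate_cohort(config, bank)
        roster.latent["theta"] += 50  # theta -> +inf surrogate
        from mhq.simulate import _ratings_from_latents

        eps = roster.latent[[f"eps_{e}" for e in bank.element_ids]].to_numpy()
        groups = {
            c[2:]: roster.latent[c].to_numpy()
            for c in roster.latent.columns if c.startswith("u_")
        }
        ratings = _ratings_from_latents(
            bank, config.response, roster.latent["theta"].to_numpy(), groups, eps
        )
        scored = score_roster(ratings, bank)
        assert (scored["mhq_score"] == 200.0).all()
        assert (ratings[bank.spectrum_ids] == 9).all().all()
        assert (ratings[bank.problem_ids] == 1).all().all()

    def test_related_pair_correlates_more_than_unrelated(self, bank):
        roster = generate_cohort(default_config(n=20000, seed=3), bank)
        table = internal_consistency(roster.data).set_index("pair")
        assert table.loc["self_regard", "r"] > table.loc["memory_intimacy", "r"]

    def test_demographics_respect_enums(self, small_cohort):
        df = small_cohort.data
        assert df["age"].between(18, 85).all()
        assert set(df["employment_status"]) <= {
            "employed", "homemaker", "unemployed", "retired", "studying",
            "not_able_to_work",
        }
        assert set(df["sleep_sufficiency"]) <= set(
            ["all the time", "most of the time", "some of the time", "hardly ever"]
        )


class TestGenerateRetests:
    def test_requires_latent_state(self, bank, small_cohort):
        from mhq.instrument import Roster

        bare = Roster(data=small_cohort.data.copy())
        with pytest.raises(ValueError, match="latent"):
            generate_retests(bare, default_config(n=10, seed=1), bank)

    def test_perfect_stability_reproduces_scores(self, bank):
        config = default_config(
            n=400, seed=4,
            retest={"stability": 1.0, "item_stability": 1.0, "fraction": 1.0},
        )
        roster = generate_cohort(config, bank)
        second = generate_retests(roster, config, bank)
        s1 = score_roster(roster.data, bank)["mhq_score"]
        s2 = score_roster(second.data, bank)["mhq_score"]
        assert np.corrcoef(s1, s2)[0, 1] == pytest.approx(1.0)

    def test_zero_stability_decorrelates(self, bank):
        config = default_config(
            n=2000, seed=5,
            retest={"stability": 0.0, "item_stability": 0.0, "fraction": 1.0},
        )
        roster = generate_cohort(config, bank)
        second = generate_retests(roster, config, bank)
        s1 = score_roster(roster.data, bank)["mhq_score"]
        s2 = score_roster(second.data, bank)["mhq_score"]
        assert abs(np.corrcoef(s1, s2)[0, 1]) < 0.06

    def test_gap_distribution_exercises_exclusion(self, bank):
        config = default_config(n=3000, seed=6)
        roster = generate_cohort(config, bank)
        second = generate_retests(roster, config, bank)
        gaps = (
            second.data.set_index("respondent_id")["attempt_day"]
            - roster.data.set_index("respondent_id")["attempt_day"]
        ).dropna()
        assert (gaps < 3).mean() > 0.05  # short gaps present ...
        both = pd.concat([roster.data, second.data], ignore_index=True)
        pairs = pair_retests(both)
        assert (pairs.gap_days >= 3).all()  # ... and excluded by pairing
        assert len(pairs) < len(second.data)


class TestGenerateProbes:
    def test_probe_only_for_high_ratings(self, bank, small_cohort):
        config = default_config(n=len(small_cohort), seed=123)
        probes = generate_probes(small_cohort, config)
        assert (probes["life_impact"] >= 5).all()
        n_eligible = (small_cohort.data["sadness"] >= 5).sum()
        assert len(probes) == n_eligible

    def test_supports(self, bank, small_cohort):
        probes = generate_probes(small_cohort, default_config(n=0, seed=123))
        assert probes["frequency"].between(0, 7).all()
        assert probes["severity"].between(1, 5).all()

    def test_frequency_anchor_at_rating_8(self, bank):
        config = default_config(n=40000, seed=7)
        roster = generate_cohort(config, bank)
        probes = generate_probes(roster, config)
        at8 = probes.loc[probes["life_impact"] == 8, "frequency"]
        assert at8.mean() == pytest.approx(5.0, abs=0.25)


class TestGenerateProductivity:
    def test_supports_and_determinism(self, bank, small_cohort):
        config = default_config(n=len(small_cohort), seed=123)
        scored = score_roster(small_cohort.data, bank)
        a = generate_productivity(scored, config)
        b = generate_productivity(scored, config)
        pd.testing.assert_frame_equal(a, b)
        assert a["days_missed"].between(0, 31).all()
        assert a["reduced_days"].between(0, 31).all()

    def test_top_scores_lose_few_days(self, bank):
        config = default_config(n=0, seed=8)
        scored = pd.DataFrame(
            {"respondent_id": [f"x{i}" for i in range(4000)],
             "mhq_score": np.full(4000, 200.0)}
        )
        prod = generate_productivity(scored, config)
        # E[M | 200] = a*exp(-200b) + c, close to the floor c
        expected = config.productivity.absent_mean(np.array([200.0]))[0]
        assert expected < 0.25
        assert prod["days_missed"].mean() == pytest.approx(expected, abs=0.1)

    def test_bin_means_decrease_with_score(self, bank):
        config = default_config(n=8000, seed=9)
        roster = generate_cohort(config, bank)
        scored = score_roster(roster.data, bank)
        prod = generate_productivity(scored, config)
        merged = scored.join(prod[["days_missed", "reduced_days"]])
        from mhq.productivity import aggregate_by_bin

        table = aggregate_by_bin(merged)
        ok = table[table["n"] >= 50]
        assert (np.diff(ok["m_mean"]) < 1).all()  # non-increasing up to noise
        assert ok["m_mean"].iloc[0] > ok["m_mean"].iloc[-1]
        assert ok["r_mean"].iloc[0] > ok["r_mean"].iloc[-1]
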