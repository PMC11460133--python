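"""Synthetic survey generator: determinism, composition, bounds, margins."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from schoolpa.config import DETERMINANTS, DeterminantModel, PopulationConfig
from schoolpa.exceptions import ConfigurationError, SchemaError
from schoolpa.population import (
    apply_school_filter,
    ethnic_group,
    generate_margins,
    generate_population,
    margin_variable,
)

from conftest import make_participants


class TestGeneratePopulation:
    def test_size_and_schema(self, default_population):
        participants, determinants = default_population
        assert len(participants) == 6906
        assert len(determinants) == 6906
        assert list(determinants.columns) == list(DETERMINANTS)
        assert participants["id"].is_unique
        assert (participants["base_weight"] > 0).all()
        assert participants["age"].between(12, 17).all()

    def test_same_seed_is_bit_identical(self):
        cfg = PopulationConfig(seed=11, n_surveyed=500, n_clusters=10)
        p1, d1 = generate_population(cfg)
        p2, d2 = generate_population(cfg)
        pd.testing.assert_frame_equal(p1, p2)
        pd.testing.assert_frame_equal(d1, d2)

    def test_different_seeds_differ(self):
        p1, d1 = generate_population(
            PopulationConfig(seed=1, n_surveyed=500, n_clusters=10))
        p2, d2 = generate_population(
            PopulationConfig(seed=2, n_surveyed=500, n_clusters=10))
        assert not d1.equals(d2)

    def test_category_proportions_near_targets(self, default_population):
        """Every single-select composition lands within 2 percentage points
        of its target at the full survey size."""
        participants, _ = default_population
        cfg = PopulationConfig()
        n = len(participants)
        share = (participants["gender"] == "female").mean()
        assert abs(share - cfg.gender_distribution["female"]) < 0.02
        for age, target in cfg.age_distribution.items():
            assert abs((participants["age"] == age).mean() - target) < 0.02
        for dep, target in cfg.deprivation_distribution.items():
            obs = (participants["deprivation"] == dep).mean()
            assert abs(obs - target) < 0.02
        for lab, target in cfg.ethnicity_rates.items():
            obs = participants[f"eth_{lab}"].mean()
            assert abs(obs - target) < 0.02

    def test_degenerate_gender_distribution(self):
        cfg = PopulationConfig(
            seed=3, n_surveyed=200, n_clusters=5,
            gender_distribution={"female": 1.0},
        )
        participants, _ = generate_population(cfg)
        assert (participants["gender"] == "female").all()

    def test_ethnicities_never_empty(self, small_population):
        participants, _ = small_population
        eth = [c for c in participants.columns if c.startswith("eth_")]
        assert participants[eth].any(axis=1).all()

    def test_invalid_config_names_field(self):
        cfg = PopulationConfig(disability_rate=1.5)
        with pytest.raises(ConfigurationError, match="disability_rate"):
            generate_population(cfg)
        cfg = PopulationConfig(
            deprivation_distribution={"low": 0.6, "mid": 0.5})
        with pytest.raises(ConfigurationError,
                           match="deprivation_distribution"):
            generate_population(cfg)
        with pytest.raises(ConfigurationError, match="n_clusters"):
            generate_population(
                PopulationConfig(n_surveyed=10, n_clusters=50))

    @settings(max_examples=10)
    @given(
        seed=st.integers(0, 2**16),
        mean_h=st.floats(2.0, 20.0),
        mean_s=st.floats(0.5, 6.0),
        mean_lit=st.floats(10.0, 19.0),
    )
    def test_determinant_bounds_hold_for_random_configs(
        self, seed, mean_h, mean_s, mean_lit
    ):
        targets = PopulationConfig().determinant_targets.copy()
        targets["pa_hours_week"] = DeterminantModel(
            "gamma", mean=mean_h, sd=6.0, cluster_sd=0.3)
        targets["n_settings"] = DeterminantModel(
            "poisson", mean=mean_s, upper=10, cluster_sd=0.05)
        targets["physical_literacy"] = DeterminantModel(
            "truncnorm", mean=mean_lit, sd=2.5, lower=4, upper=20,
            cluster_sd=0.1)
        cfg = PopulationConfig(seed=seed, n_surveyed=300, n_clusters=10,
                               determinant_targets=targets)
        _, det = generate_population(cfg)
        assert (det["pa_hours_week"] >= 0).all()
        for count in ("n_settings", "n_types"):
            values = det[count].to_numpy()
            assert np.array_equal(values, np.round(values))
            assert (values >= 0).all()
        assert det["n_settings"].le(10).all()
        assert det["physical_literacy"].between(4, 20).all()
        assert det["social_support"].between(5, 25).all()

    def test_strata_shift_moves_only_the_stratum(self):
        cfg = PopulationConfig(seed=5, n_surveyed=400, n_clusters=8)
        base_p, base_d = generate_population(cfg)
        cfg2 = PopulationConfig(
            seed=5, n_surveyed=400, n_clusters=8,
            strata_shifts={"pa_hours_week": {"gender": {"male": 2.0}}},
        )
        _, shifted = generate_population(cfg2)
        male = base_p["gender"] == "male"
        np.testing.assert_allclose(
            shifted.loc[male, "pa_hours_week"],
            base_d.loc[male, "pa_hours_week"] + 2.0,
        )
        np.testing.assert_allclose(
            shifted.loc[~male, "pa_hours_week"],
            base_d.loc[~male, "pa_hours_week"],
        )


class TestSchoolFilter:
    def test_all_attend(self):
        p = make_participants(20, attends_school=True)
        out = apply_school_filter(p)
        pd.testing.assert_frame_equal(out, p)

    def test_none_attend(self):
        p = make_participants(20, attends_school=False)
        assert len(apply_school_filter(p)) == 0

    def test_order_preserved_and_aligned(self, small_population):
        p, d = small_population
        pf, df = apply_school_filter(p, d)
        assert pf["id"].is_monotonic_increasing
        assert (pf.index == df.index).all()

    def test_filtered_size_matches_binomial_expectation(self):
        """Mean filtered size over many seeds tracks n × attendance rate."""
        rate = 5035 / 6906
        n, n_seeds = 1000, 200
        sizes = []
        for seed in range(n_seeds):
            cfg = PopulationConfig(seed=seed, n_surveyed=n, n_clusters=20)
            p, _ = generate_population(cfg)
            sizes.append(len(apply_school_filter(p)))
        expected = n * rate
        se_mean = np.sqrt(n * rate * (1 - rate) / n_seeds)
        assert abs(np.mean(sizes) - expected) < 4 * se_mean


class TestMargins:
    def test_single_margin_scale_one_equals_counts(self):
        p = make_participants(50)
        (margin,) = generate_margins(p, ["gender"])
        counts = p["gender"].value_counts()
        for cat, total in margin.totals.items():
            assert total == counts[cat]

    def test_margins_share_grand_total(self, filtered_population):
        p, _ = filtered_population
        margins = generate_margins(
            p, ["district_gender", "ethnic_group"], population_total=278240
        )
        totals = [m.grand_total() for m in margins]
        assert all(abs(t - 278240) < 1e-9 * 278240 for t in totals)

    def test_unknown_margin_variable_raises(self):
        p = make_participants(10)
        with pytest.raises(SchemaError, match="favourite_sport"):
            generate_margins(p, ["favourite_sport"])

    def test_ethnic_group_priority(self):
        p = make_participants(3)
        p["eth_maori"] = [True, False, False]
        p["eth_pacific"] = [True, True, False]
        p["eth_european"] = [True, True, True]
        assert list(ethnic_group(p)) == ["maori", "pacific", "european"]

    def test_cross_variable_resolution(self):
        p = make_participants(10)
        crossed = margin_variable(p, "district_x_gender")
        assert crossed.str.contains(r"\|").all()
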