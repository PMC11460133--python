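"""Eligibility rules, effect application, scenarios, and the scorecard."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from schoolpa.exceptions import ConfigurationError, EffectSpecError
from schoolpa.interventions import (
    Effect,
    Eligibility,
    InterventionSpec,
    StrataOverride,
    apply_intervention,
    eligibility_mask,
    is_eligible,
    percent_change,
    rank_interventions,
    run_scenario,
)
from schoolpa.presets import (
    ELIGIBILITY_PRESETS,
    published_delta_frame,
)

from conftest import make_participants

DET_NAMES = ("pa_hours_week", "n_settings", "n_types",
             "physical_literacy", "social_support")


def _random_determinants(n, rng):
    return pd.DataFrame({
        "pa_hours_week": rng.gamma(2.0, 4.0, size=n),
        "n_settings": rng.integers(0, 10, size=n).astype(float),
        "n_types": rng.integers(0, 15, size=n).astype(float),
        "physical_literacy": rng.uniform(4, 20, size=n),
        "social_support": rng.uniform(5, 25, size=n),
    })


class TestEligibility:
    def test_age_restricted_preset_excludes_other_ages(self):
        spec = InterventionSpec("PL", ELIGIBILITY_PRESETS["PL"])
        row = {"attends_school": True, "takes_pe": True, "age": 15,
               "gender": "female"}
        assert not is_eligible(row, spec)
        row["age"] = 13
        assert is_eligible(row, spec)

    def test_pe_only_preset(self):
        spec = InterventionSpec("TAPE", ELIGIBILITY_PRESETS["TAPE"])
        row = {"attends_school": True, "takes_pe": False, "age": 15,
               "gender": "male"}
        assert not is_eligible(row, spec)
        row["takes_pe"] = True
        assert is_eligible(row, spec)

    def test_universal_preset_covers_every_attendee(self):
        p = make_participants(30)
        spec = InterventionSpec("NE", ELIGIBILITY_PRESETS["NE"])
        assert eligibility_mask(p, spec).all()

    def test_non_attendees_always_ineligible(self):
        p = make_participants(10, attends_school=False)
        for name, elig in ELIGIBILITY_PRESETS.items():
            spec = InterventionSpec(name, elig)
            assert not eligibility_mask(p, spec).any()


class TestApplyIntervention:
    def test_all_modes_none_is_identity(self):
        rng = np.random.default_rng(0)
        p = make_participants(20, rng=rng)
        det = _random_determinants(20, rng)
        spec = InterventionSpec(
            "noop", Eligibility(),
            effects={name: Effect("none") for name in DET_NAMES},
        )
        out = apply_intervention(det, p, spec)
        pd.testing.assert_frame_equal(out, det)

    def test_absolute_shift_applies_exactly(self):
        rng = np.random.default_rng(1)
        p = make_participants(30, rng=rng)
        det = _random_determinants(30, rng)
        spec = InterventionSpec(
            "shift", Eligibility(),
            effects={"pa_hours_week": Effect("absolute", 0.2)},
        )
        out = apply_intervention(det, p, spec)
        np.testing.assert_allclose(out["pa_hours_week"],
                                   det["pa_hours_week"] + 0.2)

    def test_input_not_mutated(self):
        rng = np.random.default_rng(2)
        p = make_participants(15, rng=rng)
        det = _random_determinants(15, rng)
        before = det.copy()
        spec = InterventionSpec(
            "shift", Eligibility(),
            effects={"social_support": Effect("relative", 0.1)},
        )
        apply_intervention(det, p, spec)
        pd.testing.assert_frame_equal(det, before)

    def test_age_restricted_preset_leaves_other_ages_bit_identical(self):
        rng = np.random.default_rng(3)
        p = make_participants(60, rng=rng)
        det = _random_determinants(60, rng)
        spec = InterventionSpec(
            "PL", ELIGIBILITY_PRESETS["PL"],
            effects={"n_types": Effect("absolute", 2.0)},
        )
        out = apply_intervention(det, p, spec)
        other = ~p["age"].between(13, 14).to_numpy()
        assert (out.loc[other] == det.loc[other]).all().all()

    def test_clamp_rounds_counts_and_respects_bounds(self):
        p = make_participants(4)
        det = _random_determinants(4, np.random.default_rng(4))
        det["n_settings"] = [9.0, 2.0, 0.0, 5.0]
        spec = InterventionSpec(
            "cap", Eligibility(),
            effects={"n_settings": Effect("relative", 0.25, clamp=True)},
        )
        out = apply_intervention(det, p, spec)
        values = out["n_settings"].to_numpy()
        assert np.array_equal(values, np.round(values))
        assert values.max() <= 10
        # 2 * 1.25 = 2.5 rounds half away from zero to 3
        assert values[1] == 3.0

    def test_strata_override_supersedes_base_value(self):
        p = make_participants(40, rng=np.random.default_rng(5))
        det = _random_determinants(40, np.random.default_rng(5))
        spec = InterventionSpec(
            "strat", Eligibility(),
            effects={"pa_hours_week": Effect(
                "absolute", 1.0,
                strata_overrides=(StrataOverride(3.0, genders=("male",)),),
            )},
        )
        out = apply_intervention(det, p, spec)
        male = (p["gender"] == "male").to_numpy()
        np.testing.assert_allclose(
            out.loc[male, "pa_hours_week"],
            det.loc[male, "pa_hours_week"] + 3.0)
        np.testing.assert_allclose(
            out.loc[~male, "pa_hours_week"],
            det.loc[~male, "pa_hours_week"] + 1.0)

    def test_unknown_determinant_rejected(self):
        p = make_participants(5)
        det = _random_determinants(5, np.random.default_rng(6))
        spec = InterventionSpec(
            "bad", Eligibility(), effects={"bmi": Effect("absolute", 1.0)}
        )
        with pytest.raises(EffectSpecError, match="bmi"):
            apply_intervention(det, p, spec)

    @given(
        seed=st.integers(0, 10_000),
        pe_only=st.booleans(),
        lo=st.integers(12, 17),
        span=st.integers(0, 5),
        mode=st.sampled_from(["absolute", "relative"]),
        value=st.floats(-0.5, 3.0),
        clamp=st.booleans(),
    )
    def test_ineligible_vectors_bit_identical_under_random_specs(
        self, seed, pe_only, lo, span, mode, value, clamp
    ):
        rng = np.random.default_rng(seed)
        p = make_participants(50, rng=rng)
        p["attends_school"] = rng.uniform(size=50) < 0.8
        det = _random_determinants(50, rng)
        hi = min(lo + span, 17)
        spec = InterventionSpec(
            "rand", Eligibility(pe_only=pe_only, age_range=(lo, hi)),
            effects={name: Effect(mode, value, clamp=clamp)
                     for name in DET_NAMES},
        )
        out = apply_intervention(det, p, spec)
        mask = eligibility_mask(p, spec)
        assert (out.loc[~mask] == det.loc[~mask]).all().all()


class TestScenario:
    def test_null_intervention_yields_zero_deltas(self):
        rng = np.random.default_rng(7)
        p = make_participants(80, rng=rng)
        det = _random_determinants(80, rng)
        spec = InterventionSpec("noop", Eligibility())
        res = run_scenario(p, det, np.ones(80), spec)
        assert all(d == 0.0 for d in res.delta.values())
        assert all(c == 0.0 for c in res.percent_change.values())

    def test_fully_eligible_absolute_effect_recovers_exactly(self):
        rng = np.random.default_rng(8)
        p = make_participants(100, rng=rng)
        det = _random_determinants(100, rng)
        spec = InterventionSpec(
            "full", Eligibility(),
            effects={"pa_hours_week": Effect("absolute", 0.7)},
        )
        res = run_scenario(p, det, rng.uniform(0.5, 2, 100), spec)
        assert res.eligible_weight_share == pytest.approx(1.0)
        assert res.delta["pa_hours_week"] == pytest.approx(0.7, abs=1e-9)

    def test_partial_eligibility_effect_recovery(self):
        """delta / eligible_weight_share returns the configured effect."""
        rng = np.random.default_rng(9)
        p = make_participants(200, rng=rng)
        det = _random_determinants(200, rng)
        w = rng.uniform(0.5, 2.0, size=200)
        spec = InterventionSpec(
            "partial", Eligibility(age_range=(13, 14)),
            effects={"pa_hours_week": Effect("absolute", 1.3)},
        )
        res = run_scenario(p, det, w, spec)
        share = res.eligible_weight_share
        assert 0 < share < 1
        assert res.delta["pa_hours_week"] / share == pytest.approx(
            1.3, abs=1e-9)

    def test_clamped_effect_recovers_at_most_configured(self):
        rng = np.random.default_rng(10)
        p = make_participants(200, rng=rng)
        det = _random_determinants(200, rng)
        spec = InterventionSpec(
            "clamped", Eligibility(),
            effects={"physical_literacy": Effect("absolute", 3.0,
                                                 clamp=True)},
        )
        res = run_scenario(p, det, np.ones(200), spec)
        assert res.delta["physical_literacy"] <= 3.0 + 1e-12


class TestPercentChange:
    def test_simple_cases(self):
        assert percent_change(10.0, 10.5) == pytest.approx(5.0)
        assert percent_change(4.2, 4.2) == 0.0

    def test_inverts_relative_definition(self):
        base = 16.49
        assert percent_change(base, base * 1.036) == pytest.approx(
            3.6, abs=1e-9)

    def test_zero_baseline_rejected(self):
        with pytest.raises(ConfigurationError):
            percent_change(0.0, 1.0)


class TestScorecard:
    def test_published_improvements_rank_as_published(self):
        deltas = published_delta_frame()
        ranks = rank_interventions(deltas)
        expected = pd.DataFrame(
            {
                "TAPE": [2, 2, 3, 3, 3],
                "PL": [4, 4, 2, 1, 2],
                "PAL": [3, 3, 4, 2, 1],
                "NE": [1, 1, 1, 4, 4],
            },
            index=["pa_hours_week", "n_settings", "n_types",
                   "physical_literacy", "social_support"],
        )
        pd.testing.assert_frame_equal(ranks.astype(int), expected)

    def test_rows_are_permutations(self):
        rng = np.random.default_rng(11)
        deltas = pd.DataFrame(rng.normal(size=(5, 4)),
                              index=list(DET_NAMES),
                              columns=["a", "b", "c", "d"])
        ranks = rank_interventions(deltas)
        for _, row in ranks.iterrows():
            assert sorted(row) == [1, 2, 3, 4]

    def test_ranks_decrease_with_delta(self):
        deltas = pd.DataFrame(
            {"a": [0.3], "b": [0.1], "c": [0.2]}, index=["pa_hours_week"]
        )
        ranks = rank_interventions(deltas)
        assert list(ranks.loc["pa_hours_week", ["a", "c", "b"]]) == [1, 2, 3]

    def test_ties_break_by_name(self):
        deltas = pd.DataFrame(
            {"z": [1.0], "a": [1.0], "m": [1.0]}, index=["n_types"]
        )
        ranks = rank_interventions(deltas)
        assert ranks.loc["n_types", "a"] == 1
        assert ranks.loc["n_types", "m"] == 2
        assert ranks.loc["n_types", "z"] == 3
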