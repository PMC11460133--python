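"""Shipped intervention presets.

Four secondary-school interventions are modelled:

TAPE  Technologically augmented physical education — teacher training to
      bring internet/technology-based learning into PE classes; reaches
      PE students only.
PL    Peer-led mentoring — older peers mentor 13–14-year-olds to try new
      activity types; reaches 13–14-year-olds only.
PAL   Physically active learning — PA integrated into curriculum teaching;
      reaches all secondary-school students.
NE    Natural environment — a dedicated nature-inclusive play area;
      reaches all secondary-school students.

Two effect presets are provided.  The ``published`` preset back-solves the
published population-level changes (e.g. NE +0.2 h/week; PAL social support
+5%) into per-eligible-participant absolute effects by dividing each
aggregate delta by the intervention's eligible weight share, so that
applying the preset to any population reproduces those aggregate changes
exactly; it is constructed with clamping off so the inversion is exact.
The per-participant effect sizes underlying the original analysis are not
published, so this preset validates the apply/estimate/rank pipeline rather
than asserting micro-level truth.  The ``illustrative`` preset uses round
numbers for tutorials and property tests.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd

from .costing import CostComponent, CostInputs
from .exceptions import ConfigurationError
from .interventions import (
    Effect,
    Eligibility,
    InterventionSpec,
    eligible_weight_share,
)

INTERVENTIONS = ("TAPE", "PL", "PAL", "NE")

ELIGIBILITY_PRESETS: dict[str, Eligibility] = {
    "TAPE": Eligibility(pe_only=True),
    "PL": Eligibility(age_range=(13, 14)),
    "PAL": Eligibility(),
    "NE": Eligibility(),
}

#: Published population-level changes: absolute for the three unit-scale
#: determinants (h/week, settings/week, types/week) and percent of the
#: baseline mean for the two bounded scores.
PUBLISHED_UNIT_DELTAS: dict[str, dict[str, float]] = {
    "TAPE": {"pa_hours_week": 0.08, "n_settings": 1.29, "n_types": 0.34},
    "PL": {"pa_hours_week": -0.06, "n_settings": 0.73, "n_types": 1.05},
    "PAL": {"pa_hours_week": 0.05, "n_settings": 1.21, "n_types": 0.15},
    "NE": {"pa_hours_week": 0.20, "n_settings": 1.75, "n_types": 1.57},
}
PUBLISHED_PERCENT_DELTAS: dict[str, dict[str, float]] = {
    "TAPE": {"physical_literacy": 0.43, "social_support": 1.46},
    "PL": {"physical_literacy": 3.6, "social_support": 1.9},
    "PAL": {"physical_literacy": 3.3, "social_support": 5.0},
    "NE": {"physical_literacy": 0.12, "social_support": 0.57},
}

COST_PRESETS: dict[str, CostInputs] = {
    "TAPE": CostInputs(
        components=(CostComponent(
            "teacher online workshops, resources and mentor support",
            8064.82, "AUD", 2020,
        ),),
        published_per_student=10.25,
    ),
    "PL": CostInputs(
        components=(CostComponent(
            "facilitator training, materials and implementation",
            2520.0, "GBP", 2019,
        ),),
        published_per_student=7.18,
    ),
    "PAL": CostInputs(
        components=(
            CostComponent("teacher training", 910.0, "GBP", 2019),
            CostComponent("school resources", 180.0, "USD", 2011),
        ),
        published_per_student=2.98,
    ),
    "NE": CostInputs(
        components=(CostComponent(
            "schoolyard greening design and implementation",
            50000.0, "EUR", 2021,
        ),),
        published_per_student=119.40,
    ),
}


def published_delta_specs(
    participants: pd.DataFrame,
    weights,
    baseline_means: Mapping[str, float],
) -> list[InterventionSpec]:
    """Build the ``published`` preset for a given (filtered) population.

    Each aggregate delta d becomes a per-eligible absolute effect
    d / eligible_weight_share; percent score changes are first converted to
    mean deltas against the supplied baseline means.
    """
    specs = []
    for name in INTERVENTIONS:
        elig = ELIGIBILITY_PRESETS[name]
        probe = InterventionSpec(name=name, eligibility=elig)
        share = eligible_weight_share(participants, weights, probe)
        if share <= 0:
            raise ConfigurationError(
                f"intervention {name!r} reaches no one in this population"
            )
        effects: dict[str, Effect] = {}
        for det, delta in PUBLISHED_UNIT_DELTAS[name].items():
            effects[det] = Effect(
                mode="absolute", value=delta / share, clamp=False
            )
        for det, pct in PUBLISHED_PERCENT_DELTAS[name].items():
            delta = pct / 100.0 * baseline_means[det]
            effects[det] = Effect(
                mode="absolute", value=delta / share, clamp=False
            )
        specs.append(InterventionSpec(
            name=name, eligibility=elig, effects=effects,
            cost_inputs=COST_PRESETS[name],
        ))
    return specs


def illustrative_specs() -> list[InterventionSpec]:
    """Round-number effect preset for tutorials and tests: absolute changes
    on the unit determinants, relative changes (clamped) on the scores."""
    specs = []
    round_effects = {
        "TAPE": (0.25, 1, 1, 0.01, 0.01),
        "PL": (-0.10, 1, 1, 0.04, 0.02),
        "PAL": (0.10, 1, 0, 0.03, 0.05),
        "NE": (0.25, 2, 2, 0.01, 0.01),
    }
    for name in INTERVENTIONS:
        h, s, t, lit, sup = round_effects[name]
        specs.append(InterventionSpec(
            name=name,
            eligibility=ELIGIBILITY_PRESETS[name],
            effects={
                "pa_hours_week": Effect("absolute", h, clamp=True),
                "n_settings": Effect("absolute", float(s), clamp=True),
                "n_types": Effect("absolute", float(t), clamp=True),
                "physical_literacy": Effect("relative", lit, clamp=True),
                "social_support": Effect("relative", sup, clamp=True),
            },
            cost_inputs=COST_PRESETS[name],
        ))
    return specs


def published_delta_frame() -> pd.DataFrame:
    """Determinant × intervention frame of the published aggregate changes
    (units for the first three determinants, percent for the scores) — the
    quantities the scorecard ranks."""
    rows = {}
    for name in INTERVENTIONS:
        rows[name] = {**PUBLISHED_UNIT_DELTAS[name],
                      **PUBLISHED_PERCENT_DELTAS[name]}
    frame = pd.DataFrame(rows)
    return frame.astype(float)
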