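"""Intervention eligibility, effect application and scenario comparison.

An intervention is described by an eligibility rule (PE students only,
and/or an age range, always restricted to school attendees) and one effect
per determinant.  Effects are *absolute* (added in determinant units) or
*relative* (multiplicative fraction), may be overridden for age/gender
strata, and may be clamped onto the determinant's valid range (with counts
rounded to the nearest integer, half away from zero).  Scenario results
compare design-based baseline and post-intervention estimates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .config import DETERMINANTS
from .estimation import SurveyEstimate, estimate_mean, weighted_mean
from .exceptions import ConfigurationError, EffectSpecError

#: Determinants stored as integer counts.
COUNT_DETERMINANTS = frozenset({"n_settings", "n_types"})

#: Valid ranges used when an effect requests clamping.
DEFAULT_BOUNDS: dict[str, tuple[float, float]] = {
    "pa_hours_week": (0.0, math.inf),
    "n_settings": (0.0, 10.0),
    "n_types": (0.0, 20.0),
    "physical_literacy": (4.0, 20.0),
    "social_support": (5.0, 25.0),
}


@dataclass(frozen=True)
class StrataOverride:
    """Replacement effect value for an age range and/or gender set."""

    value: float
    age_range: tuple[int, int] | None = None
    genders: tuple[str, ...] | None = None


@dataclass(frozen=True)
class Effect:
    mode: str = "none"  # "absolute" | "relative" | "none"
    value: float = 0.0
    strata_overrides: tuple[StrataOverride, ...] = ()
    clamp: bool = False

    def validate(self, determinant: str) -> None:
        if self.mode not in ("absolute", "relative", "none"):
            raise EffectSpecError(
                f"effect on {determinant!r}: unknown mode {self.mode!r}"
            )
        if self.mode == "relative" and self.value <= -1.0:
            raise EffectSpecError(
                f"relative effect on {determinant!r} must be > -1"
            )
        for ov in self.strata_overrides:
            if ov.age_range is not None:
                lo, hi = ov.age_range
                if not (12 <= lo <= hi <= 17):
                    raise EffectSpecError(
                        f"override on {determinant!r}: age range "
                        f"{ov.age_range} outside 12-17"
                    )
            if ov.genders is not None:
                bad = set(ov.genders) - {"male", "female", "diverse"}
                if bad:
                    raise EffectSpecError(
                        f"override on {determinant!r}: unknown genders {bad}"
                    )


@dataclass(frozen=True)
class Eligibility:
    pe_only: bool = False
    age_range: tuple[int, int] | None = None  # inclusive; None = all ages


@dataclass
class InterventionSpec:
    name: str
    eligibility: Eligibility = field(default_factory=Eligibility)
    effects: dict[str, Effect] = field(default_factory=dict)
    cost_inputs: object | None = None  # costing.CostInputs

    def validate(self) -> None:
        unknown = set(self.effects) - set(DETERMINANTS)
        if unknown:
            raise EffectSpecError(
                f"intervention {self.name!r} targets unknown determinants "
                f"{sorted(unknown)}"
            )
        for det, eff in self.effects.items():
            eff.validate(det)


@dataclass
class ScenarioResult:
    intervention: str
    baseline: dict[str, SurveyEstimate]
    post: dict[str, SurveyEstimate]
    delta: dict[str, float]
    percent_change: dict[str, float]
    eligible_weight_share: float

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for name in DETERMINANTS:
            b, p = self.baseline[name], self.post[name]
            rows.append({
                "scenario": self.intervention, "determinant": name,
                "n": p.n, "baseline_mean": b.mean, "mean": p.mean,
                "se": p.se, "ci_low": p.ci_low, "ci_high": p.ci_high,
                "delta": self.delta[name],
                "percent_change": self.percent_change[name],
                "eligible_weight_share": self.eligible_weight_share,
            })
        return pd.DataFrame(rows)


# ----------------------------------------------------------------------

def eligibility_mask(
    participants: pd.DataFrame, spec: InterventionSpec
) -> np.ndarray:
    """Boolean eligibility per participant under the spec's rule."""
    mask = participants["attends_school"].to_numpy().astype(bool).copy()
    if spec.eligibility.pe_only:
        mask &= participants["takes_pe"].to_numpy().astype(bool)
    if spec.eligibility.age_range is not None:
        lo, hi = spec.eligibility.age_range
        age = participants["age"].to_numpy()
        mask &= (age >= lo) & (age <= hi)
    return mask


def is_eligible(participant: Mapping, spec: InterventionSpec) -> bool:
    """Scalar convenience wrapper around :func:`eligibility_mask`."""
    row = pd.DataFrame([dict(participant)])
    return bool(eligibility_mask(row, spec)[0])


def _round_half_away(values: np.ndarray) -> np.ndarray:
    return np.sign(values) * np.floor(np.abs(values) + 0.5)


def apply_intervention(
    determinants: pd.DataFrame,
    participants: pd.DataFrame,
    spec: InterventionSpec,
    bounds: Mapping[str, tuple[float, float]] | None = None,
) -> pd.DataFrame:
    """Return post-intervention determinant vectors.

    Eligible participants have each targeted determinant shifted per the
    effect spec; ineligible participants' vectors are returned bit-identical.
    The input frame is never mutated.
    """
    spec.validate()
    if bounds is None:
        bounds = DEFAULT_BOUNDS
    if len(determinants) != len(participants):
        raise ConfigurationError("determinants and participants must align")
    out = determinants.copy()
    eligible = eligibility_mask(participants, spec)
    if not eligible.any():
        return out
    age = participants["age"].to_numpy()[eligible]
    gender = participants["gender"].to_numpy()[eligible]

    for det, eff in spec.effects.items():
        if eff.mode == "none":
            continue
        y = out[det].to_numpy(dtype=float).copy()
        v = np.full(eligible.sum(), eff.value, dtype=float)
        for ov in eff.strata_overrides:
            sel = np.ones(len(v), dtype=bool)
            if ov.age_range is not None:
                sel &= (age >= ov.age_range[0]) & (age <= ov.age_range[1])
            if ov.genders is not None:
                sel &= np.isin(gender, ov.genders)
            v[sel] = ov.value
        ye = y[eligible]
        ye = ye + v if eff.mode == "absolute" else ye * (1.0 + v)
        if eff.clamp:
            lo, hi = bounds.get(det, (-math.inf, math.inf))
            if det in COUNT_DETERMINANTS:
                ye = _round_half_away(ye)
            ye = np.clip(ye, lo, hi)
        y[eligible] = ye
        out[det] = y
    return out


def percent_change(baseline_mean: float, post_mean: float) -> float:
    """Relative change of the population mean, in percent of baseline."""
    if baseline_mean == 0:
        raise ConfigurationError(
            "percent change undefined for a zero baseline mean"
        )
    return 100.0 * (post_mean - baseline_mean) / baseline_mean


def eligible_weight_share(
    participants: pd.DataFrame, weights, spec: InterventionSpec
) -> float:
    """Weighted share of the (filtered) population the intervention reaches."""
    w = np.asarray(weights, dtype=float)
    mask = eligibility_mask(participants, spec)
    return float(w[mask].sum() / w.sum())


def run_scenario(
    participants: pd.DataFrame,
    determinants: pd.DataFrame,
    weights,
    spec: InterventionSpec,
    level: float = 0.95,
    bounds: Mapping[str, tuple[float, float]] | None = None,
) -> ScenarioResult:
    """Apply one intervention and compare post vs baseline estimates."""
    post_det = apply_intervention(determinants, participants, spec, bounds)
    clusters = participants["cluster_id"].to_numpy()
    w = np.asarray(weights, dtype=float)
    baseline, post, delta, pct = {}, {}, {}, {}
    for name in DETERMINANTS:
        b = estimate_mean(determinants[name], w, clusters, level)
        p = estimate_mean(post_det[name], w, clusters, level)
        baseline[name], post[name] = b, p
        delta[name] = p.mean - b.mean
        pct[name] = percent_change(b.mean, p.mean)
    return ScenarioResult(
        intervention=spec.name,
        baseline=baseline,
        post=post,
        delta=delta,
        percent_change=pct,
        eligible_weight_share=eligible_weight_share(participants, w, spec),
    )


def rank_interventions(deltas: pd.DataFrame) -> pd.DataFrame:
    """Scorecard ranking interventions per determinant.

    ``deltas`` is a determinant × intervention frame of improvements; rank 1
    marks the largest improvement.  Ties are broken by intervention name in
    lexicographic order so the scorecard is deterministic.
    """
    if deltas.shape[1] < 2:
        raise ConfigurationError("ranking needs at least two interventions")
    if not np.isfinite(deltas.to_numpy(dtype=float)).all():
        raise ConfigurationError("deltas must be finite")
    ranks = pd.DataFrame(index=deltas.index, columns=deltas.columns,
                         dtype=int)
    for det, row in deltas.iterrows():
        order = sorted(row.index, key=lambda name: (-row[name], name))
        for pos, name in enumerate(order, start=1):
            ranks.loc[det, name] = pos
    return ranks
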