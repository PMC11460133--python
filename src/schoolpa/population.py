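"""Synthetic adolescent survey population.

Generates microdata emulating a national youth physical-activity survey:
sociodemographics with the analytic sample's composition, a cluster design
nested in districts, PE participation by year group, and five determinants of
future physical activity calibrated so the national (weighted) baselines land
on the published estimates.

Determinant values are drawn by *jittered systematic* inverse-CDF sampling:
each participant receives one uniform stratum ``(rank + U) / n`` from a random
permutation of ``0..n-1``.  The empirical distribution therefore tracks the
target distribution much more tightly than i.i.d. sampling would (a standard
variance-reduction device when constructing synthetic populations that must
match national estimates), while the random permutation keeps between-cluster
variability essentially identical to multinomial sampling — so cluster-robust
variance estimation on the synthetic data remains realistic.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .config import DETERMINANTS, DeterminantModel, PopulationConfig
from .exceptions import ConfigurationError, SchemaError

#: Priority order used to collapse multi-select ethnicity into one
#: mutually exclusive "ethnic_group" for raking margins, mirroring the
#: prioritised-ethnicity output convention used in NZ official statistics.
ETHNICITY_PRIORITY = ("maori", "pacific", "asian", "other", "european")

PARTICIPANT_COLUMNS = [
    "id", "district", "cluster_id", "age", "gender", "disability",
    "deprivation", "attends_school", "takes_pe", "base_weight",
]


@dataclass(frozen=True)
class MarginTable:
    """Known population totals for one raking margin.

    variable:
        name of the (possibly derived) categorical variable, e.g.
        ``district_gender`` or ``ethnic_group``.
    totals:
        mapping category -> positive population total.
    """

    variable: str
    totals: dict[str, float]

    def grand_total(self) -> float:
        return float(sum(self.totals.values()))


# ----------------------------------------------------------------------
# Determinant marginal calibration
# ----------------------------------------------------------------------

def _truncated_poisson_mean(lam: float, upper: float) -> float:
    if not np.isfinite(upper):
        return lam
    k = np.arange(0, int(upper) + 1)
    pmf = stats.poisson.pmf(k, lam)
    return float((k * pmf).sum() / pmf.sum())


def _calibrate_poisson(model: DeterminantModel) -> float:
    """Rate lambda whose truncation at ``upper`` has the target mean."""
    target = model.mean
    if not np.isfinite(model.upper):
        return target
    lo, hi = 1e-6, max(4.0 * target, target + 5.0)
    return float(optimize.brentq(
        lambda lam: _truncated_poisson_mean(lam, model.upper) - target,
        lo, hi, xtol=1e-12,
    ))


def _truncnorm_params(mu: float, sd: float, lower: float, upper: float):
    a = (lower - mu) / sd
    b = (upper - mu) / sd
    return a, b


def _calibrate_truncnorm(model: DeterminantModel) -> float:
    """Location mu whose [lower, upper]-truncation has the target mean."""
    def gap(mu: float) -> float:
        a, b = _truncnorm_params(mu, model.sd, model.lower, model.upper)
        return stats.truncnorm.mean(a, b, loc=mu, scale=model.sd) - model.mean

    lo = model.lower - 2.0 * model.sd
    hi = model.upper + 8.0 * model.sd
    return float(optimize.brentq(gap, lo, hi, xtol=1e-12))


def _systematic_uniforms(n: int, rng: np.random.Generator) -> np.ndarray:
    """One jittered stratified uniform per participant, randomly assigned."""
    u = (rng.permutation(n) + rng.uniform(size=n)) / n
    return np.clip(u, 1e-12, 1.0 - 1e-12)


def _draw_determinant(
    model: DeterminantModel,
    u: np.ndarray,
    cluster_effect: np.ndarray,
) -> np.ndarray:
    """Inverse-CDF draw with an additive cluster-level mean shift."""
    if model.kind == "gamma":
        shape = (model.mean / model.sd) ** 2
        scale = model.sd ** 2 / model.mean
        values = stats.gamma.ppf(u, shape, scale=scale) + cluster_effect
        return np.maximum(values, 0.0)
    if model.kind == "poisson":
        lam0 = _calibrate_poisson(model)
        lam = np.maximum(lam0 + cluster_effect, 1e-9)
        if np.isfinite(model.upper):
            cap = stats.poisson.cdf(model.upper, lam)
            return stats.poisson.ppf(u * cap, lam)
        return stats.poisson.ppf(u, lam)
    if model.kind == "truncnorm":
        mu0 = _calibrate_truncnorm(model)
        mu = mu0 + cluster_effect
        a, b = _truncnorm_params(mu, model.sd, model.lower, model.upper)
        return stats.truncnorm.ppf(u, a, b, loc=mu, scale=model.sd)
    raise ConfigurationError(f"unknown determinant kind {model.kind!r}")


# ----------------------------------------------------------------------
# Population generation
# ----------------------------------------------------------------------

def _draw_categorical(
    dist: Mapping, n: int, rng: np.random.Generator
) -> np.ndarray:
    cats = list(dist.keys())
    probs = np.asarray([dist[c] for c in cats], dtype=float)
    probs = probs / probs.sum()  # guard rounding at the 1e-9 tolerance
    idx = rng.choice(len(cats), size=n, p=probs)
    return np.asarray(cats, dtype=object)[idx]


def generate_population(
    config: PopulationConfig,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate the synthetic survey.

    Returns
    -------
    participants : DataFrame
        One row per surveyed adolescent with sociodemographics, cluster
        design fields, ``eth_<label>`` multi-select indicators, PE status
        and unit base weights.
    determinants : DataFrame
        One row per participant with the five determinant values, aligned
        with ``participants`` by position and index.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_surveyed

    cluster_id = rng.integers(0, config.n_clusters, size=n)
    # Clusters are nested in districts by construction.
    cluster_to_district = rng.integers(0, config.n_districts,
                                       size=config.n_clusters)
    district = cluster_to_district[cluster_id]

    age = _draw_categorical(config.age_distribution, n, rng).astype(int)
    gender = _draw_categorical(config.gender_distribution, n, rng)
    deprivation = _draw_categorical(config.deprivation_distribution, n, rng)
    disability = rng.uniform(size=n) < config.disability_rate
    attends_school = rng.uniform(size=n) < config.school_attendance_rate

    # Multi-select ethnicity: independent Bernoulli per label, with the
    # fallback label (European) forced on when a draw yields an empty set —
    # an empty ethnicity set is not observable in the survey.  The fallback
    # label's Bernoulli rate is back-solved so that its *observed* marginal
    # (own draws plus forced assignments) still hits the configured target.
    eth_labels = list(config.ethnicity_rates.keys())
    fallback = "european" if "european" in eth_labels else eth_labels[0]
    others = [lab for lab in eth_labels if lab != fallback]
    eth = {
        lab: rng.uniform(size=n) < config.ethnicity_rates[lab]
        for lab in others
    }
    q_empty = float(np.prod(
        [1.0 - config.ethnicity_rates[lab] for lab in others]
    ))
    target = config.ethnicity_rates[fallback]
    adj = ((target - q_empty) / (1.0 - q_empty) if q_empty < 1.0
           else target)
    eth[fallback] = rng.uniform(size=n) < min(max(adj, 0.0), 1.0)
    none_selected = ~np.logical_or.reduce(
        [eth[lab] for lab in eth_labels]
    )
    if none_selected.any():
        eth[fallback] = eth[fallback] | none_selected

    pe_rate = np.asarray(
        [config.pe_participation_by_age[a] for a in age], dtype=float
    )
    takes_pe = rng.uniform(size=n) < pe_rate

    participants = pd.DataFrame({
        "id": np.arange(n),
        "district": pd.array([f"D{d:02d}" for d in district], dtype=object),
        "cluster_id": pd.array([f"C{c:03d}" for c in cluster_id],
                               dtype=object),
        "age": age,
        "gender": gender,
        "disability": disability,
        "deprivation": deprivation,
        "attends_school": attends_school,
        "takes_pe": takes_pe,
        "base_weight": np.ones(n),
    })
    for lab in eth_labels:
        participants[f"eth_{lab}"] = eth[lab]

    cols = {}
    for name in DETERMINANTS:
        model = config.determinant_targets[name]
        b = (rng.normal(0.0, model.cluster_sd, size=config.n_clusters)
             if model.cluster_sd > 0 else np.zeros(config.n_clusters))
        u = _systematic_uniforms(n, rng)
        values = _draw_determinant(model, u, b[cluster_id])
        values = _apply_strata_shifts(values, name, config, participants)
        cols[name] = values
    determinants = pd.DataFrame(cols, index=participants.index)
    return participants, determinants


def _apply_strata_shifts(
    values: np.ndarray,
    name: str,
    config: PopulationConfig,
    participants: pd.DataFrame,
) -> np.ndarray:
    """Optional additive sociodemographic shifts (defaults: none)."""
    shifts = config.strata_shifts.get(name)
    if not shifts:
        return values
    model = config.determinant_targets[name]
    out = values.astype(float).copy()
    for variable, table in shifts.items():
        if variable not in participants.columns:
            raise SchemaError(
                f"strata_shifts[{name}] references unknown variable "
                f"{variable!r}"
            )
        col = participants[variable].to_numpy()
        for category, delta in table.items():
            out[col == category] += delta
    out = np.clip(out, model.lower, model.upper)
    if model.kind == "poisson":
        out = np.round(out)
    return out


def apply_school_filter(
    participants: pd.DataFrame,
    determinants: pd.DataFrame | None = None,
):
    """Restrict to adolescents enrolled in a secondary school or Kura
    Kaupapa, preserving order.

    With ``determinants`` given, returns the aligned pair of filtered
    frames; otherwise returns the filtered participants only.
    """
    mask = participants["attends_school"].to_numpy().astype(bool)
    filtered = participants.loc[mask]
    if determinants is None:
        return filtered
    return filtered, determinants.loc[mask]


# ----------------------------------------------------------------------
# Derived margin variables and margin tables
# ----------------------------------------------------------------------

def ethnic_group(participants: pd.DataFrame) -> pd.Series:
    """Single-select primary ethnic group from the multi-select indicators.

    Applies the fixed priority Māori > Pacific > Asian > Other > European so
    that raking margins partition the population.
    """
    eth_cols = [c for c in participants.columns if c.startswith("eth_")]
    if not eth_cols:
        raise SchemaError("no eth_<label> indicator columns present")
    labels = [c[len("eth_"):] for c in eth_cols]
    prioritized = [lab for lab in ETHNICITY_PRIORITY if lab in labels]
    prioritized += [lab for lab in labels if lab not in prioritized]
    out = pd.Series("", index=participants.index, dtype=object)
    for lab in reversed(prioritized):
        out[participants[f"eth_{lab}"].astype(bool)] = lab
    if (out == "").any():
        raise SchemaError("participant with empty ethnicity set")
    return out


_DERIVED_VARIABLES: dict[str, Callable[[pd.DataFrame], pd.Series]] = {
    "ethnic_group": ethnic_group,
    "district_gender": lambda p: (
        p["district"].astype(str) + "|" + p["gender"].astype(str)
    ),
}


def margin_variable(participants: pd.DataFrame, variable: str) -> pd.Series:
    """Resolve a margin variable: a participant column, a derived variable,
    or a ``a_x_b`` cross of two columns."""
    if variable in participants.columns:
        return participants[variable].astype(str)
    if variable in _DERIVED_VARIABLES:
        return _DERIVED_VARIABLES[variable](participants).astype(str)
    if "_x_" in variable:
        left, right = variable.split("_x_", 1)
        return (margin_variable(participants, left) + "|"
                + margin_variable(participants, right))
    raise SchemaError(
        f"margin variable {variable!r} is not a participant column or a "
        "derived variable"
    )


def generate_margins(
    participants: pd.DataFrame,
    margin_definitions: Sequence[str],
    population_total: float | None = None,
    perturb: Mapping[str, Mapping[str, float]] | None = None,
) -> list[MarginTable]:
    """Build "known population" margin tables from the filtered sample.

    Observed category counts are scaled to a common ``population_total``
    (default: the sample size itself, scale 1).  ``perturb`` optionally
    applies multiplicative distortions per category before renormalising to
    the common total — useful for exercising raking with margins that the
    base weights do not already satisfy.
    """
    if len(participants) == 0:
        raise SchemaError("cannot build margins from an empty population")
    if population_total is None:
        population_total = float(len(participants))
    margins = []
    for variable in margin_definitions:
        values = margin_variable(participants, variable)
        counts = values.value_counts().sort_index()
        totals = counts.astype(float)
        if perturb and variable in perturb:
            for category, factor in perturb[variable].items():
                if category not in totals.index:
                    raise SchemaError(
                        f"perturbation references unknown category "
                        f"{category!r} of margin {variable!r}"
                    )
                totals[category] *= factor
        totals = totals * (population_total / totals.sum())
        margins.append(
            MarginTable(variable=variable, totals=totals.to_dict())
        )
    return margins


# ----------------------------------------------------------------------
# CSV I/O
# ----------------------------------------------------------------------

def write_population_csv(
    path,
    participants: pd.DataFrame,
    determinants: pd.DataFrame,
    weights: np.ndarray | None = None,
) -> None:
    out = participants.copy()
    out["weight"] = (weights if weights is not None
                     else participants["base_weight"].to_numpy())
    for name in DETERMINANTS:
        out[name] = determinants[name].to_numpy()
    out.to_csv(path, index=False)


def read_population_csv(path) -> tuple[pd.DataFrame, pd.DataFrame, np.ndarray]:
    df = pd.read_csv(path)
    missing = [c for c in PARTICIPANT_COLUMNS + list(DETERMINANTS)
               if c not in df.columns]
    if missing:
        raise SchemaError(f"population CSV missing columns {missing}")
    determinants = df[list(DETERMINANTS)].copy()
    weights = (df["weight"] if "weight" in df.columns
               else df["base_weight"]).to_numpy(dtype=float)
    participants = df.drop(
        columns=[c for c in list(DETERMINANTS) + ["weight"]
                 if c in df.columns]
    )
    return participants, determinants, weights


def write_margins_csv(path, margins: Sequence[MarginTable]) -> None:
    rows = [
        {"variable": m.variable, "category": cat, "total": tot}
        for m in margins for cat, tot in sorted(m.totals.items())
    ]
    pd.DataFrame(rows, columns=["variable", "category", "total"]).to_csv(
        path, index=False
    )


def read_margins_csv(path) -> list[MarginTable]:
    df = pd.read_csv(path)
    margins = []
    for variable, grp in df.groupby("variable", sort=False):
        margins.append(MarginTable(
            variable=str(variable),
            totals=dict(zip(grp["category"].astype(str), grp["total"])),
        ))
    return margins
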