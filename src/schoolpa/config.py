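"""Configuration objects for the synthetic population and the full pipeline.

All distributions and rates are explicit so that a run is fully specified by
(config, seed).  Defaults describe the analytic sample the model emulates: a
national survey of 6,906 New Zealand adolescents aged 12-17, of whom 5,035
attended a secondary school or Kura Kaupapa and enter the analysis.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from typing import Any, Mapping, Sequence

import yaml

from .exceptions import ConfigurationError

#: Canonical determinant order used across the package.
DETERMINANTS = (
    "pa_hours_week",
    "n_settings",
    "n_types",
    "physical_literacy",
    "social_support",
)

#: Human-readable labels for tables and figures.
DETERMINANT_LABELS = {
    "pa_hours_week": "Current weekly PA duration (h/week)",
    "n_settings": "Current number of PA settings (per week)",
    "n_types": "Current number of PA types (per week)",
    "physical_literacy": "Current physical literacy score",
    "social_support": "Current social support for PA score",
}

_PROB_TOL = 1e-9


@dataclass(frozen=True)
class DeterminantModel:
    """Marginal model for one determinant of future physical activity.

    kind:
        "gamma"     non-negative continuous (weekly PA hours),
        "poisson"   count truncated at ``upper`` (settings / types per week),
        "truncnorm" bounded continuous score (physical literacy, social
                    support).
    mean:
        target population mean on the observed scale (after truncation).
    sd:
        marginal standard deviation parameter (gamma / truncnorm only).
    lower, upper:
        support bounds of the observed scale.
    cluster_sd:
        standard deviation of the additive cluster-level random intercept.
    """

    kind: str
    mean: float
    sd: float = 0.0
    lower: float = 0.0
    upper: float = float("inf")
    cluster_sd: float = 0.0

    def validate(self, name: str) -> None:
        if self.kind not in ("gamma", "poisson", "truncnorm"):
            raise ConfigurationError(
                f"determinant_targets[{name}].kind: unknown kind {self.kind!r}"
            )
        if not self.mean > 0:
            raise ConfigurationError(
                f"determinant_targets[{name}].mean must be positive"
            )
        if self.kind in ("gamma", "truncnorm") and not self.sd > 0:
            raise ConfigurationError(
                f"determinant_targets[{name}].sd must be positive for "
                f"kind={self.kind}"
            )
        if not self.lower < self.upper:
            raise ConfigurationError(
                f"determinant_targets[{name}]: lower must be < upper"
            )
        if not (self.lower <= self.mean <= self.upper):
            raise ConfigurationError(
                f"determinant_targets[{name}].mean outside [lower, upper]"
            )
        if self.cluster_sd < 0:
            raise ConfigurationError(
                f"determinant_targets[{name}].cluster_sd must be >= 0"
            )


def _default_determinants() -> dict[str, DeterminantModel]:
    return {
        "pa_hours_week": DeterminantModel(
            kind="gamma", mean=9.88, sd=8.0, lower=0.0, cluster_sd=0.30
        ),
        "n_settings": DeterminantModel(
            kind="poisson", mean=3.15, lower=0.0, upper=10, cluster_sd=0.05
        ),
        "n_types": DeterminantModel(
            kind="poisson", mean=4.93, lower=0.0, upper=20, cluster_sd=0.08
        ),
        "physical_literacy": DeterminantModel(
            kind="truncnorm", mean=16.49, sd=2.5, lower=4.0, upper=20.0,
            cluster_sd=0.10,
        ),
        "social_support": DeterminantModel(
            kind="truncnorm", mean=21.19, sd=2.0, lower=5.0, upper=25.0,
            cluster_sd=0.08,
        ),
    }


# Sociodemographic composition of the n = 5035 analytic sample.  Proportions
# are exact category counts over 5035 so every distribution sums to one; the
# 17 respondents with missing deprivation are folded into "unknown".
_AGE_COUNTS = {12: 92, 13: 981, 14: 1253, 15: 1132, 16: 922, 17: 655}
_GENDER_COUNTS = {"male": 2144, "female": 2852, "diverse": 39}
_DEPRIVATION_COUNTS = {"low": 1867, "mid": 1632, "high": 725, "unknown": 811}
_N_ANALYTIC = 5035


def _counts_to_props(counts: Mapping[Any, int]) -> dict[Any, float]:
    total = sum(counts.values())
    return {k: v / total for k, v in counts.items()}


@dataclass
class PopulationConfig:
    """Parameters of the synthetic adolescent survey population."""

    n_surveyed: int = 6906
    school_attendance_rate: float = _N_ANALYTIC / 6906
    age_distribution: dict[int, float] = field(
        default_factory=lambda: _counts_to_props(_AGE_COUNTS)
    )
    gender_distribution: dict[str, float] = field(
        default_factory=lambda: _counts_to_props(_GENDER_COUNTS)
    )
    # Multi-select: marginal rate per label, need not sum to 1.
    ethnicity_rates: dict[str, float] = field(
        default_factory=lambda: {
            "maori": 0.138,
            "european": 0.845,
            "pacific": 0.047,
            "asian": 0.114,
            "other": 0.025,
        }
    )
    disability_rate: float = 0.061
    deprivation_distribution: dict[str, float] = field(
        default_factory=lambda: _counts_to_props(_DEPRIVATION_COUNTS)
    )
    # Share of students taking PE in each year group; national figures are
    # not published, so the default encodes the well-known PE drop-off from
    # near-universal participation at 12 to a minority at 17.
    pe_participation_by_age: dict[int, float] = field(
        default_factory=lambda: {
            12: 0.95, 13: 0.83, 14: 0.71, 15: 0.59, 16: 0.47, 17: 0.35
        }
    )
    n_districts: int = 16
    n_clusters: int = 100
    determinant_targets: dict[str, DeterminantModel] = field(
        default_factory=_default_determinants
    )
    # Optional additive shifts on determinant means by stratum, e.g.
    # {"pa_hours_week": {"gender": {"male": +0.5}}}.  Defaults to none so the
    # calibrated national baselines are untouched.
    strata_shifts: dict[str, dict[str, dict[Any, float]]] = field(
        default_factory=dict
    )
    seed: int = 0

    # ------------------------------------------------------------------
    def validate(self) -> None:
        if self.n_surveyed < 1:
            raise ConfigurationError("n_surveyed must be a positive integer")
        if not (0.0 < self.school_attendance_rate <= 1.0):
            raise ConfigurationError(
                "school_attendance_rate must lie in (0, 1]"
            )
        for name, dist in (
            ("age_distribution", self.age_distribution),
            ("gender_distribution", self.gender_distribution),
            ("deprivation_distribution", self.deprivation_distribution),
        ):
            if not dist:
                raise ConfigurationError(f"{name} is empty")
            for cat, p in dist.items():
                if not (0.0 <= p <= 1.0):
                    raise ConfigurationError(
                        f"{name}[{cat}] = {p} outside [0, 1]"
                    )
            if abs(sum(dist.values()) - 1.0) > _PROB_TOL:
                raise ConfigurationError(f"{name} does not sum to 1")
        for cat, p in self.ethnicity_rates.items():
            if not (0.0 <= p <= 1.0):
                raise ConfigurationError(
                    f"ethnicity_rates[{cat}] = {p} outside [0, 1]"
                )
        if not self.ethnicity_rates:
            raise ConfigurationError("ethnicity_rates is empty")
        if not (0.0 <= self.disability_rate <= 1.0):
            raise ConfigurationError("disability_rate outside [0, 1]")
        for age in self.age_distribution:
            if age not in range(12, 18):
                raise ConfigurationError(
                    f"age_distribution contains age {age} outside 12-17"
                )
        for age, p in self.pe_participation_by_age.items():
            if not (0.0 <= p <= 1.0):
                raise ConfigurationError(
                    f"pe_participation_by_age[{age}] outside [0, 1]"
                )
        missing_pe = set(self.age_distribution) - set(
            self.pe_participation_by_age
        )
        if missing_pe:
            raise ConfigurationError(
                f"pe_participation_by_age missing ages {sorted(missing_pe)}"
            )
        if self.n_districts < 1:
            raise ConfigurationError("n_districts must be >= 1")
        if not (1 <= self.n_clusters <= self.n_surveyed):
            raise ConfigurationError(
                "need n_surveyed >= n_clusters >= 1"
            )
        if set(self.determinant_targets) != set(DETERMINANTS):
            raise ConfigurationError(
                "determinant_targets must define exactly "
                f"{sorted(DETERMINANTS)}"
            )
        for name, model in self.determinant_targets.items():
            model.validate(name)

    # ------------------------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["determinant_targets"] = {
            k: dataclasses.asdict(v) for k, v in self.determinant_targets.items()
        }
        return d

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "PopulationConfig":
        d = dict(d)
        if "determinant_targets" in d:
            d["determinant_targets"] = {
                k: (v if isinstance(v, DeterminantModel)
                    else DeterminantModel(**v))
                for k, v in d["determinant_targets"].items()
            }
        if "age_distribution" in d:
            d["age_distribution"] = {
                int(k): float(v) for k, v in d["age_distribution"].items()
            }
        if "pe_participation_by_age" in d:
            d["pe_participation_by_age"] = {
                int(k): float(v)
                for k, v in d["pe_participation_by_age"].items()
            }
        cfg = cls(**d)
        cfg.validate()
        return cfg


@dataclass
class RunConfig:
    """Configuration of a full pipeline run."""

    population: PopulationConfig = field(default_factory=PopulationConfig)
    # Raking margins: list of derived margin variables (see population module)
    raking_margins: Sequence[str] = ("district_gender", "ethnic_group")
    population_total: float = 376 * 740  # national secondary-school roll
    raking_tol: float = 1e-8
    raking_max_iter: int = 200
    ci_level: float = 0.95
    interventions: str | Sequence[Any] = "published_deltas"
    n_schools: int = 376
    students_per_school: int = 740
    seed: int = 0

    def validate(self) -> None:
        self.population.validate()
        if not (0.0 < self.ci_level < 1.0):
            raise ConfigurationError("ci_level must lie in (0, 1)")
        if self.raking_tol <= 0:
            raise ConfigurationError("raking_tol must be positive")
        if self.raking_max_iter < 1:
            raise ConfigurationError("raking_max_iter must be >= 1")
        if self.population_total <= 0:
            raise ConfigurationError("population_total must be positive")
        if self.n_schools < 1 or self.students_per_school < 1:
            raise ConfigurationError(
                "n_schools and students_per_school must be >= 1"
            )

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["population"] = self.population.to_dict()
        d["raking_margins"] = list(self.raking_margins)
        return d

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "RunConfig":
        d = dict(d)
        if "population" in d:
            pop = d["population"]
            d["population"] = (
                pop if isinstance(pop, PopulationConfig)
                else PopulationConfig.from_dict(pop)
            )
        cfg = cls(**d)
        cfg.validate()
        return cfg

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def load_run_config(path: str) -> RunConfig:
    """Load and validate a YAML (or JSON) run configuration file."""
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    if raw is None:
        raw = {}
    if not isinstance(raw, Mapping):
        raise ConfigurationError(f"config file {path} is not a mapping")
    return RunConfig.from_dict(raw)
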