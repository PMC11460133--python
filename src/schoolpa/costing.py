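"""Intervention costing in 2019 New Zealand dollars.

Costs reported in foreign currencies and other years are first inflated
within their source currency using a consumer price index (CPI) series, then
converted to NZD with a purchasing-power-parity (PPP) factor expressed as
units of source currency per NZD.  Per-school costs scale to a per-student
cost (dividing by the average secondary-school roll, 740 in 2019) and to a
national rollout cost across all 376 secondary schools.

Internal arithmetic is kept at full precision; rounding half-up to the cent
happens only at reporting boundaries.
"""

from __future__ import annotations

import importlib.resources
import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Sequence

import pandas as pd

from .exceptions import ConfigurationError, DataCoverageError

_KNOWN_CURRENCIES = {"NZD", "AUD", "USD", "GBP", "EUR", "CAD", "JPY", "CHF"}

DEFAULT_N_SCHOOLS = 376
DEFAULT_STUDENTS_PER_SCHOOL = 740


@dataclass(frozen=True)
class CostComponent:
    label: str
    amount: float
    currency: str
    year: int

    def validate(self) -> None:
        if self.amount <= 0:
            raise ConfigurationError(
                f"cost component {self.label!r}: amount must be positive"
            )
        if self.currency not in _KNOWN_CURRENCIES:
            raise ConfigurationError(
                f"cost component {self.label!r}: unknown currency "
                f"{self.currency!r}"
            )


@dataclass(frozen=True)
class CostInputs:
    """Cost components of one intervention.

    basis:
        "per_school" if each component is already an average per school;
        otherwise ``n_schools_basis`` gives the number of schools the
        component totals cover and the sum is divided by it.
    """

    components: tuple[CostComponent, ...]
    basis: str = "per_school"  # "per_school" | "total_for_n_schools"
    n_schools_basis: int = 1
    #: per-student value printed in the source material, if any (used only
    #: by the published-figure consistency check)
    published_per_student: float | None = None

    def validate(self) -> None:
        if not self.components:
            raise ConfigurationError("cost inputs need >= 1 component")
        for c in self.components:
            c.validate()
        if self.basis not in ("per_school", "total_for_n_schools"):
            raise ConfigurationError(f"unknown cost basis {self.basis!r}")
        if self.basis == "total_for_n_schools" and self.n_schools_basis < 1:
            raise ConfigurationError("n_schools_basis must be >= 1")


@dataclass(frozen=True)
class CostResult:
    intervention: str
    per_school_nzd: float
    per_student_nzd: float
    national_nzd: float
    n_schools: int = DEFAULT_N_SCHOOLS
    students_per_school: int = DEFAULT_STUDENTS_PER_SCHOOL


# ----------------------------------------------------------------------
# CPI / PPP tables
# ----------------------------------------------------------------------

class CpiSeries:
    """Consumer price index values per (currency, year)."""

    def __init__(self, table: dict[tuple[str, int], float]):
        for (cur, year), idx in table.items():
            if idx <= 0:
                raise ConfigurationError(
                    f"CPI index for ({cur}, {year}) must be positive"
                )
        self._table = dict(table)

    def __getitem__(self, key: tuple[str, int]) -> float:
        cur, year = key
        try:
            return self._table[(cur, int(year))]
        except KeyError:
            raise DataCoverageError(
                f"CPI series has no entry for ({cur}, {year})"
            ) from None

    @classmethod
    def from_csv(cls, path) -> "CpiSeries":
        df = pd.read_csv(path)
        return cls({
            (str(r.currency), int(r.year)): float(r.index)
            for r in df.itertuples()
        })


class PppFactor:
    """Units of a currency per NZD at purchasing-power parity."""

    def __init__(self, factors: dict[str, float], reference_year: int = 2019):
        for cur, f in factors.items():
            if f <= 0:
                raise ConfigurationError(
                    f"PPP factor for {cur} must be positive"
                )
        factors = dict(factors)
        factors.setdefault("NZD", 1.0)
        if factors["NZD"] != 1.0:
            raise ConfigurationError("PPP factor for NZD must equal 1")
        self._factors = factors
        self.reference_year = reference_year

    def __getitem__(self, currency: str) -> float:
        try:
            return self._factors[currency]
        except KeyError:
            raise DataCoverageError(
                f"no PPP factor for currency {currency!r}"
            ) from None

    @classmethod
    def from_csv(cls, path) -> "PppFactor":
        df = pd.read_csv(path)
        year = int(df["year"].iloc[0]) if "year" in df.columns else 2019
        return cls(
            {str(r.currency): float(r.factor_per_nzd)
             for r in df.itertuples()},
            reference_year=year,
        )


def load_default_tables() -> tuple[CpiSeries, PppFactor]:
    """CPI/PPP tables shipped with the package.

    These are small editable reference tables calibrated so that the
    package's shipped intervention cost presets convert to their published
    2019-NZD per-school values; replace them with official OECD series when
    costing new interventions.
    """
    data = importlib.resources.files("schoolpa") / "data"
    cpi = CpiSeries.from_csv(str(data / "cpi.csv"))
    ppp = PppFactor.from_csv(str(data / "ppp.csv"))
    return cpi, ppp


# ----------------------------------------------------------------------
# Operations
# ----------------------------------------------------------------------

def cpi_adjust(
    amount: float, currency: str, from_year: int, to_year: int,
    cpi: CpiSeries,
) -> float:
    """Inflate/deflate within a currency: amount × CPI(to) / CPI(from)."""
    return amount * cpi[(currency, to_year)] / cpi[(currency, from_year)]


def ppp_convert(amount: float, currency: str, ppp: PppFactor) -> float:
    """Convert to NZD at purchasing-power parity: amount / factor."""
    return amount / ppp[currency]


def cost_to_nzd_2019(
    inputs: CostInputs,
    cpi: CpiSeries,
    ppp: PppFactor,
    target_year: int = 2019,
) -> float:
    """Per-school cost in target-year NZD.

    Each component is CPI-adjusted within its source currency to the target
    year and then PPP-converted to NZD; components are summed and, for a
    ``total_for_n_schools`` basis, divided by the number of schools covered.
    """
    inputs.validate()
    total = 0.0
    for comp in inputs.components:
        adjusted = cpi_adjust(
            comp.amount, comp.currency, comp.year, target_year, cpi
        )
        total += ppp_convert(adjusted, comp.currency, ppp)
    if inputs.basis == "total_for_n_schools":
        total /= inputs.n_schools_basis
    return total


def _round_cent(value: float) -> float:
    return float(
        Decimal(repr(value)).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP)
    )


def per_student_cost(
    per_school_nzd: float,
    students_per_school: int = DEFAULT_STUDENTS_PER_SCHOOL,
) -> float:
    """Per-student cost: per-school cost over the average school roll,
    rounded half-up to the cent."""
    if students_per_school < 1:
        raise ConfigurationError("students_per_school must be >= 1")
    return _round_cent(per_school_nzd / students_per_school)


def national_rollout_cost(
    per_school_nzd: float, n_schools: int = DEFAULT_N_SCHOOLS
) -> float:
    """Cost of nationwide implementation across all secondary schools."""
    if n_schools < 1:
        raise ConfigurationError("n_schools must be >= 1")
    return per_school_nzd * n_schools


def cost_intervention(
    name: str,
    inputs: CostInputs,
    cpi: CpiSeries,
    ppp: PppFactor,
    n_schools: int = DEFAULT_N_SCHOOLS,
    students_per_school: int = DEFAULT_STUDENTS_PER_SCHOOL,
) -> CostResult:
    per_school = cost_to_nzd_2019(inputs, cpi, ppp)
    return CostResult(
        intervention=name,
        per_school_nzd=_round_cent(per_school),
        per_student_nzd=per_student_cost(per_school, students_per_school),
        national_nzd=_round_cent(
            national_rollout_cost(_round_cent(per_school), n_schools)
        ),
        n_schools=n_schools,
        students_per_school=students_per_school,
    )


@dataclass(frozen=True)
class ConsistencyFinding:
    intervention: str
    computed_per_student: float
    published_per_student: float
    consistent: bool


def check_published_per_student(
    name: str,
    per_school_nzd: float,
    published_per_student: float,
    students_per_school: int = DEFAULT_STUDENTS_PER_SCHOOL,
    tol: float = 0.005,
) -> ConsistencyFinding:
    """Check a published per-student figure against the per-school figure.

    The published cost table is internally inconsistent for one intervention
    (a per-school cost of $88,755 implies $119.94 per student over a
    740-student roll, not the $119.40 printed); this check surfaces such
    discrepancies rather than silently adopting either number.
    """
    computed = per_student_cost(per_school_nzd, students_per_school)
    return ConsistencyFinding(
        intervention=name,
        computed_per_student=computed,
        published_per_student=published_per_student,
        consistent=math.isclose(
            computed, published_per_student, abs_tol=tol
        ),
    )
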