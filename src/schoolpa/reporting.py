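"""Report tables and figures: sample composition, estimate plots, manifest."""

from __future__ import annotations

import json
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, Sequence

import pandas as pd
from matplotlib.figure import Figure

from .config import DETERMINANT_LABELS, DETERMINANTS
from .exceptions import EmptyDomainError


def round_half_up(value: float, digits: int = 1) -> float:
    """Display rounding with ties away from zero, e.g. 0.25 -> 0.3."""
    q = Decimal(1).scaleb(-digits)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def _pct(n: int, total: int) -> float:
    return round_half_up(100.0 * n / total, 1) if total else 0.0


def demographic_table(participants: pd.DataFrame) -> pd.DataFrame:
    """Counts and percentages by sociodemographic category.

    Ethnicity rows are computed on the multi-select indicator columns and
    may total more than 100%; all percentages are rounded half-up to one
    decimal of the (filtered) sample size.
    """
    if len(participants) == 0:
        raise EmptyDomainError("cannot tabulate an empty population")
    total = len(participants)
    rows: list[dict] = []

    def add(variable: str, category, n: int) -> None:
        rows.append({
            "variable": variable, "category": str(category),
            "n": int(n), "percent": _pct(int(n), total),
        })

    for age, n in participants["age"].value_counts().sort_index().items():
        add("age", age, n)
    for g in ("male", "female", "diverse"):
        add("gender", g, int((participants["gender"] == g).sum()))
    for col in [c for c in participants.columns if c.startswith("eth_")]:
        add("ethnicity", col[len("eth_"):],
            int(participants[col].astype(bool).sum()))
    add("disability", "yes", int(participants["disability"].sum()))
    for dep in ("low", "mid", "high", "unknown"):
        add("deprivation", dep,
            int((participants["deprivation"] == dep).sum()))
    return pd.DataFrame(rows, columns=["variable", "category", "n",
                                       "percent"])


def render_estimates_figure(
    baseline: pd.DataFrame,
    scenarios: Sequence[pd.DataFrame] = (),
    path=None,
) -> Figure:
    """Point estimates with 95% CI whiskers, one panel per determinant,
    one condition per column (baseline first, then each intervention)."""
    frames = [("Baseline", baseline)]
    frames += [(str(df["scenario"].iloc[0]), df) for df in scenarios]

    fig = Figure(figsize=(3.0 * len(DETERMINANTS), 4.0))
    axes = fig.subplots(1, len(DETERMINANTS))
    for ax, det in zip(axes, DETERMINANTS):
        for x, (label, df) in enumerate(frames):
            row = df[df["determinant"] == det].iloc[0]
            mean = float(row["mean"])
            lo = float(row.get("ci_low", mean))
            hi = float(row.get("ci_high", mean))
            err = [[mean - lo], [hi - mean]]
            ax.errorbar([x], [mean], yerr=err, fmt="o", capsize=3)
        ax.set_xticks(range(len(frames)))
        ax.set_xticklabels([lab for lab, _ in frames], rotation=45,
                           ha="right", fontsize=8)
        ax.set_title(DETERMINANT_LABELS[det], fontsize=8)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path)
    return fig


def write_manifest(path, payload: Mapping) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(dict(payload), fh, indent=2, sort_keys=True)
        fh.write("\n")
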