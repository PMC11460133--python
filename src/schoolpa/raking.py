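"""Survey weight calibration by iterative proportional fitting (raking).

Weights are cyclically rescaled, margin by margin, so that the weighted
category totals match known population totals (e.g. the population in each
district by gender, and by ethnic group).  For consistent margins IPF
converges to the unique calibration with a multiplicative factor per margin
category; the final weight / base weight ratio is constant within every cell
of the cross-classification of all margins.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .exceptions import (
    MarginConsistencyError,
    MarginInfeasibleError,
    SchemaError,
)
from .population import MarginTable

_GRAND_TOTAL_RTOL = 1e-6


@dataclass
class RakingResult:
    weights: np.ndarray
    n_iterations: int
    converged: bool
    max_margin_deviation: float
    #: max relative margin deviation after each full cycle
    history: list[float] = field(default_factory=list)


def _margin_arrays(
    memberships: pd.DataFrame, margins: Sequence[MarginTable]
) -> list[tuple[np.ndarray, np.ndarray, int]]:
    """Per margin: (category index per participant, totals array, k)."""
    prepared = []
    for margin in margins:
        if margin.variable not in memberships.columns:
            raise SchemaError(
                f"memberships lack a column for margin {margin.variable!r}"
            )
        cats = sorted(margin.totals)
        values = memberships[margin.variable].astype(str)
        unknown = set(values.unique()) - set(cats)
        if unknown:
            raise SchemaError(
                f"participants carry categories {sorted(unknown)} absent "
                f"from margin {margin.variable!r}"
            )
        index = pd.Categorical(values, categories=cats).codes
        totals = np.asarray([margin.totals[c] for c in cats], dtype=float)
        if (totals <= 0).any():
            bad = cats[int(np.argmin(totals))]
            raise MarginInfeasibleError(
                f"margin {margin.variable!r} category {bad!r} has a "
                "non-positive total"
            )
        prepared.append((index, totals, len(cats)))
    return prepared


def margin_deviation(
    weights: np.ndarray,
    memberships: pd.DataFrame,
    margins: Sequence[MarginTable],
) -> float:
    """Largest absolute relative gap between a weighted category total and
    its margin total, across all margins and categories."""
    weights = np.asarray(weights, dtype=float)
    worst = 0.0
    for index, totals, k in _margin_arrays(memberships, margins):
        observed = np.bincount(index, weights=weights, minlength=k)
        worst = max(worst, float(np.max(np.abs(observed - totals) / totals)))
    return worst


def ipf_rake(
    base_weights: np.ndarray,
    memberships: pd.DataFrame,
    margins: Sequence[MarginTable],
    tol: float = 1e-8,
    max_iter: int = 200,
    trim: Callable[[np.ndarray], np.ndarray] | None = None,
) -> RakingResult:
    """Calibrate ``base_weights`` to the margin totals.

    Parameters
    ----------
    base_weights : positive design weights, one per participant.
    memberships : DataFrame with one column per margin variable giving each
        participant's category.
    margins : known population totals; all grand totals must agree to within
        a relative 1e-6.
    tol : convergence tolerance on the maximum relative margin deviation.
    max_iter : maximum number of full cycles over the margins.
    trim : optional weight-trimming hook applied after each cycle; default
        is the identity (no trimming).
    """
    w = np.asarray(base_weights, dtype=float).copy()
    if w.ndim != 1 or len(w) != len(memberships):
        raise SchemaError("base_weights must align with memberships rows")
    if (w <= 0).any():
        raise MarginInfeasibleError("all base weights must be positive")
    if not margins:
        raise SchemaError("at least one margin is required")

    prepared = _margin_arrays(memberships, margins)

    grand = [m.grand_total() for m in margins]
    ref = grand[0]
    for margin, g in zip(margins, grand):
        if abs(g - ref) > _GRAND_TOTAL_RTOL * ref:
            raise MarginConsistencyError(
                f"margin {margin.variable!r} grand total {g!r} disagrees "
                f"with {margins[0].variable!r} total {ref!r}"
            )

    # infeasibility: a category with no positively weighted participant
    for margin, (index, totals, k) in zip(margins, prepared):
        support = np.bincount(index, weights=w, minlength=k)
        if (support <= 0).any():
            cats = sorted(margin.totals)
            bad = cats[int(np.argmin(support))]
            raise MarginInfeasibleError(
                f"margin {margin.variable!r} category {bad!r} has no "
                "participant with positive weight"
            )

    history: list[float] = []
    converged = False
    n_iterations = 0
    for _ in range(max_iter):
        for index, totals, k in prepared:
            observed = np.bincount(index, weights=w, minlength=k)
            w = w * (totals / observed)[index]
        if trim is not None:
            w = trim(w)
        n_iterations += 1
        dev = margin_deviation(w, memberships, margins)
        history.append(dev)
        if dev <= tol:
            converged = True
            break

    return RakingResult(
        weights=w,
        n_iterations=n_iterations,
        converged=converged,
        max_margin_deviation=history[-1],
        history=history,
    )
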