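"""Design-based estimation of determinant means.

National estimates are Hájek (ratio) weighted means.  Standard errors use
Taylor linearisation with the ultimate-cluster (between-PSU) variance
estimator: the linearised score of participant *i* is

    z_i = w_i (y_i - ybar_w) / sum(w),

scores are summed within each primary sampling unit to Z_c, and

    var(ybar_w) = m/(m-1) * sum_c (Z_c - Zbar)^2

over the m clusters.  Confidence intervals use Student's t with m - 1
design degrees of freedom.  With equal weights and singleton clusters this
reduces exactly to s^2/n with the (n-1)-divisor sample variance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .config import DETERMINANTS
from .exceptions import (
    ConfigurationError,
    DegenerateDesignError,
    EmptyDomainError,
)


@dataclass(frozen=True)
class SurveyEstimate:
    """Weighted mean with cluster-robust uncertainty for one determinant."""

    mean: float
    se: float
    ci_low: float
    ci_high: float
    n: int
    n_clusters: int
    df: int
    level: float


def weighted_mean(values, weights) -> float:
    """Hájek ratio mean sum(w*y)/sum(w)."""
    y = np.asarray(values, dtype=float)
    w = np.asarray(weights, dtype=float)
    if y.size == 0:
        raise EmptyDomainError("weighted_mean of an empty domain")
    if y.shape != w.shape:
        raise ConfigurationError("values and weights must align")
    if (w <= 0).any():
        raise ConfigurationError("weights must be positive")
    return float(np.dot(w, y) / w.sum())


def linearised_se(values, weights, cluster_ids) -> float:
    """Taylor-linearised SE of the Hájek mean, ultimate-cluster estimator."""
    y = np.asarray(values, dtype=float)
    w = np.asarray(weights, dtype=float)
    clusters = pd.Categorical(np.asarray(cluster_ids))
    m = len(clusters.categories)
    if m < 2:
        raise DegenerateDesignError(
            "cluster-robust variance needs at least 2 clusters"
        )
    ybar = weighted_mean(y, w)
    z = w * (y - ybar) / w.sum()
    zc = np.bincount(clusters.codes, weights=z, minlength=m)
    zbar = zc.mean()
    var = m / (m - 1) * np.sum((zc - zbar) ** 2)
    return float(np.sqrt(var))


def confidence_interval(
    mean: float, se: float, df: int, level: float = 0.95
) -> tuple[float, float]:
    """Symmetric t-interval ``mean ± t(df, 1-(1-level)/2) * se``."""
    if not (0.0 < level < 1.0):
        raise ConfigurationError("level must lie in (0, 1)")
    if df < 1:
        raise ConfigurationError("df must be >= 1")
    if se < 0:
        raise ConfigurationError("se must be non-negative")
    half = float(stats.t.ppf(1.0 - (1.0 - level) / 2.0, df)) * se
    return mean - half, mean + half


def estimate_mean(
    values, weights, cluster_ids, level: float = 0.95
) -> SurveyEstimate:
    """Full design-based estimate for one determinant."""
    y = np.asarray(values, dtype=float)
    mean = weighted_mean(y, weights)
    se = linearised_se(y, weights, cluster_ids)
    m = pd.unique(np.asarray(cluster_ids)).size
    df = m - 1
    lo, hi = confidence_interval(mean, se, df, level)
    return SurveyEstimate(
        mean=mean, se=se, ci_low=lo, ci_high=hi,
        n=int(y.size), n_clusters=int(m), df=int(df), level=level,
    )


def summarize_determinants(
    participants: pd.DataFrame,
    determinants: pd.DataFrame,
    weights=None,
    scheme: str = "weighted",
    level: float = 0.95,
) -> pd.DataFrame:
    """Per-determinant summary table.

    scheme="weighted" gives the national survey estimates (Hájek mean,
    linearised SE, t-interval); scheme="unweighted" gives raw sample means
    and standard deviations (divisor n - 1).
    """
    if len(participants) == 0:
        raise EmptyDomainError("cannot summarise an empty population")
    if scheme not in ("weighted", "unweighted"):
        raise ConfigurationError(f"unknown scheme {scheme!r}")
    rows = []
    for name in DETERMINANTS:
        y = determinants[name].to_numpy(dtype=float)
        if scheme == "weighted":
            w = (np.ones(len(y)) if weights is None
                 else np.asarray(weights, dtype=float))
            est = estimate_mean(
                y, w, participants["cluster_id"].to_numpy(), level
            )
            rows.append({
                "determinant": name, "scheme": "weighted", "n": est.n,
                "mean": est.mean, "sd_or_se": est.se,
                "ci_low": est.ci_low, "ci_high": est.ci_high,
            })
        else:
            sd = float(np.std(y, ddof=1)) if len(y) > 1 else 0.0
            rows.append({
                "determinant": name, "scheme": "unweighted", "n": len(y),
                "mean": float(np.mean(y)), "sd_or_se": sd,
                "ci_low": np.nan, "ci_high": np.nan,
            })
    return pd.DataFrame(rows)
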