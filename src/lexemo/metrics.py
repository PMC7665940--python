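"""Diagnostic-accuracy battery for token-level tagger validation.

Treating each word token as one observation and the human coding as the
reference standard, a tagger's performance for one category is a 2×2
confusion table, from which the standard screening-test quantities follow:

* sensitivity (recall)  = TP / (TP + FN)
* specificity           = TN / (TN + FP)
* PPV (precision)       = TP / (TP + FP)
* NPV                   = TN / (TN + FN)
* F score               = 2·PPV·sens / (PPV + sens)

Proportions carry 95% confidence intervals (Wilson score by default, Wald
optionally).  Taggers are compared with pooled two-proportion z tests under
a Bonferroni-corrected family-wise alpha.  PPV's dependence on category
prevalence π follows Bayes' rule:

    PPV = sens·π / (sens·π + (1 − spec)·(1 − π))

which the package uses both analytically and as an internal consistency
identity against confusion-table PPV.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.proportion import proportion_confint

from .errors import (
    DegenerateTestError,
    UndefinedCorrelationError,
    UndefinedMetricError,
)
from .reference import AlignedCorpus

__all__ = [
    "ComparisonResult",
    "ConfusionCounts",
    "FScoreValue",
    "ProportionEstimate",
    "bonferroni",
    "confusion",
    "f_score",
    "npv",
    "pearson_correlation",
    "ppv",
    "ppv_from_prevalence",
    "proportion_ci",
    "sensitivity",
    "specificity",
    "two_proportion_test",
    "two_proportion_z",
]


@dataclass(frozen=True)
class ConfusionCounts:
    """One-vs-rest token counts for a single category and tagger."""

    category: str
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @property
    def reference_positives(self) -> int:
        return self.tp + self.fn

    @property
    def prevalence(self) -> float:
        if self.total == 0:
            raise UndefinedMetricError("empty confusion table")
        return self.reference_positives / self.total


@dataclass(frozen=True)
class ProportionEstimate:
    """A proportion with its 95% CI and denominator."""

    value: float
    ci_low: float
    ci_high: float
    n: int

    def __post_init__(self):
        if not (0.0 <= self.ci_low <= self.value <= self.ci_high <= 1.0):
            raise ValueError(
                f"CI must bracket the estimate in [0,1]: "
                f"{self.ci_low}, {self.value}, {self.ci_high}"
            )

    def covers(self, p: float) -> bool:
        return self.ci_low <= p <= self.ci_high


@dataclass(frozen=True)
class FScoreValue:
    """Harmonic mean of PPV (precision) and sensitivity (recall)."""

    value: float
    ppv: float
    sensitivity: float


@dataclass(frozen=True)
class ComparisonResult:
    """Outcome of a pooled two-proportion z test."""

    p1: float
    p2: float
    n1: int
    n2: int
    z: float
    p_value: float
    alpha_corrected: float
    approximate: bool = False

    @property
    def significant(self) -> bool:
        return self.p_value < self.alpha_corrected


# ---------------------------------------------------------------------------
# confusion counting


def confusion(aligned: AlignedCorpus, category: str) -> ConfusionCounts:
    """Tally one-vs-rest TP/FP/FN/TN for a category over all word tokens."""
    if category not in aligned.categories:
        raise KeyError(f"category {category!r} not in aligned corpus")
    ref = aligned.ref_column(category)
    pred = aligned.pred_column(category)
    tp = int(np.count_nonzero(ref & pred))
    fp = int(np.count_nonzero(~ref & pred))
    fn = int(np.count_nonzero(ref & ~pred))
    tn = int(np.count_nonzero(~ref & ~pred))
    return ConfusionCounts(category, tp=tp, fp=fp, fn=fn, tn=tn)


# ---------------------------------------------------------------------------
# proportions with confidence intervals


def proportion_ci(
    count: int, nobs: int, method: str = "wilson", alpha: float = 0.05
) -> ProportionEstimate:
    """A binomial proportion with its CI (Wilson score or Wald)."""
    if nobs <= 0:
        raise UndefinedMetricError("proportion denominator is zero")
    if method not in ("wilson", "wald"):
        raise ValueError(f"unknown CI method {method!r}")
    sm_method = "wilson" if method == "wilson" else "normal"
    lo, hi = proportion_confint(count, nobs, alpha=alpha, method=sm_method)
    value = count / nobs
    # Wald intervals can stray outside [0,1]; clip, preserving ordering
    lo = min(max(float(lo), 0.0), value)
    hi = max(min(float(hi), 1.0), value)
    return ProportionEstimate(value=value, ci_low=lo, ci_high=hi, n=nobs)


def sensitivity(
    counts: ConfusionCounts, method: str = "wilson"
) -> ProportionEstimate:
    """TP / (TP + FN): fraction of reference-positive words the tagger flags."""
    return proportion_ci(counts.tp, counts.tp + counts.fn, method)


def specificity(
    counts: ConfusionCounts, method: str = "wilson"
) -> ProportionEstimate:
    """TN / (TN + FP): fraction of reference-negative words left unflagged."""
    return proportion_ci(counts.tn, counts.tn + counts.fp, method)


def ppv(counts: ConfusionCounts, method: str = "wilson") -> ProportionEstimate:
    """TP / (TP + FP): fraction of flagged words the coders agree with."""
    return proportion_ci(counts.tp, counts.tp + counts.fp, method)


def npv(counts: ConfusionCounts, method: str = "wilson") -> ProportionEstimate:
    """TN / (TN + FN): fraction of unflagged words the coders agree with."""
    return proportion_ci(counts.tn, counts.tn + counts.fn, method)


# ---------------------------------------------------------------------------
# F score


def f_score(ppv_value: float, sens_value: float) -> FScoreValue:
    """2·PPV·sens / (PPV + sens); undefined when both inputs are zero."""
    if not (0.0 <= ppv_value <= 1.0 and 0.0 <= sens_value <= 1.0):
        raise ValueError("PPV and sensitivity must lie in [0, 1]")
    if ppv_value + sens_value == 0.0:
        raise UndefinedMetricError("F undefined when PPV + sensitivity = 0")
    value = 2.0 * ppv_value * sens_value / (ppv_value + sens_value)
    return FScoreValue(value=value, ppv=ppv_value, sensitivity=sens_value)


# ---------------------------------------------------------------------------
# hypothesis tests


def two_proportion_z(
    x1: np.ndarray | int,
    n1: np.ndarray | int,
    x2: np.ndarray | int,
    n2: np.ndarray | int,
):
    """Vectorized pooled two-proportion z statistic and two-sided p-value.

    Degenerate tables (pooled proportion 0 or 1) yield z = nan, p = nan.
    """
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    n1 = np.asarray(n1, dtype=float)
    n2 = np.asarray(n2, dtype=float)
    pooled = (x1 + x2) / (n1 + n2)
    var = pooled * (1.0 - pooled) * (1.0 / n1 + 1.0 / n2)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (x1 / n1 - x2 / n2) / np.sqrt(var)
    z = np.where(var > 0, z, np.nan)
    p = 2.0 * stats.norm.sf(np.abs(z))
    return z, p


def two_proportion_test(
    p1: float,
    n1: int,
    p2: float,
    n2: int,
    alpha_corrected: float = 0.05,
    approximate: bool = False,
) -> ComparisonResult:
    """Pooled two-sample z test of p1 vs p2, two-sided.

    z = (p1 − p2) / sqrt(p̂(1 − p̂)(1/n1 + 1/n2)) with p̂ the pooled
    proportion.  Success counts are reconstructed as round(p·n).
    """
    if n1 <= 0 or n2 <= 0:
        raise ValueError("denominators must be positive")
    if not (0.0 <= p1 <= 1.0 and 0.0 <= p2 <= 1.0):
        raise ValueError("proportions must lie in [0, 1]")
    x1 = round(p1 * n1)
    x2 = round(p2 * n2)
    pooled = (x1 + x2) / (n1 + n2)
    if pooled in (0.0, 1.0):
        raise DegenerateTestError(
            "pooled proportion is 0 or 1; z test undefined"
        )
    z, p = two_proportion_z(x1, n1, x2, n2)
    return ComparisonResult(
        p1=p1, p2=p2, n1=n1, n2=n2,
        z=float(z), p_value=float(p),
        alpha_corrected=alpha_corrected,
        approximate=approximate,
    )


def bonferroni(alpha_family: float, m: int) -> float:
    """Per-test threshold alpha/m controlling the family-wise error rate."""
    if m < 1:
        raise ValueError("number of comparisons must be ≥ 1")
    if not (0.0 < alpha_family < 1.0):
        raise ValueError("family alpha must lie in (0, 1)")
    return alpha_family / m


# ---------------------------------------------------------------------------
# correlations


def pearson_correlation(
    table_a: pd.DataFrame, table_b: pd.DataFrame
) -> pd.DataFrame:
    """Product-moment correlations between two per-participant tables.

    Rows are participants (matched by index), columns are categories;
    the result has ``table_a``'s columns as rows and ``table_b``'s as
    columns.  A constant column on either side raises
    :class:`UndefinedCorrelationError`.
    """
    if len(table_a) < 3:
        raise ValueError("need at least 3 participants for a correlation")
    b = table_b.reindex(table_a.index)
    if b.isna().any().any():
        raise ValueError("tables must be indexed by the same participants")
    a_vals = table_a.to_numpy(dtype=float)
    b_vals = b.to_numpy(dtype=float)
    for tbl, vals in (("first", a_vals), ("second", b_vals)):
        if np.any(vals.std(axis=0) == 0.0):
            raise UndefinedCorrelationError(
                f"constant column in {tbl} table"
            )
    k = a_vals.shape[1]
    full = np.corrcoef(a_vals, b_vals, rowvar=False)
    return pd.DataFrame(
        full[:k, k:], index=table_a.columns, columns=b.columns
    )


# ---------------------------------------------------------------------------
# prevalence dependence of PPV


def ppv_from_prevalence(
    sens: float, spec: float, prevalence: float
) -> float:
    """Expected PPV at a given prevalence, by Bayes' rule.

    PPV = sens·π / (sens·π + (1 − spec)(1 − π)).  PPV rises with prevalence
    for fixed sensitivity and specificity, which is why precision measured
    on an emotionally expressive population overstates precision in a less
    expressive one.
    """
    for name, v in (("sens", sens), ("spec", spec),
                    ("prevalence", prevalence)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} must lie in [0, 1]")
    denom = sens * prevalence + (1.0 - spec) * (1.0 - prevalence)
    if denom == 0.0:
        if prevalence == 0.0:
            return 0.0
        raise UndefinedMetricError(
            "no positive predictions possible at these parameters"
        )
    return sens * prevalence / denom
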