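"""Cohort comparison statistics.

Everything reported across demographic groups: exact two-sided Fisher
tests on 2x2 tables, Mann-Whitney U for mutation-burden distributions,
unscaled median/MAD summaries, Kaplan-Meier survival at a horizon, the
log-rank test, and the feature-by-grouping contrast grid. P-values are
reported raw (no multiplicity adjustment).
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom, mannwhitneyu

logger = logging.getLogger(__name__)

#: Relative tolerance when comparing hypergeometric point probabilities, so
#: tables that are analytically tied with the observed one are not excluded
#: by floating-point noise.
FISHER_REL_TOL = 1e-7


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 counts: rows are groups, columns feature present/absent."""

    a: int  # group 1, feature present
    b: int  # group 1, feature absent
    c: int  # group 2, feature present
    d: int  # group 2, feature absent

    def __post_init__(self):
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("counts must be non-negative")
        if self.total == 0:
            raise ValueError("empty table")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d

    @classmethod
    def from_counts(cls, present1: int, n1: int, present2: int, n2: int):
        return cls(present1, n1 - present1, present2, n2 - present2)


def fisher_exact_two_sided(table: ContingencyTable | Sequence[Sequence[int]]) -> float:
    """Exact two-sided Fisher p-value by hypergeometric enumeration.

    Sums the probabilities of every margin-preserving 2x2 table whose
    point probability does not exceed the observed table's (point-
    probability criterion, within relative tolerance ``FISHER_REL_TOL``).
    A table with a zero row or column margin returns p = 1 with a warning.
    """
    if not isinstance(table, ContingencyTable):
        (a, b), (c, d) = table
        table = ContingencyTable(a, b, c, d)
    r1 = table.a + table.b
    r2 = table.c + table.d
    c1 = table.a + table.c
    c2 = table.b + table.d
    n = table.total
    if 0 in (r1, r2, c1, c2):
        warnings.warn("contingency table has an empty margin; p = 1")
        return 1.0
    rv = hypergeom(n, r1, c1)
    support = np.arange(max(0, c1 - r2), min(r1, c1) + 1)
    probs = rv.pmf(support)
    p_obs = rv.pmf(table.a)
    p = float(probs[probs <= p_obs * (1 + FISHER_REL_TOL)].sum())
    return min(p, 1.0)


def mann_whitney_u(a: Sequence[float], b: Sequence[float]) -> float:
    """Two-sided Mann-Whitney U p-value.

    Exact permutation null when the combined sample has at most 20
    observations and no ties; otherwise the normal approximation with tie
    and continuity corrections.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    no_ties = np.unique(pooled).size == pooled.size
    if a.size + b.size <= 20 and no_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = mannwhitneyu(a, b, alternative="two-sided", method=method,
                       use_continuity=True)
    return float(res.pvalue)


def median_mad(values: Sequence[float]) -> tuple[float, float]:
    """Median (midpoint convention) and unscaled median absolute deviation."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("empty value list")
    med = float(np.median(values))
    mad = float(np.median(np.abs(values - med)))
    return med, mad


@dataclass(frozen=True)
class SurvivalRecord:
    sample: str
    time: float  # months
    event: bool  # progressed/died (True) or censored (False)
    group: str = ""

    def __post_init__(self):
        if self.time <= 0:
            raise ValueError("survival time must be positive")


def km_survival_at(records: Sequence[SurvivalRecord], horizon: float) -> float:
    """Kaplan-Meier survival estimate S(horizon) with right censoring."""
    if not records:
        raise ValueError("no survival records")
    if horizon <= 0:
        raise ValueError("horizon must be positive")
    from lifelines import KaplanMeierFitter

    kmf = KaplanMeierFitter()
    kmf.fit([r.time for r in records], [r.event for r in records])
    return float(kmf.predict(horizon))


def log_rank(a: Sequence[SurvivalRecord], b: Sequence[SurvivalRecord]) -> float:
    """One-degree-of-freedom log-rank test p-value between two groups."""
    if not a or not b:
        raise ValueError("both groups must be non-empty")
    if not any(r.event for r in a) and not any(r.event for r in b):
        warnings.warn("no events in either group; log-rank p = 1")
        return 1.0
    from lifelines.statistics import logrank_test

    res = logrank_test(
        [r.time for r in a], [r.time for r in b],
        event_observed_A=[r.event for r in a],
        event_observed_B=[r.event for r in b],
    )
    return float(res.p_value)


# ---------------------------------------------------------------------------
# contrast grid

#: Grouping name -> (column, level-of-group-1, level-of-group-2).
DEFAULT_GROUPINGS: dict[str, tuple[str, str, str]] = {
    "age": ("age_group", "<50", ">=50"),
    "sex": ("sex", "male", "female"),
    "smoking": ("smoking", "ever", "never"),
}


@dataclass(frozen=True)
class GroupComparisonResult:
    feature: str
    grouping: str
    test: str
    p_value: float
    n_per_group: tuple[int, int]
    estimate_per_group: tuple  # proportions, or (median, MAD) pairs

    @property
    def p_printed(self) -> str:
        """The p-value rounded for display, <=3 significant figures."""
        return format_p(self.p_value)


def format_p(p: float) -> str:
    if p >= 0.995:
        return "1"
    if p < 0.001:
        return "<0.001"
    for digits in (2, 3):
        s = f"{p:.{digits}f}"
        if float(s) != 0:
            return s.rstrip("0") if "." in s and s.rstrip("0")[-1] != "." else s
    return f"{p:.3f}"


def run_contrast_grid(
    table: pd.DataFrame,
    contrasts: Sequence[Mapping[str, str]],
    groupings: Mapping[str, tuple[str, str, str]] | None = None,
) -> list[GroupComparisonResult]:
    """Run every requested (feature, grouping) comparison.

    ``table`` holds one row per sample with boolean feature columns, a
    numeric ``tmb`` column, and grouping columns. Binary features get a
    two-sided Fisher exact test on the 2x2 counts; numeric features get a
    Mann-Whitney U test with median/MAD estimates. Samples whose grouping
    value is missing or outside the two levels (e.g. smoking "unknown")
    are excluded from that contrast.
    """
    groupings = dict(groupings or DEFAULT_GROUPINGS)
    results = []
    for spec in contrasts:
        feature = spec["feature"]
        grouping = spec["grouping"]
        if feature not in table.columns:
            raise KeyError(
                f"feature {feature!r} not in table; available: "
                f"{sorted(table.columns)}"
            )
        col, lvl1, lvl2 = groupings[grouping]
        g1 = table[table[col] == lvl1]
        g2 = table[table[col] == lvl2]
        if pd.api.types.is_bool_dtype(table[feature]) or set(
            table[feature].dropna().unique()
        ) <= {0, 1, True, False}:
            x1 = int(g1[feature].sum())
            x2 = int(g2[feature].sum())
            n1, n2 = len(g1), len(g2)
            ct = ContingencyTable.from_counts(x1, n1, x2, n2)
            if x1 + x2 == 0 or x1 + x2 == n1 + n2:
                warnings.warn(
                    f"feature {feature!r} is constant across samples; "
                    "degenerate margin, p = 1"
                )
            p = fisher_exact_two_sided(ct)
            results.append(GroupComparisonResult(
                feature, grouping, "fisher_exact", p, (n1, n2),
                (x1 / n1 if n1 else float("nan"), x2 / n2 if n2 else float("nan")),
            ))
        else:
            v1 = g1[feature].dropna().to_numpy(dtype=float)
            v2 = g2[feature].dropna().to_numpy(dtype=float)
            p = mann_whitney_u(v1, v2)
            results.append(GroupComparisonResult(
                feature, grouping, "mann_whitney_u", p, (len(v1), len(v2)),
                (median_mad(v1), median_mad(v2)),
            ))
    return results


def results_to_frame(results: Sequence[GroupComparisonResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        rows.append({
            "feature": r.feature,
            "grouping": r.grouping,
            "test": r.test,
            "n_group1": r.n_per_group[0],
            "n_group2": r.n_per_group[1],
            "estimate_group1": _fmt_est(r.estimate_per_group[0]),
            "estimate_group2": _fmt_est(r.estimate_per_group[1]),
            "p": r.p_value,
            "p_printed": r.p_printed,
        })
    return pd.DataFrame(rows)


def _fmt_est(est) -> str:
    if isinstance(est, tuple):
        return f"{est[0]:.4g} (MAD={est[1]:.4g})"
    return f"{est:.4g}"
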