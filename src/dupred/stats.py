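"""The statistical battery used throughout the analysis.

Fisher's exact test on 2x2 tables, two-sample Wilcoxon rank-sum, Pearson
correlation test, age stratification of paralog-pair metrics, and the
age-binned hypergeometric group test that asks whether disease-gene pairs
beat non-disease pairs in more age groups than chance allows.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats as sps

from .errors import ValidationError

__all__ = [
    "ContingencyTable2x2",
    "AgeBin",
    "fisher_exact_2x2",
    "wilcoxon_rank_sum",
    "stratify_by_age",
    "age_group_hypergeom_test",
    "pearson_correlation_test",
    "complex_comembership_table",
]

# Relative tolerance for the probability-mass two-sided rule: a table counts
# toward the p-value when its probability is <= observed * (1 + _REL_TIE_TOL).
_REL_TIE_TOL = 1e-7


@dataclass(frozen=True)
class ContingencyTable2x2:
    a: int
    b: int
    c: int
    d: int
    row_labels: tuple[str, str] = ("row1", "row2")
    col_labels: tuple[str, str] = ("col1", "col2")

    def __post_init__(self) -> None:
        for v in (self.a, self.b, self.c, self.d):
            if v < 0 or int(v) != v:
                raise ValidationError(f"counts must be non-negative integers, got {v}")
        if self.a + self.b + self.c + self.d == 0:
            raise ValidationError("table has no positive margin")

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=np.int64)


def fisher_exact_2x2(table) -> tuple[float, float]:
    """Fisher's exact test on a 2x2 table.

    Returns ``(odds_ratio, p_two_sided)``.  The odds ratio is the sample odds
    ratio a*d / (b*c) (``inf`` when b*c == 0 with a*d > 0, ``nan`` when both
    products are zero).  The two-sided p-value is the conditional exact one:
    the sum, over all tables with the observed margins, of hypergeometric
    probabilities no larger than that of the observed table.
    """
    if not isinstance(table, ContingencyTable2x2):
        arr = np.asarray(table)
        table = ContingencyTable2x2(*[int(v) for v in arr.ravel()])
    a, b, c, d = table.a, table.b, table.c, table.d

    ad, bc = a * d, b * c
    if bc == 0:
        odds = math.nan if ad == 0 else math.inf
    else:
        odds = ad / bc

    n_total = a + b + c + d
    r1, c1 = a + b, a + c
    lo = max(0, r1 + c1 - n_total)
    hi = min(r1, c1)
    support = np.arange(lo, hi + 1)
    pmf = sps.hypergeom.pmf(support, n_total, r1, c1)
    p_obs = pmf[a - lo]
    p = float(pmf[pmf <= p_obs * (1.0 + _REL_TIE_TOL)].sum())
    return odds, min(p, 1.0)


def wilcoxon_rank_sum(
    x: Sequence[float],
    y: Sequence[float],
    alternative: str = "two-sided",
) -> tuple[float, float]:
    """Two-sample Wilcoxon rank-sum (Mann–Whitney) test.

    Exact null distribution when ``min(n, m) <= 8`` and there are no ties;
    otherwise the normal approximation with tie and continuity corrections.
    Returns the Mann–Whitney U statistic of ``x`` and the p-value.
    """
    x = np.asarray([v for v in x if v is not None and not math.isnan(v)], dtype=float)
    y = np.asarray([v for v in y if v is not None and not math.isnan(v)], dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValidationError("wilcoxon_rank_sum requires non-empty samples")
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (min(x.size, y.size) <= 8 and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative=alternative, method=method)
    return float(res.statistic), float(res.pvalue)


@dataclass
class AgeBin:
    """All metric samples of one duplication-age class (one species-tree
    node), split into disease-pair and non-disease-pair groups."""

    age: float
    md_values: list[float] = field(default_factory=list)
    nd_values: list[float] = field(default_factory=list)

    def is_valid(self, min_n: int = 3) -> bool:
        return len(self.md_values) >= min_n and len(self.nd_values) >= min_n

    @property
    def md_mean(self) -> float:
        return float(np.mean(self.md_values)) if self.md_values else math.nan

    @property
    def nd_mean(self) -> float:
        return float(np.mean(self.nd_values)) if self.nd_values else math.nan


def stratify_by_age(
    ages: Sequence[float],
    is_md: Sequence[bool],
    values: Sequence[float],
    min_n: int = 3,
) -> list[AgeBin]:
    """Group per-pair metric values into one bin per distinct age.

    Missing values (``nan``) are dropped.  Bins failing ``min_n`` in either
    group are kept in the output but flagged invalid by
    :meth:`AgeBin.is_valid`; raising happens only when no valid bin remains.
    """
    bins: dict[float, AgeBin] = {}
    for age, md, value in zip(ages, is_md, values):
        if value is None or (isinstance(value, float) and math.isnan(value)):
            continue
        bin_ = bins.setdefault(float(age), AgeBin(age=float(age)))
        (bin_.md_values if md else bin_.nd_values).append(float(value))
    out = [bins[a] for a in sorted(bins)]
    if not any(b.is_valid(min_n) for b in out):
        raise ValidationError("no age bin has enough samples in both groups")
    return out


def age_group_hypergeom_test(
    bins: Iterable[AgeBin],
    direction: str = "md_higher",
    tail: str = "upper",
    min_bins: int = 5,
    min_n: int = 3,
) -> tuple[int, int, float]:
    """Hypergeometric group test over valid age bins.

    ``q`` = number of valid bins where the MD-group mean beats the ND-group
    mean in the requested ``direction`` (ties never count toward ``q``);
    ``K`` = number of valid bins.  With the hypergeometric parameters set to
    m = n = k = K, the default upper tail returns P(X >= q); ``tail='lower'``
    gives the literal P(X <= q).
    """
    valid = [b for b in bins if b.is_valid(min_n)]
    K = len(valid)
    if K < min_bins:
        raise ValidationError(
            f"too few valid age groups ({K} < {min_bins})"
        )
    if direction == "md_higher":
        q = sum(1 for b in valid if b.md_mean > b.nd_mean)
    elif direction == "md_lower":
        q = sum(1 for b in valid if b.md_mean < b.nd_mean)
    else:
        raise ValueError(f"unknown direction {direction!r}")
    dist = sps.hypergeom(2 * K, K, K)
    if tail == "upper":
        p = float(dist.sf(q - 1))
    elif tail == "lower":
        p = float(dist.cdf(q))
    else:
        raise ValueError(f"unknown tail {tail!r}")
    return q, K, min(p, 1.0)


def pearson_correlation_test(
    x: Sequence[float], y: Sequence[float]
) -> tuple[float, float]:
    """Pearson r with a two-sided p-value from the t-transform (n-2 df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValidationError("pearson_correlation_test requires n >= 3 paired values")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValidationError("non-finite values in input")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValidationError("zero variance in input")
    res = sps.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def complex_comembership_table(
    pairs_a: Iterable[tuple[str, str]],
    pairs_b: Iterable[tuple[str, str]],
    complexes: Mapping[str, Iterable[str]],
    labels: tuple[str, str] = ("group_a", "group_b"),
) -> ContingencyTable2x2:
    """2x2 table of pairs that do / do not share at least one protein
    complex, for two groups of gene pairs.

    A pair with neither member in any complex counts as not co-member.
    """
    if not complexes:
        raise ValidationError("complexes must be non-empty")
    membership: dict[str, set[str]] = {}
    for cpx, genes in complexes.items():
        for g in genes:
            membership.setdefault(g, set()).add(cpx)

    def count(pairs) -> tuple[int, int]:
        co = total = 0
        for ga, gb in pairs:
            total += 1
            if membership.get(ga, set()) & membership.get(gb, set()):
                co += 1
        return co, total - co

    co_a, not_a = count(pairs_a)
    co_b, not_b = count(pairs_b)
    return ContingencyTable2x2(
        co_a,
        not_a,
        co_b,
        not_b,
        row_labels=labels,
        col_labels=("co_member", "not_co_member"),
    )
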