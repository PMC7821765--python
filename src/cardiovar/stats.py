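"""Subgroup statistics and percentage utilities.

Continuous clinical covariates are screened with Shapiro–Wilk and, being
skewed in practice, compared across arms with the Kruskal–Wallis test
followed by Dunn's pairwise rank comparisons with Bonferroni correction
(the convention of mainstream clinical-statistics software).  Carrier
counts are compared with the chi-square test, falling back to the
two-sided Fisher exact test for 2x2 tables with any expected count
below 5.

All printed percentages use half-up rounding so that tables recompute
exactly from their integer numerators and denominators.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from fractions import Fraction
from typing import Dict, List, Optional, Sequence

import numpy as np
from scipy import stats as sps

__all__ = [
    "InsufficientDataError",
    "DegenerateTableError",
    "percent",
    "round_half_up",
    "format_p",
    "normality_gate",
    "PairwiseComparison",
    "GroupTestResult",
    "kruskal_wallis_pairwise",
    "two_sided_fisher",
    "CarrierTestResult",
    "carrier_test",
]


class InsufficientDataError(ValueError):
    """Too few or degenerate observations for the requested test."""


class DegenerateTableError(ValueError):
    """A contingency table with an all-zero margin."""


def round_half_up(x: float, decimals: int = 1) -> float:
    """Round with ties away from zero (the convention of printed tables),
    avoiding binary-float artifacts for ratio-valued inputs."""
    q = Decimal(1).scaleb(-decimals)
    if isinstance(x, Fraction):
        d = Decimal(x.numerator) / Decimal(x.denominator)
    else:
        d = Decimal(str(x))
    return float(d.quantize(q, rounding=ROUND_HALF_UP))


def percent(n, d, decimals: int = 1) -> Optional[float]:
    """100*n/d rounded half-up; None (undefined) when d == 0."""
    if d == 0:
        return None
    if isinstance(n, int) and isinstance(d, int):
        return round_half_up(Fraction(100 * n, d), decimals)
    return round_half_up(100.0 * n / d, decimals)


def format_p(p: float) -> str:
    """Display format for p-values: three decimals, '0.000' below 0.0005."""
    return f"{p:.3f}"


def normality_gate(sample: Sequence[float], alpha: float = 0.05) -> str:
    """Shapiro–Wilk gate: 'normal' iff p > alpha, else 'non_normal'."""
    x = np.asarray(sample, dtype=float)
    if x.size < 3:
        raise InsufficientDataError(f"normality test needs n >= 3, got n = {x.size}")
    if np.ptp(x) == 0:
        raise InsufficientDataError("constant sample: normality is undefined")
    _, p = sps.shapiro(x)
    return "normal" if p > alpha else "non_normal"


@dataclass(frozen=True)
class PairwiseComparison:
    group_a: str
    group_b: str
    z: float
    p_raw: float
    p_adj: float


@dataclass
class GroupTestResult:
    variable: str
    groups: List[str]
    n: Dict[str, int]
    median: Dict[str, float]
    q25: Dict[str, float]
    q75: Dict[str, float]
    statistic: float
    p_overall: float
    pairwise: List[PairwiseComparison] = field(default_factory=list)


def _tie_correction(all_values: np.ndarray) -> float:
    _, counts = np.unique(all_values, return_counts=True)
    return float(np.sum(counts**3 - counts))


def _kw_statistic(values: np.ndarray, codes: np.ndarray, n_groups: int) -> float:
    """Tie-corrected Kruskal–Wallis H for integer-coded groups."""
    n = values.size
    ranks = sps.rankdata(values)
    h = 0.0
    for g in range(n_groups):
        r = ranks[codes == g]
        h += r.sum() ** 2 / r.size
    h = 12.0 / (n * (n + 1)) * h - 3 * (n + 1)
    tie = _tie_correction(values)
    denom = 1.0 - tie / (n**3 - n)
    if denom <= 0:
        raise InsufficientDataError("all observations tied: H is undefined")
    return h / denom


def _exact_kw_p(values: np.ndarray, codes: np.ndarray, n_groups: int) -> float:
    """Exact permutation p: share of group relabellings with H >= observed."""
    h_obs = _kw_statistic(values, codes, n_groups)
    n = values.size
    count = 0
    total = 0
    for perm in itertools.permutations(range(n)):
        permuted = codes[list(perm)]
        total += 1
        if _kw_statistic(values, permuted, n_groups) >= h_obs - 1e-12:
            count += 1
    return count / total


def kruskal_wallis_pairwise(
    values: Sequence[float],
    labels: Sequence[str],
    variable: str = "",
    method: str = "asymptotic",
) -> GroupTestResult:
    """Kruskal–Wallis across groups plus Dunn pairwise post-hocs.

    The overall p uses the chi-square approximation with tie correction
    (``method="asymptotic"``); ``method="exact"`` enumerates all group
    relabellings and is feasible only for tiny samples.  Pairwise Dunn z
    statistics use the pooled tie-corrected rank variance, two-sided
    normal p, Bonferroni-adjusted over all unordered pairs and capped
    at 1.
    """
    values = np.asarray(values, dtype=float)
    labels = list(labels)
    if len(values) != len(labels):
        raise ValueError("values and labels differ in length")
    groups = sorted(set(labels), key=labels.index)
    by_group = {g: values[[i for i, l in enumerate(labels) if l == g]] for g in groups}
    if len(groups) < 2:
        raise InsufficientDataError("need at least 2 groups")
    small = [g for g in groups if by_group[g].size < 2]
    if small:
        raise InsufficientDataError(f"groups with fewer than 2 observations: {small}")

    codes = np.array([groups.index(l) for l in labels])
    h = _kw_statistic(values, codes, len(groups))
    if method == "exact":
        p_overall = _exact_kw_p(values, codes, len(groups))
    elif method == "asymptotic":
        p_overall = float(sps.chi2.sf(h, df=len(groups) - 1))
    else:
        raise ValueError(f"unknown method {method!r}")

    # Dunn pairwise comparisons on the pooled ranks
    n = values.size
    ranks = sps.rankdata(values)
    mean_rank = {g: float(np.mean(ranks[codes == groups.index(g)])) for g in groups}
    tie = _tie_correction(values)
    sigma2_base = n * (n + 1) / 12.0 - tie / (12.0 * (n - 1))
    pairs = list(itertools.combinations(groups, 2))
    m = len(pairs)
    pairwise = []
    for a, b in pairs:
        na, nb = by_group[a].size, by_group[b].size
        se = math.sqrt(sigma2_base * (1.0 / na + 1.0 / nb))
        z = abs(mean_rank[a] - mean_rank[b]) / se if se > 0 else 0.0
        p_raw = 2.0 * float(sps.norm.sf(z))
        pairwise.append(
            PairwiseComparison(a, b, z=z, p_raw=min(p_raw, 1.0), p_adj=min(1.0, m * p_raw))
        )

    return GroupTestResult(
        variable=variable,
        groups=groups,
        n={g: int(by_group[g].size) for g in groups},
        median={g: float(np.median(by_group[g])) for g in groups},
        q25={g: float(np.percentile(by_group[g], 25)) for g in groups},
        q75={g: float(np.percentile(by_group[g], 75)) for g in groups},
        statistic=h,
        p_overall=p_overall,
        pairwise=pairwise,
    )


def two_sided_fisher(table: Sequence[Sequence[int]]) -> float:
    """Two-sided Fisher exact p for a 2x2 table by point-probability
    summation: the sum of hypergeometric outcomes no more probable than
    the observed one (the convention of R and scipy)."""
    (a, b), (c, d) = table
    return float(sps.fisher_exact([[a, b], [c, d]], alternative="two-sided")[1])


@dataclass(frozen=True)
class CarrierTestResult:
    p: float
    test: str  # "fisher_exact" or "chi_square"
    statistic: Optional[float] = None


def carrier_test(table: Sequence[Sequence[int]]) -> CarrierTestResult:
    """Compare categorical counts across arms.

    2x2 tables with any expected count < 5 use the two-sided Fisher
    exact test; everything else uses the Pearson chi-square test
    (uncorrected).  Raises :class:`DegenerateTableError` when a margin
    is all zero.
    """
    t = np.asarray(table, dtype=float)
    if t.ndim != 2 or (t < 0).any() or not np.allclose(t, np.round(t)):
        raise ValueError("contingency table must be 2-D with nonnegative integer cells")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise DegenerateTableError("table has an all-zero margin")
    expected = sps.contingency.expected_freq(t)
    if t.shape == (2, 2) and (expected < 5).any():
        return CarrierTestResult(p=two_sided_fisher(t.astype(int).tolist()), test="fisher_exact")
    chi2, p, _, _ = sps.chi2_contingency(t, correction=False)
    return CarrierTestResult(p=float(p), test="chi_square", statistic=float(chi2))
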