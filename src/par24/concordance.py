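"""Paired agreement statistics for method-comparison studies.

Implements the nonparametric toolkit used to compare two measurements of
the same quantity on the same participants (instrument vs criterion, or
replicate administrations): Spearman rank correlation, the Wilcoxon
signed-rank test for a within-pair shift, the Wilcoxon rank-sum test for
between-stratum differences, the median of per-participant differences
(which is *not* in general the difference of the medians), and
Bland-Altman bias with 95% limits of agreement.

The two Wilcoxon tests use exact null distributions on small samples
(sign-flip enumeration for the signed-rank test, rank-split enumeration for
the rank-sum test) and the usual normal approximation with continuity and
tie corrections above the exact-size thresholds.  All p-values are
two-sided.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from math import comb
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
from scipy import stats

from .errors import ContractError, ValidationError

#: Largest number of nonzero differences for which the signed-rank null is
#: enumerated exactly (2^n sign patterns, evaluated by dynamic programming).
SIGNED_RANK_EXACT_MAX_N = 25

#: Largest combined sample size for which the rank-sum null is enumerated
#: exactly over all C(n_x + n_y, n_x) rank splits.
RANK_SUM_EXACT_MAX_TOTAL = 12

#: Limits of agreement multiplier (95% under normality of differences).
LOA_MULTIPLIER = 1.96

#: Stratum cut points for the stratified comparisons.
AGE_CUT_YEARS = 60.0
BMI_CUT = 25.0

Stratifier = Literal["age", "gender", "bmi"]
PercentDenominator = Literal["per_pair", "of_medians"]


@dataclass(frozen=True)
class PairedObservation:
    """One participant's quantity under method/recall A and B, with covariates."""

    participant_id: str
    value_a: float
    value_b: float
    age: float | None = None
    gender: str | None = None
    bmi: float | None = None

    def __post_init__(self) -> None:
        if self.value_a < 0 or self.value_b < 0:
            raise ValidationError(
                f"{self.participant_id}: paired values must be nonnegative"
            )
        if self.gender is not None and self.gender not in ("male", "female"):
            raise ValidationError(
                f"{self.participant_id}: gender must be 'male' or 'female'"
            )


@dataclass(frozen=True)
class SignedRankResult:
    p_value: float
    statistic: float  # W+, sum of positive-difference ranks
    n_nonzero: int
    exact: bool
    degenerate: bool = False  # all differences zero


@dataclass(frozen=True)
class RankSumResult:
    p_value: float
    statistic: float  # rank sum of the first group
    exact: bool


@dataclass(frozen=True)
class BlandAltmanResult:
    bias: float
    loa_lower: float
    loa_upper: float
    means: np.ndarray  # per-pair (a + b) / 2
    diffs: np.ndarray  # per-pair a - b


@dataclass(frozen=True)
class AgreementResult:
    """All agreement statistics for one quantity (one table row)."""

    label: str
    n: int
    spearman_r: float
    p_method_diff: float
    median_a: float
    median_b: float
    median_diff: float
    median_pct_diff: float
    bias: float
    loa_lower: float
    loa_upper: float
    degenerate: bool = False

    def __post_init__(self) -> None:
        if not -1.0 - 1e-12 <= self.spearman_r <= 1.0 + 1e-12:
            raise ValidationError(f"spearman_r {self.spearman_r} outside [-1, 1]")
        if not 0.0 <= self.p_method_diff <= 1.0:
            raise ValidationError(f"p-value {self.p_method_diff} outside [0, 1]")
        if not self.loa_lower - 1e-9 <= self.bias <= self.loa_upper + 1e-9:
            raise ValidationError("limits of agreement must bracket the bias")


@dataclass(frozen=True)
class StratifiedComparison:
    """Per-stratum agreement plus the between-strata rank-sum p-value."""

    stratifier: Stratifier
    strata: Mapping[str, AgreementResult]
    between_strata_p: float


def _paired_arrays(pairs: Sequence[PairedObservation]) -> tuple[np.ndarray, np.ndarray]:
    a = np.array([p.value_a for p in pairs], dtype=float)
    b = np.array([p.value_b for p in pairs], dtype=float)
    return a, b


def spearman(x: Sequence[float], y: Sequence[float]) -> float:
    """Spearman rank correlation: Pearson correlation of midranks."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ContractError("vectors must have equal length")
    if x.size < 3:
        raise ContractError(f"need at least 3 pairs, got {x.size}")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValidationError("correlation undefined for a constant vector")
    rx = stats.rankdata(x)  # average ranks for ties
    ry = stats.rankdata(y)
    return float(np.corrcoef(rx, ry)[0, 1])


def spearman_pairs(pairs: Sequence[PairedObservation]) -> float:
    a, b = _paired_arrays(pairs)
    return spearman(a, b)


def _two_sided_from_cdf(p_le: float, p_ge: float) -> float:
    return float(min(1.0, 2.0 * min(p_le, p_ge)))


def _signed_rank_exact(ranks: np.ndarray, w_plus: float) -> float:
    """Exact two-sided p by enumerating all sign patterns of the ranks.

    Midranks are doubled to land the rank-sum distribution on an integer
    grid; the 2^n patterns are counted by dynamic programming.
    """
    doubled = np.rint(2.0 * ranks).astype(np.int64)
    total = int(doubled.sum())
    counts = np.zeros(total + 1)
    counts[0] = 1.0
    for value in doubled:
        shifted = np.zeros_like(counts)
        shifted[value:] = counts[: total + 1 - value]
        counts += shifted
    n_patterns = 2.0 ** len(doubled)
    w2 = int(np.rint(2.0 * w_plus))
    p_le = counts[: w2 + 1].sum() / n_patterns
    p_ge = counts[w2:].sum() / n_patterns
    return _two_sided_from_cdf(p_le, p_ge)


def wilcoxon_signed_rank(
    diffs: Sequence[float],
    zero_method: Literal["drop", "pratt"] = "drop",
    exact_max_n: int = SIGNED_RANK_EXACT_MAX_N,
) -> SignedRankResult:
    """Two-sided Wilcoxon signed-rank test on paired differences.

    Zero differences are dropped before ranking (classic Wilcoxon
    convention; ``zero_method="pratt"`` ranks them and then discards their
    ranks instead).  With at most ``exact_max_n`` nonzero differences the
    null distribution is enumerated exactly — conditional on the observed
    |differences|, so tied midranks are handled exactly too; larger samples
    use the normal approximation with continuity and tie corrections.
    """
    diffs = np.asarray(diffs, dtype=float)
    if diffs.size == 0:
        raise ContractError("need at least one difference")
    nonzero = diffs[diffs != 0]
    if nonzero.size == 0:
        return SignedRankResult(
            p_value=1.0, statistic=0.0, n_nonzero=0, exact=True, degenerate=True
        )
    if zero_method == "pratt":
        all_ranks = stats.rankdata(np.abs(diffs))
        ranks = all_ranks[diffs != 0]
    elif zero_method == "drop":
        ranks = stats.rankdata(np.abs(nonzero))
    else:
        raise ValidationError(f"unknown zero_method {zero_method!r}")
    w_plus = float(ranks[nonzero > 0].sum())
    n = nonzero.size
    if n <= exact_max_n:
        p = _signed_rank_exact(ranks, w_plus)
        return SignedRankResult(p_value=p, statistic=w_plus, n_nonzero=n, exact=True)
    mu = float(ranks.sum()) / 2.0
    variance = float(np.square(ranks).sum()) / 4.0  # equals the tie-corrected
    # n(n+1)(2n+1)/24 - sum(t^3 - t)/48 for midranks of the nonzero |diffs|
    sigma = np.sqrt(variance)
    delta = w_plus - mu
    z = (delta - 0.5 * np.sign(delta)) / sigma if sigma > 0 else 0.0
    p = float(min(1.0, 2.0 * stats.norm.sf(abs(z))))
    return SignedRankResult(p_value=p, statistic=w_plus, n_nonzero=n, exact=False)


def wilcoxon_rank_sum(
    group_x: Sequence[float],
    group_y: Sequence[float],
    exact_max_total: int = RANK_SUM_EXACT_MAX_TOTAL,
) -> RankSumResult:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    Exact by enumeration of all C(n_x + n_y, n_x) rank splits when the
    combined sample size is at most ``exact_max_total``; otherwise the
    midrank normal approximation with continuity and tie corrections.
    """
    x = np.asarray(group_x, dtype=float)
    y = np.asarray(group_y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ContractError("both groups must be non-empty")
    combined = np.concatenate([x, y])
    ranks = stats.rankdata(combined)
    w = float(ranks[: x.size].sum())
    n_x, n_y = x.size, y.size
    total = n_x + n_y
    if total <= exact_max_total:
        sums = np.array(
            [sum(ranks[list(idx)]) for idx in combinations(range(total), n_x)]
        )
        n_splits = comb(total, n_x)
        eps = 1e-9
        p_le = np.count_nonzero(sums <= w + eps) / n_splits
        p_ge = np.count_nonzero(sums >= w - eps) / n_splits
        return RankSumResult(p_value=_two_sided_from_cdf(p_le, p_ge), statistic=w, exact=True)
    mu = n_x * (total + 1) / 2.0
    _, tie_counts = np.unique(combined, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts)) / (total * (total - 1))
    variance = n_x * n_y / 12.0 * ((total + 1) - tie_term)
    sigma = np.sqrt(variance)
    delta = w - mu
    z = (delta - 0.5 * np.sign(delta)) / sigma if sigma > 0 else 0.0
    p = float(min(1.0, 2.0 * stats.norm.sf(abs(z))))
    return RankSumResult(p_value=p, statistic=w, exact=False)


def median_of_differences(
    pairs: Sequence[PairedObservation],
    denominator: PercentDenominator = "per_pair",
) -> tuple[float, float]:
    """Median of per-participant differences (a - b) and its percent version.

    Note the median of the differences does not in general equal the
    difference of the medians.  With ``denominator="per_pair"`` (default)
    the percent difference is the median of 100*(a - b)/b over pairs with
    b > 0; ``"of_medians"`` divides the median difference by the median of
    b instead.
    """
    if not pairs:
        raise ContractError("need at least one pair")
    a, b = _paired_arrays(pairs)
    diffs = a - b
    median_diff = float(np.median(diffs))
    if denominator == "per_pair":
        positive = b > 0
        if not positive.any():
            return median_diff, float("nan")
        pct = float(np.median(100.0 * diffs[positive] / b[positive]))
    elif denominator == "of_medians":
        median_b = float(np.median(b))
        pct = 100.0 * median_diff / median_b if median_b > 0 else float("nan")
    else:
        raise ValidationError(f"unknown percent denominator rule {denominator!r}")
    return median_diff, pct


def bland_altman(
    pairs: Sequence[PairedObservation], loa_multiplier: float = LOA_MULTIPLIER
) -> BlandAltmanResult:
    """Bland-Altman bias and limits of agreement for paired measurements.

    bias = mean(a - b); limits = bias +/- ``loa_multiplier`` * SD(a - b)
    with the sample (n-1) standard deviation.  The per-pair points
    ((a + b)/2, a - b) are returned for plotting by the caller.
    """
    if len(pairs) < 2:
        raise ContractError(f"need at least 2 pairs, got {len(pairs)}")
    a, b = _paired_arrays(pairs)
    diffs = a - b
    bias = float(diffs.mean())
    half_width = loa_multiplier * float(diffs.std(ddof=1))
    return BlandAltmanResult(
        bias=bias,
        loa_lower=bias - half_width,
        loa_upper=bias + half_width,
        means=(a + b) / 2.0,
        diffs=diffs,
    )


def method_agreement(
    pairs: Sequence[PairedObservation],
    label: str = "",
    denominator: PercentDenominator = "per_pair",
) -> AgreementResult:
    """Bundle all agreement statistics for one quantity into a table row."""
    if len(pairs) < 3:
        raise ContractError(f"{label or 'agreement'}: need at least 3 pairs")
    a, b = _paired_arrays(pairs)
    r = spearman(a, b)
    signed = wilcoxon_signed_rank(a - b)
    median_diff, median_pct = median_of_differences(pairs, denominator)
    ba = bland_altman(pairs)
    return AgreementResult(
        label=label,
        n=len(pairs),
        spearman_r=r,
        p_method_diff=signed.p_value,
        median_a=float(np.median(a)),
        median_b=float(np.median(b)),
        median_diff=median_diff,
        median_pct_diff=median_pct,
        bias=ba.bias,
        loa_lower=ba.loa_lower,
        loa_upper=ba.loa_upper,
        degenerate=signed.degenerate,
    )


def split_strata(
    pairs: Sequence[PairedObservation], stratifier: Stratifier
) -> dict[str, list[PairedObservation]]:
    """Partition pairs into the two study strata of ``stratifier``.

    Cut points: age at 60 years, BMI at 25.0 kg/m^2, both with >= on the
    upper stratum; gender splits into men/women.  Pairs missing the
    covariate are left out of both strata.
    """
    if stratifier == "age":
        labels = (f"age<{AGE_CUT_YEARS:g}", f"age>={AGE_CUT_YEARS:g}")
        key = lambda p: None if p.age is None else int(p.age >= AGE_CUT_YEARS)
    elif stratifier == "gender":
        labels = ("men", "women")
        key = lambda p: None if p.gender is None else int(p.gender == "female")
    elif stratifier == "bmi":
        labels = (f"bmi<{BMI_CUT:g}", f"bmi>={BMI_CUT:g}")
        key = lambda p: None if p.bmi is None else int(p.bmi >= BMI_CUT)
    else:
        raise ValidationError(f"unknown stratifier {stratifier!r}")
    out: dict[str, list[PairedObservation]] = {labels[0]: [], labels[1]: []}
    for pair in pairs:
        bucket = key(pair)
        if bucket is not None:
            out[labels[bucket]].append(pair)
    return out


def stratified_comparison(
    pairs: Sequence[PairedObservation],
    stratifier: Stratifier,
    denominator: PercentDenominator = "per_pair",
) -> StratifiedComparison:
    """Agreement per stratum plus a rank-sum test of whether the
    per-participant differences (a - b) differ between the two strata."""
    strata = split_strata(pairs, stratifier)
    for name, members in strata.items():
        if not members:
            raise ValidationError(f"stratum {name!r} is empty")
    results = {
        name: method_agreement(members, label=name, denominator=denominator)
        for name, members in strata.items()
    }
    (x, y) = (np.array([p.value_a - p.value_b for p in members]) for members in strata.values())
    between = wilcoxon_rank_sum(x, y)
    return StratifiedComparison(
        stratifier=stratifier, strata=results, between_strata_p=between.p_value
    )


def icc_two_way_random(x: Sequence[float], y: Sequence[float]) -> float:
    """Two-way random-effects single-measure intraclass correlation, ICC(2,1).

    Optional extra for reliability analyses; the tabulated reliability
    statistic of this package is the Spearman correlation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ContractError("need equal-length vectors with at least 3 pairs")
    data = np.column_stack([x, y])
    n, k = data.shape
    grand = data.mean()
    row_means = data.mean(axis=1)
    col_means = data.mean(axis=0)
    ms_rows = k * np.sum((row_means - grand) ** 2) / (n - 1)
    ms_cols = n * np.sum((col_means - grand) ** 2) / (k - 1)
    ss_err = np.sum((data - row_means[:, None] - col_means[None, :] + grand) ** 2)
    ms_err = ss_err / ((n - 1) * (k - 1))
    denom = ms_rows + (k - 1) * ms_err + k * (ms_cols - ms_err) / n
    return float((ms_rows - ms_err) / denom)
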