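"""Summary statistics and paired tests used in the comparison analyses.

Implements means with 95% t-confidence intervals and ranges, the paired
t-test, the exact Wilcoxon–Pratt signed-rank test (zero differences are
ranked with the rest and then discarded from the statistic; mid-ranks for
ties; exact two-sided p by enumeration of all 2^m sign assignments of the
nonzero differences up to a cutoff, beyond which a tie- and zero-corrected
normal approximation is used and labelled as such), Bonferroni adjustment
with the truncated reporting threshold (0.05/6 → "<0.008"), ordinal
frequency tables with a NOT_ASSESSED denominator convention, and the
pairwise comparison report (rows = stain comparisons, columns = locations).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from ._utils import round_half_up

PAIRED_T = "PAIRED_T"
WILCOXON_PRATT_EXACT = "WILCOXON_PRATT_EXACT"
WILCOXON_PRATT_APPROX = "WILCOXON_PRATT_APPROX"

NOT_ASSESSED = "NOT_ASSESSED"

DEFAULT_EXACT_CUTOFF = 20


@dataclass
class SummaryStats:
    n: int
    mean: float
    ci_low: float
    ci_high: float
    min: float
    max: float
    ci_defined: bool = True


@dataclass
class TestResult:
    method: str
    statistic: float
    p_value: float
    n_used: int
    n_excluded: int = 0


@dataclass
class PairedSample:
    """Paired measurements keyed by subject; incomplete pairs are excluded
    from tests with the exclusion count reported."""

    subject_ids: list
    x: np.ndarray
    y: np.ndarray
    labels: tuple = ("x", "y")

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=np.float64)
        self.y = np.asarray(self.y, dtype=np.float64)
        if not (len(self.subject_ids) == len(self.x) == len(self.y)):
            raise ValueError("subject_ids, x and y must have equal length")

    def complete_differences(self) -> tuple[np.ndarray, int]:
        ok = np.isfinite(self.x) & np.isfinite(self.y)
        return (self.x - self.y)[ok], int((~ok).sum())

    @classmethod
    def from_long(
        cls, df: pd.DataFrame, condition_a: str, condition_b: str,
        subject: str = "subject", condition: str = "condition", value: str = "value",
    ) -> "PairedSample":
        for cond in (condition_a, condition_b):
            if cond not in set(df[condition]):
                raise KeyError(f"condition {cond!r} missing from data")
        wide = df.pivot_table(index=subject, columns=condition, values=value, aggfunc="first")
        return cls(
            list(wide.index),
            wide[condition_a].to_numpy(),
            wide[condition_b].to_numpy(),
            (condition_a, condition_b),
        )


def summarize(values) -> SummaryStats:
    """Mean, two-sided 95% t-interval and range; n=1 flags the CI undefined."""
    v = np.asarray(values, dtype=np.float64)
    v = v[np.isfinite(v)]
    n = len(v)
    if n == 0:
        raise ValueError("cannot summarize an empty sample")
    mean = float(v.mean())
    if n == 1:
        return SummaryStats(1, mean, float("nan"), float("nan"), mean, mean, ci_defined=False)
    sem = v.std(ddof=1) / np.sqrt(n)
    tq = sps.t.ppf(0.975, n - 1)
    return SummaryStats(n, mean, float(mean - tq * sem), float(mean + tq * sem), float(v.min()), float(v.max()))


def paired_t(sample: PairedSample) -> TestResult:
    """Two-sided paired t-test on complete pairs."""
    d, n_excl = sample.complete_differences()
    n = len(d)
    if n < 2:
        raise ValueError("paired t-test needs at least 2 complete pairs")
    sd = d.std(ddof=1)
    if sd == 0:
        # Identical pairs are a well-defined no-difference result (t=0, p=1);
        # a constant nonzero difference leaves t undefined and is an error.
        if np.all(d == 0):
            return TestResult(PAIRED_T, 0.0, 1.0, n, n_excl)
        raise ValueError("differences have zero variance; paired t-test is degenerate")
    t = float(d.mean() / (sd / np.sqrt(n)))
    p = float(2 * sps.t.sf(abs(t), n - 1))
    return TestResult(PAIRED_T, t, p, n, n_excl)


def _pratt_ranks(d: np.ndarray) -> tuple[np.ndarray, int]:
    """Mid-ranks of |d| including zeros; returns (ranks of nonzero d, #zeros)."""
    ranks = sps.rankdata(np.abs(d))
    nonzero = d != 0
    return ranks[nonzero], int((~nonzero).sum())


def _exact_wplus_distribution(ranks: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """All 2^m values of W+ by meet-in-the-middle enumeration."""
    m = len(ranks)
    half = m // 2
    def sums(rs: np.ndarray) -> np.ndarray:
        s = np.zeros(1)
        for r in rs:
            s = np.concatenate([s, s + r])
        return s
    a = sums(ranks[:half])
    b = sums(ranks[half:])
    allsums = (a[:, None] + b[None, :]).ravel()
    return allsums, np.full(allsums.shape, 1.0 / len(allsums))


def wilcoxon_pratt(sample: PairedSample, exact_cutoff: int = DEFAULT_EXACT_CUTOFF) -> TestResult:
    """Wilcoxon signed-rank test with Pratt zero handling.

    Exact two-sided p (doubling rule, capped at 1) by full sign-assignment
    enumeration when the number of nonzero differences is at most
    ``exact_cutoff``; otherwise a normal approximation with the Pratt zero
    correction and tie-corrected variance.  All-zero differences give p=1.
    """
    d, n_excl = sample.complete_differences()
    if len(d) == 0:
        raise ValueError("no complete pairs")
    ranks_nz, n_zero = _pratt_ranks(d)
    m = len(ranks_nz)
    w_plus = float(ranks_nz[(d[d != 0] > 0)].sum())
    if m == 0:
        return TestResult(WILCOXON_PRATT_EXACT, w_plus, 1.0, len(d), n_excl)
    if m <= exact_cutoff:
        support, probs = _exact_wplus_distribution(ranks_nz)
        eps = 1e-9
        p_le = probs[support <= w_plus + eps].sum()
        p_ge = probs[support >= w_plus - eps].sum()
        p = min(1.0, 2.0 * min(p_le, p_ge))
        return TestResult(WILCOXON_PRATT_EXACT, w_plus, float(p), len(d), n_excl)
    # Normal approximation with Pratt zero and tie corrections.
    n_tot = len(d)
    z = n_zero
    mean = (n_tot * (n_tot + 1) - z * (z + 1)) / 4.0
    var = (n_tot * (n_tot + 1) * (2 * n_tot + 1) - z * (z + 1) * (2 * z + 1)) / 24.0
    _, tie_counts = np.unique(ranks_nz, return_counts=True)
    var -= (tie_counts**3 - tie_counts).sum() / 48.0
    if var <= 0:
        return TestResult(WILCOXON_PRATT_APPROX, w_plus, 1.0, n_tot, n_excl)
    zstat = (w_plus - mean) / np.sqrt(var)
    p = float(2 * sps.norm.sf(abs(zstat)))
    return TestResult(WILCOXON_PRATT_APPROX, w_plus, min(p, 1.0), n_tot, n_excl)


# Backwards-friendly alias used elsewhere in the package.
wilcoxon_pratt_exact = wilcoxon_pratt


@dataclass
class BonferroniThreshold:
    alpha: float
    m: int
    threshold: float
    reported: float  # threshold truncated to 3 decimals, as printed

    def __str__(self) -> str:
        return f"<{self.reported:.3f}"


def bonferroni(alpha: float, m: int) -> BonferroniThreshold:
    """Bonferroni-adjusted significance threshold alpha/m.

    The ``reported`` field truncates to three decimals, the convention used
    when a threshold like 0.05/6 is printed as "<0.008".
    """
    if not (0 < alpha < 1):
        raise ValueError("alpha must be in (0, 1)")
    if m < 1:
        raise ValueError("m must be a positive integer")
    thr = alpha / m
    return BonferroniThreshold(alpha, m, thr, np.floor(thr * 1000) / 1000)


def frequency_table(values, categories) -> pd.DataFrame:
    """Ordinal n (%) table with a NOT_ASSESSED-aware denominator.

    Percentages are 100*count/assessed_n rounded half-up to one decimal;
    NOT_ASSESSED entries are excluded from the denominator and reported in
    the table attrs (``assessed_n``, ``not_assessed_n``).
    """
    vals = pd.Series(list(values))
    na = int((vals == NOT_ASSESSED).sum()) + int(vals.isna().sum())
    assessed = vals[(vals != NOT_ASSESSED) & vals.notna()]
    n = len(assessed)
    if n == 0:
        raise ValueError("no assessed values; frequency table undefined")
    unknown = set(assessed) - set(categories)
    if unknown:
        raise ValueError(f"values {sorted(map(str, unknown))} not covered by categories")
    counts = [int((assessed == c).sum()) for c in categories]
    pct = [round_half_up(100.0 * c / n, 1) for c in counts]
    out = pd.DataFrame({"category": list(categories), "n": counts, "pct": pct})
    out.attrs["assessed_n"] = n
    out.attrs["not_assessed_n"] = na
    return out


def frequency_table_from_counts(counts: dict, not_assessed: int = 0) -> pd.DataFrame:
    """Same table computed directly from per-category counts."""
    values = [c for c, k in counts.items() for _ in range(k)]
    values += [NOT_ASSESSED] * not_assessed
    return frequency_table(values, list(counts))


def included_after_exclusions(enrolled: int, exclusions) -> int:
    """Cohort bookkeeping: participants remaining after listed exclusions."""
    if enrolled < 0 or any(e < 0 for e in exclusions):
        raise ValueError("counts must be non-negative")
    out = enrolled - sum(exclusions)
    if out < 0:
        raise ValueError("exclusions exceed enrolment")
    return out


@dataclass
class PairwiseComparisonReport:
    p_values: pd.DataFrame  # rows = comparisons, columns = locations
    significant: pd.DataFrame
    threshold: BonferroniThreshold
    methods: pd.DataFrame = field(default=None, repr=False)  # type: ignore[assignment]


def pairwise_comparison_report(
    data: pd.DataFrame,
    comparisons: list[tuple[str, str]],
    alpha: float = 0.05,
    exact_cutoff: int = DEFAULT_EXACT_CUTOFF,
    subject: str = "subject",
    condition: str = "condition",
    value: str = "value",
    location: str = "location",
) -> PairwiseComparisonReport:
    """One Wilcoxon–Pratt test per comparison per location.

    ``data`` is long-format (subject, condition, value[, location]).  The
    significance flag uses the Bonferroni threshold for the number of
    comparisons per location.
    """
    if location not in data:
        data = data.assign(**{location: "ALL"})
    locations = list(pd.unique(data[location]))
    thr = bonferroni(alpha, len(comparisons))
    rows = [f"{a} vs. {b}" for a, b in comparisons]
    pvals = pd.DataFrame(index=rows, columns=locations, dtype=float)
    methods = pd.DataFrame(index=rows, columns=locations, dtype=object)
    for loc in locations:
        sub = data[data[location] == loc]
        for (a, b), row in zip(comparisons, rows):
            sample = PairedSample.from_long(sub, a, b, subject, condition, value)
            res = wilcoxon_pratt(sample, exact_cutoff)
            pvals.loc[row, loc] = res.p_value
            methods.loc[row, loc] = res.method
    return PairwiseComparisonReport(pvals, pvals < thr.threshold, thr, methods)
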