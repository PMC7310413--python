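"""Paired two-technique cohort statistics.

The cohort design is paired: every patient is planned with both techniques,
so per-metric comparisons use the exact Wilcoxon signed-rank test.  The
exact null distribution is computed by dynamic programming over all ``2^n``
sign assignments of the realized rank multiset, which stays correct in the
presence of midranks from tied absolute differences (a conditional exact
test); zero differences are dropped before ranking (Wilcoxon's convention)
and the number dropped is reported.

Complementary summaries mirror a clinical comparison table: per-arm
mean +/- SD (sample SD, n-1 denominator), per-patient differences
(reference minus rival), per-patient relative risk (rival / reference) with
its cohort mean +/- SD, and counts of patients whose NTCP difference falls
in the bins <=5, >5 to <=10, >10 percentage points.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata, wilcoxon as _scipy_wilcoxon

from .errors import DegenerateSampleError, RangeError, UndefinedValueError

__all__ = [
    "PairedSample",
    "WilcoxonResult",
    "ComparisonRow",
    "exact_wilcoxon_signed_rank",
    "compare_paired_metric",
    "delta_ntcp_bins",
    "relative_risk",
    "summarize_volumes",
]

_EXACT_LIMIT = 25


@dataclass(frozen=True)
class PairedSample:
    """Per-patient values for two techniques, in consistent patient order.

    ``values_a`` is the reference arm (minuend of the difference,
    denominator of the relative risk)."""

    label_a: str
    label_b: str
    values_a: np.ndarray
    values_b: np.ndarray
    unit: str = ""

    def __post_init__(self) -> None:
        a = np.asarray(self.values_a, dtype=float)
        b = np.asarray(self.values_b, dtype=float)
        object.__setattr__(self, "values_a", a)
        object.__setattr__(self, "values_b", b)
        if a.ndim != 1 or a.shape != b.shape or a.size < 1:
            raise RangeError("paired sample needs equal-length arms, n >= 1")

    @property
    def n(self) -> int:
        return int(self.values_a.size)


@dataclass(frozen=True)
class WilcoxonResult:
    statistic: float          # smaller of the positive/negative rank sums
    pvalue: float
    n_used: int               # pairs remaining after dropping zero differences
    n_zero_dropped: int
    method: str               # "exact" or "normal"
    note: str = ""


def _signed_rank_counts(ranks2: np.ndarray) -> np.ndarray:
    """Distribution of the positive rank sum over all sign assignments.

    ``ranks2`` holds doubled ranks (integers even with midranks).
    ``counts[s]`` is the number of assignments with positive rank sum ``s/2``.
    """
    total = int(ranks2.sum())
    counts = np.zeros(total + 1, dtype=np.int64)
    counts[0] = 1
    for r in ranks2:
        r = int(r)
        counts[r:] = counts[r:] + counts[: total + 1 - r]
    return counts


def exact_wilcoxon_signed_rank(values_a, values_b) -> WilcoxonResult:
    """Exact two-sided Wilcoxon signed-rank test for paired data.

    ``W`` is the smaller of the positive/negative rank sums of the non-zero
    differences (midranks for ties); the two-sided p doubles the exact lower
    tail, ``p = min(1, 2 * P(W* <= W))``.  Above 25 informative pairs the
    normal approximation is used and flagged in ``method``.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise RangeError("paired test needs equal-length 1-d samples")
    d = a - b
    nonzero = d != 0
    n_dropped = int((~nonzero).sum())
    d = d[nonzero]
    n = d.size
    if n == 0:
        raise DegenerateSampleError(
            "all paired differences are zero; the signed-rank test is undefined")
    ranks = rankdata(np.abs(d))
    w_pos = float(ranks[d > 0].sum())
    w_neg = float(ranks[d < 0].sum())
    w = min(w_pos, w_neg)
    note = f"{n_dropped} zero difference(s) dropped" if n_dropped else ""
    if n > _EXACT_LIMIT:
        res = _scipy_wilcoxon(d, zero_method="wilcox", correction=True,
                              method="approx")
        return WilcoxonResult(w, float(res.pvalue), n, n_dropped, "normal",
                              (note + "; " if note else "")
                              + "normal approximation (n > 25)")
    ranks2 = np.rint(2 * ranks).astype(np.int64)
    counts = _signed_rank_counts(ranks2)
    w2 = int(round(2 * w))
    lower_tail = counts[: w2 + 1].sum() / counts.sum()
    p = min(1.0, 2.0 * float(lower_tail))
    return WilcoxonResult(w, p, n, n_dropped, "exact", note)


@dataclass(frozen=True)
class ComparisonRow:
    """One metric/endpoint's paired-cohort comparison."""

    metric: str
    unit: str
    label_a: str
    label_b: str
    mean_a: float
    sd_a: float
    mean_b: float
    sd_b: float
    p_two_sided: float                      # nan when degenerate
    significant: bool | None
    deltas: np.ndarray = field(repr=False)  # per patient, a - b
    rr: np.ndarray | None = field(default=None, repr=False)  # b / a
    rr_mean: float | None = None
    rr_sd: float | None = None
    delta_bin_counts: tuple[int, int, int] | None = None
    n_zero_dropped: int = 0
    note: str = ""


def _mean_sd(x: np.ndarray) -> tuple[float, float]:
    mean = float(np.mean(x))
    sd = float(np.std(x, ddof=1)) if x.size > 1 else float("nan")
    return mean, sd


def compare_paired_metric(sample: PairedSample, metric: str = "",
                          alpha: float = 0.05,
                          include_rr: bool = False,
                          include_bins: bool = False) -> ComparisonRow:
    """Build one comparison-table row from a paired sample.

    A degenerate sample (all differences zero) yields ``p = nan`` with an
    explanatory note instead of raising, so a cohort run can continue.
    ``include_bins`` assumes the values are percentages (NTCP in %), since
    the difference bins are defined in percentage points.
    """
    mean_a, sd_a = _mean_sd(sample.values_a)
    mean_b, sd_b = _mean_sd(sample.values_b)
    deltas = sample.values_a - sample.values_b
    note = ""
    try:
        res = exact_wilcoxon_signed_rank(sample.values_a, sample.values_b)
        p, signif, dropped = res.pvalue, res.pvalue < alpha, res.n_zero_dropped
        if res.note:
            note = res.note
    except DegenerateSampleError as exc:
        p, signif, dropped, note = float("nan"), None, sample.n, str(exc)
    rr = rr_mean = rr_sd = None
    if include_rr:
        rr, rr_mean, rr_sd = relative_risk(sample)
    bins = delta_ntcp_bins(deltas) if include_bins else None
    return ComparisonRow(metric, sample.unit, sample.label_a, sample.label_b,
                         mean_a, sd_a, mean_b, sd_b, p, signif, deltas, rr,
                         rr_mean, rr_sd, bins, dropped, note)


def delta_ntcp_bins(deltas) -> tuple[int, int, int]:
    """Count patients with NTCP difference <=5, >5 to <=10, >10 points."""
    d = np.asarray(deltas, dtype=float)
    if not np.all(np.isfinite(d)):
        raise RangeError("difference bins need finite values")
    le5 = int((d <= 5.0).sum())
    mid = int(((d > 5.0) & (d <= 10.0)).sum())
    gt10 = int((d > 10.0).sum())
    return le5, mid, gt10


def relative_risk(sample: PairedSample) -> tuple[np.ndarray, float, float]:
    """Per-patient risk ratios rival/reference, with cohort mean +/- SD.

    The cohort summary is the mean of the per-patient ratios (not the ratio
    of means), so its SD is the patient-to-patient spread of the ratio.
    """
    a, b = sample.values_a, sample.values_b
    zero = np.nonzero(a == 0)[0]
    if zero.size:
        raise UndefinedValueError(
            f"reference value is zero for patient index {int(zero[0])}; "
            "relative risk undefined")
    rr = b / a
    mean, sd = _mean_sd(rr)
    return rr, mean, sd


def summarize_volumes(values, unit: str = "cc") -> tuple[float, tuple[float, float]]:
    """Sample median and (min, max) range."""
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise RangeError("cannot summarize an empty sample")
    return float(np.median(x)), (float(x.min()), float(x.max()))
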