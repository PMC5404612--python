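"""Occupancy (ΔBP) and test–retest reliability statistics.

ΔBP is the percent reduction in binding potential from baseline to the
post-challenge scan, ``100 * (BP_base - BP_post) / BP_base`` — positive when
BP falls, i.e. when released dopamine competes with the tracer.  Reliability
of baseline BP across the two baseline scans is summarized by an intraclass
correlation, a Wilcoxon signed-rank test, and the mean absolute percent
difference.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "DeltaBPResult",
    "TestRetestResult",
    "delta_bp",
    "test_retest_variability",
    "icc_baseline",
    "wilcoxon_signed_rank",
]


@dataclass(frozen=True)
class DeltaBPResult:
    subject_id: str
    condition: str
    region: str
    bp_baseline: float
    bp_post: float
    delta_bp: float            # percent; NaN + flag when baseline BP is 0
    undefined: bool = False


@dataclass(frozen=True)
class TestRetestResult:
    region: str
    icc: float
    icc_undefined: bool
    wilcoxon_p: float
    wilcoxon_degenerate: bool
    mean_abs_percent_var: float


def delta_bp(
    bp_baseline: float | np.ndarray,
    bp_post: float | np.ndarray,
    fractional: bool = False,
) -> float | np.ndarray:
    """Percent (or fractional) change in BP from baseline to post scan.

    ``100 * (bp_baseline - bp_post) / bp_baseline``; positive values mean BP
    decreased.  Undefined (NaN) where the baseline BP is zero.
    """
    base = np.asarray(bp_baseline, dtype=float)
    post = np.asarray(bp_post, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(base != 0.0, (base - post) / base, np.nan)
    if not fractional:
        out = 100.0 * out
    if np.ndim(bp_baseline) == 0 and np.ndim(bp_post) == 0:
        return float(out)
    return out


def test_retest_variability(bp_scan1: np.ndarray, bp_scan2: np.ndarray) -> float:
    """Mean intra-subject absolute percent difference between two scans.

    Symmetric form: ``mean(100 * |bp1 - bp2| / ((bp1 + bp2) / 2))``.
    """
    a = np.asarray(bp_scan1, dtype=float)
    b = np.asarray(bp_scan2, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or a.size < 1:
        raise ValueError("scan vectors must be equal-length 1-D with n >= 1")
    if np.any(a <= 0) or np.any(b <= 0):
        raise ValueError("BP values must be positive for percent variability")
    return float(np.mean(100.0 * np.abs(a - b) / ((a + b) / 2.0)))


# the name matches the statistic, not a test case
test_retest_variability.__test__ = False  # type: ignore[attr-defined]


def icc_baseline(bp_matrix: np.ndarray) -> tuple[float, bool]:
    """ICC(1,1): one-way random-effects, single-measure intraclass correlation.

    The two baseline scans are unordered replicates, so the one-way model is
    appropriate (no scan/session fixed effect).  Computed from the one-way
    ANOVA decomposition::

        ICC = (BMS - WMS) / (BMS + (k - 1) * WMS)

    Returns ``(icc, undefined_flag)``; flagged when the total variance is
    zero (all entries identical).
    """
    m = np.asarray(bp_matrix, dtype=float)
    if m.ndim != 2 or m.shape[0] < 2 or m.shape[1] < 2:
        raise ValueError("need a subjects x scans matrix with >= 2 subjects, >= 2 scans")
    n, k = m.shape
    grand = m.mean()
    if np.allclose(m, grand):
        return float("nan"), True
    row_means = m.mean(axis=1)
    bms = k * np.sum((row_means - grand) ** 2) / (n - 1)
    wms = np.sum((m - row_means[:, None]) ** 2) / (n * (k - 1))
    denom = bms + (k - 1) * wms
    if denom == 0.0:
        return float("nan"), True
    return float((bms - wms) / denom), False


def wilcoxon_signed_rank(bp_scan1: np.ndarray, bp_scan2: np.ndarray) -> tuple[float, bool]:
    """Two-sided Wilcoxon signed-rank p for paired scans.

    Zero differences are dropped; the exact null distribution is used for
    n <= 25 pairs, the normal approximation with continuity correction
    above.  All-zero differences return ``(1.0, degenerate=True)``.
    """
    a = np.asarray(bp_scan1, dtype=float)
    b = np.asarray(bp_scan2, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired vectors must share length")
    d = a - b
    d = d[d != 0.0]
    if d.size == 0:
        return 1.0, True
    method = "exact" if d.size <= 25 else "approx"
    res = stats.wilcoxon(d, alternative="two-sided", method=method, correction=True)
    return float(res.pvalue), False
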