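"""Test-retest reliability statistics.

Repeatability of the binding-potential measurement is summarized by the
per-subject test-retest variability

    variability% = 100 * |x1 - x2| / ((x1 + x2) / 2),

its group mean, a group mean with relative standard error, and an exact
two-sided Wilcoxon signed-rank test of the paired test/retest values.

The module also carries the closed-form noise calibration used for
simulation: for paired measurements x = mu * (1 + eps) with eps ~
N(0, sigma^2) independent, the expected variability percent is
100 * 2 * sigma / sqrt(pi) (to first order in sigma), so a target
variability V maps to sigma = V * sqrt(pi) / 200.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "TestRetestResult",
    "testretest_variability",
    "wilcoxon_signed_rank",
    "group_summary",
    "testretest_summary",
    "cv_for_target_variability",
    "simulate_variability_pairs",
    "DEFAULT_TARGET_VARIABILITY_PERCENT",
]

#: default target test-retest variability of the reliability simulation (%)
DEFAULT_TARGET_VARIABILITY_PERCENT = 9.0


@dataclass
class TestRetestResult:
    subject_ids: list
    bp_test: np.ndarray
    bp_retest: np.ndarray
    variability_percent: np.ndarray
    mean_variability_percent: float
    wilcoxon_p: float
    mean_test: float
    rse_test_percent: float
    mean_retest: float
    rse_retest_percent: float


def testretest_variability(x1: float, x2: float) -> float:
    """Absolute difference over the pairwise mean, as a percentage.

    Symmetric in its arguments and invariant to a common positive scale.
    """
    mean = (x1 + x2) / 2.0
    if mean <= 0:
        raise ValueError("pairwise mean must be positive")
    return 100.0 * abs(x1 - x2) / mean


def _signed_ranks(diffs: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Average ranks of |d| and the sign pattern, zero differences dropped."""
    d = np.asarray(diffs, dtype=float)
    d = d[d != 0.0]
    ranks = stats.rankdata(np.abs(d))  # average ranks on ties
    return ranks, d > 0


def wilcoxon_signed_rank(pairs, mode: str = "exact") -> float:
    """Two-sided Wilcoxon signed-rank p-value for paired measurements.

    ``pairs`` is a sequence of (x1, x2).  Zero differences are dropped
    before ranking.  For n <= 12 the exact null distribution of the
    positive-rank sum W is obtained by enumerating all 2^n sign patterns
    (with average ranks for tied magnitudes); above 12 a normal
    approximation with continuity and tie correction is used.  If all
    differences are zero the test is degenerate and p = 1.
    """
    arr = np.asarray(pairs, dtype=float)
    diffs = arr[:, 0] - arr[:, 1]
    ranks, positive = _signed_ranks(diffs)
    n = len(ranks)
    if n == 0:
        return 1.0
    if n < 2:
        raise ValueError("need at least two non-zero differences")
    w = float(ranks[positive].sum())
    use_exact = mode in ("exact", "auto") and n <= 12
    if use_exact:
        # all 2^n sign assignments, vectorized over a bit table
        patterns = (np.arange(2 ** n)[:, None] >> np.arange(n)[None, :]) & 1
        w_all = patterns @ ranks
        p_le = np.mean(w_all <= w + 1e-12)
        p_ge = np.mean(w_all >= w - 1e-12)
        return float(min(1.0, 2.0 * min(p_le, p_ge)))
    mean_w = n * (n + 1) / 4.0
    # tie correction on the variance
    _, counts = np.unique(ranks, return_counts=True)
    tie_term = np.sum(counts ** 3 - counts) / 48.0
    var_w = n * (n + 1) * (2 * n + 1) / 24.0 - tie_term
    if var_w <= 0:
        return 1.0
    z = (w - mean_w - 0.5 * np.sign(w - mean_w)) / np.sqrt(var_w)
    return float(min(1.0, 2.0 * stats.norm.sf(abs(z))))


def group_summary(values) -> tuple[float, float]:
    """(mean, relative standard error percent) of a group of measurements.

    RSE% = 100 * (SD / sqrt(n)) / mean, with the sample SD (n-1).  A
    non-positive mean leaves the RSE undefined (returned as nan).
    """
    v = np.asarray(values, dtype=float)
    if len(v) < 2:
        raise ValueError("need at least two values")
    mean = float(v.mean())
    se = float(v.std(ddof=1) / np.sqrt(len(v)))
    if mean <= 0:
        return mean, float("nan")
    return mean, 100.0 * se / mean


def testretest_summary(bp_test, bp_retest, subject_ids=None) -> TestRetestResult:
    """Full test-retest report for paired per-subject BP values."""
    x1 = np.asarray(bp_test, dtype=float)
    x2 = np.asarray(bp_retest, dtype=float)
    if x1.shape != x2.shape:
        raise ValueError("test and retest arrays must align")
    ids = list(subject_ids) if subject_ids is not None else list(range(len(x1)))
    var = np.array([testretest_variability(a, b) for a, b in zip(x1, x2)])
    p = wilcoxon_signed_rank(np.stack([x1, x2], axis=1))
    m1, rse1 = group_summary(x1)
    m2, rse2 = group_summary(x2)
    return TestRetestResult(ids, x1, x2, var, float(var.mean()), p,
                            m1, rse1, m2, rse2)


def cv_for_target_variability(target_percent: float) -> float:
    """Per-measurement noise SD sigma giving an expected variability of V%.

    Inverts E[variability%] ~= 100 * 2 * sigma / sqrt(pi):
    sigma = V * sqrt(pi) / 200.
    """
    if target_percent < 0:
        raise ValueError("target variability must be non-negative")
    return target_percent * np.sqrt(np.pi) / 200.0


def simulate_variability_pairs(
    n_pairs: int,
    target_percent: float = DEFAULT_TARGET_VARIABILITY_PERCENT,
    mu: float = 6.6,
    seed: int | np.random.Generator = 0,
) -> float:
    """Mean test-retest variability over simulated noisy measurement pairs.

    Each measurement is mu * (1 + eps) with eps ~ N(0, sigma^2), sigma set
    by :func:`cv_for_target_variability`.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    sigma = cv_for_target_variability(target_percent)
    x = mu * (1.0 + rng.normal(0.0, sigma, size=(n_pairs, 2)))
    means = x.mean(axis=1)
    valid = means > 0
    return float((100.0 * np.abs(x[valid, 0] - x[valid, 1]) / means[valid]).mean())
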