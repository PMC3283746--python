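"""Statistical tests used throughout the pipeline.

Thin, uniformly-reported wrappers: Pearson correlation (t-based p), Welch's
t, Mann-Whitney U (normal approximation with tie correction and continuity
correction; exact enumeration for small samples), Fisher's exact 2x2 test by
hypergeometric summation, Grubbs's single-outlier test and the add-one
empirical permutation p.

Every test returns a :class:`TestReport` so pipeline TSVs embed a uniform set
of fields.  All tests are two-sided unless stated otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from math import sqrt

import numpy as np
from scipy import stats as sps
from scipy.special import gammaln

__all__ = [
    "TestReport",
    "pearson",
    "welch_t",
    "mann_whitney_u",
    "fisher_exact_2x2",
    "grubbs_test",
    "empirical_p",
]


@dataclass
class TestReport:
    statistic: float
    p_value: float
    n: tuple[int, ...]
    method: str
    direction: str = "two-sided"
    extra: dict = field(default_factory=dict)
    reliable: bool = True

    def __post_init__(self) -> None:
        if not (np.isnan(self.p_value) or 0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p-value {self.p_value} outside [0, 1]")


def pearson(x, y) -> TestReport:
    """Pearson r with the two-sided t-based p (t = r*sqrt((n-2)/(1-r^2)))."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise ValueError("pearson needs two equal-length vectors of length >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("pearson requires nonzero variance in both vectors")
    r, p = sps.pearsonr(x, y)
    return TestReport(float(r), float(p), (len(x),), "pearson")


def welch_t(a, b) -> TestReport:
    """Welch's unequal-variance t-test, two-sided."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("welch_t needs n >= 2 per sample")
    res = sps.ttest_ind(a, b, equal_var=False)
    return TestReport(
        float(res.statistic),
        float(res.pvalue),
        (len(a), len(b)),
        "welch_t",
        extra={"df": float(res.df), "mean_a": float(a.mean()), "mean_b": float(b.mean())},
    )


def _mwu_exact_p(a: np.ndarray, b: np.ndarray, u: float) -> float:
    """Two-sided exact Mann-Whitney p by enumerating all rank assignments."""
    pooled = np.concatenate([a, b])
    n1, n2 = len(a), len(b)
    mu = n1 * n2 / 2.0
    obs_dev = abs(u - mu)
    ranks = sps.rankdata(pooled)
    count = 0
    total = 0
    for idx in combinations(range(n1 + n2), n1):
        r1 = ranks[list(idx)].sum()
        u1 = r1 - n1 * (n1 + 1) / 2.0
        total += 1
        if abs(u1 - mu) >= obs_dev - 1e-12:
            count += 1
    return count / total


def mann_whitney_u(a, b, method: str = "auto") -> TestReport:
    """Mann-Whitney U test.

    ``method``: 'asymptotic' uses the normal approximation with midranks,
    tie-corrected variance and continuity correction; 'exact' enumerates all
    rank assignments (feasible for min(n) <= 8); 'auto' picks 'exact' when
    both samples have <= 8 observations.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 1 or len(b) < 1:
        raise ValueError("mann_whitney_u needs n >= 1 per sample")
    u = float(sps.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic").statistic)
    if method == "auto":
        method = "exact" if max(len(a), len(b)) <= 8 else "asymptotic"
    if method == "exact":
        p = _mwu_exact_p(a, b, u)
    else:
        p = float(
            sps.mannwhitneyu(
                a, b, alternative="two-sided", method="asymptotic", use_continuity=True
            ).pvalue
        )
    return TestReport(
        u,
        p,
        (len(a), len(b)),
        f"mann_whitney_u[{method}]",
        extra={"median_a": float(np.median(a)), "median_b": float(np.median(b))},
    )


def _hypergeom_logpmf_vector(n: int, r1: int, c1: int) -> tuple[np.ndarray, np.ndarray]:
    """Log-pmf of table cell ``a`` given margins (total n, row1 r1, col1 c1)."""
    a_lo = max(0, r1 + c1 - n)
    a_hi = min(r1, c1)
    a = np.arange(a_lo, a_hi + 1)
    logpmf = (
        gammaln(r1 + 1)
        - gammaln(a + 1)
        - gammaln(r1 - a + 1)
        + gammaln(n - r1 + 1)
        - gammaln(c1 - a + 1)
        - gammaln(n - r1 - c1 + a + 1)
        - (gammaln(n + 1) - gammaln(c1 + 1) - gammaln(n - c1 + 1))
    )
    return a, logpmf


def fisher_exact_2x2(table) -> TestReport:
    """Two-sided Fisher's exact test on a 2x2 count table.

    The p-value sums the hypergeometric probabilities of all tables (with the
    observed margins) whose probability does not exceed the observed table's,
    up to a small relative tolerance guarding against round-off.
    """
    t = np.asarray(table, dtype=np.int64)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("fisher_exact_2x2 needs a 2x2 nonnegative integer table")
    a, b, c, d = int(t[0, 0]), int(t[0, 1]), int(t[1, 0]), int(t[1, 1])
    n = a + b + c + d
    if n < 1:
        raise ValueError("fisher_exact_2x2: empty table")
    avals, logpmf = _hypergeom_logpmf_vector(n, a + b, a + c)
    pmf = np.exp(logpmf)
    obs = pmf[avals == a][0]
    p = float(pmf[pmf <= obs * (1 + 1e-7)].sum())
    p = min(1.0, p)
    if b * c == 0:
        odds = float("inf") if a * d > 0 else float("nan")
    else:
        odds = a * d / (b * c)
    return TestReport(
        odds, p, (a + b, c + d), "fisher_exact", extra={"table": [[a, b], [c, d]]}
    )


def grubbs_test(x) -> TestReport:
    """Grubbs's single-outlier test, two-sided.

    G = max|x_i - mean| / sd (sample sd, ddof=1); the p-value comes from the
    t-distribution relation for the one-outlier statistic:
    t^2 = G^2 n (n-2) / ((n-1)^2 - n G^2),  p = min(1, 2n * P(T_{n-2} > t)).
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n < 3:
        raise ValueError("grubbs_test needs n >= 3")
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("grubbs_test: zero variance")
    dev = np.abs(x - x.mean())
    idx = int(dev.argmax())
    g = float(dev[idx] / sd)
    gmax = (n - 1) / sqrt(n)  # algebraic maximum of G
    denom = (n - 1) ** 2 - n * g * g
    if denom <= 0:
        p = 0.0
    else:
        tval = sqrt(g * g * n * (n - 2) / denom)
        p = min(1.0, 2 * n * float(sps.t.sf(tval, n - 2)))
    return TestReport(
        g, p, (n,), "grubbs", extra={"outlier_index": idx, "g_max": gmax}
    )


def empirical_p(observed: float, null_draws, tail: str = "ge") -> float:
    """Add-one empirical p: (count of null draws in the tail + 1) / (n + 1).

    Never returns 0; 0 exceedances out of 1000 trials gives 1/1001.
    """
    null_draws = np.asarray(null_draws, dtype=float)
    if null_draws.size < 1:
        raise ValueError("empirical_p needs at least one null draw")
    if tail == "ge":
        b = int((null_draws >= observed).sum())
    elif tail == "le":
        b = int((null_draws <= observed).sum())
    else:
        raise ValueError("tail must be 'ge' or 'le'")
    return (b + 1) / (null_draws.size + 1)
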