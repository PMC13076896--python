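"""Statistical tests used throughout the cohort analyses.

Small, explicit wrappers that always return a :class:`TestResult`, so every
comparison in reports carries its method name, statistic and p-value in one
shape.  The Fisher-Pitman permutation test is implemented here (no SciPy
equivalent with exact enumeration semantics); rank and count tests delegate
to SciPy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations, permutations
from typing import Optional, Sequence

import numpy as np
from scipy import stats as sps

__all__ = [
    "TestResult",
    "fisher_pitman",
    "mann_whitney",
    "fisher_exact_2x2",
    "correlation",
    "benjamini_hochberg",
]

_EXACT_LIMIT = 200_000
_REL_TOL = 1e-12


@dataclass
class TestResult:
    statistic: float
    p_value: float
    method: str
    exact: bool = False
    n_permutations: Optional[int] = None
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (-1e-12 <= self.p_value <= 1 + 1e-12):
            raise ValueError(f"p-value {self.p_value} outside [0, 1]")
        self.p_value = float(min(max(self.p_value, 0.0), 1.0))


def fisher_pitman(
    x: Sequence[float],
    y: Sequence[float],
    mode: str = "auto",
    n_perm: int = 10_000,
    seed: Optional[int] = None,
) -> TestResult:
    """Two-sided Fisher-Pitman permutation test on the difference in means.

    The statistic is ``T = mean(x) - mean(y)``.  In exact mode all
    ``C(n, |x|)`` relabelings are enumerated (used automatically when that
    count is <= 200,000); otherwise Monte Carlo permutations are drawn with
    the observed assignment included in numerator and denominator, so p > 0.
    """
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    n, nx = pooled.size, x.size
    t_obs = x.mean() - y.mean()
    thresh = abs(t_obs) * (1 - _REL_TOL) - 1e-15

    n_comb = math.comb(n, nx)
    if mode == "auto":
        mode = "exact" if n_comb <= _EXACT_LIMIT else "monte_carlo"
    if mode == "exact":
        total_sum = pooled.sum()
        hits = 0
        for idx in combinations(range(n), nx):
            sx = sum(pooled[i] for i in idx)
            t = sx / nx - (total_sum - sx) / (n - nx)
            if abs(t) >= thresh:
                hits += 1
        return TestResult(t_obs, hits / n_comb, "fisher_pitman", exact=True,
                          n_permutations=n_comb)
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100 for monte_carlo mode")
    rng = np.random.default_rng(seed)
    hits = 1  # observed assignment counted in numerator and denominator
    total_sum = pooled.sum()
    for start in range(0, n_perm, 50_000):
        chunk = min(50_000, n_perm - start)
        idx = np.argsort(rng.random((chunk, n)), axis=1)[:, :nx]
        sx = pooled[idx].sum(axis=1)
        t = sx / nx - (total_sum - sx) / (n - nx)
        hits += int((np.abs(t) >= thresh).sum())
    return TestResult(t_obs, hits / (n_perm + 1), "fisher_pitman", exact=False,
                      n_permutations=n_perm)


def mann_whitney(x, y, two_sided: bool = True) -> TestResult:
    """Mann-Whitney U with midrank ties.

    Exact null distribution when min(n) <= 8 and there are no ties; normal
    approximation with tie and continuity correction otherwise.
    """
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    no_ties = np.unique(pooled).size == pooled.size
    exact = no_ties and min(x.size, y.size) <= 8
    res = sps.mannwhitneyu(
        x, y,
        alternative="two-sided" if two_sided else "greater",
        method="exact" if exact else "asymptotic",
        use_continuity=True,
    )
    return TestResult(float(res.statistic), float(res.pvalue), "mann_whitney",
                      exact=exact)


def fisher_exact_2x2(a: int, b: int, c: int, d: int) -> TestResult:
    """Two-sided Fisher exact test on the 2x2 table [[a, b], [c, d]].

    p sums the hypergeometric probabilities of all tables with the observed
    margins whose probability is <= that of the observed table.  An all-zero
    margin gives p = 1 by convention (flagged in ``extra``).
    """
    for v in (a, b, c, d):
        if v < 0 or int(v) != v:
            raise ValueError("cells must be non-negative integers")
    table = np.array([[a, b], [c, d]], dtype=int)
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        odds = float("nan")
        return TestResult(odds, 1.0, "fisher_exact", exact=True,
                          extra={"degenerate_margin": True})
    odds, p = sps.fisher_exact(table, alternative="two-sided")
    return TestResult(float(odds), float(p), "fisher_exact", exact=True)


def correlation(
    x,
    y,
    method: str = "pearson",
    n_perm: int = 10_000,
    seed: Optional[int] = None,
) -> TestResult:
    """Pearson or Spearman correlation with a p-value.

    Pearson p comes from the t transform.  Spearman uses midranks; its p is
    an exact permutation enumeration for n <= 7, otherwise Monte Carlo
    permutation (seeded, observed ordering included).
    """
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance: correlation undefined")
    if method == "pearson":
        r, p = sps.pearsonr(x, y)
        return TestResult(float(r), float(p), "pearson", exact=False)
    if method != "spearman":
        raise ValueError(f"unknown method {method!r}")
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    r_obs = float(np.corrcoef(rx, ry)[0, 1])
    thresh = abs(r_obs) * (1 - _REL_TOL) - 1e-15
    n = x.size
    if n <= 7:
        hits = total = 0
        for perm in permutations(ry):
            total += 1
            if abs(np.corrcoef(rx, perm)[0, 1]) >= thresh:
                hits += 1
        return TestResult(r_obs, hits / total, "spearman", exact=True,
                          n_permutations=total)
    rng = np.random.default_rng(seed)
    hits = 1
    for _ in range(n_perm):
        if abs(np.corrcoef(rx, rng.permutation(ry))[0, 1]) >= thresh:
            hits += 1
    return TestResult(r_obs, hits / (n_perm + 1), "spearman", exact=False,
                      n_permutations=n_perm)


def benjamini_hochberg(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (monotone step-up)."""
    p = np.asarray(list(p_values), dtype=float)
    n = p.size
    order = np.argsort(p)
    ranked = p[order] * n / np.arange(1, n + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.clip(ranked, 0, 1)
    return out
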