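"""Shared statistical primitives for the connectivity pipelines.

This module collects the small set of tests and transforms both analysis
chains rely on: the Fisher variance-stabilising transform of a Pearson
correlation, Benjamini–Hochberg step-up FDR control, Student t-tests
(one-sample / paired / unpaired), an exact one-sample Wilcoxon signed-rank
test, and Kruskal–Wallis with Dunn's post-hoc pairwise comparisons.

Where an established implementation exists (scipy t-tests and Kruskal–Wallis
H, statsmodels BH adjustment) it is used behind the interface here; the
exact Wilcoxon null (dynamic programming over signed midranks) and Dunn's
z statistics are implemented directly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Sequence

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "TestResult",
    "FdrDecision",
    "fisher_z",
    "inverse_fisher_z",
    "bh_fdr",
    "t_test",
    "wilcoxon_one_sample",
    "kruskal_dunn",
]


@dataclass(frozen=True)
class TestResult:
    """Outcome of a single hypothesis test.

    ``n`` is the sample size, or a tuple of per-group sizes for two-sample
    tests.  ``extra`` carries method-specific bookkeeping (degrees of
    freedom, number of zero differences dropped, ...).
    """

    statistic: float
    p_value: float
    n: int | tuple[int, ...]
    method: str
    two_sided: bool = True
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0 or np.isnan(self.p_value)):
            raise ValueError(f"p_value outside [0, 1]: {self.p_value}")


@dataclass(frozen=True)
class FdrDecision:
    """Benjamini–Hochberg decisions over a family of p-values.

    ``adjusted_p`` and ``rejected`` are aligned with ``raw_p`` in the
    original input order.
    """

    raw_p: np.ndarray
    q_threshold: float
    adjusted_p: np.ndarray
    rejected: np.ndarray

    @property
    def n_rejected(self) -> int:
        return int(np.sum(self.rejected))


def fisher_z(r, clip_eps: float = 1e-7):
    """Fisher z-transform ``atanh(r)`` with clipping away from ±1.

    Correlations of exactly ±1 (e.g. a trace correlated with itself or a
    duplicate) would map to ±inf; they are clipped into
    ``[-1 + clip_eps, 1 - clip_eps]`` first so downstream averages stay
    finite.  NaN entries (missing correlations) pass through unchanged.

    Parameters
    ----------
    r : float or array-like
        Pearson correlation(s) in [-1, 1].
    clip_eps : float
        Clipping margin, in (0, 1e-3].

    Returns
    -------
    float or ndarray of the same shape as ``r``.
    """
    if not 0.0 < clip_eps <= 1e-3:
        raise ValueError("clip_eps must be in (0, 1e-3]")
    arr = np.asarray(r, dtype=float)
    if np.any(np.isinf(arr)):
        raise ValueError("invalid correlation: non-finite input")
    out = np.arctanh(np.clip(arr, -1.0 + clip_eps, 1.0 - clip_eps))
    out = np.where(np.isnan(arr), np.nan, out)
    if np.isscalar(r) or arr.ndim == 0:
        return float(out)
    return out


def inverse_fisher_z(z):
    """Inverse of :func:`fisher_z` (tanh)."""
    out = np.tanh(np.asarray(z, dtype=float))
    if np.isscalar(z) or out.ndim == 0:
        return float(out)
    return out


def bh_fdr(raw_p: Sequence[float], q: float = 0.05) -> FdrDecision:
    """Benjamini–Hochberg step-up FDR control.

    Adjusted p-values follow the standard step-up definition
    ``min_{j>=i} m * p_(j) / j`` (capped at 1) on the sorted p-values, with
    the result mapped back to the input order.  A test is rejected iff its
    adjusted p-value is at most ``q``.
    """
    if not 0.0 < q < 1.0:
        raise ValueError("q must be in (0, 1)")
    p = np.asarray(raw_p, dtype=float)
    if p.size == 0:
        empty = np.array([], dtype=float)
        return FdrDecision(empty, q, empty.copy(), np.array([], dtype=bool))
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    rejected, adjusted, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return FdrDecision(p.copy(), q, adjusted, rejected)


def t_test(
    x: Sequence[float],
    y: Sequence[float] | None = None,
    mode: str = "one_sample",
    mu: float = 0.0,
    equal_var: bool = True,
) -> TestResult:
    """Student t-test in one-sample, paired, or unpaired form.

    The unpaired test defaults to the classical pooled-variance form;
    ``equal_var=False`` selects Welch's correction.  Two-sided p-values
    throughout.

    Raises
    ------
    ValueError
        If the tested quantity has zero variance ("degenerate sample") or
        sample sizes are below 2 per group.
    """
    x = np.asarray(x, dtype=float)
    if mode not in ("one_sample", "paired", "unpaired"):
        raise ValueError(f"unknown mode {mode!r}")
    if mode == "one_sample":
        if y is not None:
            raise ValueError("one_sample mode takes no second sample")
        if x.size < 2:
            raise ValueError("need at least 2 observations")
        if np.ptp(x) == 0:
            raise ValueError("degenerate sample: zero variance")
        res = sps.ttest_1samp(x, popmean=mu)
        return TestResult(
            float(res.statistic), float(res.pvalue), int(x.size),
            method="one_sample_t", extra={"df": int(x.size - 1), "mu": mu},
        )
    if y is None:
        raise ValueError(f"{mode} mode requires a second sample")
    y = np.asarray(y, dtype=float)
    if mode == "paired":
        if x.size != y.size:
            raise ValueError("paired mode requires equal lengths")
        if x.size < 2:
            raise ValueError("need at least 2 pairs")
        d = x - y
        if np.ptp(d) == 0:
            raise ValueError("degenerate sample: zero variance of differences")
        res = sps.ttest_rel(x, y)
        return TestResult(
            float(res.statistic), float(res.pvalue), int(x.size),
            method="paired_t", extra={"df": int(x.size - 1)},
        )
    # unpaired
    if x.size < 2 or y.size < 2:
        raise ValueError("need at least 2 observations per group")
    if np.ptp(x) == 0 and np.ptp(y) == 0:
        raise ValueError("degenerate sample: zero variance in both groups")
    res = sps.ttest_ind(x, y, equal_var=equal_var)
    df = x.size + y.size - 2 if equal_var else float(res.df)
    return TestResult(
        float(res.statistic), float(res.pvalue), (int(x.size), int(y.size)),
        method="unpaired_t" if equal_var else "welch_t",
        extra={"df": df, "equal_var": equal_var},
    )


def _wilcoxon_exact_sf(ranks2: np.ndarray) -> np.ndarray:
    """Exact null distribution of 2*W+ for signed-rank statistics.

    ``ranks2`` are the doubled midranks (integers, so ties are exact).
    Returns the probability mass function of the doubled positive-rank sum
    over 0..sum(ranks2), each sign pattern equiprobable (2^-n).
    """
    total = int(np.sum(ranks2))
    pmf = np.zeros(total + 1)
    pmf[0] = 1.0
    for r in ranks2:
        r = int(r)
        shifted = np.zeros_like(pmf)
        shifted[r:] = pmf[: total + 1 - r]
        pmf = 0.5 * (pmf + shifted)
    return pmf


def wilcoxon_one_sample(x: Sequence[float], mu: float = 0.0) -> TestResult:
    """Two-sided one-sample Wilcoxon signed-rank test against ``mu``.

    Differences exactly equal to zero are dropped before ranking
    (Wilcoxon's original zero policy); the number dropped is reported in
    ``extra['n_zeros_dropped']``.  For n <= 25 retained differences the
    p-value is exact, from the full null distribution of the signed-rank
    sum with midranks for ties; above that a normal approximation with
    tie correction and continuity correction is used.
    """
    x = np.asarray(x, dtype=float)
    d = x - mu
    n_zero = int(np.sum(d == 0))
    d = d[d != 0]
    n = d.size
    if n == 0:
        raise ValueError("no non-zero differences")
    ranks = sps.rankdata(np.abs(d))
    w_pos = float(np.sum(ranks[d > 0]))
    extra = {"n_zeros_dropped": n_zero, "mu": mu}
    if n <= 25:
        ranks2 = np.rint(2 * ranks).astype(int)
        pmf = _wilcoxon_exact_sf(ranks2)
        w2 = int(round(2 * w_pos))
        p_ge = float(pmf[w2:].sum())
        p_le = float(pmf[: w2 + 1].sum())
        p = min(1.0, 2.0 * min(p_ge, p_le))
        extra["exact"] = True
    else:
        mean = n * (n + 1) / 4.0
        # tie correction on the variance of W+
        _, counts = np.unique(ranks, return_counts=True)
        tie_term = np.sum(counts**3 - counts) / 48.0
        var = n * (n + 1) * (2 * n + 1) / 24.0 - tie_term
        delta = w_pos - mean
        z = (delta - 0.5 * np.sign(delta)) / np.sqrt(var)
        p = float(2.0 * sps.norm.sf(abs(z)))
        p = min(1.0, p)
        extra["exact"] = False
        extra["z"] = float(z)
    return TestResult(w_pos, p, n, method="wilcoxon_signed_rank", extra=extra)


def kruskal_dunn(
    groups: Sequence[Sequence[float]],
    q: float = 0.05,
    adjust: str = "fdr_bh",
) -> tuple[TestResult, list[TestResult]]:
    """Kruskal–Wallis test plus Dunn's pairwise post-hoc comparisons.

    The omnibus H statistic is tie-corrected with a chi-square reference on
    k-1 degrees of freedom.  Dunn's z for a pair (i, j) compares mean ranks
    from the joint ranking:

        z = (Rbar_i - Rbar_j) / sqrt((N(N+1)/12 - T) * (1/n_i + 1/n_j))

    with tie correction T = sum(t^3 - t) / (12 (N - 1)).  Pairwise p-values
    are multiplicity-adjusted with Benjamini–Hochberg by default
    (``adjust='bonferroni'`` for the classical alternative); each pairwise
    result carries ``extra['adjusted_p']`` and ``extra['significant']`` at
    level ``q``.
    """
    arrs = [np.asarray(g, dtype=float) for g in groups]
    arrs = [a for a in arrs if a.size > 0]
    if len(arrs) < 2:
        raise ValueError("need at least 2 non-empty groups")
    if adjust not in ("fdr_bh", "bonferroni"):
        raise ValueError(f"unknown adjustment {adjust!r}")
    pooled = np.concatenate(arrs)
    k = len(arrs)
    ns = np.array([a.size for a in arrs])
    if np.ptp(pooled) == 0:
        # all observations identical: no evidence against equality
        omnibus = TestResult(0.0, 1.0, tuple(int(n) for n in ns),
                             method="kruskal_wallis", extra={"df": k - 1})
    else:
        h, p = sps.kruskal(*arrs)
        omnibus = TestResult(float(h), float(p), tuple(int(n) for n in ns),
                             method="kruskal_wallis", extra={"df": k - 1})

    ranks = sps.rankdata(pooled)
    bounds = np.concatenate([[0], np.cumsum(ns)])
    mean_ranks = np.array(
        [ranks[bounds[i]: bounds[i + 1]].mean() for i in range(k)]
    )
    n_tot = pooled.size
    _, counts = np.unique(pooled, return_counts=True)
    tie_corr = np.sum(counts**3 - counts) / (12.0 * (n_tot - 1)) if n_tot > 1 else 0.0
    base_var = n_tot * (n_tot + 1) / 12.0 - tie_corr

    pair_stats = []
    for i, j in combinations(range(k), 2):
        se = np.sqrt(base_var * (1.0 / ns[i] + 1.0 / ns[j]))
        z = (mean_ranks[i] - mean_ranks[j]) / se if se > 0 else 0.0
        p_raw = float(2.0 * sps.norm.sf(abs(z))) if se > 0 else 1.0
        pair_stats.append((i, j, float(z), p_raw))

    raw_ps = [p for *_, p in pair_stats]
    if adjust == "fdr_bh":
        adj = bh_fdr(raw_ps, q).adjusted_p
    else:
        adj = np.minimum(np.asarray(raw_ps) * len(raw_ps), 1.0)
    pairwise = [
        TestResult(
            z, p_raw, (int(ns[i]), int(ns[j])), method="dunn",
            extra={
                "pair": (i, j),
                "adjusted_p": float(adj[idx]),
                "significant": bool(adj[idx] <= q),
                "adjust": adjust,
            },
        )
        for idx, (i, j, z, p_raw) in enumerate(pair_stats)
    ]
    return omnibus, pairwise


def results_to_rows(results: Sequence[TestResult]) -> list[dict]:
    """Flatten test results into rows for a TSV dump (one row per test)."""
    rows = []
    for r in results:
        rows.append(
            {
                "method": r.method,
                "statistic": r.statistic,
                "n": r.n if isinstance(r.n, int) else "/".join(map(str, r.n)),
                "p_value": r.p_value,
                "adjusted_p": r.extra.get("adjusted_p", ""),
                "rejected": r.extra.get("significant", ""),
            }
        )
    return rows
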