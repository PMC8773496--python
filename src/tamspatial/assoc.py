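"""Association tests between CD163 metrics and clinicopathologic factors.

Continuous metric vs continuous factor: Spearman rank correlation with a
Fisher-z (inverse hyperbolic tangent) confidence interval.  Continuous
metric vs categorical factor: Kruskal–Wallis.  Dichotomized metric vs
categorical factor: Fisher's exact test (2×2 exact; r×c by exhaustive
enumeration for small tables, seeded Monte-Carlo otherwise).  Continuous
age between two groups: two-sample Wilcoxon rank-sum.  Within each family
of related tests, p-values are adjusted by Holm's step-down procedure,
which controls the family-wise error rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import numpy as np
from scipy import stats
from scipy.special import gammaln
from statsmodels.stats.multitest import multipletests

__all__ = [
    "TestResult",
    "spearman_ci",
    "kruskal_wallis",
    "fisher_exact_rxc",
    "wilcoxon_ranksum",
    "holm_adjust",
]


@dataclass
class TestResult:
    method: str
    statistic: float
    p_raw: float
    p_adjusted: float | None = None
    family: str | None = None
    estimate: float | None = None
    ci_low: float | None = None
    ci_high: float | None = None
    extra: dict = field(default_factory=dict)


def spearman_ci(x, y, level: float = 0.95) -> TestResult:
    """Spearman correlation with a Fisher-z CI (SE = 1/sqrt(n-3))."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size != y.size or x.size < 4:
        raise ValueError("need >= 4 paired observations")
    if np.unique(x).size < 2 or np.unique(y).size < 2:
        raise ValueError("constant input: Spearman correlation undefined")
    rho, p = stats.spearmanr(x, y)
    z = np.arctanh(np.clip(rho, -1 + 1e-15, 1 - 1e-15))
    se = 1.0 / np.sqrt(x.size - 3)
    zcrit = stats.norm.ppf(0.5 + level / 2)
    lo, hi = np.tanh(z - zcrit * se), np.tanh(z + zcrit * se)
    return TestResult(
        method="spearman",
        statistic=float(rho),
        p_raw=float(p),
        estimate=float(rho),
        ci_low=float(lo),
        ci_high=float(hi),
        extra={"n": int(x.size), "ci_level": level},
    )


def kruskal_wallis(values, groups) -> TestResult:
    """Tie-corrected Kruskal–Wallis H with a chi-square (k-1 df) reference."""
    values = np.asarray(values, float)
    groups = np.asarray(groups)
    levels = np.unique(groups)
    if levels.size < 2:
        raise ValueError("Kruskal-Wallis needs >= 2 groups")
    samples = [values[groups == g] for g in levels]
    if any(s.size == 0 for s in samples):
        raise ValueError("every group must be nonempty")
    if np.unique(values).size == 1:
        return TestResult(method="kruskal-wallis", statistic=0.0, p_raw=1.0, extra={"df": levels.size - 1})
    h, p = stats.kruskal(*samples)
    return TestResult(method="kruskal-wallis", statistic=float(h), p_raw=float(p), extra={"df": int(levels.size - 1)})


def _log_table_prob(table: np.ndarray, row_margins, col_margins, n) -> float:
    # multivariate hypergeometric probability of a table given fixed margins
    return float(
        gammaln(row_margins + 1).sum()
        + gammaln(col_margins + 1).sum()
        - gammaln(n + 1)
        - gammaln(table + 1).sum()
    )


def _enumerate_tables(row_margins: np.ndarray, col_margins: np.ndarray):
    """Yield all non-negative integer tables with the given margins (DFS)."""
    r, c = len(row_margins), len(col_margins)
    table = np.zeros((r, c), dtype=np.int64)

    def fill(i: int, cols_left: np.ndarray):
        if i == r - 1:
            if (cols_left >= 0).all():
                table[i] = cols_left
                yield table
            return
        target = row_margins[i]

        def row_fill(j: int, remaining: int):
            if j == c - 1:
                if 0 <= remaining <= cols_left[j]:
                    table[i, j] = remaining
                    yield True
                    table[i, j] = 0
                return
            for v in range(min(remaining, cols_left[j]) + 1):
                table[i, j] = v
                yield from row_fill(j + 1, remaining - v)
            table[i, j] = 0

        def consume(j=0, remaining=target):
            for _ in row_fill(j, remaining):
                yield from fill(i + 1, cols_left - table[i])

        yield from consume()

    yield from fill(0, col_margins.copy())


def fisher_exact_rxc(
    table,
    *,
    max_enumeration: int = 200_000,
    n_mc: int = 100_000,
    seed: int | None = 0,
) -> TestResult:
    """Two-sided Fisher's exact test for an r×c contingency table.

    The p-value is the total probability, under the multivariate
    hypergeometric null with fixed margins, of tables no more probable
    than the observed one.  Small tables are enumerated exhaustively;
    larger tables fall back to seeded Monte-Carlo sampling of tables with
    fixed margins (flagged in ``extra['simulated']``).
    """
    tab = np.asarray(table, dtype=np.int64)
    if tab.ndim != 2 or (tab < 0).any():
        raise ValueError("table must be a 2-D array of non-negative counts")
    row_m = tab.sum(axis=1)
    col_m = tab.sum(axis=0)
    n = int(tab.sum())
    if (row_m == 0).any() or (col_m == 0).any() or n == 0:
        return TestResult(method="fisher-exact", statistic=float("nan"), p_raw=1.0, extra={"degenerate": True})
    if tab.shape == (2, 2):
        _, p = stats.fisher_exact(tab, alternative="two-sided")
        return TestResult(method="fisher-exact", statistic=float("nan"), p_raw=float(p), extra={"simulated": False})

    log_obs = _log_table_prob(tab, row_m, col_m, n)
    tol = 1e-9  # tables equal in probability up to rounding count as "as extreme"

    # crude bound on enumeration size to decide the route
    est = 1.0
    for rm in row_m[:-1]:
        est *= min(rm + 1, 50) ** (len(col_m) - 1)
        if est > max_enumeration:
            break
    if est <= max_enumeration:
        total = 0.0
        for t in _enumerate_tables(row_m, col_m):
            lp = _log_table_prob(t, row_m, col_m, n)
            if lp <= log_obs + tol:
                total += np.exp(lp)
        return TestResult(
            method="fisher-exact", statistic=float("nan"), p_raw=float(min(1.0, total)), extra={"simulated": False}
        )

    # Monte-Carlo: permute column labels against row labels
    rng = np.random.default_rng(seed)
    rows = np.repeat(np.arange(len(row_m)), row_m)
    cols = np.repeat(np.arange(len(col_m)), col_m)
    hits = 0
    for _ in range(n_mc):
        perm = rng.permutation(cols)
        t = np.zeros_like(tab)
        np.add.at(t, (rows, perm), 1)
        if _log_table_prob(t, row_m, col_m, n) <= log_obs + tol:
            hits += 1
    p = (hits + 1) / (n_mc + 1)
    return TestResult(
        method="fisher-exact", statistic=float("nan"), p_raw=float(p), extra={"simulated": True, "n_mc": n_mc}
    )


def wilcoxon_ranksum(a, b, *, paired: bool = False) -> TestResult:
    """Two-sided two-sample Wilcoxon rank-sum (Mann–Whitney) test.

    Exact when the combined sample is small and tie-free; tie-corrected
    normal approximation otherwise.  ``paired=True`` switches to the
    signed-rank test for genuinely paired data.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be nonempty")
    if paired:
        stat, p = stats.wilcoxon(a, b)
        return TestResult(method="wilcoxon-signed-rank", statistic=float(stat), p_raw=float(p))
    method = "exact" if (a.size + b.size <= 20 and np.unique(np.concatenate([a, b])).size == a.size + b.size) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return TestResult(method="wilcoxon-rank-sum", statistic=float(res.statistic), p_raw=float(res.pvalue))


def holm_adjust(p_values) -> np.ndarray:
    """Holm step-down adjusted p-values, in the input order."""
    p = np.asarray(p_values, float)
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    _, p_adj, _, _ = multipletests(p, method="holm")
    return p_adj


def adjust_family(results: list[TestResult], family: str) -> list[TestResult]:
    """Attach Holm-adjusted p-values to one family of tests, in place."""
    adj = holm_adjust([r.p_raw for r in results])
    for r, pa in zip(results, adj):
        r.p_adjusted = float(pa)
        r.family = family
    return results
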