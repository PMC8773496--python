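"""CD163+ TAM phenotyping via a background upper tolerance limit (UTL).

Cancer cells do not express CD163, so the CD163 signal measured on cancer
cells within a core is pure background (autofluorescence, bleed-through,
segmentation spill-over).  A one-sided non-parametric upper tolerance limit
with content ``p`` and confidence ``gamma`` is an order statistic X_(r) of
the n background intensities chosen so that, with probability at least
``gamma`` over the sampling of the background, at least a fraction ``p`` of
the background population lies below X_(r).  A stromal cell whose CD163
intensity exceeds this per-core limit is called a CD163+ TAM.

The exact construction uses the binomial distribution of the number of
background observations below the population p-quantile: the r-th order
statistic exceeds that quantile with probability P[Binomial(n, p) <= r-1],
so the smallest rank r with binom.cdf(r-1, n, p) >= gamma attains nominal
confidence.  For n below the attainability bound (n < ~90 at p=0.95,
gamma=0.99) no rank qualifies; the sample maximum is used and the result is
flagged degenerate with its achieved confidence 1 - p**n.

An alternative ``quantile-table`` mode reproduces rank selection from a
published rank table (CSV of n, rank) with linear interpolation on n.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd
from scipy import stats

from .core import CoreTable

__all__ = ["UtlSpec", "UtlResult", "utl_rank", "background_utl", "classify_tams"]

MIN_BACKGROUND_CELLS = 10


@dataclass(frozen=True)
class UtlSpec:
    """Content/confidence specification of the tolerance limit."""

    content: float = 0.95
    confidence: float = 0.99
    mode: Literal["exact-binomial", "quantile-table"] = "exact-binomial"
    rank_table_path: str | Path | None = None

    def __post_init__(self) -> None:
        if not (0 < self.content < 1):
            raise ValueError(f"content must be in (0,1), got {self.content}")
        if not (0 < self.confidence < 1):
            raise ValueError(f"confidence must be in (0,1), got {self.confidence}")
        if self.mode == "quantile-table" and self.rank_table_path is None:
            raise ValueError("quantile-table mode needs rank_table_path")


@dataclass(frozen=True)
class UtlResult:
    """Selected order-statistic rank and (optionally) the limit itself."""

    rank: int  # 1-based ascending order-statistic index
    achieved_confidence: float
    degenerate: bool
    n: int
    utl_value: float | None = None


def _rank_exact(n: int, p: float, gamma: float) -> tuple[int, float, bool]:
    # smallest r with P[Bin(n,p) <= r-1] >= gamma; r=n degenerate fallback
    r_candidates = np.arange(1, n + 1)
    conf = stats.binom.cdf(r_candidates - 1, n, p)
    ok = np.flatnonzero(conf >= gamma)
    if ok.size:
        r = int(r_candidates[ok[0]])
        return r, float(conf[ok[0]]), False
    return n, float(1.0 - p**n), True


def _rank_table(n: int, path: str | Path) -> tuple[int, float, bool]:
    tab = pd.read_csv(path)
    if not {"n", "rank"} <= set(tab.columns):
        raise ValueError("rank table must have columns 'n' and 'rank'")
    tab = tab.sort_values("n")
    ns = tab["n"].to_numpy(float)
    ranks = tab["rank"].to_numpy(float)
    if n < ns[0]:
        # below the table's smallest sample size: conservative maximum
        return n, float("nan"), True
    r = float(np.interp(n, ns, ranks))
    r_int = min(n, max(1, int(round(r))))
    return r_int, float("nan"), False


def utl_rank(n: int, spec: UtlSpec = UtlSpec()) -> UtlResult:
    """Order-statistic rank of the upper tolerance limit for sample size n."""
    if n < 1:
        raise ValueError(f"sample size must be >= 1, got {n}")
    if spec.mode == "exact-binomial":
        r, conf, degen = _rank_exact(n, spec.content, spec.confidence)
    else:
        r, conf, degen = _rank_table(n, spec.rank_table_path)
    return UtlResult(rank=r, achieved_confidence=conf, degenerate=degen, n=n)


def background_utl(core: CoreTable, spec: UtlSpec = UtlSpec()) -> UtlResult:
    """UTL of the cancer-cell (background) CD163 intensities of one core."""
    bg = np.sort(core.cells.loc[core.is_cancer, "cd163"].to_numpy(float))
    if bg.size < MIN_BACKGROUND_CELLS:
        raise ValueError(
            f"core {core.core_id!r}: {bg.size} cancer cells < {MIN_BACKGROUND_CELLS} required for a background UTL"
        )
    res = utl_rank(bg.size, spec)
    return UtlResult(
        rank=res.rank,
        achieved_confidence=res.achieved_confidence,
        degenerate=res.degenerate,
        n=res.n,
        utl_value=float(bg[res.rank - 1]),
    )


def classify_tams(core: CoreTable, utl: UtlResult) -> int:
    """Label stromal cells as CD163+ TAM iff intensity strictly exceeds the UTL.

    Fills the core's ``tam`` column in place (cancer cells are never TAM)
    and returns the CD163+ TAM count.
    """
    if utl.utl_value is None:
        raise ValueError("UtlResult carries no utl_value; run background_utl on the core first")
    stromal = core.is_stromal
    pos = stromal & (core.cells["cd163"].to_numpy(float) > utl.utl_value)
    labels = pd.array(np.where(stromal, pos, False), dtype="boolean")
    core.cells["tam"] = labels
    return int(pos.sum())


def phenotype_core(core: CoreTable, spec: UtlSpec = UtlSpec()) -> tuple[UtlResult, int]:
    """Convenience: compute the background UTL and label the core's TAMs."""
    utl = background_utl(core, spec)
    return utl, classify_tams(core, utl)


def min_attaining_n(spec: UtlSpec = UtlSpec()) -> int:
    """Smallest n at which the nominal confidence is attainable (r = n works)."""
    return math.ceil(math.log(1 - spec.confidence) / math.log(spec.content))
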