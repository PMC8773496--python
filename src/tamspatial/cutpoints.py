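"""Data-driven dichotomization of a continuous biomarker for survival.

A survival tree restricted to a single first split on one metric: candidate
thresholds are midpoints between consecutive unique metric values (with a
minimum leaf size on both sides); the split maximizing the two-sample
log-rank statistic is selected and retained only if the 10-fold
cross-validated held-out deviance of the one-split exponential-hazard model
improves on the no-split model — the pruning analogue of cost-complexity
cross-validation in a survival CART.

The selection is wrapped in a bootstrap: the first-split threshold is
recomputed in B resamples; the median of the bootstrap thresholds is the
reported cutoff and the 5th/95th percentiles its non-parametric 90% CI.
``direction`` records which side of the cutoff is the high-risk group, so
downstream hazard ratios always contrast high-risk vs low-risk.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np

from ._rng import as_seedseq

__all__ = [
    "CutpointResult",
    "NoSplit",
    "tree_cutpoint",
    "bootstrap_cutpoint",
    "dichotomize",
    "combined_marker",
    "logrank_scan",
]

MIN_LEAF_DEFAULT = 7
MIN_SPLIT_DEFAULT = 20


class NoSplit(Exception):
    """The tree pruned to the root: no threshold is supported by the data."""


@dataclass(frozen=True)
class Cutpoint:
    cutoff: float
    direction: Literal["high", "low"]  # which side of the cutoff is high-risk
    statistic: float  # log-rank chi-square of the selected split


@dataclass
class CutpointResult:
    cutoff: float
    ci90: tuple[float, float]
    direction: Literal["high", "low"]
    bootstrap_cutoffs: np.ndarray
    n_failed: int
    B: int
    extra: dict = field(default_factory=dict)


def logrank_scan(metric: np.ndarray, time: np.ndarray, event: np.ndarray, candidates: np.ndarray):
    """Two-sample log-rank statistic for every candidate threshold at once.

    Returns ``(chi2, u)`` arrays over candidates, where ``u`` is the
    observed-minus-expected event count in the high (> threshold) group;
    ``u > 0`` means the high group has excess hazard.
    """
    n = metric.size
    J = candidates.size
    order = np.argsort(time, kind="stable")
    t = time[order]
    e = event[order].astype(bool)
    x = metric[order]
    # distinct event times
    new = np.empty(n, dtype=bool)
    new[0] = True
    new[1:] = t[1:] != t[:-1]
    grp = np.cumsum(new) - 1
    K = grp[-1] + 1
    d_k = np.bincount(grp, weights=e.astype(float), minlength=K)  # events at each time
    n_k = np.bincount(grp, minlength=K)[::-1].cumsum()[::-1].astype(float)  # at risk
    # bucket b_i = number of candidates below x_i; "x > c_j" <=> b_i > j.
    # Candidates are midpoints strictly between consecutive unique metric
    # values, so no data point ever coincides with a candidate.
    bucket = np.searchsorted(candidates, x)
    B = J + 1
    flat = grp * B + bucket
    M = np.bincount(flat, minlength=K * B).reshape(K, B).astype(float)
    ME = np.bincount(flat[e], minlength=K * B).reshape(K, B).astype(float)
    # suffix over buckets -> counts with x > c_j; suffix over time -> at risk
    Sb = M[:, ::-1].cumsum(axis=1)[:, ::-1]
    n1_k = Sb[::-1].cumsum(axis=0)[::-1][:, 1:]  # (K, J)
    d1_k = ME[:, ::-1].cumsum(axis=1)[:, ::-1][:, 1:]
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = n1_k / n_k[:, None]
        u = (d1_k - d_k[:, None] * frac).sum(axis=0)
        v_k = d_k[:, None] * frac * (1 - frac) * ((n_k - d_k) / np.maximum(n_k - 1, 1))[:, None]
        v = v_k.sum(axis=0)
        chi2 = np.where(v > 0, u * u / np.maximum(v, 1e-300), 0.0)
    return chi2, u


def _heldout_deviance(d, tt, lam) -> float:
    # exponential-hazard (Poisson-offset) deviance of held-out observations
    eps = 1e-12
    mu = lam * tt
    return float(2 * np.sum(np.where(d > 0, d * np.log(np.maximum(d, eps) / mu), 0.0) - (d - mu)))


def _cv_deviance(metric, time, event, candidates, min_leaf, folds, rng) -> tuple[float, float]:
    """Honest 10-fold CV: re-select the best split within each training fold.

    The one-split "model" being validated includes the split selection
    itself, so each fold re-runs the log-rank argmax on its training 90%
    and scores the held-out 10% by exponential-hazard deviance against
    the no-split (root) model.  A training fold in which no split is
    feasible contributes the root prediction for both models.
    """
    n = time.size
    folds = int(min(folds, n))
    assign = rng.permutation(np.arange(n) % folds)
    dev_split = 0.0
    dev_root = 0.0
    eps = 1e-12
    for f in range(folds):
        test = assign == f
        train = ~test
        x_tr, t_tr, e_tr = metric[train], time[train], event[train]
        lam_root = max(e_tr.sum(), 0.5) / max(t_tr.sum(), eps)
        cutoff_f = None
        if e_tr.sum() > 0:
            cnt = np.bincount(np.searchsorted(candidates, x_tr), minlength=candidates.size + 1)
            n_hi = cnt[::-1].cumsum()[::-1][1:]
            ok = (n_hi >= min_leaf) & ((x_tr.size - n_hi) >= min_leaf)
            if ok.any():
                chi2, _ = logrank_scan(x_tr, t_tr, e_tr, candidates[ok])
                if chi2.max() > 0:
                    cutoff_f = float(candidates[ok][int(np.argmax(chi2))])
        d_te, t_te = event[test].astype(float), time[test]
        dev_root += _heldout_deviance(d_te, t_te, lam_root)
        if cutoff_f is None:
            dev_split += _heldout_deviance(d_te, t_te, lam_root)
            continue
        hi_tr = x_tr > cutoff_f
        hi_te = metric[test] > cutoff_f
        for side in (True, False):
            m_tr = hi_tr == side
            lam = max(e_tr[m_tr].sum(), 0.5) / max(t_tr[m_tr].sum(), eps)
            m_te = hi_te == side
            if m_te.any():
                dev_split += _heldout_deviance(d_te[m_te], t_te[m_te], lam)
    return dev_split, dev_root


def tree_cutpoint(
    metric,
    time,
    event,
    *,
    min_leaf: int = MIN_LEAF_DEFAULT,
    min_split: int = MIN_SPLIT_DEFAULT,
    folds: int = 10,
    seed=None,
) -> Cutpoint:
    """First split of a survival tree on one metric, or raise :class:`NoSplit`.

    ``folds=0`` disables cross-validated pruning (pure log-rank argmax),
    which is useful for tiny worked examples and oracle tests.
    """
    metric = np.asarray(metric, float)
    time = np.asarray(time, float)
    event = np.asarray(event).astype(bool)
    n = metric.size
    if n < max(2 * min_leaf, min_split if folds else 2 * min_leaf):
        raise NoSplit(f"n={n} below minimum split size")
    if event.sum() == 0:
        raise NoSplit("no events")
    uniq = np.unique(metric)
    if uniq.size < 2:
        raise NoSplit("metric is constant")
    mids = (uniq[:-1] + uniq[1:]) / 2.0
    # leaf-size feasibility per candidate
    cnt = np.bincount(np.searchsorted(mids, metric), minlength=mids.size + 1)
    n_hi = cnt[::-1].cumsum()[::-1][1:]
    ok = (n_hi >= min_leaf) & ((n - n_hi) >= min_leaf)
    if not ok.any():
        raise NoSplit("no candidate split satisfies the leaf-size constraint")
    mids = mids[ok]
    chi2, u = logrank_scan(metric, time, event, mids)
    best = int(np.argmax(chi2))
    if chi2[best] <= 0:
        raise NoSplit("log-rank statistic vanishes at every candidate")
    cutoff = float(mids[best])
    direction: Literal["high", "low"] = "high" if u[best] >= 0 else "low"
    if folds and folds > 1:
        rng = np.random.default_rng(seed)
        dev_split, dev_root = _cv_deviance(metric, time, event, mids, min_leaf, folds, rng)
        if dev_split > dev_root:
            raise NoSplit("cross-validation prunes the split")
    return Cutpoint(cutoff=cutoff, direction=direction, statistic=float(chi2[best]))


def bootstrap_cutpoint(
    metric,
    time,
    event,
    *,
    B: int = 1000,
    min_leaf: int = MIN_LEAF_DEFAULT,
    min_split: int = MIN_SPLIT_DEFAULT,
    folds: int = 10,
    seed=None,
) -> CutpointResult:
    """Bootstrap distribution of the survival-tree first-split threshold.

    The reported cutoff is the median of the B bootstrap thresholds and
    the 90% CI their 5th/95th percentiles; resamples in which the tree
    prunes to the root are excluded from the distribution and counted in
    ``n_failed``.  Fully reproducible from ``seed``; replicate b uses the
    b-th spawned child stream, so enlarging B extends (not reshuffles) the
    sequence.
    """
    metric = np.asarray(metric, float)
    time = np.asarray(time, float)
    event = np.asarray(event).astype(bool)
    n = metric.size
    children = as_seedseq(seed).spawn(B)
    cutoffs = []
    directions = []
    n_failed = 0
    for b in range(B):
        rng = np.random.default_rng(children[b])
        idx = rng.integers(0, n, size=n)
        try:
            cp = tree_cutpoint(
                metric[idx], time[idx], event[idx],
                min_leaf=min_leaf, min_split=min_split, folds=folds, seed=rng,
            )
            cutoffs.append(cp.cutoff)
            directions.append(cp.direction)
        except NoSplit:
            n_failed += 1
    if not cutoffs:
        raise NoSplit(
            f"all {B} bootstrap resamples pruned to the root; the metric's prognostic signal "
            "is too weak at this sample size"
        )
    cutoffs = np.asarray(cutoffs)
    cutoff = float(np.median(cutoffs))
    lo, hi = np.percentile(cutoffs, [5, 95])
    n_high_dir = sum(1 for d in directions if d == "high")
    direction: Literal["high", "low"] = "high" if n_high_dir * 2 >= len(directions) else "low"
    return CutpointResult(
        cutoff=cutoff,
        ci90=(float(lo), float(hi)),
        direction=direction,
        bootstrap_cutoffs=cutoffs,
        n_failed=n_failed,
        B=B,
        extra={"direction_agreement": n_high_dir / len(directions)},
    )


def dichotomize(values, cutoff: float, direction: Literal["high", "low"] = "high") -> np.ndarray:
    """Binary high-risk marker: 1 iff value > cutoff (or <= cutoff when the
    low side is the high-risk side).  Values exactly at the cutoff are low
    under the default direction."""
    if not np.isfinite(cutoff):
        raise ValueError("cutoff must be finite")
    v = np.asarray(values, float)
    hi = v > cutoff
    return (hi if direction == "high" else ~hi).astype(float)


def combined_marker(comm_high, nnd_median_low) -> np.ndarray:
    """Three-category combined TAM marker.

    Category 1 (reference, lowest risk): low communicating-TAM count and
    high median cancer-to-TAM NND; category 2: low count, low NND;
    category 3: high count, any NND.  Missing inputs propagate as NaN.
    """
    comm_high = np.asarray(comm_high, float)
    nnd_median_low = np.asarray(nnd_median_low, float)
    out = np.where(
        comm_high == 1, 3.0, np.where(nnd_median_low == 1, 2.0, 1.0)
    )
    out = np.where(np.isnan(comm_high) | (np.isnan(nnd_median_low) & (comm_high != 1)), np.nan, out)
    return out
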