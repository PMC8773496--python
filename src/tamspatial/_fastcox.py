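"""Vectorized Newton solver for the Cox partial likelihood (Efron ties).

The bootstrap loops (survival-tree cutpoints, optimism correction) fit the
same small Cox model tens of thousands of times; a DataFrame-based fitter
dominates the runtime there.  This module implements the Efron-tie partial
likelihood with fully vectorized gradient/Hessian (no per-event Python
loop), suitable for n in the hundreds and a handful of covariates.  It is
cross-checked against lifelines in the test suite and is not part of the
public API.

With observations sorted by descending time, risk-set sums are cumulative
sums.  For an event time with d tied events, Efron's approximation uses d
denominator terms S - (l/d) * S_D, l = 0..d-1, where S is the risk-set sum
and S_D the sum over the tied deaths; the per-term index structure depends
only on (time, event), so it is precomputed once per fit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["CoxNewtonResult", "fast_coxph"]

_MAX_ITER = 50
_TOL = 1e-9


@dataclass(frozen=True)
class CoxNewtonResult:
    coef: np.ndarray
    se: np.ndarray
    loglik: float
    n: int
    n_events: int
    converged: bool

    @property
    def zvalues(self) -> np.ndarray:
        return self.coef / self.se


class CoxSeparationError(RuntimeError):
    """Monotone likelihood: a coefficient diverges (quasi-separation)."""


def _prepare(time: np.ndarray, event: np.ndarray):
    """Index structure of the Efron partial likelihood (fixed given time/event)."""
    order = np.argsort(-time, kind="stable")
    t = time[order]
    e = event[order].astype(bool)
    n = t.size
    new_time = np.empty(n, dtype=bool)
    new_time[0] = True
    new_time[1:] = t[1:] != t[:-1]
    grp_of_obs = np.cumsum(new_time) - 1  # 0-based distinct-time group, ascending desc-time
    n_grp = grp_of_obs[-1] + 1
    grp_start = np.flatnonzero(new_time)
    grp_end = np.append(grp_start[1:], n) - 1  # last obs index of each group
    # event rows (already grouped contiguously by grp in sorted order)
    ev_rows = np.flatnonzero(e)
    ev_grp = grp_of_obs[ev_rows]
    d_per_grp = np.bincount(ev_grp, minlength=n_grp)
    event_grps = np.flatnonzero(d_per_grp > 0)
    d_list = d_per_grp[event_grps]
    # reduceat offsets into ev_rows for per-event-group sums
    red_off = np.concatenate([[0], np.cumsum(d_list)[:-1]]) if event_grps.size else np.empty(0, int)
    # one "Efron slot" per tied death: index into event_grps plus fraction l/d
    slot_eg = np.repeat(np.arange(event_grps.size), d_list)
    l_idx = np.concatenate([np.arange(d) for d in d_list]) if event_grps.size else np.empty(0, int)
    slot_frac = l_idx / np.maximum(np.repeat(d_list, d_list), 1)
    return {
        "order": order,
        "e": e,
        "grp_end": grp_end,
        "event_grps": event_grps,
        "ev_rows": ev_rows,
        "red_off": red_off,
        "slot_eg": slot_eg,
        "slot_frac": slot_frac,
    }


def fast_coxph(
    time: np.ndarray,
    event: np.ndarray,
    X: np.ndarray,
    *,
    max_coef: float = 25.0,
    init: np.ndarray | None = None,
) -> CoxNewtonResult:
    """Fit a Cox proportional-hazards model; returns coefficients and SEs.

    Raises ``ValueError`` for degenerate inputs (no events, constant
    covariate) and ``CoxSeparationError`` when the likelihood is monotone.
    """
    time = np.asarray(time, float)
    event = np.asarray(event).astype(bool)
    X = np.asarray(X, float)
    if X.ndim == 1:
        X = X[:, None]
    n, p = X.shape
    n_events = int(event.sum())
    if n_events == 0:
        raise ValueError("no events: Cox model undefined")
    const = np.flatnonzero(np.ptp(X, axis=0) == 0)
    if const.size:
        raise ValueError(f"covariate column {int(const[0])} is constant")

    st = _prepare(time, event)
    Xs = X[st["order"]]
    center = Xs.mean(axis=0)
    Xs = Xs - center
    ev_rows = st["ev_rows"]
    red_off = st["red_off"]
    slot_eg = st["slot_eg"]
    slot_frac = st["slot_frac"]
    grp_sel = st["grp_end"][st["event_grps"]]  # risk-set boundary per event group
    Xe = Xs[ev_rows]
    XXe = Xe[:, :, None] * Xe[:, None, :]
    XX = Xs[:, :, None] * Xs[:, None, :]
    sum_eta_x = Xe.sum(axis=0)

    def loglik_only(beta):
        eta = np.clip(Xs @ beta, -500, 500)
        w = np.exp(eta)
        S0 = np.cumsum(w)[grp_sel]
        D0 = np.add.reduceat(w[ev_rows], red_off) if ev_rows.size else np.empty(0)
        den = S0[slot_eg] - slot_frac * D0[slot_eg]
        return float(eta[ev_rows].sum() - np.log(den).sum())

    def slices(beta):
        eta = np.clip(Xs @ beta, -500, 500)
        w = np.exp(eta)
        we = w[ev_rows]
        wx = w[:, None] * Xs
        wxx = w[:, None, None] * XX
        S0 = np.cumsum(w)[grp_sel]
        S1 = np.cumsum(wx, axis=0)[grp_sel]
        S2 = np.cumsum(wxx, axis=0)[grp_sel]
        D0 = np.add.reduceat(we, red_off)
        D1 = np.add.reduceat(we[:, None] * Xe, red_off, axis=0)
        D2 = np.add.reduceat(we[:, None, None] * XXe, red_off, axis=0)
        f = slot_frac[:, None]
        den = S0[slot_eg] - slot_frac * D0[slot_eg]
        num1 = S1[slot_eg] - f * D1[slot_eg]
        num2 = S2[slot_eg] - f[:, :, None] * D2[slot_eg]
        xbar = num1 / den[:, None]
        ll = float(eta[ev_rows].sum() - np.log(den).sum())
        grad = sum_eta_x - xbar.sum(axis=0)
        info = (num2 / den[:, None, None]).sum(axis=0) - np.einsum("si,sj->ij", xbar, xbar)
        return ll, grad, info

    beta = np.zeros(p) if init is None else np.asarray(init, float).copy()
    ll_old = -np.inf
    converged = False
    ll_new = None
    for _ in range(_MAX_ITER):
        ll, grad, info = slices(beta)
        try:
            step = np.linalg.solve(info, grad)
        except np.linalg.LinAlgError as exc:
            raise CoxSeparationError("singular information matrix") from exc
        # step-halving to guarantee likelihood ascent
        scale = 1.0
        for _h in range(30):
            ll_new = loglik_only(beta + scale * step)
            if ll_new >= ll - 1e-12:
                break
            scale *= 0.5
        beta = beta + scale * step
        if np.abs(beta).max() > max_coef:
            raise CoxSeparationError("coefficient diverging: likely separation")
        if abs(ll_new - ll_old) < _TOL * (abs(ll_old) + 1):
            converged = True
            ll_old = ll_new
            break
        ll_old = ll_new
    # monotone likelihoods flatten out and "converge" at an extreme
    # coefficient with an enormous SE; treat that as separation too
    if np.abs(beta).max() > 0.6 * max_coef:
        raise CoxSeparationError("coefficient at boundary: likely separation")
    ll_final, _, info = slices(beta)
    try:
        cov = np.linalg.inv(info)
    except np.linalg.LinAlgError as exc:
        raise CoxSeparationError("singular information at optimum") from exc
    se = np.sqrt(np.clip(np.diag(cov), 0, None))
    return CoxNewtonResult(coef=beta, se=se, loglik=ll_final, n=n, n_events=n_events, converged=converged)
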