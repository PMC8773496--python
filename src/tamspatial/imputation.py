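"""Multiple imputation of clinicopathologic covariates by chained equations.

Missingness is assumed to lie only in covariates (never in the PFS outcome)
and to be missing-at-random given observed data.  Each incomplete variable
is imputed from its own univariate model given all other covariates plus
two outcome carriers — the event indicator and the Nelson–Aalen marginal
cumulative hazard of the survival time — which is the standard way to keep
an imputation model compatible with a downstream Cox analysis.

Model per variable type: binary -> logistic; unordered categorical ->
multinomial logistic; ordered categorical -> proportional odds (with a
multinomial fallback when the ordinal fit fails); continuous -> Bayesian
linear regression.  Parameter uncertainty is propagated with the bootstrap
variant of chained equations: at every sweep the univariate model is fitted
on a resample of the complete rows before drawing the imputations, so the
m completed datasets reflect both sampling and parameter uncertainty.

``hormone_compliance`` is special-cased: it is structurally defined only
for HR+ tumors, so it is imputed as a binary variable within HR+ rows and
the 3-level combined factor ``hr_hormone`` is rebuilt afterwards.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression

from ._rng import as_seedseq

__all__ = ["ImputationSet", "mice_impute", "nelson_aalen_cumhaz"]

DEFAULT_M = 40
DEFAULT_SWEEPS = 10

#: variable -> model type; order fixes the visit sequence
VARIABLE_TYPES = {
    "age": "continuous",
    "race": "binary",
    "grade": "ordered",
    "node": "binary",
    "size_cat": "ordered",
    "hr_status": "binary",
    "her2": "binary",
    "radiation": "binary",
    "hormone_compliance": "binary-conditional",  # only defined for HR+
}

_ORDERED_LEVELS = {"grade": [1, 2, 3], "size_cat": ["<2cm", "2-5cm", ">5cm"]}
_BINARY_LEVELS = {
    "race": ["white", "non-white"],
    "node": ["negative", "positive"],
    "hr_status": ["HR+", "HR-"],
    "her2": ["negative", "positive"],
    "radiation": [False, True],
    "hormone_compliance": ["compliant", "non-compliant"],
}


@dataclass
class ImputationSet:
    datasets: list[pd.DataFrame]
    model_types: dict[str, str]
    seed: object = None
    extra: dict = field(default_factory=dict)

    @property
    def m(self) -> int:
        return len(self.datasets)


def nelson_aalen_cumhaz(time: np.ndarray, event: np.ndarray) -> np.ndarray:
    """Marginal Nelson–Aalen cumulative hazard evaluated at each subject's time."""
    time = np.asarray(time, float)
    event = np.asarray(event).astype(float)
    order = np.argsort(time, kind="stable")
    t = time[order]
    e = event[order]
    n = t.size
    at_risk = n - np.arange(n)
    # collapse ties: hazard increment d_k / n_k at each distinct time
    increments = np.zeros(n)
    i = 0
    while i < n:
        j = i
        while j < n and t[j] == t[i]:
            j += 1
        d = e[i:j].sum()
        increments[i:j] = d / at_risk[i]
        # within a tie block every subject gets the same increment once
        increments[i + 1 : j] = 0.0
        i = j
    ch_sorted = np.cumsum(increments)
    # carry each distinct time's cumulative value to all tied subjects
    i = 0
    while i < n:
        j = i
        while j < n and t[j] == t[i]:
            j += 1
        ch_sorted[i:j] = ch_sorted[j - 1]
        i = j
    out = np.empty(n)
    out[order] = ch_sorted
    return out


def _fit_logistic_irls(X, y, ridge: float = 1e-6, max_iter: int = 30) -> np.ndarray:
    """Logistic regression by IRLS with a whisper of ridge for stability."""
    X1 = np.column_stack([np.ones(X.shape[0]), X])
    beta = np.zeros(X1.shape[1])
    for _ in range(max_iter):
        eta = np.clip(X1 @ beta, -35, 35)
        p = 1.0 / (1.0 + np.exp(-eta))
        w = np.maximum(p * (1 - p), 1e-10)
        H = (X1 * w[:, None]).T @ X1 + ridge * np.eye(X1.shape[1])
        g = X1.T @ (y - p) - ridge * beta
        step = np.linalg.solve(H, g)
        beta = beta + step
        if np.abs(step).max() < 1e-8:
            break
        if np.abs(beta).max() > 30:  # separation guard
            break
    return beta


def _draw_binary(X, y01, X_mis, rng) -> np.ndarray:
    n = y01.size
    boot = rng.integers(0, n, size=n)
    yb = y01[boot]
    if yb.min() == yb.max():  # resample degenerate: draw from observed marginal
        p = np.full(X_mis.shape[0], y01.mean())
    else:
        beta = _fit_logistic_irls(X[boot], yb)
        eta = np.clip(np.column_stack([np.ones(X_mis.shape[0]), X_mis]) @ beta, -35, 35)
        p = 1.0 / (1.0 + np.exp(-eta))
    return (rng.random(X_mis.shape[0]) < p).astype(float)


def _draw_multinomial(X, y_codes, X_mis, n_levels, rng) -> np.ndarray:
    n = y_codes.size
    boot = rng.integers(0, n, size=n)
    yb = y_codes[boot]
    present = np.unique(yb)
    if present.size == 1:
        probs = np.zeros((X_mis.shape[0], n_levels))
        probs[:, int(present[0])] = 1.0
    else:
        clf = LogisticRegression(max_iter=200)
        clf.fit(X[boot], yb)
        raw = clf.predict_proba(X_mis)
        probs = np.zeros((X_mis.shape[0], n_levels))
        probs[:, clf.classes_.astype(int)] = raw
    cum = np.cumsum(probs, axis=1)
    u = rng.random(X_mis.shape[0])[:, None]
    return (u > cum[:, :-1]).sum(axis=1).astype(float)


def _prop_odds_nll_grad(theta, X, y, K):
    """Cumulative-logit negative log-likelihood with analytic gradient.

    theta = (a1, gamma_2..gamma_{K-1}, beta); thresholds are
    alpha_k = a1 + cumsum(exp(gamma)) which keeps them ordered.
    P(Y <= k | x) = sigmoid(alpha_k - x beta).
    """
    n, p = X.shape
    a1 = theta[0]
    gammas = theta[1 : K - 1]
    beta = theta[K - 1 :]
    alphas = a1 + np.concatenate([[0.0], np.cumsum(np.exp(gammas))])  # (K-1,)
    eta = X @ beta
    z = alphas[None, :] - eta[:, None]  # (n, K-1)
    F = 1.0 / (1.0 + np.exp(-np.clip(z, -35, 35)))
    f = F * (1 - F)
    Fpad = np.concatenate([np.zeros((n, 1)), F, np.ones((n, 1))], axis=1)
    pk = Fpad[np.arange(n), y + 1] - Fpad[np.arange(n), y]
    pk = np.maximum(pk, 1e-12)
    nll = -np.log(pk).sum()
    # d pk / d alpha_j:  +f_j if j == y, -f_j if j == y-1 (0-based alpha idx)
    galpha = np.zeros(K - 1)
    gbeta = np.zeros(p)
    inv = 1.0 / pk
    for j in range(K - 1):
        upper = (y == j).astype(float)  # alpha_j is the upper bound of cell y
        lower = (y == j + 1).astype(float)  # alpha_j is the lower bound
        w = (upper - lower) * f[:, j] * inv
        galpha[j] = -w.sum()
        gbeta += (w[:, None] * X[:, :]).sum(axis=0)  # d z/d beta = -x → sign flips
    # chain rule through the monotone threshold parametrization
    grad = np.empty_like(theta)
    grad[0] = galpha.sum()
    for jj in range(1, K - 1):
        grad[jj] = np.exp(gammas[jj - 1]) * galpha[jj:].sum()
    grad[K - 1 :] = gbeta
    return nll, grad


def _fit_prop_odds(X, y, K):
    from scipy.optimize import minimize

    p = X.shape[1]
    # start from intercept-only thresholds at the empirical cumulative logits
    cum = np.clip(np.cumsum(np.bincount(y, minlength=K))[:-1] / y.size, 1e-3, 1 - 1e-3)
    logits = np.log(cum / (1 - cum))
    theta0 = np.zeros(K - 1 + p)
    theta0[0] = logits[0]
    if K > 2:
        theta0[1 : K - 1] = np.log(np.maximum(np.diff(logits), 1e-3))
    res = minimize(_prop_odds_nll_grad, theta0, args=(X, y, K), jac=True, method="L-BFGS-B", options={"maxiter": 200})
    return res.x


def _prop_odds_probs(theta, X, K):
    n = X.shape[0]
    a1 = theta[0]
    gammas = theta[1 : K - 1]
    beta = theta[K - 1 :]
    alphas = a1 + np.concatenate([[0.0], np.cumsum(np.exp(gammas))])
    z = alphas[None, :] - (X @ beta)[:, None]
    F = 1.0 / (1.0 + np.exp(-np.clip(z, -35, 35)))
    Fpad = np.concatenate([np.zeros((n, 1)), F, np.ones((n, 1))], axis=1)
    return np.maximum(np.diff(Fpad, axis=1), 0.0)


def _draw_ordered(X, y_codes, X_mis, n_levels, rng) -> np.ndarray:
    """Proportional-odds draw; falls back to multinomial if the fit fails."""
    n = y_codes.size
    boot = rng.integers(0, n, size=n)
    yb = y_codes[boot].astype(int)
    if np.unique(yb).size < n_levels:
        # a level vanished from the resample: multinomial handles it cleanly
        return _draw_multinomial(X, y_codes, X_mis, n_levels, rng)
    try:
        theta = _fit_prop_odds(X[boot], yb, n_levels)
        probs = _prop_odds_probs(theta, X_mis, n_levels)
    except Exception:
        return _draw_multinomial(X, y_codes, X_mis, n_levels, rng)
    probs /= probs.sum(axis=1, keepdims=True)
    cum = np.cumsum(probs, axis=1)
    u = rng.random(X_mis.shape[0])[:, None]
    return (u > cum[:, :-1]).sum(axis=1).astype(float)


def _draw_continuous(X, y, X_mis, rng) -> np.ndarray:
    n = y.size
    boot = rng.integers(0, n, size=n)
    Xb = np.column_stack([np.ones(boot.size), X[boot]])
    beta, *_ = np.linalg.lstsq(Xb, y[boot], rcond=None)
    resid = y[boot] - Xb @ beta
    dof = max(Xb.shape[0] - Xb.shape[1], 1)
    sigma = float(np.sqrt((resid**2).sum() / dof))
    X1 = np.column_stack([np.ones(X_mis.shape[0]), X_mis])
    return X1 @ beta + rng.normal(0, sigma, size=X_mis.shape[0])


def mice_impute(
    df: pd.DataFrame,
    *,
    m: int = DEFAULT_M,
    sweeps: int = DEFAULT_SWEEPS,
    seed=None,
) -> ImputationSet:
    """Create ``m`` completed datasets by chained equations.

    ``df`` is a patient-level frame with columns ``pfs_months``,
    ``progressed`` (complete) and the covariates of
    :data:`VARIABLE_TYPES` (possibly incomplete).  Observed cells are
    identical across the m outputs; only missing cells vary.
    """
    if df["pfs_months"].isna().any() or df["progressed"].isna().any():
        raise ValueError("outcome columns must be complete; missingness is covariate-only")
    variables = [v for v in VARIABLE_TYPES if v in df.columns]
    model_types: dict[str, str] = {}
    masks: dict[str, np.ndarray] = {}
    for var in variables:
        kind = VARIABLE_TYPES[var]
        miss = df[var].isna().to_numpy()
        if var == "hormone_compliance":
            hrpos = (df["hr_status"] == "HR+").to_numpy()
            miss = miss & hrpos  # structurally absent for HR- is not missing
        if miss.all():
            raise ValueError(f"covariate {var!r} has no observed values")
        frac = miss.mean()
        if frac > 0.5:
            warnings.warn(f"covariate {var!r} is {frac:.0%} missing; imputations will be unstable")
        masks[var] = miss
        model_types[var] = {
            "continuous": "linear",
            "binary": "logistic",
            "binary-conditional": "logistic",
            "ordered": "proportional-odds",
            "unordered": "multinomial",
        }[kind]

    outcome = pd.DataFrame(
        {
            "_event": df["progressed"].astype(float).to_numpy(),
            "_cumhaz": nelson_aalen_cumhaz(df["pfs_months"].to_numpy(float), df["progressed"].to_numpy()),
        },
        index=df.index,
    )

    # --- encode everything once into a numeric working matrix -------------
    # one column per covariate (codes), plus the two outcome carriers;
    # sweeps then touch only numpy arrays.
    n = len(df)
    hrpos = (df["hr_status"] == "HR+").to_numpy() if "hr_status" in df.columns else np.zeros(n, bool)

    def encode(var) -> np.ndarray:
        s = df[var]
        kind = VARIABLE_TYPES[var]
        if kind == "continuous":
            return pd.to_numeric(s, errors="coerce").to_numpy(float)
        if kind == "ordered":
            return s.map({lv: float(i) for i, lv in enumerate(_ORDERED_LEVELS[var])}).to_numpy(float)
        if var == "hormone_compliance":
            # combined scale usable as predictor: HR- 0, compliant 0.5, non-compliant 1
            out = np.where(~hrpos, 0.0, np.nan)
            out = np.where(hrpos & (s == "compliant").to_numpy(), 0.5, out)
            out = np.where(hrpos & (s == "non-compliant").to_numpy(), 1.0, out)
            return out
        lv = _BINARY_LEVELS[var]
        return s.map({lv[0]: 0.0, lv[1]: 1.0}).to_numpy(float)

    col_of = {v: i for i, v in enumerate(variables)}
    M0 = np.column_stack([encode(v) for v in variables])
    outcome_cols = np.column_stack(
        [
            df["progressed"].astype(float).to_numpy(),
            nelson_aalen_cumhaz(df["pfs_months"].to_numpy(float), df["progressed"].to_numpy()),
        ]
    )
    incomplete = [v for v in variables if masks[v].any()]

    def decode(var, codes: np.ndarray):
        kind = VARIABLE_TYPES[var]
        if kind == "continuous":
            return codes
        if kind == "ordered":
            return np.asarray(_ORDERED_LEVELS[var], object)[codes.astype(int)]
        if var == "hormone_compliance":
            return np.where(codes >= 0.75, "non-compliant", "compliant")
        return np.asarray(_BINARY_LEVELS[var], object)[codes.astype(int)]

    children = as_seedseq(seed).spawn(m)
    datasets: list[pd.DataFrame] = []
    for k in range(m):
        rng = np.random.default_rng(children[k])
        M = M0.copy()
        # initial fill: random draws from the observed marginal
        for var in incomplete:
            j = col_of[var]
            obs_rows = ~np.isnan(M0[:, j])
            if var == "hormone_compliance":
                obs_rows &= hrpos
            pool = M0[obs_rows, j]
            M[masks[var], j] = pool[rng.integers(0, pool.size, size=int(masks[var].sum()))]
        for _sweep in range(sweeps if incomplete else 0):
            for var in incomplete:
                j = col_of[var]
                miss = masks[var]
                kind = VARIABLE_TYPES[var]
                fit_rows = (~miss) & hrpos if kind == "binary-conditional" else ~miss
                X_all = np.column_stack([np.delete(M, j, axis=1), outcome_cols])
                X_fit, X_mis = X_all[fit_rows], X_all[miss]
                y = M[fit_rows, j]
                if kind == "continuous":
                    M[miss, j] = _draw_continuous(X_fit, y, X_mis, rng)
                elif kind == "binary":
                    M[miss, j] = _draw_binary(X_fit, y, X_mis, rng)
                elif kind == "binary-conditional":
                    # codes 0.5 / 1.0 on the combined scale -> 0/1 for the fit
                    M[miss, j] = 0.5 + 0.5 * _draw_binary(X_fit, (y >= 0.75).astype(float), X_mis, rng)
                else:  # ordered
                    n_lv = len(_ORDERED_LEVELS[var])
                    M[miss, j] = _draw_ordered(X_fit, y, X_mis, n_lv, rng)
        work = df.copy()
        for var in incomplete:
            miss = masks[var]
            if work[var].dtype != float and VARIABLE_TYPES[var] != "continuous":
                work[var] = work[var].astype(object)
            work.loc[miss, var] = decode(var, M[miss, col_of[var]])
        if "grade" in work.columns:
            work["grade"] = pd.to_numeric(work["grade"]).astype(int)
        if "hr_status" in work.columns and "hormone_compliance" in work.columns:
            work["hr_hormone"] = np.where(
                work["hr_status"] == "HR-",
                "HR-",
                np.where(work["hormone_compliance"] == "compliant", "HR+ compliant", "HR+ non-compliant"),
            )
        datasets.append(work)
    return ImputationSet(datasets=datasets, model_types=model_types, seed=seed)
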