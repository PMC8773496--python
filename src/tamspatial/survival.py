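"""Kaplan–Meier estimation and Cox proportional-hazards modelling.

Thin, typed wrappers around lifelines with the conventions fixed for this
pipeline: Efron handling of tied event times, dummy coding with the
clinically conventional reference levels (grade 1, size <2 cm, node
negative, 'HR+ compliant' for the combined hormone factor), Wald 95% CIs on
the log-hazard scale, and proportional-hazards checking via scaled
Schoenfeld-residual score tests with automatic stratification of violating
categorical terms.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import proportional_hazard_test

__all__ = [
    "SurvivalData",
    "CoxFit",
    "km_estimate",
    "cox_fit",
    "ph_check",
    "refit_with_strata",
    "PARSIMONIOUS_TERMS",
    "FULL_TERMS",
    "build_design",
]

#: covariate-set presets for the multivariable models: the parsimonious
#: model holds the a-priori prognostic factors; the full model adds
#: demographics and radiation.
PARSIMONIOUS_TERMS = ("grade", "hr_hormone", "node", "size_cat")
FULL_TERMS = PARSIMONIOUS_TERMS + ("age", "race", "radiation")

_REFERENCES = {
    "grade": 1,
    "size_cat": "<2cm",
    "node": "negative",
    "hr_hormone": "HR+ compliant",
    "race": "white",
    "her2": "negative",
}
_LEVELS = {
    "grade": [1, 2, 3],
    "size_cat": ["<2cm", "2-5cm", ">5cm"],
    "node": ["negative", "positive"],
    "hr_hormone": ["HR+ compliant", "HR+ non-compliant", "HR-"],
    "race": ["white", "non-white"],
    "her2": ["negative", "positive"],
}


@dataclass
class SurvivalData:
    """Design matrix plus outcome, ready for partial-likelihood fitting."""

    time: np.ndarray
    event: np.ndarray
    X: pd.DataFrame  # dummy-coded covariates
    strata: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if (np.asarray(self.time, float) < 0).any():
            raise ValueError("negative survival times")


@dataclass
class CoxFit:
    """Per-term log hazard ratios with Wald inference."""

    terms: list[str]
    coef: np.ndarray
    se: np.ndarray
    n: int
    n_events: int
    strata: list[str] = field(default_factory=list)
    converged: bool = True
    loglik: float = float("nan")

    @property
    def hr(self) -> np.ndarray:
        return np.exp(self.coef)

    @property
    def ci(self) -> tuple[np.ndarray, np.ndarray]:
        lo = np.exp(self.coef - 1.959963984540054 * self.se)
        hi = np.exp(self.coef + 1.959963984540054 * self.se)
        return lo, hi

    @property
    def p(self) -> np.ndarray:
        from scipy import stats

        return 2 * stats.norm.sf(np.abs(self.coef / self.se))

    def summary_frame(self) -> pd.DataFrame:
        lo, hi = self.ci
        return pd.DataFrame(
            {
                "term": self.terms,
                "log_hr": self.coef,
                "se": self.se,
                "hr": self.hr,
                "hr_ci_low": lo,
                "hr_ci_high": hi,
                "p": self.p,
            }
        )


def build_design(df: pd.DataFrame, terms: tuple[str, ...] | list[str]) -> pd.DataFrame:
    """Dummy-code the requested covariates with fixed reference levels.

    Continuous terms (age) pass through; binary booleans become 0/1;
    categorical terms expand into k−1 indicators against the recorded
    reference level.
    """
    cols = {}
    for term in terms:
        s = df[term]
        if term in _LEVELS:
            levels = _LEVELS[term]
            ref = _REFERENCES[term]
            for lv in levels:
                if lv == ref:
                    continue
                cols[f"{term}[{lv}]"] = (s == lv).astype(float)
            known = s.isin(levels) | s.isna()
            if not known.all():
                raise ValueError(f"unknown level in {term!r}: {s[~known].iloc[0]!r}")
        elif s.dtype == bool or str(s.dtype) == "boolean" or s.dropna().isin([True, False]).all():
            cols[term] = s.astype(float)
        else:
            cols[term] = pd.to_numeric(s, errors="raise").astype(float)
    out = pd.DataFrame(cols, index=df.index)
    # propagate missingness of the source column to all its dummies
    for term in terms:
        if term in _LEVELS:
            na = df[term].isna()
            if na.any():
                for c in out.columns:
                    if c.startswith(f"{term}["):
                        out.loc[na, c] = np.nan
    return out


def km_estimate(time, event, groups=None) -> dict[str, pd.DataFrame]:
    """Product-limit survival estimates, optionally per group.

    Returns a mapping from group label ('all' when ungrouped) to a frame
    with columns ``t`` and ``s`` (the step function evaluated at the
    observed times, S(0) = 1).
    """
    time = np.asarray(time, float)
    event = np.asarray(event).astype(bool)
    if groups is None:
        groups = np.full(time.size, "all")
    groups = np.asarray(groups)
    out: dict[str, pd.DataFrame] = {}
    for g in np.unique(groups):
        m = groups == g
        if not m.any():
            continue
        kmf = KaplanMeierFitter()
        kmf.fit(time[m], event_observed=event[m])
        sf = kmf.survival_function_
        out[str(g)] = pd.DataFrame({"t": sf.index.to_numpy(float), "s": sf.iloc[:, 0].to_numpy(float)})
    return out


def _assemble_frame(data: SurvivalData) -> tuple[pd.DataFrame, list[str] | None]:
    df = data.X.copy()
    df["_time"] = np.asarray(data.time, float)
    df["_event"] = np.asarray(data.event).astype(int)
    strata_cols = None
    if data.strata is not None and data.strata.shape[1] > 0:
        for c in data.strata.columns:
            df[c] = data.strata[c].to_numpy()
        strata_cols = list(data.strata.columns)
    return df, strata_cols


def cox_fit(data: SurvivalData) -> CoxFit:
    """Maximize the Efron partial likelihood; deterministic given the data."""
    if int(np.asarray(data.event).sum()) < 1:
        raise ValueError("no events in the data")
    const = [c for c in data.X.columns if data.X[c].nunique(dropna=True) <= 1]
    if const:
        raise ValueError(f"covariate {const[0]!r} is constant; drop it or stratify")
    df, strata_cols = _assemble_frame(data)
    cph = CoxPHFitter()
    converged = True
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            cph.fit(df, duration_col="_time", event_col="_event", strata=strata_cols)
        except Exception as exc:  # convergence / separation
            raise RuntimeError(f"Cox fit failed: {exc}") from exc
    summ = cph.summary
    return CoxFit(
        terms=list(summ.index),
        coef=summ["coef"].to_numpy(float),
        se=summ["se(coef)"].to_numpy(float),
        n=int(df.shape[0]),
        n_events=int(df["_event"].sum()),
        strata=strata_cols or [],
        converged=converged,
        loglik=float(cph.log_likelihood_),
    )


def ph_check(data: SurvivalData, fit: CoxFit, alpha: float = 0.05) -> pd.DataFrame:
    """Scaled Schoenfeld-residual score test of proportional hazards per term."""
    df, strata_cols = _assemble_frame(data)
    cph = CoxPHFitter()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cph.fit(df, duration_col="_time", event_col="_event", strata=strata_cols)
        res = proportional_hazard_test(cph, df, time_transform="rank")
    summ = res.summary.reset_index().rename(columns={"index": "term"})
    if "test_statistic" in summ.columns:
        summ = summ.rename(columns={"test_statistic": "statistic"})
    summ["violates"] = summ["p"] < alpha
    return summ[[c for c in ("term", "statistic", "p", "violates") if c in summ.columns]]


def refit_with_strata(data: SurvivalData, violating_terms: list[str]) -> CoxFit:
    """Move PH-violating terms from the linear predictor into strata and refit.

    A dummy column named like ``factor[level]`` strafies on the underlying
    factor; the stratified term's coefficient rows disappear from the fit.
    """
    base = sorted({t.split("[")[0] for t in violating_terms})
    keep = [c for c in data.X.columns if c.split("[")[0] not in base]
    strata = pd.DataFrame(index=data.X.index)
    for b in base:
        cols = [c for c in data.X.columns if c.split("[")[0] == b]
        if len(cols) == 1 and cols[0] == b:
            vals = data.X[b]
            strata[b] = (vals > np.nanmedian(vals.to_numpy(float))).astype(int) if vals.nunique() > 2 else vals
        else:
            lab = np.full(len(data.X), "ref", dtype=object)
            for c in cols:
                lab[data.X[c].to_numpy(float) == 1.0] = c
            strata[b] = lab
    # collapse strata levels without events into the reference level
    ev = np.asarray(data.event).astype(bool)
    for b in strata.columns:
        for lv in pd.unique(strata[b]):
            m = (strata[b] == lv).to_numpy()
            if m.any() and not ev[m].any():
                warnings.warn(f"stratum {b}={lv!r} has no events; collapsed into reference")
                strata.loc[m, b] = "ref"
    if data.strata is not None:
        strata = pd.concat([data.strata, strata], axis=1)
    return cox_fit(SurvivalData(time=data.time, event=data.event, X=data.X[keep], strata=strata))
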