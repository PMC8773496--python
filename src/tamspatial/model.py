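"""Model/Results interface for the optimism-corrected dichotomized-marker Cox analysis.

:class:`OptimismCorrectedCox` is built from a patient-level DataFrame that
carries the outcome (``pfs_months``, ``progressed``), one continuous CD163
metric, and optional clinicopathologic covariates.  ``fit`` runs the whole
inferential chain — bootstrap survival-tree cutpoint, multiple imputation
of incomplete covariates, per-imputation bootstrap optimism correction of
the marker's log hazard ratio, Rubin pooling — and returns a results
object with estimates, uncertainties and a ``summary()`` table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cutpoints import CutpointResult, bootstrap_cutpoint
from .imputation import VARIABLE_TYPES, mice_impute
from .survival import FULL_TERMS, PARSIMONIOUS_TERMS, build_design
from .validation import OptimismResult, PooledResult, optimism_correct, rubin_pool

__all__ = ["OptimismCorrectedCox", "OptimismCorrectedCoxResults"]

_PRESETS = {"parsimonious": PARSIMONIOUS_TERMS, "full": FULL_TERMS, "none": ()}


class OptimismCorrectedCox:
    """Optimism-corrected Cox model of a data-driven dichotomized biomarker.

    Parameters
    ----------
    data
        One row per patient with columns ``pfs_months`` (months, ≥ 0),
        ``progressed`` (bool), the ``metric`` column, and whichever
        covariates the preset requires (they may contain missing values).
    metric
        Name of the continuous CD163 metric to dichotomize.
    covariate_preset
        'none' (univariable marker model), 'parsimonious' (grade, combined
        hormone factor, node status, tumor size) or 'full' (adds age, race,
        radiation).  Terms absent from ``data`` are dropped with a note.
    """

    def __init__(self, data: pd.DataFrame, metric: str, covariate_preset: str = "parsimonious"):
        if metric not in data.columns:
            raise KeyError(f"metric column {metric!r} not in data")
        for col in ("pfs_months", "progressed"):
            if col not in data.columns:
                raise KeyError(f"data lacks outcome column {col!r}")
        if covariate_preset not in _PRESETS:
            raise ValueError(f"unknown covariate preset {covariate_preset!r}")
        if data[metric].isna().any():
            raise ValueError(f"metric {metric!r} has missing values")
        self.data = data.reset_index(drop=True)
        self.metric = metric
        self.covariate_preset = covariate_preset
        self.terms = tuple(t for t in _PRESETS[covariate_preset] if t in data.columns)

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, metric: str, **kwargs) -> "OptimismCorrectedCox":
        return cls(data, metric, **kwargs)

    def fit(
        self,
        *,
        B_cutpoint: int = 1000,
        B_optimism: int = 500,
        m: int = 40,
        sweeps: int = 10,
        min_leaf: int = 7,
        min_split: int = 20,
        folds: int = 10,
        seed=None,
    ) -> "OptimismCorrectedCoxResults":
        from ._rng import as_seedseq

        seeds = as_seedseq(seed).spawn(3)
        time = self.data["pfs_months"].to_numpy(float)
        event = self.data["progressed"].to_numpy(bool)
        x = self.data[self.metric].to_numpy(float)

        cutpoint = bootstrap_cutpoint(
            x, time, event, B=B_cutpoint, min_leaf=min_leaf, min_split=min_split, folds=folds, seed=seeds[0]
        )

        impute_vars = [t for t in self.terms if t in VARIABLE_TYPES or t == "hr_hormone"]
        needs_mi = any(
            self.data[t].isna().any() for t in impute_vars if t in self.data.columns and t != "hr_hormone"
        ) or ("hr_hormone" in self.terms and self.data["hr_hormone"].isna().any())
        if needs_mi:
            imp = mice_impute(self.data, m=m, sweeps=sweeps, seed=seeds[1])
            datasets = imp.datasets
        else:
            datasets = [self.data]

        per_imp: list[OptimismResult] = []
        child_seeds = seeds[2].spawn(len(datasets))
        for k, dset in enumerate(datasets):
            Z = build_design(dset, self.terms) if self.terms else None
            if Z is not None:
                # drop empty dummies (levels unobserved in this cohort)
                Z = Z.loc[:, Z.nunique() > 1]
                if Z.shape[1] == 0:
                    Z = None
            per_imp.append(
                optimism_correct(
                    dset,
                    self.metric,
                    covariates=Z,
                    B=B_optimism,
                    direction=cutpoint.direction,
                    min_leaf=min_leaf,
                    min_split=min_split,
                    folds=folds,
                    seed=child_seeds[k],
                )
            )
        n_cov = build_design(datasets[0], self.terms).shape[1] if self.terms else 0
        df_complete = max(float(event.sum()) - (1 + n_cov), 1.0)
        pooled = rubin_pool(
            [r.corrected_log_hr for r in per_imp],
            [r.se_log_hr**2 for r in per_imp],
            df_complete=df_complete,
        )
        pooled_apparent = rubin_pool(
            [r.apparent_log_hr for r in per_imp],
            [r.se_log_hr**2 for r in per_imp],
            df_complete=df_complete,
        )
        return OptimismCorrectedCoxResults(
            model=self,
            cutpoint=cutpoint,
            per_imputation=per_imp,
            pooled=pooled,
            pooled_apparent=pooled_apparent,
            m=len(datasets),
        )


@dataclass
class OptimismCorrectedCoxResults:
    """Fitted estimates of the dichotomized-marker Cox analysis."""

    model: OptimismCorrectedCox
    cutpoint: CutpointResult
    per_imputation: list[OptimismResult]
    pooled: PooledResult
    pooled_apparent: PooledResult
    m: int
    extra: dict = field(default_factory=dict)

    @property
    def corrected_log_hr(self) -> float:
        return self.pooled.estimate

    @property
    def corrected_hr(self) -> float:
        return float(np.exp(self.pooled.estimate))

    @property
    def apparent_log_hr(self) -> float:
        return self.pooled_apparent.estimate

    @property
    def mean_optimism(self) -> float:
        return float(np.mean([r.mean_optimism for r in self.per_imputation]))

    @property
    def conf_int(self) -> tuple[float, float]:
        """95% CI of the corrected hazard ratio."""
        return (float(np.exp(self.pooled.ci_low)), float(np.exp(self.pooled.ci_high)))

    def summary(self) -> pd.DataFrame:
        lo, hi = self.conf_int
        return pd.DataFrame(
            [
                {
                    "metric": self.model.metric,
                    "covariates": self.model.covariate_preset,
                    "cutoff": self.cutpoint.cutoff,
                    "cutoff_ci90_low": self.cutpoint.ci90[0],
                    "cutoff_ci90_high": self.cutpoint.ci90[1],
                    "direction": self.cutpoint.direction,
                    "hr_apparent": float(np.exp(self.apparent_log_hr)),
                    "mean_optimism_log": self.mean_optimism,
                    "hr_corrected": self.corrected_hr,
                    "hr_ci_low": lo,
                    "hr_ci_high": hi,
                    "p": self.pooled.p,
                    "m_imputations": self.m,
                }
            ]
        )

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        lo, hi = self.conf_int
        return (
            f"<OptimismCorrectedCoxResults {self.model.metric}: cutoff={self.cutpoint.cutoff:.3g} "
            f"({self.cutpoint.direction}-risk), HR={self.corrected_hr:.2f} [{lo:.2f}, {hi:.2f}]>"
        )
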