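"""Bootstrap optimism correction, Rubin pooling, and the pipeline runner.

Deriving a dichotomization threshold and evaluating its hazard ratio on
the same patients inflates the apparent effect.  The bootstrap optimism
correction repeats the whole selection inside each of B resamples: the
tree-derived threshold of resample b gives a "bootstrap performance" log HR
(fitted in the resample) and a "test performance" log HR (same threshold,
fitted in the original data); their difference, averaged over b, is the
mean optimism, which is subtracted from the apparent log HR.  Because the
marker is always oriented high-risk vs low-risk, the optimism is positive
on average and the corrected estimate is honest even under the null.

With multiply-imputed covariates the correction runs independently on each
completed dataset and per-dataset corrected estimates are pooled by Rubin's
rule with the Barnard–Rubin small-sample degrees of freedom.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import cutpoints
from ._fastcox import CoxSeparationError, fast_coxph
from ._rng import as_seedseq
from .cutpoints import NoSplit, dichotomize, tree_cutpoint

__all__ = ["OptimismResult", "PooledResult", "optimism_correct", "rubin_pool", "run_pipeline"]


@dataclass
class OptimismResult:
    apparent_log_hr: float
    mean_optimism: float
    corrected_log_hr: float
    se_log_hr: float
    cutoff: float
    direction: str
    B: int
    n_skipped: int
    extra: dict = field(default_factory=dict)


@dataclass
class PooledResult:
    estimate: float
    total_variance: float
    df: float
    ci_low: float
    ci_high: float
    p: float
    m: int

    @property
    def se(self) -> float:
        return float(np.sqrt(self.total_variance))


def _marker_log_hr(marker, time, event, Z, init=None):
    """Log HR (and SE) of the binary marker, optionally covariate-adjusted."""
    X = marker[:, None] if Z is None else np.column_stack([marker, Z])
    res = fast_coxph(time, event, X, init=init)
    return float(res.coef[0]), float(res.se[0]), res.coef


def optimism_correct(
    df: pd.DataFrame,
    metric: str,
    *,
    covariates: np.ndarray | pd.DataFrame | None = None,
    B: int = 500,
    direction: str = "high",
    min_leaf: int = cutpoints.MIN_LEAF_DEFAULT,
    min_split: int = cutpoints.MIN_SPLIT_DEFAULT,
    folds: int = 10,
    seed=None,
    time_col: str = "pfs_months",
    event_col: str = "progressed",
) -> OptimismResult:
    """Optimism-corrected log HR of the tree-dichotomized ``metric``.

    ``df`` must be complete (run imputation first).  ``covariates`` is an
    optional numeric adjustment matrix aligned with ``df`` (dummy-coded).
    Resamples whose tree prunes to the root or whose Cox fit separates are
    skipped and counted; a warning is issued past 20% skips.

    ``direction`` is the fixed per-metric contrast convention ('high':
    values above the cutoff are the flagged group; 'low': inverted, as for
    nearest-neighbor distances where small values are adverse).  It is
    deliberately NOT re-derived per bootstrap resample: re-orienting each
    replicate toward its own high-risk side would make the test-performance
    log HR positively biased under the null (the orientation would leak
    information from the shared patients), leaving inflation the optimism
    subtraction cannot remove.
    """
    time = df[time_col].to_numpy(float)
    event = df[event_col].to_numpy(bool)
    x = df[metric].to_numpy(float)
    Z = None
    if covariates is not None:
        Z = covariates.to_numpy(float) if isinstance(covariates, pd.DataFrame) else np.asarray(covariates, float)
    n = x.size

    children = as_seedseq(seed).spawn(B + 1)
    rng0 = np.random.default_rng(children[0])
    apparent_cp = tree_cutpoint(x, time, event, min_leaf=min_leaf, min_split=min_split, folds=folds, seed=rng0)
    marker0 = dichotomize(x, apparent_cp.cutoff, direction)
    apparent, se, beta0 = _marker_log_hr(marker0, time, event, Z)

    optimisms = []
    boot_lhrs = []
    n_skipped = 0
    for b in range(B):
        rng = np.random.default_rng(children[b + 1])
        idx = rng.integers(0, n, size=n)
        try:
            cp = tree_cutpoint(
                x[idx], time[idx], event[idx], min_leaf=min_leaf, min_split=min_split, folds=folds, seed=rng
            )
            mk_boot = dichotomize(x[idx], cp.cutoff, direction)
            mk_test = dichotomize(x, cp.cutoff, direction)
            Zb = Z[idx] if Z is not None else None
            boot_lhr, _, _ = _marker_log_hr(mk_boot, time[idx], event[idx], Zb, init=beta0)
            test_lhr, _, _ = _marker_log_hr(mk_test, time, event, Z, init=beta0)
            optimisms.append(boot_lhr - test_lhr)
            boot_lhrs.append(boot_lhr)
        except (NoSplit, CoxSeparationError, ValueError):
            n_skipped += 1
    if not optimisms:
        raise RuntimeError("every bootstrap replicate failed; effect or sample too small")
    if n_skipped > 0.2 * B:
        warnings.warn(f"{n_skipped}/{B} bootstrap replicates skipped in optimism correction")
    mean_optimism = float(np.mean(optimisms))
    # The corrected estimate inherits two error sources: the Wald variance
    # of the apparent fit at its chosen cutpoint, and the variability of
    # the data-driven selection itself, for which the spread of the
    # bootstrap performances is the natural plug-in.  Their sum is a
    # deliberately conservative variance for a non-smooth selection
    # pipeline (it counts the fit noise embedded in the bootstrap spread a
    # second time), erring wide where the cutpoint is unstable.
    var_select = float(np.var(boot_lhrs, ddof=1)) if len(boot_lhrs) > 1 else 0.0
    se_total = float(np.sqrt(se**2 + var_select))
    return OptimismResult(
        apparent_log_hr=apparent,
        mean_optimism=mean_optimism,
        corrected_log_hr=apparent - mean_optimism,
        se_log_hr=se_total,
        cutoff=apparent_cp.cutoff,
        direction=direction,
        B=B,
        n_skipped=n_skipped,
        extra={"optimisms": np.asarray(optimisms), "se_apparent": se, "boot_log_hrs": np.asarray(boot_lhrs)},
    )


def rubin_pool(estimates, variances, *, df_complete: float | None = None, level: float = 0.95) -> PooledResult:
    """Rubin's combining rule for m repeated-imputation estimates.

    pooled = mean(estimates); T = W + (1 + 1/m) * B with W the mean
    within-imputation variance and B the between-imputation variance.
    Degrees of freedom use the classical formula, shrunk by the
    Barnard–Rubin adjustment when ``df_complete`` is supplied.
    """
    q = np.asarray(estimates, float)
    u = np.asarray(variances, float)
    if q.size == 0:
        raise ValueError("need at least one (estimate, variance) pair")
    if q.size != u.size:
        raise ValueError("estimates and variances must pair up")
    m = q.size
    qbar = float(q.mean())
    w = float(u.mean())
    b = float(q.var(ddof=1)) if m > 1 else 0.0
    t = w + (1 + 1 / m) * b
    if m == 1 or b == 0:
        nu = float("inf")
    else:
        r = (1 + 1 / m) * b / w
        nu = (m - 1) * (1 + 1 / r) ** 2
        if df_complete is not None:
            nu_obs = (df_complete + 1) / (df_complete + 3) * df_complete * (1 - (1 + 1 / m) * b / t)
            nu = 1 / (1 / nu + 1 / nu_obs)
    tdist = stats.t(df=nu) if np.isfinite(nu) else stats.norm
    crit = tdist.ppf(0.5 + level / 2)
    se = np.sqrt(t)
    p = 2 * tdist.sf(abs(qbar) / se) if t > 0 else (0.0 if qbar != 0 else 1.0)
    return PooledResult(
        estimate=qbar,
        total_variance=float(t),
        df=float(nu),
        ci_low=float(qbar - crit * se),
        ci_high=float(qbar + crit * se),
        p=float(p),
        m=m,
    )


# ---------------------------------------------------------------------------
# end-to-end pipeline
# ---------------------------------------------------------------------------


def run_pipeline(config: dict) -> dict:
    """Run read → QC → phenotype → dedup → metrics → cutpoints →
    imputation → optimism-corrected Cox, per a config mapping.

    Required config keys: ``cell_table``, ``clinical_table``, ``seed``.
    Optional: ``metrics`` (names to analyse), ``B_cutpoint``,
    ``B_optimism``, ``m``, ``utl`` {content, confidence}, ``radii``
    {adjacent_um, communicating_um}, ``truncation_um``, ``min_cancer``,
    ``covariate_preset`` ('parsimonious' | 'full' | 'none'), ``out_dir``.

    Returns a bundle of tidy DataFrames plus a manifest; writes CSV/JSON
    into ``out_dir`` when given.
    """
    from pathlib import Path

    from .core import dedup_cores, patients_to_frame, qc_filter, read_clinical_table, read_core_table, write_manifest
    from .model import OptimismCorrectedCox
    from .phenotyping import UtlSpec, phenotype_core
    from .spatial import METRIC_NAMES, compute_metric_suite

    for key in ("cell_table", "clinical_table", "seed"):
        if key not in config:
            raise KeyError(f"config missing required key {key!r}")
    seed = int(config["seed"])
    stage = "read"
    try:
        cores = read_core_table(config["cell_table"], config.get("column_map"))
        patients = read_clinical_table(config["clinical_table"])
        stage = "qc_filter"
        kept, excluded = qc_filter(cores, min_cancer=int(config.get("min_cancer", 10)))
        stage = "phenotype"
        utl_cfg = config.get("utl", {})
        spec = UtlSpec(content=float(utl_cfg.get("content", 0.95)), confidence=float(utl_cfg.get("confidence", 0.99)))
        tam_counts = {}
        for core in kept:
            _, tam_counts[core.core_id] = phenotype_core(core, spec)
        stage = "dedup"
        chosen, dropped = dedup_cores(kept, tam_counts)
        stage = "metrics"
        radii = config.get("radii", {})
        rows = []
        for pid, core in sorted(chosen.items()):
            ms = compute_metric_suite(
                core,
                adjacent_um=float(radii.get("adjacent_um", 12.0)),
                communicating_um=float(radii.get("communicating_um", 250.0)),
                truncation_um=float(config.get("truncation_um", 600.0)),
            )
            rows.append({"patient_id": pid, "core_id": core.core_id, **ms.as_dict()})
        metrics_df = pd.DataFrame(rows)
        clin = patients_to_frame(patients)
        data = clin.merge(metrics_df, on="patient_id", how="inner")
        stage = "analysis"
        metric_names = list(config.get("metrics", METRIC_NAMES))
        results = {}
        for i, name in enumerate(metric_names):
            model = OptimismCorrectedCox(
                data,
                metric=name,
                covariate_preset=config.get("covariate_preset", "parsimonious"),
            )
            results[name] = model.fit(
                B_cutpoint=int(config.get("B_cutpoint", 1000)),
                B_optimism=int(config.get("B_optimism", 500)),
                m=int(config.get("m", 40)),
                seed=seed + 1000 + i,
            )
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    marker_table = pd.DataFrame(
        [
            {
                "metric": name,
                "cutoff": r.cutpoint.cutoff,
                "cutoff_ci90_low": r.cutpoint.ci90[0],
                "cutoff_ci90_high": r.cutpoint.ci90[1],
                "direction": r.cutpoint.direction,
                "hr_corrected": float(np.exp(r.pooled.estimate)),
                "hr_ci_low": float(np.exp(r.pooled.ci_low)),
                "hr_ci_high": float(np.exp(r.pooled.ci_high)),
                "p": r.pooled.p,
            }
            for name, r in results.items()
        ]
    )
    manifest = {
        "seed": seed,
        "n_cores_read": len(cores),
        "n_cores_kept": len(kept),
        "exclusions": [e.__dict__ for e in excluded + dropped],
        "n_patients_analysed": int(data.shape[0]),
        "metrics": metric_names,
        "utl": {"content": spec.content, "confidence": spec.confidence},
    }
    bundle = {"metrics": metrics_df, "data": data, "results": results, "marker_table": marker_table, "manifest": manifest}
    out_dir = config.get("out_dir")
    if out_dir:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        metrics_df.to_csv(out / "per_core_metrics.csv", index=False)
        marker_table.to_csv(out / "marker_table.csv", index=False)
        write_manifest(out / "manifest.json", manifest)
    return bundle
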