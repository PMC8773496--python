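"""Synthetic cores and cohorts with known ground truth.

No public cell-table accession exists for this kind of study, so every
pipeline stage is exercised on generated data whose truth is known:

* :func:`generate_core` draws a single TMA core — cancer cells from a
  parent–offspring cluster process (tumor nests), CD163− stromal cells
  uniform in the circular window, and true TAMs placed uniformly
  ("random"), near cancer cells ("attracted": Gaussian displacement from a
  random cancer cell) or away from them ("repulsed").  CD163 intensity is
  log-normal background for cancer and CD163− stromal cells and a shifted
  log-normal for true TAMs, so phenotyping has a recoverable signal.

* :func:`generate_cohort` builds a patient-level study: one core per
  patient with a varying TAM fraction, the designated metric computed from
  the *true* TAM labels, survival times from an exponential (or Weibull)
  baseline multiplied by exp(beta * 1[metric > c] + covariate effects),
  independent censoring, clinicopathologic covariates from realistic
  marginals, and missing-at-random covariate gaps whose probability
  depends on always-observed variables (age, node status).

Ground-truth labels, the threshold c and beta are returned separately and
never written into the tables the pipeline consumes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd

from .core import CoreTable, Window
from .spatial import SpatialMetricSet, metric_suite_from_arrays

__all__ = ["CoreGenSpec", "CohortGenSpec", "generate_core", "generate_cohort", "write_cohort_csvs"]

_REJECTION_LIMIT = 100_000


@dataclass(frozen=True)
class CoreGenSpec:
    """Generative parameters of one synthetic tissue core."""

    n_cancer: int = 150
    n_stromal: int = 250
    tam_fraction: float = 0.10
    proximity_mode: Literal["attracted", "random", "repulsed"] = "random"
    attraction_sd: float = 30.0  # μm
    n_parents: int = 5
    offspring_sd: float = 40.0  # μm, spread of cancer cells around nest centers
    bg_log_mean: float = 2.0  # background CD163, log intensity units
    bg_log_sd: float = 0.25
    tam_log_shift: float = 1.0  # additive log-mean shift for true TAMs (> 0)
    diameter: float = 600.0  # μm

    def __post_init__(self) -> None:
        if self.n_cancer < 0 or self.n_stromal < 0:
            raise ValueError("counts must be >= 0")
        if not (0 <= self.tam_fraction <= 1):
            raise ValueError("tam_fraction must be in [0, 1]")
        if self.tam_log_shift <= 0:
            raise ValueError("tam_log_shift must be > 0 for identifiable phenotyping")


def _uniform_disc(rng: np.random.Generator, n: int, window: Window) -> np.ndarray:
    r = window.radius * np.sqrt(rng.random(n))
    theta = rng.random(n) * 2 * np.pi
    return np.column_stack([window.center_x + r * np.cos(theta), window.center_y + r * np.sin(theta)])


def _cluster_points(rng: np.random.Generator, n: int, spec: CoreGenSpec, window: Window) -> np.ndarray:
    if n == 0:
        return np.empty((0, 2))
    parents = _uniform_disc(rng, max(spec.n_parents, 1), window)
    out = np.empty((0, 2))
    tries = 0
    while out.shape[0] < n:
        need = n - out.shape[0]
        assign = rng.integers(0, parents.shape[0], size=2 * need + 8)
        pts = parents[assign] + rng.normal(0, spec.offspring_sd, size=(assign.size, 2))
        keep = window.contains(pts[:, 0], pts[:, 1])
        out = np.vstack([out, pts[keep]])
        tries += assign.size
        if tries > _REJECTION_LIMIT:
            raise RuntimeError("cluster rejection sampling exhausted; reduce offspring_sd")
    return out[:n]


def _attracted_points(rng, n, cancer_xy, sd, window: Window) -> np.ndarray:
    out = np.empty((0, 2))
    tries = 0
    while out.shape[0] < n:
        need = n - out.shape[0]
        anchors = cancer_xy[rng.integers(0, cancer_xy.shape[0], size=2 * need + 8)]
        pts = anchors + rng.normal(0, sd, size=(anchors.shape[0], 2))
        keep = window.contains(pts[:, 0], pts[:, 1])
        out = np.vstack([out, pts[keep]])
        tries += anchors.shape[0]
        if tries > _REJECTION_LIMIT:
            raise RuntimeError("attracted-TAM rejection sampling exhausted; reduce attraction_sd")
    return out[:n]


def _repulsed_points(rng, n, cancer_xy, window: Window) -> np.ndarray:
    from scipy.spatial import cKDTree

    # distance threshold: median nearest-cancer distance of uniform points
    probe = _uniform_disc(rng, 512, window)
    tree = cKDTree(cancer_xy)
    med = float(np.median(tree.query(probe, k=1)[0]))
    out = np.empty((0, 2))
    tries = 0
    while out.shape[0] < n:
        need = n - out.shape[0]
        pts = _uniform_disc(rng, 4 * need + 8, window)
        d = tree.query(pts, k=1)[0]
        out = np.vstack([out, pts[d > med]])
        tries += pts.shape[0]
        if tries > _REJECTION_LIMIT:
            raise RuntimeError("repulsed-TAM rejection sampling exhausted")
    return out[:n]


def _sample_core(spec: CoreGenSpec, rng: np.random.Generator):
    """Geometry + intensities as plain arrays: (cancer_xy, tam_xy, neg_xy, cd163s)."""
    window = Window(0.0, 0.0, spec.diameter)
    cancer_xy = _cluster_points(rng, spec.n_cancer, spec, window)
    n_tam = int(round(spec.tam_fraction * spec.n_stromal))
    n_neg = spec.n_stromal - n_tam
    neg_xy = _uniform_disc(rng, n_neg, window)
    if n_tam == 0:
        tam_xy = np.empty((0, 2))
    elif spec.proximity_mode == "random" or spec.n_cancer == 0:
        tam_xy = _uniform_disc(rng, n_tam, window)
    elif spec.proximity_mode == "attracted":
        tam_xy = _attracted_points(rng, n_tam, cancer_xy, spec.attraction_sd, window)
    else:
        tam_xy = _repulsed_points(rng, n_tam, cancer_xy, window)
    n_total = spec.n_cancer + n_tam + n_neg
    log_int = rng.normal(spec.bg_log_mean, spec.bg_log_sd, size=n_total)
    log_int[spec.n_cancer : spec.n_cancer + n_tam] += spec.tam_log_shift
    return window, cancer_xy, tam_xy, neg_xy, np.exp(log_int)


def _assemble_core(
    spec: CoreGenSpec, window, cancer_xy, tam_xy, neg_xy, cd163, core_id: str, patient_id: str
) -> tuple[CoreTable, np.ndarray]:
    n_tam = tam_xy.shape[0]
    n_neg = neg_xy.shape[0]
    xy = np.vstack([cancer_xy, tam_xy, neg_xy])
    compartment = np.array(["cancer"] * spec.n_cancer + ["stromal"] * (n_tam + n_neg))
    truth = np.array([False] * spec.n_cancer + [True] * n_tam + [False] * n_neg)
    cells = pd.DataFrame(
        {
            "cell_id": np.arange(xy.shape[0]).astype(str),
            "x": xy[:, 0],
            "y": xy[:, 1],
            "compartment": compartment,
            "cd163": cd163,
        }
    )
    return CoreTable(core_id, patient_id, cells, window), truth


def generate_core(
    spec: CoreGenSpec, seed=None, *, core_id: str = "core0", patient_id: str = "p0"
) -> tuple[CoreTable, np.ndarray]:
    """One synthetic core plus the hidden ground-truth TAM indicator.

    The returned boolean array marks the *true* TAMs among the core's
    cells (always False for cancer cells); the CoreTable itself carries no
    truth — its ``tam`` column is unset until phenotyping runs.
    """
    rng = np.random.default_rng(seed)
    window, cancer_xy, tam_xy, neg_xy, cd163 = _sample_core(spec, rng)
    return _assemble_core(spec, window, cancer_xy, tam_xy, neg_xy, cd163, core_id, patient_id)


@dataclass(frozen=True)
class CohortGenSpec:
    """Generative parameters of a synthetic patient cohort.

    The designated metric carries a true threshold effect: hazard is
    multiplied by exp(beta) for patients whose metric (computed from the
    true TAM labels) exceeds ``true_cutpoint``.
    """

    n_patients: int = 400
    metric: str = "tam_count"
    true_cutpoint: float = 25.5
    beta: float = float(np.log(3))
    core: CoreGenSpec = field(default_factory=CoreGenSpec)
    tam_fraction_range: tuple[float, float] = (0.0, 0.30)
    covariate_effects: dict = field(
        default_factory=lambda: {"grade3": 0.4, "node_positive": 0.5, "hr_negative": 0.4, "size_large": 0.3}
    )
    baseline_rate: float = 0.0035  # events per month for the reference patient (~60% events)
    weibull_shape: float = 1.0  # 1.0 = exponential baseline
    censor_low: float = 24.0  # months, uniform censoring window
    censor_high: float = 140.0
    missingness: dict = field(
        default_factory=lambda: {
            "race": 0.02,
            "grade": 0.05,
            "size_cat": 0.04,
            "her2": 0.03,
            "radiation": 0.02,
            "hormone_compliance": 0.12,
        }
    )

    def __post_init__(self) -> None:
        if not np.isfinite(self.beta):
            raise ValueError("beta must be finite")


def _draw_covariates(rng: np.random.Generator, n: int) -> pd.DataFrame:
    age = np.clip(rng.normal(56, 11, n), 25, 90)
    race = np.where(rng.random(n) < 0.70, "white", "non-white")
    grade = rng.choice([1, 2, 3], size=n, p=[0.20, 0.45, 0.35])
    node = np.where(rng.random(n) < 0.45, "positive", "negative")
    size_cat = rng.choice(["<2cm", "2-5cm", ">5cm"], size=n, p=[0.40, 0.50, 0.10])
    hr_status = np.where(rng.random(n) < 0.75, "HR+", "HR-")
    her2 = np.where(rng.random(n) < 0.20, "positive", "negative")
    radiation = rng.random(n) < 0.70
    compliance = np.where(
        hr_status == "HR-", "not-applicable", np.where(rng.random(n) < 0.15, "non-compliant", "compliant")
    )
    return pd.DataFrame(
        {
            "age": age,
            "race": race,
            "grade": grade,
            "node": node,
            "size_cat": size_cat,
            "hr_status": hr_status,
            "her2": her2,
            "radiation": radiation,
            "hormone_compliance": compliance,
        }
    )


def generate_cohort(
    spec: CohortGenSpec, seed=None, *, compute_all_metrics: bool = False, keep_cores: bool = True
) -> tuple[pd.DataFrame, list[CoreTable], dict]:
    """Synthetic cohort: patient table, per-patient cores, ground truth.

    Returns ``(patients, cores, truth)`` where ``patients`` has one row
    per patient with outcome, covariates (with MAR gaps) and the
    designated metric computed from the true TAM labels; ``truth`` records
    the cutpoint, beta, per-patient true marker and TAM labels.  Set
    ``compute_all_metrics`` to also attach the full seven-metric suite;
    ``keep_cores=False`` skips materializing CoreTables (``cores`` comes
    back empty), which large simulation studies use for speed.
    """
    rng = np.random.default_rng(seed)
    n = spec.n_patients
    cov = _draw_covariates(rng, n)

    cores: list[CoreTable] = []
    truth_labels: list[np.ndarray] = []
    metric_vals = np.empty(n)
    all_metrics: list[SpatialMetricSet] = []
    frac_lo, frac_hi = spec.tam_fraction_range
    core_seeds = np.random.SeedSequence(rng.integers(2**31)).spawn(n)
    for i in range(n):
        frac = frac_lo + (frac_hi - frac_lo) * rng.random()
        cspec = CoreGenSpec(
            n_cancer=spec.core.n_cancer,
            n_stromal=spec.core.n_stromal,
            tam_fraction=frac,
            proximity_mode=spec.core.proximity_mode,
            attraction_sd=spec.core.attraction_sd,
            n_parents=spec.core.n_parents,
            offspring_sd=spec.core.offspring_sd,
            bg_log_mean=spec.core.bg_log_mean,
            bg_log_sd=spec.core.bg_log_sd,
            tam_log_shift=spec.core.tam_log_shift,
            diameter=spec.core.diameter,
        )
        crng = np.random.default_rng(core_seeds[i])
        window, cancer_xy, tam_xy, neg_xy, cd163 = _sample_core(cspec, crng)
        # metric from the *true* labels (ground truth, not phenotyping)
        ms = metric_suite_from_arrays(cancer_xy, tam_xy, cspec.n_stromal, core_id=f"c{i:04d}")
        all_metrics.append(ms)
        metric_vals[i] = getattr(ms, spec.metric)
        if keep_cores:
            core, truth = _assemble_core(
                cspec, window, cancer_xy, tam_xy, neg_xy, cd163, f"c{i:04d}", f"p{i:04d}"
            )
            cores.append(core)
            truth_labels.append(truth)

    high = (metric_vals > spec.true_cutpoint).astype(float)
    lin = spec.beta * high
    eff = spec.covariate_effects
    lin += eff.get("grade3", 0.0) * (cov["grade"].to_numpy() == 3)
    lin += eff.get("node_positive", 0.0) * (cov["node"].to_numpy() == "positive")
    lin += eff.get("hr_negative", 0.0) * (cov["hr_status"].to_numpy() == "HR-")
    lin += eff.get("size_large", 0.0) * (cov["size_cat"].to_numpy() == ">5cm")
    u = rng.random(n)
    rate = spec.baseline_rate * np.exp(lin)
    if spec.weibull_shape == 1.0:
        t_event = -np.log(u) / rate
    else:  # Weibull with proportional hazards: S(t) = exp(-(rate) t^shape)
        t_event = (-np.log(u) / rate) ** (1.0 / spec.weibull_shape)
    t_cens = rng.uniform(spec.censor_low, spec.censor_high, n)
    time = np.minimum(t_event, t_cens)
    event = t_event <= t_cens
    ev_frac = event.mean()
    if not (0.05 < ev_frac < 0.95):
        import warnings

        warnings.warn(f"event fraction {ev_frac:.2f} outside (0.05, 0.95); adjust baseline/censoring")

    patients = cov.copy()
    patients.insert(0, "patient_id", [f"p{i:04d}" for i in range(n)])
    patients["pfs_months"] = time
    patients["progressed"] = event
    patients[spec.metric] = metric_vals
    if compute_all_metrics:
        for name in all_metrics[0].as_dict():
            if name != spec.metric:
                patients[name] = [getattr(ms, name) for ms in all_metrics]

    # MAR missingness: probability depends on observed age and node status
    z_age = (cov["age"].to_numpy() - 56.0) / 11.0
    z_node = (cov["node"].to_numpy() == "positive").astype(float)
    for var, rate_miss in spec.missingness.items():
        if rate_miss <= 0 or var not in patients.columns:
            continue
        eta = 0.4 * z_age + 0.5 * z_node
        base = np.log(rate_miss / (1 - rate_miss))
        pmiss = 1 / (1 + np.exp(-(base + eta - np.log(np.mean(np.exp(eta))))))
        mask = rng.random(n) < pmiss
        if var == "hormone_compliance":
            mask &= (cov["hr_status"] == "HR+").to_numpy()
        if mask.any():
            if patients[var].dtype != float:
                patients[var] = patients[var].astype(object)
            patients.loc[mask, var] = None if patients[var].dtype == object else np.nan

    def _comb(row):
        hr, hc = row["hr_status"], row["hormone_compliance"]
        if pd.isna(hr):
            return None
        if hr == "HR-":
            return "HR-"
        if pd.isna(hc):
            return None
        return "HR+ compliant" if hc == "compliant" else "HR+ non-compliant"

    patients["hr_hormone"] = patients.apply(_comb, axis=1)

    truth = {
        "metric": spec.metric,
        "true_cutpoint": spec.true_cutpoint,
        "beta": spec.beta,
        "true_high": high,
        "true_metric": metric_vals.copy(),
        "tam_labels": truth_labels,
        "event_fraction": float(ev_frac),
    }
    return patients, cores, truth


def write_cohort_csvs(patients: pd.DataFrame, cores: list[CoreTable], out_dir, truth: dict | None = None) -> dict:
    """Write cell + clinical CSVs (and optionally a ground-truth JSON).

    The cell and clinical tables never contain ground-truth columns; the
    truth file is a separate artifact for evaluation only.
    """
    from .core import write_core_table

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cell_path = out / "cells.csv"
    clin_path = out / "clinical.csv"
    write_core_table(cores, cell_path)
    clin_cols = [
        "patient_id", "pfs_months", "progressed", "age", "race", "grade", "node",
        "size_cat", "hr_status", "her2", "radiation", "hormone_compliance",
    ]
    clin = patients[[c for c in clin_cols if c in patients.columns]].copy()
    clin.to_csv(clin_path, index=False)
    paths = {"cells": str(cell_path), "clinical": str(clin_path)}
    if truth is not None:
        tr = {
            "metric": truth["metric"],
            "true_cutpoint": truth["true_cutpoint"],
            "beta": truth["beta"],
            "event_fraction": truth["event_fraction"],
        }
        (out / "truth.json").write_text(json.dumps(tr, indent=2) + "\n")
        paths["truth"] = str(out / "truth.json")
    return paths
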