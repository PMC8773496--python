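"""Marked-point-pattern spatial metrics of TAM–cancer-cell interaction.

Each phenotyped core is viewed as a multitype marked point pattern: cell
centroids in the circular core window carrying one of three marks —
``cancer``, ``tam`` (CD163+ stromal) or ``stromal-`` (CD163− stromal).
Seven per-core metrics summarise TAM density and proximity to cancer:

- ``tam_count``: CD163+ TAMs in the sampled core area (0.28 mm² for the
  default 600 μm core);
- ``tam_proportion``: fraction of stromal cells that are CD163+;
- ``nnd_p10``, ``nnd_p25``, ``nnd_p50``: percentiles of the distribution of
  nearest-neighbor distances from each cancer cell to the closest TAM;
- ``adj_mean``: mean number of TAMs within juxtacrine range (<12 μm) of a
  cancer cell;
- ``comm_mean``: mean number of TAMs within paracrine signalling range
  (<250 μm) of a cancer cell.

Cores with zero TAMs stay in the analysis: count metrics are 0 and the NND
percentiles are set to the truncation value (600 μm, the core diameter).
No edge correction is applied; distances are raw Euclidean μm.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .core import CoreTable, Window

__all__ = [
    "MarkedPointPattern",
    "SpatialMetricSet",
    "METRIC_NAMES",
    "build_mmpp",
    "nnd_set",
    "summarize_nnd",
    "mean_count_within",
    "compute_metric_suite",
    "metric_suite_from_arrays",
]

ADJACENT_RADIUS_UM = 12.0
COMMUNICATING_RADIUS_UM = 250.0
TRUNCATION_UM = 600.0

METRIC_NAMES = (
    "tam_count",
    "tam_proportion",
    "nnd_p10",
    "nnd_p25",
    "nnd_p50",
    "adj_mean",
    "comm_mean",
)


@dataclass(frozen=True)
class MarkedPointPattern:
    """Point locations with categorical marks inside a circular window."""

    points: np.ndarray  # (n, 2) μm
    marks: np.ndarray  # (n,) in {"cancer", "tam", "stromal-"}
    window: Window

    def __post_init__(self) -> None:
        if self.points.shape[0] != self.marks.shape[0]:
            raise ValueError("points and marks length mismatch")

    def of(self, mark: str) -> np.ndarray:
        return self.points[self.marks == mark]

    @property
    def mark_counts(self) -> dict[str, int]:
        return {m: int((self.marks == m).sum()) for m in ("cancer", "tam", "stromal-")}


@dataclass(frozen=True)
class SpatialMetricSet:
    tam_count: int
    tam_proportion: float
    nnd_p10: float
    nnd_p25: float
    nnd_p50: float
    adj_mean: float
    comm_mean: float

    def as_dict(self) -> dict[str, float]:
        return {k: getattr(self, k) for k in METRIC_NAMES}


def build_mmpp(core: CoreTable) -> MarkedPointPattern:
    """Map a phenotyped core to its three-type marked point pattern."""
    if not core.phenotyped:
        raise RuntimeError(f"core {core.core_id!r} has unlabeled stromal cells; run phenotyping first")
    tam = core.cells["tam"].fillna(False).to_numpy(dtype=bool)
    marks = np.where(core.is_cancer, "cancer", np.where(tam, "tam", "stromal-"))
    return MarkedPointPattern(points=core.coords(), marks=marks, window=core.window)


def nnd_set(pattern: MarkedPointPattern) -> np.ndarray:
    """Distance from each cancer cell to its nearest CD163+ TAM.

    Returns one value per cancer cell; ``inf`` is the "no neighbor"
    sentinel when the core has no TAMs.
    """
    cancer = pattern.of("cancer")
    if cancer.shape[0] == 0:
        raise ValueError("pattern has no cancer cells")
    tams = pattern.of("tam")
    if tams.shape[0] == 0:
        return np.full(cancer.shape[0], np.inf)
    dist, _ = cKDTree(tams).query(cancer, k=1)
    return np.asarray(dist, float)


def summarize_nnd(distances: np.ndarray, truncation: float = TRUNCATION_UM) -> tuple[float, float, float]:
    """10th/25th/50th percentiles of the NND distribution, truncated.

    Distances above ``truncation`` (including the no-TAM ``inf`` sentinel)
    are capped at ``truncation`` before percentiles are taken; percentiles
    use linear interpolation between order statistics.
    """
    d = np.asarray(distances, float)
    if d.size == 0:
        raise ValueError("empty distance set: core has no cancer cells")
    d = np.minimum(d, truncation)
    p10, p25, p50 = np.percentile(d, [10, 25, 50])
    return float(p10), float(p25), float(p50)


def mean_count_within(pattern: MarkedPointPattern, radius: float) -> float:
    """Mean over cancer cells of the number of TAMs strictly within ``radius``."""
    if not (radius > 0):
        raise ValueError(f"radius must be > 0, got {radius}")
    cancer = pattern.of("cancer")
    if cancer.shape[0] == 0:
        raise ValueError("pattern has no cancer cells")
    tams = pattern.of("tam")
    if tams.shape[0] == 0:
        return 0.0
    # sparse pairwise distances within the closed ball, then strict "<"
    pairs = cKDTree(cancer).sparse_distance_matrix(cKDTree(tams), max_distance=radius, output_type="coo_matrix")
    counts = np.zeros(cancer.shape[0])
    inside = pairs.data < radius
    np.add.at(counts, pairs.row[inside], 1.0)
    return float(counts.mean())


def metric_suite_from_arrays(
    cancer_xy: np.ndarray,
    tam_xy: np.ndarray,
    n_stromal: int,
    *,
    adjacent_um: float = ADJACENT_RADIUS_UM,
    communicating_um: float = COMMUNICATING_RADIUS_UM,
    truncation_um: float = TRUNCATION_UM,
    core_id: str = "?",
) -> SpatialMetricSet:
    """Seven-metric suite from raw coordinate arrays (shared kernel)."""
    cancer_xy = np.asarray(cancer_xy, float).reshape(-1, 2)
    tam_xy = np.asarray(tam_xy, float).reshape(-1, 2)
    if cancer_xy.shape[0] == 0:
        raise ValueError("no cancer cells")
    tam_count = int(tam_xy.shape[0])
    if n_stromal == 0:
        warnings.warn(f"core {core_id!r} has no stromal cells; tam_proportion set to 0")
        tam_proportion = 0.0
    else:
        tam_proportion = tam_count / n_stromal
    if tam_count == 0:
        nnd = np.full(cancer_xy.shape[0], np.inf)
        adj = comm = 0.0
    else:
        tree = cKDTree(tam_xy)
        nnd, _ = tree.query(cancer_xy, k=1)
        ctree = cKDTree(cancer_xy)
        adj = _mean_strict_count(ctree, tree, cancer_xy.shape[0], adjacent_um)
        comm = _mean_strict_count(ctree, tree, cancer_xy.shape[0], communicating_um)
    p10, p25, p50 = summarize_nnd(np.asarray(nnd, float), truncation=truncation_um)
    return SpatialMetricSet(
        tam_count=tam_count,
        tam_proportion=float(tam_proportion),
        nnd_p10=p10,
        nnd_p25=p25,
        nnd_p50=p50,
        adj_mean=float(adj),
        comm_mean=float(comm),
    )


def _mean_strict_count(cancer_tree: cKDTree, tam_tree: cKDTree, n_cancer: int, radius: float) -> float:
    pairs = cancer_tree.sparse_distance_matrix(tam_tree, max_distance=radius, output_type="coo_matrix")
    counts = np.zeros(n_cancer)
    inside = pairs.data < radius
    np.add.at(counts, pairs.row[inside], 1.0)
    return float(counts.mean())


def compute_metric_suite(
    core: CoreTable,
    *,
    adjacent_um: float = ADJACENT_RADIUS_UM,
    communicating_um: float = COMMUNICATING_RADIUS_UM,
    truncation_um: float = TRUNCATION_UM,
) -> SpatialMetricSet:
    """All seven CD163+ TAM metrics for one phenotyped core."""
    pattern = build_mmpp(core)
    return metric_suite_from_arrays(
        pattern.of("cancer"),
        pattern.of("tam"),
        core.n_stromal,
        adjacent_um=adjacent_um,
        communicating_um=communicating_um,
        truncation_um=truncation_um,
        core_id=core.core_id,
    )
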