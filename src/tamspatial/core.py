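"""Data model, file I/O and cohort-level inclusion filters.

The unit of spatial analysis is a tissue-microarray (TMA) core: a circular
disc of tumor tissue (600 μm diameter by default) whose segmented cells are
given as centroid coordinates in μm, a compartment label (``cancer`` vs
``stromal``) and a CD163 mean immunofluorescence intensity in arbitrary
units.  The unit of outcome analysis is the patient, carrying
progression-free survival (PFS) and clinicopathologic covariates.

The fixed order of cohort preparation is::

    read -> qc_filter -> phenotype -> dedup_cores -> metrics

because the duplicate-core rule keeps the core with the larger CD163+ TAM
count, which requires phenotyping to have run first.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CellTableFormatError",
    "Window",
    "CoreTable",
    "PatientRecord",
    "Cohort",
    "Exclusion",
    "CELL_COLUMNS",
    "read_core_table",
    "write_core_table",
    "read_clinical_table",
    "qc_filter",
    "dedup_cores",
]

#: canonical column names of a cell table after mapping
CELL_COLUMNS = ("core_id", "patient_id", "x_um", "y_um", "compartment", "cd163_intensity")

COMPARTMENTS = frozenset({"cancer", "stromal"})

#: default TMA core diameter, μm
DEFAULT_CORE_DIAMETER_UM = 600.0


class CellTableFormatError(ValueError):
    """Raised when a delimited cell/clinical table violates the expected layout."""


@dataclass(frozen=True)
class Window:
    """Circular observation window (the physical TMA core)."""

    center_x: float
    center_y: float
    diameter: float = DEFAULT_CORE_DIAMETER_UM

    def __post_init__(self) -> None:
        if not (self.diameter > 0):
            raise ValueError(f"window diameter must be > 0, got {self.diameter}")

    @property
    def radius(self) -> float:
        return self.diameter / 2.0

    @property
    def area_mm2(self) -> float:
        """Sampled area of the core in mm² (π r², coordinates in μm)."""
        r_mm = self.radius / 1000.0
        return math.pi * r_mm * r_mm

    def contains(self, x: np.ndarray, y: np.ndarray, atol: float = 1e-9) -> np.ndarray:
        d2 = (np.asarray(x, float) - self.center_x) ** 2 + (np.asarray(y, float) - self.center_y) ** 2
        return d2 <= (self.radius + atol) ** 2


@dataclass
class CoreTable:
    """All segmented cells of one tissue core.

    ``cells`` holds one row per cell with columns ``cell_id``, ``x``, ``y``
    (μm), ``compartment`` ({'cancer','stromal'}) and ``cd163`` (arbitrary
    units, ≥ 0).  ``tam`` is a nullable boolean column filled in by
    phenotyping: True for stromal cells called CD163+ TAM, False for
    stromal CD163− cells, and NA before phenotyping (always False/NA for
    cancer cells, which are never TAMs).
    """

    core_id: str
    patient_id: str
    cells: pd.DataFrame
    window: Window

    def __post_init__(self) -> None:
        required = {"cell_id", "x", "y", "compartment", "cd163"}
        missing = required - set(self.cells.columns)
        if missing:
            raise ValueError(f"cells frame missing columns: {sorted(missing)}")
        if "tam" not in self.cells.columns:
            self.cells["tam"] = pd.array([pd.NA] * len(self.cells), dtype="boolean")
        bad = set(self.cells["compartment"].unique()) - COMPARTMENTS
        if bad:
            raise ValueError(f"unknown compartment labels: {sorted(bad)}")
        xy = self.cells[["x", "y"]].to_numpy(float)
        if not np.isfinite(xy).all():
            raise ValueError("non-finite cell coordinates")
        if (self.cells["cd163"].to_numpy(float) < 0).any():
            raise ValueError("negative CD163 intensities")

    # -- convenience views -------------------------------------------------
    @property
    def n_cells(self) -> int:
        return len(self.cells)

    @property
    def is_cancer(self) -> np.ndarray:
        return (self.cells["compartment"] == "cancer").to_numpy()

    @property
    def is_stromal(self) -> np.ndarray:
        return (self.cells["compartment"] == "stromal").to_numpy()

    @property
    def n_cancer(self) -> int:
        return int(self.is_cancer.sum())

    @property
    def n_stromal(self) -> int:
        return int(self.is_stromal.sum())

    @property
    def phenotyped(self) -> bool:
        return not self.cells.loc[self.is_stromal, "tam"].isna().any()

    @property
    def n_tam(self) -> int:
        if not self.phenotyped:
            raise RuntimeError(f"core {self.core_id!r}: stromal cells not yet phenotyped")
        return int((self.cells["tam"] == True).sum())  # noqa: E712  (nullable boolean)

    def coords(self, mask: np.ndarray | None = None) -> np.ndarray:
        xy = self.cells[["x", "y"]].to_numpy(float)
        return xy if mask is None else xy[mask]


def _infer_window(x: np.ndarray, y: np.ndarray, diameter: float) -> Window:
    """Circle centered at the centroid bounding-box center; grown if needed."""
    cx = (x.min() + x.max()) / 2.0
    cy = (y.min() + y.max()) / 2.0
    need = 2.0 * float(np.hypot(x - cx, y - cy).max())
    return Window(cx, cy, max(diameter, need * (1 + 1e-12)))


def read_core_table(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    *,
    sep: str | None = None,
    diameter: float = DEFAULT_CORE_DIAMETER_UM,
) -> list[CoreTable]:
    """Read a delimited cell table into one :class:`CoreTable` per core id.

    Parameters
    ----------
    path
        CSV/TSV file with a header row.
    column_map
        Maps canonical names (``core_id``, ``patient_id``, ``x_um``,
        ``y_um``, ``compartment``, ``cd163_intensity``) to the file's
        column names.  Identity by default.
    sep
        Field separator; inferred from the extension when None.
    diameter
        Core diameter in μm used for the inferred circular window.
    """
    path = Path(path)
    if sep is None:
        sep = "\t" if path.suffix.lower() in {".tsv", ".txt"} else ","
    df = pd.read_csv(path, sep=sep, dtype=str)
    cmap = dict(column_map or {})
    for canon in CELL_COLUMNS:
        src = cmap.get(canon, canon)
        if src not in df.columns:
            raise CellTableFormatError(f"cell table {path.name!r} lacks required column {src!r} (for {canon!r})")
        if src != canon:
            df = df.rename(columns={src: canon})
    for col in ("x_um", "y_um", "cd163_intensity"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() & df[col].notna()
        if bad.any() or df[col].isna().any():
            row = int(np.flatnonzero(vals.isna())[0])
            raise CellTableFormatError(f"non-numeric value in column {col!r} at data row {row}")
        df[col] = vals
    df["compartment"] = df["compartment"].str.strip().str.lower()
    bad = ~df["compartment"].isin(sorted(COMPARTMENTS))
    if bad.any():
        raise CellTableFormatError(
            f"unknown compartment label {df.loc[bad, 'compartment'].iloc[0]!r} at data row {int(np.flatnonzero(bad)[0])}"
        )

    cores: list[CoreTable] = []
    for core_id, grp in df.groupby("core_id", sort=True):
        pids = grp["patient_id"].unique()
        if len(pids) > 1:
            raise CellTableFormatError(f"core {core_id!r} maps to multiple patients: {sorted(pids)}")
        cells = pd.DataFrame(
            {
                "cell_id": np.arange(len(grp)).astype(str),
                "x": grp["x_um"].to_numpy(float),
                "y": grp["y_um"].to_numpy(float),
                "compartment": grp["compartment"].to_numpy(),
                "cd163": grp["cd163_intensity"].to_numpy(float),
            }
        )
        win = _infer_window(cells["x"].to_numpy(), cells["y"].to_numpy(), diameter)
        cores.append(CoreTable(str(core_id), str(pids[0]), cells, win))
    return cores


def write_core_table(cores: Iterable[CoreTable], path: str | Path) -> None:
    """Write cores back to the canonical CSV layout (round-trip safe)."""
    rows = []
    for core in cores:
        for _, c in core.cells.iterrows():
            rows.append(
                {
                    "core_id": core.core_id,
                    "patient_id": core.patient_id,
                    "x_um": repr(float(c["x"])),
                    "y_um": repr(float(c["y"])),
                    "compartment": c["compartment"],
                    "cd163_intensity": repr(float(c["cd163"])),
                }
            )
    pd.DataFrame(rows, columns=list(CELL_COLUMNS)).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# clinical table
# ---------------------------------------------------------------------------

RACE_LEVELS = ("white", "non-white")
GRADE_LEVELS = (1, 2, 3)
NODE_LEVELS = ("negative", "positive")
SIZE_LEVELS = ("<2cm", "2-5cm", ">5cm")
HR_LEVELS = ("HR+", "HR-")
HER2_LEVELS = ("negative", "positive")
COMPLIANCE_LEVELS = ("compliant", "non-compliant", "not-applicable")

#: combined hormone-receptor / hormone-therapy-compliance factor; HR− tumors
#: form their own level since compliance is undefined for them.
HR_HORMONE_LEVELS = ("HR+ compliant", "HR+ non-compliant", "HR-")


@dataclass
class PatientRecord:
    """One patient's outcome and clinicopathologic covariates.

    Any covariate (but not the outcome pair) may be missing (None).
    """

    patient_id: str
    pfs_months: float
    progressed: bool
    age: float | None = None
    race: str | None = None
    grade: int | None = None
    node: str | None = None
    size_cat: str | None = None
    hr_status: str | None = None
    her2: str | None = None
    radiation: bool | None = None
    hormone_compliance: str | None = None

    def __post_init__(self) -> None:
        if not (self.pfs_months >= 0):
            raise ValueError(f"patient {self.patient_id!r}: pfs_months must be >= 0")
        for name, val, levels in (
            ("race", self.race, RACE_LEVELS),
            ("node", self.node, NODE_LEVELS),
            ("size_cat", self.size_cat, SIZE_LEVELS),
            ("hr_status", self.hr_status, HR_LEVELS),
            ("her2", self.her2, HER2_LEVELS),
            ("hormone_compliance", self.hormone_compliance, COMPLIANCE_LEVELS),
        ):
            if val is not None and val not in levels:
                raise ValueError(f"patient {self.patient_id!r}: bad {name} {val!r}")
        if self.grade is not None and self.grade not in GRADE_LEVELS:
            raise ValueError(f"patient {self.patient_id!r}: bad grade {self.grade!r}")

    @property
    def hr_hormone(self) -> str | None:
        """3-level combined hormone factor (reference 'HR+ compliant')."""
        if self.hr_status is None:
            return None
        if self.hr_status == "HR-":
            return "HR-"
        if self.hormone_compliance is None:
            return None
        return "HR+ compliant" if self.hormone_compliance == "compliant" else "HR+ non-compliant"


def read_clinical_table(path: str | Path) -> list[PatientRecord]:
    """Read a per-patient clinical CSV; empty strings are missing values."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    required = {"patient_id", "pfs_months", "progressed"}
    missing = required - set(df.columns)
    if missing:
        raise CellTableFormatError(f"clinical table lacks columns: {sorted(missing)}")

    def opt(row, col, conv=str):
        v = row.get(col, "")
        if v is None or str(v).strip() == "":
            return None
        return conv(str(v).strip())

    out = []
    for _, row in df.iterrows():
        out.append(
            PatientRecord(
                patient_id=str(row["patient_id"]),
                pfs_months=float(row["pfs_months"]),
                progressed=str(row["progressed"]).strip().lower() in {"1", "true", "yes"},
                age=opt(row, "age", float),
                race=opt(row, "race"),
                grade=opt(row, "grade", lambda s: int(float(s))),
                node=opt(row, "node"),
                size_cat=opt(row, "size_cat"),
                hr_status=opt(row, "hr_status"),
                her2=opt(row, "her2"),
                radiation=opt(row, "radiation", lambda s: s.lower() in {"1", "true", "yes"}),
                hormone_compliance=opt(row, "hormone_compliance"),
            )
        )
    return out


def patients_to_frame(patients: Sequence[PatientRecord]) -> pd.DataFrame:
    """Tidy patient-level DataFrame (one row per patient, NaN for missing)."""
    rows = []
    for p in patients:
        rows.append(
            {
                "patient_id": p.patient_id,
                "pfs_months": p.pfs_months,
                "progressed": bool(p.progressed),
                "age": p.age,
                "race": p.race,
                "grade": p.grade,
                "node": p.node,
                "size_cat": p.size_cat,
                "hr_status": p.hr_status,
                "her2": p.her2,
                "radiation": p.radiation,
                "hormone_compliance": p.hormone_compliance,
                "hr_hormone": p.hr_hormone,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# cohort filters
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Exclusion:
    core_id: str
    patient_id: str
    reason: str
    detail: str = ""


def qc_filter(
    cores: Sequence[CoreTable], min_cancer: int = 10
) -> tuple[list[CoreTable], list[Exclusion]]:
    """Drop cores with fewer than ``min_cancer`` cancer cells (inclusive keep).

    Returns ``(kept, excluded)``; the two lists partition the input.
    """
    kept: list[CoreTable] = []
    excluded: list[Exclusion] = []
    for core in cores:
        if core.n_cancer < min_cancer:
            excluded.append(
                Exclusion(core.core_id, core.patient_id, "min_cancer", f"{core.n_cancer} < {min_cancer}")
            )
        else:
            kept.append(core)
    return kept, excluded


def dedup_cores(
    cores: Sequence[CoreTable], tam_counts: Mapping[str, int]
) -> tuple[dict[str, CoreTable], list[Exclusion]]:
    """One core per patient: keep the core with more CD163+ TAMs.

    Ties are broken by lexicographically smallest ``core_id`` so the result
    is deterministic.  Requires phenotyping to have run (``tam_counts`` maps
    core_id -> CD163+ TAM count).
    """
    dropped: list[Exclusion] = []
    by_patient: dict[str, list[CoreTable]] = {}
    for core in cores:
        if core.core_id not in tam_counts:
            raise KeyError(f"no TAM count for core {core.core_id!r}; run phenotyping first")
        by_patient.setdefault(core.patient_id, []).append(core)
    chosen: dict[str, CoreTable] = {}
    for pid, plist in by_patient.items():
        best = min(plist, key=lambda c: (-tam_counts[c.core_id], c.core_id))
        chosen[pid] = best
        for c in plist:
            if c is not best:
                dropped.append(Exclusion(c.core_id, pid, "duplicate_core", f"kept {best.core_id}"))
    return chosen, dropped


@dataclass
class Cohort:
    """Patients plus their (deduplicated) cores keyed by patient id."""

    patients: list[PatientRecord]
    cores: dict[str, CoreTable] = field(default_factory=dict)

    def __post_init__(self) -> None:
        pids = {p.patient_id for p in self.patients}
        orphans = set(self.cores) - pids
        if orphans:
            raise ValueError(f"cores without a clinical record: {sorted(orphans)[:5]}")

    @property
    def n_patients(self) -> int:
        return len(self.patients)


def write_manifest(path: str | Path, manifest: dict) -> None:
    Path(path).write_text(json.dumps(manifest, indent=2, default=str) + "\n")
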