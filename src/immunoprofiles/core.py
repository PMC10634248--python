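"""Domain types, the canonical 59-marker registry, and cohort file I/O.

The activation-marker panel covers four compartments of chronic immune
activation in treated HIV infection: CD4+ ("T4") and CD8+ ("T8") T-cell
activation / exhaustion / senescence / differentiation phenotypes, NK-cell
activation and dysfunction, monocyte activation (sCD163), systemic
inflammation (sTNFRI) and endothelial activation (tPA, sEPCR).  T-cell and
NK phenotypes are quantified both as percentages of the parent subset and
as absolute counts; soluble markers as plasma concentrations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd

Lineage = Literal[
    "CD4_T", "CD8_T", "NK", "monocyte", "inflammation", "endothelium", "global"
]
Measure = Literal["percent", "count", "concentration"]

#: Annotation column names reserved in cohort files; everything else is a marker.
RESERVED_COLUMNS = ("patient_id", "nci_class", "fazekas_pv", "fazekas_deep")

NCI_CLASSES = ("none", "ANI", "MND", "unknown")


@dataclass(frozen=True)
class MarkerDescriptor:
    """Identity, lineage, phenotype and measurement scale of one marker."""

    id: str
    lineage: Lineage
    phenotype: str
    measure: Measure
    units: str

    def __post_init__(self) -> None:
        if self.measure == "percent" and self.units != "%":
            raise ValueError(f"percent marker {self.id!r} must have units '%'")
        if self.measure == "count" and self.units != "cells/µL":
            raise ValueError(f"count marker {self.id!r} must have units 'cells/µL'")

    def lower_bound(self) -> float:
        return 0.0

    def upper_bound(self) -> float:
        return 100.0 if self.measure == "percent" else np.inf


# (id fragment, phenotype label) for the T-cell phenotypes carried by both
# lineages; each exists as a percentage of the lineage and an absolute count.
_T_PHENOTYPES = [
    ("HLADR", "HLA-DR+"),
    ("CD38", "CD38+"),
    ("HLADR_CD38pos", "HLA-DR+CD38+"),
    ("HLADR_CD38neg", "HLA-DR+CD38-"),
    ("PD1", "PD-1+"),
    ("CD57", "CD57+"),
    ("CD57_CD28neg", "CD57+CD28-"),
    ("CD57_CD28neg_CD27neg", "CD57+CD28-CD27-"),
    ("naive", "CD45RA+CD27+ naive"),
    ("cm", "CD45RA-CD27+ central memory"),
    ("em", "CD45RA-CD27- effector memory"),
]

_NK_PHENOTYPES = [
    ("HLADR", "HLA-DR+"),
    ("CD56neg", "CD56-"),
    ("CD57", "CD57+"),
]


@dataclass(frozen=True)
class MarkerRegistry:
    """The canonical ordered panel of 59 activation markers."""

    entries: tuple[MarkerDescriptor, ...]

    def __post_init__(self) -> None:
        ids = [m.id for m in self.entries]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate marker id in registry")

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    def ids(self) -> list[str]:
        return [m.id for m in self.entries]

    def get(self, marker_id: str) -> MarkerDescriptor:
        for m in self.entries:
            if m.id == marker_id:
                return m
        raise KeyError(marker_id)

    def __contains__(self, marker_id: str) -> bool:
        return any(m.id == marker_id for m in self.entries)

    def to_tsv(self, path: str | Path) -> None:
        """Export (id, units) as a two-column TSV for documentation."""
        pd.DataFrame(
            {"id": self.ids(), "units": [m.units for m in self.entries]}
        ).to_csv(path, sep="\t", index=False)


def build_registry() -> MarkerRegistry:
    """Build the canonical 59-marker registry.

    Composition: per T lineage, the lineage itself (% of lymphocytes and
    absolute count) plus 11 phenotypes each as percent and count (24 x 2 =
    48); three NK phenotypes as percent and count (6); four soluble markers
    (4); total lymphocyte count (1).  Ordering is fixed and stable.
    """
    entries: list[MarkerDescriptor] = []
    for prefix, lineage, label in (("T4", "CD4_T", "CD4+ T"), ("T8", "CD8_T", "CD8+ T")):
        entries.append(
            MarkerDescriptor(f"{prefix}_pct", lineage, f"{label} (total)", "percent", "%")
        )
        entries.append(
            MarkerDescriptor(
                f"{prefix}_cnt", lineage, f"{label} (total)", "count", "cells/µL"
            )
        )
        for frag, pheno in _T_PHENOTYPES:
            entries.append(
                MarkerDescriptor(
                    f"{prefix}_{frag}_pct", lineage, f"{pheno} {label}", "percent", "%"
                )
            )
            entries.append(
                MarkerDescriptor(
                    f"{prefix}_{frag}_cnt",
                    lineage,
                    f"{pheno} {label}",
                    "count",
                    "cells/µL",
                )
            )
    for frag, pheno in _NK_PHENOTYPES:
        entries.append(
            MarkerDescriptor(f"NK_{frag}_pct", "NK", f"{pheno} NK", "percent", "%")
        )
        entries.append(
            MarkerDescriptor(f"NK_{frag}_cnt", "NK", f"{pheno} NK", "count", "cells/µL")
        )
    entries.append(
        MarkerDescriptor("sCD163", "monocyte", "sCD163", "concentration", "pg/mL")
    )
    entries.append(
        MarkerDescriptor("sTNFRI", "inflammation", "sTNFRI", "concentration", "pg/mL")
    )
    entries.append(
        MarkerDescriptor("tPA", "endothelium", "tPA", "concentration", "ng/mL")
    )
    entries.append(
        MarkerDescriptor("sEPCR", "endothelium", "sEPCR", "concentration", "ng/mL")
    )
    entries.append(
        MarkerDescriptor("lymph_cnt", "global", "lymphocytes", "count", "cells/µL")
    )
    return MarkerRegistry(tuple(entries))


@dataclass
class CohortTable:
    """Participants x markers numeric matrix with an explicit missingness mask."""

    patient_ids: list[str]
    markers: list[MarkerDescriptor]
    values: np.ndarray  # float, shape (n_patients, n_markers)
    missing_mask: np.ndarray  # bool, same shape; True = missing

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
        n, p = len(self.patient_ids), len(self.markers)
        if self.values.shape != (n, p):
            raise ValueError(
                f"values shape {self.values.shape} != ({n} patients, {p} markers)"
            )
        if self.missing_mask.shape != (n, p):
            raise ValueError("missing_mask shape mismatch")
        if len(set(self.patient_ids)) != n:
            raise ValueError("duplicate patient id")
        ids = [m.id for m in self.markers]
        if len(set(ids)) != p:
            raise ValueError("duplicate marker id")

    @property
    def n_patients(self) -> int:
        return len(self.patient_ids)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    def marker_ids(self) -> list[str]:
        return [m.id for m in self.markers]

    def marker_index(self, marker_id: str) -> int:
        try:
            return self.marker_ids().index(marker_id)
        except ValueError:
            raise KeyError(marker_id) from None

    def column(self, marker_id: str, observed_only: bool = False) -> np.ndarray:
        """Values for one marker; missing cells as NaN (or dropped)."""
        j = self.marker_index(marker_id)
        col = self.values[:, j].copy()
        col[self.missing_mask[:, j]] = np.nan
        if observed_only:
            col = col[~self.missing_mask[:, j]]
        return col

    def select_markers(self, marker_ids: Sequence[str]) -> "CohortTable":
        idx = [self.marker_index(m) for m in marker_ids]
        return CohortTable(
            list(self.patient_ids),
            [self.markers[j] for j in idx],
            self.values[:, idx].copy(),
            self.missing_mask[:, idx].copy(),
        )

    def to_dataframe(self) -> pd.DataFrame:
        """Marker matrix as a DataFrame (missing cells NaN), indexed by patient."""
        vals = self.values.copy()
        vals[self.missing_mask] = np.nan
        return pd.DataFrame(vals, index=self.patient_ids, columns=self.marker_ids())

    def copy(self) -> "CohortTable":
        return CohortTable(
            list(self.patient_ids),
            list(self.markers),
            self.values.copy(),
            self.missing_mask.copy(),
        )


@dataclass
class ClinicalAnnotations:
    """Per-patient clinical annotation: NCI class and Fazekas WMH scores.

    ``nci_class`` holds one of ``none`` / ``ANI`` / ``MND`` / ``unknown``
    (Frascati classification; ANI = asymptomatic neurocognitive impairment,
    MND = mild neurocognitive disorder).  Fazekas periventricular and deep
    scores are 0-3 integers, NaN when no MRI rating is available.
    """

    patient_ids: list[str]
    nci_class: np.ndarray  # object array of NCI_CLASSES strings
    fazekas_pv: np.ndarray  # float array, values in {0,1,2,3} or NaN
    fazekas_deep: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.patient_ids)
        self.nci_class = np.asarray(self.nci_class, dtype=object)
        self.fazekas_pv = np.asarray(self.fazekas_pv, dtype=float)
        self.fazekas_deep = np.asarray(self.fazekas_deep, dtype=float)
        for name, arr in (
            ("nci_class", self.nci_class),
            ("fazekas_pv", self.fazekas_pv),
            ("fazekas_deep", self.fazekas_deep),
        ):
            if arr.shape != (n,):
                raise ValueError(f"{name} length != number of patients")
        bad = set(self.nci_class) - set(NCI_CLASSES)
        if bad:
            raise ValueError(f"invalid nci_class values: {sorted(bad)}")
        for name, arr in (("fazekas_pv", self.fazekas_pv), ("fazekas_deep", self.fazekas_deep)):
            vals = arr[~np.isnan(arr)]
            if not np.all(np.isin(vals, [0.0, 1.0, 2.0, 3.0])):
                raise ValueError(f"{name} values must be in {{0,1,2,3}} or missing")

    @property
    def n(self) -> int:
        return len(self.patient_ids)

    @property
    def nci_flag(self) -> np.ndarray:
        """Boolean: True iff the patient has ANI or MND."""
        return np.isin(self.nci_class, ("ANI", "MND"))

    @property
    def nci_known(self) -> np.ndarray:
        return self.nci_class != "unknown"

    def subset(self, index: np.ndarray | list[int]) -> "ClinicalAnnotations":
        index = np.asarray(index)
        return ClinicalAnnotations(
            [self.patient_ids[i] for i in index],
            self.nci_class[index],
            self.fazekas_pv[index],
            self.fazekas_deep[index],
        )


def _infer_descriptor(column: str) -> MarkerDescriptor:
    """Descriptor for a marker column not in the canonical registry."""
    if column.endswith("_pct"):
        return MarkerDescriptor(column, "global", column, "percent", "%")
    if column.endswith("_cnt"):
        return MarkerDescriptor(column, "global", column, "count", "cells/µL")
    return MarkerDescriptor(column, "global", column, "concentration", "pg/mL")


def load_cohort(
    path: str | Path, format: Literal["csv", "tsv"] | None = None
) -> tuple[CohortTable, ClinicalAnnotations]:
    """Load a cohort table plus clinical annotations from CSV/TSV.

    The header names the columns; ``patient_id``, ``nci_class``,
    ``fazekas_pv`` and ``fazekas_deep`` are reserved annotation columns,
    every other column is a marker.  Empty cells and ``NA`` denote missing.
    Marker columns not in the canonical registry are retained with a
    warning.  Duplicate patient ids and non-numeric marker cells are hard
    errors.
    """
    path = Path(path)
    if format is None:
        format = "tsv" if path.suffix.lower() in (".tsv", ".tab", ".txt") else "csv"
    sep = "\t" if format == "tsv" else ","
    df = pd.read_csv(
        path, sep=sep, dtype=str, keep_default_na=False, comment="#"
    )
    if "patient_id" not in df.columns:
        raise ValueError(f"{path}: missing required 'patient_id' column")
    patient_ids = df["patient_id"].tolist()
    if len(set(patient_ids)) != len(patient_ids):
        dupes = sorted({p for p in patient_ids if patient_ids.count(p) > 1})
        raise ValueError(f"{path}: duplicate patient id(s): {dupes}")

    registry = build_registry()
    marker_cols = [c for c in df.columns if c not in RESERVED_COLUMNS]
    unknown = [c for c in marker_cols if c not in registry]
    if unknown:
        warnings.warn(
            f"{path.name}: {len(unknown)} marker column(s) not in the canonical "
            f"registry retained: {unknown}",
            stacklevel=2,
        )
    markers = [
        registry.get(c) if c in registry else _infer_descriptor(c) for c in marker_cols
    ]

    n, p = len(patient_ids), len(marker_cols)
    values = np.zeros((n, p))
    mask = np.zeros((n, p), dtype=bool)
    for j, col in enumerate(marker_cols):
        raw = df[col].str.strip()
        missing = (raw == "") | (raw.str.upper() == "NA")
        mask[:, j] = missing.to_numpy()
        parsed = pd.to_numeric(raw.where(~missing), errors="coerce")
        bad = parsed.isna() & ~missing
        if bad.any():
            i = int(np.flatnonzero(bad)[0])
            raise ValueError(
                f"{path}: non-numeric value {raw.iloc[i]!r} for marker "
                f"{col!r}, patient {patient_ids[i]!r}"
            )
        values[:, j] = parsed.fillna(0.0).to_numpy()

    def _ann_str(col: str, default: str) -> np.ndarray:
        if col not in df.columns:
            return np.full(n, default, dtype=object)
        raw = df[col].str.strip()
        return raw.where((raw != "") & (raw.str.upper() != "NA"), default).to_numpy(
            dtype=object
        )

    def _ann_float(col: str) -> np.ndarray:
        if col not in df.columns:
            return np.full(n, np.nan)
        raw = df[col].str.strip()
        missing = (raw == "") | (raw.str.upper() == "NA")
        return pd.to_numeric(raw.where(~missing), errors="raise").to_numpy(dtype=float)

    ann = ClinicalAnnotations(
        patient_ids,
        _ann_str("nci_class", "unknown"),
        _ann_float("fazekas_pv"),
        _ann_float("fazekas_deep"),
    )
    return CohortTable(patient_ids, markers, values, mask), ann


def write_cohort(
    table: CohortTable,
    ann: ClinicalAnnotations,
    path: str | Path,
    format: Literal["csv", "tsv"] | None = None,
    header_comment: str | None = None,
) -> None:
    """Write a cohort as CSV/TSV: patient_id, annotations, then markers.

    Missing cells are written empty; values carry 6 significant digits.
    """
    path = Path(path)
    if format is None:
        format = "tsv" if path.suffix.lower() in (".tsv", ".tab", ".txt") else "csv"
    sep = "\t" if format == "tsv" else ","
    if ann.patient_ids != table.patient_ids:
        raise ValueError("annotation patient ids do not match the table")

    def fmt_val(v: float) -> str:
        return f"{v:.6g}"

    def fmt_faz(v: float) -> str:
        return "" if np.isnan(v) else str(int(v))

    cols: dict[str, list[str]] = {"patient_id": list(table.patient_ids)}
    cols["nci_class"] = [str(c) for c in ann.nci_class]
    cols["fazekas_pv"] = [fmt_faz(v) for v in ann.fazekas_pv]
    cols["fazekas_deep"] = [fmt_faz(v) for v in ann.fazekas_deep]
    for j, m in enumerate(table.markers):
        cols[m.id] = [
            "" if table.missing_mask[i, j] else fmt_val(table.values[i, j])
            for i in range(table.n_patients)
        ]
    out = pd.DataFrame(cols)
    with open(path, "w", newline="") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        out.to_csv(fh, sep=sep, index=False)
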