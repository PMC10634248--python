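"""Marker-level quality control.

Three ordered stages, mirroring the screening pipeline's QC conventions:

1. discard markers with more than 10% missing values;
2. impute each remaining missing cell with the mean of the marker's values
   in the two nearest-neighbour patients (z-scored, overlap-normalised
   Euclidean distance over the markers observed in both patients);
3. when two markers correlate above 95%, keep only the one that best
   separates neurocognitively impaired from unimpaired patients by a
   pooled-variance Student t statistic (applied per connected component of
   the high-correlation graph, which makes the result order-invariant).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from immunoprofiles.core import ClinicalAnnotations, CohortTable

__all__ = [
    "PreprocessReport",
    "drop_high_missing",
    "impute_knn2",
    "dedup_correlated",
    "run_preprocess",
]


@dataclass
class PreprocessReport:
    """Audit trail of one preprocessing stage."""

    #: (marker id, missing fraction) of discarded markers
    dropped_markers: list[tuple[str, float]] = field(default_factory=list)
    #: (patient id, marker id, imputed value, (neighbour ids))
    imputed_cells: list[tuple[str, str, float, tuple[str, str]]] = field(
        default_factory=list
    )
    #: (kept id, removed id, |r|, t_kept, t_removed)
    dedup_decisions: list[tuple[str, str, float, float, float]] = field(
        default_factory=list
    )

    def merge(self, other: "PreprocessReport") -> "PreprocessReport":
        return PreprocessReport(
            self.dropped_markers + other.dropped_markers,
            self.imputed_cells + other.imputed_cells,
            self.dedup_decisions + other.dedup_decisions,
        )

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("stage\tfield1\tfield2\tfield3\tfield4\tfield5\n")
            for mid, frac in self.dropped_markers:
                fh.write(f"dropped\t{mid}\t{frac:.4f}\t\t\t\n")
            for pid, mid, val, (n1, n2) in self.imputed_cells:
                fh.write(f"imputed\t{pid}\t{mid}\t{val:.6g}\t{n1}\t{n2}\n")
            for kept, removed, r, tk, tr in self.dedup_decisions:
                fh.write(f"dedup\t{kept}\t{removed}\t{r:.4f}\t{tk:.4f}\t{tr:.4f}\n")


def drop_high_missing(
    table: CohortTable, threshold: float = 0.10
) -> tuple[CohortTable, PreprocessReport]:
    """Discard markers missing in strictly more than ``threshold`` of patients."""
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must lie in (0,1)")
    frac = table.missing_mask.mean(axis=0)
    keep = frac <= threshold
    if not keep.any():
        raise ValueError("all markers exceed the missingness threshold")
    report = PreprocessReport(
        dropped_markers=[
            (m.id, float(frac[j])) for j, m in enumerate(table.markers) if not keep[j]
        ]
    )
    out = CohortTable(
        list(table.patient_ids),
        [m for j, m in enumerate(table.markers) if keep[j]],
        table.values[:, keep].copy(),
        table.missing_mask[:, keep].copy(),
    )
    return out, report


def _zscore_observed(values: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Z-score each column by its observed mean/SD; missing cells NaN."""
    vals = values.copy()
    vals[mask] = np.nan
    mu = np.nanmean(vals, axis=0)
    sd = np.nanstd(vals, axis=0, ddof=1)
    sd = np.where((sd == 0) | np.isnan(sd), 1.0, sd)
    return (vals - mu) / sd


def impute_knn2(table: CohortTable) -> tuple[CohortTable, PreprocessReport]:
    """Fill each missing cell with the mean of its 2 nearest neighbours' values.

    Neighbour distance between patients is the Euclidean distance of the
    z-scored values over the markers observed in both, divided by the
    square root of the number of shared markers (so overlaps of different
    sizes are comparable).  A neighbour must itself have the target marker
    observed.
    """
    mask = table.missing_mask
    if not mask.any():
        return table.copy(), PreprocessReport()
    observed_per_marker = (~mask).sum(axis=0)
    thin = observed_per_marker < 2
    if thin.any():
        bad = [table.markers[j].id for j in np.flatnonzero(thin)]
        raise ValueError(f"markers with fewer than 2 observed values: {bad}")

    z = _zscore_observed(table.values, mask)
    obs = ~mask
    n = table.n_patients

    # pairwise overlap-normalised distances; NaN where no shared marker
    dist = np.full((n, n), np.nan)
    for i in range(n):
        shared = obs[i] & obs  # (n, p)
        diff = np.where(shared, z[i] - z, 0.0)
        cnt = shared.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            d = np.sqrt((diff**2).sum(axis=1)) / np.sqrt(cnt)
        d[cnt == 0] = np.nan
        dist[i] = d
    np.fill_diagonal(dist, np.nan)

    values = table.values.copy()
    report = PreprocessReport()
    for i in range(n):
        missing_j = np.flatnonzero(mask[i])
        if missing_j.size == 0:
            continue
        if np.all(np.isnan(dist[i])):
            raise ValueError(
                f"patient {table.patient_ids[i]!r} shares no observed marker "
                "with any other patient; cannot impute"
            )
        for j in missing_j:
            cand = np.flatnonzero(obs[:, j] & ~np.isnan(dist[i]))
            if cand.size < 2:
                raise ValueError(
                    f"patient {table.patient_ids[i]!r}: fewer than 2 usable "
                    f"neighbours for marker {table.markers[j].id!r}"
                )
            order = cand[np.lexsort((cand, dist[i][cand]))]
            nb = order[:2]
            val = float(table.values[nb, j].mean())
            values[i, j] = val
            report.imputed_cells.append(
                (
                    table.patient_ids[i],
                    table.markers[j].id,
                    val,
                    (table.patient_ids[nb[0]], table.patient_ids[nb[1]]),
                )
            )
    out = CohortTable(
        list(table.patient_ids),
        list(table.markers),
        values,
        np.zeros_like(mask),
    )
    return out, report


def _pooled_t(values: np.ndarray, flags: np.ndarray) -> float:
    """Two-sample pooled-variance Student t statistic (group 0 minus group 1)."""
    a, b = values[~flags], values[flags]
    na, nb = len(a), len(b)
    sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    if sp2 == 0:
        return 0.0 if a.mean() == b.mean() else np.inf
    return float((a.mean() - b.mean()) / np.sqrt(sp2 * (1 / na + 1 / nb)))


def dedup_correlated(
    table: CohortTable,
    ann: ClinicalAnnotations,
    r_threshold: float = 0.95,
) -> tuple[CohortTable, PreprocessReport]:
    """Collapse groups of >95%-correlated markers to their most discriminative member.

    Pearson correlations are computed on the (fully imputed) matrix; within
    each connected component of the graph linking pairs with |r| strictly
    above the threshold, the marker with the largest |t| (pooled-variance
    Student t between NCI+ and NCI- patients) is retained.
    """
    if table.missing_mask.any():
        raise ValueError("dedup requires an imputed table (no missing values)")
    known = ann.nci_known
    flags = ann.nci_flag[known]
    if flags.sum() < 2 or (~flags).sum() < 2:
        raise ValueError("need >= 2 patients per NCI group for dedup retention")

    vals = table.values
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(vals, rowvar=False)
    corr = np.nan_to_num(corr, nan=0.0)
    np.fill_diagonal(corr, 0.0)
    adj = np.abs(corr) > r_threshold
    n_comp, labels = connected_components(csr_matrix(adj), directed=False)

    tstats = np.array(
        [_pooled_t(vals[known, j], flags) for j in range(table.n_markers)]
    )
    abs_t = np.where(np.isnan(tstats), -np.inf, np.abs(tstats))

    keep = np.zeros(table.n_markers, dtype=bool)
    report = PreprocessReport()
    for c in range(n_comp):
        members = np.flatnonzero(labels == c)
        winner = members[np.argmax(abs_t[members])]
        keep[winner] = True
        for j in members:
            if j != winner:
                report.dedup_decisions.append(
                    (
                        table.markers[winner].id,
                        table.markers[j].id,
                        float(abs(corr[winner, j])),
                        float(tstats[winner]),
                        float(tstats[j]),
                    )
                )
    out = CohortTable(
        list(table.patient_ids),
        [m for j, m in enumerate(table.markers) if keep[j]],
        vals[:, keep].copy(),
        table.missing_mask[:, keep].copy(),
    )
    return out, report


def run_preprocess(
    table: CohortTable,
    ann: ClinicalAnnotations,
    missing_threshold: float = 0.10,
    r_threshold: float = 0.95,
) -> tuple[CohortTable, PreprocessReport]:
    """drop -> impute -> dedup, with a merged report."""
    t1, r1 = drop_high_missing(table, missing_threshold)
    t2, r2 = impute_knn2(t1)
    t3, r3 = dedup_correlated(t2, ann, r_threshold)
    return t3, r1.merge(r2).merge(r3)
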