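"""Double hierarchical clustering into immune-activation profiles.

Patients are clustered on the Euclidean distance between their z-scored
marker vectors and markers on ``1 - |Pearson r|``, both with Ward's
minimum-variance linkage, reproducing the classic double-dendrogram
heat-map view of immuno-monitoring panels.  Percentages (plus the four
soluble concentrations) are used for profiling by default, absolute
counts being less stable over time.  Clusterability is quantified by the
Hopkins statistic and the number of patient clusters is chosen with the
mean silhouette width and the Tibshirani gap statistic (the gap decision
wins when they disagree).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import dendrogram, fcluster, linkage
from scipy.spatial.distance import pdist, squareform

from immunoprofiles.core import CohortTable

__all__ = [
    "ProfileResult",
    "ChooseKResult",
    "profiling_marker_ids",
    "zscore_markers",
    "patient_distance",
    "marker_distance",
    "ward_linkage",
    "hopkins",
    "silhouette_curve",
    "choose_k",
    "assign_profiles",
    "heatmap_export",
    "double_clustering",
]


def profiling_marker_ids(table: CohortTable) -> list[str]:
    """Markers used for profiling: percentages and soluble concentrations."""
    return [m.id for m in table.markers if m.measure in ("percent", "concentration")]


def zscore_markers(table: CohortTable) -> tuple[np.ndarray, list[str]]:
    """Columns centred/scaled to mean 0, SD 1; zero-variance columns dropped.

    Returns the matrix and the ids of the retained markers.
    """
    if table.missing_mask.any():
        raise ValueError("z-scoring requires an imputed table")
    X = table.values
    sd = X.std(axis=0, ddof=0)
    keep = sd > 0
    if not keep.all():
        dropped = [m.id for j, m in enumerate(table.markers) if not keep[j]]
        warnings.warn(f"dropping zero-variance marker(s): {dropped}", stacklevel=2)
    Z = (X[:, keep] - X[:, keep].mean(axis=0)) / sd[keep]
    return Z, [m.id for j, m in enumerate(table.markers) if keep[j]]


def patient_distance(Z: np.ndarray) -> np.ndarray:
    """Symmetric Euclidean distance matrix between patients."""
    Z = np.asarray(Z, dtype=float)
    if not np.all(np.isfinite(Z)):
        raise ValueError("Z must be finite")
    return squareform(pdist(Z, metric="euclidean"))


def marker_distance(Z: np.ndarray) -> np.ndarray:
    """1 - |Pearson correlation| dissimilarity between markers (columns)."""
    Z = np.asarray(Z, dtype=float)
    if Z.shape[0] < 3:
        raise ValueError("need >= 3 patients for marker correlations")
    if np.any(Z.std(axis=0) == 0):
        raise ValueError("zero-variance marker; drop it before marker_distance")
    D = 1.0 - np.abs(np.corrcoef(Z, rowvar=False))
    np.fill_diagonal(D, 0.0)
    return np.clip(D, 0.0, None)


def ward_linkage(D: np.ndarray) -> np.ndarray:
    """Ward minimum-variance linkage on a distance matrix.

    Uses the Lance-Williams update on squared dissimilarities (heights
    returned on the distance scale, non-decreasing along the merges).
    """
    D = np.asarray(D, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1] or not np.allclose(D, D.T):
        raise ValueError("D must be a symmetric square distance matrix")
    if D.shape[0] < 2:
        raise ValueError("need at least 2 items")
    return linkage(squareform(D, checks=False), method="ward")


def hopkins(
    Z: np.ndarray, sample_fraction: float = 0.1, seed: int = 0
) -> float:
    """Hopkins clusterability statistic, ~0.5 for spatially random data,
    approaching 1 for strongly clustered data.

    For m sampled rows and m uniform points in the per-dimension bounding
    box: H = sum(u) / (sum(u) + sum(w)), where u are nearest-neighbour
    distances from the uniform points to the data and w from the sampled
    rows to the rest of the data.
    """
    Z = np.asarray(Z, dtype=float)
    n = Z.shape[0]
    if n < 20:
        raise ValueError("Hopkins statistic needs >= 20 rows")
    rng = np.random.default_rng(seed)
    m = max(1, int(np.floor(sample_fraction * n)))

    lo, hi = Z.min(axis=0), Z.max(axis=0)
    uniform = rng.uniform(lo, hi, size=(m, Z.shape[1]))
    du = np.sqrt(((uniform[:, None, :] - Z[None, :, :]) ** 2).sum(axis=2))
    u = du.min(axis=1)

    rows = rng.choice(n, size=m, replace=False)
    dw = np.sqrt(((Z[rows, None, :] - Z[None, :, :]) ** 2).sum(axis=2))
    dw[np.arange(m), rows] = np.inf  # exclude self
    w = dw.min(axis=1)
    return float(u.sum() / (u.sum() + w.sum()))


def _mean_silhouette(D: np.ndarray, labels: np.ndarray) -> float:
    """Mean silhouette width from a distance matrix; singletons score 0."""
    uniq = np.unique(labels)
    if len(uniq) < 2:
        raise ValueError("silhouette needs >= 2 clusters")
    s = np.zeros(len(labels))
    masks = {c: labels == c for c in uniq}
    for i in range(len(labels)):
        own = masks[labels[i]]
        n_own = own.sum()
        if n_own == 1:
            s[i] = 0.0
            continue
        a = D[i, own].sum() / (n_own - 1)
        b = min(D[i, masks[c]].mean() for c in uniq if c != labels[i])
        s[i] = (b - a) / max(a, b)
    return float(s.mean())


def _within_dispersion(D2: np.ndarray, labels: np.ndarray) -> float:
    """W = sum_c sum_{i,i' in c} d^2 / (2 n_c), from squared distances."""
    W = 0.0
    for c in np.unique(labels):
        mask = labels == c
        n_c = mask.sum()
        W += D2[np.ix_(mask, mask)].sum() / (2.0 * n_c)
    return W


def silhouette_curve(
    D: np.ndarray, tree: np.ndarray, k_values
) -> np.ndarray:
    """Mean silhouette width of the tree cut at each k."""
    return np.array(
        [_mean_silhouette(D, fcluster(tree, t=k, criterion="maxclust")) for k in k_values]
    )


@dataclass
class ChooseKResult:
    k: int
    k_sil: int
    k_gap: int
    k_values: np.ndarray
    silhouette: np.ndarray
    gap: np.ndarray
    gap_se: np.ndarray


def choose_k(
    Z: np.ndarray,
    D_patients: np.ndarray,
    k_range=range(2, 11),
    B: int = 50,
    seed: int = 0,
    tree: np.ndarray | None = None,
) -> ChooseKResult:
    """Select the number of patient clusters by silhouette and gap statistic.

    Gap(k) = mean_b log W*_kb - log W_k with B uniform bounding-box
    reference data sets clustered by the same Ward pipeline, and
    s_k = sd_b(log W*) * sqrt(1 + 1/B).  The gap choice is the smallest k
    with Gap(k) >= Gap(k+1) - s_{k+1}; the silhouette choice is the
    argmax.  When the two disagree, the gap choice is final (both are
    reported).
    """
    Z = np.asarray(Z, dtype=float)
    n = Z.shape[0]
    ks = np.array([k for k in k_range if 2 <= k <= n - 1])
    if ks.size == 0:
        raise ValueError("empty k range")
    if tree is None:
        tree = ward_linkage(D_patients)
    sil = silhouette_curve(D_patients, tree, ks)

    D2 = D_patients**2
    log_w = np.array(
        [
            np.log(_within_dispersion(D2, fcluster(tree, t=k, criterion="maxclust")))
            for k in ks
        ]
    )
    rng = np.random.default_rng(seed)
    lo, hi = Z.min(axis=0), Z.max(axis=0)
    ref_log_w = np.empty((B, ks.size))
    for b in range(B):
        ref = rng.uniform(lo, hi, size=Z.shape)
        d_ref = pdist(ref, metric="euclidean")
        tree_ref = linkage(d_ref, method="ward")
        d2_ref = squareform(d_ref) ** 2
        for i, k in enumerate(ks):
            labels = fcluster(tree_ref, t=k, criterion="maxclust")
            ref_log_w[b, i] = np.log(_within_dispersion(d2_ref, labels))
    gap = ref_log_w.mean(axis=0) - log_w
    se = ref_log_w.std(axis=0, ddof=1) * np.sqrt(1.0 + 1.0 / B)

    k_gap = int(ks[-1])
    for i in range(ks.size - 1):
        if gap[i] >= gap[i + 1] - se[i + 1]:
            k_gap = int(ks[i])
            break
    k_sil = int(ks[np.argmax(sil)])
    return ChooseKResult(
        k=k_gap, k_sil=k_sil, k_gap=k_gap, k_values=ks,
        silhouette=sil, gap=gap, gap_se=se,
    )


def assign_profiles(tree: np.ndarray, k: int) -> np.ndarray:
    """Cut the patient tree at k clusters; labels 1..k by decreasing size
    (ties broken by first patient index)."""
    n = tree.shape[0] + 1
    if k > n:
        raise ValueError(f"k={k} exceeds {n} patients")
    raw = fcluster(tree, t=k, criterion="maxclust")
    order = sorted(
        np.unique(raw),
        key=lambda c: (-(raw == c).sum(), int(np.flatnonzero(raw == c)[0])),
    )
    remap = {c: i + 1 for i, c in enumerate(order)}
    return np.array([remap[c] for c in raw])


@dataclass
class ProfileResult:
    """Output of the double clustering."""

    patient_tree: np.ndarray
    marker_tree: np.ndarray
    k: int
    labels: np.ndarray  # 1..k per patient
    hopkins: float
    diagnostics: ChooseKResult
    Z: np.ndarray
    marker_ids: list[str]
    patient_ids: list[str]

    def diagnostics_to_tsv(self, path, header_comment: str | None = None) -> None:
        import pandas as pd

        d = self.diagnostics
        df = pd.DataFrame(
            {
                "k": d.k_values,
                "silhouette": d.silhouette,
                "gap": d.gap,
                "gap_se": d.gap_se,
            }
        )
        with open(path, "w") as fh:
            if header_comment:
                fh.write(f"# {header_comment}\n")
            fh.write(
                f"# hopkins={self.hopkins:.4f} k_sil={d.k_sil} k_gap={d.k_gap} "
                f"k={self.k}\n"
            )
            df.to_csv(fh, sep="\t", index=False)


def double_clustering(
    table: CohortTable,
    k_range=range(2, 11),
    B: int = 50,
    seed: int = 0,
    sample_fraction: float = 0.1,
    marker_ids: list[str] | None = None,
    k: int | None = None,
) -> ProfileResult:
    """Full profiling pipeline on an imputed cohort.

    z-score -> Hopkins -> patient Ward tree (Euclidean) + marker Ward tree
    (1-|r|) -> silhouette/gap choice of k (unless ``k`` forces it) ->
    profile labels.
    """
    ids = marker_ids if marker_ids is not None else profiling_marker_ids(table)
    sub = table.select_markers(ids)
    Z, kept_ids = zscore_markers(sub)
    D_pat = patient_distance(Z)
    D_mark = marker_distance(Z)
    pat_tree = ward_linkage(D_pat)
    mark_tree = ward_linkage(D_mark)
    # Hopkins needs a reasonable sample; report NaN on very small cohorts
    h = (
        hopkins(Z, sample_fraction=sample_fraction, seed=seed)
        if Z.shape[0] >= 20
        else float("nan")
    )
    diag = choose_k(Z, D_pat, k_range=k_range, B=B, seed=seed, tree=pat_tree)
    k_final = k if k is not None else diag.k
    labels = assign_profiles(pat_tree, k_final)
    return ProfileResult(
        patient_tree=pat_tree,
        marker_tree=mark_tree,
        k=k_final,
        labels=labels,
        hopkins=h,
        diagnostics=diag,
        Z=Z,
        marker_ids=kept_ids,
        patient_ids=list(table.patient_ids),
    )


def heatmap_export(
    result: ProfileResult,
    image_path,
    matrix_path=None,
) -> None:
    """Write the dendrogram-ordered heat map (PNG/SVG) and, optionally, the
    ordered z-score matrix as a TSV (patients in patient-leaf order as rows,
    markers in marker-leaf order as columns, profile label annotated)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    import pandas as pd

    pat_order = dendrogram(result.patient_tree, no_plot=True)["leaves"]
    mark_order = dendrogram(result.marker_tree, no_plot=True)["leaves"]
    M = result.Z[np.ix_(pat_order, mark_order)]

    fig, (ax_band, ax) = plt.subplots(
        2, 1, figsize=(10, 7), height_ratios=[1, 24],
        sharex=True, constrained_layout=True,
    )
    lim = max(1.0, np.percentile(np.abs(M), 99))
    ax.imshow(
        M.T, aspect="auto", cmap="RdBu_r", vmin=-lim, vmax=lim,
        interpolation="nearest",
    )
    ax.set_yticks(range(len(mark_order)))
    ax.set_yticklabels([result.marker_ids[j] for j in mark_order], fontsize=5)
    ax.set_xlabel("patients (dendrogram order)")
    band = result.labels[pat_order][None, :]
    ax_band.imshow(band, aspect="auto", cmap="tab10", interpolation="nearest")
    ax_band.set_yticks([0])
    ax_band.set_yticklabels(["profile"], fontsize=7)
    fig.savefig(image_path, dpi=150)
    plt.close(fig)

    if matrix_path is not None:
        df = pd.DataFrame(
            M,
            index=[result.patient_ids[i] for i in pat_order],
            columns=[result.marker_ids[j] for j in mark_order],
        )
        df.insert(0, "profile", result.labels[pat_order])
        df.round(6).to_csv(matrix_path, sep="\t")
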