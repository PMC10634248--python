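"""Univariate marker screening against neurocognitive status.

Markers are screened with a Kruskal-Wallis test across the Frascati
outcome groups (none / ANI / MND by default), with Benjamini-Hochberg
control of the false discovery rate across the whole surviving marker
family.  Each marker additionally gets a two-group NCI+ vs NCI-
comparison using Student's t or Mann-Whitney "as appropriate" (normality
judged per group by Shapiro-Wilk), plus the white-matter-hyperintensity
comparisons on dichotomized Fazekas scores.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from immunoprofiles.core import ClinicalAnnotations, CohortTable

__all__ = [
    "kruskal_wallis",
    "bh_adjust",
    "two_group_compare",
    "TwoGroupResult",
    "screen_markers",
    "ScreenResult",
    "wmh_compare",
    "WMHComparison",
    "prevalence_summary",
    "PrevalenceSummary",
]


def kruskal_wallis(values, groups) -> tuple[float, float]:
    """Kruskal-Wallis H (midrank ties, tie-corrected) and chi-square p-value.

    The degenerate all-values-identical case (tie correction denominator 0)
    is defined as H = 0, p = 1.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    if len(values) != len(groups):
        raise ValueError("values and groups lengths differ")
    samples = [values[groups == g] for g in pd.unique(groups)]
    if len(samples) < 2 or any(len(s) == 0 for s in samples):
        raise ValueError("need >= 2 groups each with >= 1 observation")
    if np.all(values == values[0]):
        return 0.0, 1.0
    h, p = stats.kruskal(*samples)
    return float(h), float(p)


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order.

    q_(i) = min_{j >= i} ( p_(j) * m / j ), clipped at 1.
    """
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise ValueError("p-values must lie in [0,1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


@dataclass
class TwoGroupResult:
    """One two-group comparison (group 0 = NCI-, group 1 = NCI+)."""

    test_name: str  # "t" or "mann-whitney"
    statistic: float
    p: float
    mean0: float
    sd0: float
    n0: int
    mean1: float
    sd1: float
    n1: int


def _group_is_normal(x: np.ndarray, alpha: float) -> bool:
    if np.ptp(x) == 0:  # Shapiro-Wilk undefined on constant data
        return False
    return stats.shapiro(x).pvalue > alpha


def two_group_compare(values, flags, normality_alpha: float = 0.05) -> TwoGroupResult:
    """Student t (pooled) or Mann-Whitney two-group comparison, as appropriate.

    Both groups are checked with Shapiro-Wilk at ``normality_alpha``; only
    if neither rejects is the pooled-variance two-sided Student t used,
    otherwise a two-sided Mann-Whitney with normal approximation and
    tie/continuity correction.
    """
    values = np.asarray(values, dtype=float)
    flags = np.asarray(flags, dtype=bool)
    x0, x1 = values[~flags], values[flags]
    if len(x0) < 3 or len(x1) < 3:
        raise ValueError("both groups need >= 3 observations")
    summary = dict(
        mean0=float(x0.mean()),
        sd0=float(x0.std(ddof=1)),
        n0=len(x0),
        mean1=float(x1.mean()),
        sd1=float(x1.std(ddof=1)),
        n1=len(x1),
    )
    if np.all(values == values[0]):
        return TwoGroupResult("mann-whitney", 0.0, 1.0, **summary)
    normal = _group_is_normal(x0, normality_alpha) and _group_is_normal(
        x1, normality_alpha
    )
    if normal:
        res = stats.ttest_ind(x0, x1, equal_var=True)
        return TwoGroupResult("t", float(res.statistic), float(res.pvalue), **summary)
    res = stats.mannwhitneyu(
        x0, x1, alternative="two-sided", method="asymptotic", use_continuity=True
    )
    return TwoGroupResult(
        "mann-whitney", float(res.statistic), float(res.pvalue), **summary
    )


@dataclass
class ScreenResult:
    """Per-marker screening statistics with BH-adjusted significance flags."""

    table: pd.DataFrame  # one row per marker
    alpha: float
    grouping: str  # "three" (none/ANI/MND) or "two" (NCI-/NCI+)

    @property
    def selected(self) -> list[str]:
        return self.table.loc[self.table["selected"], "marker"].tolist()

    def to_tsv(self, path, header_comment: str | None = None) -> None:
        with open(path, "w") as fh:
            if header_comment:
                fh.write(f"# {header_comment}\n")
            self.table.to_csv(fh, sep="\t", index=False)


def screen_markers(
    table: CohortTable,
    ann: ClinicalAnnotations,
    alpha: float = 0.05,
    grouping: str = "three",
) -> ScreenResult:
    """Kruskal-Wallis screen of every marker against the NCI outcome.

    ``grouping="three"`` tests none vs ANI vs MND; ``"two"`` collapses ANI
    and MND.  BH adjustment spans all screened markers; a marker is
    selected when its adjusted p-value is <= ``alpha``.  A two-group
    NCI+ vs NCI- comparison (t or Mann-Whitney) is reported per marker.
    """
    if grouping not in ("two", "three"):
        raise ValueError("grouping must be 'two' or 'three'")
    if table.missing_mask.any():
        raise ValueError("screen requires an imputed table")
    known = ann.nci_known
    if known.sum() == 0:
        raise ValueError("no patients with known NCI class")
    classes = ann.nci_class[known]
    flags = ann.nci_flag[known]
    groups = classes if grouping == "three" else np.where(flags, "NCI+", "NCI-")

    rows = []
    for j, m in enumerate(table.markers):
        vals = table.values[known, j]
        h, p = kruskal_wallis(vals, groups)
        two = two_group_compare(vals, flags)
        rows.append(
            {
                "marker": m.id,
                "H": h,
                "p_kw": p,
                "two_group_test": two.test_name,
                "two_group_stat": two.statistic,
                "p_two_group": two.p,
                "mean_nci_neg": two.mean0,
                "sd_nci_neg": two.sd0,
                "mean_nci_pos": two.mean1,
                "sd_nci_pos": two.sd1,
            }
        )
    df = pd.DataFrame(rows)
    df["q"] = bh_adjust(df["p_kw"].to_numpy())
    df["selected"] = df["q"] <= alpha
    order = [
        "marker", "H", "p_kw", "q", "selected",
        "two_group_test", "two_group_stat", "p_two_group",
        "mean_nci_neg", "sd_nci_neg", "mean_nci_pos", "sd_nci_pos",
    ]
    return ScreenResult(df[order], alpha=alpha, grouping=grouping)


@dataclass
class WMHComparison:
    """Marker vs white-matter-hyperintensity comparisons.

    Fazekas scores are dichotomized 0-1 vs 2-3; ``periventricular`` /
    ``deep`` are None when a dichotomized group is empty or too small.
    """

    periventricular: TwoGroupResult | None
    deep: TwoGroupResult | None
    spearman_r: float
    n_rated: int


def wmh_compare(
    table: CohortTable, ann: ClinicalAnnotations, marker_id: str
) -> WMHComparison:
    """Compare one marker across dichotomized Fazekas groups (0-1 vs 2-3)."""
    col = table.column(marker_id)
    rated_both = ~np.isnan(ann.fazekas_pv) & ~np.isnan(ann.fazekas_deep)
    if (~np.isnan(ann.fazekas_pv)).sum() < 10 and (~np.isnan(ann.fazekas_deep)).sum() < 10:
        raise ValueError("need Fazekas annotations for >= 10 patients")

    def compare(scores: np.ndarray) -> TwoGroupResult | None:
        ok = ~np.isnan(scores) & ~np.isnan(col)
        if ok.sum() == 0:
            return None
        high = scores[ok] >= 2
        try:
            return two_group_compare(col[ok], high)
        except ValueError:
            return None  # a dichotomized group empty or too small

    if rated_both.sum() >= 2:
        rho = stats.spearmanr(
            ann.fazekas_pv[rated_both], ann.fazekas_deep[rated_both]
        ).statistic
        # identical constant vectors: perfect monotone agreement
        if np.isnan(rho) and np.array_equal(
            ann.fazekas_pv[rated_both], ann.fazekas_deep[rated_both]
        ):
            rho = 1.0
    else:
        rho = np.nan
    return WMHComparison(
        periventricular=compare(ann.fazekas_pv),
        deep=compare(ann.fazekas_deep),
        spearman_r=float(rho),
        n_rated=int(rated_both.sum()),
    )


@dataclass
class PrevalenceSummary:
    """NCI prevalence among patients with a known Frascati classification."""

    pct_nci: int
    pct_ani: int
    pct_mnd: int
    frac_nci: float
    frac_ani: float
    frac_mnd: float
    counts: dict[str, int]


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def prevalence_summary(ann: ClinicalAnnotations) -> PrevalenceSummary:
    """Percentages of NCI (ANI or MND), ANI and MND among classified patients."""
    known = ann.nci_known
    total = int(known.sum())
    if total == 0:
        raise ValueError("no classified patients")
    counts = {
        c: int((ann.nci_class[known] == c).sum()) for c in ("none", "ANI", "MND")
    }
    frac_ani = counts["ANI"] / total
    frac_mnd = counts["MND"] / total
    frac_nci = frac_ani + frac_mnd
    return PrevalenceSummary(
        pct_nci=_round_half_up(100 * frac_nci),
        pct_ani=_round_half_up(100 * frac_ani),
        pct_mnd=_round_half_up(100 * frac_mnd),
        frac_nci=frac_nci,
        frac_ani=frac_ani,
        frac_mnd=frac_mnd,
        counts=counts,
    )
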