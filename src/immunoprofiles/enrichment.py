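"""Profile characterization and NCI-enrichment statistics.

Each immune-activation profile is characterized by profile-vs-rest marker
comparisons and, where external age-matched reference moments exist, by
Welch t tests against those summary statistics.  Profile-outcome
association uses Fisher's exact test on the 2x2 table (profile membership
x NCI status) with a Haldane-Anscombe-corrected odds ratio and Woolf
confidence interval.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from immunoprofiles.core import CohortTable
from immunoprofiles.screen import TwoGroupResult, two_group_compare

__all__ = [
    "ContingencyTable2x2",
    "EnrichmentResult",
    "fisher_exact",
    "odds_ratio_ci",
    "nci_enrichment",
    "profile_vs_rest_markers",
    "compare_to_reference",
]


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts: rows = in target profile yes/no, columns = NCI yes/no."""

    a: int  # profile & NCI+
    b: int  # profile & NCI-
    c: int  # rest & NCI+
    d: int  # rest & NCI-

    def __post_init__(self) -> None:
        cells = (self.a, self.b, self.c, self.d)
        if any(x < 0 for x in cells):
            raise ValueError("cell counts must be non-negative")
        if sum(cells) == 0:
            raise ValueError("empty contingency table")

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]])


def fisher_exact(t: ContingencyTable2x2) -> float:
    """Two-sided Fisher exact p: total hypergeometric probability of all
    tables with the observed margins whose probability does not exceed the
    observed table's (within a small relative tolerance)."""
    return float(stats.fisher_exact(t.as_array(), alternative="two-sided")[1])


def odds_ratio_ci(
    t: ContingencyTable2x2, level: float = 0.95
) -> tuple[float, float, float]:
    """Odds ratio with Woolf (log-normal) confidence interval.

    The Haldane-Anscombe +0.5 correction is applied to every cell if and
    only if some cell is zero, keeping the estimate finite.
    """
    a, b, c, d = (float(x) for x in (t.a, t.b, t.c, t.d))
    if min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    or_ = (a * d) / (b * c)
    z = stats.norm.ppf(0.5 + level / 2.0)
    se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return (
        float(or_),
        float(np.exp(np.log(or_) - z * se)),
        float(np.exp(np.log(or_) + z * se)),
    )


@dataclass
class EnrichmentResult:
    """NCI enrichment of a set of profiles versus the rest."""

    target_profiles: tuple[int, ...]
    table: ContingencyTable2x2
    odds_ratio: float
    ci_low: float
    ci_high: float
    p: float
    corrected: bool  # Haldane-Anscombe applied


def nci_enrichment(
    labels: np.ndarray, nci: np.ndarray, target: set[int] | tuple[int, ...] | int
) -> EnrichmentResult:
    """Fisher test and odds ratio of NCI in the target profile(s) vs the rest.

    Patients whose NCI status is unknown should be excluded before calling.
    """
    labels = np.asarray(labels)
    nci = np.asarray(nci, dtype=bool)
    if labels.shape != nci.shape:
        raise ValueError("labels and flags lengths differ")
    if isinstance(target, (int, np.integer)):
        target = (int(target),)
    target = tuple(sorted(set(int(t) for t in target)))
    if not target:
        raise ValueError("target profile set is empty")
    in_target = np.isin(labels, target)
    if in_target.all() or not in_target.any():
        raise ValueError("target profiles cover all (or no) patients; no rest group")
    tab = ContingencyTable2x2(
        a=int((in_target & nci).sum()),
        b=int((in_target & ~nci).sum()),
        c=int((~in_target & nci).sum()),
        d=int((~in_target & ~nci).sum()),
    )
    or_, lo, hi = odds_ratio_ci(tab)
    return EnrichmentResult(
        target_profiles=target,
        table=tab,
        odds_ratio=or_,
        ci_low=lo,
        ci_high=hi,
        p=fisher_exact(tab),
        corrected=min(tab.a, tab.b, tab.c, tab.d) == 0,
    )


def profile_vs_rest_markers(
    table: CohortTable, labels: np.ndarray, profile: int
) -> pd.DataFrame:
    """Two-group comparison of every marker: profile members vs all others.

    Returns one row per marker (means +/- SDs on both sides, test used,
    p-value), ranked by ascending p.
    """
    labels = np.asarray(labels)
    flags = labels == profile
    if not flags.any() or flags.all():
        raise ValueError(f"profile {profile} empty, or equal to the whole cohort")
    if table.missing_mask.any():
        raise ValueError("profile characterization requires an imputed table")
    rows = []
    for j, m in enumerate(table.markers):
        # group 1 = the profile of interest, group 0 = the rest
        res: TwoGroupResult = two_group_compare(table.values[:, j], flags)
        rows.append(
            {
                "marker": m.id,
                "mean_profile": res.mean1,
                "sd_profile": res.sd1,
                "mean_rest": res.mean0,
                "sd_rest": res.sd0,
                "test": res.test_name,
                "statistic": res.statistic,
                "p": res.p,
            }
        )
    return (
        pd.DataFrame(rows).sort_values("p", kind="stable").reset_index(drop=True)
    )


def compare_to_reference(
    table: CohortTable,
    labels: np.ndarray,
    profile: int,
    reference: dict[str, tuple[float, float, int]],
) -> pd.DataFrame:
    """Welch t tests of profile members against external reference moments.

    ``reference`` maps marker id -> (mean, SD, n) established in an
    age-matched general population; markers of the cohort without a
    reference entry are skipped with a warning.
    """
    labels = np.asarray(labels)
    flags = labels == profile
    if not flags.any():
        raise ValueError(f"profile {profile} is empty")
    missing = [m for m in reference if m not in table.marker_ids()]
    rows = []
    for mid, (ref_mean, ref_sd, ref_n) in reference.items():
        if mid in missing:
            warnings.warn(f"reference marker {mid!r} absent from cohort; skipped",
                          stacklevel=2)
            continue
        vals = table.column(mid)[flags]
        vals = vals[~np.isnan(vals)]
        res = stats.ttest_ind_from_stats(
            vals.mean(), vals.std(ddof=1), len(vals),
            ref_mean, ref_sd, ref_n, equal_var=False,
        )
        rows.append(
            {
                "marker": mid,
                "mean_profile": float(vals.mean()),
                "sd_profile": float(vals.std(ddof=1)),
                "n_profile": len(vals),
                "mean_ref": ref_mean,
                "sd_ref": ref_sd,
                "n_ref": ref_n,
                "t": float(res.statistic),
                "p": float(res.pvalue),
            }
        )
    return pd.DataFrame(rows)
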