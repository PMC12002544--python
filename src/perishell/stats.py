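"""Nonparametric test battery with Benjamini-Hochberg FDR control.

Group contrasts (HC vs MS tissue) use the Mann-Whitney U test for
independent samples; within-patient tissue contrasts (avgLesion, avgPL,
NAWM, NAGM) use the Wilcoxon signed-rank test.  Each contrast family --
the nine biomarker tests of one tissue comparison -- is corrected with
the Benjamini-Hochberg step-up procedure at alpha = 0.05.

Exact null distributions are used whenever the sample is small enough and
free of ties (Mann-Whitney) or tied absolute differences (Wilcoxon);
otherwise the tie-corrected normal approximation with continuity
correction is applied.  The study-scale samples (13 and 14 subjects) are
well inside the exact regime.

In all outputs, ``p_adjusted`` is the BH-adjusted p-value and ``q_crit``
the BH critical value rank/m * alpha at the p-value's rank within its
family (the rank-1 critical value for a nine-test family at alpha = 0.05
is 0.05/9 ~= 0.0056).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "FDRResult",
    "TestResult",
    "benjamini_hochberg",
    "mann_whitney_u",
    "run_test_battery",
    "wilcoxon_signed_rank",
]

#: Largest sample size for which exact null enumeration is attempted.
EXACT_THRESHOLD = 25

#: The seven contrast families: (name, kind, voi_a, voi_b).  MWU contrasts
#: compare an HC VOI against an MS VOI; Wilcoxon contrasts pair two VOIs
#: within each MS patient.
CONTRASTS: list[tuple[str, str, str, str]] = [
    ("HCWM_vs_NAWM", "mwu", "WM", "NAWM"),
    ("HCGM_vs_NAGM", "mwu", "GM", "NAGM"),
    ("lesion_vs_PL", "wilcoxon", "avgLesion", "avgPL"),
    ("lesion_vs_NAWM", "wilcoxon", "avgLesion", "NAWM"),
    ("lesion_vs_NAGM", "wilcoxon", "avgLesion", "NAGM"),
    ("PL_vs_NAWM", "wilcoxon", "avgPL", "NAWM"),
    ("PL_vs_NAGM", "wilcoxon", "avgPL", "NAGM"),
]


@dataclass(frozen=True)
class TestResult:
    method: str
    statistic: float
    n: tuple[int, ...]
    p: float
    exact: bool
    n_ties: int = 0
    n_zero: int = 0
    warning: str | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.p <= 1.0):
            raise ValueError(f"p-value outside [0, 1]: {self.p}")


def mann_whitney_u(x, y) -> TestResult:
    """Two-sided Mann-Whitney U test for two independent samples.

    Exact when min(n1, n2) <= 25 and the pooled sample has no ties;
    otherwise midrank normal approximation with tie and continuity
    correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    n_ties = pooled.size - np.unique(pooled).size
    exact = n_ties == 0 and min(x.size, y.size) <= EXACT_THRESHOLD
    res = sps.mannwhitneyu(
        x, y, alternative="two-sided", method="exact" if exact else "asymptotic"
    )
    return TestResult(
        method="mann-whitney-u",
        statistic=float(res.statistic),
        n=(x.size, y.size),
        p=float(min(res.pvalue, 1.0)),
        exact=exact,
        n_ties=n_ties,
    )


def wilcoxon_signed_rank(x, y, zero_method: str = "wilcox") -> TestResult:
    """Two-sided Wilcoxon signed-rank test for paired samples.

    Zero differences are dropped by default (classical convention;
    ``zero_method='pratt'`` keeps them in the ranking).  Exact when the
    effective n <= 25 with untied absolute differences; all-zero
    differences yield p = 1 with a warning flag instead of an error.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("paired samples must have equal length")
    if x.size == 0:
        raise ValueError("paired samples must be non-empty")
    d = x - y
    n_zero = int((d == 0).sum())
    if n_zero == d.size:
        return TestResult(
            method="wilcoxon-signed-rank",
            statistic=0.0,
            n=(0,),
            p=1.0,
            exact=True,
            n_zero=n_zero,
            warning="all paired differences are zero",
        )
    d_eff = d[d != 0] if zero_method == "wilcox" else d
    absd = np.abs(d_eff)
    n_ties = absd.size - np.unique(absd).size
    exact = n_ties == 0 and d_eff.size <= EXACT_THRESHOLD and zero_method == "wilcox"
    res = sps.wilcoxon(
        x,
        y,
        zero_method=zero_method,
        correction=not exact,
        alternative="two-sided",
        method="exact" if exact else "approx",
    )
    return TestResult(
        method="wilcoxon-signed-rank",
        statistic=float(res.statistic),
        n=(int((d != 0).sum()) if zero_method == "wilcox" else d.size,),
        p=float(min(res.pvalue, 1.0)),
        exact=exact,
        n_ties=n_ties,
        n_zero=n_zero,
    )


@dataclass
class FDRResult:
    """Benjamini-Hochberg step-up correction of one test family."""

    pvalues: np.ndarray  # raw p, original order
    adjusted: np.ndarray  # BH-adjusted p, original order
    reject: np.ndarray  # bool, original order
    critical: np.ndarray  # rank/m*alpha at each test's rank, original order
    alpha: float
    family: str = ""
    n_rejected: int = field(init=False)

    def __post_init__(self) -> None:
        self.n_rejected = int(self.reject.sum())

    @property
    def rank1_critical(self) -> float:
        """The rank-1 BH critical value alpha/m."""
        return self.alpha / len(self.pvalues)


def benjamini_hochberg(pvals, alpha: float = 0.05, family: str = "") -> FDRResult:
    """Step-up BH procedure controlling the false discovery rate.

    Rejects hypotheses 1..k where k is the largest rank i with
    p_(i) <= i/m * alpha; adjusted p-values are the monotone envelope
    min_{j>=i} m * p_(j) / j, capped at 1.
    """
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value family")
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order]
    ranks = np.arange(1, m + 1)
    crit_sorted = ranks / m * alpha
    passed = ranked <= crit_sorted
    k = int(np.max(np.nonzero(passed)[0]) + 1) if passed.any() else 0
    reject_sorted = np.zeros(m, dtype=bool)
    reject_sorted[:k] = True
    adj_sorted = np.minimum.accumulate((m * ranked / ranks)[::-1])[::-1]
    adj_sorted = np.minimum(adj_sorted, 1.0)

    inv = np.empty(m, dtype=int)
    inv[order] = np.arange(m)
    return FDRResult(
        pvalues=p,
        adjusted=adj_sorted[inv],
        reject=reject_sorted[inv],
        critical=crit_sorted[inv],
        alpha=alpha,
        family=family,
    )


def _subject_wide(cohort: pd.DataFrame) -> pd.DataFrame:
    subj = cohort[cohort["level"] == "subject"]
    return subj.pivot_table(
        index=["group", "subject"], columns=["biomarker", "voi"], values="value"
    )


def run_test_battery(
    cohort: pd.DataFrame,
    alpha: float = 0.05,
    biomarkers: list[str] | None = None,
) -> tuple[pd.DataFrame, dict[str, FDRResult]]:
    """Run the full contrast battery on a subject-level cohort table.

    Per biomarker: Mann-Whitney U for HC-vs-MS white and grey matter, and
    Wilcoxon signed-rank for the five within-MS tissue contrasts.  BH
    correction is applied within each contrast family (the nine biomarker
    tests of one contrast).  Subjects with a missing cell are dropped
    pairwise for that biomarker, mirroring a missing modality.

    Returns a tidy results frame and the per-family FDR results.
    """
    wide = _subject_wide(cohort)
    if biomarkers is None:
        biomarkers = sorted({b for b, _ in wide.columns})

    groups = set(wide.index.get_level_values("group"))
    rows = []
    for contrast, kind, voi_a, voi_b in CONTRASTS:
        for bm in biomarkers:
            col_a, col_b = (bm, voi_a), (bm, voi_b)
            if kind == "mwu":
                if "HC" not in groups or "MS" not in groups:
                    continue
                if col_a not in wide.columns or col_b not in wide.columns:
                    continue
                a = wide.xs("HC", level="group")[col_a].dropna()
                b = wide.xs("MS", level="group")[col_b].dropna()
                if a.empty or b.empty:
                    continue
                res = mann_whitney_u(a.to_numpy(), b.to_numpy())
            else:
                if "MS" not in groups:
                    continue
                if col_a not in wide.columns or col_b not in wide.columns:
                    continue
                ms = wide.xs("MS", level="group")[[col_a, col_b]].dropna()
                if ms.empty:
                    continue
                res = wilcoxon_signed_rank(ms[col_a].to_numpy(), ms[col_b].to_numpy())
            rows.append(
                {
                    "contrast": contrast,
                    "biomarker": bm,
                    "method": res.method,
                    "statistic": res.statistic,
                    "n": res.n,
                    "p": res.p,
                    "exact": res.exact,
                }
            )
    results = pd.DataFrame(rows)
    fdr: dict[str, FDRResult] = {}
    if results.empty:
        return results, fdr
    results["p_adjusted"] = np.nan
    results["q_crit"] = np.nan
    results["reject_fdr"] = False
    for contrast, grp in results.groupby("contrast"):
        fam = benjamini_hochberg(grp["p"].to_numpy(), alpha=alpha, family=contrast)
        fdr[contrast] = fam
        results.loc[grp.index, "p_adjusted"] = fam.adjusted
        results.loc[grp.index, "q_crit"] = fam.critical
        results.loc[grp.index, "reject_fdr"] = fam.reject
    return results, fdr
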