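"""Per-feature between-group comparison with a normality gate.

Mirrors the common clinical-imaging convention: test each feature for
normality in both groups with Shapiro-Wilk; if both groups pass, compare
the groups with a two-sample t-test (pooled variance by default),
otherwise with the two-tailed Mann-Whitney U test.  No multiplicity
correction is applied by default; an optional Benjamini-Hochberg pass is
available.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .classification import FeatureTable, NEGATIVE_LABEL, POSITIVE_LABEL

__all__ = ["GroupComparison", "compare_groups", "feature_report"]


@dataclass
class GroupComparison:
    feature: str
    mean_a: float
    sd_a: float
    mean_b: float
    sd_b: float
    test_used: str            # "t" or "mann_whitney"
    statistic: float
    p_value: float
    significant_at_0_05: bool


def compare_groups(values_a, values_b, alpha_normality: float = 0.05,
                   feature: str = "", welch: bool = False) -> GroupComparison:
    """Shapiro-Wilk gate, then a two-tailed t or Mann-Whitney comparison.

    Both groups must pass Shapiro-Wilk at ``alpha_normality`` for the
    parametric branch.  The t-test uses pooled variance unless ``welch``.
    Mann-Whitney uses the exact null distribution for small samples
    (n < 8, no ties) and the tie-corrected normal approximation otherwise.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 3 or b.size < 3:
        raise ValueError("each group needs at least 3 observations")
    if a.std(ddof=0) == 0 and b.std(ddof=0) == 0:
        if np.allclose(a.mean(), b.mean()):
            # identical constants: no evidence of difference by convention
            return GroupComparison(feature, float(a.mean()), 0.0,
                                   float(b.mean()), 0.0, "t", 0.0, 1.0, False)
        raise ValueError("constant data in both groups with different values")

    def normal(x):
        if x.std(ddof=0) == 0:
            return False
        return stats.shapiro(x).pvalue > alpha_normality

    if normal(a) and normal(b):
        res = stats.ttest_ind(a, b, equal_var=not welch)
        test_used, statistic, p = "t", float(res.statistic), float(res.pvalue)
    else:
        method = "exact" if min(a.size, b.size) < 8 else "asymptotic"
        try:
            res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
        except ValueError:
            res = stats.mannwhitneyu(a, b, alternative="two-sided",
                                     method="asymptotic")
        test_used, statistic, p = "mann_whitney", float(res.statistic), float(res.pvalue)

    return GroupComparison(
        feature,
        float(a.mean()), float(a.std(ddof=1)),
        float(b.mean()), float(b.std(ddof=1)),
        test_used, statistic, min(p, 1.0), p < 0.05,
    )


def feature_report(table: FeatureTable, alpha_normality: float = 0.05,
                   welch: bool = False, bh_correct: bool = False
                   ) -> pd.DataFrame:
    """One gated group comparison per feature column.

    Group A is the control group, group B the patient group, matching the
    column order of the clinical tables (controls first).  Returns a
    DataFrame with columns ``feature, mean_hc, sd_hc, mean_ad, sd_ad, test,
    statistic, p_two_tailed, significant_0_05``.
    """
    labels = np.array(table.labels)
    hc = labels == NEGATIVE_LABEL
    ad = labels == POSITIVE_LABEL
    if hc.sum() < 3 or ad.sum() < 3:
        raise ValueError("each group needs at least 3 subjects")
    rows = []
    for name in table.features.columns:
        vals = table.features[name].to_numpy(dtype=float)
        comp = compare_groups(vals[hc], vals[ad], alpha_normality,
                              feature=name, welch=welch)
        rows.append({
            "feature": name,
            "mean_hc": comp.mean_a, "sd_hc": comp.sd_a,
            "mean_ad": comp.mean_b, "sd_ad": comp.sd_b,
            "test": comp.test_used,
            "statistic": comp.statistic,
            "p_two_tailed": comp.p_value,
            "significant_0_05": comp.significant_at_0_05,
        })
    report = pd.DataFrame(rows)
    if bh_correct:
        p = report["p_two_tailed"].to_numpy()
        order = np.argsort(p)
        m = len(p)
        adj = np.empty(m)
        running = 1.0
        for rank in range(m - 1, -1, -1):
            idx = order[rank]
            running = min(running, p[idx] * m / (rank + 1))
            adj[idx] = running
        report["p_bh"] = adj
        report["significant_0_05"] = report["p_bh"] < 0.05
    return report
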