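"""Three-zone statistical comparison of depth-profile values.

For any analyte, values grouped by water-column zone (oxic / methane
oxidation / anoxic) are compared with the procedure: Shapiro-Wilk normality
per group; if every group passes at alpha, one-way ANOVA followed by Tukey's
HSD; otherwise Kruskal-Wallis followed by pairwise Mann-Whitney tests.
Pairwise tests run only when the omnibus test is significant.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .errors import SampleSizeError

__all__ = ["ZoneComparison", "PairwiseResult", "compare_zones"]


@dataclass
class PairwiseResult:
    group_a: str
    group_b: str
    test: str
    statistic: float
    p_value: float
    significant: bool


@dataclass
class ZoneComparison:
    """Result bundle of one zone comparison."""

    analyte: str
    groups: dict[str, np.ndarray]
    normality_p: dict[str, float]
    branch: str                      # "parametric" | "nonparametric"
    omnibus_test: str
    omnibus_statistic: float
    omnibus_p: float
    pairwise: list[PairwiseResult] = field(default_factory=list)
    alpha: float = 0.05
    excluded_groups: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "analyte": self.analyte,
                "zone_a": "omnibus",
                "zone_b": "",
                "test": self.omnibus_test,
                "statistic": self.omnibus_statistic,
                "p": self.omnibus_p,
                "significant": self.omnibus_p < self.alpha,
            }
        ]
        for pw in self.pairwise:
            rows.append(
                {
                    "analyte": self.analyte,
                    "zone_a": pw.group_a,
                    "zone_b": pw.group_b,
                    "test": pw.test,
                    "statistic": pw.statistic,
                    "p": pw.p_value,
                    "significant": pw.significant,
                }
            )
        return pd.DataFrame(rows)


def compare_zones(
    values_by_zone: dict[str, np.ndarray],
    alpha: float = 0.05,
    analyte: str = "",
    bonferroni: bool = False,
) -> ZoneComparison:
    """Compare analyte values across water-column zones.

    Groups with fewer than 3 finite values are excluded with a warning; at
    least two usable groups are required. The parametric branch (ANOVA +
    Tukey HSD) is chosen iff every group passes Shapiro-Wilk normality at
    *alpha*; otherwise Kruskal-Wallis + pairwise Mann-Whitney. Pairwise
    p-values are unadjusted unless *bonferroni* is set.
    """
    groups: dict[str, np.ndarray] = {}
    excluded: list[str] = []
    for name, vals in values_by_zone.items():
        arr = np.asarray(vals, dtype=float)
        arr = arr[np.isfinite(arr)]
        if arr.size < 3:
            import warnings

            warnings.warn(
                f"zone {name!r} has {arr.size} usable value(s) (<3); excluded",
                stacklevel=2,
            )
            excluded.append(name)
        else:
            groups[name] = arr
    if len(groups) < 2:
        raise SampleSizeError(
            f"need >= 2 groups with >= 3 values; got {len(groups)} usable"
        )

    normality = {}
    for name, arr in groups.items():
        if np.ptp(arr) == 0:
            normality[name] = 0.0  # degenerate constant group: not normal
        else:
            normality[name] = float(stats.shapiro(arr).pvalue)
    parametric = all(p >= alpha for p in normality.values())

    names = list(groups)
    samples = [groups[n] for n in names]
    if all(np.ptp(s) == 0 for s in samples) and all(
        s[0] == samples[0][0] for s in samples
    ):
        # all values identical everywhere: trivially no difference
        branch = "nonparametric"
        omnibus_test, stat, p = "kruskal_wallis", 0.0, 1.0
    elif parametric:
        branch = "parametric"
        res = stats.f_oneway(*samples)
        omnibus_test, stat, p = "one_way_anova", float(res.statistic), float(res.pvalue)
    else:
        branch = "nonparametric"
        res = stats.kruskal(*samples)
        omnibus_test, stat, p = "kruskal_wallis", float(res.statistic), float(res.pvalue)

    comparison = ZoneComparison(
        analyte=analyte,
        groups=groups,
        normality_p=normality,
        branch=branch,
        omnibus_test=omnibus_test,
        omnibus_statistic=stat,
        omnibus_p=p,
        alpha=alpha,
        excluded_groups=excluded,
    )

    if p < alpha:
        if branch == "parametric":
            tukey = stats.tukey_hsd(*samples)
            for i, j in combinations(range(len(names)), 2):
                pv = float(tukey.pvalue[i, j])
                comparison.pairwise.append(
                    PairwiseResult(
                        names[i], names[j], "tukey_hsd",
                        float(tukey.statistic[i, j]), pv, pv < alpha,
                    )
                )
        else:
            pairs = list(combinations(range(len(names)), 2))
            m = len(pairs)
            for i, j in pairs:
                res = stats.mannwhitneyu(samples[i], samples[j])
                pv = float(res.pvalue)
                if bonferroni:
                    pv = min(1.0, pv * m)
                comparison.pairwise.append(
                    PairwiseResult(
                        names[i], names[j],
                        "mann_whitney" + ("_bonferroni" if bonferroni else ""),
                        float(res.statistic), pv, pv < alpha,
                    )
                )
    return comparison
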