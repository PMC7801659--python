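"""Rank-based and parametric group comparisons.

Implements the Kruskal–Wallis test with midrank tie correction, Dunn's
rank-based pairwise post-hoc test, and one-way ANOVA with Bonferroni-
adjusted pairwise t tests. These are written out explicitly (rather
than delegated to a statistics library) so the tie handling and
post-hoc variance terms are inspectable; library routines serve as
cross-checks in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.stats import chi2
from scipy.stats import f as f_dist
from scipy.stats import norm, rankdata
from scipy.stats import t as t_dist


@dataclass
class GroupedSample:
    """Values partitioned into named groups."""

    groups: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.groups) != len(self.values):
            raise ValueError("one group label per value required")
        if len(set(self.groups)) < 2:
            raise ValueError("need at least 2 groups")

    @classmethod
    def from_dict(cls, data: dict[str, list[float]]) -> "GroupedSample":
        groups, values = [], []
        for g, vals in data.items():
            groups.extend([g] * len(vals))
            values.extend(vals)
        return cls(groups=groups, values=np.asarray(values))

    def group_arrays(self) -> dict[str, np.ndarray]:
        out: dict[str, np.ndarray] = {}
        for g in dict.fromkeys(self.groups):
            out[g] = self.values[[gi == g for gi in self.groups]]
        return out


@dataclass
class KruskalWallisResult:
    h: float
    df: int
    p_value: float
    tie_correction: float


def kruskal_wallis(sample: GroupedSample) -> KruskalWallisResult:
    """Tie-corrected Kruskal–Wallis H with chi-square p-value.

    Midranks are assigned to ties; H is divided by the tie-correction
    factor ``1 − Σ(t³ − t)/(N³ − N)``. When all values are identical the
    statistic is defined as H = 0 with p = 1.
    """
    arrays = sample.group_arrays()
    if len(sample.values) < 3:
        raise ValueError("need at least 3 observations in total")
    n_total = len(sample.values)
    ranks = rankdata(sample.values)
    h = 0.0
    start_groups = list(arrays)
    rank_by_group = {}
    pos = 0
    # ranks follow the original value order; regroup by label
    labels = np.asarray(sample.groups, dtype=object)
    for g in start_groups:
        rank_by_group[g] = ranks[labels == g]
    h = 12.0 / (n_total * (n_total + 1)) * sum(
        len(r) * r.mean() ** 2 for r in rank_by_group.values()
    ) - 3.0 * (n_total + 1)
    _, counts = np.unique(sample.values, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts))
    correction = 1.0 - tie_term / (n_total**3 - n_total)
    if correction == 0.0:  # all values identical
        return KruskalWallisResult(
            h=0.0, df=len(arrays) - 1, p_value=1.0, tie_correction=0.0
        )
    h /= correction
    df = len(arrays) - 1
    return KruskalWallisResult(
        h=float(h), df=df, p_value=float(chi2.sf(h, df)), tie_correction=correction
    )


def dunn_posthoc(sample: GroupedSample, adjustment: str = "none") -> pd.DataFrame:
    """Dunn's pairwise z tests on mean ranks after Kruskal–Wallis.

    z_ij = (R̄_i − R̄_j) / sqrt((N(N+1)/12 − Σ(t³−t)/(12(N−1))) ·
    (1/n_i + 1/n_j)), two-sided p from the standard normal, optionally
    Bonferroni-adjusted over the number of pairs.
    """
    if adjustment not in ("none", "bonferroni"):
        raise ValueError("adjustment must be 'none' or 'bonferroni'")
    arrays = sample.group_arrays()
    n_total = len(sample.values)
    ranks = rankdata(sample.values)
    labels = np.asarray(sample.groups, dtype=object)
    mean_ranks = {g: ranks[labels == g].mean() for g in arrays}
    ns = {g: (labels == g).sum() for g in arrays}
    _, counts = np.unique(sample.values, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts))
    var_base = n_total * (n_total + 1) / 12.0 - tie_term / (12.0 * (n_total - 1))
    if var_base <= 0:
        raise ValueError("degenerate rank variance (all values tied)")
    pairs = list(combinations(arrays, 2))
    m = len(pairs)
    rows = []
    for g1, g2 in pairs:
        se = np.sqrt(var_base * (1.0 / ns[g1] + 1.0 / ns[g2]))
        z = (mean_ranks[g1] - mean_ranks[g2]) / se
        p = 2.0 * norm.sf(abs(z))
        if adjustment == "bonferroni":
            p = min(1.0, m * p)
        rows.append({"group1": g1, "group2": g2, "z": float(z), "p_value": float(p)})
    return pd.DataFrame(rows)


@dataclass
class AnovaResult:
    f: float
    df_between: int
    df_within: int
    p_value: float
    pairwise: pd.DataFrame | None = None


def anova_oneway(sample: GroupedSample, posthoc: str | None = None) -> AnovaResult:
    """One-way ANOVA by the standard sum-of-squares decomposition.

    F = MSB/MSW with df (k−1, N−k). With ``posthoc="bonferroni"``,
    pairwise two-sample t tests using the pooled within-group variance
    are reported with Bonferroni-adjusted p-values.
    """
    arrays = sample.group_arrays()
    k = len(arrays)
    n_total = len(sample.values)
    grand = sample.values.mean()
    ssb = sum(len(a) * (a.mean() - grand) ** 2 for a in arrays.values())
    ssw = sum(((a - a.mean()) ** 2).sum() for a in arrays.values())
    df_b, df_w = k - 1, n_total - k
    if df_w <= 0 or ssw == 0:
        raise ValueError("zero within-group variance")
    msb, msw = ssb / df_b, ssw / df_w
    f = msb / msw
    result = AnovaResult(
        f=float(f), df_between=df_b, df_within=df_w,
        p_value=float(f_dist.sf(f, df_b, df_w)),
    )
    if posthoc == "bonferroni":
        pairs = list(combinations(arrays, 2))
        m = len(pairs)
        rows = []
        for g1, g2 in pairs:
            a, b = arrays[g1], arrays[g2]
            se = np.sqrt(msw * (1.0 / len(a) + 1.0 / len(b)))
            t = (a.mean() - b.mean()) / se
            p = min(1.0, m * 2.0 * t_dist.sf(abs(t), df_w))
            rows.append(
                {"group1": g1, "group2": g2, "t": float(t), "p_value": float(p)}
            )
        result.pairwise = pd.DataFrame(rows)
    elif posthoc is not None:
        raise ValueError("posthoc must be None or 'bonferroni'")
    return result
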