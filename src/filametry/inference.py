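"""Tie-adjusted Kruskal-Wallis omnibus test and Dunn's post hoc pairs.

Dose-response panels (one strain x compound, doses 0/10/50/100/200 µM) are
compared nonparametrically: f-measure distributions are skewed and group
sizes unequal, so rank methods are the appropriate omnibus tool.

Kruskal-Wallis statistic on pooled mid-ranks, with the tie correction:

    H = [ 12 / (N (N+1)) * sum_i n_i (Rbar_i - (N+1)/2)^2 ]
        / [ 1 - sum_t (t^3 - t) / (N^3 - N) ]

referred to chi-square with k - 1 degrees of freedom.

Dunn's pairwise comparison of groups i, j on the same pooled mid-ranks:

    z = (Rbar_i - Rbar_j) / se,
    se = sqrt[ ( N (N+1)/12 - sum_t (t^3 - t) / (12 (N-1)) )
               * (1/n_i + 1/n_j) ],

with two-sided standard-normal p-values and Bonferroni adjustment
p_adj = min(1, p * k(k-1)/2). Rows are ordered lower concentration first
and the difference is Rbar_low - Rbar_high, so induced filamentation at
higher doses shows up as negative test statistics. A Holm step-down
adjustment is available for users who find plain Bonferroni too
conservative.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .outliers import screen_table

__all__ = [
    "KWResult",
    "DunnRow",
    "midranks",
    "tie_term",
    "kruskal_wallis",
    "dunn_pairwise",
    "dose_response_report",
]


@dataclass(frozen=True)
class KWResult:
    """Kruskal-Wallis omnibus result for one panel."""

    total_n: int
    chi2: float
    df: int
    p: float

    def __post_init__(self):
        if self.chi2 < 0 or not (0 <= self.p <= 1):
            raise ValueError("invalid test result")


@dataclass(frozen=True)
class DunnRow:
    """One Dunn pairwise comparison (lower concentration listed first)."""

    pair: tuple[float, float]
    rank_mean_diff: float
    se: float
    z: float
    p: float
    p_adj: float


def midranks(values: Sequence[float]) -> np.ndarray:
    """Mid-ranks of a pooled sample: ties share the average of the ranks
    they span; the ranks always sum to N(N+1)/2 exactly."""
    return stats.rankdata(np.asarray(values, dtype=float), method="average")


def tie_term(values: Sequence[float]) -> float:
    """sum over tie groups of (t^3 - t), on the pooled sample."""
    _, counts = np.unique(np.asarray(values, dtype=float), return_counts=True)
    t = counts.astype(float)
    return float(np.sum(t**3 - t))


def _check_groups(groups: Sequence[Sequence[float]]) -> list[np.ndarray]:
    gs = [np.asarray(g, dtype=float) for g in groups]
    if len(gs) < 2:
        raise ValueError("need at least 2 groups")
    if any(len(g) == 0 for g in gs):
        raise ValueError("every group needs at least one value")
    if sum(len(g) for g in gs) < 3:
        raise ValueError("need total N >= 3")
    return gs


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> KWResult:
    """Tie-adjusted Kruskal-Wallis test across k independent groups.

    Raises on fully degenerate input (all values identical), where the tie
    correction denominator vanishes.
    """
    gs = _check_groups(groups)
    pooled = np.concatenate(gs)
    n_total = len(pooled)
    ranks = midranks(pooled)
    correction = 1.0 - tie_term(pooled) / (n_total**3 - n_total)
    if correction <= 0:
        raise ValueError("degenerate: no variation (all values identical)")

    h = 0.0
    start = 0
    expected = (n_total + 1) / 2.0
    for g in gs:
        r_mean = ranks[start : start + len(g)].mean()
        h += len(g) * (r_mean - expected) ** 2
        start += len(g)
    h *= 12.0 / (n_total * (n_total + 1))
    h /= correction
    df = len(gs) - 1
    p = float(stats.chi2.sf(h, df))
    return KWResult(total_n=n_total, chi2=float(h), df=df, p=p)


def _adjust(pvals: np.ndarray, method: str) -> np.ndarray:
    m = len(pvals)
    if method == "none":
        return pvals.copy()
    if method == "bonferroni":
        return np.minimum(1.0, pvals * m)
    if method == "holm":
        order = np.argsort(pvals)
        adj = np.empty(m)
        running = 0.0
        for rank, idx in enumerate(order):
            running = max(running, (m - rank) * pvals[idx])
            adj[idx] = min(1.0, running)
        return adj
    raise ValueError(f"unknown adjustment {method!r}")


def dunn_pairwise(
    groups: Sequence[Sequence[float]],
    labels: Sequence[float] | None = None,
    adjust: str = "bonferroni",
) -> list[DunnRow]:
    """Dunn's post hoc comparisons on pooled mid-ranks, tie-adjusted.

    ``labels`` (e.g. concentrations) name the groups and fix the row
    order: pairs are emitted with the lower label first and
    rank_mean_diff = Rbar_low - Rbar_high. Without labels, group index is
    used. Adjustment: "bonferroni" (default), "holm", or "none".
    """
    gs = _check_groups(groups)
    if labels is None:
        labels = list(range(len(gs)))
    labels = list(labels)
    if len(labels) != len(gs):
        raise ValueError("labels must match the number of groups")

    # sort groups by label so the lower concentration comes first
    order = np.argsort(labels, kind="stable")
    gs = [gs[i] for i in order]
    labels = [labels[i] for i in order]

    pooled = np.concatenate(gs)
    n_total = len(pooled)
    ranks = midranks(pooled)
    ties = tie_term(pooled)

    r_means, sizes = [], []
    start = 0
    for g in gs:
        r_means.append(ranks[start : start + len(g)].mean())
        sizes.append(len(g))
        start += len(g)

    base_var = n_total * (n_total + 1) / 12.0 - ties / (12.0 * (n_total - 1))
    pairs = list(combinations(range(len(gs)), 2))
    rows = []
    pvals = []
    for i, j in pairs:
        diff = r_means[i] - r_means[j]
        se = float(np.sqrt(base_var * (1.0 / sizes[i] + 1.0 / sizes[j])))
        z = diff / se
        p = float(2.0 * stats.norm.sf(abs(z)))
        pvals.append(p)
        rows.append((i, j, diff, se, z, p))
    p_adj = _adjust(np.asarray(pvals), adjust)

    return [
        DunnRow(
            pair=(labels[i], labels[j]),
            rank_mean_diff=float(diff),
            se=se,
            z=float(z),
            p=p,
            p_adj=float(pa),
        )
        for (i, j, diff, se, z, p), pa in zip(rows, p_adj)
    ]


def dunn_table(rows: Sequence[DunnRow]) -> pd.DataFrame:
    """Dunn rows as a DataFrame with a significance flag at alpha = 0.05."""
    return pd.DataFrame(
        [
            {
                "condition_1": r.pair[0],
                "condition_2": r.pair[1],
                "rank_mean_diff": r.rank_mean_diff,
                "se": r.se,
                "z": r.z,
                "p": r.p,
                "p_adj": r.p_adj,
                "significant": r.p < 0.05,
                "significant_adj": r.p_adj < 0.05,
            }
            for r in rows
        ]
    )


def dose_response_report(
    table: pd.DataFrame,
    threshold: float = 3.5,
    adjust: str = "bonferroni",
    value_col: str = "f",
    screen: bool = True,
) -> dict[tuple[str, str], dict]:
    """Omnibus + post hoc inference for every strain x compound panel.

    Applies per-group modified z-score screening (unless ``screen=False``),
    then the tie-adjusted Kruskal-Wallis test and Dunn's pairwise
    comparisons per panel. Returns, per (strain, compound):
    ``{"kw": KWResult, "dunn": DataFrame, "summary": DataFrame}``.
    Panels with fewer than 2 concentrations raise.
    """
    from .outliers import summarize_groups

    results: dict[tuple[str, str], dict] = {}
    for (strain, compound), panel in table.groupby(["strain", "compound"], sort=True):
        concs = np.sort(panel["concentration_uM"].unique())
        if len(concs) < 2:
            raise ValueError(
                f"panel {strain} x {compound} has a single concentration; "
                "dose-response inference needs >= 2"
            )
        summary = summarize_groups(panel, threshold=threshold, value_col=value_col)
        if screen:
            kept, _ = screen_table(panel, threshold=threshold, value_col=value_col)
        else:
            kept = panel
        groups = [
            kept.loc[kept["concentration_uM"] == c, value_col].to_numpy(dtype=float)
            for c in concs
        ]
        kw = kruskal_wallis(groups)
        dunn = dunn_table(dunn_pairwise(groups, labels=list(concs), adjust=adjust))
        results[(strain, compound)] = {"kw": kw, "dunn": dunn, "summary": summary}
    return results
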