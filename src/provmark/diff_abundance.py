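"""Per-taxon differential abundance between provenance groups.

For every taxon at every rank (obtained by aggregating the proportion
table rank by rank) and every unordered pair of groups, a two-sided
Wilcoxon rank-sum test compares per-sample aggregated proportions, with
effect size log2(median ratio).  The resulting table carries exactly the
statistics that color a comparative heat tree; rendering is out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu
from statsmodels.stats.multitest import multipletests

from .core import RANKS, GroupLabels, OtuTable
from .preprocess import aggregate_rank

__all__ = ["WilcoxonResult", "wilcoxon_rank_sum", "tree_differential"]


@dataclass
class WilcoxonResult:
    statistic: float  # Mann-Whitney U for the first sample
    pvalue: float


def wilcoxon_rank_sum(x, y) -> WilcoxonResult:
    """Two-sided Mann-Whitney U test.

    Exact p when the smaller sample has at most 8 observations and there
    are no ties; otherwise the normal approximation with tie correction.
    Two identical constant samples are a full tie: U = nm/2, p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return WilcoxonResult(x.size * y.size / 2.0, 1.0)
    u, p = mannwhitneyu(x, y, alternative="two-sided", method="auto")
    return WilcoxonResult(float(u), float(min(p, 1.0)))


def tree_differential(
    table: OtuTable,
    groups: GroupLabels,
    alpha: float = 0.05,
    bh_correct: bool = False,
    ranks: tuple[str, ...] = RANKS,
) -> pd.DataFrame:
    """Group-pair Wilcoxon comparisons for every taxon at every rank.

    ``table`` must be in proportion mode.  Effect size is
    ``log2(median_A / median_B)``; when either median is zero, ``eps`` (half the
    smallest nonzero proportion in the table) is added to both so zero medians never
    produce infinities.  ``bh_correct`` applies Benjamini-Hochberg across
    all rows before flagging significance; the default flags raw p < alpha.
    """
    if not table.proportions:
        raise ValueError("tree_differential requires a proportion-mode table")
    if len(groups.groups) < 2:
        raise ValueError("need at least 2 groups")
    nonzero = table.counts[table.counts > 0]
    eps = (nonzero.min() / 2.0) if nonzero.size else 1e-12

    group_cols = {
        g: [table.sample_index(s) for s in groups.samples_in(g)]
        for g in groups.groups
    }
    records = []
    for rank in ranks:
        agg = aggregate_rank(table, rank)
        for i, taxon in enumerate(agg.otu_ids):
            row = agg.counts[i]
            for ga, gb in combinations(groups.groups, 2):
                a, b = row[group_cols[ga]], row[group_cols[gb]]
                res = wilcoxon_rank_sum(a, b)
                med_a, med_b = float(np.median(a)), float(np.median(b))
                # eps enters only when a median is zero, keeping swap antisymmetry
                if med_a == 0.0 or med_b == 0.0:
                    ratio = (med_a + eps) / (med_b + eps)
                else:
                    ratio = med_a / med_b
                records.append(
                    {
                        "taxon": taxon,
                        "rank": rank,
                        "lineage": agg.lineages[i].to_string(),
                        "group_a": ga,
                        "group_b": gb,
                        "median_a": med_a,
                        "median_b": med_b,
                        "log2_ratio": float(np.log2(ratio)),
                        "u": res.statistic,
                        "p": res.pvalue,
                    }
                )
    df = pd.DataFrame.from_records(records)
    if df.empty:
        df["significant"] = []
        return df
    if bh_correct:
        df["p_adj"] = multipletests(df["p"], method="fdr_bh")[1]
        df["significant"] = df["p_adj"] < alpha
    else:
        df["significant"] = df["p"] < alpha
    return df
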