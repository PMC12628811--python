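"""Indicator-species analysis and chained biomarker-panel selection.

Each OTU's association with a provenance group is the point-biserial
correlation: the Pearson correlation between its per-sample relative
abundance and the 0/1 membership indicator of the group.  An OTU is
assigned to the group maximizing r, and is a *candidate* for that group
when a one-sided label-permutation test gives p <= alpha.

Biomarker panels chain two selections: per group, the indicator
candidates are intersected with the classifier's cumulative-importance
OTU list, ordered by model importance, and truncated to the top k
(default 5).  Panel suitability is assessed by Kruskal-Wallis contrasts
of relative abundance across groups with a compact letter display built
from pairwise tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import NamedTuple

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .core import GroupLabels, OtuTable
from .diversity import kruskal_wallis

__all__ = [
    "PointBiserial",
    "IndicatorResult",
    "BiomarkerPanel",
    "point_biserial",
    "permutation_p",
    "indicator_analysis",
    "chain_select",
    "assess_suitability",
    "compact_letter_display",
]


class PointBiserial(NamedTuple):
    r: float
    degenerate: bool  # zero-variance abundance: r defined as 0


def _standardize(v: np.ndarray) -> tuple[np.ndarray, bool]:
    v = np.asarray(v, dtype=float)
    sd = v.std()
    if sd == 0:
        return np.zeros_like(v), True
    return (v - v.mean()) / sd, False


def point_biserial(abundance, membership) -> PointBiserial:
    """Point-biserial correlation: Pearson r with a 0/1 group indicator."""
    a = np.asarray(abundance, dtype=float)
    m = np.asarray(membership, dtype=float)
    if a.shape != m.shape or a.size < 2:
        raise ValueError("need equal-length vectors of at least 2 samples")
    if not (m > 0).any() or not (m == 0).any():
        raise ValueError("both membership classes must be non-empty")
    za, degen_a = _standardize(a)
    zm, _ = _standardize(m)
    if degen_a:
        return PointBiserial(0.0, True)
    return PointBiserial(float(np.mean(za * zm)), False)


def _weighted_point_biserial(a: np.ndarray, m: np.ndarray, w: np.ndarray) -> float:
    """Group-size-equalized ('r.g'-style) variant: weighted Pearson r with
    weights giving each group equal total mass."""
    wsum = w.sum()
    ma, mm = (w * a).sum() / wsum, (w * m).sum() / wsum
    cov = (w * (a - ma) * (m - mm)).sum()
    va = (w * (a - ma) ** 2).sum()
    vm = (w * (m - mm) ** 2).sum()
    if va == 0 or vm == 0:
        return 0.0
    return float(cov / np.sqrt(va * vm))


def permutation_p(
    abundance,
    membership,
    n_perm: int = 999,
    seed: int | None = None,
    exact: bool = False,
) -> float:
    """One-sided permutation p-value for the point-biserial association.

    Labels are permuted across samples.  Monte Carlo:
    ``p = (1 + #{r_perm >= r_obs}) / (1 + n_perm)``.  With ``exact=True``
    all distinct membership arrangements are enumerated and
    ``p = #{r_perm >= r_obs} / #arrangements`` (the observed arrangement
    counts itself).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    a = np.asarray(abundance, dtype=float)
    m = np.asarray(membership, dtype=float)
    r_obs = point_biserial(a, m).r
    za, degen = _standardize(a)
    n = a.size
    k = int((m > 0).sum())
    if exact:
        count = total = 0
        for combo in combinations(range(n), k):
            perm = np.zeros(n)
            perm[list(combo)] = 1.0
            zm, _ = _standardize(perm)
            r = 0.0 if degen else float(np.mean(za * zm))
            total += 1
            if r >= r_obs - 1e-12:
                count += 1
        return count / total
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        zm, _ = _standardize(rng.permutation(m))
        r = 0.0 if degen else float(np.mean(za * zm))
        if r >= r_obs - 1e-12:
            count += 1
    return (1 + count) / (1 + n_perm)


@dataclass
class IndicatorResult:
    """Per-OTU group assignment with permutation significance.

    ``table`` columns: otu_id, group (argmax-r group), r, p, candidate.
    ``candidates`` maps each group to its candidate OTU list; every OTU
    appears in at most one list.
    """

    table: pd.DataFrame
    candidates: dict[str, list[str]]
    alpha: float
    n_perm: int


def indicator_analysis(
    table: OtuTable,
    groups: GroupLabels,
    alpha: float = 0.05,
    n_perm: int = 999,
    seed: int = 0,
    equalize_groups: bool = False,
    bh_correct: bool = False,
) -> IndicatorResult:
    """Point-biserial indicator analysis of every OTU against every group.

    Each OTU is assigned to the single group maximizing r (no group
    combinations), and its permutation p is computed for that membership.
    ``equalize_groups`` switches to the group-size-corrected correlation;
    ``bh_correct`` applies Benjamini-Hochberg across OTUs before the
    candidate cut at ``alpha``.
    """
    if len(groups.groups) < 2:
        raise ValueError("need at least 2 groups")
    groups.validate_against(table)
    x = table.counts.T.astype(float)  # samples x OTUs
    n, p = x.shape
    labels = groups.labels_for(table.sample_ids)

    sd = x.std(axis=0)
    degen = sd == 0
    zx = np.zeros_like(x)
    nz = ~degen
    zx[:, nz] = (x[:, nz] - x[:, nz].mean(axis=0)) / sd[nz]

    memberships = np.stack(
        [(labels == g).astype(float) for g in groups.groups], axis=1
    )  # n x k
    if equalize_groups:
        r_matrix = np.empty((p, len(groups.groups)))
        for gi, g in enumerate(groups.groups):
            m = memberships[:, gi]
            w = np.where(m > 0, 1.0 / m.sum(), 1.0 / (n - m.sum()))
            for oi in range(p):
                r_matrix[oi, gi] = _weighted_point_biserial(x[:, oi], m, w)
    else:
        zm = np.stack([_standardize(memberships[:, gi])[0] for gi in range(len(groups.groups))], axis=1)
        r_matrix = zx.T @ zm / n  # OTUs x groups

    best = r_matrix.argmax(axis=1)
    r_best = r_matrix[np.arange(p), best]

    # shared label permutations, vectorized per group over all OTUs
    rng = np.random.default_rng(seed)
    perms = np.stack([rng.permutation(n) for _ in range(n_perm)], axis=1)  # n x n_perm
    pvals = np.empty(p)
    for gi, g in enumerate(groups.groups):
        rows = np.flatnonzero(best == gi)
        if rows.size == 0:
            continue
        if equalize_groups:
            m = memberships[:, gi]
            w = np.where(m > 0, 1.0 / m.sum(), 1.0 / (n - m.sum()))
            exceed = np.zeros(rows.size, dtype=int)
            for t in range(n_perm):
                mp = m[perms[:, t]]
                wp = w[perms[:, t]]
                for ri, oi in enumerate(rows):
                    if _weighted_point_biserial(x[:, oi], mp, wp) >= r_matrix[oi, gi] - 1e-12:
                        exceed[ri] += 1
            pvals[rows] = (1 + exceed) / (1 + n_perm)
        else:
            zm_perm = np.stack(
                [_standardize(memberships[perms[:, t], gi])[0] for t in range(n_perm)],
                axis=1,
            )  # n x n_perm
            r_perm = zx[:, rows].T @ zm_perm / n  # rows x n_perm
            exceed = (r_perm >= (r_best[rows][:, None] - 1e-12)).sum(axis=1)
            pvals[rows] = (1 + exceed) / (1 + n_perm)
    pvals[degen] = 1.0

    df = pd.DataFrame(
        {
            "otu_id": table.otu_ids,
            "group": [groups.groups[b] for b in best],
            "r": r_best,
            "p": pvals,
        }
    )
    pcol = "p"
    if bh_correct:
        df["p_adj"] = multipletests(df["p"], method="fdr_bh")[1]
        pcol = "p_adj"
    df["candidate"] = df[pcol] <= alpha
    candidates = {
        g: df.loc[(df["group"] == g) & df["candidate"], "otu_id"].tolist()
        for g in groups.groups
    }
    return IndicatorResult(df, candidates, alpha, n_perm)


# ---------------------------------------------------------------------------
# panel selection and suitability
# ---------------------------------------------------------------------------

@dataclass
class BiomarkerPanel:
    """Per-group ranked biomarker OTUs with optional suitability statistics."""

    members: dict[str, list[str]]  # group -> OTU ids ordered by model importance
    detail: pd.DataFrame  # otu_id, group, importance_rank, r, p
    k: int
    warnings: list[str] = field(default_factory=list)
    suitability: pd.DataFrame | None = None  # filled by assess_suitability


def chain_select(
    indicators: IndicatorResult, important: list[str], k: int = 5
) -> BiomarkerPanel:
    """Intersect per-group indicator candidates with the importance list.

    ``important`` must be ordered by model importance descending.  Each
    group's panel is its candidates restricted to ``important``, ordered by
    importance rank and truncated to ``k`` members.
    """
    if k < 0:
        raise ValueError("k must be non-negative")
    rank = {o: i for i, o in enumerate(important)}
    members: dict[str, list[str]] = {}
    notes: list[str] = []
    rows = []
    itab = indicators.table.set_index("otu_id")
    for group, cands in indicators.candidates.items():
        kept = sorted((o for o in cands if o in rank), key=rank.__getitem__)[:k]
        members[group] = kept
        if not kept and k > 0:
            notes.append(
                f"group {group!r}: no indicator candidate is among the important "
                "OTUs; provenance falls back to exclusion against other panels"
            )
        for o in kept:
            rows.append(
                {
                    "otu_id": o,
                    "group": group,
                    "importance_rank": rank[o],
                    "r": float(itab.loc[o, "r"]),
                    "p": float(itab.loc[o, "p"]),
                }
            )
    for msg in notes:
        warnings.warn(msg)
    detail = pd.DataFrame(rows, columns=["otu_id", "group", "importance_rank", "r", "p"])
    return BiomarkerPanel(members=members, detail=detail, k=k, warnings=notes)


def compact_letter_display(
    group_names: list[str], significant_pairs: set[tuple[str, str]]
) -> dict[str, str]:
    """Assign letters so two groups share a letter iff their pairwise
    comparison is non-significant (insert-and-absorb algorithm)."""
    columns: list[set[str]] = [set(group_names)]
    for a, b in significant_pairs:
        new_cols: list[set[str]] = []
        for col in columns:
            if a in col and b in col:
                new_cols.append(col - {a})
                new_cols.append(col - {b})
            else:
                new_cols.append(col)
        # absorb: drop any column that is a proper subset of another, dedupe
        columns = []
        for col in new_cols:
            if any(col < other for other in new_cols):
                continue
            if col not in columns:
                columns.append(col)
    letters = "abcdefghijklmnopqrstuvwxyz"
    out = {g: "" for g in group_names}
    for i, col in enumerate(columns):
        for g in group_names:
            if g in col:
                out[g] += letters[i % len(letters)]
    return out


def assess_suitability(
    table: OtuTable,
    groups: GroupLabels,
    panel: BiomarkerPanel,
    alpha: float = 0.05,
) -> BiomarkerPanel:
    """Fill per-member and cumulative abundance statistics into a panel.

    For every panel member and for the per-sample sum of each group's
    panel ('cumulative'): a Kruskal-Wallis test across all groups, per-group
    mean relative abundance (%), a compact letter display from pairwise
    two-group rank tests at ``alpha``, and a 'discriminating' flag set when
    the home group's letters are disjoint from every other group's.
    """
    if not table.proportions:
        raise ValueError("suitability assessment requires a proportion-mode table")
    rows = []
    for group, otus in panel.members.items():
        targets: list[tuple[str, np.ndarray]] = []
        for o in otus:
            targets.append((o, table.counts[table.otu_index(o), :]))
        if otus:
            cum = np.sum(
                [table.counts[table.otu_index(o), :] for o in otus], axis=0
            )
            targets.append(("cumulative", cum))
        for name, values in targets:
            series = dict(zip(table.sample_ids, values))
            kw = kruskal_wallis(series, groups)
            sig_pairs = set()
            for a, b in combinations(groups.groups, 2):
                pair = kruskal_wallis(series, groups, use_groups=[a, b])
                if pair.pvalue < alpha:
                    sig_pairs.add((a, b))
            letters = compact_letter_display(groups.groups, sig_pairs)
            home = set(letters[group])
            discriminating = all(
                home.isdisjoint(set(letters[g])) for g in groups.groups if g != group
            ) and bool(home)
            row = {
                "otu_id": name,
                "group": group,
                "kw_h": kw.statistic,
                "kw_p": kw.pvalue,
                "discriminating": discriminating,
            }
            for g in groups.groups:
                gvals = [series[s] for s in groups.samples_in(g)]
                row[f"mean_pct_{g}"] = float(np.mean(gvals)) * 100.0
                row[f"letters_{g}"] = letters[g]
            rows.append(row)
    panel.suitability = pd.DataFrame(rows)
    return panel
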