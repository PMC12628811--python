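"""Alpha diversity, Jaccard beta diversity, PCoA, clustering and group tests.

Alpha indices follow the usual estimator definitions:

* observed richness ``S_obs`` = number of OTUs with count > 0;
* Chao1 (bias-corrected) = ``S_obs + F1(F1-1) / (2(F2+1))`` with ``F1``,
  ``F2`` the singleton and doubleton counts;
* ACE with the standard rare/abundant cutoff of 10 and the coefficient of
  variation term floored at zero;
* Shannon ``H = -sum p_i ln p_i`` (natural log);
* Pielou ``J = H / ln S_obs`` (undefined, reported as NaN, when S_obs < 2).

Beta diversity is Jaccard dissimilarity on presence/absence, ordinated by
classical metric scaling (PCoA) and clustered by average-linkage (UPGMA).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from math import comb, log

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage, to_tree
from scipy.spatial.distance import pdist, squareform
from scipy.stats import rankdata
from scipy.stats import kruskal as _scipy_kruskal

from .core import GroupLabels, OtuTable

__all__ = [
    "DistanceMatrix",
    "Ordination",
    "Dendrogram",
    "KruskalWallisResult",
    "alpha_profile",
    "jaccard_matrix",
    "pcoa",
    "upgma_cluster",
    "kruskal_wallis",
]

ACE_RARE_CUTOFF = 10


# ---------------------------------------------------------------------------
# alpha diversity
# ---------------------------------------------------------------------------

def _chao1(counts: np.ndarray, bias_corrected: bool = True) -> float:
    s_obs = int((counts > 0).sum())
    f1 = int((counts == 1).sum())
    f2 = int((counts == 2).sum())
    if not bias_corrected and f2 > 0:
        return s_obs + f1 * f1 / (2 * f2)
    return s_obs + f1 * (f1 - 1) / (2 * (f2 + 1))


def _ace(counts: np.ndarray, rare_cutoff: int = ACE_RARE_CUTOFF) -> float:
    counts = counts[counts > 0]
    rare = counts[counts <= rare_cutoff]
    s_abund = int((counts > rare_cutoff).sum())
    s_rare = len(rare)
    if s_rare == 0:
        return float(s_abund)
    n_rare = int(rare.sum())
    f1 = int((rare == 1).sum())
    c_ace = 1.0 - f1 / n_rare
    if c_ace == 0.0:
        return float("nan")  # all rare taxa are singletons: estimator undefined
    fi = np.bincount(rare.astype(int), minlength=rare_cutoff + 1)
    sum_term = sum(i * (i - 1) * fi[i] for i in range(1, rare_cutoff + 1))
    if n_rare > 1:
        gamma2 = max(s_rare / c_ace * sum_term / (n_rare * (n_rare - 1)) - 1.0, 0.0)
    else:
        gamma2 = 0.0
    return s_abund + s_rare / c_ace + f1 / c_ace * gamma2


def _shannon(counts: np.ndarray) -> float:
    p = counts[counts > 0].astype(float)
    p /= p.sum()
    return float(-(p * np.log(p)).sum())


def alpha_profile(table: OtuTable, bias_corrected_chao1: bool = True) -> pd.DataFrame:
    """Per-sample alpha-diversity profile.

    Returns a DataFrame indexed by sample id with columns ``s_obs``,
    ``chao1``, ``ace``, ``shannon`` and ``pielou``.  Undefined values
    (Pielou with a single observed OTU, ACE when all rare taxa are
    singletons) are NaN.
    """
    if table.proportions:
        raise ValueError("alpha diversity requires a count-mode table")
    if np.any(table.depths() == 0):
        bad = table.sample_ids[int(np.argmin(table.depths()))]
        raise ValueError(f"sample {bad!r} has zero depth")
    rows = []
    for j, sid in enumerate(table.sample_ids):
        c = table.counts[:, j]
        s_obs = int((c > 0).sum())
        h = _shannon(c)
        j_even = h / log(s_obs) if s_obs >= 2 else float("nan")
        rows.append(
            {
                "s_obs": s_obs,
                "chao1": _chao1(c, bias_corrected_chao1),
                "ace": _ace(c),
                "shannon": h,
                "pielou": j_even,
            }
        )
    return pd.DataFrame(rows, index=pd.Index(table.sample_ids, name="sample_id"))


# ---------------------------------------------------------------------------
# beta diversity
# ---------------------------------------------------------------------------

@dataclass
class DistanceMatrix:
    sample_ids: list[str]
    matrix: np.ndarray

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        n = len(self.sample_ids)
        if self.matrix.shape != (n, n):
            raise ValueError("distance matrix shape mismatch")
        if not np.allclose(self.matrix, self.matrix.T, atol=1e-12):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.abs(np.diag(self.matrix)) > 1e-12) or self.matrix.min() < -1e-12:
            raise ValueError("distances must be non-negative with zero diagonal")

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.sample_ids, columns=self.sample_ids)


def jaccard_matrix(table: OtuTable) -> DistanceMatrix:
    """Jaccard dissimilarity between samples on presence/absence.

    ``d(a,b) = 1 - |Pa & Pb| / |Pa | Pb|``; a pair of samples with no
    observed OTUs at all is assigned distance 0.
    """
    if table.n_samples < 2:
        raise ValueError("need at least 2 samples")
    presence = (table.counts > 0).T  # samples x OTUs
    d = pdist(presence, metric="jaccard")  # scipy defines empty-vs-empty as 0
    return DistanceMatrix(list(table.sample_ids), squareform(d))


@dataclass
class Ordination:
    """PCoA result: sample coordinates on axes sorted by eigenvalue."""

    sample_ids: list[str]
    coordinates: np.ndarray  # samples x positive axes
    eigenvalues: np.ndarray  # all eigenvalues, descending
    proportion_explained: np.ndarray  # per positive axis

    def to_dataframe(self) -> pd.DataFrame:
        cols = [f"PCo{i + 1}" for i in range(self.coordinates.shape[1])]
        return pd.DataFrame(self.coordinates, index=self.sample_ids, columns=cols)


def pcoa(dist: DistanceMatrix) -> Ordination:
    """Classical metric scaling of a distance matrix.

    Double-centers ``-D**2 / 2``, eigendecomposes, and keeps axes with
    positive eigenvalues; coordinates are eigenvectors scaled by the square
    root of their eigenvalue, and each axis explains ``lambda_k / sum of
    positive lambda`` of the variance.
    """
    d = dist.matrix
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d ** 2) @ j
    eigval, eigvec = np.linalg.eigh((b + b.T) / 2)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    tol = 1e-10 * max(abs(eigval).max(), 1.0)
    pos = eigval > tol
    if not pos.any():
        warnings.warn("all eigenvalues are zero; no coordinates produced")
        return Ordination(
            list(dist.sample_ids),
            np.zeros((n, 0)),
            eigval,
            np.zeros(0),
        )
    coords = eigvec[:, pos] * np.sqrt(eigval[pos])
    props = eigval[pos] / eigval[pos].sum()
    return Ordination(list(dist.sample_ids), coords, eigval, props)


@dataclass
class Dendrogram:
    """Agglomerative clustering result (scipy linkage encoding)."""

    sample_ids: list[str]
    linkage_matrix: np.ndarray

    def merge_heights(self) -> np.ndarray:
        return self.linkage_matrix[:, 2]

    def to_newick(self) -> str:
        tree = to_tree(self.linkage_matrix)

        def fmt(node, parent_height):
            length = parent_height - node.dist
            if node.is_leaf():
                return f"{self.sample_ids[node.id]}:{length:.10g}"
            inner = ",".join(fmt(c, node.dist) for c in (node.left, node.right))
            return f"({inner}):{length:.10g}"

        inner = ",".join(fmt(c, tree.dist) for c in (tree.left, tree.right))
        return f"({inner});"


def upgma_cluster(dist: DistanceMatrix, method: str = "average") -> Dendrogram:
    """Hierarchical clustering of a distance matrix (UPGMA by default)."""
    if len(dist.sample_ids) < 2:
        raise ValueError("need at least 2 samples")
    if method not in ("average", "complete", "single"):
        raise ValueError(f"unsupported linkage {method!r}")
    z = linkage(squareform(dist.matrix, checks=False), method=method)
    return Dendrogram(list(dist.sample_ids), z)


# ---------------------------------------------------------------------------
# Kruskal-Wallis
# ---------------------------------------------------------------------------

@dataclass
class KruskalWallisResult:
    statistic: float
    df: int
    pvalue: float
    method: str


def _tie_corrected_h(ranks: np.ndarray, group_slices: list[np.ndarray], n: int,
                     tie_term: float) -> float:
    s = sum(ranks[idx].sum() ** 2 / len(idx) for idx in group_slices)
    h = 12.0 / (n * (n + 1)) * s - 3 * (n + 1)
    return h / tie_term if tie_term > 0 else 0.0


def _assignments(sizes: list[int]):
    """Yield all partitions of range(n) into groups of the given sizes."""
    n = sum(sizes)

    def rec(remaining: tuple[int, ...], sizes_left: list[int]):
        if len(sizes_left) == 1:
            yield [np.array(remaining)]
            return
        k = sizes_left[0]
        for combo in combinations(remaining, k):
            rest = tuple(x for x in remaining if x not in set(combo))
            for tail in rec(rest, sizes_left[1:]):
                yield [np.array(combo)] + tail

    yield from rec(tuple(range(n)), sizes)


def kruskal_wallis(
    values,
    groups: GroupLabels,
    method: str = "asymptotic",
    use_groups: list[str] | None = None,
    max_exhaustive: int = 500_000,
    n_perm: int = 9999,
    seed: int | None = None,
) -> KruskalWallisResult:
    """Kruskal-Wallis H test of a per-sample quantity across groups.

    ``values`` is a mapping / pandas Series keyed by sample id.  The
    default p-value is the tie-corrected chi-square approximation with
    ``k - 1`` degrees of freedom; ``method='permutation'`` instead compares
    H against the label-permutation distribution (exhaustive when the
    number of distinct assignments is at most ``max_exhaustive``, Monte
    Carlo otherwise).  Restrict to two groups via ``use_groups`` for
    pairwise use.
    """
    if isinstance(values, pd.Series):
        values = values.to_dict()
    names = use_groups if use_groups is not None else groups.groups
    if len(names) < 2:
        raise ValueError("need at least 2 groups")
    samples_by_group = []
    for g in names:
        sids = [s for s in groups.samples_in(g) if s in values]
        if len(sids) < 2:
            raise ValueError(f"group {g!r} has fewer than 2 observations")
        samples_by_group.append([values[s] for s in sids])
    pooled = np.concatenate([np.asarray(v, dtype=float) for v in samples_by_group])
    for g, v in zip(names, samples_by_group):
        if np.any(np.isnan(v)):
            raise ValueError(f"group {g!r} contains missing observations")
    if np.all(pooled == pooled[0]):
        df = len(names) - 1
        return KruskalWallisResult(0.0, df, 1.0, method)

    df = len(names) - 1
    if method == "asymptotic":
        h, p = _scipy_kruskal(*samples_by_group)
        return KruskalWallisResult(float(h), df, float(p), method)
    if method != "permutation":
        raise ValueError(f"unknown method {method!r}")

    sizes = [len(v) for v in samples_by_group]
    n = sum(sizes)
    ranks = rankdata(pooled)
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = 1.0 - (tie_counts ** 3 - tie_counts).sum() / (n ** 3 - n)
    bounds = np.cumsum([0] + sizes)
    obs_slices = [np.arange(bounds[i], bounds[i + 1]) for i in range(len(sizes))]
    h_obs = _tie_corrected_h(ranks, obs_slices, n, tie_term)

    n_total = 1
    rem = n
    for k in sizes[:-1]:
        n_total *= comb(rem, k)
        rem -= k
    if n_total <= max_exhaustive:
        count = sum(
            _tie_corrected_h(ranks, parts, n, tie_term) >= h_obs - 1e-12
            for parts in _assignments(sizes)
        )
        return KruskalWallisResult(h_obs, df, count / n_total, "permutation-exhaustive")
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        parts = [perm[bounds[i]:bounds[i + 1]] for i in range(len(sizes))]
        if _tie_corrected_h(ranks, parts, n, tie_term) >= h_obs - 1e-12:
            count += 1
    return KruskalWallisResult(h_obs, df, (1 + count) / (1 + n_perm), "permutation-mc")
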