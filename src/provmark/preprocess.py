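"""Filtering, normalization, rarefaction and rank aggregation.

The filtering rules mirror standard microbiome preprocessing for
classifier and diversity work on read-classification OTU tables:

* prevalence — keep an OTU only if it is present (count > 0) in strictly
  more than a fraction of samples (default 25%);
* low count — drop OTUs whose total count across samples is below a
  floor (default 5); a per-sample-maximum variant is available;
* lineage — optionally keep only OTUs with a complete 7-rank lineage.

Each rule is row-local given the fixed sample set, so the retained OTU
set does not depend on the order the rules run in; the report still
attributes removals to stages in the order prevalence -> low count ->
lineage.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .core import RANKS, Lineage, OtuTable

__all__ = [
    "FilterReport",
    "apply_filters",
    "to_relative_abundance",
    "rarefy",
    "aggregate_rank",
]


@dataclass
class FilterReport:
    """Per-stage removal accounting for :func:`apply_filters`."""

    stages: list[dict] = field(default_factory=list)
    emptied: bool = False

    def add(self, rule: str, removed: int, retained: int) -> None:
        self.stages.append({"rule": rule, "removed": removed, "retained": retained})

    def to_json(self) -> str:
        return json.dumps(
            {"stages": self.stages, "emptied": self.emptied}, indent=2
        )


def apply_filters(
    table: OtuTable,
    min_prevalence_fraction: float = 0.25,
    min_total_count: int = 5,
    require_complete_lineage: bool = False,
    low_count_mode: str = "total",
) -> tuple[OtuTable, FilterReport]:
    """Apply prevalence, low-count and lineage filters to a count table.

    Prevalence is strict: an OTU present in exactly
    ``min_prevalence_fraction`` of samples is removed.  The low-count rule
    keeps OTUs with total count >= ``min_total_count`` (``low_count_mode=
    'total'``) or per-sample maximum >= the floor (``'per_sample_max'``).
    Returns the filtered table and a per-stage :class:`FilterReport`.
    """
    if table.proportions:
        raise ValueError("filters operate on count-mode tables")
    if table.n_otus == 0 or table.n_samples == 0:
        raise ValueError("cannot filter an empty table")
    if low_count_mode not in ("total", "per_sample_max"):
        raise ValueError(f"unknown low_count_mode {low_count_mode!r}")

    report = FilterReport()
    present = table.counts > 0
    prevalence_ok = present.sum(axis=1) > min_prevalence_fraction * table.n_samples
    if low_count_mode == "total":
        count_ok = table.counts.sum(axis=1) >= min_total_count
    else:
        count_ok = table.counts.max(axis=1) >= min_total_count
    lineage_ok = (
        np.array([lin.is_complete for lin in table.lineages])
        if require_complete_lineage
        else np.ones(table.n_otus, dtype=bool)
    )

    keep = prevalence_ok.copy()
    report.add("prevalence", int((~keep).sum()), int(keep.sum()))
    before = int(keep.sum())
    keep &= count_ok
    report.add("low_count", before - int(keep.sum()), int(keep.sum()))
    before = int(keep.sum())
    keep &= lineage_ok
    report.add("lineage", before - int(keep.sum()), int(keep.sum()))

    out = table.select_otus(keep)
    report.emptied = out.n_otus == 0
    return out, report


def to_relative_abundance(table: OtuTable) -> OtuTable:
    """Total-sum scaling: convert counts to per-sample proportions."""
    if table.proportions:
        return table.copy()
    depths = table.depths()
    if np.any(depths == 0):
        bad = table.sample_ids[int(np.argmin(depths))]
        raise ValueError(f"sample {bad!r} has zero total count")
    props = table.counts / depths[np.newaxis, :]
    return OtuTable(
        otu_ids=list(table.otu_ids),
        lineages=list(table.lineages),
        counts=props,
        sample_ids=list(table.sample_ids),
        proportions=True,
    )


def rarefy(table: OtuTable, depth: int, seed: int) -> OtuTable:
    """Subsample every sample without replacement to exactly ``depth`` reads."""
    if table.proportions:
        raise ValueError("rarefaction operates on count-mode tables")
    depths = table.depths()
    if np.any(depths < depth):
        bad = table.sample_ids[int(np.argmin(depths))]
        raise ValueError(
            f"depth {depth} exceeds total count of sample {bad!r} ({int(depths.min())})"
        )
    rng = np.random.default_rng(seed)
    out = np.empty_like(table.counts)
    for j in range(table.n_samples):
        out[:, j] = rng.multivariate_hypergeometric(table.counts[:, j], depth)
    return OtuTable(
        otu_ids=list(table.otu_ids),
        lineages=list(table.lineages),
        counts=out,
        sample_ids=list(table.sample_ids),
    )


def aggregate_rank(table: OtuTable, rank: str) -> OtuTable:
    """Sum rows sharing the same label at ``rank``.

    OTUs with an empty slot at that rank are pooled into an ``unassigned``
    row, so total counts are conserved.  Aggregated lineages keep the ranks
    down to ``rank`` (taken from the first member) and blank the deeper ones.
    """
    if rank not in RANKS:
        raise ValueError(f"unknown rank {rank!r}; expected one of {RANKS}")
    ridx = RANKS.index(rank)
    labels: list[str] = []
    lineages: list[Lineage] = []
    rows: dict[str, np.ndarray] = {}
    for i, lin in enumerate(table.lineages):
        label = lin.ranks[ridx]
        key = label if label else "unassigned"
        if key not in rows:
            labels.append(key)
            rows[key] = np.zeros(table.n_samples, dtype=table.counts.dtype)
            if label:
                lineages.append(Lineage(lin.ranks[: ridx + 1] + ("",) * (6 - ridx)))
            else:
                lineages.append(Lineage.empty())
        rows[key] = rows[key] + table.counts[i]
    if "unassigned" in rows:  # keep the pool last for readability
        k = labels.index("unassigned")
        labels.append(labels.pop(k))
        lineages.append(lineages.pop(k))
    counts = np.stack([rows[k] for k in labels]) if labels else np.zeros((0, table.n_samples))
    return OtuTable(
        otu_ids=labels,
        lineages=lineages,
        counts=counts,
        sample_ids=list(table.sample_ids),
        proportions=table.proportions,
    )
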