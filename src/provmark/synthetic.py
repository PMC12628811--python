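"""Synthetic gut-bacteriome OTU tables with planted provenance markers.

The generator emulates the statistical shape of a post-classification
OTU count table from a multi-site fish cohort: four provenance groups of
30 samples, a couple thousand background OTUs with complete 7-rank
lineages, a heavy-tailed base composition in which one phylum dominates
(>90% of reads), log-normally uneven sequencing depths around 40,000
reads, and a small disjoint set of group-specific marker OTUs whose
relative abundance is multiplied by a known fold change (default 8) in
exactly one group.

The planted truth is returned alongside the table so that the full
pipeline (filters -> normalization -> classifier -> indicators -> panel
selection) can be scored for marker recovery.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import log

import numpy as np

from .core import Lineage, OtuTable, GroupLabels

__all__ = ["SyntheticSpec", "GroundTruth", "simulate", "recovery_score"]

_DEFAULT_GROUPS = ("Center-North", "Center", "Center-South", "South")


@dataclass
class SyntheticSpec:
    """Parameters of the simulated cohort (defaults = study-like conditions)."""

    n_groups: int = 4
    samples_per_group: int = 30
    n_background_otus: int = 2000
    n_markers_per_group: int = 5
    marker_fold_change: float = 8.0
    depth_log_mean: float = log(40_000)
    depth_log_sd: float = 0.4
    theta: float = 0.5  # symmetric Dirichlet concentration of the base composition
    phylum_skew: float = 0.9  # fraction of mass carried by the top phylum
    overdispersion: float = 0.0  # >0: per-sample Dirichlet resampling, larger = milder
    incomplete_lineage_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.n_groups < 2 or self.samples_per_group < 1:
            raise ValueError("need >= 2 groups with >= 1 sample each")
        if self.n_background_otus < 1:
            raise ValueError("need at least one background OTU")
        if self.marker_fold_change < 1:
            raise ValueError("marker fold change must be >= 1")
        if not 0 < self.phylum_skew < 1:
            raise ValueError("phylum_skew must be in (0, 1)")
        if self.n_groups * self.n_markers_per_group > self.n_background_otus:
            raise ValueError("more markers requested than background OTUs")
        if not 0 <= self.incomplete_lineage_fraction <= 1:
            raise ValueError("incomplete_lineage_fraction must be in [0, 1]")


@dataclass
class GroundTruth:
    """Planted marker OTU ids per group (disjoint across groups)."""

    markers: dict[str, list[str]]
    fold_change: float
    base_proportions: dict[str, float] = field(default_factory=dict)

    def all_markers(self) -> set[str]:
        return {o for lst in self.markers.values() for o in lst}


def _synth_lineages(n: int, rng: np.random.Generator,
                    incomplete_fraction: float) -> tuple[list[Lineage], np.ndarray]:
    """Random 7-rank lineages over a nested taxonomy; returns lineages and
    the per-OTU phylum index (0 = the designated dominant phylum)."""
    n_phyla = 15
    # heavy-tailed phylum assignment so one phylum holds the most OTUs
    w = 1.0 / (np.arange(1, n_phyla + 1) ** 1.5)
    phylum_idx = rng.choice(n_phyla, size=n, p=w / w.sum())
    lineages = []
    incomplete = rng.random(n) < incomplete_fraction
    for i in range(n):
        p = int(phylum_idx[i])
        c = int(rng.integers(1, 4))
        o = int(rng.integers(1, 4))
        f = int(rng.integers(1, 5))
        g = int(rng.integers(1, 6))
        ranks = (
            "Bacteria",
            f"Phylum_{p:02d}",
            f"Class_{p:02d}_{c}",
            f"Order_{p:02d}_{c}_{o}",
            f"Family_{p:02d}_{c}_{o}_{f}",
            "" if incomplete[i] else f"Genus_{p:02d}_{c}_{o}_{f}_{g}",
            f"Species_{i:05d}",
        )
        lineages.append(Lineage(ranks))
    return lineages, phylum_idx


def simulate(spec: SyntheticSpec) -> tuple[OtuTable, GroupLabels, GroundTruth]:
    """Draw one synthetic cohort; byte-identical under the same spec."""
    rng = np.random.default_rng(spec.seed)
    n_otus = spec.n_background_otus

    lineages, phylum_idx = _synth_lineages(
        n_otus, rng, spec.incomplete_lineage_fraction
    )
    # base composition: symmetric Dirichlet, then reweighted so the dominant
    # phylum's OTUs carry phylum_skew of the mass
    gam = rng.gamma(spec.theta, 1.0, size=n_otus)
    base = gam / gam.sum()
    top = phylum_idx == 0
    if top.any() and (~top).any():
        base[top] *= spec.phylum_skew / base[top].sum()
        base[~top] *= (1.0 - spec.phylum_skew) / base[~top].sum()

    otu_ids = [f"OTU_{i:05d}" for i in range(n_otus)]
    group_names = (
        list(_DEFAULT_GROUPS)
        if spec.n_groups == len(_DEFAULT_GROUPS)
        else [f"Group-{i + 1}" for i in range(spec.n_groups)]
    )

    # plant markers in distinct mid-abundance OTUs (base-proportion quantiles
    # 0.5-0.9) so prevalence/low-count filters never remove them
    qlo, qhi = np.quantile(base, [0.5, 0.9])
    pool = np.flatnonzero((base >= qlo) & (base <= qhi))
    chosen = rng.choice(pool, size=spec.n_groups * spec.n_markers_per_group,
                        replace=False)
    markers = {
        g: sorted(otu_ids[i] for i in chosen[gi * spec.n_markers_per_group:
                                             (gi + 1) * spec.n_markers_per_group])
        for gi, g in enumerate(group_names)
    }
    marker_rows = {
        g: np.array([otu_ids.index(o) for o in markers[g]]) for g in group_names
    }

    group_comps = {}
    for g in group_names:
        comp = base.copy()
        comp[marker_rows[g]] *= spec.marker_fold_change
        group_comps[g] = comp / comp.sum()

    sample_ids: list[str] = []
    mapping: dict[str, str] = {}
    counts = np.zeros((n_otus, spec.n_groups * spec.samples_per_group),
                      dtype=np.int64)
    col = 0
    for g in group_names:
        for rep in range(spec.samples_per_group):
            sid = f"{g}_{rep + 1:02d}"
            sample_ids.append(sid)
            mapping[sid] = g
            depth = max(1, int(round(rng.lognormal(spec.depth_log_mean,
                                                   spec.depth_log_sd))))
            comp = group_comps[g]
            if spec.overdispersion > 0:
                comp = rng.dirichlet(comp * spec.overdispersion)
            counts[:, col] = rng.multinomial(depth, comp)
            col += 1

    table = OtuTable(otu_ids, lineages, counts, sample_ids)
    labels = GroupLabels(mapping, group_names)
    truth = GroundTruth(
        markers=markers,
        fold_change=spec.marker_fold_change,
        base_proportions={otu_ids[i]: float(base[i]) for i in chosen},
    )
    return table, labels, truth


def recovery_score(panel, truth: GroundTruth) -> float:
    """Fraction of planted markers recovered in their home group's panel.

    ``panel`` may be a BiomarkerPanel or a plain group -> OTU-list mapping.
    """
    panel_members = getattr(panel, "members", panel)
    total = sum(len(v) for v in truth.markers.values())
    if total == 0:
        return 0.0
    hits = sum(
        sum(1 for o in truth.markers[g] if o in set(panel_members.get(g, [])))
        for g in truth.markers
    )
    return hits / total
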