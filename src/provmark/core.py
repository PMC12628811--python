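"""Core domain types and I/O for OTU count tables.

The central object is :class:`OtuTable`: a dense non-negative matrix of
read counts (OTUs x samples) where every row carries a 7-rank taxonomic
lineage.  An OTU here is any taxonomic-rank assignment emitted by a read
classifier, so a single table mixes phylum-, genus- and species-level
rows.  Tables can be read from plain TSV or assembled from standard
Kraken2-style report files (one per sample); sample-to-group metadata is
a two-column TSV.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "RANKS",
    "Lineage",
    "OtuTable",
    "GroupLabels",
    "read_otu_table",
    "write_otu_table",
    "read_kraken2_reports",
    "read_metadata",
    "write_metadata",
]

#: The seven fixed taxonomic ranks, outermost first.
RANKS = ("kingdom", "phylum", "class", "order", "family", "genus", "species")

_PREFIX_RE = re.compile(r"^[a-zA-Z]__")


@dataclass(frozen=True)
class Lineage:
    """A 7-slot taxonomic lineage; any slot may be empty ('')."""

    ranks: tuple[str, ...]

    def __post_init__(self):
        if len(self.ranks) != len(RANKS):
            raise ValueError(
                f"lineage must have exactly {len(RANKS)} ranks, got {len(self.ranks)}"
            )

    @property
    def is_complete(self) -> bool:
        return all(r != "" for r in self.ranks)

    def at(self, rank: str) -> str:
        return self.ranks[RANKS.index(rank)]

    @classmethod
    def empty(cls) -> "Lineage":
        return cls(("",) * len(RANKS))

    @classmethod
    def from_string(cls, s: str, strip_prefixes: bool = False) -> "Lineage":
        """Parse a semicolon-separated lineage string.

        Fewer than 7 fields are right-padded with empty ranks; with
        ``strip_prefixes`` leading ``k__``/``p__``-style markers are removed.
        """
        parts = [p.strip() for p in s.split(";")] if s else []
        if len(parts) > len(RANKS):
            raise ValueError(f"lineage has more than {len(RANKS)} ranks: {s!r}")
        if strip_prefixes:
            parts = [_PREFIX_RE.sub("", p) for p in parts]
        parts += [""] * (len(RANKS) - len(parts))
        return cls(tuple(parts))

    def to_string(self) -> str:
        return ";".join(self.ranks)


@dataclass
class OtuTable:
    """Dense OTU x sample table with per-row lineages.

    ``proportions`` marks a normalized table whose columns each sum to 1;
    otherwise entries are non-negative integer read counts.
    """

    otu_ids: list[str]
    lineages: list[Lineage]
    counts: np.ndarray
    sample_ids: list[str]
    proportions: bool = False

    def __post_init__(self):
        self.otu_ids = list(self.otu_ids)
        self.sample_ids = list(self.sample_ids)
        self.lineages = list(self.lineages)
        self.counts = np.asarray(self.counts)
        if len(set(self.otu_ids)) != len(self.otu_ids):
            dupes = sorted({x for x in self.otu_ids if self.otu_ids.count(x) > 1})
            raise ValueError(f"duplicate OTU ids: {dupes[:5]}")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample ids")
        if self.counts.shape != (len(self.otu_ids), len(self.sample_ids)):
            raise ValueError(
                f"counts shape {self.counts.shape} does not match "
                f"({len(self.otu_ids)}, {len(self.sample_ids)})"
            )
        if len(self.lineages) != len(self.otu_ids):
            raise ValueError("one lineage required per OTU")
        if self.counts.size and self.counts.min() < 0:
            raise ValueError("negative entries in count matrix")
        if self.proportions:
            self.counts = self.counts.astype(float)
            if self.n_otus and self.n_samples:
                sums = self.counts.sum(axis=0)
                if not np.allclose(sums, 1.0, atol=1e-9):
                    raise ValueError("proportion-mode columns must sum to 1")
        else:
            if self.counts.size and not np.all(np.equal(np.mod(self.counts, 1), 0)):
                raise ValueError("count-mode entries must be integral")
            self.counts = self.counts.astype(np.int64)

    # -- basic accessors -------------------------------------------------
    @property
    def n_otus(self) -> int:
        return len(self.otu_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def depths(self) -> np.ndarray:
        """Per-sample totals (read depth in count mode)."""
        return self.counts.sum(axis=0)

    def sample_index(self, sample_id: str) -> int:
        return self.sample_ids.index(sample_id)

    def otu_index(self, otu_id: str) -> int:
        return self.otu_ids.index(otu_id)

    def select_otus(self, keep: np.ndarray) -> "OtuTable":
        """Row subset by boolean mask or integer index array."""
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        return OtuTable(
            otu_ids=[self.otu_ids[i] for i in keep],
            lineages=[self.lineages[i] for i in keep],
            counts=self.counts[keep, :],
            sample_ids=self.sample_ids,
            proportions=self.proportions,
        )

    def select_samples(self, sample_ids: list[str]) -> "OtuTable":
        idx = [self.sample_index(s) for s in sample_ids]
        return OtuTable(
            otu_ids=list(self.otu_ids),
            lineages=list(self.lineages),
            counts=self.counts[:, idx],
            sample_ids=list(sample_ids),
            proportions=self.proportions,
        )

    def copy(self) -> "OtuTable":
        return replace(self, counts=self.counts.copy())

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.counts, index=self.otu_ids, columns=self.sample_ids)
        df.index.name = "otu_id"
        return df


@dataclass
class GroupLabels:
    """Sample id -> provenance group, with groups in first-appearance order."""

    mapping: dict[str, str]
    groups: list[str] = field(default_factory=list)

    def __post_init__(self):
        if not self.groups:
            seen: list[str] = []
            for g in self.mapping.values():
                if g not in seen:
                    seen.append(g)
            self.groups = seen
        missing = set(self.mapping.values()) - set(self.groups)
        if missing:
            raise ValueError(f"groups {missing} missing from group list")

    def labels_for(self, sample_ids: list[str]) -> np.ndarray:
        try:
            return np.array([self.mapping[s] for s in sample_ids], dtype=object)
        except KeyError as e:
            raise KeyError(f"sample {e.args[0]!r} has no group label") from None

    def samples_in(self, group: str) -> list[str]:
        return [s for s, g in self.mapping.items() if g == group]

    def validate_against(self, table: OtuTable, min_groups: int = 2,
                         min_per_group: int = 2) -> None:
        """Check labels cover table samples and group sizes allow statistics."""
        extra = set(self.mapping) - set(table.sample_ids)
        if extra:
            raise ValueError(f"labeled samples not in table: {sorted(extra)[:5]}")
        if len(self.groups) < min_groups:
            raise ValueError(f"need at least {min_groups} groups")
        for g in self.groups:
            if len(self.samples_in(g)) < min_per_group:
                raise ValueError(f"group {g!r} has fewer than {min_per_group} samples")


# ---------------------------------------------------------------------------
# TSV input / output
# ---------------------------------------------------------------------------

def read_otu_table(path, dialect: str = "plain", proportions: bool = False) -> OtuTable:
    """Read an OTU table from TSV.

    Layout: an ``otu_id`` column, an optional ``taxonomy`` column holding a
    semicolon-separated lineage, and one numeric column per sample.
    ``dialect='prefixed'`` strips ``k__``-style rank prefixes from lineages.
    """
    if dialect not in ("plain", "prefixed"):
        raise ValueError(f"unknown dialect {dialect!r}")
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if df.columns[0] != "otu_id":
        raise ValueError("first column must be 'otu_id'")
    otu_ids = df["otu_id"].tolist()
    if len(set(otu_ids)) != len(otu_ids):
        dupes = df["otu_id"][df["otu_id"].duplicated()].unique().tolist()
        raise ValueError(f"duplicate OTU ids in {path}: {dupes[:5]}")
    has_tax = len(df.columns) > 1 and df.columns[1] == "taxonomy"
    if has_tax:
        lineages = [
            Lineage.from_string(s, strip_prefixes=(dialect == "prefixed"))
            for s in df["taxonomy"]
        ]
        sample_cols = list(df.columns[2:])
    else:
        lineages = [Lineage.empty() for _ in otu_ids]
        sample_cols = list(df.columns[1:])
    if not sample_cols:
        raise ValueError("table has no sample columns")
    counts = np.empty((len(otu_ids), len(sample_cols)), dtype=float)
    for j, col in enumerate(sample_cols):
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any():
            row = int(vals.index[vals.isna()][0])
            raise ValueError(
                f"non-numeric count at row {row + 2} (OTU {otu_ids[row]!r}), "
                f"column {col!r}"
            )
        counts[:, j] = vals.to_numpy()
    if counts.size and counts.min() < 0:
        i, j = np.unravel_index(int(np.argmin(counts)), counts.shape)
        raise ValueError(
            f"negative count for OTU {otu_ids[i]!r} in sample {sample_cols[j]!r}"
        )
    if not proportions and counts.size and not np.all(np.mod(counts, 1) == 0):
        i, j = map(int, next(zip(*np.nonzero(np.mod(counts, 1)))))
        raise ValueError(
            f"non-integer count for OTU {otu_ids[i]!r} in sample {sample_cols[j]!r}"
        )
    return OtuTable(otu_ids, lineages, counts, sample_cols, proportions=proportions)


def write_otu_table(table: OtuTable, path) -> None:
    """Write a table as TSV (``otu_id``, ``taxonomy``, one column per sample)."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("otu_id\ttaxonomy\t" + "\t".join(table.sample_ids) + "\n")
        for i, oid in enumerate(table.otu_ids):
            row = table.counts[i]
            if table.proportions:
                cells = [format(float(v), ".17g") for v in row]
            else:
                cells = [str(int(v)) for v in row]
            fh.write(f"{oid}\t{table.lineages[i].to_string()}\t" + "\t".join(cells) + "\n")


def read_metadata(path) -> GroupLabels:
    """Read sample->group metadata from a two-column TSV (header optional)."""
    mapping: dict[str, str] = {}
    groups: list[str] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path}: line {lineno}: expected 2 columns")
            sid, grp = parts[0].strip(), parts[1].strip()
            if lineno == 1 and (sid, grp) == ("sample_id", "group"):
                continue
            if not grp:
                raise ValueError(f"{path}: line {lineno}: empty group name")
            if sid in mapping and mapping[sid] != grp:
                raise ValueError(
                    f"{path}: sample {sid!r} assigned to both "
                    f"{mapping[sid]!r} and {grp!r}"
                )
            mapping[sid] = grp
            if grp not in groups:
                groups.append(grp)
    return GroupLabels(mapping, groups)


def write_metadata(labels: GroupLabels, path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("sample_id\tgroup\n")
        for sid, grp in labels.mapping.items():
            fh.write(f"{sid}\t{grp}\n")


# ---------------------------------------------------------------------------
# Kraken2-style report ingestion
# ---------------------------------------------------------------------------

# rank-code letter -> lineage slot index ('D' covers domain-as-kingdom)
_RANK_SLOT = {"D": 0, "K": 0, "P": 1, "C": 2, "O": 3, "F": 4, "G": 5, "S": 6}


def _parse_report(path):
    """Yield (taxid, name, rank_code, count, lineage) per ranked taxon line."""
    stack: list[tuple[int, str, str]] = []  # (indent depth, base code, name)
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 6:
                raise ValueError(f"{path}: line {lineno}: expected 6 tab-separated columns")
            _, _, taxon_count, rank_code, taxid, raw_name = parts[:6]
            try:
                count = int(taxon_count)
                taxid = int(taxid)
            except ValueError:
                raise ValueError(f"{path}: line {lineno}: malformed counts/taxid") from None
            name = raw_name.lstrip(" ")
            depth = (len(raw_name) - len(name)) // 2
            base = rank_code[0] if rank_code else ""
            while stack and stack[-1][0] >= depth:
                stack.pop()
            stack.append((depth, rank_code, name))
            if base == "U" or not base:
                continue
            slots = [""] * len(RANKS)
            for _, code, nm in stack:
                if code in _RANK_SLOT:  # base codes only; sub-ranks don't overwrite
                    slots[_RANK_SLOT[code]] = nm
            yield taxid, name, rank_code, count, Lineage(tuple(slots))


def read_kraken2_reports(paths, sample_ids, rank_whitelist=None) -> OtuTable:
    """Assemble one OtuTable from per-sample Kraken2-style reports.

    Every ranked taxon line becomes its own OTU (identified by taxid);
    unclassified ('U') lines are dropped.  ``rank_whitelist`` optionally
    restricts to a set of rank codes (e.g. ``{'P','G','S'}``; matching is on
    the full code so sub-ranks like ``S1`` are distinct).
    """
    paths = list(paths)
    sample_ids = list(sample_ids)
    if len(paths) != len(sample_ids):
        raise ValueError(
            f"{len(paths)} report paths but {len(sample_ids)} sample ids"
        )
    if len(set(sample_ids)) != len(sample_ids):
        raise ValueError("duplicate sample ids")
    info: dict[int, tuple[str, Lineage]] = {}
    per_sample: list[dict[int, int]] = []
    order: list[int] = []
    for path in paths:
        col: dict[int, int] = {}
        for taxid, name, code, count, lineage in _parse_report(path):
            if rank_whitelist is not None and code not in rank_whitelist:
                continue
            if taxid not in info:
                info[taxid] = (name, lineage)
                order.append(taxid)
            col[taxid] = col.get(taxid, 0) + count
        per_sample.append(col)
    order = sorted(order)  # canonical row order: by taxid
    counts = np.zeros((len(order), len(sample_ids)), dtype=np.int64)
    row_of = {t: i for i, t in enumerate(order)}
    for j, col in enumerate(per_sample):
        for taxid, c in col.items():
            counts[row_of[taxid], j] = c
    return OtuTable(
        otu_ids=[str(t) for t in order],
        lineages=[info[t][1] for t in order],
        counts=counts,
        sample_ids=sample_ids,
    )
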