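#!/usr/bin/env python
"""Per-taxon differential abundance between group pairs at every rank.

Wilcoxon rank-sum tests on rank-aggregated relative abundances with
log2 median-ratio effect sizes — the statistics that would color a
comparative heat tree.
"""

import argparse
from pathlib import Path

from provmark import read_metadata, read_otu_table, tree_differential


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--results", type=Path, default=Path("results"))
    ap.add_argument("--alpha", type=float, default=0.05)
    args = ap.parse_args()

    props = read_otu_table(args.results / "proportions.tsv", proportions=True)
    labels = read_metadata(args.results / "data" / "metadata.tsv")
    df = tree_differential(props, labels, alpha=args.alpha)
    df.to_csv(args.results / "diff_abundance.tsv", sep="\t", index=False,
              lineterminator="\n")
    print(f"{len(df)} taxon x group-pair records, "
          f"{int(df['significant'].sum())} significant at p < {args.alpha}")
    by_rank = df[df["significant"]].groupby("rank", sort=False).size()
    for rank, n in by_rank.items():
        print(f"  {rank}: {n}")


if __name__ == "__main__":
    main()
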