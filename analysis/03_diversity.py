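#!/usr/bin/env python
"""Alpha and beta diversity of the filtered cohort.

Per-sample Chao1, ACE, Shannon and Pielou indices with Kruskal-Wallis
contrasts across provenance groups; Jaccard dissimilarities ordinated by
PCoA and clustered by UPGMA.
"""

import argparse
from itertools import combinations
from pathlib import Path

import pandas as pd

from provmark import (
    alpha_profile,
    jaccard_matrix,
    kruskal_wallis,
    pcoa,
    read_metadata,
    read_otu_table,
    upgma_cluster,
)


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--results", type=Path, default=Path("results"))
    args = ap.parse_args()

    table = read_otu_table(args.results / "filtered_table.tsv")
    labels = read_metadata(args.results / "data" / "metadata.tsv")

    profile = alpha_profile(table)
    profile.to_csv(args.results / "alpha_diversity.tsv", sep="\t",
                   lineterminator="\n")
    rows = []
    for index in profile.columns:
        vals = profile[index].dropna()
        res = kruskal_wallis(vals, labels)
        rows.append({"index": index, "scope": "omnibus", "H": res.statistic,
                     "df": res.df, "p": res.pvalue})
        print(f"{index}: H = {res.statistic:.3f}, p = {res.pvalue:.3g}")
        for a, b in combinations(labels.groups, 2):
            pair = kruskal_wallis(vals, labels, use_groups=[a, b])
            rows.append({"index": index, "scope": f"{a}|{b}",
                         "H": pair.statistic, "df": pair.df, "p": pair.pvalue})
    pd.DataFrame(rows).to_csv(args.results / "alpha_kruskal.tsv", sep="\t",
                              index=False, lineterminator="\n")

    dm = jaccard_matrix(table)
    dm.to_dataframe().to_csv(args.results / "jaccard.tsv", sep="\t",
                             lineterminator="\n")
    ordn = pcoa(dm)
    ordn.to_dataframe().to_csv(args.results / "pcoa.tsv", sep="\t",
                               lineterminator="\n")
    two = 100 * ordn.proportion_explained[:2]
    print(f"PCoA: first two axes explain {two.sum():.1f}% "
          f"(PCo1 {two[0]:.2f}%, PCo2 {two[1]:.2f}%)")
    dendro = upgma_cluster(dm)
    (args.results / "cluster.nwk").write_text(dendro.to_newick() + "\n")


if __name__ == "__main__":
    main()
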