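#!/usr/bin/env python
"""Chained biomarker-panel selection and suitability assessment.

Point-biserial indicator analysis assigns each OTU to the group it is
most associated with (permutation-tested); per group the significant
candidates are intersected with the classifier's cumulative-importance
OTUs and the top five become the provenance panel.  Panel members and
each panel's cumulative abundance are contrasted across groups by
Kruskal-Wallis with compact letter displays, and — since the cohort is
synthetic — the panels are scored against the planted truth.
"""

import argparse
import json
from pathlib import Path

from provmark import (
    GroundTruth,
    assess_suitability,
    chain_select,
    indicator_analysis,
    read_metadata,
    read_otu_table,
    recovery_score,
)
from provmark.pipeline import derive_seed


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--results", type=Path, default=Path("results"))
    ap.add_argument("--alpha", type=float, default=0.05)
    ap.add_argument("--n-perm", type=int, default=999)
    ap.add_argument("--k", type=int, default=5)
    args = ap.parse_args()

    props = read_otu_table(args.results / "proportions.tsv", proportions=True)
    labels = read_metadata(args.results / "data" / "metadata.tsv")
    important = json.loads((args.results / "important_otus.json").read_text())

    ind = indicator_analysis(props, labels, alpha=args.alpha, n_perm=args.n_perm,
                             seed=derive_seed(args.seed, "indicators"))
    ind.table.to_csv(args.results / "indicators.tsv", sep="\t", index=False,
                     lineterminator="\n")
    print("indicator candidates per group:",
          {g: len(v) for g, v in ind.candidates.items()})

    panel = chain_select(ind, important, k=args.k)
    panel = assess_suitability(props, labels, panel, alpha=args.alpha)
    (args.results / "panel.json").write_text(
        json.dumps({"members": panel.members, "k": args.k,
                    "warnings": panel.warnings}, indent=2, sort_keys=True) + "\n")
    panel.suitability.to_csv(args.results / "suitability.tsv", sep="\t",
                             index=False, lineterminator="\n")
    for g, members in panel.members.items():
        print(f"{g} panel: {', '.join(members) if members else '(empty)'}")

    truth_doc = json.loads((args.results / "data" / "truth.json").read_text())
    truth = GroundTruth(markers=truth_doc["markers"],
                        fold_change=truth_doc["fold_change"])
    score = recovery_score(panel, truth)
    n_disc = int(panel.suitability["discriminating"].sum())
    print(f"planted-marker recovery: {score:.2f}; "
          f"{n_disc} suitability contrasts fully discriminate the home group")


if __name__ == "__main__":
    main()
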