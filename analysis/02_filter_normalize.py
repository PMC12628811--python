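#!/usr/bin/env python
"""Apply the prevalence / low-count / lineage filters and normalize.

Keeps OTUs present in strictly more than 25% of samples, with total
count at least 5 and a complete 7-rank lineage, then converts the
filtered counts to per-sample relative abundances (total-sum scaling).
"""

import argparse
from pathlib import Path

from provmark import apply_filters, read_otu_table, to_relative_abundance, \
    write_otu_table


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--results", type=Path, default=Path("results"))
    args = ap.parse_args()

    table = read_otu_table(args.results / "data" / "otu_table.tsv")
    filtered, report = apply_filters(table, require_complete_lineage=True)
    props = to_relative_abundance(filtered)
    write_otu_table(filtered, args.results / "filtered_table.tsv")
    write_otu_table(props, args.results / "proportions.tsv")
    (args.results / "filter_report.json").write_text(report.to_json() + "\n")
    print(f"{table.n_otus} OTUs in, {filtered.n_otus} retained:")
    for stage in report.stages:
        print(f"  {stage['rule']}: removed {stage['removed']}, "
              f"retained {stage['retained']}")


if __name__ == "__main__":
    main()
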