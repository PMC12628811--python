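#!/usr/bin/env python
"""Train the provenance classifier and extract important OTUs.

Stratified 70/30 split, multiclass gradient-boosted trees (40 trees,
depth 8, learning rate 0.1, 5-fold CV), train/test confusion matrices,
and the gain-importance ranking with the 80% cumulative cutoff.
"""

import argparse
import json
from pathlib import Path

from provmark import (
    GbmParams,
    confusion,
    fit_gbm,
    predict,
    read_metadata,
    read_otu_table,
    select_cumulative_importance,
    split_train_test,
)
from provmark.pipeline import derive_seed


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--results", type=Path, default=Path("results"))
    ap.add_argument("--importance-threshold", type=float, default=0.80)
    args = ap.parse_args()

    props = read_otu_table(args.results / "proportions.tsv", proportions=True)
    labels = read_metadata(args.results / "data" / "metadata.tsv")
    params = GbmParams(seed=derive_seed(args.seed, "classifier"))
    train_ids, test_ids = split_train_test(props, labels, params)
    model = fit_gbm(props.select_samples(train_ids), labels, params)

    for name, ids in (("train", train_ids), ("test", test_ids)):
        pred, _ = predict(model, props.select_samples(ids))
        summary = confusion(labels.labels_for(ids), pred.to_numpy(), labels.groups)
        summary.matrix.to_csv(args.results / f"confusion_{name}.tsv", sep="\t",
                              lineterminator="\n")
        per_group = ", ".join(
            f"{g} {100 * v:.1f}%" for g, v in summary.per_group_accuracy.items()
        )
        print(f"{name} accuracy: {100 * summary.global_accuracy:.1f}% "
              f"({per_group})")
    print(f"cross-validation mean accuracy: "
          f"{100 * model.cv_summary['mean_accuracy']:.1f}%")

    imp = model.importances.sort_values(ascending=False)
    imp.to_frame().assign(cumulative=imp.cumsum()).to_csv(
        args.results / "importance.tsv", sep="\t", lineterminator="\n")
    important = select_cumulative_importance(model, args.importance_threshold)
    (args.results / "important_otus.json").write_text(
        json.dumps(important, indent=2) + "\n")
    print(f"{len(important)} OTUs reach {args.importance_threshold:.0%} "
          f"cumulative gain importance")


if __name__ == "__main__":
    main()
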