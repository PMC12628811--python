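"""Pipeline orchestration: config, seed fan-out, stage chaining, run report.

A run executes filters -> proportions -> diversity -> differential
abundance -> classifier -> indicators -> panel selection -> suitability
on either a real OTU table + metadata or a synthetic cohort, writing
every stage's tables plus a machine-readable ``report.json`` that records
all effective parameters (including defaults filling unstated choices:
learning rate, alpha, permutation count, linkage) and warnings.  The
same config + seed reproduces every output byte for byte.
"""

from __future__ import annotations

import json
import logging
import warnings as _warnings
import zlib
from itertools import combinations
from pathlib import Path
from typing import Literal, Optional

import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, model_validator

from . import core, diff_abundance, diversity, gbm, indicators, preprocess, synthetic

__all__ = ["PipelineConfig", "run_pipeline", "derive_seed"]

logger = logging.getLogger(__name__)


def derive_seed(seed: int, stage: str) -> int:
    """Stage-specific seed from the global one (splitmix-style mix), < 2^31."""
    z = (seed + 0x9E3779B97F4A7C15 * (1 + zlib.crc32(stage.encode()))) % (1 << 64)
    z = ((z ^ (z >> 30)) * 0xBF58476D1CE4E5B9) % (1 << 64)
    z = ((z ^ (z >> 27)) * 0x94D049BB133111EB) % (1 << 64)
    return (z ^ (z >> 31)) % (1 << 31)


class _Base(BaseModel):
    model_config = ConfigDict(extra="forbid")


class SyntheticConfig(_Base):
    n_groups: int = 4
    samples_per_group: int = 30
    n_background_otus: int = 2000
    n_markers_per_group: int = 5
    marker_fold_change: float = 8.0
    depth_log_mean: float = synthetic.SyntheticSpec.depth_log_mean
    depth_log_sd: float = 0.4
    theta: float = 0.5
    phylum_skew: float = 0.9
    overdispersion: float = 0.0
    incomplete_lineage_fraction: float = 0.0


class InputConfig(_Base):
    synthetic: Optional[SyntheticConfig] = None
    otu_table: Optional[str] = None
    metadata: Optional[str] = None
    dialect: Literal["plain", "prefixed"] = "plain"

    @model_validator(mode="after")
    def _one_source(self):
        if self.synthetic is None and (self.otu_table is None or self.metadata is None):
            raise ValueError("input needs either 'synthetic' or 'otu_table'+'metadata'")
        if self.synthetic is not None and self.otu_table is not None:
            raise ValueError("give either a synthetic spec or file paths, not both")
        return self


class FilterConfig(_Base):
    enabled: bool = True
    min_prevalence_fraction: float = 0.25
    min_total_count: int = 5
    require_complete_lineage: bool = True
    low_count_mode: Literal["total", "per_sample_max"] = "total"


class DiversityConfig(_Base):
    enabled: bool = True
    linkage: Literal["average", "complete", "single"] = "average"


class DiffAbundanceConfig(_Base):
    enabled: bool = True
    alpha: float = 0.05
    bh_correct: bool = False


class ClassifierConfig(_Base):
    enabled: bool = True
    n_trees: int = 40
    max_depth: int = 8
    learning_rate: float = 0.1
    n_folds: int = 5
    score_interval_trees: int = 5
    train_fraction: float = 0.70
    importance_threshold: float = 0.80
    compute_cv: bool = True


class IndicatorConfig(_Base):
    enabled: bool = True
    alpha: float = 0.05
    n_perm: int = 999
    equalize_groups: bool = False
    bh_correct: bool = False


class PanelConfig(_Base):
    k: int = 5


class PipelineConfig(_Base):
    seed: int
    input: InputConfig
    filters: FilterConfig = FilterConfig()
    diversity: DiversityConfig = DiversityConfig()
    diff_abundance: DiffAbundanceConfig = DiffAbundanceConfig()
    classifier: ClassifierConfig = ClassifierConfig()
    indicators: IndicatorConfig = IndicatorConfig()
    panel: PanelConfig = PanelConfig()

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh)
        return cls.model_validate(data)


def _write_df(df, path: Path) -> None:
    df.to_csv(path, sep="\t", lineterminator="\n")


def run_pipeline(config: PipelineConfig | dict | str | Path, out_dir) -> dict:
    """Execute the configured stages; returns the run report (also written
    to ``<out_dir>/report.json``).  Partial outputs survive a stage failure,
    with the report marking the failure point."""
    if isinstance(config, (str, Path)):
        config = PipelineConfig.from_yaml(config)
    elif isinstance(config, dict):
        config = PipelineConfig.model_validate(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    report: dict = {
        "config": json.loads(config.model_dump_json()),
        "stages": {},
        "warnings": [],
        "failed_stage": None,
    }
    seed = config.seed

    def finish() -> dict:
        (out / "report.json").write_text(
            json.dumps(report, indent=2, sort_keys=True) + "\n", encoding="utf-8"
        )
        return report

    try:
        with _warnings.catch_warnings(record=True) as caught:
            _warnings.simplefilter("always")
            result = _run_stages(config, out, seed, report)
        report["warnings"].extend(str(w.message) for w in caught)
        report.update(result)
    except Exception as exc:  # report the failure point, keep partial outputs
        report["failed_stage"] = report.get("_current_stage")
        report["error"] = f"{type(exc).__name__}: {exc}"
        finish()
        raise
    finally:
        report.pop("_current_stage", None)
    return finish()


def _run_stages(config: PipelineConfig, out: Path, seed: int, report: dict) -> dict:
    summary: dict = {}
    report["_current_stage"] = "input"
    inp = config.input
    if inp.synthetic is not None:
        spec = synthetic.SyntheticSpec(
            **inp.synthetic.model_dump(), seed=derive_seed(seed, "simulate")
        )
        table, labels, truth = synthetic.simulate(spec)
        core.write_otu_table(table, out / "otu_table.tsv")
        core.write_metadata(labels, out / "metadata.tsv")
        (out / "truth.json").write_text(
            json.dumps({"markers": truth.markers, "fold_change": truth.fold_change},
                       indent=2, sort_keys=True) + "\n",
            encoding="utf-8",
        )
    else:
        for p in (inp.otu_table, inp.metadata):
            if not Path(p).exists():
                raise FileNotFoundError(f"input file missing: {p}")
        table = core.read_otu_table(inp.otu_table, dialect=inp.dialect)
        labels = core.read_metadata(inp.metadata)
        truth = None
    labels.validate_against(table)
    report["stages"]["input"] = {
        "n_otus": table.n_otus,
        "n_samples": table.n_samples,
        "groups": labels.groups,
    }

    report["_current_stage"] = "filters"
    if config.filters.enabled:
        table, frep = preprocess.apply_filters(
            table,
            min_prevalence_fraction=config.filters.min_prevalence_fraction,
            min_total_count=config.filters.min_total_count,
            require_complete_lineage=config.filters.require_complete_lineage,
            low_count_mode=config.filters.low_count_mode,
        )
        (out / "filter_report.json").write_text(frep.to_json() + "\n", encoding="utf-8")
        core.write_otu_table(table, out / "filtered_table.tsv")
        report["stages"]["filters"] = {"stages": frep.stages, "n_otus": table.n_otus}
    else:
        report["stages"]["filters"] = {"skipped": True, "n_otus": table.n_otus}

    props = preprocess.to_relative_abundance(table)
    core.write_otu_table(props, out / "proportions.tsv")

    if config.diversity.enabled:
        report["_current_stage"] = "diversity"
        profile = diversity.alpha_profile(table)
        _write_df(profile, out / "alpha_diversity.tsv")
        kw_rows = []
        for index in profile.columns:
            vals = profile[index].dropna()
            res = diversity.kruskal_wallis(vals, labels)
            kw_rows.append(
                {"index": index, "H": res.statistic, "df": res.df, "p": res.pvalue}
            )
            for a, b in combinations(labels.groups, 2):
                pair = diversity.kruskal_wallis(vals, labels, use_groups=[a, b])
                kw_rows.append(
                    {"index": f"{index}:{a}|{b}", "H": pair.statistic,
                     "df": pair.df, "p": pair.pvalue}
                )
        _write_df(pd.DataFrame(kw_rows).set_index("index"), out / "alpha_kruskal.tsv")
        dm = diversity.jaccard_matrix(table)
        _write_df(dm.to_dataframe(), out / "jaccard.tsv")
        ord_ = diversity.pcoa(dm)
        odf = ord_.to_dataframe()
        odf.loc["eigenvalue"] = list(ord_.eigenvalues[: odf.shape[1]])
        odf.loc["proportion_explained"] = list(ord_.proportion_explained)
        _write_df(odf, out / "pcoa.tsv")
        dendro = diversity.upgma_cluster(dm, method=config.diversity.linkage)
        (out / "cluster.nwk").write_text(dendro.to_newick() + "\n", encoding="utf-8")
        report["stages"]["diversity"] = {
            "linkage": config.diversity.linkage,
            "pcoa_first_two_pct": [
                round(float(p) * 100, 4) for p in ord_.proportion_explained[:2]
            ],
        }

    if config.diff_abundance.enabled:
        report["_current_stage"] = "diff_abundance"
        da = diff_abundance.tree_differential(
            props, labels,
            alpha=config.diff_abundance.alpha,
            bh_correct=config.diff_abundance.bh_correct,
        )
        da.to_csv(out / "diff_abundance.tsv", sep="\t", index=False,
                  lineterminator="\n")
        report["stages"]["diff_abundance"] = {
            "records": int(len(da)),
            "significant": int(da["significant"].sum()) if len(da) else 0,
        }

    model = None
    important: list[str] = []
    if config.classifier.enabled:
        report["_current_stage"] = "classifier"
        params = gbm.GbmParams(
            n_trees=config.classifier.n_trees,
            max_depth=config.classifier.max_depth,
            learning_rate=config.classifier.learning_rate,
            n_folds=config.classifier.n_folds,
            score_interval_trees=config.classifier.score_interval_trees,
            train_fraction=config.classifier.train_fraction,
            seed=derive_seed(seed, "classifier"),
        )
        train_ids, test_ids = gbm.split_train_test(props, labels, params)
        train_tab = props.select_samples(train_ids)
        test_tab = props.select_samples(test_ids)
        model = gbm.fit_gbm(train_tab, labels, params,
                            compute_cv=config.classifier.compute_cv)
        stats = {}
        for name, tab, ids in (("train", train_tab, train_ids),
                               ("test", test_tab, test_ids)):
            pred, _ = gbm.predict(model, tab)
            conf = gbm.confusion(labels.labels_for(ids), pred.to_numpy(),
                                 labels.groups)
            _write_df(conf.matrix, out / f"confusion_{name}.tsv")
            stats[f"{name}_accuracy"] = conf.global_accuracy
            stats[f"{name}_per_group"] = {
                g: (None if not v == v else v)
                for g, v in conf.per_group_accuracy.items()
            }
        imp = model.importances.sort_values(ascending=False)
        imp.to_frame().assign(cumulative=imp.cumsum()).to_csv(
            out / "importance.tsv", sep="\t", lineterminator="\n"
        )
        important = gbm.select_cumulative_importance(
            model, config.classifier.importance_threshold
        )
        stats["n_important"] = len(important)
        stats["cv"] = model.cv_summary
        stats["deviance_history"] = model.history
        report["stages"]["classifier"] = stats

    if config.indicators.enabled:
        report["_current_stage"] = "indicators"
        ind = indicators.indicator_analysis(
            props, labels,
            alpha=config.indicators.alpha,
            n_perm=config.indicators.n_perm,
            seed=derive_seed(seed, "indicators"),
            equalize_groups=config.indicators.equalize_groups,
            bh_correct=config.indicators.bh_correct,
        )
        ind.table.to_csv(out / "indicators.tsv", sep="\t", index=False,
                         lineterminator="\n")
        report["stages"]["indicators"] = {
            "candidates_per_group": {g: len(v) for g, v in ind.candidates.items()}
        }

        if config.classifier.enabled:
            report["_current_stage"] = "panel"
            panel = indicators.chain_select(ind, important, k=config.panel.k)
            panel = indicators.assess_suitability(
                props, labels, panel, alpha=config.indicators.alpha
            )
            (out / "panel.json").write_text(
                json.dumps({"members": panel.members, "k": panel.k,
                            "warnings": panel.warnings}, indent=2, sort_keys=True)
                + "\n",
                encoding="utf-8",
            )
            panel.suitability.to_csv(out / "suitability.tsv", sep="\t",
                                     index=False, lineterminator="\n")
            stage = {"members": panel.members}
            if truth is not None:
                stage["recovery_score"] = synthetic.recovery_score(panel, truth)
            report["stages"]["panel"] = stage

    report["_current_stage"] = None
    return summary
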