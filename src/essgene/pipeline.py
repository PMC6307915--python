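"""End-to-end orchestration: subsample, pre-process, discretise, select,
train, predict with confidence, evaluate, and summarise.

The run mirrors the workflow of a knockout-phenotype essentiality study:

1. read or synthesise a labelled gene x feature table;
2. drop features missing beyond a threshold, then build repeated
   class-balanced training subsets by majority undersampling;
3. cross-validate each subset and keep the one whose accuracy is closest
   to the mean (a representativeness rule that avoids cherry-picking);
4. impute and ChiMerge-discretise the chosen subset, rank features by
   information gain, and optionally run the GA wrapper search;
5. train the final classifier (random forest by default) on the selected
   features, score the held-out genes with vote-fraction confidence,
   and compare confidences of correct vs incorrect calls;
6. summarise per-chromosome class proportions and interaction-network
   topology when a gene->chromosome map or an edge list is available.

Every stage is seeded from the run seed, so a config + seed pair fully
determines all outputs.
"""

from __future__ import annotations

import dataclasses
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import chimerge, evaluate, netstats, selection, synth, tableio
from .model import ModelSpec, predict_with_confidence, predictions_frame, train_model
from .tableio import ESSENTIAL, FeatureTable


class PipelineError(RuntimeError):
    """A stage failure, tagged with the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """One run's inputs, thresholds and seeds (exactly one input source:
    a synthetic spec, or a table path)."""

    synthetic: synth.SyntheticSpec | None = None
    table_path: str | None = None
    label_column: str = "essentiality"
    edges_path: str | None = None
    chromosome_map_path: str | None = None

    max_missing_fraction: float = 0.30
    n_subsets: int = 10
    significance: float = 0.95
    selection_strategy: str = "info_gain"  # none | info_gain | info_gain_top_k | ga
    top_k: int = 40
    ga_params: selection.GAParams | None = None
    model: ModelSpec = field(default_factory=lambda: ModelSpec("random_forest"))
    cv_folds: int = 10
    seed: int = 0
    out_dir: str | None = None

    def validate(self) -> None:
        sources = [s is not None for s in (self.synthetic, self.table_path)]
        if sum(sources) != 1:
            raise ValueError("exactly one input source (synthetic spec or table path) required")
        for p in (self.table_path, self.edges_path, self.chromosome_map_path):
            if p is not None and not Path(p).exists():
                raise ValueError(f"input path not found: {p}")
        if self.selection_strategy not in ("none", "info_gain", "info_gain_top_k", "ga"):
            raise ValueError(f"unknown selection strategy {self.selection_strategy!r}")


def config_from_yaml(path: str | Path) -> RunConfig:
    """Load a RunConfig from a YAML/JSON mapping; the ``synthetic`` block
    accepts SyntheticSpec fields with per-block dictionaries."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if "synthetic" in raw and raw["synthetic"] is not None:
        sy = dict(raw["synthetic"])
        if "blocks" in sy:
            sy["blocks"] = [synth.FeatureBlock(**b) for b in sy["blocks"]]
        raw["synthetic"] = synth.SyntheticSpec(**sy)
    if "model" in raw and raw["model"] is not None:
        raw["model"] = ModelSpec(**raw["model"])
    if "ga_params" in raw and raw["ga_params"] is not None:
        raw["ga_params"] = selection.GAParams(**raw["ga_params"])
    return RunConfig(**raw)


@dataclass
class ChromosomeSummary:
    """Per-chromosome counts and percentages of the four status x class
    cells, plus the genome-wide essential/non-essential split."""

    table: pd.DataFrame
    unmapped: list[str]
    genome_pct_essential: float
    genome_pct_nonessential: float


def chromosome_distribution(statuses: pd.DataFrame, chrom_map: dict[str, str]) -> ChromosomeSummary:
    """Tabulate (known|predicted) x (essential|non-essential) per
    chromosome.

    ``statuses`` is indexed by gene with columns ``origin`` in
    {known, predicted} and ``class`` in {essential, non-essential}.
    Unmapped genes are reported and excluded.  Each chromosome's
    essential + non-essential percentages sum to 100.
    """
    if len(statuses) == 0:
        raise ValueError("empty status table")
    unmapped = [g for g in statuses.index if g not in chrom_map]
    kept = statuses.loc[[g for g in statuses.index if g in chrom_map]].copy()
    if len(kept) == 0:
        raise ValueError("no genes could be mapped to a chromosome")
    kept["chromosome"] = [chrom_map[g] for g in kept.index]

    cells = ["known_essential", "predicted_essential", "known_non-essential", "predicted_non-essential"]
    rows = {}
    for chrom, sub in kept.groupby("chromosome"):
        counts = {c: 0 for c in cells}
        for _, r in sub.iterrows():
            counts[f"{r['origin']}_{r['class']}"] += 1
        total = len(sub)
        ess = counts["known_essential"] + counts["predicted_essential"]
        row = dict(counts)
        row["total"] = total
        row["pct_essential"] = 100.0 * ess / total
        row["pct_non-essential"] = 100.0 * (total - ess) / total
        rows[chrom] = row
    table = pd.DataFrame.from_dict(rows, orient="index").sort_index()

    ess_all = (kept["class"] == ESSENTIAL).sum()
    return ChromosomeSummary(
        table=table,
        unmapped=unmapped,
        genome_pct_essential=100.0 * ess_all / len(kept),
        genome_pct_nonessential=100.0 * (len(kept) - ess_all) / len(kept),
    )


@dataclass
class ValidationScorecard:
    """Agreement of predictions with an external truth set."""

    n_overlap: int
    n_correct: int
    percent_correct: float
    per_class_percent: dict[str, float]
    mean_confidence_correct: float | None
    mean_confidence_incorrect: float | None
    comparison: evaluate.ConfidenceComparison | None


def validation_scorecard(predictions, external_truth: pd.Series) -> ValidationScorecard:
    """Score predictions against an independently derived truth set
    (e.g. phenotypes from a different mutagenesis methodology)."""
    tableio.validate_labels(external_truth)
    by_gene = {r.gene_id: r for r in predictions}
    overlap = [g for g in external_truth.index if g in by_gene]
    if not overlap:
        raise ValueError("no overlap between predictions and external truth")
    correct_conf, incorrect_conf = [], []
    per_class = {}
    for cls in sorted(external_truth.unique()):
        genes = [g for g in overlap if external_truth[g] == cls]
        if genes:
            n_ok = sum(by_gene[g].predicted_class == external_truth[g] for g in genes)
            per_class[cls] = 100.0 * n_ok / len(genes)
    for g in overlap:
        r = by_gene[g]
        (correct_conf if r.predicted_class == external_truth[g] else incorrect_conf).append(
            r.confidence
        )
    comparison = None
    if len(correct_conf) >= 3 and len(incorrect_conf) >= 3:
        comparison = evaluate.compare_confidences(correct_conf, incorrect_conf)
    n_correct = len(correct_conf)
    return ValidationScorecard(
        n_overlap=len(overlap),
        n_correct=n_correct,
        percent_correct=100.0 * n_correct / len(overlap),
        per_class_percent=per_class,
        mean_confidence_correct=float(np.mean(correct_conf)) if correct_conf else None,
        mean_confidence_incorrect=float(np.mean(incorrect_conf)) if incorrect_conf else None,
        comparison=comparison,
    )


@dataclass
class RunReport:
    config: RunConfig
    subset_cv_accuracies: list[float]
    representative_index: int
    ranking: selection.FeatureRanking
    selected_features: list[str]
    ga_trace: list[float] | None
    holdout_counts: evaluate.ConfusionCounts | None
    holdout_metrics: evaluate.MetricSet | None
    holdout_comparison: evaluate.ConfidenceComparison | None
    predictions: pd.DataFrame
    genome_split: dict[str, float]
    chromosome_summary: ChromosomeSummary | None
    network_summary: netstats.NetworkSummary | None


class _StageLog:
    def __init__(self, out_dir: Path | None):
        self.path = out_dir / "run_log.jsonl" if out_dir else None
        if self.path:
            self.path.write_text("")

    def record(self, stage: str, seed: int | None = None, **params) -> "_Stage":
        return _Stage(self, stage, seed, params)


class _Stage:
    def __init__(self, log: _StageLog, stage: str, seed, params):
        self.log, self.stage, self.seed, self.params = log, stage, seed, params

    def __enter__(self):
        self.t0 = time.monotonic()
        return self

    def __exit__(self, exc_type, exc, tb):
        if self.log.path:
            entry = {
                "stage": self.stage,
                "seed": self.seed,
                "parameters": self.params,
                "duration_s": round(time.monotonic() - self.t0, 3),
                "ok": exc is None,
            }
            with open(self.log.path, "a") as fh:
                fh.write(json.dumps(entry) + "\n")
        if exc is not None and not isinstance(exc, PipelineError):
            raise PipelineError(self.stage, exc) from exc
        return False


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute the full workflow; see the module docstring for the stage
    list.  Deterministic given the config's seeds; artifacts (predictions
    TSV, report JSON, JSONL stage log) are written when ``out_dir`` is
    set."""
    config.validate()
    out_dir = Path(config.out_dir) if config.out_dir else None
    if out_dir:
        out_dir.mkdir(parents=True, exist_ok=True)
    log = _StageLog(out_dir)
    seed = config.seed

    with log.record("load", seed=seed):
        if config.synthetic is not None:
            table, labels, _ = synth.generate_table(config.synthetic)
        else:
            table, labels = tableio.read_feature_table(
                config.table_path, label_column=config.label_column
            )
            if labels is None:
                raise ValueError("input table has no label column")

    with log.record("drop_sparse", max_missing_fraction=config.max_missing_fraction):
        table, dropped = tableio.drop_sparse_features(table, config.max_missing_fraction)

    with log.record("balanced_subsets", seed=seed, n_subsets=config.n_subsets):
        subsets = tableio.balanced_subsets(table, labels, config.n_subsets, seed=seed)

    with log.record("subset_cv", seed=seed, folds=config.cv_folds):
        accs = []
        for i, genes in enumerate(subsets):
            sub = table.subset_genes(genes)
            res = evaluate.cross_validate(
                sub,
                labels.loc[genes],
                config.model,
                k=config.cv_folds,
                seed=seed + i,
                significance=config.significance,
            )
            accs.append(res.pooled_accuracy)
        rep = tableio.choose_representative_subset(accs)

    with log.record("preprocess", subset=rep):
        train_genes = subsets[rep]
        train_raw = table.subset_genes(train_genes)
        imp = tableio.fit_impute(train_raw)
        train_imp = tableio.apply_impute(imp, train_raw)
        train_disc, schemes = chimerge.discretise_table(
            train_imp, labels.loc[train_genes], config.significance
        )

    with log.record("rank_features"):
        ranking = selection.rank_by_information_gain(train_disc, labels.loc[train_genes])
        retained = [f for f, _ in ranking.retained]

    ga_trace = None
    with log.record("select_features", strategy=config.selection_strategy):
        if config.selection_strategy == "none":
            selected = train_disc.features
        elif config.selection_strategy == "info_gain":
            selected = retained
        elif config.selection_strategy == "info_gain_top_k":
            selected = retained[: config.top_k]
        else:  # ga
            ga_params = config.ga_params or selection.GAParams(seed=seed)
            ga = selection.ga_feature_search(
                train_disc.subset_features(retained or train_disc.features),
                labels.loc[train_genes],
                ga_params,
                config.model,
            )
            selected = ga.selected
            ga_trace = ga.trace
        if not selected:
            raise ValueError("feature selection retained no features")

    with log.record("train", seed=seed):
        final = train_model(
            train_disc.subset_features(selected), labels.loc[train_genes], config.model
        )

    holdout_genes = [g for g in table.gene_ids if g not in set(train_genes)]
    holdout_counts = holdout_metrics = holdout_cmp = None
    with log.record("holdout_eval", n=len(holdout_genes)):
        if holdout_genes:
            ho = table.subset_genes(holdout_genes)
            ho = tableio.apply_impute(imp, ho)
            ho = chimerge.apply_schemes(ho, schemes)
            ho_recs = predict_with_confidence(final, ho.subset_features(selected))
            truth = labels.loc[holdout_genes]
            holdout_counts, holdout_metrics = evaluate.confusion_and_metrics(ho_recs, truth)
            ok = [r.confidence for r in ho_recs if r.predicted_class == truth[r.gene_id]]
            bad = [r.confidence for r in ho_recs if r.predicted_class != truth[r.gene_id]]
            if len(ok) >= 3 and len(bad) >= 3:
                holdout_cmp = evaluate.compare_confidences(ok, bad)

    with log.record("predict_all"):
        full = tableio.apply_impute(imp, table)
        full = chimerge.apply_schemes(full, schemes)
        all_recs = predict_with_confidence(final, full.subset_features(selected))
        preds = predictions_frame(all_recs)

    with log.record("genome_split"):
        # known status for training genes, predicted for the rest
        train_set = set(train_genes)
        status_class = [
            labels[g] if g in train_set else preds.loc[g, "predicted_class"]
            for g in table.gene_ids
        ]
        n_ess = sum(c == ESSENTIAL for c in status_class)
        genome_split = {
            "pct_essential": 100.0 * n_ess / table.n_genes,
            "pct_nonessential": 100.0 * (table.n_genes - n_ess) / table.n_genes,
        }
        statuses = pd.DataFrame(
            {
                "origin": ["known" if g in train_set else "predicted" for g in table.gene_ids],
                "class": status_class,
            },
            index=table.gene_ids,
        )

    chrom_summary = None
    if config.chromosome_map_path:
        with log.record("chromosomes"):
            cmap = _read_chromosome_map(config.chromosome_map_path)
            chrom_summary = chromosome_distribution(statuses, cmap)

    net_summary = None
    if config.edges_path:
        with log.record("netstats"):
            graph = netstats.filter_interactions(netstats.read_edge_list(config.edges_path))
            net_summary = netstats.network_summary(graph)

    report = RunReport(
        config=config,
        subset_cv_accuracies=accs,
        representative_index=rep,
        ranking=ranking,
        selected_features=selected,
        ga_trace=ga_trace,
        holdout_counts=holdout_counts,
        holdout_metrics=holdout_metrics,
        holdout_comparison=holdout_cmp,
        predictions=preds,
        genome_split=genome_split,
        chromosome_summary=chrom_summary,
        network_summary=net_summary,
    )
    if out_dir:
        _write_report(report, out_dir)
    return report


def _read_chromosome_map(path: str | Path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return dict(zip(df.iloc[:, 0], df.iloc[:, 1]))


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, pd.DataFrame):
        return json.loads(obj.to_json(orient="index"))
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple, set)):
        return [_jsonable(v) for v in obj]
    return obj


def _write_report(report: RunReport, out_dir: Path) -> None:
    report.predictions.to_csv(out_dir / "predictions.tsv", sep="\t")
    payload = {
        "subset_cv_accuracies": report.subset_cv_accuracies,
        "representative_index": report.representative_index,
        "feature_scores": report.ranking.scores,
        "selected_features": report.selected_features,
        "ga_trace": report.ga_trace,
        "holdout_counts": report.holdout_counts,
        "holdout_metrics": report.holdout_metrics,
        "holdout_comparison": report.holdout_comparison,
        "genome_split": report.genome_split,
        "chromosome_summary": report.chromosome_summary.table if report.chromosome_summary else None,
        "network_summary": report.network_summary,
    }
    (out_dir / "report.json").write_text(json.dumps(_jsonable(payload), indent=1))
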