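"""End-to-end orchestration: ingest/generate -> partition -> feature-cluster
-> train both measure-optimized ensembles -> evaluate (models + meta-models)
-> screen -> rank -> chem-cluster -> select representatives.

Defaults reproduce the reference configuration: four row groups, three
feature-clusters, tie-to-Active majority voting, a 0.35 Tanimoto distance cap
and a 21-compound final selection.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from mcscreen._version import __version__
from mcscreen.chem_clustering import (
    diversity_stats,
    leader_cluster,
    select_representatives,
    write_cluster_report,
)
from mcscreen.core_data import (
    ACTIVE,
    CompoundTable,
    Schema,
    partition_rows,
    read_compound_table,
    write_compound_table,
)
from mcscreen.feature_clustering import cluster_features
from mcscreen.mcs_model import (
    MINIMIZE_FP,
    MINIMIZE_FN,
    MetaModel,
    ROSTERS,
    build_mcs,
    combine_meta,
    predict,
)
from mcscreen.metrics import confusion_matrix, fp_reduction_percent, metric_report
from mcscreen.ranking import make_candidates, rank_candidates, write_ranking
from mcscreen.synthetic_data import (
    SyntheticSpec,
    generate_dataset,
    generate_screening_library,
)

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Resolved configuration of one pipeline run; written next to outputs."""

    out_dir: str = "mcscreen_run"
    seed: int = 0
    input_path: str | None = None  # labeled training TSV; None -> synthetic
    screen_path: str | None = None  # unlabeled library TSV; None -> synthetic
    synthetic: dict = field(default_factory=dict)  # SyntheticSpec overrides
    screen_prevalence: float = 0.05
    screen_size: int | None = None
    n_groups: int = 4
    cluster_group: int = 2  # group used for feature clustering (reused for training)
    test_group: int = 4
    k_clusters: int = 3
    cv_folds: int = 5
    roster: str = "default"
    voting: str = "majority"
    meta_rule: str = MINIMIZE_FP
    chem_threshold: float = 0.35
    selection_size: int = 21
    stratify: bool = True

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _evaluate(name, truth, pred, report, log):
    cm = confusion_matrix(truth, list(pred.labels))
    report[name] = metric_report(cm)
    log.append(f"evaluate {name}: {cm.as_dict()}")
    return cm


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute the full workflow; returns the artifact directory.

    Every artifact is regenerable from (input, resolved config, seed) alone.
    Stage failures surface with the stage name in the exception message.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log: list[str] = [f"mcscreen {__version__} seed={config.seed}"]
    stage = "ingest"
    try:
        # ---- data -------------------------------------------------------
        if config.input_path:
            table = read_compound_table(config.input_path, Schema())
        else:
            spec = SyntheticSpec(**{"seed": config.seed, **config.synthetic})
            table, _ = generate_dataset(spec)
            write_compound_table(table, out / "training_data.tsv")
        log.append(f"ingest: {len(table)} compounds, {len(table.feature_names)} features")

        stage = "partition"
        groups = partition_rows(
            table, config.n_groups, seed=config.seed, stratify=config.stratify
        )
        (out / "groups.json").write_text(
            json.dumps(
                {"n_groups": groups.n_groups, "seed": groups.seed,
                 "assignment": groups.assignment},
                indent=2,
            ),
            encoding="utf-8",
        )
        test_rows = groups.group_indices(table, config.test_group)
        train_rows = [
            r for r in range(len(table))
            if groups.assignment[table.ids[r]] != config.test_group
        ]
        cluster_rows = groups.group_indices(table, config.cluster_group)
        log.append(
            f"partition: sizes={groups.sizes()} train={len(train_rows)} test={len(test_rows)}"
        )

        stage = "cluster-features"
        cluster_table = table.subset(cluster_rows)
        clustering = cluster_features(cluster_table, k=config.k_clusters)
        clustering.save(out / "feature_clusters.json")
        log.append(f"cluster-features: k={clustering.k} sizes={[len(c) for c in clustering.clusters]}")

        stage = "train"
        roster = ROSTERS[config.roster]()
        train_table = table.subset(train_rows)
        model_mcc = build_mcs(
            train_table, clustering, "MCC", roster=roster,
            cv_folds=config.cv_folds, seed=config.seed, voting=config.voting,
        )
        model_ppv = build_mcs(
            train_table, clustering, "PPV", roster=roster,
            cv_folds=config.cv_folds, seed=config.seed, voting=config.voting,
        )
        model_mcc.save(out / "model_mcc.joblib")
        model_ppv.save(out / "model_ppv.joblib")
        log.append(
            "train: mcc=[%s] ppv=[%s]"
            % (
                ", ".join(c.spec_name for c in model_mcc.classifiers),
                ", ".join(c.spec_name for c in model_ppv.classifiers),
            )
        )

        stage = "evaluate"
        test_table = table.subset(test_rows)
        truth = list(test_table.labels)
        report: dict = {}
        pred_mcc = predict(model_mcc, test_table)
        pred_ppv = predict(model_ppv, test_table)
        _evaluate("model_mcc", truth, pred_mcc, report, log)
        _evaluate("model_ppv", truth, pred_ppv, report, log)
        cm_fp = _evaluate(
            "minimize_fp", truth, combine_meta(pred_mcc, pred_ppv, MINIMIZE_FP), report, log
        )
        cm_fn = _evaluate(
            "minimize_fn", truth, combine_meta(pred_mcc, pred_ppv, MINIMIZE_FN), report, log
        )
        if cm_fn.fp > 0:
            report["fp_reduction_percent_vs_minimize_fn"] = fp_reduction_percent(cm_fp, cm_fn)
        (out / "evaluation.json").write_text(json.dumps(report, indent=2), encoding="utf-8")

        stage = "screen"
        if config.screen_path:
            library = read_compound_table(config.screen_path, Schema())
        else:
            spec = SyntheticSpec(**{"seed": config.seed, **config.synthetic})
            library, hidden = generate_screening_library(
                spec, prevalence=config.screen_prevalence, n_total=config.screen_size
            )
            write_compound_table(library, out / "screening_library.tsv")
            (out / "screening_truth.json").write_text(
                json.dumps(dict(zip(library.ids, hidden.tolist())), indent=2),
                encoding="utf-8",
            )
        meta = MetaModel(model_mcc=model_mcc, model_ppv=model_ppv, rule=config.meta_rule)
        screen_pred = meta.predict(library)
        n_active = int((screen_pred.labels == ACTIVE).sum())
        log.append(f"screen: {n_active}/{len(library)} predicted Active ({config.meta_rule})")

        stage = "rank"
        candidates = rank_candidates(make_candidates(screen_pred))
        write_ranking(candidates, out / "ranked_candidates.tsv")
        log.append(f"rank: {len(candidates)} candidates")

        stage = "chem-cluster"
        theta_by_id = {c.id: c.theta for c in candidates}
        id_set = set(theta_by_id)
        fps = [
            (cid, library.bits[r])
            for r, cid in enumerate(library.ids)
            if cid in id_set
        ]
        clusters = leader_cluster(
            fps, config.chem_threshold, ordering=[c.id for c in candidates]
        )
        write_cluster_report(clusters, theta_by_id, out / "chem_clusters.tsv")
        log.append(f"chem-cluster: {len(clusters)} clusters from {len(fps)} actives")

        stage = "select"
        reps = select_representatives(clusters, theta_by_id)
        reps = sorted(reps, key=lambda c: (-theta_by_id[c], c))[: config.selection_size]
        selection = {"selected": reps, "theta": {c: theta_by_id[c] for c in reps}}
        if len(reps) >= 2:
            lib_row = {cid: r for r, cid in enumerate(library.ids)}
            stats = diversity_stats(
                [library.bits[lib_row[c]] for c in reps],
                [table.bits[r] for r in train_rows],
            )
            selection["diversity"] = dataclasses.asdict(stats)
            log.append(
                f"select: {len(reps)} compounds, pairwise distance "
                f"{stats.pairwise_mean:.2f}±{stats.pairwise_sd:.2f}, "
                f"nearest-training {stats.nearest_training_mean:.2f}±{stats.nearest_training_sd:.2f}"
            )
        (out / "selection.json").write_text(json.dumps(selection, indent=2), encoding="utf-8")

        stage = "finalize"
        (out / "config.json").write_text(
            json.dumps({"version": __version__, **config.to_dict()}, indent=2),
            encoding="utf-8",
        )
        (out / "run.log").write_text("\n".join(log) + "\n", encoding="utf-8")
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc
    return out
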