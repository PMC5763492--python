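"""End-to-end pipeline: windows → redundancy filter → negative sampling →
MDD clustering → profile training → threshold calibration → SVM stacking →
cross-validated evaluation, with a manifest recording every decision."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

from .combo import ComboModel, train_combo
from .config import RunConfig
from .evaluation import MetricSet, cross_validate, repeated_resampling_eval
from .mdd import MddTree, export_logo_counts, mdd_cluster
from .seq_windows import (
    Dataset,
    ProteinRecord,
    SiteAnnotation,
    build_candidate_sites,
    reduce_redundancy,
    sample_negatives,
)

logger = logging.getLogger("carbmotif")


@dataclass
class PipelineResult:
    config: RunConfig
    dataset: Dataset
    tree: MddTree
    model: ComboModel
    metrics: MetricSet
    manifest: dict


def _manifest_hash(manifest: dict) -> str:
    canon = json.dumps(manifest, sort_keys=True, separators=(",", ":"))
    return hashlib.sha256(canon.encode()).hexdigest()


def _combo_factory(config: RunConfig, seed: int):
    """Per-fold trainer: recluster the fold's positives and retrain the full
    two-layer model, so CV never sees leaked structure."""

    def factory(train_pos, train_neg):
        tree = mdd_cluster(
            list(train_pos),
            group_map=config.group_map(),
            threshold=config.chi2_threshold,
            max_cluster_size=config.max_cluster_size,
            criterion=config.split_criterion,
            split_mode=config.split_mode,
        )
        return train_combo(
            list(train_pos),
            list(train_neg),
            tree,
            pseudocount=config.pseudocount,
            c_grid=config.c_grid,
            gamma_grid=config.gamma_grid,
            cv=config.folds,
            seed=seed,
        )

    return factory


def run_pipeline(
    config: RunConfig,
    proteins: Sequence[ProteinRecord],
    sites: Sequence[SiteAnnotation],
    out_dir: Optional[str | Path] = None,
    repeats: Optional[int] = None,
) -> PipelineResult:
    """Execute the full training/evaluation pipeline for one residue type.

    *repeats* overrides ``config.repeats`` for the resampling evaluation;
    ``repeats=1`` runs a single stratified CV on one negative sample (the
    default here, since 30 repeats is a production-scale run). The manifest
    captures config, per-stage counts, split decisions, the SVM grid winner
    and the metrics, and hashes deterministically.
    """
    stage_counts: dict = {}

    raw = build_candidate_sites(proteins, sites, config.residue, n=config.n)
    stage_counts["candidate_positives"] = len(raw.positives)
    stage_counts["candidate_negatives"] = len(raw.negatives)
    logger.info("[windows] %d positives, %d candidate negatives",
                len(raw.positives), len(raw.negatives))

    pos = reduce_redundancy(raw.positives, config.identity_threshold)
    neg = reduce_redundancy(
        raw.negatives, config.identity_threshold, reference=pos
    )
    stage_counts["nonredundant_positives"] = len(pos)
    stage_counts["nonredundant_negatives"] = len(neg)
    logger.info("[redundancy] kept %d positives, %d negatives", len(pos), len(neg))

    filtered = Dataset(residue=config.residue, positives=pos, negatives=neg,
                       n=config.n)
    dataset = sample_negatives(
        filtered, ratio=config.neg_ratio, seed=config.stage_seed("sample")
    )
    stage_counts["sampled_negatives"] = len(dataset.negatives)

    tree = mdd_cluster(
        dataset.positives,
        group_map=config.group_map(),
        threshold=config.chi2_threshold,
        max_cluster_size=config.max_cluster_size,
        criterion=config.split_criterion,
        split_mode=config.split_mode,
    )
    stage_counts["mdd_leaves"] = len(tree.leaves)
    for leaf in tree.leaves:
        logger.info("[mdd] leaf %s: %d members", leaf.leaf_id, len(leaf.members))

    model = train_combo(
        dataset.positives,
        dataset.negatives,
        tree,
        pseudocount=config.pseudocount,
        c_grid=config.c_grid,
        gamma_grid=config.gamma_grid,
        cv=config.folds,
        seed=config.stage_seed("svm"),
    )
    logger.info("[svm] grid winner c=%g gamma=%g (cv acc %.3f)",
                model.best_c, model.best_gamma, model.cv_accuracy)

    n_rep = config.repeats if repeats is None else repeats
    factory = _combo_factory(config, config.stage_seed("cv"))
    if n_rep <= 1:
        metrics, _ = cross_validate(
            dataset, factory, k=config.folds, seed=config.stage_seed("cv")
        )
    else:
        metrics, _ = repeated_resampling_eval(
            dataset.positives,
            filtered.negatives,
            factory,
            repeats=n_rep,
            ratio=config.neg_ratio,
            k=config.folds,
            seed=config.stage_seed("cv"),
        )
    logger.info("[eval] Sn=%.3f Sp=%.3f Acc=%.3f MCC=%.3f AUC=%.3f",
                metrics.sn, metrics.sp, metrics.acc, metrics.mcc, metrics.auc)

    manifest = {
        "config": config.to_dict(),
        "stage_counts": stage_counts,
        "tree": tree.to_dict(),
        "profile_thresholds": {
            p.subgroup_id: round(p.bit_threshold, 9) for p in model.profiles
        },
        "svm": {
            "c": model.best_c,
            "gamma": model.best_gamma,
            "cv_accuracy": round(model.cv_accuracy, 9),
        },
        "metrics": {k: round(v, 9) for k, v in metrics.as_dict().items()},
    }
    manifest["hash"] = _manifest_hash(manifest)

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        model.save(out / "model")
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
        (out / "tree.json").write_text(json.dumps(tree.to_dict(), indent=1))
        (out / "metrics.json").write_text(json.dumps(manifest["metrics"], indent=1))
        for leaf in tree.leaves:
            export_logo_counts(leaf).to_csv(
                out / f"logo_{leaf.leaf_id}.tsv", sep="\t"
            )

    return PipelineResult(
        config=config, dataset=dataset, tree=tree, model=model,
        metrics=metrics, manifest=manifest,
    )
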