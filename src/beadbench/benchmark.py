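"""Factorial benchmark: normalization strategies x analytical approaches.

Each cell runs preprocess -> normalize -> differential expression ->
detection filter and yields one probe set.  The bundle adds per-approach
strategy concordance, per-strategy approach concordance, optional pathway
enrichment/concordance, and a machine-readable manifest with full
provenance.  A failing cell is recorded in the manifest and skipped; the
bundle is still produced.
"""
from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

from .concord import approach_concordance, pathway_concordance, strategy_concordance
from .diffexp import ProbeSet, illumina_custom_de, ttest_de
from .enrich import enrich_pathways
from .feature_select import maxcover_de
from .io_bead import BeadSummaryMatrix, ClassLabels, PathwayAnnotation
from .normalize import STRATEGIES, normalize
from .preprocess import background_correct, detection_pvalues, filter_unexpressed

__all__ = ["BenchmarkConfig", "BenchmarkResult", "run_benchmark", "APPROACHES"]

logger = logging.getLogger("beadbench")

APPROACHES = ("illumina", "ttest", "maxcover")


@dataclass
class BenchmarkConfig:
    strategies: tuple[str, ...] = tuple(sorted(STRATEGIES))
    approaches: tuple[str, ...] = APPROACHES
    background: bool = True
    alpha: float = 0.05
    detection_threshold: float = 0.01
    filter_first: bool = False
    fdr: str | None = None
    seed: int = 0
    maxcover_kwargs: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.strategies or not self.approaches:
            raise ValueError("strategies and approaches must be non-empty")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")
        unknown = set(self.strategies) - set(STRATEGIES)
        if unknown:
            raise ValueError(f"unknown strategies {sorted(unknown)}")
        unknown = set(self.approaches) - set(APPROACHES)
        if unknown:
            raise ValueError(f"unknown approaches {sorted(unknown)}")


@dataclass
class BenchmarkResult:
    probe_sets: dict[tuple[str, str], ProbeSet]
    manifest: dict
    strategy_reports: dict[str, dict]
    approach_reports: dict[str, dict]
    enrichment: dict | None = None
    pathway_reports: dict | None = None

    @property
    def n_cells_failed(self) -> int:
        return len(self.manifest.get("errors", []))


def _run_de(approach: str, norm, labels: ClassLabels, cfg: BenchmarkConfig) -> ProbeSet:
    if approach == "ttest":
        return ttest_de(norm, labels, alpha=cfg.alpha, fdr=cfg.fdr)
    if approach == "illumina":
        return illumina_custom_de(norm, labels, alpha=cfg.alpha, fdr=cfg.fdr)
    if approach == "maxcover":
        return maxcover_de(norm, labels, **cfg.maxcover_kwargs)
    raise ValueError(f"unknown approach {approach!r}")  # pragma: no cover


def _subset_detected(matrix: BeadSummaryMatrix, det, threshold: float) -> BeadSummaryMatrix:
    keep = [
        i for i, p in enumerate(matrix.probe_ids)
        if not all(g > threshold for g in det.group_p(p))
    ]
    return BeadSummaryMatrix(
        probe_ids=[matrix.probe_ids[i] for i in keep],
        sample_ids=matrix.sample_ids,
        signal=matrix.signal[keep, :],
        bead_se=None if matrix.bead_se is None else matrix.bead_se[keep, :],
        detection_p=None if matrix.detection_p is None else matrix.detection_p[keep, :],
        neg_control=matrix.neg_control,
        background_corrected=matrix.background_corrected,
    )


def run_benchmark(
    matrix: BeadSummaryMatrix,
    labels: ClassLabels,
    cfg: BenchmarkConfig,
    annotation: PathwayAnnotation | None = None,
    out_dir: str | Path | None = None,
) -> BenchmarkResult:
    """Run every (strategy, approach) cell and assemble the report bundle."""
    labels.validate_for(matrix)
    det = detection_pvalues(matrix, labels)
    base = background_correct(matrix) if cfg.background else matrix

    probe_sets: dict[tuple[str, str], ProbeSet] = {}
    errors: list[dict] = []
    cells: list[dict] = []
    for strategy in cfg.strategies:
        for approach in cfg.approaches:
            cell_id = f"{strategy}__{approach}"
            try:
                work = _subset_detected(base, det, cfg.detection_threshold) \
                    if cfg.filter_first else base
                norm = normalize(work, strategy)
                ps = _run_de(approach, norm, labels, cfg)
                if not cfg.filter_first:
                    ps = filter_unexpressed(ps, det, cfg.detection_threshold)
                ps.provenance.update(
                    {"seed": cfg.seed, "detection_threshold": cfg.detection_threshold,
                     "filter_first": cfg.filter_first}
                )
                probe_sets[(strategy, approach)] = ps
                cells.append({
                    "cell": cell_id,
                    "strategy": strategy,
                    "approach": approach,
                    "n_probes": len(ps),
                    "provenance": ps.provenance,
                })
                logger.info("cell %s: %d probes", cell_id, len(ps))
            except Exception as exc:  # noqa: BLE001 - cell errors are recorded
                logger.error("cell %s failed: %s", cell_id, exc)
                errors.append({"cell": cell_id, "error": str(exc)})

    strategy_reports: dict[str, dict] = {}
    for approach in cfg.approaches:
        sets = {
            s: probe_sets[(s, approach)]
            for s in cfg.strategies if (s, approach) in probe_sets
        }
        try:
            strategy_reports[approach] = strategy_concordance(sets)
        except ValueError as exc:
            strategy_reports[approach] = {"error": str(exc)}

    approach_reports: dict[str, dict] = {}
    for strategy in cfg.strategies:
        sets = {
            a: probe_sets[(strategy, a)]
            for a in cfg.approaches if (strategy, a) in probe_sets
        }
        if len(sets) >= 2:
            rep = approach_concordance(sets)
            approach_reports[strategy] = {
                "per_approach": rep["per_approach"],
                "totals": rep["totals"],
            }
        else:
            approach_reports[strategy] = {"error": "fewer than 2 approaches succeeded"}

    enrichment = None
    pathway_reports = None
    if annotation is not None:
        enrichment = {}
        pathway_reports = {}
        for strategy in cfg.strategies:
            enriched_ids: dict[str, list[str]] = {}
            for approach in cfg.approaches:
                ps = probe_sets.get((strategy, approach))
                if ps is None:
                    continue
                results = enrich_pathways(ps, annotation)
                enrichment[f"{strategy}__{approach}"] = [
                    {"pathway_id": r.pathway_id, "k": r.k, "n": r.n, "K": r.K,
                     "N": r.N, "fold_enrichment": r.fold_enrichment,
                     "p_value": r.p_value, "significant": r.significant}
                    for r in results
                ]
                enriched_ids[approach] = [r.pathway_id for r in results if r.significant]
            if len(enriched_ids) >= 2:
                pathway_reports[strategy] = pathway_concordance(enriched_ids)

    manifest = {
        "config": {
            "strategies": list(cfg.strategies),
            "approaches": list(cfg.approaches),
            "background": cfg.background,
            "alpha": cfg.alpha,
            "detection_threshold": cfg.detection_threshold,
            "filter_first": cfg.filter_first,
            "fdr": cfg.fdr,
            "seed": cfg.seed,
        },
        "n_probe_sets": len(probe_sets),
        "cells": cells,
        "errors": errors,
    }

    result = BenchmarkResult(
        probe_sets=probe_sets,
        manifest=manifest,
        strategy_reports=strategy_reports,
        approach_reports=approach_reports,
        enrichment=enrichment,
        pathway_reports=pathway_reports,
    )
    if out_dir is not None:
        write_bundle(result, out_dir)
    return result


def write_bundle(result: BenchmarkResult, out_dir: str | Path) -> None:
    """Write probe-set tables, concordance reports and the manifest."""
    out = Path(out_dir)
    (out / "probe_sets").mkdir(parents=True, exist_ok=True)
    files: dict[str, dict] = {}
    for (strategy, approach), ps in sorted(result.probe_sets.items()):
        rel = f"probe_sets/{strategy}__{approach}.tsv"
        ps.write_table(out / rel)
        text = (out / rel).read_bytes()
        files[rel] = {"sha256": hashlib.sha256(text).hexdigest(), "n_probes": len(ps)}
    result.manifest["files"] = files

    def dump(obj, name: str) -> None:
        (out / name).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")

    dump(result.strategy_reports, "strategy_concordance.json")
    dump(result.approach_reports, "approach_concordance.json")
    if result.enrichment is not None:
        dump(result.enrichment, "enrichment.json")
    if result.pathway_reports is not None:
        dump(result.pathway_reports, "pathway_concordance.json")
    dump(result.manifest, "manifest.json")
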