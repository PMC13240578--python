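"""End-to-end orchestration: io -> qc -> clones -> patterns -> indices -> scoring.

A :class:`RunConfig` (constructible from a YAML or JSON file) names the
inputs and parameters; :func:`run_full` executes the stages in order, writes
every output table as TSV into the output directory, and returns a run
report (also written as ``report.json``) with per-stage record counts, the
full parameter set, and accumulated warnings.  Reruns over unchanged inputs
are byte-identical.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

from . import io as rio
from .clonotypes import build_clone_table, expansion_counts, isotype_composition
from .errors import CloneshareError, ValidationError
from .indices import expansion_index_table, migration_index, transition_index
from .io import ClonePolicy, Dialect
from .patterns import classify_clones, pattern_proportions, project_to_cells
from .qc import QcThresholds, apply_cell_qc, log_normalize
from .scoring import annotate, build_references, summarize_predictions

logger = logging.getLogger("cloneshare")

COMPARTMENT_PAIRS = [("LUNG", "BALF"), ("LUNG", "PBMC"), ("BALF", "PBMC")]


@dataclass
class RunConfig:
    """Paths and parameters of a full pipeline run."""

    contigs: str
    cells: str
    outdir: str
    contig_dialect: str = "TENX_CSV"
    mtx: Optional[str] = None
    features: Optional[str] = None
    barcodes: Optional[str] = None
    max_mito_fraction: float = 0.10
    min_genes: int = 200
    clone_policy: str = "NT_VJ"
    min_size: int = 2
    min_cells: int = 1
    normalize_indices: bool = True
    weight: str = "clones"
    scoring: bool = False
    genes_per_pair: int = 50
    margin: float = 0.05
    seed: int = 0

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        path = Path(path)
        payload = yaml.safe_load(path.read_text())
        if not isinstance(payload, dict):
            raise ValidationError(f"config file {path} must hold a mapping")
        return cls(**payload)

    def validate(self) -> None:
        for name in ("contigs", "cells"):
            p = getattr(self, name)
            if not Path(p).exists():
                raise ValidationError(f"input path does not exist: {name}={p}")
        for name in ("mtx", "features", "barcodes"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise ValidationError(f"input path does not exist: {name}={p}")


class _ReportLogHandler(logging.Handler):
    def __init__(self):
        super().__init__(level=logging.WARNING)
        self.messages: list[str] = []

    def emit(self, record):
        self.messages.append(record.getMessage())


def run_full(config: RunConfig) -> dict:
    """Execute all stages; returns the run report (written as report.json)."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = _ReportLogHandler()
    logger.addHandler(handler)
    report: dict = {"parameters": asdict(config), "stages": {}, "warnings": []}
    stage = "io"
    try:
        contigs = rio.read_contig_table(config.contigs, Dialect(config.contig_dialect))
        cells = rio.read_cell_metadata(config.cells)
        expr = None
        if config.mtx:
            expr = rio.read_expression_matrix(config.mtx, config.features, config.barcodes)
        report["stages"]["io"] = {
            "contigs": len(contigs),
            "cells": len(cells),
            "genes": None if expr is None else len(expr.genes),
        }

        stage = "qc"
        thresholds = QcThresholds(config.max_mito_fraction, config.min_genes)
        kept, removed = apply_cell_qc(cells, thresholds)
        report["stages"]["qc"] = {"kept": len(kept), "removed": len(removed)}

        stage = "clones"
        assignments = rio.collapse_to_clonotypes(
            contigs, kept, ClonePolicy(config.clone_policy)
        )
        table = build_clone_table(assignments, kept)
        rio.write_clone_assignments(assignments, outdir / "assignments.tsv")
        table.to_tsv(outdir / "clone_table.tsv")
        exp_counts = expansion_counts(table, min_size=config.min_size, by="cluster")
        exp_counts.rename("n_expanded_cells").to_csv(
            outdir / "expansion_counts.tsv", sep="\t"
        )
        iso = isotype_composition(table)
        if len(iso):
            iso.to_csv(outdir / "isotype_composition.tsv", sep="\t")
        report["stages"]["clones"] = {
            "assignments": len(assignments),
            "clones": int(table.clone_sizes().shape[0]),
        }

        stage = "patterns"
        clone_labels = classify_clones(
            table, min_size=config.min_size, min_cells=config.min_cells
        )
        clone_labels.to_csv(outdir / "clone_patterns.tsv", sep="\t", index=False)
        proportions = pattern_proportions(clone_labels, weight=config.weight)
        proportions.to_csv(outdir / "pattern_proportions.tsv", sep="\t")
        cell_labels = project_to_cells(clone_labels, assignments, kept)
        cell_labels.rename_axis("barcode").to_frame().to_csv(
            outdir / "cell_patterns.tsv", sep="\t"
        )
        report["stages"]["patterns"] = {
            "clones_classified": int(
                (clone_labels["pattern"] != "UNCLASSIFIED").sum()
            ),
            "cells_labelled": int(len(cell_labels)),
        }

        stage = "indices"
        frames = [expansion_index_table(table, by="cluster")]
        for cluster in [None] + table.clusters:
            frames.append(migration_index(table, cluster=cluster,
                                          normalize=config.normalize_indices))
            for pair in COMPARTMENT_PAIRS:
                frames.append(
                    migration_index(table, cluster=cluster, compartments=list(pair),
                                    normalize=config.normalize_indices)
                )
        frames.append(transition_index(table, normalize=config.normalize_indices))
        index_table = pd.concat(frames, ignore_index=True)
        index_table.to_csv(outdir / "indices.tsv", sep="\t", index=False)
        report["stages"]["indices"] = {"rows": int(len(index_table))}

        if config.scoring:
            stage = "scoring"
            if expr is None:
                raise ValidationError("scoring requested but no expression matrix given")
            norm = log_normalize(expr)
            ref_labels = cell_labels[cell_labels.isin(["P1A", "P1B", "P2", "OTHER"])]
            ref_labels = ref_labels[ref_labels.index.isin(set(norm.barcodes))]
            refs = build_references(norm, ref_labels, genes_per_pair=config.genes_per_pair)
            predictions = annotate(norm, refs, margin=config.margin)
            predictions.to_csv(outdir / "pattern_scores.tsv", sep="\t")
            summary = summarize_predictions(predictions)
            summary.rename_axis("final_label").to_csv(
                outdir / "prediction_summary.tsv", sep="\t"
            )
            report["stages"]["scoring"] = {
                "reference_cells": int(len(ref_labels)),
                "queries": int(len(predictions)),
            }
    except CloneshareError as exc:
        logger.removeHandler(handler)
        raise CloneshareError(f"stage '{stage}' failed: {exc}") from exc
    finally:
        if handler in logger.handlers:
            logger.removeHandler(handler)
    report["warnings"] = handler.messages
    (outdir / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    return report
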