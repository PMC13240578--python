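"""Synthetic cohort generator with ground truth.

Generates paired repertoire + expression cohorts whose clonal structure,
sharing patterns and expression programs are known, so every pipeline stage
can be verified without access to patient data.  The stated world:

* per subject, clone sizes follow a geometric (or zipf) law with a
  configurable expanded fraction; singletons stay singletons;
* each clone draws a sharing pattern from ``pattern_mix`` and allocates its
  cells to that pattern's allowed compartments (P1A: lung+BALF; P1B: lung;
  P2: lung+PBMC; OTHER: all three) by a Dirichlet-multinomial; because a
  sharing pattern is *defined by* occupancy, the default
  (``ensure_occupancy=True``) seats one cell in every allowed compartment
  first, the remainder being stochastic;
* expression is overdispersed (negative binomial) counts over canonical
  phenotype markers (resident ITGAE/CXCR6/CXCR3, circulating
  CX3CR1/FGFBP2/KLRG1, cycling MKI67, cytotoxic GZMB/GNLY), additional
  pattern-specific program genes (real transcriptional programs span dozens
  of co-regulated genes), and flat background genes; program effects are
  multiplicative ``2**effect`` shifts of the NB mean;
* QC covariates (mitochondrial fraction, genes detected) are drawn
  independently of the small simulated gene panel, emulating
  whole-transcriptome detection.

The same seed yields byte-identical output files.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .errors import ValidationError
from . import io as rio
from .io import (
    CellRecord, Chain, Compartment, ContigRecord, Dialect, ExpressionMatrix,
    Group, ReceptorType,
)

logger = logging.getLogger("cloneshare")

CANONICAL_PROGRAMS: dict[str, dict[str, float]] = {
    "P1A": {"ITGAE": 2.0, "CXCR6": 2.0, "CXCR3": 2.0,
            "GZMB": 2.0, "GNLY": 2.0, "MKI67": 2.0},
    "P1B": {"ITGAE": 2.0, "CXCR6": 2.0},
    "P2": {"CX3CR1": 2.0, "FGFBP2": 2.0, "KLRG1": 2.0},
    "OTHER": {},
}

DEFAULT_ALLOCATION: dict[str, dict[str, float]] = {
    "P1A": {"LUNG": 4.0, "BALF": 4.0},
    "P1B": {"LUNG": 4.0},
    "P2": {"LUNG": 4.0, "PBMC": 4.0},
    "OTHER": {"LUNG": 2.0, "BALF": 2.0, "PBMC": 2.0},
}

DEFAULT_CLUSTER_MIX: dict[str, dict[str, float]] = {
    "P1A": {"T8_rm": 0.6, "Cycling": 0.4},
    "P1B": {"T8_rm": 1.0},
    "P2": {"T8_eff": 0.6, "T8_NK-like": 0.4},
    "OTHER": {"T8_rm": 0.25, "Cycling": 0.25, "T8_eff": 0.25, "T8_NK-like": 0.25},
}

PATTERN_ORDER = ["P1A", "P1B", "P2", "OTHER"]


@dataclass
class SimulationConfig:
    """Stated world of the generator; defaults document the emulated cohort."""

    n_subjects: int = 5
    clones_per_subject: int = 200
    pattern_mix: tuple[float, float, float, float] = (0.5, 0.2, 0.3, 0.0)
    clone_size_law: str = "geometric"  # or "zipf"
    clone_size_param: float = 0.3      # geometric p, or zipf exponent s
    expansion_fraction: float = 0.6
    compartment_allocation: dict[str, dict[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_ALLOCATION.items()}
    )
    ensure_occupancy: bool = True
    cluster_mix: dict[str, dict[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_CLUSTER_MIX.items()}
    )
    programs: dict[str, dict[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in CANONICAL_PROGRAMS.items()}
    )
    program_genes_per_pattern: int = 30
    program_effect: float = 2.0
    n_background_genes: int = 100
    nb_dispersion: float = 10.0
    baseline_mean: float = 0.5
    mito_beta: tuple[float, float] = (2.0, 38.0)
    n_genes_mean: float = 2500.0
    n_genes_sd: float = 400.0
    receptor: str = "TCR"
    isotype_mix: dict[str, float] = field(
        default_factory=lambda: {"IGHA1": 0.6, "IGHG1": 0.4}
    )
    group_control_subjects: int = 0

    def __post_init__(self) -> None:
        mix = np.asarray(self.pattern_mix, dtype=float)
        if mix.size != 4 or (mix < 0).any() or abs(mix.sum() - 1.0) > 1e-9:
            raise ValidationError("pattern_mix must be 4 nonnegative probs summing to 1")
        for pattern, conc in self.compartment_allocation.items():
            if mix[PATTERN_ORDER.index(pattern)] > 0 and not conc:
                raise ValidationError(f"pattern {pattern} has no allowed compartments")
            if any(v <= 0 for v in conc.values()):
                raise ValidationError("Dirichlet concentrations must be > 0")
        if self.clone_size_law not in ("geometric", "zipf"):
            raise ValidationError("clone_size_law must be 'geometric' or 'zipf'")
        if not 0 <= self.expansion_fraction <= 1:
            raise ValidationError("expansion_fraction must lie in [0, 1]")
        if self.receptor not in ("TCR", "BCR"):
            raise ValidationError("receptor must be 'TCR' or 'BCR'")

    def gene_panel(self) -> tuple[list[str], dict[str, dict[str, float]]]:
        """Full gene list and effective per-pattern programs (with PRG genes)."""
        programs = {k: dict(v) for k, v in self.programs.items()}
        for pattern in PATTERN_ORDER:
            programs.setdefault(pattern, {})
            for i in range(self.program_genes_per_pattern):
                programs[pattern][f"PRG_{pattern}_{i:02d}"] = self.program_effect
        named = sorted({g for prog in programs.values() for g in prog})
        background = [f"BG{i:04d}" for i in range(self.n_background_genes)]
        return named + background, programs


@dataclass
class SyntheticTruth:
    """Generator bookkeeping: per-clone and per-cell ground truth."""

    clones: pd.DataFrame  # subject_id, clone_id, pattern, size, lung_n, balf_n, pbmc_n
    cells: pd.DataFrame   # barcode, subject_id, clone_id, compartment, cluster, pattern

    def to_json(self, path) -> None:
        payload = {
            "clones": self.clones.to_dict(orient="list"),
            "cells": self.cells.to_dict(orient="list"),
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path) -> "SyntheticTruth":
        payload = json.loads(Path(path).read_text())
        return cls(
            clones=pd.DataFrame(payload["clones"]),
            cells=pd.DataFrame(payload["cells"]),
        )


@dataclass
class SyntheticCohort:
    contigs: list[ContigRecord]
    cells: list[CellRecord]
    expr: ExpressionMatrix
    truth: SyntheticTruth
    config: SimulationConfig
    seed: int


_NT = np.array(list("ACGT"))
_AA = np.array(list("ACDEFGHIKLMNPQRSTVWY"))


def _unique_cdr3(rng: np.random.Generator, index: int) -> tuple[str, str]:
    """CDR3 sequences unique per clone: random prefix + base-4 encoded index."""
    tag = np.base_repr(index, base=4).zfill(8)
    nt_tag = "".join(_NT[int(d)] for d in tag)
    nt = "TGT" + "".join(rng.choice(_NT, size=24)) + nt_tag + "TTT"
    aa_tag = "".join(_AA[int(d, 20)] for d in np.base_repr(index, base=20).zfill(5))
    aa = "CASS" + "".join(rng.choice(_AA, size=6)) + aa_tag + "F"
    return nt, aa


def _draw_size(rng: np.random.Generator, cfg: SimulationConfig) -> int:
    """Expanded clone size (>= 2) under the configured law."""
    if cfg.clone_size_law == "geometric":
        return 1 + int(rng.geometric(cfg.clone_size_param))
    while True:  # zipf, rejected below 2
        s = int(rng.zipf(cfg.clone_size_param))
        if s >= 2:
            return s


def simulate_cohort(
    config: Optional[SimulationConfig] = None,
    seed: int = 0,
    outdir=None,
    dialect: Dialect = Dialect.TENX_CSV,
) -> SyntheticCohort:
    """Generate a cohort; optionally write its files to ``outdir``.

    Files written: contigs.csv (or contigs.tsv for AIRR), matrix.mtx,
    features.tsv, barcodes.tsv, cells.tsv, truth.json.  Identical seeds give
    byte-identical files.
    """
    cfg = config or SimulationConfig()
    rng = np.random.default_rng(seed)
    genes, programs = cfg.gene_panel()
    receptor = ReceptorType(cfg.receptor)

    clone_rows, cell_rows, contigs = [], [], []
    clone_counter = 0
    for si in range(cfg.n_subjects):
        subject = f"S{si + 1:02d}"
        group = (
            Group.CONTROL
            if si >= cfg.n_subjects - cfg.group_control_subjects
            else Group.PNEUMONIA
        )
        for ci in range(cfg.clones_per_subject):
            clone_counter += 1
            pattern = PATTERN_ORDER[
                rng.choice(4, p=np.asarray(cfg.pattern_mix, dtype=float))
            ]
            expanded = rng.random() < cfg.expansion_fraction
            size = _draw_size(rng, cfg) if expanded else 1

            conc = cfg.compartment_allocation[pattern]
            allowed = sorted(conc)
            probs = rng.dirichlet([conc[c] for c in allowed])
            counts = np.zeros(len(allowed), dtype=int)
            remaining = size
            if cfg.ensure_occupancy and size >= len(allowed):
                counts += 1
                remaining -= len(allowed)
            if remaining:
                counts += rng.multinomial(remaining, probs)

            clone_id = f"{subject}_clone{ci + 1:04d}"
            nt, aa = _unique_cdr3(rng, clone_counter)
            if receptor is ReceptorType.TCR:
                chains = [
                    (Chain.TRB, f"TRBV{1 + ci % 20}", f"TRBJ{1 + ci % 2}-1", nt, aa, ""),
                    (Chain.TRA, f"TRAV{1 + ci % 15}", f"TRAJ{1 + ci % 3}", "AAG" + nt[3:], "K" + aa[1:], ""),
                ]
            else:
                iso_names = sorted(cfg.isotype_mix)
                iso_probs = np.array([cfg.isotype_mix[k] for k in iso_names], dtype=float)
                isotype = iso_names[rng.choice(len(iso_names), p=iso_probs / iso_probs.sum())]
                chains = [
                    (Chain.IGH, f"IGHV{1 + ci % 20}", f"IGHJ{1 + ci % 4}", nt, aa, isotype),
                    (Chain.IGK, f"IGKV{1 + ci % 10}", f"IGKJ{1 + ci % 2}", "AAG" + nt[3:], "K" + aa[1:], ""),
                ]

            clusters = cfg.cluster_mix[pattern]
            cluster_names = sorted(clusters)
            cluster_probs = np.array([clusters[c] for c in cluster_names], dtype=float)
            cluster_probs /= cluster_probs.sum()

            comp_counts = dict(zip(allowed, counts))
            clone_rows.append(
                {
                    "subject_id": subject,
                    "clone_id": clone_id,
                    "pattern": pattern,
                    "size": size,
                    "lung_n": comp_counts.get("LUNG", 0),
                    "balf_n": comp_counts.get("BALF", 0),
                    "pbmc_n": comp_counts.get("PBMC", 0),
                }
            )
            for comp, n_cells in zip(allowed, counts):
                for _ in range(n_cells):
                    barcode = f"{subject}-{len(cell_rows):06d}"
                    cluster = cluster_names[rng.choice(len(cluster_names), p=cluster_probs)]
                    cell_rows.append(
                        {
                            "barcode": barcode,
                            "subject_id": subject,
                            "clone_id": clone_id,
                            "compartment": comp,
                            "cluster": cluster,
                            "pattern": pattern,
                            "group": group.value,
                        }
                    )
                    for chain, v, j, c_nt, c_aa, c_gene in chains:
                        contigs.append(
                            ContigRecord(
                                barcode=barcode,
                                chain=chain,
                                v_gene=v,
                                j_gene=j,
                                cdr3_nt=c_nt,
                                cdr3_aa=c_aa,
                                productive=True,
                                umis=int(1 + rng.poisson(9)),
                                c_gene=c_gene,
                                raw_clonotype_id=clone_id,
                            )
                        )

    truth_cells = pd.DataFrame(cell_rows)
    truth_clones = pd.DataFrame(clone_rows)

    # QC covariates, independent of the simulated panel
    n = len(truth_cells)
    mito = rng.beta(*cfg.mito_beta, size=n)
    n_genes = np.clip(
        np.round(rng.normal(cfg.n_genes_mean, cfg.n_genes_sd, size=n)), 0, None
    ).astype(int)

    cells = [
        CellRecord(
            barcode=row.barcode,
            subject_id=row.subject_id,
            compartment=Compartment(row.compartment),
            group=Group(row.group),
            cluster=row.cluster,
            mito_fraction=float(mito[i]),
            n_genes=int(n_genes[i]),
        )
        for i, row in enumerate(truth_cells.itertuples(index=False))
    ]

    # expression: NB counts with multiplicative 2**effect program shifts
    effects = np.zeros((len(genes), 4))
    gene_pos = {g: i for i, g in enumerate(genes)}
    for pi, pattern in enumerate(PATTERN_ORDER):
        for g, eff in programs[pattern].items():
            effects[gene_pos[g], pi] = eff
    pattern_idx = truth_cells["pattern"].map(PATTERN_ORDER.index).to_numpy()
    mu = cfg.baseline_mean * np.exp2(effects[:, pattern_idx])  # genes x cells
    theta = cfg.nb_dispersion
    counts = rng.negative_binomial(theta, theta / (theta + mu))
    import scipy.sparse as sp

    expr = ExpressionMatrix(
        genes=genes,
        barcodes=list(truth_cells["barcode"]),
        counts=sp.csr_matrix(counts),
    )

    truth = SyntheticTruth(
        clones=truth_clones,
        cells=truth_cells.drop(columns=["group"]),
    )
    cohort = SyntheticCohort(
        contigs=contigs, cells=cells, expr=expr, truth=truth,
        config=cfg, seed=seed,
    )
    if outdir is not None:
        write_cohort(cohort, outdir, dialect=dialect)
    return cohort


def write_cohort(cohort: SyntheticCohort, outdir, dialect: Dialect = Dialect.TENX_CSV) -> dict:
    """Write the cohort in exactly the dialects the readers accept."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    dialect = Dialect(dialect)
    contig_path = outdir / ("contigs.csv" if dialect is Dialect.TENX_CSV else "contigs.tsv")
    rio.write_contig_table(cohort.contigs, contig_path, dialect)
    rio.write_cell_metadata(cohort.cells, outdir / "cells.tsv")
    rio.write_expression_matrix(
        cohort.expr, outdir / "matrix.mtx", outdir / "features.tsv",
        outdir / "barcodes.tsv",
    )
    cohort.truth.to_json(outdir / "truth.json")
    return {
        "contigs": str(contig_path),
        "cells": str(outdir / "cells.tsv"),
        "mtx": str(outdir / "matrix.mtx"),
        "features": str(outdir / "features.tsv"),
        "barcodes": str(outdir / "barcodes.tsv"),
        "truth": str(outdir / "truth.json"),
    }


def evaluate_against_truth(
    clone_labels: pd.DataFrame,
    assignments,
    truth: SyntheticTruth,
    min_size: int = 2,
) -> dict:
    """Compare pipeline clone-pattern calls with the generator's truth.

    Pipeline clone ids differ from generator ids (they are built from
    chains), so clones are matched through their member cells.  Accuracy is
    the fraction of expanded truth clones (size >= ``min_size``) whose
    predicted pattern equals the true one; the confusion matrix is true x
    predicted over those clones.
    """
    pred_by_barcode = {}
    label_of = dict(zip(clone_labels["clone_id"], clone_labels["pattern"]))
    for a in assignments:
        pred_by_barcode[a.barcode] = label_of.get(a.clone_id)
    merged = truth.cells.copy()
    merged["predicted"] = merged["barcode"].map(pred_by_barcode)
    per_clone = (
        merged.dropna(subset=["predicted"])
        .groupby(["subject_id", "clone_id"])
        .agg(pattern=("pattern", "first"), predicted=("predicted", "first"),
             n_pred=("predicted", "nunique"))
    )
    if (per_clone["n_pred"] > 1).any():
        raise ValidationError("cohort mismatch: one truth clone maps to several predictions")
    sizes = truth.clones.set_index(["subject_id", "clone_id"])["size"]
    expanded = per_clone[sizes.reindex(per_clone.index) >= min_size]
    if expanded.empty:
        raise ValidationError("no expanded clones to evaluate")
    accuracy = float((expanded["pattern"] == expanded["predicted"]).mean())
    confusion = pd.crosstab(expanded["pattern"], expanded["predicted"])
    return {
        "pattern_accuracy": accuracy,
        "confusion": confusion,
        "n_evaluated": int(len(expanded)),
    }


def truth_migration_index(
    truth: SyntheticTruth,
    compartments: Optional[list[str]] = None,
    normalize: bool = True,
) -> float:
    """Migration index computed from generator bookkeeping (per-clone counts).

    Serves as the analytic value for ``index_errors`` when allocations are
    fixed by construction; matches the pooled pipeline computation.
    """
    cols = {"LUNG": "lung_n", "BALF": "balf_n", "PBMC": "pbmc_n"}
    compartments = compartments or list(cols)
    mat = truth.clones[[cols[c] for c in compartments]].to_numpy(dtype=float)
    totals = mat.sum(axis=1)
    mat = mat[totals > 0]
    totals = totals[totals > 0]
    q = mat / totals[:, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        h = -np.nansum(np.where(q > 0, q * np.log(q), 0.0), axis=1)
    value = float((totals / totals.sum() * h).sum())
    if normalize:
        value /= np.log(len(compartments))
    return value
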