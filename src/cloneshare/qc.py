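"""Cell-level QC, normalization, signature scoring and group statistics.

QC follows the study-standard rule for low-quality droplets: a cell is
removed when its mitochondrial read fraction exceeds 10% or it has fewer
than 200 detected genes.  Both thresholds are read as strict inequalities,
so boundary cells (exactly 10% mitochondrial, exactly 200 genes) are kept.

Normalization is library-size scaling followed by log1p:
``x = ln(1 + scale * count / total)`` with ``scale`` defaulting to 1e4.
Differential expression uses the two-sided Wilcoxon rank-sum test per gene
with Benjamini-Hochberg control of the FDR.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.stats
from statsmodels.stats.multitest import multipletests

from .errors import ValidationError
from .io import CellRecord, ExpressionMatrix

logger = logging.getLogger("cloneshare")


@dataclass(frozen=True)
class QcThresholds:
    """Removal thresholds: mito fraction strictly above, genes strictly below."""

    max_mito_fraction: float = 0.10
    min_genes: int = 200

    def __post_init__(self) -> None:
        if not 0 < self.max_mito_fraction < 1:
            raise ValidationError("max_mito_fraction must lie in (0, 1)")
        if self.min_genes < 0:
            raise ValidationError("min_genes must be >= 0")


def apply_cell_qc(
    cells: Sequence[CellRecord], thresholds: QcThresholds = QcThresholds()
) -> tuple[list[CellRecord], list[CellRecord]]:
    """Partition cells into (kept, removed) under the QC thresholds.

    A cell is removed iff ``mito_fraction > max_mito_fraction`` or
    ``n_genes < min_genes`` (both strict).  Cells missing either covariate
    raise a :class:`ValidationError` listing the offending barcodes.
    """
    missing = [c.barcode for c in cells if c.mito_fraction is None or c.n_genes is None]
    if missing:
        raise ValidationError(
            f"{len(missing)} cells missing QC fields, e.g. {missing[:5]}"
        )
    kept, removed = [], []
    for cell in cells:
        fails = (
            cell.mito_fraction > thresholds.max_mito_fraction
            or cell.n_genes < thresholds.min_genes
        )
        (removed if fails else kept).append(cell)
    return kept, removed


def log_normalize(expr: ExpressionMatrix, scale: float = 1e4) -> ExpressionMatrix:
    """Return a copy of ``expr`` with the normalized layer populated.

    normalized[g, c] = ln(1 + scale * counts[g, c] / total_counts[c]).
    Cells with zero total counts get an all-zero normalized column and a
    logged warning.
    """
    if scale <= 0:
        raise ValidationError("scale must be positive")
    counts = expr.counts.tocsc().astype(float)
    totals = np.asarray(counts.sum(axis=0)).ravel()
    zero_cells = int((totals == 0).sum())
    if zero_cells:
        logger.warning("log_normalize: %d cells with zero total counts", zero_cells)
    safe = np.where(totals == 0, 1.0, totals)
    norm = counts.multiply(scale / safe[None, :]).tocsr()
    norm.data = np.log1p(norm.data)
    return ExpressionMatrix(
        genes=list(expr.genes),
        barcodes=list(expr.barcodes),
        counts=expr.counts,
        normalized=norm,
    )


@dataclass(frozen=True)
class SignatureScore:
    barcode: str
    signature_name: str
    score: float


def score_signature(
    expr: ExpressionMatrix, gene_set: Sequence[str], name: str
) -> list[SignatureScore]:
    """Per-cell mean of normalized expression over the signature's genes.

    Genes absent from the matrix are dropped (count logged); an empty
    intersection is an error naming the signature.
    """
    if expr.normalized is None:
        raise ValidationError("normalized layer missing; call log_normalize first")
    idx = expr.gene_index(gene_set)
    n_dropped = len(set(gene_set)) - len(idx)
    if not idx:
        raise ValidationError(f"signature '{name}': no genes present in the matrix")
    if n_dropped:
        logger.info("signature '%s': %d genes absent from matrix", name, n_dropped)
    sub = expr.normalized[idx, :]
    means = np.asarray(sub.mean(axis=0)).ravel()
    return [
        SignatureScore(barcode=b, signature_name=name, score=float(s))
        for b, s in zip(expr.barcodes, means)
    ]


def read_signatures(path) -> dict[str, list[str]]:
    """Read signature definitions from a TSV (signature_name, gene_symbol)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in ("signature_name", "gene_symbol"):
        if col not in df.columns:
            raise ValidationError(f"signature file missing column {col}")
    out: dict[str, list[str]] = {}
    for row in df.itertuples(index=False):
        out.setdefault(row.signature_name, []).append(row.gene_symbol)
    return out


def benjamini_hochberg(p_values: Sequence[float]) -> np.ndarray:
    """BH-adjusted q-values (monotone, clipped to [0, 1])."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def differential_expression(
    expr: ExpressionMatrix,
    group_a_barcodes: Sequence[str],
    group_b_barcodes: Sequence[str],
    method: str = "wilcoxon",
) -> pd.DataFrame:
    """Per-gene two-group test on normalized values with BH correction.

    Returns a DataFrame (gene, log_fold_change, p_value, fdr) where
    ``log_fold_change`` is the difference of group means on the ln-normalized
    scale (group A minus group B).  The default test is the two-sided
    Wilcoxon rank-sum; ``method='ttest'`` selects Welch's t-test.  Genes that
    are constant across both groups get p = 1 by convention.
    """
    if expr.normalized is None:
        raise ValidationError("normalized layer missing; call log_normalize first")
    set_a, set_b = set(group_a_barcodes), set(group_b_barcodes)
    overlap = set_a & set_b
    if overlap:
        raise ValidationError(f"groups overlap: {sorted(overlap)[:5]}")
    if len(set_a) < 3 or len(set_b) < 3:
        raise ValidationError("both groups need at least 3 cells")
    pos = {b: i for i, b in enumerate(expr.barcodes)}
    try:
        idx_a = [pos[b] for b in group_a_barcodes]
        idx_b = [pos[b] for b in group_b_barcodes]
    except KeyError as exc:
        raise ValidationError(f"barcode not in matrix: {exc.args[0]}") from None

    dense = np.asarray(expr.normalized.todense())
    a = dense[:, idx_a]
    b = dense[:, idx_b]
    lfc = a.mean(axis=1) - b.mean(axis=1)
    p = np.ones(len(expr.genes))
    for i in range(len(expr.genes)):
        row_a, row_b = a[i], b[i]
        if np.ptp(np.concatenate([row_a, row_b])) == 0:
            continue  # constant gene: p = 1, lfc = 0 by construction
        if method == "wilcoxon":
            p[i] = scipy.stats.mannwhitneyu(row_a, row_b, alternative="two-sided").pvalue
        elif method == "ttest":
            p[i] = scipy.stats.ttest_ind(row_a, row_b, equal_var=False).pvalue
        else:
            raise ValidationError(f"unknown method: {method}")
    return pd.DataFrame(
        {
            "gene": expr.genes,
            "log_fold_change": lfc,
            "p_value": p,
            "fdr": benjamini_hochberg(p),
        }
    )


def composition_stats(
    proportions: pd.DataFrame, groups: dict[str, str]
) -> pd.DataFrame:
    """Per-cell-type two-group Wilcoxon rank-sum across subjects, BH over types.

    ``proportions`` is subjects x cell types, each row summing to 1 (tol 1e-9);
    ``groups`` maps subject id to group label (exactly two labels).  n refers
    to subjects, never cells.
    """
    sums = proportions.sum(axis=1)
    off = sums[(sums - 1).abs() > 1e-9]
    if len(off):
        raise ValidationError(
            f"proportions must sum to 1 per subject; offending: {list(off.index)[:5]}"
        )
    labels = pd.Series({s: groups[s] for s in proportions.index})
    uniq = sorted(labels.unique())
    if len(uniq) != 2:
        raise ValidationError(f"exactly two groups required, got {uniq}")
    idx_a = labels[labels == uniq[0]].index
    idx_b = labels[labels == uniq[1]].index
    if len(idx_a) < 2 or len(idx_b) < 2:
        raise ValidationError("each group needs at least 2 subjects")
    rows = []
    for ct in proportions.columns:
        x, y = proportions.loc[idx_a, ct], proportions.loc[idx_b, ct]
        if np.ptp(np.concatenate([x, y])) == 0:
            p = 1.0
        else:
            p = scipy.stats.mannwhitneyu(x, y, alternative="two-sided").pvalue
        rows.append({"cell_type": ct, "p_value": p,
                     "n_a": len(idx_a), "n_b": len(idx_b)})
    out = pd.DataFrame(rows)
    out["fdr"] = benjamini_hochberg(out["p_value"])
    return out


def correlate_proportions(
    type_a: Sequence[float], type_b: Sequence[float]
) -> tuple[float, float]:
    """Pearson r and p between two per-subject proportion vectors."""
    a = np.asarray(type_a, dtype=float)
    b = np.asarray(type_b, dtype=float)
    if a.shape != b.shape or a.size < 3:
        raise ValidationError("need equal-length vectors with >= 3 subjects")
    r, p = scipy.stats.pearsonr(a, b)
    return float(r), float(p)
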