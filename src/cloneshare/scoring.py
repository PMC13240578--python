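"""Correlation-based pattern annotation with iterative fine-tuning.

Labelled cells (e.g. patient cells carrying a clone-derived sharing-pattern
label) are aggregated into per-pattern pseudo-bulk reference profiles
(per-gene median of normalized expression).  Query cells are then scored by
Spearman rank correlation against each profile over a marker-gene set — the
union, over ordered pattern pairs (A, B), of the genes most elevated in A
relative to B — and iteratively fine-tuned: patterns scoring within
``margin`` of the top are retained, scores are recomputed on the surviving
patterns' pairwise markers only, and the process repeats until a single
pattern remains or the retained set stops shrinking.

This is the scheme used to ask whether unlabelled (e.g. control-lung) cells
transcriptionally resemble any of the sharing patterns; scores are
rank-based, hence invariant to monotone transforms of the query.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import scipy.stats

from .errors import ValidationError
from .io import ExpressionMatrix

logger = logging.getLogger("cloneshare")

AMBIGUOUS = "AMBIGUOUS"


@dataclass
class ReferenceProfileSet:
    """Pattern-level pseudo-bulk profiles and pairwise marker genes."""

    patterns: list[str]
    profiles: pd.DataFrame  # genes x patterns
    marker_genes: dict[tuple[str, str], list[str]]

    def evaluation_genes(self, patterns: Optional[Sequence[str]] = None) -> list[str]:
        """Union of pairwise marker genes among the given patterns (sorted)."""
        patterns = list(self.patterns if patterns is None else patterns)
        genes: set[str] = set()
        for a in patterns:
            for b in patterns:
                if a != b:
                    genes.update(self.marker_genes[(a, b)])
        return sorted(genes)


def build_references(
    expr: ExpressionMatrix,
    labels: pd.Series,
    genes_per_pair: int = 50,
    min_cells: int = 10,
    aggregate: str = "median",
) -> ReferenceProfileSet:
    """Aggregate labelled cells into per-pattern reference profiles.

    ``labels`` maps barcode -> pattern for the reference (training) cells.
    Patterns with fewer than ``min_cells`` cells are dropped with a warning;
    fewer than two surviving patterns is an error.  Markers for the ordered
    pair (A, B) are the ``genes_per_pair`` genes with the largest strictly
    positive difference profile_A - profile_B (ties broken by gene name), so
    a constant gene is never selected.
    """
    if expr.normalized is None:
        raise ValidationError("normalized layer missing; call log_normalize first")
    if aggregate not in ("median", "mean"):
        raise ValidationError("aggregate must be 'median' or 'mean'")
    pos = {b: i for i, b in enumerate(expr.barcodes)}
    unknown = [b for b in labels.index if b not in pos]
    if unknown:
        raise ValidationError(f"labelled barcodes not in matrix: {unknown[:5]}")

    profiles = {}
    for pattern in sorted(labels.unique()):
        barcodes = labels.index[labels == pattern]
        if len(barcodes) < min_cells:
            logger.warning(
                "build_references: pattern %s has %d < %d cells, dropped",
                pattern, len(barcodes), min_cells,
            )
            continue
        cols = [pos[b] for b in barcodes]
        dense = np.asarray(expr.normalized[:, cols].todense())
        profiles[pattern] = (
            np.median(dense, axis=1) if aggregate == "median" else dense.mean(axis=1)
        )
    if len(profiles) < 2:
        raise ValidationError(
            f"need at least 2 patterns with >= {min_cells} cells, got {len(profiles)}"
        )
    patterns = sorted(profiles)
    prof_df = pd.DataFrame(profiles, index=expr.genes)[patterns]

    markers: dict[tuple[str, str], list[str]] = {}
    for a in patterns:
        for b in patterns:
            if a == b:
                continue
            diff = prof_df[a] - prof_df[b]
            pos_diff = diff[diff > 0]
            ordered = pos_diff.sort_values(ascending=False, kind="stable")
            # deterministic tie-break within equal differences: gene name
            ordered = ordered.iloc[
                np.lexsort((ordered.index.to_numpy(), -ordered.to_numpy()))
            ]
            markers[(a, b)] = list(ordered.index[:genes_per_pair])
            if not markers[(a, b)]:
                logger.warning(
                    "build_references: no positive markers for pair (%s, %s)", a, b
                )
    return ReferenceProfileSet(patterns=patterns, profiles=prof_df, marker_genes=markers)


def _spearman(x: np.ndarray, y: np.ndarray) -> float:
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return 0.0  # zero-variance vector: correlation undefined, scored 0
    rho = scipy.stats.spearmanr(x, y).statistic
    return float(rho) if np.isfinite(rho) else 0.0


def score_cell(
    query: pd.Series,
    refs: ReferenceProfileSet,
    patterns: Optional[Sequence[str]] = None,
    min_genes: int = 20,
) -> dict[str, float]:
    """Spearman correlation of a query cell against each reference profile.

    The evaluation gene set is the union of pairwise marker genes among the
    considered patterns, intersected with the query's genes; fewer than
    ``min_genes`` evaluation genes is an error.  Ties are mid-ranked (the
    Spearman convention).
    """
    patterns = list(refs.patterns if patterns is None else patterns)
    genes = [g for g in refs.evaluation_genes(patterns) if g in query.index]
    if len(genes) < min_genes:
        raise ValidationError(
            f"evaluation set too small: {len(genes)} genes < {min_genes}"
        )
    q = query.loc[genes].to_numpy(dtype=float)
    return {
        p: _spearman(q, refs.profiles.loc[genes, p].to_numpy(dtype=float))
        for p in patterns
    }


def fine_tune(
    query: pd.Series,
    refs: ReferenceProfileSet,
    margin: float = 0.05,
    initial_scores: Optional[dict[str, float]] = None,
) -> str:
    """Iteratively narrow the candidate patterns for one query cell.

    Each round retains patterns scoring >= (top - margin) and rescores using
    only the surviving patterns' pairwise markers.  Terminates when one
    pattern remains or the retained set stops shrinking; at a stall, a
    strictly highest raw score wins and an exact tie yields AMBIGUOUS
    (tied labels logged).
    """
    if margin < 0:
        raise ValidationError("margin must be >= 0")
    candidates = list(refs.patterns)
    scores = dict(initial_scores) if initial_scores is not None else score_cell(query, refs)
    while len(candidates) > 1:
        top = max(scores[p] for p in candidates)
        retained = [p for p in candidates if scores[p] >= top - margin]
        if len(retained) == len(candidates):
            break
        candidates = retained
        if len(candidates) == 1:
            break
        try:
            scores = score_cell(query, refs, patterns=candidates, min_genes=2)
        except ValidationError:
            break  # pairwise marker set degenerate: stall and tie-break
    if len(candidates) == 1:
        return candidates[0]
    best = max(scores[p] for p in candidates)
    winners = sorted(p for p in candidates if scores[p] == best)
    if len(winners) > 1:
        logger.info("fine_tune: exact score tie among %s -> AMBIGUOUS", winners)
        return AMBIGUOUS
    return winners[0]


def annotate(
    expr: ExpressionMatrix,
    refs: ReferenceProfileSet,
    margin: float = 0.05,
    min_genes: int = 20,
) -> pd.DataFrame:
    """Score and fine-tune every cell of ``expr`` against the references.

    Returns a DataFrame indexed by barcode with one ``score_<pattern>``
    column per pattern (initial scores), ``initial_label`` (argmax),
    ``final_label`` (after fine-tuning) and ``pruned`` (True when
    fine-tuning could not separate the top candidates).
    """
    if expr.normalized is None:
        raise ValidationError("normalized layer missing; call log_normalize first")
    genes = [g for g in refs.evaluation_genes() if g in set(expr.genes)]
    if len(genes) < min_genes:
        raise ValidationError(
            f"evaluation set too small: {len(genes)} genes < {min_genes}"
        )
    gi = expr.gene_index(genes)
    dense = np.asarray(expr.normalized[gi, :].todense())
    rows = []
    for j, barcode in enumerate(expr.barcodes):
        query = pd.Series(dense[:, j], index=genes)
        scores = score_cell(query, refs, min_genes=min_genes)
        initial = sorted(scores, key=lambda p: (-scores[p], p))[0]
        final = fine_tune(query, refs, margin=margin, initial_scores=scores)
        row = {f"score_{p}": scores[p] for p in refs.patterns}
        row.update(
            barcode=barcode,
            initial_label=initial,
            final_label=final,
            pruned=final == AMBIGUOUS,
        )
        rows.append(row)
    return pd.DataFrame(rows).set_index("barcode")


def summarize_predictions(results: pd.DataFrame) -> pd.DataFrame:
    """Counts and proportions of final labels (counts sum to the query count)."""
    if results.empty:
        return pd.DataFrame(columns=["count", "proportion"])
    counts = results["final_label"].value_counts().sort_index()
    return pd.DataFrame({"count": counts, "proportion": counts / counts.sum()})
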