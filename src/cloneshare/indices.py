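"""Entropy-based clonality indices: expansion, migration, transition.

All three are built on the Shannon entropy (natural log) of clone-level
frequency distributions:

* expansion index of a stratum: ``1 - H(p) / ln N`` where ``p`` is the
  clone-frequency vector in the stratum and ``N`` the number of distinct
  clones — 0 for all-singleton repertoires, 1 for a monoclonal one
  (one minus Pielou evenness);
* migration index: clone-size-weighted mean entropy of each clone's
  distribution across compartments (lung / BALF / PBMC), optionally
  restricted to a compartment pair;
* transition index: the same machinery across phenotype clusters.

Normalized variants divide by ``ln k`` (k categories considered) so values
are comparable across pair sizes.  Aggregation across subjects computes the
index per subject first, then averages weighted by each subject's stratum
cell count; because clone ids are subject-scoped this coincides with the
pooled computation, which is also available for comparison.
"""

from __future__ import annotations

import logging
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .clonotypes import COMPARTMENTS, CloneTable
from .errors import ValidationError

logger = logging.getLogger("cloneshare")


def shannon_entropy(p: Sequence[float]) -> float:
    """H(p) = -sum p_i ln p_i, with 0 * ln 0 := 0."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        raise ValidationError("empty probability vector")
    if (p < 0).any():
        raise ValidationError("probabilities must be nonnegative")
    if abs(p.sum() - 1.0) > 1e-9:
        raise ValidationError(f"probabilities must sum to 1 (got {p.sum()!r})")
    nz = p[p > 0]
    return float(-(nz * np.log(nz)).sum())


def expansion_index(sizes: Sequence[int]) -> float:
    """Clonal expansion of a stratum from its clone sizes, in [0, 1].

    ``1 - H(p)/ln N`` over the clone-frequency vector; with a single clone
    the index is 1 if that clone has >= 2 cells and 0 for a lone singleton.
    """
    sizes = np.asarray(sizes, dtype=float)
    if sizes.size == 0:
        raise ValidationError("expansion_index: empty stratum")
    if (sizes <= 0).any():
        raise ValidationError("clone sizes must be positive")
    if sizes.size == 1:
        return 1.0 if sizes[0] >= 2 else 0.0
    p = sizes / sizes.sum()
    value = float(1.0 - shannon_entropy(p) / np.log(sizes.size))
    # snap floating fuzz at the boundaries (evenness computed to ~1e-16)
    if abs(value) < 1e-12:
        return 0.0
    if abs(value - 1.0) < 1e-12:
        return 1.0
    return min(1.0, max(0.0, value))


def _weighted_clone_entropy(
    counts: pd.DataFrame, normalize: bool
) -> Optional[tuple[float, int, int]]:
    """Clone-size-weighted mean entropy of per-clone category distributions.

    ``counts`` is clones x categories; clones with zero total are dropped.
    Returns (value, n_clones, n_cells) or None when no cells remain.
    """
    totals = counts.sum(axis=1)
    counts = counts.loc[totals > 0]
    totals = totals[totals > 0]
    if counts.empty:
        return None
    q = counts.div(totals, axis=0).to_numpy()
    with np.errstate(divide="ignore", invalid="ignore"):
        h = -np.nansum(np.where(q > 0, q * np.log(q), 0.0), axis=1)
    w = totals.to_numpy() / totals.sum()
    value = float((w * h).sum())
    if normalize:
        # a single category admits no sharing: raw value is 0, kept as 0
        value = value / np.log(counts.shape[1]) if counts.shape[1] > 1 else 0.0
    return value, len(counts), int(totals.sum())


def _aggregate_rows(per_subject: list[dict], kind: str, cluster, pair) -> list[dict]:
    """Append the cell-weighted across-subject mean as a 'pooled' row."""
    rows = list(per_subject)
    if per_subject:
        w = np.array([r["n_cells"] for r in per_subject], dtype=float)
        v = np.array([r["value"] for r in per_subject], dtype=float)
        rows.append(
            {
                "subject_id": "pooled",
                "cluster": cluster,
                "kind": kind,
                "pair": pair,
                "value": float((w * v).sum() / w.sum()),
                "n_clones": int(sum(r["n_clones"] for r in per_subject)),
                "n_cells": int(w.sum()),
            }
        )
    return rows


def _entropy_index(
    table: CloneTable,
    kind: str,
    categories_of: str,
    cluster: Optional[str],
    categories: Optional[Sequence[str]],
    normalize: bool,
) -> pd.DataFrame:
    df = table.cells
    if cluster is not None:
        df = df[df["cluster"] == cluster]
    if categories is None:
        categories = (
            COMPARTMENTS if categories_of == "compartment"
            else sorted(df[categories_of].unique())
        )
        pair = None
    else:
        categories = list(categories)
        if len(categories) < 2:
            raise ValidationError("need at least two categories")
        pair = ",".join(categories)
    df = df[df[categories_of].isin(categories)]
    if df.empty:
        logger.warning("%s_index: stratum with zero cells omitted (cluster=%s)", kind.lower(), cluster)
        return pd.DataFrame(
            columns=["subject_id", "cluster", "kind", "pair", "value", "n_clones", "n_cells"]
        )
    per_subject = []
    for subject in sorted(df["subject_id"].unique()):
        sub = df[df["subject_id"] == subject]
        counts = (
            sub.groupby(["clone_id", categories_of]).size().unstack(fill_value=0)
            .reindex(columns=categories, fill_value=0)
        )
        res = _weighted_clone_entropy(counts, normalize)
        if res is None:
            continue
        value, n_clones, n_cells = res
        per_subject.append(
            {
                "subject_id": subject,
                "cluster": cluster,
                "kind": kind,
                "pair": pair,
                "value": value,
                "n_clones": n_clones,
                "n_cells": n_cells,
            }
        )
    return pd.DataFrame(_aggregate_rows(per_subject, kind, cluster, pair))


def migration_index(
    table: CloneTable,
    cluster: Optional[str] = None,
    compartments: Optional[Sequence[str]] = None,
    normalize: bool = True,
) -> pd.DataFrame:
    """Cross-compartment migration index, per subject plus a pooled row.

    ``compartments`` may name a pair (pairwise analysis: clones are
    restricted to their cells in those two compartments and clones absent
    from both are dropped) or be None for all three.
    """
    return _entropy_index(table, "MIGRATION", "compartment", cluster,
                          compartments, normalize)


def transition_index(
    table: CloneTable,
    clusters: Optional[Sequence[str]] = None,
    normalize: bool = True,
) -> pd.DataFrame:
    """Cross-cluster transition index (same machinery over cluster labels)."""
    return _entropy_index(table, "TRANSITION", "cluster", None, clusters, normalize)


def migration_index_pooled(
    table: CloneTable,
    cluster: Optional[str] = None,
    compartments: Optional[Sequence[str]] = None,
    normalize: bool = True,
) -> Optional[float]:
    """Single pooled-computation migration index (all subjects' cells at once).

    With subject-scoped clone ids this equals the cell-weighted mean of the
    per-subject values; kept as an explicit alternative for comparison.
    """
    df = table.cells
    if cluster is not None:
        df = df[df["cluster"] == cluster]
    categories = list(compartments) if compartments is not None else COMPARTMENTS
    df = df[df["compartment"].isin(categories)]
    if df.empty:
        return None
    counts = (
        df.groupby(["clone_id", "compartment"]).size().unstack(fill_value=0)
        .reindex(columns=categories, fill_value=0)
    )
    res = _weighted_clone_entropy(counts, normalize)
    return None if res is None else res[0]


def expansion_index_table(table: CloneTable, by: str = "cluster") -> pd.DataFrame:
    """Expansion index per stratum, per subject plus a pooled row.

    Clone sizes are counted within the stratum; the pooled row is the
    cell-weighted mean over subjects.
    """
    if by not in ("cluster", "compartment"):
        raise ValidationError("by must be 'cluster' or 'compartment'")
    rows = []
    for stratum in sorted(table.cells[by].unique()):
        sub = table.cells[table.cells[by] == stratum]
        per_subject = []
        for subject in sorted(sub["subject_id"].unique()):
            sizes = sub[sub["subject_id"] == subject].groupby("clone_id").size()
            per_subject.append(
                {
                    "subject_id": subject,
                    "cluster": stratum,
                    "kind": "EXPANSION",
                    "pair": None,
                    "value": expansion_index(sizes.to_numpy()),
                    "n_clones": len(sizes),
                    "n_cells": int(sizes.sum()),
                }
            )
        rows.extend(_aggregate_rows(per_subject, "EXPANSION", stratum, None))
    return pd.DataFrame(rows)
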