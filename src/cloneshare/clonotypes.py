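"""Clone table construction and repertoire analytics.

The :class:`CloneTable` is the central object of the repertoire analyses: it
records, for every assigned cell, its subject, clone, compartment (lung
tissue / BALF / PBMC) and phenotype cluster.  All downstream quantities
(expansion counts, repertoire overlap, sharing patterns, entropy indices)
are derived from it by grouping.

Clone ids are subject-scoped, so pooled set operations over clone ids are
automatically within-subject.
"""

from __future__ import annotations

from typing import Optional, Sequence

import pandas as pd

from .errors import IntegrityError, ValidationError
from .io import CellRecord, CloneAssignment, Compartment, ReceptorType

COMPARTMENTS = [c.value for c in Compartment]

ISOTYPE_CLASSES = ["IGHA", "IGHG", "IGHM", "IGHD", "IGHE"]


class CloneTable:
    """Per-cell clone membership with compartment and cluster annotations.

    Attributes
    ----------
    cells : pandas.DataFrame
        One row per assigned cell with columns barcode, subject_id, clone_id,
        compartment, cluster, receptor_type, isotype.
    """

    def __init__(self, cells: pd.DataFrame):
        required = {"barcode", "subject_id", "clone_id", "compartment",
                    "cluster", "receptor_type", "isotype"}
        missing = required - set(cells.columns)
        if missing:
            raise ValidationError(f"CloneTable missing columns: {sorted(missing)}")
        self.cells = cells.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.cells)

    @property
    def subjects(self) -> list[str]:
        return sorted(self.cells["subject_id"].unique())

    @property
    def clusters(self) -> list[str]:
        return sorted(self.cells["cluster"].unique())

    def restrict(self, receptor_type: Optional[ReceptorType] = None,
                 subject_id: Optional[str] = None,
                 cluster: Optional[str] = None) -> "CloneTable":
        df = self.cells
        if receptor_type is not None:
            df = df[df["receptor_type"] == ReceptorType(receptor_type).value]
        if subject_id is not None:
            df = df[df["subject_id"] == subject_id]
        if cluster is not None:
            df = df[df["cluster"] == cluster]
        return CloneTable(df.copy())

    def clone_sizes(self) -> pd.Series:
        """Total cells per (subject_id, clone_id), across all compartments."""
        return self.cells.groupby(["subject_id", "clone_id"]).size()

    def by_compartment(self) -> pd.DataFrame:
        """Clone x compartment cell counts (columns LUNG, BALF, PBMC)."""
        tab = (
            self.cells.groupby(["subject_id", "clone_id", "compartment"])
            .size()
            .unstack(fill_value=0)
        )
        return tab.reindex(columns=COMPARTMENTS, fill_value=0)

    def by_cluster(self) -> pd.DataFrame:
        """Clone x cluster cell counts."""
        return (
            self.cells.groupby(["subject_id", "clone_id", "cluster"])
            .size()
            .unstack(fill_value=0)
        )

    def clone_isotypes(self) -> pd.Series:
        """Isotype per clone (first non-missing heavy-chain constant gene)."""
        def pick(vals):
            non_missing = [v for v in vals if isinstance(v, str) and v]
            return non_missing[0] if non_missing else None

        return self.cells.groupby(["subject_id", "clone_id"])["isotype"].agg(pick)

    def to_tsv(self, path) -> None:
        comp = self.by_compartment()
        clus = self.by_cluster()
        out = comp.join(clus, how="outer").fillna(0).astype(int)
        out.insert(0, "size_total", out[COMPARTMENTS].sum(axis=1))
        out.reset_index().to_csv(path, sep="\t", index=False)


def build_clone_table(
    assignments: Sequence[CloneAssignment], cells: Sequence[CellRecord]
) -> CloneTable:
    """Join clone assignments onto cell annotations.

    Every assigned cell is counted exactly once; cells without an assignment
    are excluded.  An assignment referencing a barcode absent from ``cells``
    is an integrity error.
    """
    meta = {c.barcode: c for c in cells}
    rows = []
    seen: set[str] = set()
    for a in assignments:
        if a.barcode in seen:
            raise IntegrityError(f"barcode {a.barcode} assigned twice")
        seen.add(a.barcode)
        cell = meta.get(a.barcode)
        if cell is None:
            raise IntegrityError(f"assignment references unknown barcode {a.barcode}")
        if cell.subject_id != a.subject_id:
            raise IntegrityError(
                f"barcode {a.barcode}: subject mismatch between assignment and metadata"
            )
        rows.append(
            {
                "barcode": a.barcode,
                "subject_id": a.subject_id,
                "clone_id": a.clone_id,
                "compartment": cell.compartment.value,
                "cluster": cell.cluster,
                "receptor_type": a.receptor_type.value,
                "isotype": a.isotype,
            }
        )
    columns = ["barcode", "subject_id", "clone_id", "compartment", "cluster",
               "receptor_type", "isotype"]
    return CloneTable(pd.DataFrame(rows, columns=columns))


def expansion_counts(
    table: CloneTable, min_size: int = 2, by: str = "cluster"
) -> pd.Series:
    """Cells belonging to expanded clones, per stratum.

    A cell is expanded iff its clone's total size within its subject (pooled
    over compartments) is >= ``min_size``.  ``by`` selects the stratifying
    column ("cluster" or "compartment").
    """
    if min_size < 2:
        raise ValidationError("min_size must be >= 2")
    if by not in ("cluster", "compartment"):
        raise ValidationError("by must be 'cluster' or 'compartment'")
    sizes = table.clone_sizes()
    df = table.cells
    key = pd.MultiIndex.from_frame(df[["subject_id", "clone_id"]])
    expanded = sizes.reindex(key).to_numpy() >= min_size
    counts = df.loc[expanded].groupby(by).size()
    return counts.reindex(sorted(df[by].unique()), fill_value=0)


def repertoire_overlap(
    table: CloneTable, stratum_a: str, stratum_b: str, by: str = "cluster"
) -> dict:
    """Clone sharing between two strata (clusters or compartments).

    shared_clones is summed over subjects; the Jaccard index is pooled over
    subject-scoped clone ids, and shared_cell_fraction_* give the fraction of
    each stratum's cells whose clone is also seen in the other stratum.
    """
    if by not in ("cluster", "compartment"):
        raise ValidationError("by must be 'cluster' or 'compartment'")
    df = table.cells
    known = set(df[by].unique())
    for s in (stratum_a, stratum_b):
        if s not in known:
            raise ValidationError(f"unknown stratum: {s}")
    in_a = df[df[by] == stratum_a]
    in_b = df[df[by] == stratum_b]
    clones_a = set(in_a["clone_id"])
    clones_b = set(in_b["clone_id"])
    shared = clones_a & clones_b
    union = clones_a | clones_b
    frac_a = float((in_a["clone_id"].isin(shared)).mean()) if len(in_a) else 0.0
    frac_b = float((in_b["clone_id"].isin(shared)).mean()) if len(in_b) else 0.0
    return {
        "shared_clones": len(shared),
        "jaccard": len(shared) / len(union) if union else 0.0,
        "shared_cell_fraction_a": frac_a,
        "shared_cell_fraction_b": frac_b,
    }


def isotype_class(isotype: Optional[str]) -> str:
    """Map a heavy-chain constant gene (e.g. IGHA1) to its class (IGHA)."""
    if not isotype:
        return "missing"
    for cls in ISOTYPE_CLASSES:
        if isotype.startswith(cls):
            return cls
    return "missing"


def isotype_composition(table: CloneTable, by: str = "cluster") -> pd.DataFrame:
    """Cell counts per isotype class, per stratum plus a 'total' row (BCR only)."""
    bcr = table.cells[table.cells["receptor_type"] == ReceptorType.BCR.value].copy()
    classes = ISOTYPE_CLASSES + ["missing"]
    if bcr.empty:
        return pd.DataFrame(columns=classes)
    bcr["isotype_class"] = bcr["isotype"].map(isotype_class)
    tab = bcr.groupby([by, "isotype_class"]).size().unstack(fill_value=0)
    tab = tab.reindex(columns=classes, fill_value=0)
    tab.loc["total"] = tab.sum(axis=0)
    return tab
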