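"""Cross-compartment sharing-pattern classification.

Expanded clones are classified by which compartments they occupy:

=========  =====  =====  =====
pattern    lung   PBMC   BALF
=========  =====  =====  =====
P1A        yes    no     yes    (interstitium-to-airway; activated)
P1B        yes    no     no     (lung-restricted; resting resident)
P2         yes    yes    no     (blood-interstitium; circulating effector)
=========  =====  =====  =====

The four remaining non-empty occupancy states (BALF-only, PBMC-only,
PBMC+BALF, triple-positive) form an explicit OTHER class; the empty state —
which can arise when a presence threshold ``min_cells`` > 1 wipes out every
compartment — and clones failing the expansion gate are UNCLASSIFIED.
Classification is per clone; cells inherit their clone's label.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum
from typing import Optional, Sequence

import pandas as pd

from .clonotypes import CloneTable
from .errors import ValidationError
from .io import CellRecord, CloneAssignment

logger = logging.getLogger("cloneshare")


class PatternLabel(str, Enum):
    P1A = "P1A"
    P1B = "P1B"
    P2 = "P2"
    OTHER = "OTHER"
    UNCLASSIFIED = "UNCLASSIFIED"


PATTERNS = [PatternLabel.P1A, PatternLabel.P1B, PatternLabel.P2, PatternLabel.OTHER]


@dataclass(frozen=True)
class OccupancyVector:
    """Presence of a clone in each compartment (>= min_cells cells)."""

    lung: bool
    pbmc: bool
    balf: bool

    def as_tuple(self) -> tuple[bool, bool, bool]:
        return (self.lung, self.pbmc, self.balf)


def occupancy(lung_n: int, pbmc_n: int, balf_n: int,
              min_cells: int = 1) -> OccupancyVector:
    """Threshold per-compartment cell counts into presence calls."""
    if min_cells < 1:
        raise ValidationError("min_cells must be >= 1")
    if min(lung_n, pbmc_n, balf_n) < 0:
        raise ValidationError("compartment counts must be >= 0")
    return OccupancyVector(
        lung=lung_n >= min_cells, pbmc=pbmc_n >= min_cells, balf=balf_n >= min_cells
    )


def classify_pattern(occ: OccupancyVector) -> PatternLabel:
    """Map an occupancy state to its sharing pattern (total on all 8 states)."""
    mapping = {
        (True, False, True): PatternLabel.P1A,
        (True, False, False): PatternLabel.P1B,
        (True, True, False): PatternLabel.P2,
        (False, False, False): PatternLabel.UNCLASSIFIED,
    }
    return mapping.get(occ.as_tuple(), PatternLabel.OTHER)


def classify_clones(
    table: CloneTable, min_size: int = 2, min_cells: int = 1
) -> pd.DataFrame:
    """Classify every clone in the table.

    Returns a DataFrame with columns subject_id, clone_id, size_total,
    lung_n, pbmc_n, balf_n, pattern.  Clones below the expansion gate
    (``size_total < min_size``) are UNCLASSIFIED: the sharing patterns
    describe expanded clones only.
    """
    if min_size < 2:
        raise ValidationError("min_size must be >= 2")
    comp = table.by_compartment().reset_index()
    comp["size_total"] = comp[["LUNG", "BALF", "PBMC"]].sum(axis=1)
    patterns = []
    for row in comp.itertuples(index=False):
        if row.size_total < min_size:
            patterns.append(PatternLabel.UNCLASSIFIED.value)
        else:
            occ = occupancy(row.LUNG, row.PBMC, row.BALF, min_cells=min_cells)
            patterns.append(classify_pattern(occ).value)
    return pd.DataFrame(
        {
            "subject_id": comp["subject_id"],
            "clone_id": comp["clone_id"],
            "size_total": comp["size_total"],
            "lung_n": comp["LUNG"],
            "pbmc_n": comp["PBMC"],
            "balf_n": comp["BALF"],
            "pattern": patterns,
        }
    )


def pattern_proportions(
    clone_labels: pd.DataFrame, weight: str = "clones"
) -> pd.DataFrame:
    """Per-subject pattern proportions over {P1A, P1B, P2, OTHER}.

    ``weight='clones'`` counts each classified clone once; ``weight='cells'``
    weights clones by their member-cell count.  UNCLASSIFIED clones are
    excluded; subjects with no classified clone are omitted with a warning.
    """
    if weight not in ("clones", "cells"):
        raise ValidationError("weight must be 'clones' or 'cells'")
    classified = clone_labels[
        clone_labels["pattern"] != PatternLabel.UNCLASSIFIED.value
    ].copy()
    dropped = set(clone_labels["subject_id"]) - set(classified["subject_id"])
    for subj in sorted(dropped):
        logger.warning("pattern_proportions: subject %s has no classified clones", subj)
    if classified.empty:
        return pd.DataFrame(columns=[p.value for p in PATTERNS])
    classified["w"] = 1 if weight == "clones" else classified["size_total"]
    tab = classified.pivot_table(
        index="subject_id", columns="pattern", values="w", aggfunc="sum", fill_value=0
    )
    tab = tab.reindex(columns=[p.value for p in PATTERNS], fill_value=0).astype(float)
    return tab.div(tab.sum(axis=1), axis=0)


def project_to_cells(
    clone_labels: pd.DataFrame,
    assignments: Sequence[CloneAssignment],
    cells: Optional[Sequence[CellRecord]] = None,
) -> pd.Series:
    """Propagate clone pattern labels to cells (barcode -> label).

    Each assigned cell inherits its clone's label.  When the full cell list
    is given, cells without a clone assignment are included as UNCLASSIFIED.
    """
    label_of = dict(zip(clone_labels["clone_id"], clone_labels["pattern"]))
    out: dict[str, str] = {}
    if cells is not None:
        for cell in cells:
            out[cell.barcode] = PatternLabel.UNCLASSIFIED.value
    for a in assignments:
        out[a.barcode] = label_of.get(a.clone_id, PatternLabel.UNCLASSIFIED.value)
    return pd.Series(out, name="pattern")
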