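"""Entropy indices: clonal expansion, cross-compartment migration, transition.

Computes the normalized indices per subject (pooled rows are cell-weighted
means) for every cluster and compartment pair.  In this cohort the
lung-BALF pair carries most of the sharing for the resident-memory and
cycling clusters (the P1A signature), while lung-PBMC sharing concentrates
in the effector clusters (P2).
"""

from pathlib import Path

import pandas as pd

import cloneshare as cs
from cloneshare.pipeline import COMPARTMENT_PAIRS

ROOT = Path(__file__).resolve().parents[1]
COHORT = ROOT / "scratch" / "cohort"


def main() -> None:
    contigs = cs.read_contig_table(COHORT / "contigs.csv")
    cells = cs.read_cell_metadata(COHORT / "cells.tsv")
    assignments = cs.collapse_to_clonotypes(contigs, cells)
    table = cs.build_clone_table(assignments, cells)

    frames = [cs.expansion_index_table(table, by="cluster")]
    for cluster in [None] + table.clusters:
        frames.append(cs.migration_index(table, cluster=cluster))
        for pair in COMPARTMENT_PAIRS:
            frames.append(cs.migration_index(table, cluster=cluster,
                                             compartments=list(pair)))
    frames.append(cs.transition_index(table))
    indices = pd.concat(frames, ignore_index=True)
    indices.to_csv(ROOT / "results" / "indices.tsv", sep="\t", index=False)

    pooled = indices[indices["subject_id"] == "pooled"]
    pair_view = pooled[(pooled["kind"] == "MIGRATION") & pooled["pair"].notna()]
    print("pooled pairwise migration indices per cluster:")
    print(pair_view.pivot_table(index="cluster", columns="pair", values="value")
          .round(3).to_string())
    print("\npooled expansion index per cluster:")
    print(pooled[pooled["kind"] == "EXPANSION"]
          .set_index("cluster")["value"].round(3).to_string())


if __name__ == "__main__":
    main()
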