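import numpy as np
import pandas as pd
import pytest

import cloneshare as cs
from cloneshare.io import CellRecord, Compartment, ContigRecord, Chain, Group


def make_cell(barcode, subject="S01", compartment="LUNG", cluster="T8_rm",
              mito=0.05, n_genes=1500, group="PNEUMONIA"):
    return CellRecord(
        barcode=barcode, subject_id=subject,
        compartment=Compartment(compartment), group=Group(group),
        cluster=cluster, mito_fraction=mito, n_genes=n_genes,
    )


def make_contig(barcode, chain="TRB", v="TRBV1", j="TRBJ1", cdr3_nt="TGTGCA",
                cdr3_aa="CA", productive=True, umis=5, c_gene="", raw_id="c1"):
    return ContigRecord(
        barcode=barcode, chain=Chain(chain), v_gene=v, j_gene=j,
        cdr3_nt=cdr3_nt, cdr3_aa=cdr3_aa, productive=productive, umis=umis,
        c_gene=c_gene, raw_clonotype_id=raw_id,
    )


@pytest.fixture(scope="session")
def small_cohort():
    """A 2-subject default-noise cohort shared across read-only tests."""
    cfg = cs.SimulationConfig(n_subjects=2, clones_per_subject=100)
    return cs.simulate_cohort(cfg, seed=11)


@pytest.fixture(scope="session")
def small_cohort_analysis(small_cohort):
    """Assignments, clone table and clone labels for the shared cohort."""
    c = small_cohort
    assignments = cs.collapse_to_clonotypes(c.contigs, c.cells)
    table = cs.build_clone_table(assignments, c.cells)
    labels = cs.classify_clones(table)
    return assignments, table, labels


def random_clone_table(rng, n_clones=20, n_subjects=2):
    """Random CloneTable for oracle comparisons."""
    clusters = ["A", "B", "C"]
    rows = []
    bc = 0
    for s in range(n_subjects):
        subject = f"S{s + 1:02d}"
        for k in range(rng.integers(1, n_clones + 1)):
            clone = f"{subject}|cl{k}"
            for _ in range(rng.integers(1, 6)):
                rows.append({
                    "barcode": f"b{bc}", "subject_id": subject, "clone_id": clone,
                    "compartment": ["LUNG", "BALF", "PBMC"][rng.integers(3)],
                    "cluster": clusters[rng.integers(3)],
                    "receptor_type": "TCR", "isotype": None,
                })
                bc += 1
    return cs.CloneTable(pd.DataFrame(rows))
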