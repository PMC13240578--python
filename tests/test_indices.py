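"""Entropy, expansion, migration and transition indices against loop oracles."""

import numpy as np
import pandas as pd
import pytest

import cloneshare as cs
from cloneshare.errors import ValidationError

from conftest import make_cell, random_clone_table
from test_clonotypes import assign


def loop_index(cells: pd.DataFrame, category: str, categories, normalize: bool):
    """Independent per-clone loop oracle for migration/transition indices."""
    cells = cells[cells[category].isin(categories)]
    total = 0.0
    n = len(cells)
    for clone in cells["clone_id"].unique():
        sub = cells[cells["clone_id"] == clone]
        h = 0.0
        for cat in categories:
            q = (sub[category] == cat).sum() / len(sub)
            if q > 0:
                h -= q * np.log(q)
        total += len(sub) / n * h
    if normalize:
        return total / np.log(len(categories)) if len(categories) > 1 else 0.0
    return total


class TestShannonEntropy:
    def test_closed_forms(self):
        assert cs.shannon_entropy([1, 0, 0]) == 0.0
        assert cs.shannon_entropy([0.5, 0.5]) == pytest.approx(np.log(2))
        assert cs.shannon_entropy([1 / 3] * 3) == pytest.approx(np.log(3))

    def test_validation(self):
        with pytest.raises(ValidationError):
            cs.shannon_entropy([0.5, 0.6])
        with pytest.raises(ValidationError):
            cs.shannon_entropy([-0.5, 1.5])


class TestExpansionIndex:
    def test_singletons_and_monoclonal(self):
        assert cs.expansion_index([1] * 10) == 0.0
        assert cs.expansion_index([10]) == 1.0
        assert cs.expansion_index([1]) == 0.0

    def test_nine_one_split_hand_value(self):
        # H(0.9, 0.1) = 0.3251; 1 - H/ln2 = 0.5310
        assert cs.expansion_index([9, 1]) == pytest.approx(0.53100, abs=1e-4)

    def test_invariant_to_uniform_scaling(self):
        rng = np.random.default_rng(12)
        sizes = rng.integers(1, 10, size=8)
        assert cs.expansion_index(sizes) == pytest.approx(
            cs.expansion_index(sizes * 3)
        )


class TestMigrationIndex:
    def _single_subject_table(self, placements):
        """placements: list of (clone, compartment) per cell."""
        cells, assignments = [], []
        for i, (clone, comp) in enumerate(placements):
            cells.append(make_cell(f"b{i}", compartment=comp))
            assignments.append(assign(f"b{i}", clone=clone))
        return cs.build_clone_table(assignments, cells)

    def test_confined_clones_give_zero(self):
        table = self._single_subject_table(
            [("c1", "LUNG")] * 3 + [("c2", "BALF")] * 2
        )
        res = cs.migration_index(table)
        assert res[res["subject_id"] == "pooled"]["value"].iloc[0] == 0.0

    def test_even_pairwise_split_gives_one(self):
        table = self._single_subject_table(
            [("c1", "LUNG")] * 5 + [("c1", "BALF")] * 5
        )
        res = cs.migration_index(table, compartments=["LUNG", "BALF"], normalize=True)
        assert res["value"].iloc[0] == pytest.approx(1.0)

    def test_matches_loop_oracle(self):
        rng = np.random.default_rng(17)
        for _ in range(20):
            table = random_clone_table(rng, n_clones=20, n_subjects=1)
            for categories in (["LUNG", "BALF", "PBMC"], ["LUNG", "BALF"]):
                got = cs.migration_index(
                    table, compartments=categories, normalize=True
                )
                if not table.cells["compartment"].isin(categories).any():
                    assert got.empty
                    continue
                row = got[got["subject_id"] != "pooled"]
                expected = loop_index(table.cells, "compartment", categories, True)
                assert abs(row["value"].iloc[0] - expected) < 1e-12

    def test_restriction_consistency(self):
        rng = np.random.default_rng(19)
        table = random_clone_table(rng, n_clones=25, n_subjects=2)
        full = cs.migration_index(table, compartments=["LUNG", "BALF"])
        no_pbmc = cs.CloneTable(
            table.cells[table.cells["compartment"] != "PBMC"].copy()
        )
        restricted = cs.migration_index(no_pbmc, compartments=["LUNG", "BALF"])
        pd.testing.assert_frame_equal(full, restricted)

    def test_subject_weighted_equals_pooled_with_scoped_ids(self):
        rng = np.random.default_rng(23)
        table = random_clone_table(rng, n_clones=30, n_subjects=3)
        per_subject = cs.migration_index(table)
        pooled_row = per_subject[per_subject["subject_id"] == "pooled"]["value"].iloc[0]
        pooled = cs.migration_index_pooled(table)
        # equality holds precisely because clone ids are subject-scoped
        assert pooled == pytest.approx(pooled_row, abs=1e-12)

    def test_invariant_to_clone_relabelling(self):
        rng = np.random.default_rng(29)
        table = random_clone_table(rng, n_clones=15, n_subjects=1)
        relabelled = table.cells.copy()
        mapping = {c: f"renamed_{i}" for i, c in enumerate(relabelled["clone_id"].unique())}
        relabelled["clone_id"] = relabelled["clone_id"].map(mapping)
        a = cs.migration_index(table)["value"]
        b = cs.migration_index(cs.CloneTable(relabelled))["value"]
        np.testing.assert_allclose(a, b)


class TestTransitionIndex:
    def test_cluster_confined_clones_give_zero(self):
        cells = [make_cell("b1", cluster="T8_rm"), make_cell("b2", cluster="T8_rm"),
                 make_cell("b3", cluster="Cycling")]
        assignments = [assign("b1"), assign("b2"),
                       assign("b3", clone="c2")]
        table = cs.build_clone_table(assignments, cells)
        res = cs.transition_index(table)
        assert res[res["subject_id"] == "pooled"]["value"].iloc[0] == 0.0

    def test_even_cluster_split_gives_one(self):
        cells = [make_cell("b1", cluster="T8_rm"), make_cell("b2", cluster="Cycling")]
        table = cs.build_clone_table([assign("b1"), assign("b2")], cells)
        res = cs.transition_index(table, clusters=["T8_rm", "Cycling"])
        assert res["value"].iloc[0] == pytest.approx(1.0)

    def test_matches_loop_oracle(self):
        rng = np.random.default_rng(31)
        for _ in range(10):
            table = random_clone_table(rng, n_clones=20, n_subjects=1)
            clusters = sorted(table.cells["cluster"].unique())
            got = cs.transition_index(table)
            row = got[got["subject_id"] != "pooled"]
            expected = loop_index(table.cells, "cluster", clusters, True)
            assert abs(row["value"].iloc[0] - expected) < 1e-12


class TestExpansionIndexTable:
    def test_values_in_unit_interval(self, small_cohort_analysis):
        _, table, _ = small_cohort_analysis
        res = cs.expansion_index_table(table)
        assert res["value"].between(0, 1).all()
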