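"""Reference profiles, Spearman scoring and fine-tuning."""

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

import cloneshare as cs
from cloneshare.errors import ValidationError
from cloneshare.io import ExpressionMatrix
from cloneshare.scoring import AMBIGUOUS


def labelled_matrix(rng, n_genes=60, n_per_pattern=30, block=20, effect=50):
    """Two patterns with disjoint elevated gene blocks; returns (norm, labels)."""
    n = 2 * n_per_pattern
    dense = rng.poisson(5, size=(n_genes, n))
    dense[:block, :n_per_pattern] += effect          # block A high in pattern X
    dense[block:2 * block, n_per_pattern:] += effect  # block B high in pattern Y
    expr = ExpressionMatrix(
        genes=[f"g{i}" for i in range(n_genes)],
        barcodes=[f"b{i}" for i in range(n)],
        counts=sp.csr_matrix(dense),
    )
    norm = cs.log_normalize(expr)
    labels = pd.Series(
        ["X"] * n_per_pattern + ["Y"] * n_per_pattern, index=norm.barcodes
    )
    return norm, labels


class TestBuildReferences:
    def test_marker_blocks_recovered(self):
        norm, labels = labelled_matrix(np.random.default_rng(1))
        refs = cs.build_references(norm, labels, genes_per_pair=10)
        assert set(refs.marker_genes[("X", "Y")]) <= {f"g{i}" for i in range(20)}
        assert set(refs.marker_genes[("Y", "X")]) <= {f"g{i}" for i in range(20, 40)}

    def test_small_pattern_dropped_then_error(self):
        norm, labels = labelled_matrix(np.random.default_rng(2))
        labels.iloc[:27] = "TINY"  # X reduced to 3 cells
        with pytest.raises(ValidationError):
            cs.build_references(norm, labels[labels != "TINY"], min_cells=10)

    def test_constant_gene_never_selected(self):
        rng = np.random.default_rng(3)
        norm, labels = labelled_matrix(rng)
        # make the last gene's *normalized* value constant everywhere
        norm.normalized = norm.normalized.tolil()
        norm.normalized[-1, :] = 1.0
        norm.normalized = norm.normalized.tocsr()
        refs = cs.build_references(norm, labels, genes_per_pair=60)
        for markers in refs.marker_genes.values():
            assert "g59" not in markers


class TestScoreCell:
    @pytest.fixture()
    def refs(self):
        norm, labels = labelled_matrix(np.random.default_rng(4))
        return cs.build_references(norm, labels, genes_per_pair=25)

    def test_reference_profile_scores_one(self, refs):
        genes = refs.evaluation_genes()
        query = refs.profiles.loc[genes, "X"]
        assert cs.score_cell(query, refs)["X"] == pytest.approx(1.0)

    def test_rank_reversed_profile_scores_minus_one(self, refs):
        genes = refs.evaluation_genes()
        profile = refs.profiles.loc[genes, "X"]
        query = pd.Series(-profile.to_numpy(), index=genes)
        assert cs.score_cell(query, refs)["X"] == pytest.approx(-1.0)

    def test_matches_rank_then_pearson_oracle(self, refs):
        rng = np.random.default_rng(5)
        genes = refs.evaluation_genes()
        query = pd.Series(rng.normal(size=len(genes)), index=genes)
        scores = cs.score_cell(query, refs)
        ranks_q = pd.Series(query).rank(method="average")
        for pattern in refs.patterns:
            ranks_r = refs.profiles.loc[genes, pattern].rank(method="average")
            expected = np.corrcoef(ranks_q, ranks_r)[0, 1]
            assert abs(scores[pattern] - expected) < 1e-12

    def test_invariant_under_monotone_transform(self, refs):
        rng = np.random.default_rng(6)
        genes = refs.evaluation_genes()
        query = pd.Series(rng.exponential(size=len(genes)), index=genes)
        base = cs.score_cell(query, refs)
        warped = cs.score_cell(np.exp(query * 2) + 7, refs)
        for pattern in refs.patterns:
            assert warped[pattern] == pytest.approx(base[pattern], abs=1e-12)

    def test_small_evaluation_set_rejected(self, refs):
        query = pd.Series([1.0, 2.0], index=refs.evaluation_genes()[:2])
        with pytest.raises(ValidationError):
            cs.score_cell(query, refs)


class TestFineTune:
    def test_dominant_pattern_returned(self):
        norm, labels = labelled_matrix(np.random.default_rng(7))
        refs = cs.build_references(norm, labels, genes_per_pair=25)
        genes = refs.evaluation_genes()
        query = refs.profiles.loc[genes, "X"] + 0.01
        assert cs.fine_tune(query, refs) == "X"

    def test_identical_profiles_ambiguous(self):
        norm, labels = labelled_matrix(np.random.default_rng(8))
        refs = cs.build_references(norm, labels, genes_per_pair=25)
        refs.profiles["Y"] = refs.profiles["X"]  # force exact ties
        genes = refs.evaluation_genes()
        rng = np.random.default_rng(9)
        query = pd.Series(rng.normal(size=len(genes)), index=genes)
        assert cs.fine_tune(query, refs) == AMBIGUOUS

    def test_retained_set_never_grows(self, monkeypatch):
        norm, labels = labelled_matrix(np.random.default_rng(10))
        refs = cs.build_references(norm, labels, genes_per_pair=25)
        sizes = []
        original = cs.score_cell

        def spy(query, r, patterns=None, min_genes=20):
            sizes.append(len(patterns) if patterns else len(r.patterns))
            return original(query, r, patterns=patterns, min_genes=min_genes)

        monkeypatch.setattr("cloneshare.scoring.score_cell", spy)
        genes = refs.evaluation_genes()
        query = pd.Series(np.random.default_rng(11).normal(size=len(genes)), index=genes)
        cs.fine_tune(query, refs)
        assert sizes == sorted(sizes, reverse=True)


class TestSummaries:
    def test_empty_and_uniform(self):
        assert cs.summarize_predictions(pd.DataFrame()).empty
        df = pd.DataFrame({"final_label": ["P1B"] * 4})
        summary = cs.summarize_predictions(df)
        assert summary.loc["P1B", "count"] == 4
        assert summary.loc["P1B", "proportion"] == 1.0

    def test_mixture_recovered_within_binomial_error(self):
        """60/40 two-program mixture recovered by fine-tuned labels."""
        rng = np.random.default_rng(13)
        norm, labels = labelled_matrix(rng, n_per_pattern=100)
        refs = cs.build_references(norm, labels, genes_per_pair=25)
        # queries: fresh draw from the same two programs, 60% X / 40% Y
        q_norm, q_labels = labelled_matrix(rng, n_per_pattern=300)
        keep = list(q_labels.index[:300]) + list(q_labels.index[300:500])
        pred = cs.annotate(
            ExpressionMatrix(
                genes=q_norm.genes,
                barcodes=keep,
                counts=q_norm.counts[:, [q_norm.barcodes.index(b) for b in keep]],
                normalized=q_norm.normalized[:, [q_norm.barcodes.index(b) for b in keep]],
            ),
            refs,
        )
        summary = cs.summarize_predictions(pred)
        n = summary["count"].sum()
        se = np.sqrt(0.6 * 0.4 / n)
        assert abs(summary.loc["X", "proportion"] - 0.6) < 3 * se
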