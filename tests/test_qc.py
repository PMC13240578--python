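"""QC thresholds, normalization, signatures, DE and composition statistics."""

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp
from hypothesis import given, settings, strategies as st

import cloneshare as cs
from cloneshare.errors import ValidationError
from cloneshare.io import ExpressionMatrix

from conftest import make_cell


def make_expr(dense, normalized=False):
    dense = np.asarray(dense)
    expr = ExpressionMatrix(
        genes=[f"g{i}" for i in range(dense.shape[0])],
        barcodes=[f"b{i}" for i in range(dense.shape[1])],
        counts=sp.csr_matrix(dense),
    )
    return cs.log_normalize(expr) if normalized else expr


class TestCellQc:
    @pytest.mark.parametrize(
        "mito,n_genes,kept",
        [
            (0.12, 1500, False),  # mito above 10% -> removed
            (0.10, 1500, True),   # boundary kept: "over" is strict
            (0.05, 199, False),   # below 200 genes -> removed
            (0.05, 200, True),    # boundary kept: "less than" is strict
        ],
    )
    def test_threshold_boundaries(self, mito, n_genes, kept):
        cell = make_cell("b1", mito=mito, n_genes=n_genes)
        kept_cells, removed_cells = cs.apply_cell_qc([cell])
        assert (cell in kept_cells) is kept
        assert (cell in removed_cells) is not kept

    def test_partition_is_exact(self, small_cohort):
        kept, removed = cs.apply_cell_qc(small_cohort.cells)
        assert len(kept) + len(removed) == len(small_cohort.cells)
        assert not set(c.barcode for c in kept) & set(c.barcode for c in removed)

    def test_missing_fields_listed(self):
        cells = [make_cell("b1"), make_cell("bad", mito=None)]
        with pytest.raises(ValidationError, match="bad"):
            cs.apply_cell_qc(cells)


class TestLogNormalize:
    def test_single_gene_cell_closed_form(self):
        norm = make_expr([[10]], normalized=True)
        assert norm.normalized[0, 0] == pytest.approx(np.log(1 + 1e4))

    def test_all_zero_cell_stays_zero(self, caplog):
        norm = make_expr([[0, 3], [0, 1]], normalized=True)
        assert norm.normalized[:, 0].nnz == 0

    def test_matches_scalar_loop_oracle(self):
        rng = np.random.default_rng(5)
        dense = rng.integers(0, 20, size=(20, 10))
        norm = make_expr(dense, normalized=True).normalized.toarray()
        totals = dense.sum(axis=0)
        for g in range(20):
            for c in range(10):
                expected = np.log1p(1e4 * dense[g, c] / totals[c]) if totals[c] else 0.0
                assert abs(norm[g, c] - expected) < 1e-12

    def test_matches_scanpy(self):
        scanpy = pytest.importorskip("scanpy")
        rng = np.random.default_rng(6)
        dense = rng.integers(0, 15, size=(12, 8))
        norm = make_expr(dense, normalized=True)
        ad = norm.to_anndata()
        scanpy.pp.normalize_total(ad, target_sum=1e4)
        scanpy.pp.log1p(ad)
        np.testing.assert_allclose(
            norm.normalized.T.toarray(), ad.X.toarray(), atol=1e-10
        )


class TestSignatureScore:
    def test_one_gene_signature_equals_its_value(self):
        norm = make_expr([[4, 0], [1, 2]], normalized=True)
        scores = cs.score_signature(norm, ["g0"], "sig")
        expected = norm.normalized[0, :].toarray().ravel()
        assert [s.score for s in scores] == pytest.approx(list(expected))

    def test_mean_over_present_genes(self):
        norm = make_expr([[4, 0], [1, 2], [3, 3]], normalized=True)
        scores = cs.score_signature(norm, ["g0", "g2", "ABSENT"], "mhc1")
        dense = norm.normalized.toarray()
        assert scores[0].score == pytest.approx(dense[[0, 2], 0].mean())

    def test_all_zero_expression_scores_zero(self):
        norm = make_expr(np.zeros((3, 2), dtype=int), normalized=True)
        assert all(s.score == 0 for s in cs.score_signature(norm, ["g0", "g1"], "z"))

    def test_empty_intersection_names_signature(self):
        norm = make_expr([[1]], normalized=True)
        with pytest.raises(ValidationError, match="mysig"):
            cs.score_signature(norm, ["NOPE"], "mysig")


class TestDifferentialExpression:
    def test_null_groups_have_no_discoveries(self):
        rng = np.random.default_rng(7)
        dense = rng.poisson(5, size=(50, 40))
        norm = make_expr(dense, normalized=True)
        res = cs.differential_expression(norm, norm.barcodes[:20], norm.barcodes[20:])
        assert (res["fdr"] < 0.05).mean() <= 0.05

    def test_shifted_gene_is_detected(self):
        rng = np.random.default_rng(8)
        dense = rng.poisson(5, size=(30, 100))
        dense[0, :50] = rng.poisson(20, size=50)  # 4-fold shift in group A
        norm = make_expr(dense, normalized=True)
        res = cs.differential_expression(norm, norm.barcodes[:50], norm.barcodes[50:])
        assert res.loc[res["gene"] == "g0", "fdr"].iloc[0] < 0.05
        assert res.loc[res["gene"] == "g0", "log_fold_change"].iloc[0] > 0

    def test_constant_gene_convention(self):
        dense = np.vstack([np.full(10, 7), np.arange(10)])
        norm = make_expr(dense)
        norm.normalized = sp.csr_matrix(dense.astype(float))  # bypass library-size scaling
        res = cs.differential_expression(norm, norm.barcodes[:5], norm.barcodes[5:])
        row = res[res["gene"] == "g0"].iloc[0]
        assert row["p_value"] == 1.0 and row["log_fold_change"] == 0.0

    def test_group_overlap_rejected(self):
        norm = make_expr(np.ones((3, 6), dtype=int), normalized=True)
        with pytest.raises(ValidationError):
            cs.differential_expression(norm, norm.barcodes[:4], norm.barcodes[3:])


class TestBenjaminiHochberg:
    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=30))
    def test_monotone_and_bounded(self, pvals):
        fdr = cs.benjamini_hochberg(pvals)
        assert ((fdr >= 0) & (fdr <= 1)).all()
        order = np.argsort(pvals)
        assert (np.diff(fdr[order]) >= -1e-12).all()


class TestComposition:
    def test_identical_groups_give_p_one(self):
        props = pd.DataFrame(
            {"T": [0.6] * 4, "B": [0.4] * 4},
            index=[f"S{i}" for i in range(4)],
        )
        groups = {"S0": "a", "S1": "a", "S2": "b", "S3": "b"}
        res = cs.composition_stats(props, groups)
        assert (res["p_value"] == 1.0).all()

    def test_rows_must_sum_to_one(self):
        props = pd.DataFrame({"T": [0.6, 0.5], "B": [0.3, 0.5]}, index=["S0", "S1"])
        with pytest.raises(ValidationError):
            cs.composition_stats(props, {"S0": "a", "S1": "b"})

    def test_correlation_extremes(self):
        a = [0.1, 0.2, 0.3, 0.4]
        r, _ = cs.correlate_proportions(a, a)
        assert r == pytest.approx(1.0)
        r, _ = cs.correlate_proportions(a, [1 - x for x in a])
        assert r == pytest.approx(-1.0)
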