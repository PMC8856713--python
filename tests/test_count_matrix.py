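"""Data model, ingestion, merging, normalization, HVG selection and PCA."""

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from nichecompare import (
    CountMatrix,
    NormalizedMatrix,
    exclude_gene_set,
    filter_genes,
    merge_union,
    normalize,
    pca,
    read_counts,
    select_hvgs,
)
from nichecompare.synthetic_data import write_dataset


def _mat(genes, cells, arr):
    return CountMatrix(genes=genes, cells=cells, counts=sp.csr_matrix(np.asarray(arr)))


class TestCountMatrixContract:
    def test_duplicate_gene_ids_rejected(self):
        with pytest.raises(ValueError, match="duplicate gene"):
            _mat(["g1", "g1"], ["c1"], [[1], [2]])

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            _mat(["g1"], ["c1", "c2"], [[1, -1]])

    def test_non_integral_counts_rejected(self):
        with pytest.raises(ValueError, match="integral"):
            _mat(["g1"], ["c1"], [[1.5]])

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError, match="shape"):
            _mat(["g1", "g2"], ["c1"], [[1]])


class TestReadCounts:
    def test_delimited_round_trip(self, tmp_path, toy_matrix, toy_annotation):
        table = pd.DataFrame(
            toy_matrix.counts.toarray(), index=toy_matrix.genes, columns=toy_matrix.cells
        )
        table.to_csv(tmp_path / "counts.tsv", sep="\t")
        toy_annotation.table.reset_index().to_csv(
            tmp_path / "meta.tsv", sep="\t", index=False
        )
        mat, ann = read_counts(
            tmp_path / "counts.tsv", format="delimited", metadata_path=tmp_path / "meta.tsv"
        )
        assert mat.genes == toy_matrix.genes
        assert mat.cells == toy_matrix.cells
        assert (mat.counts != toy_matrix.counts).nnz == 0
        assert ann.cells == mat.cells

    def test_mtx_round_trip(self, tmp_path, toy_matrix, toy_annotation):
        write_dataset(toy_matrix, toy_annotation, None, tmp_path / "d")
        mat, ann = read_counts(
            tmp_path / "d", format="mtx_10x", metadata_path=tmp_path / "d" / "metadata.tsv"
        )
        assert mat.genes == toy_matrix.genes
        assert (mat.counts != toy_matrix.counts).nnz == 0

    def test_missing_barcode_named_in_error(self, tmp_path, toy_matrix, toy_annotation):
        table = pd.DataFrame(
            toy_matrix.counts.toarray(), index=toy_matrix.genes, columns=toy_matrix.cells
        )
        table.to_csv(tmp_path / "counts.tsv", sep="\t")
        toy_annotation.table.drop("c3").reset_index().to_csv(
            tmp_path / "meta.tsv", sep="\t", index=False
        )
        with pytest.raises(ValueError, match="c3"):
            read_counts(
                tmp_path / "counts.tsv",
                format="delimited",
                metadata_path=tmp_path / "meta.tsv",
            )

    def test_missing_file_errors(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            read_counts(
                tmp_path / "nope.tsv", format="delimited", metadata_path=tmp_path / "m.tsv"
            )


class TestMergeUnion:
    def test_union_and_mass_conservation(self):
        a = _mat(["g1", "g2"], ["a1", "a2"], [[1, 2], [3, 0]])
        b = _mat(["g2", "g3"], ["b1"], [[5], [7]])
        merged = merge_union([a, b])
        assert merged.genes == ["g1", "g2", "g3"]
        assert merged.cells == ["a1", "a2", "b1"]
        dense = merged.counts.toarray()
        # g1 and g3 are zero where absent from the source dataset
        assert dense[0, 2] == 0 and dense[2, 0] == 0 and dense[2, 1] == 0
        assert dense.sum() == a.counts.sum() + b.counts.sum()

    def test_single_input_identity(self, toy_matrix):
        merged = merge_union([toy_matrix])
        assert merged.genes == toy_matrix.genes
        assert (merged.counts != toy_matrix.counts).nnz == 0

    def test_duplicate_cell_ids_rejected(self):
        a = _mat(["g1"], ["c1"], [[1]])
        b = _mat(["g1"], ["c1"], [[2]])
        with pytest.raises(ValueError, match="duplicate cell"):
            merge_union([a, b])

    def test_associative_up_to_ordering(self):
        rng = np.random.default_rng(0)
        mats = [
            _mat(
                [f"g{j}" for j in rng.choice(20, size=8, replace=False)],
                [f"m{i}c{j}" for j in range(5)],
                rng.integers(0, 5, size=(8, 5)),
            )
            for i in range(3)
        ]
        left = merge_union([merge_union(mats[:2]), mats[2]])
        right = merge_union([mats[0], merge_union(mats[1:])])
        tl = pd.DataFrame(left.counts.toarray(), index=left.genes, columns=left.cells)
        tr = pd.DataFrame(right.counts.toarray(), index=right.genes, columns=right.cells)
        pd.testing.assert_frame_equal(
            tl.sort_index(), tr.sort_index()[tl.columns], check_like=True
        )


class TestFilterGenes:
    def test_threshold_definition(self):
        # per-gene detection counts 0, 2, 3, 5 over five cells
        mat = _mat(
            ["g0", "g2", "g3", "g5"],
            [f"c{i}" for i in range(5)],
            [
                [0, 0, 0, 0, 0],
                [1, 2, 0, 0, 0],
                [1, 1, 1, 0, 0],
                [1, 1, 1, 1, 1],
            ],
        )
        out = filter_genes(mat, min_cells=3)
        assert out.genes == ["g3", "g5"]

    def test_min_cells_zero_is_identity(self, toy_matrix):
        out = filter_genes(toy_matrix, min_cells=0)
        assert out.genes == toy_matrix.genes

    def test_idempotent(self, toy_matrix):
        once = filter_genes(toy_matrix, min_cells=2)
        twice = filter_genes(once, min_cells=2)
        assert once.genes == twice.genes

    def test_empty_result_warns(self):
        mat = _mat(["g1"], ["c1", "c2"], [[1, 0]])
        with pytest.warns(UserWarning, match="every gene"):
            out = filter_genes(mat, min_cells=5)
        assert out.genes == []


class TestNormalize:
    def test_hand_computed_values(self):
        mat = _mat(["g1", "g2"], ["c1"], [[3], [1]])
        norm = normalize(mat, scale_factor=4)
        vals = norm.values.toarray().ravel()
        np.testing.assert_allclose(vals, [np.log(4), np.log(2)], rtol=1e-12)

    def test_normalization_identity(self, small_norm):
        norm, _, _ = small_norm
        sums = np.asarray(np.expm1(norm.values.todense()).sum(axis=0)).ravel()
        np.testing.assert_allclose(sums, norm.scale_factor, rtol=1e-6)

    def test_round_trip_recovers_proportions(self, toy_matrix):
        norm = normalize(toy_matrix, scale_factor=123.0)
        props = np.expm1(norm.values.toarray()) / norm.scale_factor
        expected = toy_matrix.counts.toarray() / toy_matrix.cell_totals()
        np.testing.assert_allclose(props, expected, atol=1e-10)

    def test_zero_total_cell_named(self):
        mat = _mat(["g1"], ["ok", "empty"], [[1, 0]])
        with pytest.raises(ValueError, match="empty"):
            normalize(mat)

    def test_matches_scanpy(self, small_dataset):
        """Independent cross-check against the scanpy implementation."""
        anndata = pytest.importorskip("anndata")
        sc = pytest.importorskip("scanpy")
        mat, _, _ = small_dataset
        norm = normalize(mat, scale_factor=1e4)
        ad = anndata.AnnData(X=mat.counts.T.astype(np.float64).tocsr())
        sc.pp.normalize_total(ad, target_sum=1e4)
        sc.pp.log1p(ad)
        np.testing.assert_allclose(
            norm.values.toarray(), ad.X.toarray().T, rtol=1e-10, atol=1e-12
        )


class TestHVGs:
    def test_constant_gene_never_selected(self):
        rng = np.random.default_rng(3)
        vals = rng.exponential(1.0, size=(10, 30))
        vals[4] = 0.7  # constant normalized expression
        norm = NormalizedMatrix(
            genes=[f"g{i}" for i in range(10)],
            cells=[f"c{i}" for i in range(30)],
            values=sp.csr_matrix(vals),
        )
        hvgs = select_hvgs(norm, n=9, n_bins=2)
        assert "g4" not in hvgs

    def test_planted_high_dispersion_gene_first(self):
        rng = np.random.default_rng(5)
        n_cells = 300
        base = rng.poisson(5.0, size=(50, n_cells))
        # one gene with far larger dispersion at a comparable mean
        onoff = np.where(rng.random(n_cells) < 0.1, 50, 0)
        counts = np.vstack([base, onoff[np.newaxis, :]])
        counts[:, 0] += 1
        genes = [f"g{i}" for i in range(50)] + ["burst"]
        mat = _mat(genes, [f"c{i}" for i in range(n_cells)], counts)
        hvgs = select_hvgs(normalize(mat), n=5)
        assert hvgs[0] == "burst"

    def test_requesting_too_many_warns(self, small_norm):
        norm, _, _ = small_norm
        with pytest.warns(UserWarning, match="non-constant"):
            hvgs = select_hvgs(norm, n=10 * len(norm.genes))
        assert len(hvgs) <= len(norm.genes)


class TestExcludeGeneSet:
    def test_disjoint_identity(self):
        assert exclude_gene_set(["a", "b"], ["x"]) == ["a", "b"]

    def test_order_preserving_difference(self):
        genes = [f"g{i}" for i in range(10)]
        with pytest.warns(UserWarning, match="excluded 4"):
            out = exclude_gene_set(genes, {"g1", "g3", "g5", "g7"})
        assert out == ["g0", "g2", "g4", "g6", "g8", "g9"]

    def test_total_exclusion_errors(self):
        with pytest.raises(ValueError, match="nothing left"):
            exclude_gene_set(["a"], ["a"])


class TestPCA:
    def _norm(self, arr, genes=None):
        arr = np.asarray(arr, dtype=float)
        genes = genes or [f"g{i}" for i in range(arr.shape[0])]
        return NormalizedMatrix(
            genes=genes,
            cells=[f"c{i}" for i in range(arr.shape[1])],
            values=sp.csr_matrix(arr),
        )

    def test_rank_one_input(self):
        profile = np.array([1.0, 2.0, 3.0, 4.0])
        scales = np.array([1.0, 0.5, 2.0, 1.5, 3.0])
        norm = self._norm(np.outer(profile, scales))
        res = pca(norm, norm.genes, k=2)
        assert res.explained_variance_ratio[0] >= 0.999

    def test_k_out_of_range(self):
        norm = self._norm(np.eye(3))
        with pytest.raises(ValueError, match="out of range"):
            pca(norm, norm.genes, k=4)

    def test_full_rank_reconstruction(self):
        rng = np.random.default_rng(8)
        x = rng.normal(size=(20, 50))  # genes x cells
        norm = self._norm(x)
        k = 20
        res = pca(norm, norm.genes, k=k)
        centered = (x - x.mean(axis=1, keepdims=True)).T
        recon = res.embedding @ res.components
        np.testing.assert_allclose(recon, centered, atol=1e-8)
        # loadings orthonormal, variances non-increasing, total preserved
        np.testing.assert_allclose(res.components @ res.components.T, np.eye(k), atol=1e-10)
        assert np.all(np.diff(res.explained_variance) <= 1e-12)
        np.testing.assert_allclose(
            res.explained_variance.sum(),
            centered.var(axis=0, ddof=1).sum(),
            rtol=1e-6,
        )
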