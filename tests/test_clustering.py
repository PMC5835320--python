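import logging

import numpy as np
import pytest

from comparekit import (
    ExpressionMatrix, Signature, ValidationError,
    cut_tree, render_cim, standardize_signature_matrix, ward_cluster,
)
from _oracles import ward_greedy_oracle


def matrix_from_points(points, prefix="L"):
    """Points become cell lines (columns); rows are synthetic features."""
    arr = np.asarray(points, dtype=float).T
    return ExpressionMatrix(
        gene_ids=[f"F{i}" for i in range(arr.shape[0])],
        cellline_ids=[f"{prefix}{j}" for j in range(arr.shape[1])],
        values=arr,
    )


@pytest.fixture
def four_point_matrix():
    # 1-D profiles {0, 0.1, 10, 10.1} embedded in 3 identical feature rows
    pts = [[0.0] * 3, [0.1] * 3, [10.0] * 3, [10.1] * 3]
    return matrix_from_points(pts)


class TestStandardize:
    def test_rows_are_zero_mean_unit_sd(self, rng):
        values = rng.normal(5, 2, size=(6, 10))
        expr = ExpressionMatrix(
            gene_ids=[f"G{i}" for i in range(6)],
            cellline_ids=[f"L{j}" for j in range(10)],
            values=values,
        )
        sig = Signature(positive=["G0", "G1", "G2"], negative=["G3", "G4"],
                        k_pos=3, k_neg=2)
        out = standardize_signature_matrix(expr, sig)
        assert out.shape == (5, 10)
        np.testing.assert_allclose(out.values.mean(axis=1), 0.0, atol=1e-12)
        np.testing.assert_allclose(out.values.std(axis=1), 1.0, atol=1e-12)

    def test_constant_row_becomes_zeros_with_warning(self, caplog):
        values = np.vstack([np.full(8, 3.0), np.arange(8.0),
                            np.arange(8.0) ** 2])
        expr = ExpressionMatrix(
            gene_ids=["CONST", "G1", "G2"],
            cellline_ids=[f"L{j}" for j in range(8)],
            values=values,
        )
        sig = Signature(positive=["CONST", "G2"], negative=["G1"],
                        k_pos=2, k_neg=1)
        with caplog.at_level(logging.WARNING, logger="comparekit"):
            out = standardize_signature_matrix(expr, sig)
        np.testing.assert_array_equal(out.values[0], 0.0)
        assert any("zero-variance" in r.message for r in caplog.records)

    def test_missing_signature_gene_rejected(self, small_expr):
        sig = Signature(positive=["NOPE"], negative=["EQ"], k_pos=1, k_neg=1)
        with pytest.raises(ValidationError, match="NOPE"):
            standardize_signature_matrix(small_expr, sig)


class TestWardCluster:
    def test_close_pairs_merge_first(self, four_point_matrix):
        dend = ward_cluster(four_point_matrix, axis="lines")
        first_two = {frozenset(map(int, dend.merges[0, :2])),
                     frozenset(map(int, dend.merges[1, :2]))}
        assert first_two == {frozenset({0, 1}), frozenset({2, 3})}

    def test_identical_rows_merge_at_height_zero(self):
        pts = [[1.0, 2.0, 3.0], [1.0, 2.0, 3.0], [9.0, 9.0, 9.0]]
        dend = ward_cluster(matrix_from_points(pts), axis="lines")
        assert dend.heights[0] == pytest.approx(0.0, abs=1e-12)

    def test_heights_non_decreasing(self, rng):
        pts = rng.normal(size=(12, 4))
        dend = ward_cluster(matrix_from_points(pts), axis="lines")
        assert (np.diff(dend.heights) >= -1e-9).all()

    def test_matches_greedy_sse_oracle_on_small_instances(self, rng):
        """Ward-cost heights and the k-cluster partitions agree with a direct
        SSE-based greedy agglomeration on random <=6-point instances."""
        for _ in range(20):
            n = int(rng.integers(3, 7))
            pts = rng.normal(size=(n, int(rng.integers(3, 5))))
            matrix = matrix_from_points(pts)
            dend = ward_cluster(matrix, axis="lines")
            costs, partitions = ward_greedy_oracle([list(p) for p in pts])
            np.testing.assert_allclose(np.sort(dend.heights),
                                       np.sort(costs), rtol=1e-9, atol=1e-12)
            for k in range(1, n + 1):
                assignment = cut_tree(dend, k)
                ours = frozenset(
                    frozenset(int(cid[1:]) for cid in assignment.members(lab))
                    for lab in range(1, k + 1)
                )
                assert ours == partitions[k]

    def test_axis_genes_clusters_rows(self, rng):
        values = rng.normal(size=(5, 8))
        expr = ExpressionMatrix(
            gene_ids=[f"G{i}" for i in range(5)],
            cellline_ids=[f"L{j}" for j in range(8)],
            values=values,
        )
        dend = ward_cluster(expr, axis="genes")
        assert dend.leaf_ids == expr.gene_ids

    def test_fewer_than_two_objects_rejected(self):
        expr = ExpressionMatrix(
            gene_ids=["G0", "G1", "G2"], cellline_ids=["L0"],
            values=np.array([[1.0], [2.0], [3.0]]),
        )
        with pytest.raises(ValidationError):
            ward_cluster(expr, axis="lines")

    def test_partition_invariant_to_input_order(self, rng):
        pts = np.vstack([rng.normal(0, 0.5, (5, 3)),
                         rng.normal(8, 0.5, (5, 3))])
        matrix = matrix_from_points(pts)
        perm = rng.permutation(10)
        shuffled = ExpressionMatrix(
            gene_ids=matrix.gene_ids,
            cellline_ids=[matrix.cellline_ids[j] for j in perm],
            values=matrix.values[:, perm],
        )
        part_a = _partition(cut_tree(ward_cluster(matrix, "lines"), 2))
        part_b = _partition(cut_tree(ward_cluster(shuffled, "lines"), 2))
        assert part_a == part_b

    def test_two_well_separated_groups_recovered_across_seeds(self):
        for seed in range(20):
            r = np.random.default_rng(seed)
            pts = np.vstack([r.normal(0, 0.3, (6, 4)),
                             r.normal(10, 0.3, (6, 4))])
            matrix = matrix_from_points(pts)
            assignment = cut_tree(ward_cluster(matrix, "lines"), 2)
            part = _partition(assignment)
            expected = frozenset({
                frozenset(f"L{j}" for j in range(6)),
                frozenset(f"L{j}" for j in range(6, 12)),
            })
            assert part == expected


def _partition(assignment):
    return frozenset(
        frozenset(assignment.members(lab)) for lab in range(1, assignment.k + 1)
    )


class TestCutTree:
    def test_k_equal_n_makes_singletons(self, four_point_matrix):
        dend = ward_cluster(four_point_matrix, axis="lines")
        assignment = cut_tree(dend, 4)
        assert sorted(assignment.labels.values()) == [1, 2, 3, 4]

    def test_k_one_is_single_cluster(self, four_point_matrix):
        dend = ward_cluster(four_point_matrix, axis="lines")
        assignment = cut_tree(dend, 1)
        assert set(assignment.labels.values()) == {1}

    def test_k_two_splits_near_from_far(self, four_point_matrix):
        dend = ward_cluster(four_point_matrix, axis="lines")
        part = _partition(cut_tree(dend, 2))
        assert part == frozenset({frozenset({"L0", "L1"}),
                                  frozenset({"L2", "L3"})})

    def test_labels_numbered_by_leaf_order(self, four_point_matrix):
        dend = ward_cluster(four_point_matrix, axis="lines")
        assignment = cut_tree(dend, 2)
        first_leaf = dend.leaf_order()[0]
        assert assignment.labels[first_leaf] == 1

    def test_k_out_of_range_rejected(self, four_point_matrix):
        dend = ward_cluster(four_point_matrix, axis="lines")
        with pytest.raises(ValidationError):
            cut_tree(dend, 0)
        with pytest.raises(ValidationError):
            cut_tree(dend, 5)


class TestNewickAndCim:
    def test_newick_contains_all_leaves(self, four_point_matrix):
        dend = ward_cluster(four_point_matrix, axis="lines")
        newick = dend.to_newick()
        assert newick.endswith(";")
        for leaf in dend.leaf_ids:
            assert leaf in newick

    def test_cim_file_written_and_byte_stable(self, tmp_path, rng):
        values = rng.normal(size=(6, 8))
        expr = ExpressionMatrix(
            gene_ids=[f"G{i}" for i in range(6)],
            cellline_ids=[f"L{j}" for j in range(8)],
            values=values,
        )
        rows = ward_cluster(expr, axis="genes")
        cols = ward_cluster(expr, axis="lines")
        ann = {f"L{j}": ("sensitive" if j < 4 else "resistant")
               for j in range(8)}
        p1 = render_cim(expr, rows, cols, ann, tmp_path / "a.svg")
        p2 = render_cim(expr, rows, cols, ann, tmp_path / "b.svg")
        assert p1.stat().st_size > 0
        assert p1.read_bytes() == p2.read_bytes()

    def test_cim_axis_mismatch_rejected(self, tmp_path, rng):
        values = rng.normal(size=(4, 5))
        expr = ExpressionMatrix(
            gene_ids=[f"G{i}" for i in range(4)],
            cellline_ids=[f"L{j}" for j in range(5)],
            values=values,
        )
        other = ExpressionMatrix(
            gene_ids=[f"X{i}" for i in range(4)],
            cellline_ids=[f"L{j}" for j in range(5)],
            values=values,
        )
        rows_wrong = ward_cluster(other, axis="genes")
        cols = ward_cluster(expr, axis="lines")
        with pytest.raises(ValidationError, match="row dendrogram"):
            render_cim(expr, rows_wrong, cols, None, tmp_path / "x.svg")
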