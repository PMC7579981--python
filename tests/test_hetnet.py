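"""Network construction, similarity, thresholding and serialization."""

import numpy as np
import pytest

from hetmda import (
    ExpressionTable,
    apply_threshold,
    assemble_global,
    pcc_similarity,
    read_bundle,
    read_edge_list,
    write_bundle,
    write_edge_list,
)
from hetmda.hetnet import read_node_ids, write_node_ids

from conftest import build_net, random_net


def expr(rows, ids=None):
    rows = np.asarray(rows, dtype=float)
    ids = ids or tuple(f"m{i}" for i in range(rows.shape[0]))
    return ExpressionTable(mirna_ids=tuple(ids), values=rows)


class TestPccSimilarity:
    def test_identical_profiles_score_one(self):
        sim = pcc_similarity(expr([[1, 2, 3], [1, 2, 3]]))
        assert sim[0, 1] == pytest.approx(1.0)
        assert sim[0, 0] == 0.0  # no self-loops

    def test_anticorrelated_profiles_are_cut(self):
        sim = pcc_similarity(expr([[1, 2, 3], [3, 2, 1]]))
        assert sim[0, 1] == 0.0

    def test_matches_direct_covariance_evaluation(self):
        # independent evaluation of the correlation formula
        x, y = np.array([1.0, 2.0, 4.0]), np.array([1.0, 3.0, 5.0])
        dx, dy = x - x.mean(), y - y.mean()
        expected = (dx @ dy) / np.sqrt((dx @ dx) * (dy @ dy))
        sim = pcc_similarity(expr([x, y]))
        assert sim[0, 1] == pytest.approx(expected, abs=1e-12)

    def test_zero_variance_row_warns_and_zeroes(self):
        with pytest.warns(UserWarning, match="zero-variance"):
            sim = pcc_similarity(expr([[2, 2, 2], [1, 2, 3], [2, 4, 6]]))
        assert np.all(sim[0] == 0.0) and np.all(sim[:, 0] == 0.0)
        assert sim[1, 2] == pytest.approx(1.0)

    def test_output_is_symmetric_in_unit_range(self, rng):
        sim = pcc_similarity(expr(rng.normal(size=(8, 5))))
        assert np.array_equal(sim, sim.T)
        assert sim.min() >= 0.0 and sim.max() <= 1.0
        assert np.all(np.diag(sim) == 0.0)

    def test_rejects_single_sample(self):
        with pytest.raises(ValueError, match="two samples"):
            expr([[1.0], [2.0]])


class TestAssembleGlobal:
    def test_empty_network_is_valid(self):
        net = build_net(
            np.zeros((2, 2)), np.zeros((1, 1)), np.zeros((1, 1)),
            np.zeros((2, 1)), np.zeros((2, 1)), np.zeros((1, 1)),
            thresholded=False,
        )
        T = net.global_adjacency()
        assert T.shape == (4, 4) and not T.any()

    def test_wrong_shape_names_offending_block(self):
        with pytest.raises(ValueError, match="block B"):
            assemble_global(
                ["m0", "m1"], ["p0"], ["d0"],
                M=np.zeros((2, 2)), P=np.zeros((1, 1)), D=np.zeros((1, 1)),
                B=np.zeros((1, 2)),  # transposed shape
                C=np.zeros((2, 1)), W=np.zeros((1, 1)),
            )

    def test_asymmetric_intra_block_rejected(self):
        M = np.array([[0.0, 0.4], [0.6, 0.0]])
        with pytest.raises(ValueError, match="block M is not symmetric"):
            assemble_global(["m0", "m1"], [], [],
                            M=M, P=np.zeros((0, 0)), D=np.zeros((0, 0)),
                            B=np.zeros((2, 0)), C=np.zeros((2, 0)),
                            W=np.zeros((0, 0)))

    def test_out_of_range_weight_rejected(self):
        C = np.array([[1.5]])
        with pytest.raises(ValueError, match="block C"):
            assemble_global(["m0"], [], ["d0"],
                            M=np.zeros((1, 1)), P=np.zeros((0, 0)),
                            D=np.zeros((1, 1)), B=np.zeros((1, 0)),
                            C=C, W=np.zeros((0, 1)))

    def test_global_view_exactly_symmetric(self, rng):
        net = random_net(rng, 4, 5, 3)
        T = net.global_adjacency()
        assert np.array_equal(T, T.T)


class TestApplyThreshold:
    def make(self, weights):
        n = len(weights) + 1
        M = np.zeros((n, n))
        for i, w in enumerate(weights):
            M[0, i + 1] = M[i + 1, 0] = w
        return build_net(M, np.zeros((1, 1)), np.zeros((1, 1)),
                         np.zeros((n, 1)), np.zeros((n, 1)), np.zeros((1, 1)),
                         thresholded=False)

    def test_boundary_weight_kept_below_removed(self):
        net = apply_threshold(self.make([0.49, 0.5]))
        assert net.M[0, 1] == 0.0  # strictly below the cutoff
        assert net.M[0, 2] == 0.5  # boundary survives

    def test_zero_threshold_is_identity(self):
        raw = self.make([0.2, 0.7, 0.5])
        net = apply_threshold(raw, tau=0.0)
        assert np.array_equal(net.M, raw.M)

    def test_surviving_edge_count(self):
        net = apply_threshold(self.make([0.2, 0.7, 0.5]))
        assert np.count_nonzero(np.triu(net.M)) == 2

    def test_cut_is_idempotent(self):
        once = apply_threshold(self.make([0.2, 0.7, 0.5, 0.49, 0.51]))
        rebuilt = build_net(once.M, once.P, once.D, once.B, once.C, once.W,
                            thresholded=False)
        twice = apply_threshold(rebuilt)
        for name in ("M", "P", "D", "B", "C", "W"):
            assert np.array_equal(getattr(once, name), getattr(twice, name))

    def test_double_threshold_rejected(self):
        net = apply_threshold(self.make([0.6]))
        with pytest.raises(ValueError, match="already thresholded"):
            apply_threshold(net)

    def test_invalid_tau_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            apply_threshold(self.make([0.6]), tau=1.5)


class TestEdgeListIO:
    def test_basic_read(self, tmp_path):
        path = tmp_path / "b.tsv"
        path.write_text("m1\tp1\t1.0\nm2\tp1\t1.0\n")
        block = read_edge_list(path, ["m1", "m2"], ["p1"])
        assert np.array_equal(block, [[1.0], [1.0]])

    def test_duplicate_edge_keeps_maximum(self, tmp_path):
        path = tmp_path / "b.tsv"
        path.write_text("m1\tp1\t0.3\nm1\tp1\t0.8\n")
        block = read_edge_list(path, ["m1"], ["p1"])
        assert block[0, 0] == 0.8

    def test_empty_file_warns(self, tmp_path):
        path = tmp_path / "b.tsv"
        path.write_text("# only a comment\n")
        with pytest.warns(UserWarning, match="no edges"):
            block = read_edge_list(path, ["m1"], ["p1"])
        assert not block.any()

    def test_malformed_line_reports_line_number(self, tmp_path):
        path = tmp_path / "b.tsv"
        path.write_text("m1\tp1\t0.3\nm1\tp1\n")
        with pytest.raises(ValueError, match=":2:"):
            read_edge_list(path, ["m1"], ["p1"])

    def test_non_numeric_weight_rejected(self, tmp_path):
        path = tmp_path / "b.tsv"
        path.write_text("m1\tp1\thigh\n")
        with pytest.raises(ValueError, match="non-numeric"):
            read_edge_list(path, ["m1"], ["p1"])

    def test_unknown_identifier_rejected(self, tmp_path):
        path = tmp_path / "b.tsv"
        path.write_text("mX\tp1\t0.3\n")
        with pytest.raises(ValueError, match="unknown source"):
            read_edge_list(path, ["m1"], ["p1"])

    def test_round_trip_preserves_block(self, tmp_path, rng):
        block = rng.random((4, 3)) * (rng.random((4, 3)) < 0.6)
        ids_a = [f"m{i}" for i in range(4)]
        ids_b = [f"p{i}" for i in range(3)]
        path = tmp_path / "b.tsv"
        write_edge_list(block, path, ids_a, ids_b)
        assert np.array_equal(read_edge_list(path, ids_a, ids_b), block)

    def test_node_id_round_trip(self, tmp_path):
        ids = ("m1", "m2", "hsa-miR-21")
        write_node_ids(ids, tmp_path / "ids.txt")
        assert read_node_ids(tmp_path / "ids.txt") == ids


class TestBundleIO:
    def test_round_trip_bit_exact(self, tmp_path, rng):
        net = random_net(rng, 4, 5, 3)
        write_bundle(net, tmp_path / "net")
        back = read_bundle(tmp_path / "net")
        assert back.fingerprint() == net.fingerprint()
        for name in ("M", "P", "D", "B", "C", "W"):
            assert np.array_equal(getattr(back, name), getattr(net, name))
        assert back.threshold_applied == net.threshold_applied

    def test_edge_removal_returns_copy(self, rng):
        net = random_net(rng, 4, 5, 3)
        pairs = [(i, j) for i, j in zip(*np.nonzero(net.C))][:2]
        reduced = net.without_md_edges(pairs)
        for i, j in pairs:
            assert reduced.C[i, j] == 0.0
            assert net.C[i, j] == 1.0  # original untouched


class TestThresholdProperties:
    """Invariants of the edge cut over arbitrary weight configurations."""

    from hypothesis import given, settings
    from hypothesis import strategies as st

    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1,
                    max_size=6),
           st.floats(min_value=0.0, max_value=1.0))
    @settings(deadline=None, derandomize=True, max_examples=50)
    def test_every_surviving_weight_is_zero_or_at_least_tau(self, weights, tau):
        net = TestApplyThreshold().make(weights)
        cut = apply_threshold(net, tau=tau)
        nonzero = cut.M[cut.M > 0]
        assert np.all(nonzero >= tau)
        # surviving weights are unchanged, removed ones exactly zero
        kept = net.M >= tau
        assert np.array_equal(cut.M[kept], net.M[kept])
        assert not cut.M[~kept].any()
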