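"""Connectome containers, I/O, thresholding and nodal summaries."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ctrlred import (
    Connectome,
    NodalMetrics,
    binarize,
    group_average_nodal,
    make_block_parcellation,
    network_means,
    nodal_degree,
    read_connectome,
    threshold_connectome,
    write_connectome,
)
from ctrlred.connectome import Parcellation
from ctrlred.errors import (
    ConfigurationError,
    DegenerateInputError,
    FormatError,
    ParameterError,
    ValidationError,
)

from conftest import random_binary_adjacency, random_weighted_adjacency


def _parc(n, k=3):
    return make_block_parcellation(n, k)


class TestValidation:
    def test_asymmetric_matrix_rejected(self):
        w = np.zeros((3, 3))
        w[1, 2], w[2, 1] = 5.0, 7.0
        with pytest.raises(FormatError, match=r"asymmetric at \(1, 2\)"):
            Connectome(w, _parc(3))

    def test_negative_weight_rejected(self):
        w = np.zeros((3, 3))
        w[0, 1] = w[1, 0] = -1.0
        with pytest.raises(FormatError, match="negative"):
            Connectome(w, _parc(3))

    def test_nonzero_diagonal_rejected(self):
        w = np.eye(3)
        with pytest.raises(FormatError, match="diagonal"):
            Connectome(w, _parc(3))

    def test_size_mismatch_rejected(self):
        with pytest.raises(FormatError, match="parcellation"):
            Connectome(np.zeros((4, 4)), _parc(3))


def test_write_read_round_trip(tmp_path, rng):
    parc = _parc(12)
    c = Connectome(random_weighted_adjacency(rng, 12), parc, subject_id="s1")
    path = tmp_path / "s1.tsv"
    write_connectome(c, path)
    back = read_connectome(path, parc)
    np.testing.assert_array_equal(back.weights, c.weights)


class TestThreshold:
    def test_cutoff_arithmetic(self):
        w = np.zeros((3, 3))
        w[0, 1] = w[1, 0] = 1000.0
        w[0, 2] = w[2, 0] = 5.0
        w[1, 2] = w[2, 1] = 0.5
        out = threshold_connectome(Connectome(w, _parc(3)), 0.001)
        # cutoff = 1.0: the 0.5 edge is removed, 5 and 1000 survive
        assert out.weights[1, 2] == 0.0
        assert out.weights[0, 2] == 5.0 and out.weights[0, 1] == 1000.0

    def test_zero_fraction_is_identity(self, rng):
        c = Connectome(random_weighted_adjacency(rng, 10), _parc(10))
        out = threshold_connectome(c, 0.0)
        np.testing.assert_array_equal(out.weights, c.weights)

    def test_equality_kept_strictly_below_removed(self):
        w = np.zeros((3, 3))
        w[0, 1] = w[1, 0] = 100.0
        w[1, 2] = w[2, 1] = 10.0
        out = threshold_connectome(Connectome(w, _parc(3)), 0.1)
        assert out.weights[1, 2] == 10.0  # equal to cutoff: kept

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_study_fractions_monotone_edge_counts(self, seed):
        rng = np.random.default_rng(seed)
        c = Connectome(random_weighted_adjacency(rng, 40), _parc(40))
        counts = [
            threshold_connectome(c, f).edge_count()
            for f in (0.001, 0.005, 0.010, 0.015)
        ]
        assert all(b <= a for a, b in zip(counts, counts[1:]))

    def test_edge_set_nesting(self, rng):
        c = Connectome(random_weighted_adjacency(rng, 30), _parc(30))
        lo = threshold_connectome(c, 0.002).weights > 0
        hi = threshold_connectome(c, 0.02).weights > 0
        assert np.all(lo | ~hi)  # edges at the stricter cutoff nest in the looser

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(seed=st.integers(0, 10**6),
           f1=st.floats(0.0, 0.5), f2=st.floats(0.0, 0.5))
    def test_threshold_nesting_property(self, seed, f1, f2):
        """Edge sets at a stricter fraction always nest inside looser ones."""
        lo, hi = sorted([f1, f2])
        rng = np.random.default_rng(seed)
        c = Connectome(random_weighted_adjacency(rng, 12), _parc(12))
        loose = threshold_connectome(c, lo).weights > 0
        strict = threshold_connectome(c, hi).weights > 0
        assert np.all(loose | ~strict)

    def test_all_zero_rejected(self):
        with pytest.raises(DegenerateInputError):
            threshold_connectome(Connectome(np.zeros((3, 3)), _parc(3)), 0.001)

    def test_symmetry_and_diagonal_preserved(self, rng):
        c = Connectome(random_weighted_adjacency(rng, 25), _parc(25))
        for f in (0.0, 0.005, 0.05):
            out = threshold_connectome(c, f)
            np.testing.assert_array_equal(out.weights, out.weights.T)
            assert np.all(np.diag(out.weights) == 0)


class TestBinarize:
    def test_maps_support_to_one(self, rng):
        c = Connectome(random_weighted_adjacency(rng, 15), _parc(15))
        b = binarize(c)
        assert set(np.unique(b.weights)) <= {0.0, 1.0}
        np.testing.assert_array_equal(b.weights > 0, c.weights > 0)

    def test_idempotent(self, rng):
        c = Connectome(random_weighted_adjacency(rng, 15), _parc(15))
        once = binarize(c)
        np.testing.assert_array_equal(binarize(once).weights, once.weights)

    def test_edge_count_is_half_nonzero(self, rng):
        c = Connectome(random_weighted_adjacency(rng, 15), _parc(15))
        b = binarize(c)
        assert b.edge_count() == np.count_nonzero(c.weights) // 2


class TestDegree:
    def test_triangle(self):
        a = np.ones((3, 3)) - np.eye(3)
        assert nodal_degree(Connectome(a, _parc(3))).values.tolist() == [2, 2, 2]

    def test_single_edge(self):
        a = np.zeros((3, 3))
        a[0, 1] = a[1, 0] = 1.0
        assert nodal_degree(Connectome(a, _parc(3))).values.tolist() == [1, 1, 0]

    def test_weighted_input_rejected(self, rng):
        c = Connectome(random_weighted_adjacency(rng, 10), _parc(10))
        with pytest.raises(ValidationError):
            nodal_degree(c)

    def test_matches_neighbor_set_oracle(self, rng):
        a = random_binary_adjacency(rng, 20, 0.3)
        deg = nodal_degree(Connectome(a, _parc(20))).values
        oracle = [len({j for j in range(20) if a[i, j]}) for i in range(20)]
        assert deg.tolist() == oracle


class TestNetworkMeans:
    def test_constant_vector(self):
        parc = _parc(9, 3)
        m = NodalMetrics("s", "degree", np.full(9, 4.0))
        means = network_means(m, parc).means
        assert list(means.index) == list(parc.networks)
        assert (means == 4.0).all()

    def test_two_network_example(self):
        parc = Parcellation(("a", "b", "c"), ("N1", "N1", "N2"))
        m = NodalMetrics("s", "x", np.array([1.0, 3.0, 10.0]))
        means = network_means(m, parc).means
        assert means["N1"] == 2.0 and means["N2"] == 10.0

    def test_size_weighted_conservation(self, rng):
        parc = _parc(17, 5)
        m = NodalMetrics("s", "x", rng.normal(size=17))
        means = network_means(m, parc).means
        sizes = parc.sizes()
        weighted = sum(means[n] * sizes[n] for n in parc.networks) / 17
        assert weighted == pytest.approx(m.values.mean(), abs=1e-12)


class TestGroupAverage:
    def test_single_subject_identity(self, rng):
        m = NodalMetrics("s", "x", rng.normal(size=10))
        np.testing.assert_array_equal(group_average_nodal([m]).values, m.values)

    def test_mirror_pair_gives_constant(self, rng):
        v = rng.normal(size=10)
        pair = [NodalMetrics("a", "x", v), NodalMetrics("b", "x", -v + 6.0)]
        np.testing.assert_allclose(group_average_nodal(pair).values, 3.0)

    def test_matches_column_means(self, rng):
        ms = [NodalMetrics(f"s{i}", "x", rng.normal(size=12)) for i in range(10)]
        expected = np.vstack([m.values for m in ms]).mean(axis=0)
        np.testing.assert_allclose(group_average_nodal(ms).values, expected)

    def test_mismatched_sizes_rejected(self, rng):
        ms = [NodalMetrics("a", "x", np.zeros(5)), NodalMetrics("b", "x", np.zeros(6))]
        with pytest.raises(ValidationError):
            group_average_nodal(ms)
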