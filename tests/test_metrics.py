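import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fccomm.baselines import DissimilarityMatrix
from fccomm.errors import FCCommError, UndefinedIndexError
from fccomm.metrics import (
    c_index,
    ch_index,
    dunn_index,
    hamming_distance,
    modularity,
    nmi,
    silhouette,
    vi_distance,
)
from fccomm.types import FCMatrix, Partition

from .conftest import random_fc, random_partition
from .oracles import (
    c_index_loops,
    ch_loops,
    dunn_loops,
    hamming_exhaustive,
    modularity_loops,
    nmi_loops,
    vi_loops,
)


def block_distance(sizes, within, between):
    """Block-constant dissimilarity matrix with the given level structure."""
    labels = np.repeat(np.arange(1, len(sizes) + 1), sizes)
    d = np.where(labels[:, None] == labels[None, :], within, between).astype(float)
    np.fill_diagonal(d, 0.0)
    return DissimilarityMatrix(d), Partition(labels, len(sizes))


def random_dissimilarity(n, rng):
    d = rng.uniform(0.05, 1.9, size=(n, n))
    d = 0.5 * (d + d.T)
    np.fill_diagonal(d, 0.0)
    return DissimilarityMatrix(d)


class TestSilhouette:
    def test_two_separated_blocks(self):
        D, z = block_distance([2, 2], within=0.1, between=1.0)
        assert silhouette(D, z) == pytest.approx(0.9, abs=1e-12)

    def test_shuffled_partition_scores_lower(self):
        D, z = block_distance([4, 4], within=0.1, between=1.0)
        rng = np.random.default_rng(0)
        shuffled = Partition(rng.permutation(z.labels), z.K)
        assert silhouette(D, shuffled) < silhouette(D, z)

    def test_all_equal_distances_score_zero(self):
        d = np.ones((4, 4)) - np.eye(4)
        D = DissimilarityMatrix(d)
        z = Partition(np.array([1, 1, 2, 2]), 2)
        assert silhouette(D, z) == pytest.approx(0.0, abs=1e-12)

    def test_single_community_undefined(self):
        D, _ = block_distance([4], within=0.5, between=0.5)
        with pytest.raises(UndefinedIndexError):
            silhouette(D, Partition(np.ones(4, dtype=int), 1))


class TestModularity:
    def test_single_community_is_zero(self):
        rng = np.random.default_rng(1)
        A = random_fc(6, rng)
        z = Partition(np.ones(6, dtype=int), 1)
        assert modularity(A, z) == pytest.approx(0.0, abs=1e-12)

    def test_two_disjoint_edges(self):
        w = np.eye(4)
        w[0, 1] = w[1, 0] = 1.0
        w[2, 3] = w[3, 2] = 1.0
        A = FCMatrix(w)
        z = Partition(np.array([1, 1, 2, 2]), 2)
        assert modularity(A, z) == pytest.approx(0.5, abs=1e-12)

    def test_matches_double_loop_oracle(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            A = random_fc(6, rng)
            z = random_partition(6, 3, rng)
            assert modularity(A, z) == pytest.approx(
                modularity_loops(A.weights, z.labels), abs=1e-12
            )


class TestViAndNmi:
    def test_identical_partitions(self):
        z = Partition(np.array([1, 2, 1, 3]), 3)
        assert vi_distance(z, z) == pytest.approx(0.0, abs=1e-12)
        assert nmi(z, z) == pytest.approx(1.0, abs=1e-12)

    def test_independent_balanced_table(self):
        z1 = Partition(np.array([1, 1, 2, 2]), 2)
        z2 = Partition(np.array([1, 2, 1, 2]), 2)
        assert vi_distance(z1, z2) == pytest.approx(2 * np.log(2), abs=1e-12)
        assert nmi(z1, z2) == pytest.approx(0.0, abs=1e-12)

    def test_symmetry_and_oracles(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            n = int(rng.integers(6, 12))
            z1 = random_partition(n, int(rng.integers(2, 5)), rng)
            z2 = random_partition(n, int(rng.integers(2, 5)), rng)
            assert vi_distance(z1, z2) == pytest.approx(vi_distance(z2, z1), abs=1e-12)
            assert vi_distance(z1, z2) == pytest.approx(
                vi_loops(list(z1.labels), list(z2.labels)), abs=1e-9
            )
            assert nmi(z1, z2) == pytest.approx(
                nmi_loops(list(z1.labels), list(z2.labels)), abs=1e-9
            )

    def test_nmi_matches_sklearn(self):
        from sklearn.metrics import normalized_mutual_info_score

        rng = np.random.default_rng(4)
        for _ in range(10):
            z1 = random_partition(10, 3, rng)
            z2 = random_partition(10, 4, rng)
            assert nmi(z1, z2) == pytest.approx(
                normalized_mutual_info_score(
                    z1.labels, z2.labels, average_method="geometric"
                ),
                abs=1e-12,
            )

    def test_vi_triangle_inequality(self):
        rng = np.random.default_rng(5)
        for _ in range(30):
            n = 10
            za = random_partition(n, 3, rng)
            zb = random_partition(n, 3, rng)
            zc = random_partition(n, 3, rng)
            assert vi_distance(za, zc) <= vi_distance(za, zb) + vi_distance(
                zb, zc
            ) + 1e-9

    def test_length_mismatch_rejected(self):
        z1 = Partition(np.array([1, 2]), 2)
        z2 = Partition(np.array([1, 2, 1]), 2)
        with pytest.raises(FCCommError):
            vi_distance(z1, z2)
        with pytest.raises(FCCommError):
            nmi(z1, z2)


class TestChIndex:
    def test_perfect_separation_diverges(self):
        D, z = block_distance([3, 3], within=0.0, between=1.0)
        assert ch_index(D, z) == np.inf

    def test_matches_oracle(self):
        rng = np.random.default_rng(6)
        for _ in range(20):
            D = random_dissimilarity(8, rng)
            z = random_partition(8, 3, rng)
            assert ch_index(D, z) == pytest.approx(
                ch_loops(D.d, z.labels), abs=1e-10, rel=1e-10
            )

    def test_merging_distinct_blocks_lowers_ch(self):
        D, z = block_distance([4, 4, 4], within=0.1, between=1.0)
        merged = Partition(np.where(z.labels == 3, 2, z.labels), 2)
        assert ch_index(D, merged) < ch_index(D, z)


class TestCIndex:
    def test_within_pairs_smallest(self):
        D, z = block_distance([3, 3], within=0.1, between=1.0)
        assert c_index(D, z) == pytest.approx(0.0, abs=1e-12)

    def test_within_pairs_largest(self):
        D, z = block_distance([3, 3], within=1.0, between=0.1)
        assert c_index(D, z) == pytest.approx(1.0, abs=1e-12)

    def test_matches_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            D = random_dissimilarity(7, rng)
            z = random_partition(7, 3, rng)
            assert c_index(D, z) == pytest.approx(
                c_index_loops(D.d, z.labels), abs=1e-12
            )


class TestDunn:
    def test_block_constant_value(self):
        D, z = block_distance([3, 3], within=0.2, between=1.0)
        assert dunn_index(D, z) == pytest.approx(5.0, abs=1e-12)

    def test_identical_points_in_different_communities(self):
        d = np.array(
            [
                [0.0, 0.0, 0.5],
                [0.0, 0.0, 0.5],
                [0.5, 0.5, 0.0],
            ]
        )
        D = DissimilarityMatrix(d)
        z = Partition(np.array([1, 2, 2]), 2)
        assert dunn_index(D, z) == pytest.approx(0.0, abs=1e-12)

    def test_matches_oracle(self):
        rng = np.random.default_rng(8)
        for _ in range(20):
            D = random_dissimilarity(8, rng)
            z = random_partition(8, 3, rng)
            assert dunn_index(D, z) == pytest.approx(
                dunn_loops(D.d, z.labels), abs=1e-12
            )


class TestHamming:
    def test_pure_relabeling_gives_zero(self):
        z1 = Partition(np.array([1, 1, 2, 3, 2]), 3)
        perm = np.array([3, 1, 2])
        z2 = z1.relabeled(perm)
        dist, p = hamming_distance(z1, z2)
        assert dist == 0.0
        assert np.array_equal(z2.relabeled(p).labels, z1.labels)

    def test_single_mismatch(self):
        z1 = Partition(np.array([1, 1, 2, 2]), 2)
        z2 = Partition(np.array([1, 2, 2, 2]), 2)
        dist, _ = hamming_distance(z1, z2)
        assert dist == pytest.approx(0.25, abs=1e-12)

    def test_matches_exhaustive_search(self):
        rng = np.random.default_rng(9)
        for _ in range(30):
            n = int(rng.integers(6, 13))
            K = int(rng.integers(2, 6))
            z1 = random_partition(n, K, rng)
            z2 = random_partition(n, K, rng)
            dist, _ = hamming_distance(z1, z2)
            assert dist == pytest.approx(
                hamming_exhaustive(list(z1.labels), list(z2.labels), K), abs=1e-12
            )

    def test_symmetric_and_relabel_invariant(self):
        rng = np.random.default_rng(10)
        for _ in range(10):
            z1 = random_partition(9, 3, rng)
            z2 = random_partition(9, 3, rng)
            d12, _ = hamming_distance(z1, z2)
            d21, _ = hamming_distance(z2, z1)
            assert d12 == pytest.approx(d21, abs=1e-12)
            relab = z2.relabeled(np.array([2, 3, 1]))
            d12r, _ = hamming_distance(z1, relab)
            assert d12 == pytest.approx(d12r, abs=1e-12)


@settings(deadline=None, max_examples=30, derandomize=True)
@given(st.integers(min_value=0, max_value=10_000))
def test_index_range_invariants(seed):
    """Silhouette in [-1,1], C-index in [0,1], VI >= 0, NMI in [0,1],
    Hamming in [0,1], CH >= 0, Dunn >= 0 on randomized inputs."""
    rng = np.random.default_rng(seed)
    n = int(rng.integers(6, 14))
    K = int(rng.integers(2, min(5, n - 1) + 1))
    D = random_dissimilarity(n, rng)
    z1 = random_partition(n, K, rng)
    z2 = random_partition(n, K, rng)
    assert -1.0 <= silhouette(D, z1) <= 1.0
    assert 0.0 <= c_index(D, z1) <= 1.0
    assert vi_distance(z1, z2) >= 0.0
    assert 0.0 <= nmi(z1, z2) <= 1.0
    dist, _ = hamming_distance(z1, z2)
    assert 0.0 <= dist <= 1.0
    assert dunn_index(D, z1) >= 0.0
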