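import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from genehypernet import (
    manhattan_distance_matrix,
    binarise,
    build_hypernetwork,
    connectivity,
    entropy_per_gene,
)
from genehypernet.hypernetwork import DistanceMatrix, IncidenceMatrix

from conftest import make_matrix


def naive_hypernetwork(M):
    """Triple-loop oracle for H = M·Mᵀ, its mean, and row entropies."""
    n, m = M.shape
    H = np.zeros((n, n), dtype=int)
    for i in range(n):
        for j in range(n):
            for k in range(m):
                H[i, j] += int(M[i, k] == 1 and M[j, k] == 1)
    conn = H.sum() / (n * n)
    ents = []
    for i in range(n):
        row = [H[i, j] for j in range(n) if j != i]
        s = sum(row)
        if s == 0:
            ents.append(0.0)
        else:
            ents.append(-sum(
                (v / s) * np.log2(v / s) for v in row if v > 0
            ))
    return H, conn, np.array(ents)


def random_distance_matrix(rng, n_set=6, n_total=40):
    vals = rng.uniform(0, 10, size=(n_set, n_total))
    rows = [f"g{i}" for i in range(n_set)]
    cols = [f"g{i}" for i in range(n_total)]
    for i in range(n_set):
        vals[i, i] = np.nan
    return DistanceMatrix(vals, rows, cols, ["s1"], "none")


class TestManhattanDistance:
    def test_identical_profiles_have_zero_distance(self):
        em = make_matrix([[0, 0, 0], [0, 0, 0], [1, 2, 3]], ["a", "a", "a"],
                         normalised=True)
        d = manhattan_distance_matrix(em, ["g0"], "a", transform="none")
        assert d.values[0, 1] == 0.0

    def test_hand_summed_distance(self):
        em = make_matrix([[1, 2, 3], [2, 2, 5]], ["a", "a", "a"], normalised=True)
        d = manhattan_distance_matrix(em, ["g0"], "a", transform="none")
        assert d.values[0, 1] == pytest.approx(3.0)

    def test_self_column_is_masked(self):
        em = make_matrix([[1, 2], [3, 4]], ["a", "a"], normalised=True)
        d = manhattan_distance_matrix(em, ["g0", "g1"], "a")
        assert np.isnan(d.values[0, 0]) and np.isnan(d.values[1, 1])

    def test_matches_brute_force_double_loop(self):
        rng = np.random.default_rng(0)
        vals = rng.uniform(0, 100, size=(20, 5))
        em = make_matrix(vals, ["a"] * 5, normalised=True)
        gene_set = [f"g{i}" for i in (3, 7, 11, 19)]
        d = manhattan_distance_matrix(em, gene_set, "a", transform="none")
        for r, gi in enumerate((3, 7, 11, 19)):
            for j in range(20):
                expected = np.nan if j == gi else sum(
                    abs(vals[gi, s] - vals[j, s]) for s in range(5)
                )
                if j == gi:
                    assert np.isnan(d.values[r, j])
                else:
                    assert d.values[r, j] == pytest.approx(expected)

    def test_symmetry_and_triangle_inequality(self):
        rng = np.random.default_rng(1)
        vals = rng.uniform(0, 50, size=(12, 4))
        em = make_matrix(vals, ["a"] * 4, normalised=True)
        genes = em.gene_ids
        d = manhattan_distance_matrix(em, genes, "a", transform="none").values
        for _ in range(200):
            i, j, k = rng.choice(12, size=3, replace=False)
            assert d[i, j] == pytest.approx(d[j, i])
            assert d[i, j] <= d[i, k] + d[k, j] + 1e-9

    def test_sample_order_is_irrelevant(self):
        rng = np.random.default_rng(2)
        vals = rng.uniform(0, 50, size=(8, 3))
        em = make_matrix(vals, ["a"] * 3, normalised=True)
        d1 = manhattan_distance_matrix(em, ["g0", "g1"], ["a_1", "a_2", "a_3"])
        d2 = manhattan_distance_matrix(em, ["g0", "g1"], ["a_3", "a_1", "a_2"])
        np.testing.assert_allclose(d1.values, d2.values)

    def test_errors(self):
        em = make_matrix([[1, 2]], ["a", "a"], normalised=True)
        with pytest.raises(ValueError, match="empty gene set"):
            manhattan_distance_matrix(em, [], "a")
        with pytest.raises(KeyError):
            manhattan_distance_matrix(em, ["g0"], ["nope"])
        with pytest.raises(KeyError):
            manhattan_distance_matrix(em, ["unknown"], "a")
        with pytest.raises(ValueError, match="transform"):
            manhattan_distance_matrix(em, ["g0"], "a", transform="sqrt")


class TestBinarise:
    def test_worked_decile_example(self):
        """Entries 1..10 at centile 30: t = 3.7, exactly {1,2,3} retained."""
        vals = np.arange(1, 11, dtype=float).reshape(1, 10)
        dm = DistanceMatrix(vals, ["r"], [f"c{i}" for i in range(10)], ["s"], "none")
        inc = binarise(dm, 30)
        assert inc.threshold == pytest.approx(3.7)
        assert inc.values.sum() == 3
        assert list(np.flatnonzero(inc.values[0])) == [0, 1, 2]

    def test_ties_at_threshold_are_retained(self):
        vals = np.full((3, 5), 2.0)
        dm = DistanceMatrix(vals, list("abc"), list("vwxyz"), ["s"], "none")
        inc = binarise(dm, 30)
        assert inc.values.all()

    def test_ones_fraction_tracks_the_centile(self):
        rng = np.random.default_rng(3)
        vals = rng.permutation(np.linspace(0.001, 1, 1000)).reshape(10, 100)
        dm = DistanceMatrix(vals, [f"r{i}" for i in range(10)],
                            [f"c{i}" for i in range(100)], ["s"], "none")
        inc = binarise(dm, 30)
        frac = inc.values.mean()
        assert abs(frac - 0.300) <= 0.001
        assert inc.threshold == pytest.approx(np.quantile(vals, 0.3))

    def test_masked_self_pairs_stay_zero(self):
        rng = np.random.default_rng(4)
        dm = random_distance_matrix(rng)
        inc = binarise(dm, 90)
        assert all(inc.values[i, i] == 0 for i in range(dm.n_set))

    @given(st.integers(0, 2**31 - 1), st.floats(5, 95))
    @settings(max_examples=25, deadline=None)
    def test_threshold_equals_quantile_oracle(self, seed, centile):
        rng = np.random.default_rng(seed)
        vals = rng.uniform(0, 1, size=(5, 30))
        dm = DistanceMatrix(vals.copy(), [f"r{i}" for i in range(5)],
                            [f"c{i}" for i in range(30)], ["s"], "none")
        inc = binarise(dm, centile)
        t = np.quantile(vals, centile / 100.0)
        assert inc.threshold == pytest.approx(t)
        np.testing.assert_array_equal(inc.values, (vals <= t).astype(np.uint8))

    def test_per_row_centile_option(self):
        rng = np.random.default_rng(5)
        dm = random_distance_matrix(rng, n_set=4, n_total=50)
        inc = binarise(dm, 30, per_row=True)
        # each row keeps ~30% of its 49 unmasked columns
        sums = inc.values.sum(axis=1)
        assert (np.abs(sums - 0.3 * 49) <= 1).all()

    def test_invalid_inputs(self):
        rng = np.random.default_rng(6)
        dm = random_distance_matrix(rng)
        with pytest.raises(ValueError):
            binarise(dm, 0)
        with pytest.raises(ValueError):
            binarise(dm, 100)
        empty = DistanceMatrix(np.full((1, 1), np.nan), ["r"], ["r"], ["s"], "none")
        with pytest.raises(ValueError, match="empty"):
            binarise(empty, 30)


class TestHypernetwork:
    def _inc(self, M):
        M = np.asarray(M, dtype=np.uint8)
        return IncidenceMatrix(M, [f"r{i}" for i in range(M.shape[0])],
                               [f"c{j}" for j in range(M.shape[1])], 30.0, 0.0)

    def test_shared_column_count_example(self):
        hn = build_hypernetwork(self._inc([[1, 0, 1], [1, 1, 0]]))
        np.testing.assert_array_equal(hn.H, [[2, 1], [1, 2]])
        assert hn.connectivity == pytest.approx(1.5)

    def test_zero_matrix_gives_zero_hypernetwork(self):
        hn = build_hypernetwork(self._inc(np.zeros((3, 5))))
        assert not hn.H.any()
        assert hn.connectivity == 0.0
        assert np.allclose(hn.entropy, 0.0)

    def test_identity_incidence_gives_identity(self):
        hn = build_hypernetwork(self._inc(np.eye(3)))
        np.testing.assert_array_equal(hn.H, np.eye(3, dtype=int))

    def test_non_binary_input_rejected(self):
        with pytest.raises(ValueError, match="binary"):
            build_hypernetwork(self._inc(np.array([[2, 0], [0, 1]])))

    def test_symmetry_and_diagonal_identity(self):
        rng = np.random.default_rng(7)
        M = (rng.random((15, 80)) < 0.3).astype(np.uint8)
        hn = build_hypernetwork(self._inc(M))
        assert (hn.H == hn.H.T).all()
        np.testing.assert_array_equal(np.diag(hn.H), M.sum(axis=1))
        assert (hn.H <= np.minimum.outer(np.diag(hn.H), np.diag(hn.H))).all()

    def test_gene_order_permutation_equivariance(self):
        rng = np.random.default_rng(8)
        M = (rng.random((10, 60)) < 0.3).astype(np.uint8)
        perm = rng.permutation(10)
        hn = build_hypernetwork(self._inc(M))
        hn_p = build_hypernetwork(self._inc(M[perm]))
        np.testing.assert_array_equal(hn_p.H, hn.H[np.ix_(perm, perm)])
        assert hn_p.connectivity == pytest.approx(hn.connectivity)
        assert sorted(hn_p.entropy) == pytest.approx(sorted(hn.entropy))

    def test_matches_triple_loop_oracle(self):
        rng = np.random.default_rng(9)
        for _ in range(10):
            n = rng.integers(2, 10)
            m = rng.integers(5, 60)
            M = (rng.random((n, m)) < rng.uniform(0.1, 0.6)).astype(np.uint8)
            H, conn, ents = naive_hypernetwork(M)
            hn = build_hypernetwork(self._inc(M))
            np.testing.assert_array_equal(hn.H, H)
            assert hn.connectivity == pytest.approx(conn)
            np.testing.assert_allclose(hn.entropy, ents, atol=1e-12)


class TestConnectivityEntropy:
    def test_connectivity_examples(self):
        assert connectivity(np.array([[2, 1], [1, 2]])) == 1.5
        assert connectivity(np.zeros((4, 4))) == 0.0
        assert connectivity(np.array([[2, 1], [1, 2]]), include_diagonal=False) == 1.0
        with pytest.raises(ValueError):
            connectivity(np.zeros((0, 0)))

    def test_entropy_analytic_cases(self):
        # off-diagonal rows (2,2) -> 1 bit, (4,0,0) -> 0, (1,1,1,1) -> 2
        H = np.array([[9, 2, 2], [2, 9, 2], [2, 2, 9]])
        assert entropy_per_gene(H)[0] == pytest.approx(1.0)
        H = np.array([[5, 4, 0, 0], [4, 5, 0, 0], [0, 0, 5, 0], [0, 0, 0, 5]])
        assert entropy_per_gene(H)[0] == pytest.approx(0.0)
        H = np.ones((5, 5), dtype=int)
        assert entropy_per_gene(H)[0] == pytest.approx(2.0)

    def test_zero_row_has_zero_entropy(self):
        H = np.zeros((3, 3), dtype=int)
        np.testing.assert_allclose(entropy_per_gene(H), 0.0)

    def test_entropy_bounded_by_log2_of_partners(self):
        rng = np.random.default_rng(10)
        for _ in range(20):
            n = int(rng.integers(2, 30))
            H = rng.integers(0, 50, size=(n, n))
            ents = entropy_per_gene(H)
            assert (ents >= 0).all()
            assert (ents <= np.log2(n - 1) + 1e-12).all()

    def test_single_gene_set_rejected(self):
        with pytest.raises(ValueError):
            entropy_per_gene(np.array([[3]]))
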