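import numpy as np
import pytest

from coextnet.metrics import (
    barber_modularity,
    degree_distribution,
    ensemble_metrics,
    h2prime,
    modularity_lpawb,
    wnodf,
)

# ---------------------------------------------------------------------------
# independent oracles (straightforward loop implementations)


def wnodf_bruteforce(w):
    """Plain-loop weighted NODF: ordered pairs with strictly decreasing
    marginal totals; pairwise term counts cells with 0 < lower < upper."""
    w = np.asarray(w, dtype=float)
    w = w[w.sum(axis=1) > 0][:, w.sum(axis=0) > 0]
    terms = []
    for mat in (w, w.T):
        mat = mat[np.argsort(-mat.sum(axis=1), kind="stable")]
        tot = mat.sum(axis=1)
        r = mat.shape[0]
        for u in range(r):
            for v in range(u + 1, r):
                if tot[u] <= tot[v]:
                    terms.append(0.0)
                    continue
                k = sum(1 for c in range(mat.shape[1])
                        if 0 < mat[v, c] < mat[u, c])
                nz = sum(1 for c in range(mat.shape[1]) if mat[v, c] > 0)
                terms.append(100.0 * k / nz)
    return float(np.mean(terms))


def modularity_exhaustive(w):
    """Exact optimum of Barber's Q on tiny matrices.

    Enumerates all set partitions of the rows; given a row partition each
    column independently joins its best module (or none).
    """
    w = np.asarray(w, dtype=float)
    w = w[w.sum(axis=1) > 0][:, w.sum(axis=0) > 0]
    R, C = w.shape
    F = w.sum()
    B = w - np.outer(w.sum(axis=1), w.sum(axis=0)) / F

    def partitions(n):
        if n == 0:
            yield []
            return
        for part in partitions(n - 1):
            for i in range(len(part)):
                yield part[:i] + [part[i] + [n - 1]] + part[i + 1:]
            yield part + [[n - 1]]

    best = -np.inf
    for part in partitions(R):
        q = 0.0
        for j in range(C):
            contrib = [B[rows, j].sum() for rows in part]
            q += max(0.0, max(contrib))
        best = max(best, q / F)
    return best


def degree_tally(w):
    w = np.asarray(w)
    return ((w > 0).sum(axis=1), (w > 0).sum(axis=0))


# ---------------------------------------------------------------------------


class TestDegreeDistribution:
    def test_identity_pattern(self):
        d = degree_distribution(np.eye(2))
        assert d["rows"][0].tolist() == [1]
        assert d["rows"][1].tolist() == [1.0]

    def test_fully_connected(self):
        d = degree_distribution(np.ones((3, 4)))
        assert d["rows"][0].tolist() == [4]
        assert d["cols"][0].tolist() == [3]

    def test_matches_exhaustive_tally(self):
        rng = np.random.default_rng(0)
        w = (rng.random((10, 20)) < 0.3).astype(float)
        d = degree_distribution(w)
        row_deg, col_deg = degree_tally(w)
        for guild, degs in (("rows", row_deg), ("cols", col_deg)):
            uniq, ccdf = d[guild]
            for u, c in zip(uniq, ccdf):
                assert c == pytest.approx((degs >= u).mean())
            assert (np.diff(ccdf) <= 0).all()  # complementary cumulative


class TestWNODF:
    def test_equal_marginals_give_zero(self):
        # all row totals and all column totals tied: no decreasing fill
        assert wnodf(np.ones((4, 4))) == 0.0

    def test_perfectly_nested(self):
        w = np.array([[3, 2, 1], [2, 1, 0], [1, 0, 0]])
        assert wnodf(w) == pytest.approx(wnodf_bruteforce(w))
        assert wnodf(w) == pytest.approx(100.0)

    def test_matches_bruteforce_on_random_matrices(self):
        rng = np.random.default_rng(1)
        for _ in range(200):
            r = rng.integers(2, 9)
            c = rng.integers(2, 9)
            w = rng.poisson(1.5, size=(r, c)).astype(float)
            if (w.sum(axis=1) > 0).sum() < 2 or (w.sum(axis=0) > 0).sum() < 2:
                continue
            assert wnodf(w) == pytest.approx(wnodf_bruteforce(w), abs=1e-9)

    def test_scale_invariance(self):
        rng = np.random.default_rng(2)
        w = rng.poisson(2, size=(5, 6)).astype(float) + 0.1
        assert wnodf(3.7 * w) == pytest.approx(wnodf(w))

    def test_permutation_invariance(self):
        rng = np.random.default_rng(3)
        w = rng.poisson(2, size=(5, 6)).astype(float)
        p = rng.permutation(5)
        q = rng.permutation(6)
        assert wnodf(w[np.ix_(p, q)]) == pytest.approx(wnodf(w))

    def test_empty_species_do_not_matter(self):
        rng = np.random.default_rng(4)
        w = rng.poisson(2, size=(4, 5)).astype(float) + 0.5
        padded = np.zeros((5, 6))
        padded[:4, :5] = w
        assert wnodf(padded) == pytest.approx(wnodf(w))

    def test_degenerate_matrix_rejected(self):
        with pytest.raises(ValueError):
            wnodf(np.array([[1.0, 2.0]]))


class TestH2Prime:
    def test_perfect_specialisation_on_diagonal(self):
        assert h2prime(np.diag([4.0, 4.0, 4.0, 4.0])) == pytest.approx(1.0, abs=1e-6)

    def test_independence_gives_zero(self):
        r = np.array([0.1, 0.4, 0.5])
        c = np.array([0.3, 0.3, 0.2, 0.2])
        assert h2prime(np.outer(r, c)) == pytest.approx(0.0, abs=1e-6)

    def test_integer_independence_gives_zero(self):
        # margins (20, 20) x (20, 20): expected cells are exact integers
        w = np.full((2, 2), 10.0)
        assert h2prime(w) == pytest.approx(0.0, abs=1e-6)

    def test_bounded_on_random_matrices(self):
        rng = np.random.default_rng(5)
        for _ in range(1000):
            r = rng.integers(2, 6)
            c = rng.integers(2, 6)
            w = rng.poisson(1.0, size=(r, c)).astype(float)
            if w.sum() == 0:
                continue
            v = h2prime(w)
            assert 0.0 <= v <= 1.0

    def test_permutation_invariance(self):
        rng = np.random.default_rng(6)
        w = rng.poisson(3, size=(4, 5)).astype(float)
        p = rng.permutation(4)
        q = rng.permutation(5)
        assert h2prime(w[np.ix_(p, q)]) == pytest.approx(h2prime(w))

    def test_empty_species_do_not_matter(self):
        w = np.array([[3.0, 1.0], [1.0, 2.0]])
        padded = np.zeros((3, 3))
        padded[:2, :2] = w
        assert h2prime(padded) == pytest.approx(h2prime(w))

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            h2prime(np.zeros((3, 3)))


class TestModularity:
    def test_uniform_matrix_has_no_structure(self):
        _, q = modularity_lpawb(np.ones((4, 5)), rng=0)
        assert q == pytest.approx(0.0, abs=1e-9)

    def test_block_diagonal_recovered_exactly(self):
        w = np.zeros((4, 6))
        w[:2, :3] = 2.0
        w[2:, 3:] = 3.0
        labels, q = modularity_lpawb(w, rng=0)
        # two modules matching the blocks
        assert labels["rows"][0] == labels["rows"][1] == labels["cols"][0]
        assert labels["rows"][2] == labels["rows"][3] == labels["cols"][3]
        assert labels["rows"][0] != labels["rows"][2]
        assert q == pytest.approx(modularity_exhaustive(w), abs=1e-9)
        assert q == pytest.approx(barber_modularity(w, labels["rows"], labels["cols"]))

    def test_matches_exhaustive_search_on_small_instances(self):
        rng = np.random.default_rng(7)
        for _ in range(25):
            r = rng.integers(2, 7)
            c = rng.integers(2, 7)
            w = rng.poisson(1.0, size=(r, c)).astype(float)
            w[rng.random((r, c)) < 0.3] = 0.0
            if w.sum() == 0:
                continue
            keep_r = w.sum(axis=1) > 0
            keep_c = w.sum(axis=0) > 0
            if keep_r.sum() < 1 or keep_c.sum() < 1:
                continue
            _, q = modularity_lpawb(w, n_restarts=20, rng=11)
            assert q == pytest.approx(modularity_exhaustive(w), abs=1e-9)

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(8)
        w = rng.poisson(2, size=(6, 7)).astype(float)
        l1, q1 = modularity_lpawb(w, rng=123)
        l2, q2 = modularity_lpawb(w, rng=123)
        assert q1 == q2
        assert np.array_equal(l1["rows"], l2["rows"])
        assert np.array_equal(l1["cols"], l2["cols"])

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            modularity_lpawb(np.zeros((3, 3)), rng=0)


class TestEnsembles:
    def test_identical_networks_zero_width(self):
        rng = np.random.default_rng(9)
        w = rng.poisson(2, size=(4, 5)).astype(float) + 0.5
        rep = ensemble_metrics([w, w, w], rng=0)
        for lo, hi in rep.intervals.values():
            assert lo == pytest.approx(hi)

    def test_two_networks_interval_is_min_max(self):
        a = np.array([[3.0, 1.0, 0.0], [1.0, 2.0, 1.0], [0.0, 1.0, 1.0]])
        b = a * 1.0
        b[0, 2] = 2.0
        rep = ensemble_metrics([a, b], rng=0)
        lo, hi = rep.intervals["h2prime"]
        vals = sorted([h2prime(a), h2prime(b)])
        assert lo == pytest.approx(vals[0])
        assert hi == pytest.approx(vals[1])

    def test_failed_network_excluded_and_counted(self):
        good = np.array([[2.0, 1.0], [1.0, 2.0]])
        bad = np.zeros((2, 2))
        rep = ensemble_metrics([good, bad], rng=0)
        assert rep.n_failed == 1
        assert np.isfinite(rep.h2prime)
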