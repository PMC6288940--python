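import numpy as np
import pytest
from scipy.cluster.hierarchy import cophenet, linkage
from scipy.spatial.distance import squareform
from scipy.stats import norm, pearsonr

from cnvpop.core_io import Cnvr, ContractError, GenomicInterval, ValidationError
from cnvpop.popstruct import (
    AuResult,
    BootstrapResult,
    ScoringMatrix,
    au_pvalues,
    build_matrix,
    multiscale_bootstrap,
    pca,
    sample_distance,
    upgma,
)


def region(i, samples, state="loss"):
    return Cnvr(GenomicInterval("chrT", i * 1000, i * 1000 + 500), state,
                frozenset((s, state) for s in samples), len(set(samples)) == 1)


class TestBuildMatrix:
    def test_min_share_filter(self):
        cnvrs = [region(0, ["a"]), region(1, ["a", "b"]), region(2, ["a", "b", "c", "d", "e"])]
        m = build_matrix(cnvrs, list("abcde"), min_share=2)
        assert m.n_rows == 2
        assert m.data.sum(axis=1).tolist() == [2, 5]  # row sums = member counts
        assert build_matrix(cnvrs, list("abcde"), min_share=1).n_rows == 3

    def test_unknown_member_rejected(self):
        with pytest.raises(ValidationError):
            build_matrix([region(0, ["a", "z"])], list("abc"))


class TestSampleDistance:
    def test_identical_and_complementary_columns(self):
        data = np.array([[1, 1, 0], [0, 0, 1], [1, 1, 0], [0, 0, 1]], dtype=np.uint8)
        m = ScoringMatrix(["r1", "r2", "r3", "r4"], ["a", "b", "c"], data)
        d = sample_distance(m, "correlation")
        assert d[0, 1] == pytest.approx(0.0)
        assert d[0, 2] == pytest.approx(2.0)  # antipodal binary vectors
        dj = sample_distance(m, "jaccard")
        assert dj[0, 1] == pytest.approx(0.0)
        assert dj[0, 2] == pytest.approx(1.0)

    def test_matches_formula_oracle(self):
        rng = np.random.default_rng(13)
        data = (rng.random((30, 6)) < 0.4).astype(np.uint8)
        m = ScoringMatrix([f"r{i}" for i in range(30)], list("abcdef"), data)
        d = sample_distance(m, "correlation")
        dj = sample_distance(m, "jaccard")
        for i in range(6):
            for j in range(6):
                if i == j:
                    continue
                r, _ = pearsonr(data[:, i], data[:, j])
                assert d[i, j] == pytest.approx(1 - r)
                si, sj = set(np.flatnonzero(data[:, i])), set(np.flatnonzero(data[:, j]))
                assert dj[i, j] == pytest.approx(1 - len(si & sj) / len(si | sj))

    def test_single_sample_rejected(self):
        m = ScoringMatrix(["r1"], ["a"], np.ones((1, 1), dtype=np.uint8))
        with pytest.raises(ContractError):
            sample_distance(m)


class TestUpgma:
    def test_hand_computed_three_points(self):
        d = np.array([[0.0, 2.0, 8.0], [2.0, 0.0, 8.0], [8.0, 8.0, 0.0]])
        tree = upgma(d, ["A", "B", "C"])
        assert tree.leafsets == [frozenset("AB"), frozenset("ABC")]
        assert tree.heights.tolist() == [1.0, 4.0]

    def test_equal_distances_caterpillar_by_tiebreak(self):
        n = 4
        d = np.ones((n, n)) - np.eye(n)
        tree = upgma(d, list("abcd"))
        assert tree.leafsets == [frozenset("ab"), frozenset("abc"), frozenset("abcd")]
        coph = tree.cophenetic_matrix()
        off = coph[~np.eye(n, dtype=bool)]
        assert np.allclose(off, off[0])

    def test_matches_reference_average_linkage(self):
        rng = np.random.default_rng(14)
        for _ in range(20):
            n = 8
            cond = rng.random(n * (n - 1) // 2) + 0.01
            d = squareform(cond)
            tree = upgma(d, [f"s{i}" for i in range(n)])
            ref = linkage(cond, method="average")
            assert np.allclose(squareform(cophenet(ref)), tree.cophenetic_matrix())

    def test_ultrametric_heights_nondecreasing(self):
        rng = np.random.default_rng(15)
        d = squareform(rng.random(45) + 0.01)
        tree = upgma(d, [f"s{i}" for i in range(10)])
        assert np.all(np.diff(tree.heights) >= -1e-12)

    def test_nan_rejected(self):
        d = np.array([[0.0, np.nan], [np.nan, 0.0]])
        with pytest.raises(ValueError):
            upgma(d, ["a", "b"])

    def test_newick_contains_all_leaves(self):
        d = squareform(np.arange(1, 7, dtype=float))
        tree = upgma(d, ["x", "y", "z", "w"])
        nwk = tree.to_newick(annotate=False)
        assert nwk.endswith(";")
        for leaf in "xyzw":
            assert leaf in nwk


def planted_matrix(rng, n_per_cluster=4, n_rows=40, flip=0.05):
    """Rows are informative for a two-cluster split with small label noise."""
    samples = [f"L{i}" for i in range(n_per_cluster)] + [f"R{i}" for i in range(n_per_cluster)]
    base = np.zeros((n_rows, 2 * n_per_cluster), dtype=np.uint8)
    base[: n_rows // 2, :n_per_cluster] = 1
    base[n_rows // 2:, n_per_cluster:] = 1
    noise = rng.random(base.shape) < flip
    data = np.where(noise, 1 - base, base).astype(np.uint8)
    return ScoringMatrix([f"r{i}" for i in range(n_rows)], samples, data)


class TestMultiscaleBootstrap:
    def test_true_split_has_high_bp(self):
        rng = np.random.default_rng(16)
        m = planted_matrix(rng)
        boot = multiscale_bootstrap(m, B=1000, seed=1)
        idx = {ls: i for i, ls in enumerate(boot.tree.leafsets)}
        left = frozenset(s for s in m.samples if s.startswith("L"))
        right = frozenset(s for s in m.samples if s.startswith("R"))
        assert left in idx or right in idx
        au = au_pvalues(boot)
        target = idx.get(left, idx.get(right))
        assert au.bp_p[target] >= 0.99
        assert au.au_p[target] >= 0.95

    def test_bp_decreases_with_noise(self):
        """Recovery of the planted split is monotone in label noise."""
        bps = []
        for flip in (0.02, 0.15, 0.35):
            rng = np.random.default_rng(17)
            m = planted_matrix(rng, flip=flip)
            boot = multiscale_bootstrap(m, scales=(1.0,), B=300, seed=2)
            idx = {ls: i for i, ls in enumerate(boot.tree.leafsets)}
            left = frozenset(s for s in m.samples if s.startswith("L"))
            right = frozenset(s for s in m.samples if s.startswith("R"))
            target = idx.get(left, idx.get(right))
            bps.append(0.0 if target is None else boot.counts[target, 0] / boot.B)
        assert bps[0] >= bps[1] >= bps[2]

    def test_determinism_under_seed(self):
        rng = np.random.default_rng(18)
        m = planted_matrix(rng, flip=0.2)
        b1 = multiscale_bootstrap(m, B=100, seed=5)
        b2 = multiscale_bootstrap(m, B=100, seed=5)
        assert np.array_equal(b1.counts, b2.counts)

    def test_invalid_b_rejected(self):
        rng = np.random.default_rng(19)
        m = planted_matrix(rng)
        with pytest.raises(ValueError):
            multiscale_bootstrap(m, B=0)


class TestAuPvalues:
    @staticmethod
    def _result(counts, scales, B, n_samples=4):
        d = squareform(np.arange(1, 7, dtype=float))
        tree = upgma(d, [f"s{i}" for i in range(n_samples)])
        counts = np.asarray(counts)
        n_edges = len(tree.leafsets)
        full = np.tile(counts, (n_edges, 1))
        return BootstrapResult(tree, list(scales), [max(2, round(10 * r)) for r in scales],
                               B, full)

    def test_constant_half_bp_gives_half_au(self):
        scales = [0.5 + 0.1 * i for i in range(10)]
        B = 10_000
        res = au_pvalues(self._result([B // 2] * 10, scales, B))
        assert res.au_p[0] == pytest.approx(0.5, abs=0.05)
        assert res.bp_p[0] == pytest.approx(0.5)

    def test_recovers_known_signal_and_curvature(self):
        """Counts generated from the z_r = v*sqrt(r) + c/sqrt(r) model with
        (v, c) = (1.0, 0.5) are inverted to AU within 0.02."""
        rng = np.random.default_rng(20)
        v_true, c_true, B = 1.0, 0.5, 10_000
        scales = np.array([0.5 + 0.1 * i for i in range(10)])
        p = norm.cdf(-(v_true * np.sqrt(scales) + c_true / np.sqrt(scales)))
        counts = rng.binomial(B, p)
        res = au_pvalues(self._result(counts, list(scales), B))
        expected_au = 1 - norm.cdf(v_true - c_true)
        assert res.au_p[0] == pytest.approx(expected_au, abs=0.02)
        se = 3 / np.sqrt(B)  # generous 3-sigma-scale band for (v, c)
        assert abs(res.v[0] - v_true) < 30 * se
        assert abs(res.c[0] - c_true) < 30 * se

    def test_saturated_edges(self):
        scales = [0.5 + 0.1 * i for i in range(10)]
        B = 1000
        res = au_pvalues(self._result([B] * 10, scales, B))
        assert res.au_p[0] == 1.0 and res.flags[0] == "saturated"
        res = au_pvalues(self._result([0] * 10, scales, B))
        assert res.au_p[0] == 0.0

    def test_calibration_under_no_structure(self):
        """On iid Bernoulli rows (no clusters), few edges reach au < 0.05."""
        low, total = 0, 0
        for seed in range(20):
            rng = np.random.default_rng(100 + seed)
            data = (rng.random((30, 6)) < 0.3).astype(np.uint8)
            m = ScoringMatrix([f"r{i}" for i in range(30)], list("abcdef"), data)
            boot = multiscale_bootstrap(m, B=100, seed=seed)
            res = au_pvalues(boot)
            inner = res.au_p[:-1]  # root edge is trivially present
            low += int((inner < 0.05).sum())
            total += len(inner)
        assert low / total <= 0.10


class TestPca:
    def test_variance_fractions_sum_to_one(self):
        rng = np.random.default_rng(21)
        data = (rng.random((25, 8)) < 0.4).astype(np.uint8)
        m = ScoringMatrix([f"r{i}" for i in range(25)], [f"s{i}" for i in range(8)], data)
        res = pca(m)
        assert res.variance_fraction.sum() == pytest.approx(1.0)

    def test_planted_groups_separate_on_pc1(self):
        rng = np.random.default_rng(22)
        m = planted_matrix(rng, flip=0.02)
        res = pca(m)
        left = res.scores[:4, 0]
        right = res.scores[4:, 0]
        assert (left > 0).all() != (right > 0).all()  # opposite sides
        assert min(abs(left).min(), abs(right).min()) > 0

    def test_duplicate_samples_get_identical_scores(self):
        rng = np.random.default_rng(23)
        data = (rng.random((20, 4)) < 0.4).astype(np.uint8)
        doubled = np.hstack([data, data])
        m = ScoringMatrix([f"r{i}" for i in range(20)],
                          [f"s{i}" for i in range(8)], doubled)
        res = pca(m)
        assert np.allclose(res.scores[:4], res.scores[4:])

    def test_variance_invariant_to_sample_order(self):
        rng = np.random.default_rng(24)
        data = (rng.random((20, 6)) < 0.4).astype(np.uint8)
        m1 = ScoringMatrix([f"r{i}" for i in range(20)], list("abcdef"), data)
        perm = rng.permutation(6)
        m2 = ScoringMatrix(m1.cnvr_ids, [m1.samples[i] for i in perm], data[:, perm])
        assert np.allclose(pca(m1).variance_fraction, pca(m2).variance_fraction)

    def test_too_small_rejected(self):
        m = ScoringMatrix(["r1"], ["a", "b"], np.ones((1, 2), dtype=np.uint8))
        with pytest.raises(ContractError):
            pca(m)
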