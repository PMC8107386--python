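import numpy as np
import pytest
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from agnep import (
    ClusterPartition,
    DistanceMatrix,
    PhenotypeMatrix,
    agnes,
    phenotype_distance_matrix,
    select_k,
    silhouette,
)


def random_distance_matrix(rng, d):
    pts = rng.standard_normal((d, 3))
    D = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
    return DistanceMatrix(D, [f"p{i}" for i in range(d)])


def partitions_equal(a, b):
    """Same set partition regardless of labelling."""
    return {frozenset(np.flatnonzero(a == lab)) for lab in np.unique(a)} == {
        frozenset(np.flatnonzero(b == lab)) for lab in np.unique(b)
    }


def brute_force_silhouette(D, assignment, singleton_zero=True):
    """Straight transliteration of the silhouette definition."""
    d = len(assignment)
    s = np.zeros(d)
    for i in range(d):
        own = [j for j in range(d) if assignment[j] == assignment[i] and j != i]
        a = np.mean([D[i, j] for j in own]) if own else 0.0
        b = min(
            np.mean([D[i, j] for j in range(d) if assignment[j] == lab])
            for lab in np.unique(assignment)
            if lab != assignment[i]
        )
        if max(a, b) == 0:
            s[i] = 0.0
        elif not own and singleton_zero:
            s[i] = 0.0
        else:
            s[i] = (b - a) / max(a, b)
    return s


class TestDistanceMatrix:
    def test_identical_rows_zero(self):
        Y = PhenotypeMatrix(
            np.array([[1.0, 2, 3], [1.0, 2, 3]]), ["a", "b"], ["i1", "i2", "i3"]
        )
        D = phenotype_distance_matrix(Y, standardize=False)
        assert D.values[0, 1] == 0

    def test_hand_value_unstandardized(self):
        Y = PhenotypeMatrix(
            np.array([[0.0, 0, 0], [1.0, 2, 2]]), ["a", "b"], ["i", "j", "k"]
        )
        D = phenotype_distance_matrix(Y, standardize=False)
        assert D.values[0, 1] == pytest.approx(3.0)

    def test_matches_brute_force(self, toy_phenotypes):
        D = phenotype_distance_matrix(toy_phenotypes, standardize=False)
        vals = toy_phenotypes.values
        for i in range(6):
            for j in range(6):
                expect = np.sqrt(np.sum((vals[i] - vals[j]) ** 2))
                assert D.values[i, j] == pytest.approx(expect, abs=1e-10)
        assert np.allclose(D.values, D.values.T)
        assert np.all(np.diag(D.values) == 0)

    def test_standardized_rows_used_by_default(self, toy_phenotypes):
        D = phenotype_distance_matrix(toy_phenotypes)
        vals = toy_phenotypes.values
        z = (vals - vals.mean(1, keepdims=True)) / vals.std(1, keepdims=True)
        expect = np.sqrt(np.sum((z[0] - z[1]) ** 2))
        assert D.values[0, 1] == pytest.approx(expect, abs=1e-10)

    def test_missing_rejected_with_name(self):
        vals = np.ones((2, 3))
        vals[1, 2] = np.nan
        Y = PhenotypeMatrix(vals + np.arange(3), ["a", "bad"], ["i", "j", "k"])
        with pytest.raises(ValueError, match="bad"):
            phenotype_distance_matrix(Y)


class TestAgnes:
    def test_two_obvious_clusters(self):
        pos = np.array([0.0, 0.1, 10.0, 10.1])
        D = DistanceMatrix(
            np.abs(pos[:, None] - pos[None, :]), ["a", "b", "c", "d"]
        )
        part = agnes(D, 2)
        assert partitions_equal(part.assignment, np.array([1, 1, 2, 2]))

    def test_k_equals_d(self, rng):
        D = random_distance_matrix(rng, 5)
        part = agnes(D, 5)
        assert part.merge_history == []
        assert len(np.unique(part.assignment)) == 5

    def test_merge_distances_nondecreasing(self, rng):
        D = random_distance_matrix(rng, 10)
        part = agnes(D, 1)
        dists = [m[2] for m in part.merge_history]
        assert dists == sorted(dists)

    @pytest.mark.parametrize("d", [4, 7, 12])
    def test_matches_scipy_single_linkage(self, rng, d):
        for _ in range(20):
            D = random_distance_matrix(rng, d)
            Z = linkage(squareform(D.values, checks=False), method="single")
            for K in range(1, d + 1):
                ours = agnes(D, K)
                ref = fcluster(Z, t=K, criterion="maxclust")
                assert partitions_equal(ours.assignment, ref)

    def test_nesting_property(self, rng):
        D = random_distance_matrix(rng, 9)
        for K in range(2, 9):
            coarse = agnes(D, K - 1).assignment
            fine = agnes(D, K).assignment
            fine_sets = {
                frozenset(np.flatnonzero(fine == lab)) for lab in np.unique(fine)
            }
            coarse_sets = {
                frozenset(np.flatnonzero(coarse == lab))
                for lab in np.unique(coarse)
            }
            merged = coarse_sets - fine_sets
            split = fine_sets - coarse_sets
            assert len(merged) == 1 and len(split) == 2
            assert set().union(*split) == set(next(iter(merged)))

    def test_k_out_of_range(self, rng):
        D = random_distance_matrix(rng, 4)
        with pytest.raises(ValueError, match="K"):
            agnes(D, 0)
        with pytest.raises(ValueError, match="K"):
            agnes(D, 5)

    def test_tie_break_deterministic(self):
        # four equidistant points: ties resolved lexicographically
        D = DistanceMatrix(np.ones((4, 4)) - np.eye(4), list("abcd"))
        part = agnes(D, 3)
        assert part.merge_history[0][:2] == (0, 1)


class TestSilhouette:
    def test_perfect_separation(self):
        D = np.ones((4, 4)) - np.eye(4)
        D[0, 1] = D[1, 0] = 0
        D[2, 3] = D[3, 2] = 0
        res = silhouette(
            DistanceMatrix(D, list("abcd")),
            ClusterPartition(np.array([1, 1, 2, 2]), 2, [(0, 1, 0.0), (2, 3, 0.0)]),
        )
        assert np.allclose(res.per_sample, 1.0)
        assert res.mean_s == pytest.approx(1.0)

    def test_singleton_paper_convention(self):
        D = np.array([[0, 1.0, 5], [1, 0, 5], [5, 5, 0]])
        part = ClusterPartition(np.array([1, 1, 2]), 2, [(0, 1, 1.0)])
        dm = DistanceMatrix(D, list("abc"))
        literal = silhouette(dm, part, singleton_zero=False)
        assert literal.a_values[2] == 0
        assert literal.per_sample[2] == pytest.approx(1.0)
        common = silhouette(dm, part)  # default Rousseeuw convention
        assert common.per_sample[2] == 0.0

    def test_matches_brute_force(self, rng):
        for _ in range(10):
            D = random_distance_matrix(rng, 8)
            assignment = rng.integers(1, 4, size=8)
            while len(np.unique(assignment)) < 3:
                assignment = rng.integers(1, 4, size=8)
            part = ClusterPartition(
                _relabel(assignment), int(len(np.unique(assignment))),
                [(0, 0, 0.0)] * (8 - len(np.unique(assignment))),
            )
            res = silhouette(D, part)
            expect = brute_force_silhouette(D.values, part.assignment)
            assert np.allclose(res.per_sample, expect, atol=1e-12)
            assert res.mean_s == pytest.approx(expect.mean(), abs=1e-12)

    def test_k1_rejected(self, rng):
        D = random_distance_matrix(rng, 4)
        part = ClusterPartition(np.ones(4, dtype=int), 1, [(0, 0, 0.0)] * 3)
        with pytest.raises(ValueError, match="K >= 2"):
            silhouette(D, part)

    def test_all_zero_distances_give_zero(self):
        D = DistanceMatrix(np.zeros((4, 4)), list("abcd"))
        part = ClusterPartition(np.array([1, 1, 2, 2]), 2, [(0, 1, 0.0), (2, 3, 0.0)])
        res = silhouette(D, part)
        assert np.all(res.per_sample == 0)

    def test_bounds(self, rng):
        D = random_distance_matrix(rng, 10)
        part = agnes(D, 3)
        res = silhouette(D, part)
        assert np.all(res.per_sample >= -1) and np.all(res.per_sample <= 1)


def _relabel(assignment):
    order = {lab: k + 1 for k, lab in enumerate(sorted(set(assignment)))}
    return np.array([order[lab] for lab in assignment])


class TestSelectK:
    def test_two_blocks(self, rng):
        pos = np.concatenate([rng.normal(0, 0.1, 5), rng.normal(10, 0.1, 5)])
        D = DistanceMatrix(
            np.abs(pos[:, None] - pos[None, :]), [f"p{i}" for i in range(10)]
        )
        K, part, s_by_k = select_k(D)
        assert K == 2
        # exhaustive check: K=2 really has the max brute-force silhouette
        best = max(
            s_by_k, key=lambda k: brute_force_silhouette(
                D.values, agnes(D, k).assignment
            ).mean(),
        )
        assert best == 2

    def test_default_bounds(self, rng):
        D = random_distance_matrix(rng, 6)
        _, _, s_by_k = select_k(D)
        assert sorted(s_by_k) == [2, 3, 4, 5]

    def test_tie_goes_to_smaller_k(self):
        # symmetric configuration engineered to tie; smaller K must win
        pos = np.array([0.0, 1.0, 10.0, 11.0, 20.0, 21.0])
        D = DistanceMatrix(
            np.abs(pos[:, None] - pos[None, :]), [f"p{i}" for i in range(6)]
        )
        K, part, s_by_k = select_k(D)
        ties = [k for k, v in s_by_k.items() if v == max(s_by_k.values())]
        assert K == min(ties)

    def test_returned_mean_consistent(self, rng):
        D = random_distance_matrix(rng, 8)
        K, part, s_by_k = select_k(D)
        assert s_by_k[K] == pytest.approx(silhouette(D, part).mean_s, abs=1e-12)

    def test_small_d_rejected(self, rng):
        D = random_distance_matrix(rng, 2)
        with pytest.raises(ValueError):
            select_k(D)

    def test_degenerate_all_zero_refused(self):
        D = DistanceMatrix(np.zeros((4, 4)), list("abcd"))
        with pytest.warns(UserWarning):
            with pytest.raises(ValueError, match="identical"):
                select_k(D)

    def test_simI_recovery(self):
        from agnep import make_design, simulate_genotypes, simulate_phenotypes

        hits = 0
        for seed in range(8):
            design = make_design(
                "simI", 10, seed=seed, n_individuals=1000, n_variants=50
            )
            geno = simulate_genotypes(1000, 50, design.maf_range, seed)
            pheno, _ = simulate_phenotypes(geno, design, seed + 100)
            D = phenotype_distance_matrix(pheno)
            K, part, _ = select_k(D)
            found = {
                frozenset(np.flatnonzero(part.assignment == k))
                for k in range(1, K + 1)
            }
            truth = {frozenset(g) for g in design.groups}
            hits += K == 5 and found == truth
        assert hits >= 7
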