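"""Chromosome trees, clustering-information distances, permutation test."""

import itertools

import numpy as np
import pytest

from treemosaic import (
    chromosome_tree,
    clustering_info_distance,
    code_alleles,
    permutation_test,
    plain_rf,
    scenarios,
    simulate_frequencies,
)
from treemosaic.containers import N
from treemosaic.treedist import EstimationError, TreeTopology, _entropy, _mutual_info
from treemosaic._nj import splits as parent_splits


def topology_from_parents(parents):
    leaves = frozenset(
        n for n in parents if not any(p == n for p in parents.values())
    )
    return TreeTopology(leaves=leaves, splits=parent_splits(parents))


def random_topology(labels, rng):
    """Random binary tree built by sequential attachment."""
    parents = {"root": None, labels[0]: "root", labels[1]: "root"}
    for i, lab in enumerate(labels[2:]):
        edges = [n for n, p in parents.items() if p is not None]
        target = edges[rng.integers(len(edges))]
        new = f"i{i}"
        parents[new] = parents[target]
        parents[target] = new
        parents[lab] = new
    return topology_from_parents(parents)


def brute_force_cid(t1, t2):
    """Exhaustive search over all one-to-one split matchings."""
    leaves = t1.leaves
    n = len(leaves)
    s1, s2 = list(t1.splits), list(t2.splits)
    h = sum(_entropy(len(s), n) for s in s1) + sum(_entropy(len(s), n) for s in s2)
    if not s1 or not s2:
        return h
    small, big = (s1, s2) if len(s1) <= len(s2) else (s2, s1)
    best = 0.0
    for perm in itertools.permutations(big, len(small)):
        best = max(best, sum(_mutual_info(a, b, leaves) for a, b in zip(small, perm)))
    return h - 2 * best


class TestClusteringInfoDistance:
    def test_identical_trees_zero(self, coded_rng):
        for _ in range(5):
            t = random_topology(list("ABCDEFG"), coded_rng)
            assert clustering_info_distance(t, t) == 0.0

    def test_symmetry(self, coded_rng):
        for _ in range(10):
            t1 = random_topology(list("ABCDEF"), coded_rng)
            t2 = random_topology(list("ABCDEF"), coded_rng)
            assert clustering_info_distance(t1, t2) == pytest.approx(
                clustering_info_distance(t2, t1)
            )

    def test_matches_exhaustive_matching_oracle_on_six_leaves(self, coded_rng):
        for _ in range(30):
            t1 = random_topology(list("ABCDEF"), coded_rng)
            t2 = random_topology(list("ABCDEF"), coded_rng)
            assert clustering_info_distance(t1, t2) == pytest.approx(
                brute_force_cid(t1, t2), abs=1e-12
            )

    def test_zero_iff_same_splits(self, coded_rng):
        for _ in range(20):
            t1 = random_topology(list("ABCDEFG"), coded_rng)
            t2 = random_topology(list("ABCDEFG"), coded_rng)
            d = clustering_info_distance(t1, t2)
            if t1.splits == t2.splits:
                assert d == 0.0
            else:
                assert d > 0.0
            assert (d == 0.0) == (plain_rf(t1, t2) == 0)

    def test_leaf_set_mismatch_rejected(self, coded_rng):
        t1 = random_topology(list("ABCDE"), coded_rng)
        t2 = random_topology(list("ABCDF"), coded_rng)
        with pytest.raises(EstimationError):
            clustering_info_distance(t1, t2)


class TestPlainRf:
    def test_identical_zero(self, coded_rng):
        t = random_topology(list("ABCDEF"), coded_rng)
        assert plain_rf(t, t) == 0

    def test_four_taxon_nni_distance_two(self):
        t1 = topology_from_parents(
            {"root": None, "x": "root", "A": "x", "B": "x", "y": "root", "C": "y", "D": "y"}
        )
        t2 = topology_from_parents(
            {"root": None, "x": "root", "A": "x", "C": "x", "y": "root", "B": "y", "D": "y"}
        )
        assert plain_rf(t1, t2) == 2


class TestChromosomeTree:
    def test_recovers_simulated_topology(self, six_pop_tree, tree_frequencies):
        coded = code_alleles(tree_frequencies)
        t = chromosome_tree(coded, tree_frequencies.populations, "OG")
        assert t.splits == parent_splits(dict(six_pop_tree.parents))

    def test_duplicated_population_columns_are_siblings(self, tree_frequencies):
        coded = code_alleles(tree_frequencies)
        coded = np.vstack([coded, coded[1]])
        pops = tree_frequencies.populations + ["Bcopy"]
        t = chromosome_tree(coded, pops, "OG")
        assert frozenset({pops[1], "Bcopy"}) in t.splits

    def test_invariant_to_snp_order(self, tree_frequencies):
        coded = code_alleles(tree_frequencies)
        rng = np.random.default_rng(0)
        perm = rng.permutation(coded.shape[1])
        t1 = chromosome_tree(coded, tree_frequencies.populations, "OG")
        t2 = chromosome_tree(coded[:, perm], tree_frequencies.populations, "OG")
        assert t1.splits == t2.splits

    def test_snp_floor_enforced(self, tree_frequencies):
        coded = code_alleles(tree_frequencies)[:, :50]
        with pytest.raises(EstimationError):
            chromosome_tree(coded, tree_frequencies.populations, "OG", min_snps=100)


class TestPermutationTest:
    def _coded_genome(self, graphs, snps_per_chrom, seed):
        parts, labels = [], []
        for i, g in enumerate(graphs):
            fm = simulate_frequencies(g, snps_per_chrom, scenarios.ROOT_CODED,
                                      seed=seed + i)
            parts.append(code_alleles(fm))
            labels += [f"chr{i}"] * snps_per_chrom
            pops = fm.populations
        return np.hstack(parts), pops, np.array(labels)

    def test_heterogeneous_genome_detected(self):
        t1, t2 = scenarios.six_pop_tree(), scenarios.six_pop_alternative()
        coded, pops, labels = self._coded_genome([t1] * 4 + [t2], 2000, seed=100)
        res = permutation_test(coded, pops, labels, "OG", n_permutations=50,
                               seed=0, min_snps=100)
        assert res.observed > res.null_means.max()
        assert res.p_value == pytest.approx(1 / 51)

    def test_p_value_never_zero_and_matrix_symmetric(self):
        t1 = scenarios.six_pop_tree()
        coded, pops, labels = self._coded_genome([t1] * 3, 1000, seed=200)
        res = permutation_test(coded, pops, labels, "OG", n_permutations=20,
                               seed=1, min_snps=100)
        assert res.p_value >= 1 / 21
        assert np.allclose(res.matrix, res.matrix.T)
        assert np.allclose(np.diag(res.matrix), 0.0)

    def test_needs_two_chromosomes(self):
        t1 = scenarios.six_pop_tree()
        coded, pops, labels = self._coded_genome([t1], 1000, seed=300)
        with pytest.raises(EstimationError):
            permutation_test(coded, pops, labels, "OG")

    def test_power_increases_with_drift(self):
        """Detection probability rises monotonically with the drift separating
        the two chromosome-class histories."""
        hits = []
        for drift in (0.05, 0.15, 0.3):
            t1 = scenarios.six_pop_tree(drift)
            t2 = scenarios.six_pop_alternative(drift)
            det = 0
            n_rep = 8
            for rep in range(n_rep):
                coded, pops, labels = self._coded_genome(
                    [t1] * 4 + [t2], 1500, seed=1000 * rep + int(drift * 100)
                )
                res = permutation_test(coded, pops, labels, "OG",
                                       n_permutations=19, seed=rep, min_snps=30)
                det += res.p_value <= 0.05
            hits.append(det / n_rep)
        assert hits[0] <= hits[2] and hits[1] <= hits[2]
        assert hits[2] >= 0.8
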