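"""Frequency estimation, block covariance, PCA, allele coding."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from treemosaic import (
    block_covariance,
    code_alleles,
    estimate_frequencies,
    pca_scores,
    scenarios,
    simulate_frequencies,
    simulate_poolseq,
)
from treemosaic.containers import ALT, N, REF, AlleleCountMatrix, FrequencyMatrix, snp_table
from treemosaic.freqcov import EstimationError, _block_slices
from treemosaic.graphs import PopulationGraph


def fm_from(freq, chrom=None):
    freq = np.asarray(freq, dtype=float)
    n_pops, n_snps = freq.shape
    chrom = chrom if chrom is not None else np.full(n_snps, "chr1")
    return FrequencyMatrix(
        [f"p{i}" for i in range(n_pops)], snp_table(chrom, np.arange(1, n_snps + 1)), freq
    )


class TestEstimateFrequencies:
    def test_simple_ratio(self):
        acm = AlleleCountMatrix(
            ["a"], snp_table(["chr1"], [1]), np.array([[3]]), np.array([[7]])
        )
        assert estimate_frequencies(acm).freq[0, 0] == pytest.approx(0.7)

    def test_zero_depth_missing(self):
        acm = AlleleCountMatrix(
            ["a"], snp_table(["chr1"], [1]), np.array([[0]]), np.array([[0]])
        )
        assert np.isnan(estimate_frequencies(acm, min_depth=1).freq[0, 0])

    def test_min_depth_masks_shallow_sites(self):
        acm = AlleleCountMatrix(
            ["a"], snp_table(["chr1", "chr1"], [1, 2]),
            np.array([[2, 10]]), np.array([[1, 10]]),
        )
        f = estimate_frequencies(acm, min_depth=5).freq
        assert np.isnan(f[0, 0]) and f[0, 1] == pytest.approx(0.5)

    def test_poolseq_estimates_unbiased(self):
        g = PopulationGraph({"root": None, "A": "root"}, {"A": 0.0})
        fm = simulate_frequencies(g, 10**4, 0.25, seed=0)
        counts = simulate_poolseq(fm, pool_size=24, depth=100, seed=1)
        est = estimate_frequencies(counts)
        assert abs(np.nanmean(est.freq) - 0.25) < 0.01


class TestBlockCovariance:
    def test_duplicated_population_shares_variance(self):
        rng = np.random.default_rng(0)
        row = rng.uniform(0.2, 0.8, 400)
        other = rng.uniform(0.2, 0.8, 400)
        cov = block_covariance(fm_from([row, row, other]), block_size=100)
        assert cov.matrix[0, 1] == pytest.approx(cov.matrix[0, 0], abs=1e-12)
        assert cov.matrix[0, 1] == pytest.approx(cov.matrix[1, 1], abs=1e-12)

    def test_constant_frequencies_zero_matrix(self):
        cov = block_covariance(fm_from(np.full((3, 300), 0.5)), block_size=100)
        assert np.allclose(cov.matrix, 0.0)

    def test_point_estimate_equals_full_data_covariance(self):
        # with equal-sized homogeneous blocks the mean of block covariances is
        # the full-data covariance
        rng = np.random.default_rng(1)
        f = rng.uniform(0.1, 0.9, (4, 1000))
        fm = fm_from(f)
        cov = block_covariance(fm, block_size=100, normalize="none")
        mean = f.mean(axis=0)
        x = f - mean
        full = x @ x.T / f.shape[1]
        assert np.allclose(cov.matrix, full, atol=1e-8)

    def test_se_shrinks_with_block_count(self):
        g = scenarios.five_pop_tree(0.05)
        fm_small = simulate_frequencies(g, 5_000, ("uniform", 0.2, 0.8), seed=2)
        fm_big = simulate_frequencies(g, 45_000, ("uniform", 0.2, 0.8), seed=3)
        se_small = block_covariance(fm_small, 100).se.mean()
        se_big = block_covariance(fm_big, 100).se.mean()
        # 9x the blocks: SE should drop by about 3x
        assert se_big < se_small / 2.0

    def test_star_tree_off_diagonals_near_zero(self):
        g = PopulationGraph(
            {"root": None, **{p: "root" for p in "ABCDE"}},
            {p: 0.05 for p in "ABCDE"},
        )
        fm = simulate_frequencies(g, 50_000, ("uniform", 0.35, 0.65), seed=4)
        cov = block_covariance(fm, 100, normalize="none")
        # centered model: off-diagonals are -mean(c)/n not 0; compare to model
        from treemosaic import expected_covariance, root_heterozygosity

        pops, w = expected_covariance(g, centered=True, het_decay=True)
        pred = root_heterozygosity(("uniform", 0.35, 0.65)) * w
        off = ~np.eye(5, dtype=bool)
        assert np.all(np.abs(cov.matrix - pred)[off] < 3 * cov.se[off])

    def test_partial_trailing_block_dropped(self):
        chrom = np.array(["chr1"] * 250 + ["chr2"] * 149)
        slices = _block_slices(snp_table(chrom, np.arange(1, 400))[["chrom"]].assign(pos=1), 100)
        assert len(slices) == 3  # 2 from chr1, 1 from chr2

    def test_requires_two_blocks(self):
        with pytest.raises(EstimationError):
            block_covariance(fm_from(np.random.default_rng(0).uniform(size=(3, 150))), 100)

    def test_missing_entries_pairwise_complete(self):
        rng = np.random.default_rng(5)
        f = rng.uniform(0.2, 0.8, (3, 600))
        f_missing = f.copy()
        f_missing[2, ::7] = np.nan
        c_full = block_covariance(fm_from(f), 100)
        c_miss = block_covariance(fm_from(f_missing), 100)
        # population pair (0,1) unaffected by missingness in population 2
        # (centering changes slightly; tolerance reflects that)
        assert c_miss.matrix[0, 1] == pytest.approx(c_full.matrix[0, 1], abs=0.02)
        assert np.isfinite(c_miss.matrix).all()


class TestPCA:
    def test_variance_fractions_sum_to_one(self, tree_frequencies):
        _, _, frac = pca_scores(tree_frequencies)
        assert frac.sum() == pytest.approx(1.0)

    def test_duplicated_populations_identical_scores(self):
        rng = np.random.default_rng(6)
        f = rng.uniform(0.1, 0.9, (3, 500))
        f = np.vstack([f, f[1]])
        _, scores, _ = pca_scores(fm_from(f))
        assert np.allclose(scores[1], scores[3], atol=1e-10)

    def test_reconstruction_at_full_rank(self):
        rng = np.random.default_rng(7)
        f = rng.uniform(0.1, 0.9, (5, 200))
        fm = fm_from(f)
        keep, scores, frac = pca_scores(fm)
        x = f - f.mean(axis=0)
        u, s, vt = np.linalg.svd(x, full_matrices=False)
        assert np.allclose(scores @ vt, x, atol=1e-8)

    def test_two_cluster_simulation_separated_on_pc1(self):
        g = scenarios.six_pop_tree(0.1)
        fm = simulate_frequencies(g, 10_000, ("uniform", 0.2, 0.8), seed=8)
        keep, scores, _ = pca_scores(fm, exclude={"OG"})
        pc1 = dict(zip(keep, scores[:, 0]))
        side_ab = {np.sign(pc1[p]) for p in ("A", "B")}
        side_cde = {np.sign(pc1[p]) for p in ("C", "D", "E")}
        assert len(side_ab) == 1 and len(side_cde) == 1 and side_ab != side_cde

    def test_exclusion_leaves_too_few_is_error(self, tree_frequencies):
        with pytest.raises(EstimationError):
            pca_scores(tree_frequencies, exclude=set(tree_frequencies.populations[:-1]))


class TestCodeAlleles:
    @pytest.mark.parametrize(
        "freq,expected", [(0.97, ALT), (0.95, ALT), (0.5, N), (0.03, REF), (np.nan, N)]
    )
    def test_coding_rule(self, freq, expected):
        coded = code_alleles(fm_from([[freq]]), threshold=0.95)
        assert coded[0, 0] == expected

    @given(st.floats(min_value=0.0, max_value=1.0))
    @settings(max_examples=50, deadline=None)
    def test_codes_partition_unit_interval(self, f):
        coded = code_alleles(fm_from([[f]]), threshold=0.95)[0, 0]
        if f >= 0.95:
            assert coded == ALT
        elif f <= 0.05:
            assert coded == REF
        else:
            assert coded == N

    def test_threshold_must_exceed_half(self):
        with pytest.raises(ValueError):
            code_alleles(fm_from([[0.5]]), threshold=0.4)
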