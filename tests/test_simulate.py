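"""Synthetic-data generator: drift, pool-seq sampling, genome layout, traits."""

import numpy as np
import pytest

from treemosaic import (
    block_covariance,
    estimate_frequencies,
    expected_covariance,
    scenarios,
    simulate_frequencies,
    simulate_genome_dataset,
    simulate_poolseq,
    simulate_trait_data,
)
from treemosaic.containers import snp_table
from treemosaic.graphs import PopulationGraph
from treemosaic.simulate import ConfigurationError, SimulationConfig, root_heterozygosity


def single_branch(c):
    return PopulationGraph({"root": None, "A": "root"}, {"A": c})


class TestSimulateFrequencies:
    def test_zero_drift_copies_parent(self):
        fm = simulate_frequencies(single_branch(0.0), 1000, 0.37, seed=0)
        assert np.allclose(fm.freq, 0.37)

    def test_drift_variance_matches_c_p_one_minus_p(self):
        # c = 0.1 from p = 0.5: Var(child - parent) = 0.025
        fm = simulate_frequencies(single_branch(0.1), 10**5, 0.5, seed=1)
        v = np.var(fm.freq[0] - 0.5)
        assert abs(v - 0.025) < 0.05 * 0.025

    def test_star_leaves_uncorrelated(self):
        g = PopulationGraph(
            {"root": None, "A": "root", "B": "root"}, {"A": 0.05, "B": 0.05}
        )
        fm = simulate_frequencies(g, 10**5, 0.5, seed=2)
        d = fm.freq - 0.5
        cross = np.mean(d[0] * d[1])
        # no shared branches: cross-covariance is zero up to Monte Carlo error
        assert abs(cross) < 3 * 0.05 * 0.25 / np.sqrt(10**5)

    def test_frequencies_stay_in_unit_interval(self):
        g = scenarios.six_pop_tree(0.8)
        fm = simulate_frequencies(g, 5000, ("beta", 0.3, 0.3), seed=3)
        assert fm.freq.min() >= 0.0 and fm.freq.max() <= 1.0

    def test_invalid_root_spec_is_configuration_error(self):
        with pytest.raises(ConfigurationError):
            simulate_frequencies(single_branch(0.1), 10, ("gamma", 1.0), seed=0)

    def test_reproducible_from_seed(self):
        a = simulate_frequencies(single_branch(0.1), 100, ("uniform", 0.1, 0.9), seed=5)
        b = simulate_frequencies(single_branch(0.1), 100, ("uniform", 0.1, 0.9), seed=5)
        assert np.array_equal(a.freq, b.freq)


class TestSimulatePoolseq:
    def test_fixed_frequency_gives_only_alt_reads(self):
        fm = simulate_frequencies(single_branch(0.0), 500, 1.0, seed=0)
        counts = simulate_poolseq(fm, pool_size=24, depth=30, seed=0)
        assert counts.ref_counts[~counts.missing].sum() == 0
        assert (counts.alt_counts[~counts.missing] > 0).any()

    def test_mean_alt_fraction_unbiased(self):
        fm = simulate_frequencies(single_branch(0.0), 10**5, 0.5, seed=0)
        counts = simulate_poolseq(fm, pool_size=24, depth=50, seed=1)
        depth = counts.depth
        frac = counts.alt_counts[depth > 0] / depth[depth > 0]
        assert abs(frac.mean() - 0.5) < 0.005

    def test_finite_pool_inflates_variance_over_single_stage_binomial(self):
        # oracle: single-stage Binomial(D, p) sampling at the same depths
        fm = simulate_frequencies(single_branch(0.0), 10**5, 0.5, seed=0)
        counts = simulate_poolseq(fm, pool_size=5, depth=50, seed=2)
        depth = counts.depth
        frac = counts.alt_counts[depth > 0] / depth[depth > 0]
        rng = np.random.default_rng(3)
        d = depth[depth > 0]
        single = rng.binomial(d, 0.5) / d
        assert np.var(frac) > np.var(single) * 1.2

    def test_zero_depth_recorded_missing(self):
        fm = simulate_frequencies(single_branch(0.0), 2000, 0.5, seed=0)
        counts = simulate_poolseq(fm, pool_size=24, depth=1.0, seed=4)
        assert counts.missing.any()
        freqs = estimate_frequencies(counts)
        assert np.isnan(freqs.freq[counts.missing]).all()


class TestGenomeDataset:
    def _config(self, n_chrom=4, seed=0):
        g = scenarios.six_pop_tree()
        labels = [f"chr{i}" for i in range(1, n_chrom)] + ["chrZ"]
        return SimulationConfig(
            chromosome_sizes={c: 1_000_000 for c in labels},
            snps_per_chromosome={c: 500 for c in labels},
            graph_assignment={c: g for c in labels},
            seed=seed,
        )

    def test_metadata_has_all_chromosomes(self):
        counts, truth = simulate_genome_dataset(self._config())
        assert set(counts.snps["chrom"]) == {"chr1", "chr2", "chr3", "chrZ"}
        assert truth.frequencies.n_snps == 2000

    def test_positions_strictly_increasing_within_chromosome(self):
        counts, _ = simulate_genome_dataset(self._config())
        for c, grp in counts.snps.groupby("chrom"):
            assert (np.diff(grp["pos"]) > 0).all()

    def test_leafset_mismatch_rejected(self):
        g1 = scenarios.six_pop_tree()
        g2 = scenarios.five_pop_tree(0.1)
        with pytest.raises(ConfigurationError):
            SimulationConfig(
                chromosome_sizes={"a": 1000, "b": 1000},
                snps_per_chromosome={"a": 10, "b": 10},
                graph_assignment={"a": g1, "b": g2},
            )


class TestTraitData:
    MAP = snp_table(
        np.repeat(["chr1", "chr2"], 100), np.tile(np.arange(1, 101), 2)
    )

    def test_h2_zero_phenotype_independent_of_genotype(self):
        geno, pheno, beta, _ = simulate_trait_data(2000, self.MAP, 0, 0.0, seed=0)
        assert np.all(beta == 0)
        score = geno @ np.ones(geno.shape[1])
        assert abs(np.corrcoef(score, pheno)[0, 1]) < 0.05

    def test_causal_on_one_chromosome_concentrates_va(self):
        from treemosaic import partition_va

        geno, pheno, beta, freqs = simulate_trait_data(
            50, self.MAP, 10, 0.5, seed=1, causal_indices=np.arange(10)
        )
        part = partition_va(beta, freqs, self.MAP["chrom"].to_numpy())
        assert part.proportions[part.chromosomes.index("chr1")] == pytest.approx(1.0)

    def test_realized_heritability_near_target(self):
        geno, pheno, beta, _ = simulate_trait_data(500, self.MAP, 50, 0.6, seed=2)
        g = geno @ beta
        realized = np.var(g) / np.var(pheno)
        assert abs(realized - 0.6) < 0.1

    def test_h2_one_without_causals_rejected(self):
        with pytest.raises(ConfigurationError):
            simulate_trait_data(100, self.MAP, 0, 0.5, seed=0)


def test_study_genome_config_layout():
    cfg = scenarios.study_genome_config(seed=1)
    assert cfg.n_chromosomes == 23
    z = cfg.chromosome_sizes["chrZ"]
    assert z / sum(cfg.chromosome_sizes.values()) == pytest.approx(0.055, abs=0.001)
    assert not cfg.graph_assignment["chrZ"].migrations
    weights = [
        cfg.graph_assignment[f"chr{i}"].migrations[0].weight for i in range(1, 23)
    ]
    # migration weight declines with chromosome index (sizes decline)
    assert weights[0] == max(weights) and weights[-1] == min(weights)


def test_root_heterozygosity_closed_forms_match_monte_carlo():
    rng = np.random.default_rng(0)
    u = rng.uniform(0.2, 0.8, 10**6)
    assert abs(root_heterozygosity(("uniform", 0.2, 0.8)) - np.mean(u * (1 - u))) < 1e-3
    b = rng.beta(0.5, 0.5, 10**6)
    assert abs(root_heterozygosity(("beta", 0.5, 0.5)) - np.mean(b * (1 - b))) < 1e-3


def test_simulator_covariance_matches_model_within_block_se():
    """Central simulator/model consistency: the block-resampled covariance of
    simulated frequencies matches the graph's expected covariance (exact
    heterozygosity-decay form, centered, in absolute units) entry-wise."""
    g = scenarios.five_pop_tree(scenarios.DRIFT_MODEL_CHECK)
    fm = simulate_frequencies(g, 50_000, scenarios.ROOT_MODEL_CHECK, seed=11)
    cov = block_covariance(fm, block_size=100, normalize="none")
    pops, w = expected_covariance(g, centered=True, het_decay=True)
    idx = [pops.index(p) for p in cov.populations]
    pred = root_heterozygosity(scenarios.ROOT_MODEL_CHECK) * w[np.ix_(idx, idx)]
    iu = np.triu_indices(len(pops))
    z = (cov.matrix - pred)[iu] / cov.se[iu]
    # Sidak-adjusted two-sided bound at familywise alpha = 0.05 for 15 entries
    from scipy import stats

    bound = stats.norm.ppf(1 - 0.5 * (1 - 0.95 ** (1 / len(z))))
    assert np.abs(z).max() < bound
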