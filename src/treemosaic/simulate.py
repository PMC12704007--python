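"""Synthetic data with known ground truth.

Generates population allele frequencies under admixture graphs (optionally a
different graph per chromosome class, e.g. a clean tree for the Z and a
one-edge graph for autosomes), pool-seq read counts on top of them, and a
sparse polygenic trait for the variance-partitioning stage.

All randomness flows from a single integer seed through
``numpy.random.SeedSequence`` spawning, so a dataset is reproducible from its
seed alone.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import AlleleCountMatrix, FrequencyMatrix, snp_table
from .graphs import PopulationGraph


class ConfigurationError(ValueError):
    pass


#: default root allele-frequency distribution: ancestral SNP frequencies are
#: interior (ascertained polymorphic) rather than U-shaped
DEFAULT_ROOT_DIST: tuple = ("uniform", 0.05, 0.95)


def _draw_root(dist, n_snps: int, rng: np.random.Generator) -> np.ndarray:
    if np.isscalar(dist):
        p = float(dist)
        if not 0.0 <= p <= 1.0:
            raise ConfigurationError("constant root frequency outside [0,1]")
        return np.full(n_snps, p)
    try:
        name = dist[0]
        if name == "uniform":
            lo, hi = float(dist[1]), float(dist[2])
            if not (0.0 <= lo < hi <= 1.0):
                raise ConfigurationError("uniform bounds must satisfy 0<=lo<hi<=1")
            return rng.uniform(lo, hi, n_snps)
        if name == "beta":
            return rng.beta(float(dist[1]), float(dist[2]), n_snps)
    except (TypeError, IndexError) as exc:
        raise ConfigurationError(f"invalid root frequency spec: {dist!r}") from exc
    raise ConfigurationError(f"unknown root frequency distribution {dist!r}")


def root_heterozygosity(dist) -> float:
    """E[p0 (1 - p0)] under a root frequency spec (closed form)."""
    if np.isscalar(dist):
        p = float(dist)
        return p * (1.0 - p)
    if dist[0] == "uniform":
        lo, hi = float(dist[1]), float(dist[2])
        m = (lo + hi) / 2.0
        return m - (m * m + (hi - lo) ** 2 / 12.0)
    if dist[0] == "beta":
        a, b = float(dist[1]), float(dist[2])
        m = a / (a + b)
        ep2 = a * (a + 1) / ((a + b) * (a + b + 1))
        return m - ep2
    raise ConfigurationError(f"unknown root frequency distribution {dist!r}")


def simulate_frequencies(
    graph: PopulationGraph,
    n_snps: int,
    root_freq_dist=DEFAULT_ROOT_DIST,
    seed: int | np.random.Generator = 0,
) -> FrequencyMatrix:
    """Per-SNP population frequencies under Gaussian drift on ``graph``.

    Each branch adds zero-mean Gaussian noise with variance ``c * p(1-p)``
    (``p`` the parent's frequency), truncated to [0,1].  At a migration
    destination the frequency is the mixture ``w*f(source) +
    (1-w)*f(tree_parent)`` before the destination branch's drift applies.
    """
    if n_snps < 1:
        raise ConfigurationError("n_snps must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    p0 = _draw_root(root_freq_dist, n_snps, rng)
    freq: dict[str, np.ndarray] = {}
    for node in graph.topological_order():
        parent = graph.parents[node]
        if parent is None:
            freq[node] = p0
            continue
        mig = graph.migration_into(node)
        if mig is None:
            base = freq[parent]
        else:
            base = mig.weight * freq[mig.source] + (1.0 - mig.weight) * freq[parent]
        c = graph.drift.get(node, 0.0)
        if c > 0:
            sd = np.sqrt(c * base * (1.0 - base))
            f = base + rng.normal(0.0, 1.0, n_snps) * sd
            np.clip(f, 0.0, 1.0, out=f)
        else:
            f = base.copy()
        freq[node] = f
    pops = graph.leaves
    mat = np.vstack([freq[p] for p in pops])
    snps = snp_table(np.full(n_snps, "chr1"), np.arange(1, n_snps + 1))
    return FrequencyMatrix(pops, snps, mat)


def simulate_poolseq(
    freqs: FrequencyMatrix,
    pool_size: int,
    depth: float,
    seed: int | np.random.Generator = 0,
) -> AlleleCountMatrix:
    """Two-stage pool-seq read sampling.

    Per population and SNP: sampled allele count ``k ~ Binomial(2*pool_size, p)``
    (finite pool of diploids), read depth ``D ~ Poisson(depth)``, alternate
    reads ``~ Binomial(D, k / (2*pool_size))``.  ``D = 0`` is recorded as
    missing (zero ref and alt reads).
    """
    if pool_size < 1:
        raise ConfigurationError("pool_size must be >= 1")
    if depth <= 0:
        raise ConfigurationError("depth must be > 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    p = np.nan_to_num(freqs.freq, nan=0.0)
    n_chrom_copies = 2 * pool_size
    k = rng.binomial(n_chrom_copies, p)
    d = rng.poisson(depth, size=p.shape)
    alt = rng.binomial(d, k / n_chrom_copies)
    ref = d - alt
    missing = np.isnan(freqs.freq)
    alt[missing] = 0
    ref[missing] = 0
    return AlleleCountMatrix(freqs.populations, freqs.snps.copy(), ref, alt)


@dataclass
class SimulationConfig:
    """Layout of a synthetic multi-chromosome pooled dataset.

    ``graph_assignment`` maps each chromosome label to the PopulationGraph it
    is generated from; all graphs must share one leaf set.  Defaults emulate a
    female-heterogametic genome: 22 autosomes plus the Z chromosome.
    """

    chromosome_sizes: dict[str, int]
    snps_per_chromosome: dict[str, int]
    graph_assignment: dict[str, PopulationGraph]
    pool_depth: float = 60.0
    pool_size: int = 48
    root_freq_dist: tuple = DEFAULT_ROOT_DIST
    seed: int = 0

    def __post_init__(self) -> None:
        chroms = list(self.chromosome_sizes)
        if set(self.snps_per_chromosome) != set(chroms) or set(
            self.graph_assignment
        ) != set(chroms):
            raise ConfigurationError("chromosome tables must share one label set")
        if any(s <= 0 for s in self.chromosome_sizes.values()):
            raise ConfigurationError("chromosome sizes must be positive")
        if any(s <= 0 for s in self.snps_per_chromosome.values()):
            raise ConfigurationError("SNP counts must be positive")
        leafsets = {tuple(g.leaves) for g in self.graph_assignment.values()}
        if len(leafsets) != 1:
            raise ConfigurationError("all chromosome graphs must share one leaf set")

    @property
    def n_chromosomes(self) -> int:
        return len(self.chromosome_sizes)


@dataclass
class GenomeTruth:
    """Ground truth accompanying a simulated genome."""

    config: SimulationConfig
    graphs: dict[str, PopulationGraph]
    frequencies: FrequencyMatrix


def simulate_genome_dataset(
    config: SimulationConfig,
) -> tuple[AlleleCountMatrix, GenomeTruth]:
    """Concatenate per-chromosome simulations into one pooled dataset.

    SNP positions are uniform within each chromosome; chromosomes may carry
    different admixture graphs (e.g. the Z a migration-free tree, autosomes a
    one-edge graph).
    """
    ss = np.random.SeedSequence(config.seed)
    chroms = list(config.chromosome_sizes)
    child_seeds = ss.spawn(len(chroms) + 1)
    pops = next(iter(config.graph_assignment.values())).leaves
    freq_parts, snp_parts = [], []
    for chrom, child in zip(chroms, child_seeds[:-1]):
        rng = np.random.default_rng(child)
        n = config.snps_per_chromosome[chrom]
        fm = simulate_frequencies(
            config.graph_assignment[chrom], n, config.root_freq_dist, rng
        )
        size = config.chromosome_sizes[chrom]
        if n > size:
            raise ConfigurationError(f"{chrom}: more SNPs ({n}) than base pairs ({size})")
        if size <= 2_000_000:
            pos = np.sort(rng.choice(size, size=n, replace=False)) + 1
        else:  # large chromosomes: collision-free draw without a full permutation
            pos = np.unique(rng.integers(1, size + 1, int(n * 1.05) + 16))
            while len(pos) < n:
                pos = np.unique(np.concatenate([pos, rng.integers(1, size + 1, n)]))
            pos = np.sort(rng.choice(pos, size=n, replace=False))
        snp_parts.append(snp_table(np.full(n, chrom), pos))
        freq_parts.append(fm.freq)
    snps = pd.concat(snp_parts, ignore_index=True)
    freqs = FrequencyMatrix(pops, snps, np.hstack(freq_parts))
    counts = simulate_poolseq(
        freqs, config.pool_size, config.pool_depth, np.random.default_rng(child_seeds[-1])
    )
    return counts, GenomeTruth(config, dict(config.graph_assignment), freqs)


def simulate_trait_data(
    n_individuals: int,
    snp_map: pd.DataFrame,
    n_causal: int,
    h2: float,
    seed: int = 0,
    maf_range: tuple[float, float] = (0.05, 0.95),
    causal_indices=None,
):
    """Genotypes, a sparse polygenic phenotype, and the true SNP effects.

    Genotypes are 0/1/2 draws at Hardy-Weinberg proportions from per-SNP
    frequencies; ``n_causal`` SNPs (random, or ``causal_indices`` if given)
    get standard-normal effects; environmental noise is scaled so the
    realized genetic-variance fraction is ``h2`` in expectation.

    Returns ``(genotypes, phenotype, effects, freqs)``.
    """
    if not 0.0 <= h2 <= 1.0:
        raise ConfigurationError("h2 must lie in [0, 1]")
    p_snps = len(snp_map)
    if n_causal > p_snps:
        raise ConfigurationError("n_causal exceeds the number of SNPs")
    if h2 > 0 and n_causal == 0:
        raise ConfigurationError("h2 > 0 requires at least one causal SNP")
    rng = np.random.default_rng(seed)
    freqs = rng.uniform(*maf_range, p_snps)
    geno = rng.binomial(2, freqs, size=(n_individuals, p_snps)).astype(np.int8)
    beta = np.zeros(p_snps)
    if h2 > 0:
        if causal_indices is not None:
            causal = np.asarray(causal_indices)
            if len(causal) != n_causal:
                raise ConfigurationError("causal_indices length must equal n_causal")
        else:
            causal = rng.choice(p_snps, n_causal, replace=False)
        beta[causal] = rng.normal(0.0, 1.0, n_causal)
    g = geno @ beta
    var_g = float(np.var(g))
    if h2 in (0.0, 1.0) or var_g == 0.0:
        noise_sd = 1.0 if h2 == 0.0 else 0.0
    else:
        noise_sd = np.sqrt(var_g * (1.0 - h2) / h2)
    pheno = g + rng.normal(0.0, noise_sd, n_individuals)
    return geno, pheno, beta, freqs
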