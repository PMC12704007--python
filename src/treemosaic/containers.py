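"""In-memory containers shared across the pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: coded-allele values
REF: int = 0
ALT: int = 1
N: int = -1


def snp_table(chrom, pos, ref=None, alt=None) -> pd.DataFrame:
    """Build the SNP metadata table (chromosome, 1-based position)."""
    d = {"chrom": np.asarray(chrom), "pos": np.asarray(pos, dtype=np.int64)}
    d["ref"] = np.asarray(ref) if ref is not None else np.full(len(d["pos"]), "A")
    d["alt"] = np.asarray(alt) if alt is not None else np.full(len(d["pos"]), "T")
    return pd.DataFrame(d)


@dataclass
class FrequencyMatrix:
    """Alternate-allele frequencies: populations x SNPs, NaN = missing."""

    populations: list[str]
    snps: pd.DataFrame
    freq: np.ndarray

    def __post_init__(self) -> None:
        self.freq = np.asarray(self.freq, dtype=float)
        if self.freq.shape != (len(self.populations), len(self.snps)):
            raise ValueError("freq shape does not match populations x snps")
        with np.errstate(invalid="ignore"):
            if np.nanmin(self.freq, initial=0.0) < 0 or np.nanmax(self.freq, initial=1.0) > 1:
                raise ValueError("frequencies must lie in [0, 1]")

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    def subset_chrom(self, chrom: str) -> "FrequencyMatrix":
        m = (self.snps["chrom"] == chrom).to_numpy()
        return FrequencyMatrix(
            self.populations, self.snps.loc[m].reset_index(drop=True), self.freq[:, m]
        )


@dataclass
class AlleleCountMatrix:
    """Pooled read counts: populations x SNPs, (ref reads, alt reads).

    A site with zero total reads in a population is missing there.
    """

    populations: list[str]
    snps: pd.DataFrame
    ref_counts: np.ndarray
    alt_counts: np.ndarray

    def __post_init__(self) -> None:
        self.ref_counts = np.asarray(self.ref_counts, dtype=np.int64)
        self.alt_counts = np.asarray(self.alt_counts, dtype=np.int64)
        shape = (len(self.populations), len(self.snps))
        if self.ref_counts.shape != shape or self.alt_counts.shape != shape:
            raise ValueError("count shapes do not match populations x snps")
        if (self.ref_counts < 0).any() or (self.alt_counts < 0).any():
            raise ValueError("read counts must be non-negative")

    @property
    def depth(self) -> np.ndarray:
        return self.ref_counts + self.alt_counts

    @property
    def missing(self) -> np.ndarray:
        return self.depth == 0


@dataclass
class CovarianceEstimate:
    """Population allele-frequency covariance with block-resampling SEs."""

    populations: list[str]
    matrix: np.ndarray
    se: np.ndarray
    block_size: int
    n_blocks: int

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.se = np.asarray(self.se, dtype=float)
        if not np.allclose(self.matrix, self.matrix.T, atol=1e-10):
            raise ValueError("covariance matrix must be symmetric")
        if (self.se < 0).any():
            raise ValueError("standard errors must be non-negative")


@dataclass
class WindowScore:
    """Normalized topology support in one sliding window (1-based inclusive)."""

    chrom: str
    start: int
    end: int
    scores: tuple[float, float, float]
    n_informative: int


@dataclass
class VaPartition:
    """Additive genetic variance split across chromosomes."""

    chromosomes: list[str]
    va_by_chromosome: np.ndarray
    total_va: float
    proportions: np.ndarray
    z_fraction_of_genome: float | None = None

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": self.chromosomes,
                "va": self.va_by_chromosome,
                "proportion": self.proportions,
            }
        )


@dataclass
class DistanceResult:
    """Among-chromosome tree-heterogeneity permutation test."""

    chromosomes: list[str]
    matrix: np.ndarray
    observed: float
    null_means: np.ndarray
    p_value: float
    n_permutations: int
    seed: int
    redraws: int = 0


@dataclass
class RegressionResult:
    """Standardized Bayesian regression summary."""

    beta: float
    etpi: tuple[float, float]
    prob_negative: float
    r2: float
    n: int
    flagged: bool = False
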