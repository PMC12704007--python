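"""Pool allele frequencies, covariance with block-resampling SEs, PCA, and
the discrete allele coding used by the tree and quartet analyses."""

from __future__ import annotations

import logging

import numpy as np

from .containers import ALT, N, REF, AlleleCountMatrix, CovarianceEstimate, FrequencyMatrix

logger = logging.getLogger(__name__)


class EstimationError(ValueError):
    pass


def estimate_frequencies(counts: AlleleCountMatrix, min_depth: int = 1) -> FrequencyMatrix:
    """Alternate-allele frequency ``alt / (ref + alt)`` per population.

    Sites with fewer than ``min_depth`` reads in a population are missing
    there.  Rows missing in every population are retained (and logged).
    """
    if min_depth < 1:
        raise ValueError("min_depth must be >= 1")
    depth = counts.depth
    with np.errstate(divide="ignore", invalid="ignore"):
        freq = np.where(depth >= min_depth, counts.alt_counts / depth, np.nan)
    all_missing = int(np.isnan(freq).all(axis=0).sum())
    if all_missing:
        logger.info("%d SNPs missing in every population", all_missing)
    return FrequencyMatrix(counts.populations, counts.snps.copy(), freq)


def _block_slices(snps, block_size: int) -> list[slice]:
    """Consecutive complete blocks of SNPs within chromosomes; a trailing
    partial block on each chromosome is dropped."""
    out: list[slice] = []
    chrom = snps["chrom"].to_numpy()
    start = 0
    for i in range(1, len(chrom) + 1):
        if i == len(chrom) or chrom[i] != chrom[start]:
            n_full = (i - start) // block_size
            for b in range(n_full):
                out.append(slice(start + b * block_size, start + (b + 1) * block_size))
            start = i
    return out


def block_covariance(
    freqs: FrequencyMatrix,
    block_size: int = 100,
    normalize: str = "het",
) -> CovarianceEstimate:
    """Population allele-frequency covariance with block-resampling SEs.

    Per SNP, frequencies are centered by the across-population mean (removing
    ancestral-frequency variance).  With ``normalize="het"`` each SNP's
    centered cross-products are divided by the mean heterozygosity
    ``m(1-m)`` so the matrix is in drift units; ``normalize="none"`` leaves
    absolute frequency-covariance units.  The point estimate is the mean over
    blocks of ``block_size`` consecutive SNPs within chromosomes, the SE the
    standard error over blocks.  Missing entries are handled pairwise-complete.
    """
    if block_size < 1:
        raise ValueError("block_size must be >= 1")
    if normalize not in ("het", "none"):
        raise ValueError("normalize must be 'het' or 'none'")
    f = freqs.freq
    n_pops = len(freqs.populations)
    mean = np.nanmean(f, axis=0)
    x = f - mean
    if normalize == "het":
        het = mean * (1.0 - mean)
        with np.errstate(divide="ignore", invalid="ignore"):
            x = np.where(het > 0, x / np.sqrt(het), np.nan)
    mask = np.isfinite(x)
    xz = np.where(mask, x, 0.0)
    blocks = _block_slices(freqs.snps, block_size)
    if len(blocks) < 2:
        raise EstimationError("need at least 2 complete blocks of SNPs")
    mats = np.empty((len(blocks), n_pops, n_pops))
    for k, sl in enumerate(blocks):
        xb = xz[:, sl]
        mb = mask[:, sl].astype(float)
        s = xb @ xb.T
        n_pair = mb @ mb.T
        with np.errstate(divide="ignore", invalid="ignore"):
            mats[k] = np.where(n_pair > 0, s / n_pair, np.nan)
    point = np.nanmean(mats, axis=0)
    n_eff = np.isfinite(mats).sum(axis=0)
    se = np.nanstd(mats, axis=0, ddof=1) / np.sqrt(np.maximum(n_eff, 1))
    point = (point + point.T) / 2.0
    return CovarianceEstimate(list(freqs.populations), point, se, block_size, len(blocks))


def pca_scores(
    freqs: FrequencyMatrix, exclude: set[str] | None = None
) -> tuple[list[str], np.ndarray, np.ndarray]:
    """PCA of the centered (not standardized) population x SNP matrix.

    Missing entries are imputed by the SNP mean across populations (logged).
    Returns (populations, scores, variance fractions); scores rows follow the
    population order.
    """
    exclude = exclude or set()
    keep = [p for p in freqs.populations if p not in exclude]
    if len(keep) < 2:
        raise EstimationError("need at least 2 populations after exclusion")
    idx = [freqs.populations.index(p) for p in keep]
    f = freqs.freq[idx].copy()
    missing = ~np.isfinite(f)
    if missing.any():
        logger.info("imputing %d missing entries by SNP means", int(missing.sum()))
        col_mean = np.nanmean(f, axis=0)
        col_mean = np.where(np.isfinite(col_mean), col_mean, 0.0)
        f[missing] = np.broadcast_to(col_mean, f.shape)[missing]
    x = f - f.mean(axis=0)
    u, s, _ = np.linalg.svd(x, full_matrices=False)
    scores = u * s
    var = s**2
    total = var.sum()
    frac = var / total if total > 0 else np.zeros_like(var)
    return keep, scores, frac


def code_alleles(freqs: FrequencyMatrix, threshold: float = 0.95) -> np.ndarray:
    """Discrete coding of each population's allele at each SNP.

    ALT where the alternate frequency is >= ``threshold``, REF where it is
    <= ``1 - threshold``, otherwise (including missing) ambiguous N.
    """
    if not 0.5 < threshold <= 1.0:
        raise ValueError("threshold must lie in (0.5, 1]")
    f = freqs.freq
    coded = np.full(f.shape, N, dtype=np.int8)
    with np.errstate(invalid="ignore"):
        coded[f >= threshold] = ALT
        coded[f <= 1.0 - threshold] = REF
    return coded
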