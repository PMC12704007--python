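"""Per-SNP effect estimation and additive-variance partitioning.

The partitioning formula is estimator-agnostic: given per-SNP effects beta
and allele frequencies p, the additive variance attributed to chromosome c is
``Va_c = sum_{j in c} 2 p_j (1 - p_j) beta_j^2`` (linkage cross-terms
ignored).  Effects may come from any mapping model; the bundled estimator is
ridge regression with the penalty chosen by generalized cross-validation.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .containers import VaPartition


class VaError(ValueError):
    pass


def estimate_effects(
    genotypes: np.ndarray,
    phenotype: np.ndarray,
    lam: float | str = "auto",
    n_grid: int = 50,
) -> tuple[np.ndarray, float]:
    """Ridge estimates of per-SNP (per-allele) effects.

    Genotype columns are centered and the phenotype is centered, so no
    intercept is penalized.  ``lam="auto"`` minimizes the generalized
    cross-validation score GCV(lam) = n * RSS / (n - df)^2 with
    df = sum d_i^2 / (d_i^2 + lam) over a log-spaced grid anchored at the
    squared singular values.  Returns (effects, lambda used).
    """
    x = np.asarray(genotypes, dtype=float)
    y = np.asarray(phenotype, dtype=float)
    n, p = x.shape
    if n < 10:
        raise VaError("need at least 10 individuals")
    if np.std(y) == 0:
        raise VaError("constant phenotype")
    xc = x - x.mean(axis=0)
    yc = y - y.mean()
    u, d, vt = np.linalg.svd(xc, full_matrices=False)
    uty = u.T @ yc
    d2 = d**2

    def beta_for(l: float) -> np.ndarray:
        shrink = d / (d2 + l)
        return vt.T @ (shrink * uty)

    if isinstance(lam, str):
        if lam != "auto":
            raise VaError(f"unknown lambda spec {lam!r}")
        d2pos = d2[d2 > 1e-12]
        lo, hi = d2pos.min() * 1e-4, d2pos.max() * 1e2
        grid = np.geomspace(lo, hi, n_grid)
        best_l, best_g = None, np.inf
        yss = float(yc @ yc)
        for l in grid:
            fit_coef = d2 / (d2 + l)
            df = float(fit_coef.sum())
            rss = yss - float(((2 * fit_coef - fit_coef**2) * uty**2).sum())
            gcv = n * rss / (n - df) ** 2 if n > df else np.inf
            if gcv < best_g:
                best_l, best_g = float(l), gcv
        lam = best_l
    else:
        lam = float(lam)
        if lam < 0:
            raise VaError("lambda must be non-negative")
        if lam == 0 and p >= n:
            raise VaError("lambda = 0 is singular when p >= n; use lambda > 0")
    return beta_for(lam), lam


def partition_va(
    effects: np.ndarray,
    freqs: np.ndarray,
    chrom_labels: np.ndarray,
    z_label: str | None = None,
    chrom_sizes: dict[str, int] | None = None,
) -> VaPartition:
    """Additive-variance partition ``Va_c = sum 2 p (1-p) beta^2``.

    ``z_label`` plus ``chrom_sizes`` add the genome fraction occupied by the
    Z chromosome for context.
    """
    effects = np.asarray(effects, dtype=float)
    freqs = np.asarray(freqs, dtype=float)
    chrom_labels = np.asarray(chrom_labels)
    if not (len(effects) == len(freqs) == len(chrom_labels)):
        raise VaError("effects, freqs and chromosome labels must align")
    per_snp = 2.0 * freqs * (1.0 - freqs) * effects**2
    chroms = list(pd.unique(chrom_labels))
    va = np.array([per_snp[chrom_labels == c].sum() for c in chroms])
    total = float(va.sum())
    if total == 0.0:
        raise VaError("all effects zero: proportions undefined")
    z_frac = None
    if z_label is not None and chrom_sizes:
        z_frac = chrom_sizes.get(z_label, 0) / sum(chrom_sizes.values())
    return VaPartition(
        chromosomes=[str(c) for c in chroms],
        va_by_chromosome=va,
        total_va=total,
        proportions=va / total,
        z_fraction_of_genome=z_frac,
    )


def empirical_partition_va(
    genotypes: np.ndarray,
    effects: np.ndarray,
    chrom_labels: np.ndarray,
) -> VaPartition:
    """Variant that computes the variance of per-chromosome genetic values
    from the genotypes themselves (within-chromosome linkage included)."""
    x = np.asarray(genotypes, dtype=float)
    chrom_labels = np.asarray(chrom_labels)
    chroms = list(pd.unique(chrom_labels))
    va = np.array(
        [float(np.var(x[:, chrom_labels == c] @ effects[chrom_labels == c]))
         for c in chroms]
    )
    total = float(va.sum())
    if total == 0.0:
        raise VaError("all effects zero: proportions undefined")
    return VaPartition(
        chromosomes=[str(c) for c in chroms],
        va_by_chromosome=va,
        total_va=total,
        proportions=va / total,
    )
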