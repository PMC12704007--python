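"""Estimate pool allele frequencies, per-chromosome covariance matrices with
block-resampling standard errors (blocks of 100 SNPs), and a genome-wide PCA
of the centered (not standardized) frequency matrix excluding the outgroup.
"""

from pathlib import Path

import pandas as pd

from treemosaic import block_covariance, estimate_frequencies, io, pca_scores

ROOT = Path(__file__).resolve().parents[1]
SCRATCH = ROOT / "scratch" / "sim"
RESULTS = ROOT / "results"


def main() -> None:
    counts = io.read_sync_counts(SCRATCH / "counts.sync.tsv")
    freqs = estimate_frequencies(counts, min_depth=1)
    io.write_frequency_matrix(freqs, SCRATCH / "est_freqs.tsv")

    (SCRATCH / "cov").mkdir(parents=True, exist_ok=True)
    for chrom in pd.unique(freqs.snps["chrom"]):
        cov = block_covariance(freqs.subset_chrom(chrom), block_size=100)
        io.write_covariance(cov, SCRATCH / "cov" / f"{chrom}.cov.tsv",
                            SCRATCH / "cov" / f"{chrom}.se.tsv")

    keep, scores, frac = pca_scores(freqs, exclude={"OG"})
    pd.DataFrame(
        {"population": keep, "PC1": scores[:, 0], "PC2": scores[:, 1]}
    ).to_csv(RESULTS / "pca_scores.tsv", sep="\t", index=False)
    print(f"PCA on {len(keep)} populations: "
          f"PC1 {frac[0]:.1%}, PC2 {frac[1]:.1%} of variance")
    print(f"covariance matrices for {freqs.snps['chrom'].nunique()} chromosomes "
          f"written to {SCRATCH / 'cov'}")


if __name__ == "__main__":
    main()
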