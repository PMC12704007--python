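"""Plain-text readers and writers for the pipeline's tabular formats."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .containers import AlleleCountMatrix, CovarianceEstimate, FrequencyMatrix, WindowScore, snp_table


def write_sync_counts(counts: AlleleCountMatrix, path) -> None:
    """Sync-style TSV: chrom, pos, ref, alt, then one 'ref:alt' column per
    population."""
    df = counts.snps[["chrom", "pos", "ref", "alt"]].copy()
    for i, pop in enumerate(counts.populations):
        df[pop] = [
            f"{r}:{a}" for r, a in zip(counts.ref_counts[i], counts.alt_counts[i])
        ]
    df.to_csv(path, sep="\t", index=False)


def read_sync_counts(path) -> AlleleCountMatrix:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    pops = [c for c in df.columns if c not in ("chrom", "pos", "ref", "alt")]
    ref = np.empty((len(pops), len(df)), dtype=np.int64)
    alt = np.empty_like(ref)
    for i, pop in enumerate(pops):
        parts = df[pop].str.split(":", expand=True).astype(np.int64)
        ref[i] = parts[0].to_numpy()
        alt[i] = parts[1].to_numpy()
    snps = snp_table(df["chrom"].to_numpy(), df["pos"].to_numpy(),
                     df["ref"].to_numpy(), df["alt"].to_numpy())
    return AlleleCountMatrix(pops, snps, ref, alt)


def write_frequency_matrix(freqs: FrequencyMatrix, path) -> None:
    df = freqs.snps[["chrom", "pos"]].copy()
    for i, pop in enumerate(freqs.populations):
        df[pop] = freqs.freq[i]
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_frequency_matrix(path) -> FrequencyMatrix:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    pops = [c for c in df.columns if c not in ("chrom", "pos")]
    freq = np.vstack([df[p].to_numpy(dtype=float) for p in pops])
    return FrequencyMatrix(pops, snp_table(df["chrom"], df["pos"]), freq)


def write_covariance(cov: CovarianceEstimate, path, se_path=None) -> None:
    pd.DataFrame(cov.matrix, index=cov.populations, columns=cov.populations).to_csv(
        path, sep="\t", float_format="%.8g"
    )
    if se_path is not None:
        pd.DataFrame(cov.se, index=cov.populations, columns=cov.populations).to_csv(
            se_path, sep="\t", float_format="%.8g"
        )


def read_covariance(path, se_path=None, block_size: int = 100, n_blocks: int = 0) -> CovarianceEstimate:
    m = pd.read_csv(path, sep="\t", index_col=0)
    se = (
        pd.read_csv(se_path, sep="\t", index_col=0).to_numpy()
        if se_path is not None
        else np.zeros_like(m.to_numpy())
    )
    return CovarianceEstimate(list(m.columns), m.to_numpy(), se, block_size, n_blocks)


def write_chromosome_sizes(sizes: dict[str, int], path) -> None:
    pd.DataFrame({"chrom": list(sizes), "size_bp": list(sizes.values())}).to_csv(
        path, sep="\t", index=False
    )


def read_chromosome_sizes(path) -> dict[str, int]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    return dict(zip(df["chrom"], df["size_bp"].astype(int)))


def write_coded_matrix(coded: np.ndarray, populations, snps: pd.DataFrame, path) -> None:
    """Coded alleles as TSV: chrom, pos, then one {-1,0,1} column per population."""
    df = snps[["chrom", "pos"]].copy()
    for i, pop in enumerate(populations):
        df[pop] = coded[i]
    df.to_csv(path, sep="\t", index=False)


def read_coded_matrix(path):
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    pops = [c for c in df.columns if c not in ("chrom", "pos")]
    coded = np.vstack([df[p].to_numpy(dtype=np.int8) for p in pops])
    return coded, pops, snp_table(df["chrom"], df["pos"])


def write_window_scores(windows: list[WindowScore], path) -> None:
    """BED-like TSV of sliding-window topology scores."""
    pd.DataFrame(
        {
            "chrom": [w.chrom for w in windows],
            "start": [w.start for w in windows],
            "end": [w.end for w in windows],
            "score1": [w.scores[0] for w in windows],
            "score2": [w.scores[1] for w in windows],
            "score3": [w.scores[2] for w in windows],
            "n_informative": [w.n_informative for w in windows],
        }
    ).to_csv(path, sep="\t", index=False, float_format="%.6g")


def write_graph(graph, path) -> None:
    """Extended-Newick-style text: tree with drift branch lengths, migration
    annotations appended after the semicolon."""
    Path(path).write_text(graph.to_newick() + "\n")
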