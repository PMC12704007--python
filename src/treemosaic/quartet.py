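"""Four-taxon topology votes and sliding-window scores.

Each SNP casts at most one vote: alleles are polarized by the outgroup, and a
site at which exactly two of the three focal populations carry the derived
allele supports the topology grouping those two.  Votes are tallied in
disjoint base windows (default 10 kb) and averaged over overlapping sliding
windows (default 50 kb, step 10 kb) before normalizing to sum to one; topology
1 is ((X,Y),Z) — the arrangement consistent with the species chronogram.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import N, WindowScore


@dataclass(frozen=True)
class QuartetSpec:
    x: str
    y: str
    z: str
    outgroup: str

    def __post_init__(self) -> None:
        if len({self.x, self.y, self.z, self.outgroup}) != 4:
            raise ValueError("quartet populations must be distinct")

    @property
    def taxa(self) -> tuple[str, str, str, str]:
        return (self.x, self.y, self.z, self.outgroup)


def snp_votes(coded: np.ndarray) -> np.ndarray:
    """Per-SNP topology votes from a 4 x n_snps coded-allele array.

    Rows are (X, Y, Z, outgroup).  Returns votes in {0 (none), 1, 2, 3}:
    1 = ((X,Y),Z), 2 = ((X,Z),Y), 3 = ((Y,Z),X).
    """
    if coded.shape[0] != 4:
        raise ValueError("expected 4 rows (X, Y, Z, outgroup)")
    x, y, z, o = (coded[i] for i in range(4))
    ok = (x != N) & (y != N) & (z != N) & (o != N)
    derived = np.vstack([x != o, y != o, z != o]) & ok
    nd = derived.sum(axis=0)
    votes = np.zeros(coded.shape[1], dtype=np.int8)
    two = ok & (nd == 2)
    votes[two & derived[0] & derived[1]] = 1
    votes[two & derived[0] & derived[2]] = 2
    votes[two & derived[1] & derived[2]] = 3
    return votes


def window_scores(
    votes: np.ndarray,
    positions: np.ndarray,
    chrom: str,
    chrom_size: int | None = None,
    base_window: int = 10_000,
    slide_window: int = 50_000,
    step: int = 10_000,
) -> list[WindowScore]:
    """Sliding-window normalized topology scores for one chromosome.

    Vote counts are tallied in disjoint ``base_window`` bins anchored at
    position 1, averaged across the base windows constituting each
    ``slide_window`` span (advancing by ``step``), then normalized to sum to
    one.  Windows without informative votes get missing (NaN) scores.
    """
    if slide_window % step != 0:
        raise ValueError("step must divide slide_window")
    if slide_window % base_window != 0 or step % base_window != 0:
        raise ValueError("base_window must divide slide_window and step")
    positions = np.asarray(positions)
    if len(positions) and (np.diff(positions) < 0).any():
        raise ValueError("positions must be sorted")
    span = int(chrom_size) if chrom_size else (int(positions.max()) if len(positions) else base_window)
    n_base = max(1, -(-span // base_window))
    counts = np.zeros((n_base, 3))
    if len(positions):
        bidx = (positions - 1) // base_window
        for t in (1, 2, 3):
            counts[:, t - 1] = np.bincount(
                bidx[votes == t], minlength=n_base
            )[:n_base]
    per_slide = slide_window // base_window
    stride = step // base_window
    out: list[WindowScore] = []
    start_bin = 0
    while start_bin == 0 or start_bin + per_slide <= n_base:
        block = counts[start_bin : start_bin + per_slide]
        mean_counts = block.mean(axis=0)
        total = mean_counts.sum()
        n_informative = int(block.sum())
        if total > 0:
            scores = tuple(float(s) for s in mean_counts / total)
        else:
            scores = (float("nan"),) * 3
        out.append(
            WindowScore(
                chrom=chrom,
                start=start_bin * base_window + 1,
                end=min((start_bin + per_slide) * base_window, span),
                scores=scores,
                n_informative=n_informative,
            )
        )
        start_bin += stride
        if start_bin + per_slide > n_base:
            break
    return out


def genome_window_scores(
    coded: np.ndarray,
    populations: list[str],
    snps: pd.DataFrame,
    quartet: QuartetSpec,
    chrom_sizes: dict[str, int] | None = None,
    **window_kwargs,
) -> list[WindowScore]:
    """Window scores across all chromosomes for one quartet."""
    rows = [populations.index(t) for t in quartet.taxa]
    votes = snp_votes(coded[rows])
    out: list[WindowScore] = []
    for chrom in pd.unique(snps["chrom"]):
        m = (snps["chrom"] == chrom).to_numpy()
        out.extend(
            window_scores(
                votes[m],
                snps.loc[m, "pos"].to_numpy(),
                str(chrom),
                chrom_size=(chrom_sizes or {}).get(chrom),
                **window_kwargs,
            )
        )
    return out


@dataclass
class ScoreSummary:
    per_chromosome_means: pd.DataFrame  # chrom x (score1, score2, score3)
    within_chromosome_variance: np.ndarray  # mean over chromosomes, per topology
    among_chromosome_variance: np.ndarray  # variance of chromosome means, per topology


def score_summaries(windows: list[WindowScore]) -> ScoreSummary:
    """Within- and among-chromosome variation in topology scores.

    Within-chromosome: variance of window scores across windows (population
    convention, divide by n), averaged over chromosomes.  Among-chromosome:
    variance of the per-chromosome mean scores.  Missing windows excluded.
    """
    df = pd.DataFrame(
        {
            "chrom": [w.chrom for w in windows],
            "s1": [w.scores[0] for w in windows],
            "s2": [w.scores[1] for w in windows],
            "s3": [w.scores[2] for w in windows],
        }
    ).dropna()
    chroms = df["chrom"].unique()
    if len(chroms) < 2:
        raise ValueError("need windows from at least 2 chromosomes")
    means = df.groupby("chrom", sort=False)[["s1", "s2", "s3"]].mean()
    within = df.groupby("chrom", sort=False)[["s1", "s2", "s3"]].agg(
        lambda v: float(np.var(v))
    )
    return ScoreSummary(
        per_chromosome_means=means,
        within_chromosome_variance=within.mean(axis=0).to_numpy(),
        among_chromosome_variance=np.var(means.to_numpy(), axis=0),
    )


def pearson_with_ci(
    x: np.ndarray, y: np.ndarray, alpha: float = 0.05
) -> tuple[float, tuple[float, float], float]:
    """Pearson r with Fisher-z confidence interval and two-sided t-test P."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3:
        raise ValueError("need at least 3 observations")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance: correlation undefined")
    r, p = stats.pearsonr(x, y)
    n = len(x)
    if abs(r) >= 1.0:
        return float(r), (float(r), float(r)), float(p)
    if n <= 3:  # Fisher z variance 1/(n-3) undefined: interval is vacuous
        return float(r), (-1.0, 1.0), float(p)
    zc = stats.norm.ppf(1 - alpha / 2)
    z = np.arctanh(r)
    half = zc / np.sqrt(n - 3)
    return float(r), (float(np.tanh(z - half)), float(np.tanh(z + half))), float(p)


def score_size_correlation(
    mean_scores: pd.Series | pd.DataFrame,
    chrom_sizes: dict[str, int],
    exclude: set[str] | None = None,
    topology: str = "s1",
):
    """Pearson correlation between chromosome size and mean topology score."""
    exclude = exclude or set()
    if isinstance(mean_scores, pd.DataFrame):
        mean_scores = mean_scores[topology]
    chroms = [c for c in mean_scores.index if c not in exclude and c in chrom_sizes]
    if len(chroms) < 3:
        raise ValueError("need at least 3 chromosomes after exclusion")
    sizes = np.array([chrom_sizes[c] for c in chroms], dtype=float)
    scores = mean_scores.loc[chroms].to_numpy(dtype=float)
    return pearson_with_ci(sizes, scores)
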