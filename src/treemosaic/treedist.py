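"""Per-chromosome trees, generalized Robinson-Foulds (clustering-information)
distances, and the SNP-permutation test for among-chromosome heterogeneity.

Chromosome trees are estimated from coded alleles by neighbor joining on
pairwise Hamming distances (proportion of sites at which two populations'
coded alleles differ, ambiguous sites excluded pairwise) and rooted on the
outgroup; only the topology enters the distance.  The null model permutes
SNP-to-chromosome assignments, preserving per-chromosome SNP counts, and the
P-value uses the +1 correction so that P is never zero.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from ._nj import neighbor_joining, root_on_leaf, splits
from .containers import N, DistanceResult


class EstimationError(ValueError):
    pass


@dataclass(frozen=True)
class TreeTopology:
    leaves: frozenset
    splits: frozenset  # canonical nontrivial bipartition sides
    newick: str = ""


def _coded_distance(coded: np.ndarray) -> np.ndarray:
    """Pairwise proportion of informative sites at which populations differ."""
    ok = coded != N
    okf = ok.astype(float)
    pair_n = okf @ okf.T
    c = np.where(ok, coded, 0).astype(float)
    both = c @ c.T  # count of sites where both are ALT (given ok)
    alt_counts = (c * okf) @ okf.T  # ALT in row pop, informative in col pop
    diff = alt_counts + alt_counts.T - 2.0 * both
    with np.errstate(divide="ignore", invalid="ignore"):
        d = np.where(pair_n > 0, diff / pair_n, 0.0)
    np.fill_diagonal(d, 0.0)
    return d


def _rooted_newick(parents: dict[str, str | None]) -> str:
    ch: dict[str, list[str]] = {n: [] for n in parents}
    for n, p in parents.items():
        if p is not None:
            ch[p].append(n)
    for v in ch.values():
        v.sort()

    def rec(n: str) -> str:
        if not ch[n]:
            return n
        return "(" + ",".join(rec(k) for k in ch[n]) + ")"

    root = [n for n, p in parents.items() if p is None][0]
    return rec(root) + ";"


def chromosome_tree(
    coded: np.ndarray,
    populations: list[str],
    outgroup: str,
    min_snps: int = 100,
) -> TreeTopology:
    """Neighbor-joining topology for one chromosome's coded alleles."""
    if len(populations) < 4:
        raise EstimationError("need at least 4 populations")
    if outgroup not in populations:
        raise EstimationError(f"outgroup {outgroup!r} not among populations")
    ok = coded != N
    pair_min = int((ok.astype(float) @ ok.astype(float).T).min())
    if pair_min < min_snps:
        raise EstimationError(
            f"only {pair_min} jointly informative SNPs for some population pair "
            f"(floor {min_snps})"
        )
    d = _coded_distance(coded)
    parents, _ = neighbor_joining(d, populations)
    rooted = root_on_leaf(parents, outgroup)
    return TreeTopology(
        leaves=frozenset(populations),
        splits=splits(parents),
        newick=_rooted_newick(rooted),
    )


def _entropy(a: int, n: int) -> float:
    p = a / n
    q = 1.0 - p
    out = 0.0
    if p > 0:
        out -= p * np.log2(p)
    if q > 0:
        out -= q * np.log2(q)
    return out


def _mutual_info(s1: frozenset, s2: frozenset, leaves: frozenset) -> float:
    """Mutual clustering information (bits) between two bipartitions."""
    n = len(leaves)
    cells = [
        len(s1 & s2),
        len(s1 - s2),
        len((leaves - s1) & s2),
        n - len(s1 | s2),
    ]
    col = [len(s2), n - len(s2)]
    row = [len(s1), n - len(s1)]
    marg = [
        (row[0], col[0]),
        (row[0], col[1]),
        (row[1], col[0]),
        (row[1], col[1]),
    ]
    info = 0.0
    for cnt, (r, c) in zip(cells, marg):
        if cnt > 0:
            info += (cnt / n) * np.log2(n * cnt / (r * c))
    return float(max(info, 0.0))


def clustering_info_distance(t1: TreeTopology, t2: TreeTopology) -> float:
    """Generalized Robinson-Foulds distance in bits.

    Nontrivial splits of the two trees are matched one-to-one to maximize the
    summed mutual clustering information; the distance is the total split
    entropy of both trees minus twice the matched shared information.  Zero
    exactly when the split sets coincide.
    """
    if t1.leaves != t2.leaves:
        raise EstimationError("trees must share one leaf set")
    if t1.splits == t2.splits:
        return 0.0
    leaves = t1.leaves
    n = len(leaves)
    s1 = sorted(t1.splits, key=lambda s: sorted(s))
    s2 = sorted(t2.splits, key=lambda s: sorted(s))
    h1 = sum(_entropy(len(s), n) for s in s1)
    h2 = sum(_entropy(len(s), n) for s in s2)
    if not s1 or not s2:
        return float(h1 + h2)
    gain = np.zeros((len(s1), len(s2)))
    for i, a in enumerate(s1):
        for j, b in enumerate(s2):
            gain[i, j] = _mutual_info(a, b, leaves)
    ri, ci = linear_sum_assignment(gain, maximize=True)
    shared = float(gain[ri, ci].sum())
    return float(max(h1 + h2 - 2.0 * shared, 0.0))


def plain_rf(t1: TreeTopology, t2: TreeTopology) -> int:
    """Classic Robinson-Foulds: splits present in exactly one tree."""
    if t1.leaves != t2.leaves:
        raise EstimationError("trees must share one leaf set")
    return len(t1.splits ^ t2.splits)


def mean_pairwise_distance(trees: list[TreeTopology]) -> tuple[float, np.ndarray]:
    k = len(trees)
    mat = np.zeros((k, k))
    for i, j in itertools.combinations(range(k), 2):
        mat[i, j] = mat[j, i] = clustering_info_distance(trees[i], trees[j])
    iu = np.triu_indices(k, 1)
    return float(mat[iu].mean()), mat


def permutation_test(
    coded: np.ndarray,
    populations: list[str],
    chrom_labels: np.ndarray,
    outgroup: str,
    n_permutations: int = 50,
    seed: int = 0,
    min_snps: int = 100,
    max_redraws: int = 100,
) -> DistanceResult:
    """Among-chromosome tree-heterogeneity test.

    Observed statistic: mean pairwise clustering-information distance among
    per-chromosome trees.  Each permutation shuffles the SNP-to-chromosome
    assignment (preserving per-chromosome SNP counts), re-estimates every
    tree, and recomputes the mean.  P = (1 + #{null >= observed}) /
    (1 + n_permutations).
    """
    chrom_labels = np.asarray(chrom_labels)
    chroms = list(pd.unique(chrom_labels))
    if len(chroms) < 2:
        raise EstimationError("need at least 2 chromosomes")
    counts0 = {c: int((chrom_labels == c).sum()) for c in chroms}

    def trees_for(labels: np.ndarray) -> list[TreeTopology]:
        out = []
        for c in chroms:
            out.append(
                chromosome_tree(coded[:, labels == c], populations, outgroup, min_snps)
            )
        return out

    observed, mat = mean_pairwise_distance(trees_for(chrom_labels))
    rng = np.random.default_rng(seed)
    null = np.empty(n_permutations)
    redraws = 0
    for k in range(n_permutations):
        for _ in range(max_redraws):
            perm_labels = chrom_labels[rng.permutation(len(chrom_labels))]
            assert {c: int((perm_labels == c).sum()) for c in chroms} == counts0
            try:
                null[k] = mean_pairwise_distance(trees_for(perm_labels))[0]
                break
            except EstimationError:
                redraws += 1
        else:
            raise EstimationError("too many permutations below the SNP floor")
    p = (1.0 + float((null >= observed).sum())) / (1.0 + n_permutations)
    return DistanceResult(
        chromosomes=[str(c) for c in chroms],
        matrix=mat,
        observed=observed,
        null_means=null,
        p_value=p,
        n_permutations=n_permutations,
        seed=seed,
        redraws=redraws,
    )
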