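"""Sliding-window four-taxon topology scores along every chromosome.

Site-pattern votes require populations fixed for alternative alleles, so this
step re-simulates the study topology (same migration-weight gradient across
autosomes, clean-tree Z) in a strong-drift regime at high SNP density
(1 SNP / 100 bp), working from the true frequencies.  Focal quartet:
X = C, Y = D, Z = A with the outgroup OG; the species relationship is
((C,D),A) (topology 1), and the autosomal admixture edge from the A lineage
into D lends support to topology 3, ((D,A),C), in proportion to each
autosome's migration weight.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from treemosaic import code_alleles, io, scenarios
from treemosaic.quartet import QuartetSpec, genome_window_scores, score_size_correlation, score_summaries
from treemosaic.scenarios import five_pop_tree
from treemosaic.simulate import SimulationConfig, simulate_genome_dataset

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"
SEED = 20240902

SCAN_DRIFT = {"OG": 0.8, "anc": 0.05, "n1": 0.3, "A": 0.8, "B": 0.3,
              "n2": 0.5, "C": 0.4, "D": 0.4}


def scan_config(seed: int) -> SimulationConfig:
    base = scenarios.study_genome_config(seed=seed)
    tree = five_pop_tree(SCAN_DRIFT)
    graphs = {}
    for chrom, g in base.graph_assignment.items():
        if g.migrations:
            graphs[chrom], _ = tree.add_migration_from_branch(
                "A", "D", g.migrations[0].weight
            )
        else:
            graphs[chrom] = tree
    return SimulationConfig(
        chromosome_sizes=base.chromosome_sizes,
        snps_per_chromosome={c: s // 100 for c, s in base.chromosome_sizes.items()},
        graph_assignment=graphs,
        root_freq_dist=("uniform", 0.2, 0.8),
        seed=seed,
    )


def main() -> None:
    cfg = scan_config(SEED)
    _, truth = simulate_genome_dataset(cfg)
    freqs = truth.frequencies
    coded = code_alleles(freqs)
    quartet = QuartetSpec(x="C", y="D", z="A", outgroup="OG")
    windows = genome_window_scores(
        coded, freqs.populations, freqs.snps, quartet,
        chrom_sizes=cfg.chromosome_sizes,
    )
    scratch = ROOT / "scratch"
    scratch.mkdir(exist_ok=True)
    io.write_window_scores(windows, scratch / "quartet_window_scores.tsv")

    summ = score_summaries(windows)
    summ.per_chromosome_means.to_csv(RESULTS / "quartet_chromosome_means.tsv", sep="\t")
    print(f"{sum(w.n_informative > 0 for w in windows)} informative windows "
          f"of {len(windows)}")
    print("mean within-chromosome score variance (top.1):",
          round(float(summ.within_chromosome_variance[0]), 5))
    print("among-chromosome variance of mean score (top.1):",
          round(float(summ.among_chromosome_variance[0]), 5))
    means = summ.per_chromosome_means
    print(f"Z mean scores: {means.loc['chrZ'].round(3).to_dict()}")
    autos = means.drop("chrZ")
    print(f"autosome mean scores: {autos.mean().round(3).to_dict()}")

    r, ci, p = score_size_correlation(
        means["s3"], cfg.chromosome_sizes, exclude={"chrZ"}, topology="s3"
    )
    pd.DataFrame([{"topology": "s3", "pearson_r": r, "ci_lo": ci[0],
                   "ci_hi": ci[1], "p": p}]).to_csv(
        RESULTS / "quartet_size_correlation.tsv", sep="\t", index=False)
    print(f"autosome size vs mean admixture-topology score: "
          f"r = {r:.2f} (95% CI {ci[0]:.2f} to {ci[1]:.2f}, P = {p:.2g})")


if __name__ == "__main__":
    main()
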