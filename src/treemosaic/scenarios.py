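"""Canonical synthetic study conditions.

These constructors define the ground-truth graphs and generator settings used
by the validation studies, the analysis scripts and the acceptance checks, so
every entry point exercises the same conditions.  Drift values are per-branch
variance coefficients (variance of frequency change = c * p(1-p)).

Three drift regimes appear:

* ``DRIFT_MODEL_CHECK`` (0.02) with an interior uniform root — the
  truncation-free regime where the linear Gaussian drift model is essentially
  exact, used for simulator/model covariance consistency.
* ``DRIFT_TREE`` (0.25) with a U-shaped (beta(0.5, 0.5)) root — strong drift
  under which the 0.95 coding rule yields informative sites and the
  coded-allele tree estimator recovers generating topologies reliably.
* quartet drift (~0.5-0.8 per branch segment) — very strong drift, the regime
  in which independent lineage fixation produces discordant four-taxon site
  patterns at appreciable rates.
"""

from __future__ import annotations

import numpy as np

from .graphs import MigrationEdge, PopulationGraph

DRIFT_MODEL_CHECK = 0.02
DRIFT_TREE = 0.25
ROOT_MODEL_CHECK: tuple = ("uniform", 0.35, 0.65)
ROOT_CODED: tuple = ("beta", 0.5, 0.5)


def five_pop_tree(
    drift: dict[str, float] | float = 0.1, outgroup: str = "OG"
) -> PopulationGraph:
    """Outgroup plus a balanced ingroup ((A,B),(C,D))."""
    parents = {
        "root": None, "OG": "root", "anc": "root",
        "n1": "anc", "A": "n1", "B": "n1",
        "n2": "anc", "C": "n2", "D": "n2",
    }
    if np.isscalar(drift):
        drift = {k: float(drift) for k in parents if parents[k] is not None}
    return PopulationGraph(parents, dict(drift), outgroup=outgroup)


def admixture_recovery_graph(w: float = 0.4) -> PopulationGraph:
    """One-edge admixture graph with a clearly non-tree-like signature.

    The donor lineage (A) and the recipient's parent clade branch (n2) carry
    strong drift, so the admixed tip D shares drift with two unrelated
    strongly-drifted lineages — a configuration no bifurcating tree can
    represent.  Migration enters D from the midpoint of A's branch.
    """
    base = five_pop_tree(
        {"OG": 0.1, "anc": 0.02, "n1": 0.05, "A": 0.4, "B": 0.05,
         "n2": 0.3, "C": 0.05, "D": 0.02}
    )
    graph, _ = base.add_migration_from_branch("A", "D", w)
    return graph


def six_pop_tree(drift: float = DRIFT_TREE, outgroup: str = "OG") -> PopulationGraph:
    """Outgroup plus five ingroup populations ((A,B),((C,D),E))."""
    parents = {
        "root": None, "OG": "root", "anc": "root",
        "n1": "anc", "A": "n1", "B": "n1",
        "n3": "anc", "n2": "n3", "C": "n2", "D": "n2", "E": "n3",
    }
    return PopulationGraph(
        parents, {k: drift for k in parents if parents[k] is not None}, outgroup=outgroup
    )


def six_pop_alternative(drift: float = DRIFT_TREE, outgroup: str = "OG") -> PopulationGraph:
    """Topologically distinct variant of :func:`six_pop_tree` (B and D
    exchanged), used as the second chromosome-class history."""
    parents = {
        "root": None, "OG": "root", "anc": "root",
        "n1": "anc", "A": "n1", "D": "n1",
        "n3": "anc", "n2": "n3", "C": "n2", "B": "n2", "E": "n3",
    }
    return PopulationGraph(
        parents, {k: drift for k in parents if parents[k] is not None}, outgroup=outgroup
    )


def symmetric_admixture_quartet(
    w: float = 0.5, branch_drift: float = 0.5, dest_drift: float = 0.6
) -> PopulationGraph:
    """Quartet (X, Y, Z, outgroup O) in which Y draws ancestry w from the
    X lineage and 1-w from the Z lineage, both at branch midpoints.

    At w = 0.5 the construction is exactly symmetric in X and Z, so the
    topology scores for ((X,Y),Z) and ((Y,Z),X) have equal expectation.
    """
    half = branch_drift / 2.0
    parents = {
        "root": None, "O": "root", "midX": "root", "X": "midX",
        "midZ": "root", "Z": "midZ", "Y": "midZ",
    }
    drift = {"O": branch_drift, "midX": half, "X": half,
             "midZ": half, "Z": half, "Y": dest_drift}
    return PopulationGraph(
        parents, drift, [MigrationEdge("midX", "Y", w)], outgroup="O"
    )


def study_genome_config(
    seed: int = 0,
    n_autosomes: int = 22,
    snp_density: float = 1 / 2000,
    w_range: tuple[float, float] = (0.15, 0.45),
):
    """Genome-scale study: autosomes carry one admixture edge whose weight
    grows with chromosome size; the Z evolves on the clean tree.

    Autosome sizes decline linearly from 24 Mb to 8 Mb; the Z is sized at
    ~5.5% of the genome.  Returns a
    :class:`~treemosaic.simulate.SimulationConfig`.
    """
    from .simulate import SimulationConfig

    base_drift = {"OG": 0.6, "anc": 0.05, "n1": 0.25, "A": 0.8, "B": 0.25,
                  "n2": 0.5, "C": 0.3, "D": 0.3}
    tree = five_pop_tree(base_drift)
    auto_sizes = np.linspace(24e6, 8e6, n_autosomes).astype(int)
    z_size = int(0.055 / (1 - 0.055) * auto_sizes.sum())
    sizes = {f"chr{i + 1}": int(s) for i, s in enumerate(auto_sizes)}
    sizes["chrZ"] = z_size
    lo, hi = w_range
    rel = (auto_sizes - auto_sizes.min()) / (auto_sizes.max() - auto_sizes.min())
    graphs: dict[str, PopulationGraph] = {}
    for i, r in enumerate(rel):
        g, _ = tree.add_migration_from_branch("A", "D", lo + (hi - lo) * float(r))
        graphs[f"chr{i + 1}"] = g
    graphs["chrZ"] = tree
    return SimulationConfig(
        chromosome_sizes=sizes,
        snps_per_chromosome={c: max(300, int(s * snp_density)) for c, s in sizes.items()},
        graph_assignment=graphs,
        root_freq_dist=ROOT_CODED,
        seed=seed,
    )


def clean_quartet(
    internal_drift: float = 0.6, tip_drift: float = 0.4
) -> PopulationGraph:
    """Quartet with true topology ((X,Y),Z) and no admixture."""
    parents = {"root": None, "O": "root", "a": "root",
               "xy": "a", "X": "xy", "Y": "xy", "Z": "a"}
    drift = {"O": 0.6, "a": 0.2, "xy": internal_drift,
             "X": tip_drift, "Y": tip_drift, "Z": 0.6}
    return PopulationGraph(parents, drift, outgroup="O")
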