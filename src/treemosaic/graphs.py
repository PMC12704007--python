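"""Admixture graphs: rooted drift trees with weighted migration edges.

A population graph is a rooted tree whose branches carry non-negative drift
parameters ``c`` (variance of allele-frequency change along the branch is
``c * p(1-p)``), optionally augmented with migration edges.  A migration edge
``(source, dest, w)`` makes the destination node a mixture: its frequency is
``w * f(source) + (1-w) * f(tree_parent)`` before the drift of its own branch
is applied.  Migration weights are proxies for admixture proportions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


class GraphError(ValueError):
    """Raised for structurally invalid population graphs."""


@dataclass(frozen=True)
class MigrationEdge:
    source: str
    dest: str
    weight: float


@dataclass
class PopulationGraph:
    """Rooted drift tree plus migration edges.

    Parameters
    ----------
    parents
        Map child node -> parent node.  Exactly one node (the root) must be
        absent from this map or map to ``None``.
    drift
        Map node -> drift on the branch above it (dimensionless, >= 0).
        The root carries no branch and needs no entry.
    migrations
        Migration edges; at most one incoming edge per destination node.
    outgroup
        Leaf used for rooting and allele polarization downstream.
    """

    parents: dict[str, str | None]
    drift: dict[str, float]
    migrations: list[MigrationEdge] = field(default_factory=list)
    outgroup: str | None = None

    def __post_init__(self) -> None:
        self.validate()

    # -- structure ---------------------------------------------------------

    @property
    def root(self) -> str:
        roots = [n for n, p in self.parents.items() if p is None]
        return roots[0]

    @property
    def nodes(self) -> list[str]:
        return sorted(self.parents)

    def children(self) -> dict[str, list[str]]:
        ch: dict[str, list[str]] = {n: [] for n in self.parents}
        for n, p in self.parents.items():
            if p is not None:
                ch[p].append(n)
        for v in ch.values():
            v.sort()
        return ch

    @property
    def leaves(self) -> list[str]:
        ch = self.children()
        return sorted(n for n, kids in ch.items() if not kids)

    def validate(self) -> None:
        roots = [n for n, p in self.parents.items() if p is None]
        if len(roots) != 1:
            raise GraphError(f"graph must have exactly one root, found {len(roots)}")
        for n, p in self.parents.items():
            if p is not None and p not in self.parents:
                raise GraphError(f"parent {p!r} of {n!r} is not a node")
        # tree check: every non-root node reaches the root without cycles
        for n in self.parents:
            seen = set()
            cur: str | None = n
            while cur is not None:
                if cur in seen:
                    raise GraphError(f"cycle in tree edges at {cur!r}")
                seen.add(cur)
                cur = self.parents[cur]
        for n, c in self.drift.items():
            if c < 0:
                raise GraphError(f"negative drift on branch above {n!r}")
        dests = set()
        for m in self.migrations:
            if not (0.0 < m.weight < 1.0):
                raise GraphError(f"migration weight {m.weight} not in (0,1)")
            if m.source not in self.parents or m.dest not in self.parents:
                raise GraphError("migration endpoints must be graph nodes")
            if m.dest in dests:
                raise GraphError(f"node {m.dest!r} has multiple incoming migrations")
            if self.parents[m.dest] is None:
                raise GraphError("root cannot be a migration destination")
            dests.add(m.dest)
        if self.outgroup is not None and self.outgroup not in self.leaves:
            raise GraphError(f"outgroup {self.outgroup!r} is not a leaf")
        self.topological_order()  # raises on migration-induced cycles

    @classmethod
    def _unchecked(
        cls, parents, drift, migrations, outgroup
    ) -> "PopulationGraph":
        """Construct without re-validation (hot paths; inputs already valid
        by construction)."""
        g = object.__new__(cls)
        g.parents = parents
        g.drift = drift
        g.migrations = migrations
        g.outgroup = outgroup
        return g

    def copy(self) -> "PopulationGraph":
        return PopulationGraph._unchecked(
            dict(self.parents),
            dict(self.drift),
            list(self.migrations),
            self.outgroup,
        )

    def topological_order(self) -> list[str]:
        """Nodes ordered so each node follows its tree parent and, for a
        migration destination, its migration source.  Cached per instance
        (the order depends only on topology and migration endpoints)."""
        cached = self.__dict__.get("_topo_cache")
        if cached is not None:
            return cached
        deps: dict[str, set[str]] = {n: set() for n in self.parents}
        for n, p in self.parents.items():
            if p is not None:
                deps[n].add(p)
        for m in self.migrations:
            deps[m.dest].add(m.source)
        order: list[str] = []
        ready = sorted(n for n, d in deps.items() if not d)
        deps = {n: set(d) for n, d in deps.items()}
        while ready:
            n = ready.pop()
            order.append(n)
            for k in sorted(deps):
                if n in deps[k]:
                    deps[k].discard(n)
                    if not deps[k]:
                        ready.append(k)
            ready.sort()
        if len(order) != len(self.parents):
            raise GraphError("migration edges induce a cyclic dependency")
        self.__dict__["_topo_cache"] = order
        return order

    # -- model -------------------------------------------------------------

    def migration_into(self, node: str) -> MigrationEdge | None:
        for m in self.migrations:
            if m.dest == node:
                return m
        return None

    def ancestry_coefficients(self) -> tuple[list[str], dict[str, np.ndarray]]:
        """Per-node coefficients over branch noise terms.

        Returns the branch index (non-root nodes, sorted) and a map
        node -> vector ``a`` with ``f(node) - p0 = sum_b a[b] * e_b``.
        """
        branches = sorted(n for n, p in self.parents.items() if p is not None)
        idx = {b: i for i, b in enumerate(branches)}
        coeff: dict[str, np.ndarray] = {}
        for n in self.topological_order():
            p = self.parents[n]
            if p is None:
                coeff[n] = np.zeros(len(branches))
                continue
            mig = self.migration_into(n)
            if mig is None:
                a = coeff[p].copy()
            else:
                a = mig.weight * coeff[mig.source] + (1.0 - mig.weight) * coeff[p]
            a[idx[n]] += 1.0
            coeff[n] = a
        return branches, coeff

    def branch_variances(self, het_decay: bool = False) -> dict[str, float]:
        """Effective variance contribution of each branch, in units of the
        root heterozygosity p0(1-p0).

        With ``het_decay=False`` this is just the drift parameter ``c``.  With
        ``het_decay=True`` it is ``c * (1 - V_parent)`` where ``V_parent`` is
        the parent's accumulated variance coefficient — the exact expectation
        under Gaussian drift whose variance tracks the parent's p(1-p).
        """
        branches, coeff = self.ancestry_coefficients()
        idx = {b: i for i, b in enumerate(branches)}
        v = np.zeros(len(branches))
        if not het_decay:
            for b in branches:
                v[idx[b]] = self.drift.get(b, 0.0)
            return {b: float(v[idx[b]]) for b in branches}
        for n in self.topological_order():
            p = self.parents[n]
            if p is None:
                continue
            mig = self.migration_into(n)
            if mig is None:
                a_mix = coeff[p]
            else:
                a_mix = mig.weight * coeff[mig.source] + (1.0 - mig.weight) * coeff[p]
            var_mix = float(a_mix @ (v * a_mix))
            v[idx[n]] = self.drift.get(n, 0.0) * max(0.0, 1.0 - var_mix)
        return {b: float(v[idx[b]]) for b in branches}

    # -- editing -----------------------------------------------------------

    def add_migration_from_branch(
        self, donor: str, dest: str, weight: float
    ) -> tuple["PopulationGraph", str]:
        """Insert a midpoint node on the branch above ``donor`` and add a
        migration edge from it into ``dest``.  Returns (new graph, midpoint id).
        """
        if self.parents.get(donor) is None:
            raise GraphError("donor must be a non-root node")
        mid = f"mid{len(self.migrations)}_{donor}"
        while mid in self.parents:
            mid += "x"
        parents = dict(self.parents)
        drift = dict(self.drift)
        parents[mid] = parents[donor]
        parents[donor] = mid
        c = drift.get(donor, 0.0)
        drift[mid] = c / 2.0
        drift[donor] = c / 2.0
        migs = list(self.migrations) + [MigrationEdge(mid, dest, weight)]
        return PopulationGraph(parents, drift, migs, self.outgroup), mid

    def with_weights(self, weights: dict[tuple[str, str], float]) -> "PopulationGraph":
        migs = [
            MigrationEdge(m.source, m.dest, weights.get((m.source, m.dest), m.weight))
            for m in self.migrations
        ]
        g = PopulationGraph._unchecked(
            dict(self.parents), dict(self.drift), migs, self.outgroup
        )
        if "_topo_cache" in self.__dict__:
            g.__dict__["_topo_cache"] = self.__dict__["_topo_cache"]
        return g

    def with_drift(self, drift: dict[str, float]) -> "PopulationGraph":
        g = PopulationGraph._unchecked(
            dict(self.parents), dict(drift), list(self.migrations), self.outgroup
        )
        if "_topo_cache" in self.__dict__:
            g.__dict__["_topo_cache"] = self.__dict__["_topo_cache"]
        return g

    # -- output ------------------------------------------------------------

    def to_newick(self) -> str:
        """Newick string of the tree part, drift values as branch lengths.

        Migration edges are rendered as trailing comment blocks
        ``[&migration source=.. dest=.. w=..]`` after the terminating
        semicolon, one per edge.
        """
        ch = self.children()

        def render(n: str) -> str:
            if not ch[n]:
                body = n
            else:
                body = "(" + ",".join(render(k) for k in ch[n]) + ")" + n
            if self.parents[n] is None:
                return body
            return f"{body}:{self.drift.get(n, 0.0):.6g}"

        out = render(self.root) + ";"
        for m in self.migrations:
            out += f"[&migration source={m.source} dest={m.dest} w={m.weight:.4f}]"
        return out


def random_nni(graph: PopulationGraph, rng: np.random.Generator) -> PopulationGraph:
    """One random nearest-neighbour-interchange on an internal tree edge.

    Only graphs without migration edges are perturbed (restart topologies are
    generated before edge placement).
    """
    if graph.migrations:
        raise GraphError("NNI perturbation operates on migration-free trees")
    ch = graph.children()
    internal_edges = [
        (p, n)
        for n, p in graph.parents.items()
        if p is not None and graph.parents[p] is not None and ch[n]
    ]
    if not internal_edges:
        return graph.copy()
    p, n = internal_edges[rng.integers(len(internal_edges))]
    # swap one child of n with one sibling of n (child of p other than n)
    sibs = [k for k in ch[p] if k != n]
    kids = ch[n]
    s = sibs[rng.integers(len(sibs))]
    k = kids[rng.integers(len(kids))]
    parents = dict(graph.parents)
    parents[s] = n
    parents[k] = p
    return PopulationGraph(parents, dict(graph.drift), [], graph.outgroup)
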