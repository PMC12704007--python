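"""Neighbor joining (via scikit-bio) and split/rooting utilities on plain
parent-map trees."""

from __future__ import annotations

import numpy as np
from skbio import DistanceMatrix
from skbio.tree import nj as _skbio_nj


def neighbor_joining(
    d: np.ndarray, labels: list[str]
) -> tuple[dict[str, str | None], dict[str, float]]:
    """Neighbor joining on a symmetric hollow distance matrix.

    Thin wrapper around ``skbio.tree.nj`` that returns the tree as a parent
    map (internal nodes ``nj0``, ``nj1``, ... and a trifurcating pseudo-root)
    plus branch lengths keyed by child node.
    """
    n = len(labels)
    if n < 3:
        raise ValueError("need at least 3 taxa")
    if d.shape != (n, n):
        raise ValueError("distance matrix shape mismatch")
    tree = _skbio_nj(DistanceMatrix(d, labels))
    parents: dict[str, str | None] = {}
    lengths: dict[str, float] = {}
    counter = 0
    names: dict[int, str] = {}

    def name_of(node) -> str:
        nonlocal counter
        if node.name is not None:
            return node.name
        key = id(node)
        if key not in names:
            names[key] = f"nj{counter}"
            counter += 1
        return names[key]

    root = tree.root()
    parents[name_of(root)] = None
    for node in root.preorder(include_self=False):
        child = name_of(node)
        parents[child] = name_of(node.parent)
        lengths[child] = float(node.length or 0.0)
    return parents, lengths


def _children(parents: dict[str, str | None]) -> dict[str, list[str]]:
    ch: dict[str, list[str]] = {n: [] for n in parents}
    for n, p in parents.items():
        if p is not None:
            ch[p].append(n)
    return ch


def leaf_sets(parents: dict[str, str | None]) -> dict[str, frozenset]:
    """Leaf set below each node of a rooted parent map."""
    ch = _children(parents)
    out: dict[str, frozenset] = {}

    def rec(n: str) -> frozenset:
        if not ch[n]:
            out[n] = frozenset([n])
        else:
            s: frozenset = frozenset()
            for k in ch[n]:
                s |= rec(k)
            out[n] = s
        return out[n]

    root = [n for n, p in parents.items() if p is None][0]
    rec(root)
    return out


def splits(parents: dict[str, str | None]) -> frozenset:
    """Nontrivial bipartitions of the leaf set, as canonical frozensets.

    Each split is represented by the side not containing the lexicographically
    smallest leaf, so the representation is rooting-invariant.
    """
    below = leaf_sets(parents)
    root = [n for n, p in parents.items() if p is None][0]
    all_leaves = below[root]
    n = len(all_leaves)
    anchor = min(all_leaves)
    out = set()
    for node, s in below.items():
        if node == root:
            continue
        side = all_leaves - s if anchor in s else s
        if 2 <= len(side) <= n - 2:
            out.add(side)
    return frozenset(out)


def root_on_leaf(
    parents: dict[str, str | None], outgroup: str
) -> dict[str, str | None]:
    """Re-root an (arbitrarily rooted) tree on the pendant edge of a leaf.

    Inserts a new node ``root`` between ``outgroup`` and its neighbour and
    orients all edges away from it.  Any resulting degree-two pass-through
    node (the old pseudo-root when it had two children) is suppressed.
    """
    if outgroup not in parents:
        raise ValueError(f"outgroup {outgroup!r} not in tree")
    adj: dict[str, set[str]] = {n: set() for n in parents}
    for n, p in parents.items():
        if p is not None:
            adj[n].add(p)
            adj[p].add(n)
    (nb,) = adj[outgroup]
    new: dict[str, str | None] = {"root": None, outgroup: "root", nb: "root"}
    stack = [nb]
    seen = {outgroup, nb}
    while stack:
        cur = stack.pop()
        for k in adj[cur]:
            if k not in seen:
                new[k] = cur
                seen.add(k)
                stack.append(k)
    # suppress degree-2 pass-through nodes left over from the old rooting
    ch = _children(new)
    for node in list(new):
        if node != "root" and len(ch.get(node, [])) == 1 and new[node] is not None:
            (only,) = ch[node]
            new[only] = new[node]
            del new[node]
            ch = _children(new)
    return new
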