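"""Fit population trees and admixture graphs to allele-frequency covariances.

The model is the linear drift covariance W = U diag(c) U^T, where U holds each
population's ancestry coefficients over branches and c the per-branch drift
parameters.  Because the sample covariance is computed from frequencies
centered by the across-population mean, fitting compares centered matrices on
both sides.  The per-chromosome tree-likeness statistic is PCVE: the
proportion of the covariance explained by a fitted graph.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize_scalar, nnls

from ._nj import neighbor_joining, root_on_leaf
from .containers import CovarianceEstimate
from .graphs import GraphError, PopulationGraph, random_nni


class ModelError(ValueError):
    pass


@dataclass
class FitResult:
    graph: PopulationGraph
    fitted_cov: np.ndarray  # centered model covariance, population order = graph.leaves
    pcve: float
    n_edges: int
    objective: float
    restart_log: list[float] = field(default_factory=list)
    seed: int | None = None
    converged: bool = True


def expected_covariance(
    graph: PopulationGraph, centered: bool = False, het_decay: bool = False
) -> tuple[list[str], np.ndarray]:
    """Model covariance of population allele frequencies, in drift units.

    ``W_ij = sum_b u_i(b) u_j(b) c_b`` with ancestry coefficients ``u`` that
    account for migration edges (weights w split a lineage between its donor
    and its tree parent).  ``centered=True`` applies the across-population
    centering projection ``P = I - 11^T/n`` on both sides, matching the sample
    covariance estimator.  ``het_decay=True`` replaces each ``c_b`` by its
    exact effective value under heterozygosity decay (used for
    simulator-consistency checks; see docs/methods.md).
    """
    try:
        branches, coeff = graph.ancestry_coefficients()
    except GraphError as exc:
        raise ModelError(str(exc)) from exc
    v = graph.branch_variances(het_decay=het_decay)
    varr = np.array([v[b] for b in branches])
    pops = graph.leaves
    u = np.vstack([coeff[p] for p in pops])
    w = (u * varr) @ u.T
    if centered:
        n = len(pops)
        p = np.eye(n) - np.full((n, n), 1.0 / n)
        w = p @ w @ p
    return pops, (w + w.T) / 2.0


def _unique_entries(n: int) -> tuple[np.ndarray, np.ndarray]:
    return np.triu_indices(n)


def _design_matrix(graph: PopulationGraph) -> tuple[list[str], list[str], np.ndarray]:
    """Linear map from branch drift values to unique centered-covariance
    entries: entry k = sum_b M[k, b] * c_b."""
    branches, coeff = graph.ancestry_coefficients()
    pops = graph.leaves
    n = len(pops)
    u = np.vstack([coeff[p] for p in pops])
    p = np.eye(n) - np.full((n, n), 1.0 / n)
    pu = p @ u
    iu, ju = _unique_entries(n)
    m = pu[iu] * pu[ju]
    return pops, branches, m


def _aligned_target(
    graph: PopulationGraph, cov: CovarianceEstimate, weight_by_se: bool
) -> tuple[np.ndarray, np.ndarray]:
    """Unique-entry observed vector and weights, in graph.leaves order."""
    pops = graph.leaves
    if sorted(pops) != sorted(cov.populations):
        raise ModelError("population sets of graph and covariance differ")
    idx = [cov.populations.index(p) for p in pops]
    cm = cov.matrix[np.ix_(idx, idx)]
    iu, ju = _unique_entries(len(pops))
    y = cm[iu, ju]
    if weight_by_se:
        se = cov.se[np.ix_(idx, idx)][iu, ju]
        floor = max(se[se > 0].min(), 1e-12) if (se > 0).any() else 1.0
        wts = 1.0 / np.maximum(se, floor)
    else:
        wts = np.ones_like(y)
    return y, wts


def fit_drift(
    graph: PopulationGraph, cov: CovarianceEstimate, weight_by_se: bool = False
) -> tuple[PopulationGraph, float]:
    """Non-negative least squares for all drift values, topology and
    migration weights held fixed.  Returns (updated graph, objective)."""
    _, branches, m = _design_matrix(graph)
    y, wts = _aligned_target(graph, cov, weight_by_se)
    c, _ = nnls(m * wts[:, None], y * wts)
    drift = {b: float(c[k]) for k, b in enumerate(branches)}
    g = graph.with_drift(drift)
    resid = (m @ c - y) * wts
    return g, float(resid @ resid)


def _objective(graph: PopulationGraph, cov: CovarianceEstimate, weight_by_se: bool) -> float:
    pops, w = expected_covariance(graph, centered=True)
    y, wts = _aligned_target(graph, cov, weight_by_se)
    iu, ju = _unique_entries(len(pops))
    r = (w[iu, ju] - y) * wts
    return float(r @ r)


def fit_parameters(
    graph: PopulationGraph,
    cov: CovarianceEstimate,
    weight_by_se: bool = False,
    tol: float = 1e-10,
    max_iter: int = 500,
) -> FitResult:
    """Alternating fit of drift values (non-negative least squares) and each
    migration weight (bounded scalar search) for a fixed topology and edge
    placement."""
    best = graph.copy()
    best, obj = fit_drift(best, cov, weight_by_se)
    converged = False
    for _ in range(max_iter):
        prev = obj
        for edge in list(best.migrations):

            def f(w: float, e=edge) -> float:
                g = best.with_weights({(e.source, e.dest): w})
                return _objective(g, cov, weight_by_se)

            res = minimize_scalar(f, bounds=(1e-4, 1 - 1e-4), method="bounded")
            if res.fun <= obj:
                best = best.with_weights({(edge.source, edge.dest): float(res.x)})
                obj = float(res.fun)
        best, obj = fit_drift(best, cov, weight_by_se)
        if prev - obj < tol:
            converged = True
            break
    return _result(best, cov, obj, converged)


def _result(
    graph: PopulationGraph, cov: CovarianceEstimate, obj: float, converged: bool
) -> FitResult:
    """Package a fit; fitted_cov follows cov.populations order."""
    pops, w = expected_covariance(graph, centered=True)
    perm = [pops.index(p) for p in cov.populations]
    w = w[np.ix_(perm, perm)]
    w = (w + w.T) / 2.0
    return FitResult(
        graph=graph,
        fitted_cov=w,
        pcve=pcve_from_matrices(cov.matrix, w),
        n_edges=len(graph.migrations),
        objective=obj,
        converged=converged,
    )


def pcve_from_matrices(
    observed: np.ndarray, fitted: np.ndarray, include_diagonal: bool = False
) -> float:
    """Proportion of covariance explained: 1 - SS_res / SS_tot over unique
    matrix entries, SS_tot around the grand mean of the observed entries;
    clipped to [0, 1].

    By default only off-diagonal entries (between-population covariances)
    enter: the diagonal is dominated by per-population drift, which any tree
    fits exactly through its pendant branches, so including it saturates the
    statistic and masks non-tree-like structure at small population numbers.
    ``include_diagonal=True`` gives the variant that sums over the diagonal
    too.
    """
    k = 0 if include_diagonal else 1
    iu, ju = np.triu_indices(observed.shape[0], k)
    y = observed[iu, ju]
    r = y - fitted[iu, ju]
    denom = float(((y - y.mean()) ** 2).sum())
    if denom <= 1e-24 * (1.0 + float(y @ y)):
        raise ModelError("constant observed covariance: PCVE undefined")
    return float(np.clip(1.0 - float(r @ r) / denom, 0.0, 1.0))


def pcve(fit: FitResult, cov: CovarianceEstimate, include_diagonal: bool = False) -> float:
    if sorted(fit.graph.leaves) != sorted(cov.populations):
        raise ModelError("population sets differ")
    return pcve_from_matrices(cov.matrix, fit.fitted_cov, include_diagonal)


def tree_from_covariance(
    cov: CovarianceEstimate, outgroup: str, weight_by_se: bool = False
) -> PopulationGraph:
    """Neighbor-joining start tree from covariance-implied drift distances
    ``d_ij = W_ii + W_jj - 2 W_ij``, rooted on the outgroup, drift values by
    non-negative least squares."""
    if outgroup not in cov.populations:
        raise ModelError(f"outgroup {outgroup!r} not among populations")
    w = cov.matrix
    d = np.maximum(np.diag(w)[:, None] + np.diag(w)[None, :] - 2.0 * w, 0.0)
    np.fill_diagonal(d, 0.0)
    parents, _ = neighbor_joining(d, list(cov.populations))
    rooted = root_on_leaf(parents, outgroup)
    drift = {n: 0.01 for n, p in rooted.items() if p is not None}
    g = PopulationGraph(rooted, drift, [], outgroup)
    g, _ = fit_drift(g, cov, weight_by_se)
    return g


def _edge_candidates(graph: PopulationGraph):
    """(donor branch, destination node) pairs in deterministic lexicographic
    order; structurally invalid pairs are skipped at construction time."""
    non_root = sorted(n for n, p in graph.parents.items() if p is not None)
    taken = {m.dest for m in graph.migrations}
    for donor in non_root:
        for dest in non_root:
            if dest == donor or dest in taken:
                continue
            yield donor, dest


def fit_admixture_graphs(
    cov: CovarianceEstimate,
    outgroup: str,
    max_edges: int = 8,
    restarts: int = 20,
    seed: int = 0,
    weight_by_se: bool = False,
    init_weights: tuple[float, ...] = (0.1, 0.4),
) -> list[FitResult]:
    """Greedy nested search over graphs with 0..max_edges migration edges.

    The 0-edge tree is fit from ``restarts`` starting topologies (the NJ tree
    plus NNI-perturbed variants, k ~ 1 + Poisson(1) moves per restart); the
    best m-edge graph seeds the (m+1)-edge search, whose candidate edges are
    enumerated over ordered branch pairs with each weight initialised at each
    value in ``init_weights``.
    """
    if max_edges < 0 or restarts < 1:
        raise ValueError("max_edges must be >= 0 and restarts >= 1")
    rng = np.random.default_rng(seed)
    base = tree_from_covariance(cov, outgroup, weight_by_se)
    log0: list[float] = []
    best_tree, best_obj = None, np.inf
    for r in range(restarts):
        topo = base
        if r > 0:
            k = 1 + rng.poisson(1.0)
            for _ in range(k):
                try:
                    topo = random_nni(topo, rng)
                except GraphError:
                    break
        try:
            g, obj = fit_drift(topo, cov, weight_by_se)
        except ModelError:
            continue
        log0.append(obj)
        if obj < best_obj:
            best_tree, best_obj = g, obj
    res0 = _result(best_tree, cov, best_obj, True)
    res0.restart_log = log0
    res0.seed = seed
    results = [res0]
    current = best_tree
    for m in range(1, max_edges + 1):
        # cheap screen of all candidate edges, then full refinement of the best few
        screened: list[tuple[float, PopulationGraph]] = []
        for donor, dest in _edge_candidates(current):
            for w0 in init_weights:
                try:
                    g, _ = current.add_migration_from_branch(donor, dest, w0)
                    fit = fit_parameters(g, cov, weight_by_se, max_iter=2)
                except (GraphError, ModelError):
                    continue
                screened.append((fit.objective, fit.graph))
        if not screened:
            break
        screened.sort(key=lambda t: t[0])
        cand_best, cand_obj = None, np.inf
        for _, g in screened[:3]:
            try:
                fit = fit_parameters(g, cov, weight_by_se, max_iter=100)
            except (GraphError, ModelError):
                continue
            if fit.objective < cand_obj:
                cand_best, cand_obj = fit, fit.objective
        if cand_best is None:
            break
        cand_best.seed = seed
        results.append(cand_best)
        current = cand_best.graph
    return results
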