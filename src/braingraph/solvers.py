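"""Exact combinatorial graph parameters.

Four parameters need optimization machinery:

``MinCutBalDivSum``
    minimum bisection width — the smallest total weight of edges crossing a
    vertex partition into two sides whose sizes differ by at most one —
    normalized by the total edge weight.  NP-hard; solved exactly, either by
    exhaustive enumeration (tiny graphs) or a 0/1 integer program.
``MinSpanningForest``
    minimum-cost spanning forest via Kruskal's algorithm (one tree per
    connected component); not defined for the unweighted scheme.
``MinVertexCover``
    fractional vertex cover: minimize the sum of nonnegative node values
    subject to ``x_u + x_v >= w(u, v)`` per edge — the LP relaxation of
    vertex cover, with the edge weight as the covering requirement.
``MinVertexCoverBinary``
    classical minimum vertex cover (0/1 values, requirement 1), NP-hard;
    solved exactly by integer programming.  Unweighted scheme only.

Brute-force enumeration oracles for all four problems are provided for
cross-checking on small instances.

The LP/ILP backend is the HiGHS solver behind :func:`scipy.optimize.milp` /
:func:`scipy.optimize.linprog`; optimality gap 0 is required and a time
limit raises :class:`SolverError` rather than returning an approximation.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import networkx as nx
import numpy as np
import scipy.sparse as sp
from scipy.optimize import Bounds, LinearConstraint, linprog, milp

from .graph_core import InputError, WeightedGraph, WeightScheme
from .graph_metrics import sum_weights

__all__ = [
    "Bisection",
    "VertexCoverSolution",
    "SolverError",
    "ConfigurationError",
    "min_balanced_bisection",
    "min_cut_bal_div_sum",
    "min_spanning_forest_cost",
    "min_fractional_vertex_cover",
    "min_binary_vertex_cover",
    "brute_force_oracle",
    "brute_min_bisection",
    "brute_min_vertex_cover",
    "brute_min_fractional_cover",
    "brute_min_spanning_forest",
    "brute_spanning_forest_weight",
]

#: default per-instance wall-clock limit for the MILP backend, seconds
DEFAULT_TIME_LIMIT = 600.0

# enumeration is faster than the ILP below roughly this many candidate
# bisections (covers n <= 21)
_ENUM_LIMIT = 200_000


class SolverError(RuntimeError):
    """Optimization backend failed or hit its time limit (no silent fallback)."""

    def __init__(self, message: str, best_bound: float | None = None):
        super().__init__(message)
        self.best_bound = best_bound


class ConfigurationError(ValueError):
    """A parameter was requested under an incompatible weight scheme."""


@dataclass(frozen=True)
class Bisection:
    """A balanced vertex partition and the weight of its cut."""

    side: dict[str, str]  # node -> "X" | "Y"
    cut_weight: float

    def partition(self) -> tuple[frozenset[str], frozenset[str]]:
        x = frozenset(v for v, s in self.side.items() if s == "X")
        y = frozenset(v for v, s in self.side.items() if s == "Y")
        return x, y


@dataclass(frozen=True)
class VertexCoverSolution:
    x: dict[str, float]
    objective: float


def _check_scheme(graph: WeightedGraph, forbid_unweighted: bool, name: str) -> None:
    if graph.scheme is None:
        return
    if forbid_unweighted and graph.scheme is WeightScheme.UNWEIGHTED:
        raise ConfigurationError(f"{name} is not defined for the Unweighted scheme")
    if not forbid_unweighted and graph.scheme is not WeightScheme.UNWEIGHTED:
        raise ConfigurationError(f"{name} is defined only for the Unweighted scheme")


# ---------------------------------------------------------------------------
# balanced minimum cut
# ---------------------------------------------------------------------------

def _bisection_from_mask(graph: WeightedGraph, in_x: np.ndarray) -> Bisection:
    cut = float(graph.w[in_x[graph.iu] != in_x[graph.iv]].sum())
    side = {
        name: ("X" if in_x[i] else "Y") for i, name in enumerate(graph.nodes)
    }
    return Bisection(side, cut)


def _enumerate_bisection(graph: WeightedGraph) -> Bisection:
    n = graph.n
    size_x = (n + 1) // 2
    # node 0 (lexicographically smallest) is fixed to side X: every bisection
    # or its mirror contains it, so optimality is preserved
    if size_x == 1:
        mask = np.zeros(n, dtype=bool)
        mask[0] = True
        return _bisection_from_mask(graph, mask)
    best_cut = math.inf
    best_mask: np.ndarray | None = None
    combo_iter = itertools.combinations(range(1, n), size_x - 1)
    while True:  # vectorize the cut evaluation in bounded-memory chunks
        chunk = list(itertools.islice(combo_iter, 20_000))
        if not chunk:
            break
        combos = np.asarray(chunk, dtype=np.intp)
        in_x = np.zeros((len(combos), n), dtype=bool)
        in_x[:, 0] = True
        np.put_along_axis(in_x, combos, True, axis=1)
        cuts = (in_x[:, graph.iu] != in_x[:, graph.iv]) @ graph.w
        i = int(np.argmin(cuts))
        if cuts[i] < best_cut:
            best_cut = float(cuts[i])
            best_mask = in_x[i].copy()
    assert best_mask is not None
    return _bisection_from_mask(graph, best_mask)


def _ilp_bisection(graph: WeightedGraph, time_limit: float) -> Bisection:
    n, m = graph.n, graph.n_edges
    nv = n + m  # y_v binary side indicators, z_e cut indicators
    integrality = np.concatenate([np.ones(n), np.zeros(m)])
    lb = np.zeros(nv)
    ub = np.ones(nv)
    lb[0] = 1.0  # symmetry breaking: smallest node on side X
    c = np.concatenate([np.zeros(n), graph.w])
    balance = sp.csr_matrix(
        (np.ones(n), (np.zeros(n, int), np.arange(n))), shape=(1, nv)
    )
    size_x = float((n + 1) // 2)
    rows, cols, vals = [], [], []
    for k in range(m):
        u, v = int(graph.iu[k]), int(graph.iv[k])
        # z_e - y_u + y_v >= 0  and  z_e + y_u - y_v >= 0
        rows += [2 * k] * 3 + [2 * k + 1] * 3
        cols += [n + k, u, v, n + k, u, v]
        vals += [1.0, -1.0, 1.0, 1.0, 1.0, -1.0]
    cut_cons = sp.csr_matrix((vals, (rows, cols)), shape=(2 * m, nv))
    res = milp(
        c,
        constraints=[
            LinearConstraint(balance, size_x, size_x),
            LinearConstraint(cut_cons, 0.0, np.inf),
        ],
        integrality=integrality,
        bounds=Bounds(lb, ub),
        options={"time_limit": time_limit, "mip_rel_gap": 0.0},
    )
    if res.status != 0:
        raise SolverError(
            f"bisection ILP did not reach optimality (status {res.status}: "
            f"{res.message})",
            best_bound=getattr(res, "mip_dual_bound", None),
        )
    in_x = np.asarray(res.x[:n]) > 0.5
    return _bisection_from_mask(graph, in_x)


def min_balanced_bisection(
    graph: WeightedGraph,
    method: str = "auto",
    time_limit: float = DEFAULT_TIME_LIMIT,
) -> Bisection:
    """Exact minimum bisection (balanced minimum cut).

    ``method`` is ``"auto"`` (enumeration for tiny graphs, ILP otherwise),
    ``"ilp"`` or ``"enumeration"``.  Both routes are exact.
    """
    if graph.n < 2:
        raise ValueError("bisection needs at least 2 nodes")
    if method == "auto":
        n_candidates = math.comb(graph.n - 1, (graph.n + 1) // 2 - 1)
        method = "enumeration" if n_candidates <= _ENUM_LIMIT else "ilp"
    if method == "enumeration":
        return _enumerate_bisection(graph)
    if method == "ilp":
        return _ilp_bisection(graph, time_limit)
    raise ValueError(f"unknown bisection method {method!r}")


def min_cut_bal_div_sum(
    graph: WeightedGraph,
    method: str = "auto",
    time_limit: float = DEFAULT_TIME_LIMIT,
) -> float:
    """Minimum bisection width divided by the total edge weight.

    Scale-invariant: multiplying all weights by a constant changes neither
    the optimal partition nor the ratio.  NaN for edgeless graphs.
    """
    if graph.n_edges == 0:
        return float("nan")
    bisection = min_balanced_bisection(graph, method=method, time_limit=time_limit)
    return bisection.cut_weight / sum_weights(graph)


# ---------------------------------------------------------------------------
# minimum spanning forest (Kruskal)
# ---------------------------------------------------------------------------

def min_spanning_forest_cost(graph: WeightedGraph) -> float:
    """Total weight of a minimum spanning forest, via Kruskal's algorithm.

    Equal-weight edges are taken in lexicographic endpoint order (the cost is
    tie-invariant; the tree itself is thereby deterministic).  Not defined
    for the unweighted scheme, where every spanning forest costs the same.
    """
    _check_scheme(graph, forbid_unweighted=True, name="MinSpanningForest")
    if graph.n_edges == 0:
        return 0.0
    g = graph.to_networkx()  # edges inserted in lexicographic order
    return float(
        sum(
            d["weight"]
            for _, _, d in nx.minimum_spanning_edges(g, algorithm="kruskal")
        )
    )


# ---------------------------------------------------------------------------
# vertex covers
# ---------------------------------------------------------------------------

def _cover_matrix(graph: WeightedGraph) -> sp.csr_matrix:
    m, n = graph.n_edges, graph.n
    rows = np.repeat(np.arange(m), 2)
    cols = np.empty(2 * m, dtype=int)
    cols[0::2] = graph.iu
    cols[1::2] = graph.iv
    return sp.csr_matrix((np.ones(2 * m), (rows, cols)), shape=(m, n))


def min_fractional_vertex_cover(graph: WeightedGraph) -> VertexCoverSolution:
    """Exact LP optimum of the fractional vertex cover.

    Constraint per edge: ``x_u + x_v >= w(u, v)``; for the unweighted scheme
    this is the classical relaxation with requirement 1, whose optimum is
    half-integral.
    """
    if graph.n_edges == 0:
        return VertexCoverSolution({v: 0.0 for v in graph.nodes}, 0.0)
    A = _cover_matrix(graph)
    res = linprog(
        c=np.ones(graph.n),
        A_ub=-A,
        b_ub=-graph.w,
        bounds=(0, None),
        method="highs",
    )
    if not res.success:
        raise SolverError(f"fractional vertex cover LP failed: {res.message}")
    x = {v: float(res.x[i]) for i, v in enumerate(graph.nodes)}
    return VertexCoverSolution(x, float(res.fun))


def min_binary_vertex_cover(
    graph: WeightedGraph, time_limit: float = DEFAULT_TIME_LIMIT
) -> int:
    """Exact minimum-cardinality vertex cover via integer programming."""
    _check_scheme(graph, forbid_unweighted=False, name="MinVertexCoverBinary")
    if graph.n_edges == 0:
        return 0
    A = _cover_matrix(graph)
    res = milp(
        c=np.ones(graph.n),
        constraints=[LinearConstraint(A, 1.0, np.inf)],
        integrality=np.ones(graph.n),
        bounds=Bounds(0, 1),
        options={"time_limit": time_limit, "mip_rel_gap": 0.0},
    )
    if res.status != 0:
        raise SolverError(
            f"binary vertex cover ILP did not reach optimality: {res.message}",
            best_bound=getattr(res, "mip_dual_bound", None),
        )
    return int(round(res.fun))


# ---------------------------------------------------------------------------
# brute-force oracles (test cross-checks; exhaustive enumeration)
# ---------------------------------------------------------------------------

_BISECTION_MAX_N = 16
_COVER_MAX_N = 16
_FOREST_MAX_N = 8


def brute_min_bisection(graph: WeightedGraph) -> float:
    """Exhaustive minimum bisection width (n <= 16)."""
    if graph.n > _BISECTION_MAX_N:
        raise ValueError(f"brute-force bisection limited to n <= {_BISECTION_MAX_N}")
    return _enumerate_bisection(graph).cut_weight


def brute_min_vertex_cover(graph: WeightedGraph) -> int:
    """Exhaustive minimum vertex cover cardinality (n <= 16)."""
    if graph.n > _COVER_MAX_N:
        raise ValueError(f"brute-force cover limited to n <= {_COVER_MAX_N}")
    if graph.n_edges == 0:
        return 0
    edges = list(zip(graph.iu, graph.iv))
    for size in range(0, graph.n + 1):
        for subset in itertools.combinations(range(graph.n), size):
            chosen = set(subset)
            if all(u in chosen or v in chosen for u, v in edges):
                return size
    raise AssertionError("unreachable: the full vertex set is always a cover")


def brute_min_fractional_cover(graph: WeightedGraph) -> float:
    """Exhaustive fractional cover for unweighted graphs (n <= 8).

    Searches the half-integral grid {0, 1/2, 1}^n, which contains an optimum
    of the unweighted relaxation (half-integrality of the vertex-cover LP).
    """
    if graph.n > _FOREST_MAX_N:
        raise ValueError("brute-force fractional cover limited to n <= 8")
    if graph.scheme not in (None, WeightScheme.UNWEIGHTED):
        raise ConfigurationError("fractional brute force assumes unit requirements")
    if graph.n_edges == 0:
        return 0.0
    edges = list(zip(graph.iu, graph.iv))
    best = math.inf
    for x in itertools.product((0.0, 0.5, 1.0), repeat=graph.n):
        if all(x[u] + x[v] >= 1.0 for u, v in edges):
            best = min(best, sum(x))
    return best


def _component_edge_lists(
    graph: WeightedGraph,
) -> list[tuple[list[int], list[tuple[int, int, float]]]]:
    g = graph.to_networkx()
    index = {v: i for i, v in enumerate(graph.nodes)}
    out = []
    for comp in nx.connected_components(g):
        nodes = sorted(index[v] for v in comp)
        node_set = set(nodes)
        edges = [
            (int(u), int(v), float(w))
            for u, v, w in zip(graph.iu, graph.iv, graph.w)
            if u in node_set
        ]
        out.append((nodes, edges))
    return out


def _spanning_trees_of_component(
    nodes: list[int], edges: list[tuple[int, int, float]]
):
    """Yield (total_weight, weight_product) over all spanning trees."""
    k = len(nodes)
    if k == 1:
        yield 0.0, 1.0
        return
    relabel = {v: i for i, v in enumerate(nodes)}
    for subset in itertools.combinations(edges, k - 1):
        parent = list(range(k))

        def find(a: int) -> int:
            while parent[a] != a:
                parent[a] = parent[parent[a]]
                a = parent[a]
            return a

        acyclic = True
        for u, v, _ in subset:
            ru, rv = find(relabel[u]), find(relabel[v])
            if ru == rv:
                acyclic = False
                break
            parent[ru] = rv
        if acyclic:
            total = sum(w for _, _, w in subset)
            prod = math.prod(w for _, _, w in subset)
            yield total, prod


def brute_min_spanning_forest(graph: WeightedGraph) -> float:
    """Exhaustive minimum spanning-forest cost (n <= 8)."""
    if graph.n > _FOREST_MAX_N:
        raise ValueError(f"brute-force forest limited to n <= {_FOREST_MAX_N}")
    total = 0.0
    for nodes, edges in _component_edge_lists(graph):
        total += min(t for t, _ in _spanning_trees_of_component(nodes, edges))
    return total


def brute_spanning_forest_weight(graph: WeightedGraph) -> float:
    """Exhaustive weighted spanning-forest count (n <= 8).

    Product over components of the sum over spanning trees of the product of
    edge weights — the quantity the matrix-tree theorem computes.
    """
    if graph.n > _FOREST_MAX_N:
        raise ValueError(f"brute-force forest limited to n <= {_FOREST_MAX_N}")
    result = 1.0
    for nodes, edges in _component_edge_lists(graph):
        result *= sum(p for _, p in _spanning_trees_of_component(nodes, edges))
    return result


def brute_force_oracle(graph: WeightedGraph, problem: str) -> float:
    """Dispatch to the exhaustive oracle for ``bisection``, ``vertex_cover``
    or ``spanning_forest`` (minimum cost)."""
    if problem == "bisection":
        return brute_min_bisection(graph)
    if problem == "vertex_cover":
        return float(brute_min_vertex_cover(graph))
    if problem == "spanning_forest":
        return brute_min_spanning_forest(graph)
    raise ValueError(f"unknown oracle problem {problem!r}")
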