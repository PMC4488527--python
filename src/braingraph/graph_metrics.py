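"""Spectral and counting graph parameters.

All parameters operate on the generalized (weighted) adjacency matrix ``A``,
its degree diagonal ``D``, the Laplacian ``L = D - A`` and the walk
transition matrix ``P_G = D^-1 A`` of a :class:`~braingraph.graph_core.WeightedGraph`:

``Sum``
    total edge weight (the edge count in the unweighted case).
``AdjLMaxDivD``
    largest adjacency eigenvalue divided by the average generalized degree
    ``2 * Sum / n`` — a density-normalized spectral radius.
``PGEigengap``
    difference of the two largest eigenvalues of ``P_G``; a large gap means
    fast random-walk mixing, i.e. a good expander.  Computed on the similar
    symmetric matrix ``D^-1/2 A D^-1/2``; degree-0 nodes self-transition with
    probability 1, so any disconnected graph has eigengap 0.
``HoffmanBound``
    ``1 + lambda_max / |lambda_min|``, a spectral lower bound on the
    chromatic number.
``LogSpanningForestN``
    natural log of the weighted number of spanning forests: by the
    matrix-tree theorem, the product over connected components of the sum
    over spanning trees of the product of edge weights.  Equivalent to the
    product of the non-zero Laplacian eigenvalues divided by the component
    sizes; may be negative when many weights are below 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components

from .graph_core import WeightedGraph

__all__ = [
    "SpectralSummary",
    "spectral_summary",
    "sum_weights",
    "adj_lmax_div_d",
    "pg_eigengap",
    "hoffman_bound",
    "log_spanning_forest_count",
    "graph_components",
]

_EIG_TOL = 1e-9


def graph_components(graph: WeightedGraph) -> tuple[int, np.ndarray]:
    """Number of connected components and per-node component labels."""
    if graph.n == 0:
        return 0, np.zeros(0, dtype=int)
    adj = sp.csr_matrix(
        (np.ones(graph.n_edges), (graph.iu, graph.iv)), shape=(graph.n, graph.n)
    )
    return connected_components(adj, directed=False)


@dataclass(frozen=True)
class SpectralSummary:
    """Shared eigen-decompositions backing the spectral parameters."""

    adjacency_spectrum: np.ndarray  # ascending
    transition_spectrum: np.ndarray  # ascending, of D^-1/2 A D^-1/2
    laplacian_spectrum: np.ndarray  # ascending
    component_sizes: tuple[int, ...]

    @property
    def lambda_max_adj(self) -> float:
        return float(self.adjacency_spectrum[-1])

    @property
    def lambda_min_adj(self) -> float:
        return float(self.adjacency_spectrum[0])

    @property
    def mu_1(self) -> float:
        return float(self.transition_spectrum[-1])

    @property
    def mu_2(self) -> float:
        return float(self.transition_spectrum[-2])


def _symmetrized_transition(graph: WeightedGraph) -> np.ndarray:
    d = graph.degrees
    s = np.ones_like(d)
    pos = d > 0
    s[pos] = 1.0 / np.sqrt(d[pos])
    S = s[:, None] * graph.adjacency * s[None, :]
    # degree-0 nodes keep a self-transition of 1 (stochasticity convention)
    S[~pos, ~pos] = 1.0
    return S


def spectral_summary(graph: WeightedGraph) -> SpectralSummary:
    """Dense symmetric eigen-decompositions of A, D^-1/2 A D^-1/2 and L."""
    if graph.n == 0:
        raise ValueError("spectral summary of the empty graph is undefined")
    try:
        adj_spec = np.linalg.eigvalsh(graph.adjacency)
        trans_spec = np.linalg.eigvalsh(_symmetrized_transition(graph))
        lap_spec = np.linalg.eigvalsh(graph.laplacian)
    except np.linalg.LinAlgError as exc:  # pragma: no cover
        raise RuntimeError(f"eigen-solver failed on {graph.n}-node graph") from exc
    n_comp, labels = graph_components(graph)
    sizes = tuple(int(c) for c in np.bincount(labels, minlength=n_comp))
    return SpectralSummary(adj_spec, trans_spec, lap_spec, sizes)


def sum_weights(graph: WeightedGraph) -> float:
    """Total edge weight (``Sum``); the edge count for the unweighted scheme."""
    return float(graph.w.sum())


def adj_lmax_div_d(
    graph: WeightedGraph, summary: SpectralSummary | None = None
) -> float:
    """Largest adjacency eigenvalue over the average generalized degree.

    The average degree counts every node, including isolated ones.  NaN for
    edgeless graphs.
    """
    if graph.n_edges == 0:
        return float("nan")
    summary = summary or spectral_summary(graph)
    avg_degree = 2.0 * sum_weights(graph) / graph.n
    return summary.lambda_max_adj / avg_degree


def pg_eigengap(
    graph: WeightedGraph, summary: SpectralSummary | None = None
) -> float:
    """Eigengap ``mu_1 - mu_2`` of the walk transition matrix.

    0 exactly when the graph (with the degree-0 self-transition convention)
    is disconnected; always in ``[0, 2]``.
    """
    if graph.n < 2:
        raise ValueError("eigengap needs at least 2 nodes")
    summary = summary or spectral_summary(graph)
    gap = summary.mu_1 - summary.mu_2
    # transition eigenvalues lie in [-1, 1]; clamp float spill at the ends
    return float(min(max(gap, 0.0), 2.0))


def hoffman_bound(
    graph: WeightedGraph, summary: SpectralSummary | None = None
) -> float:
    """Hoffman's chromatic-number lower bound ``1 + lambda_max/|lambda_min|``."""
    if graph.n_edges == 0:
        return float("nan")
    summary = summary or spectral_summary(graph)
    return 1.0 + summary.lambda_max_adj / abs(summary.lambda_min_adj)


def log_spanning_forest_count(
    graph: WeightedGraph, summary: SpectralSummary | None = None
) -> float:
    """Natural log of the weighted spanning-forest count (matrix-tree theorem).

    For each connected component ``C`` the weighted tree count is
    ``tau_w(C) = (prod of C's non-zero Laplacian eigenvalues) / |C|``; the
    forest count is the product over components, single vertices contributing
    a factor 1.  Returns ``-inf`` with a warning if the product underflows to
    a non-positive value numerically (weights are positive, so the true value
    is always > 0).
    """
    if graph.n == 0:
        return 0.0
    if graph.n_edges == 0:
        return 0.0  # every component a single vertex: exactly one (empty) forest
    summary = summary or spectral_summary(graph)
    k = len(summary.component_sizes)
    # drop the k zero eigenvalues (one per component), by count not threshold
    nonzero = np.sort(summary.laplacian_spectrum)[k:]
    if np.any(nonzero <= _EIG_TOL * max(1.0, float(np.max(nonzero, initial=0.0)))):
        warnings.warn(
            "numerically singular Laplacian beyond the component kernel; "
            "spanning-forest count reported as -inf",
            RuntimeWarning,
            stacklevel=2,
        )
        return float("-inf")
    log_tau = float(np.log(nonzero).sum())
    log_tau -= float(np.log(summary.component_sizes).sum())
    return log_tau
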