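"""Core connectome graph types, construction and I/O.

A structural brain graph (connectome) has one node per parcellation region
(ROI) and one undirected edge per ROI pair connected by at least one
tractography streamline.  Each edge carries a fiber-bundle summary — the
streamline count, the mean fiber length in mm and the mean fractional
anisotropy (FA) — from which five alternative edge weights are derived:

* ``Unweighted``       — every edge has weight 1;
* ``FiberN``           — the streamline count;
* ``FAMean``           — the mean fractional anisotropy;
* ``FiberLengthMean``  — the mean fiber length (mm);
* ``FiberNDivLength``  — count / mean length, the electrical conductance of
  the bundle when each fiber is modelled as a resistor proportional to its
  length.

The generalized adjacency matrix ``A`` holds the edge weights, the
generalized degree of a node is the row sum of ``A``, the Laplacian is
``D - A`` and the walk transition matrix divides each row of ``A`` by the
node's generalized degree.  Self-loops are always removed.
"""

from __future__ import annotations

import csv
import enum
import logging
import math
from dataclasses import dataclass, field
from functools import cached_property
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "FiberBundleRecord",
    "Parcellation",
    "WeightScheme",
    "WeightedGraph",
    "Scope",
    "InputError",
    "apply_weight_scheme",
    "build_graph",
    "subgraph_by_scope",
    "read_fiber_table",
    "write_fiber_table",
    "read_parcellation",
    "write_parcellation",
    "read_graph",
    "write_graph",
    "FIBER_TABLE_COLUMNS",
]

FIBER_TABLE_COLUMNS = ("node_u", "node_v", "fiber_count", "mean_length", "mean_fa")


class InputError(ValueError):
    """Malformed or inconsistent user input (exit code 1 in the CLI)."""


class WeightScheme(str, enum.Enum):
    """The five edge-weight functions."""

    UNWEIGHTED = "Unweighted"
    FIBER_N = "FiberN"
    FA_MEAN = "FAMean"
    FIBER_LENGTH_MEAN = "FiberLengthMean"
    FIBER_N_DIV_LENGTH = "FiberNDivLength"

    @classmethod
    def coerce(cls, value: "WeightScheme | str") -> "WeightScheme":
        if isinstance(value, cls):
            return value
        try:
            return cls(value)
        except ValueError:
            raise InputError(
                f"unknown weight scheme {value!r}; expected one of "
                f"{[s.value for s in cls]}"
            ) from None


class Scope(str, enum.Enum):
    """Hemisphere scope: one hemisphere's induced subgraph, or the whole graph."""

    LEFT = "Left"
    RIGHT = "Right"
    ALL = "All"

    @classmethod
    def coerce(cls, value: "Scope | str") -> "Scope":
        if isinstance(value, cls):
            return value
        try:
            return cls(value)
        except ValueError:
            raise InputError(f"unknown scope {value!r}") from None


@dataclass(frozen=True)
class FiberBundleRecord:
    """Tractography summary for one unordered ROI pair."""

    node_u: str
    node_v: str
    fiber_count: int
    mean_length: float
    mean_fa: float

    def __post_init__(self) -> None:
        if self.fiber_count < 1:
            raise InputError(f"fiber_count must be >= 1, got {self.fiber_count}")
        if not self.mean_length > 0:
            raise InputError(f"mean_length must be > 0, got {self.mean_length}")
        if not 0.0 <= self.mean_fa <= 1.0:
            raise InputError(f"mean_fa must lie in [0, 1], got {self.mean_fa}")


@dataclass(frozen=True)
class Parcellation:
    """A brain parcellation: ROI identifiers and their hemisphere labels.

    ``hemisphere`` maps every node to ``"left"``, ``"right"`` or ``"other"``
    (midline / brainstem structures that belong to neither hemisphere).
    """

    nodes: tuple[str, ...]
    hemisphere: Mapping[str, str]

    def __post_init__(self) -> None:
        if len(set(self.nodes)) != len(self.nodes):
            raise InputError("parcellation node identifiers must be unique")
        missing = [n for n in self.nodes if n not in self.hemisphere]
        if missing:
            raise InputError(f"nodes missing a hemisphere label: {missing[:5]}")
        bad = {h for h in self.hemisphere.values()} - {"left", "right", "other"}
        if bad:
            raise InputError(f"invalid hemisphere labels: {sorted(bad)}")

    @property
    def resolution(self) -> int:
        return len(self.nodes)

    def nodes_in_scope(self, scope: Scope | str) -> tuple[str, ...]:
        scope = Scope.coerce(scope)
        if scope is Scope.ALL:
            return tuple(self.nodes)
        label = "left" if scope is Scope.LEFT else "right"
        return tuple(n for n in self.nodes if self.hemisphere[n] == label)


def apply_weight_scheme(
    record: FiberBundleRecord, scheme: WeightScheme | str
) -> float:
    """Edge weight of a fiber bundle under one of the five weight functions.

    A weight of exactly 0 (possible only for ``FAMean`` with ``mean_fa == 0``)
    means "no edge"; :func:`build_graph` drops such edges and logs the count.
    """
    scheme = WeightScheme.coerce(scheme)
    if scheme is WeightScheme.UNWEIGHTED:
        return 1.0
    if scheme is WeightScheme.FIBER_N:
        return float(record.fiber_count)
    if scheme is WeightScheme.FA_MEAN:
        return float(record.mean_fa)
    if scheme is WeightScheme.FIBER_LENGTH_MEAN:
        return float(record.mean_length)
    return record.fiber_count / record.mean_length  # FiberNDivLength


# vectorized weight computation used by build_graph on fiber-table frames
def _weights_from_frame(frame: pd.DataFrame, scheme: WeightScheme) -> np.ndarray:
    if scheme is WeightScheme.UNWEIGHTED:
        return np.ones(len(frame))
    if scheme is WeightScheme.FIBER_N:
        return frame["fiber_count"].to_numpy(float)
    if scheme is WeightScheme.FA_MEAN:
        return frame["mean_fa"].to_numpy(float)
    if scheme is WeightScheme.FIBER_LENGTH_MEAN:
        return frame["mean_length"].to_numpy(float)
    return frame["fiber_count"].to_numpy(float) / frame["mean_length"].to_numpy(float)


@dataclass
class WeightedGraph:
    """Undirected weighted graph with matrix views for spectral analysis.

    Nodes are opaque strings; matrix row/column order is lexicographic in the
    node identifier, fixed at construction.  Edge endpoints are stored as
    index arrays ``iu < iv`` into :attr:`nodes` together with the positive
    weight array ``w``.
    """

    nodes: tuple[str, ...]
    iu: np.ndarray
    iv: np.ndarray
    w: np.ndarray
    scheme: WeightScheme | None = None

    def __post_init__(self) -> None:
        if list(self.nodes) != sorted(self.nodes):
            raise ValueError("nodes must be lexicographically sorted")
        self.iu = np.asarray(self.iu, dtype=np.intp)
        self.iv = np.asarray(self.iv, dtype=np.intp)
        self.w = np.asarray(self.w, dtype=float)
        if np.any(self.iu == self.iv):
            raise ValueError("self-loops are not allowed")
        if np.any(self.w <= 0):
            raise ValueError("edge weights must be positive")

    # -- basic views -------------------------------------------------------
    @property
    def n(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.w)

    def edge_dict(self) -> dict[tuple[str, str], float]:
        return {
            (self.nodes[u], self.nodes[v]): wt
            for u, v, wt in zip(self.iu, self.iv, self.w)
        }

    @cached_property
    def adjacency(self) -> np.ndarray:
        """Generalized adjacency matrix (symmetric, zero diagonal)."""
        A = np.zeros((self.n, self.n))
        A[self.iu, self.iv] = self.w
        A[self.iv, self.iu] = self.w
        return A

    @cached_property
    def degrees(self) -> np.ndarray:
        """Generalized degrees: row sums of the adjacency matrix."""
        d = np.zeros(self.n)
        np.add.at(d, self.iu, self.w)
        np.add.at(d, self.iv, self.w)
        return d

    @cached_property
    def laplacian(self) -> np.ndarray:
        return np.diag(self.degrees) - self.adjacency

    def transition_matrix(self) -> np.ndarray:
        """Row-stochastic walk matrix; degree-0 nodes self-transition with 1."""
        d = self.degrees
        P = np.zeros((self.n, self.n))
        pos = d > 0
        P[pos] = self.adjacency[pos] / d[pos, None]
        P[~pos, ~pos] = 1.0
        return P

    # -- constructors ------------------------------------------------------
    @classmethod
    def from_edge_weights(
        cls,
        nodes: Iterable[str],
        edges: Mapping[tuple[str, str], float],
        scheme: WeightScheme | None = None,
    ) -> "WeightedGraph":
        node_list = tuple(sorted(set(nodes)))
        index = {v: i for i, v in enumerate(node_list)}
        iu, iv, w = [], [], []
        for (a, b), wt in sorted(edges.items()):
            i, j = index[a], index[b]
            if i > j:
                i, j = j, i
            iu.append(i)
            iv.append(j)
            w.append(float(wt))
        return cls(node_list, np.array(iu, int), np.array(iv, int),
                   np.array(w, float), scheme)

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        g.add_weighted_edges_from(
            (self.nodes[u], self.nodes[v], float(wt))
            for u, v, wt in zip(self.iu, self.iv, self.w)
        )
        return g


def _as_fiber_frame(
    records: pd.DataFrame | Iterable[FiberBundleRecord],
) -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        missing = set(FIBER_TABLE_COLUMNS) - set(records.columns)
        if missing:
            raise InputError(f"fiber table missing columns: {sorted(missing)}")
        return records
    rows = [
        (r.node_u, r.node_v, r.fiber_count, r.mean_length, r.mean_fa)
        for r in records
    ]
    return pd.DataFrame(rows, columns=list(FIBER_TABLE_COLUMNS))


def build_graph(
    records: pd.DataFrame | Iterable[FiberBundleRecord],
    parcellation: Parcellation,
    scheme: WeightScheme | str,
) -> WeightedGraph:
    """Build the weighted connectome from per-ROI-pair fiber records.

    Self-loop records are discarded; duplicate unordered ROI pairs are an
    input error (fiber tables must be pre-aggregated per pair); parcellation
    nodes with no fibers are kept as isolated degree-0 vertices.
    """
    scheme = WeightScheme.coerce(scheme)
    frame = _as_fiber_frame(records)
    node_list = tuple(sorted(parcellation.nodes))
    index = {v: i for i, v in enumerate(node_list)}

    u_names = frame["node_u"].astype(str).to_numpy()
    v_names = frame["node_v"].astype(str).to_numpy()
    unknown = [x for x in set(u_names) | set(v_names) if x not in index]
    if unknown:
        raise InputError(
            f"fiber record endpoints not in parcellation: {sorted(unknown)[:5]}"
        )

    iu = np.array([index[x] for x in u_names], dtype=np.intp)
    iv = np.array([index[x] for x in v_names], dtype=np.intp)
    keep = iu != iv
    n_loops = int((~keep).sum())
    if n_loops:
        logger.debug("deleted %d self-loop record(s)", n_loops)
    frame = frame.loc[keep]
    iu, iv = iu[keep], iv[keep]
    lo, hi = np.minimum(iu, iv), np.maximum(iu, iv)
    pair_keys = lo * len(node_list) + hi
    if len(np.unique(pair_keys)) != len(pair_keys):
        raise InputError(
            "duplicate unordered ROI pair in fiber records; "
            "aggregate per pair upstream"
        )

    w = _weights_from_frame(frame, scheme)
    pos = w > 0
    n_dropped = int((~pos).sum())
    if n_dropped:
        logger.info("dropped %d zero-weight edge(s) under %s", n_dropped, scheme.value)
    order = np.argsort(pair_keys[pos], kind="stable")
    return WeightedGraph(node_list, lo[pos][order], hi[pos][order],
                         w[pos][order], scheme)


def subgraph_by_scope(
    graph: WeightedGraph, parcellation: Parcellation, scope: Scope | str
) -> WeightedGraph:
    """Induced subgraph on one hemisphere's nodes, or the whole graph.

    ``Left``/``Right`` exclude midline "other" nodes; ``All`` is the identity.
    """
    scope = Scope.coerce(scope)
    if scope is Scope.ALL:
        return graph
    keep_names = set(parcellation.nodes_in_scope(scope))
    keep = np.array([name in keep_names for name in graph.nodes])
    new_nodes = tuple(name for name in graph.nodes if name in keep_names)
    remap = np.full(graph.n, -1, dtype=np.intp)
    remap[keep] = np.arange(len(new_nodes))
    mask = keep[graph.iu] & keep[graph.iv]
    return WeightedGraph(
        new_nodes, remap[graph.iu[mask]], remap[graph.iv[mask]],
        graph.w[mask], graph.scheme,
    )


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------

def read_fiber_table(path: str | Path) -> pd.DataFrame:
    """Read a per-subject fiber-bundle CSV and validate record invariants."""
    path = Path(path)
    try:
        frame = pd.read_csv(path, dtype={"node_u": str, "node_v": str})
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise InputError(f"{path}: cannot parse fiber table: {exc}") from exc
    missing = set(FIBER_TABLE_COLUMNS) - set(frame.columns)
    if missing:
        raise InputError(f"{path}: missing columns {sorted(missing)}")
    bad = (
        (frame["fiber_count"] < 1)
        | (frame["mean_length"] <= 0)
        | (frame["mean_fa"] < 0)
        | (frame["mean_fa"] > 1)
    )
    if bad.any():
        line = int(np.flatnonzero(bad.to_numpy())[0]) + 2  # header is line 1
        raise InputError(f"{path}: invalid fiber record at line {line}")
    return frame


def write_fiber_table(frame: pd.DataFrame, path: str | Path) -> None:
    frame.to_csv(path, index=False, columns=list(FIBER_TABLE_COLUMNS))


def read_parcellation(path: str | Path) -> Parcellation:
    """Read a ``node_id,hemisphere`` CSV."""
    path = Path(path)
    nodes: list[str] = []
    hemi: dict[str, str] = {}
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or not {"node_id", "hemisphere"} <= set(
            reader.fieldnames
        ):
            raise InputError(f"{path}: expected header node_id,hemisphere")
        for lineno, row in enumerate(reader, start=2):
            node = row["node_id"]
            if row["hemisphere"] not in ("left", "right", "other"):
                raise InputError(
                    f"{path}:{lineno}: invalid hemisphere {row['hemisphere']!r}"
                )
            nodes.append(node)
            hemi[node] = row["hemisphere"]
    return Parcellation(tuple(nodes), hemi)


def write_parcellation(parcellation: Parcellation, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["node_id", "hemisphere"])
        for node in parcellation.nodes:
            writer.writerow([node, parcellation.hemisphere[node]])


def _detect_format(path: Path, fmt: str | None) -> str:
    if fmt is not None:
        return fmt
    return "graphml" if path.suffix.lower() == ".graphml" else "csv"


def read_graph(path: str | Path, fmt: str | None = None) -> WeightedGraph:
    """Read a weighted graph from edge-list CSV or GraphML.

    The CSV dialect is ``node_u,node_v,weight``; it cannot represent isolated
    nodes (use GraphML for those).
    """
    path = Path(path)
    fmt = _detect_format(path, fmt)
    if fmt == "graphml":
        g = nx.read_graphml(path)
        edges: dict[tuple[str, str], float] = {}
        for u, v, data in g.edges(data=True):
            wt = float(data.get("weight", 1.0))
            if wt < 0:
                raise InputError(f"{path}: negative weight on edge {u}-{v}")
            edges[(str(u), str(v))] = wt
        return WeightedGraph.from_edge_weights((str(v) for v in g.nodes), edges)
    edges = {}
    nodes: set[str] = set()
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header is None or [h.strip() for h in header[:3]] != [
            "node_u", "node_v", "weight",
        ]:
            raise InputError(f"{path}: expected header node_u,node_v,weight")
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) < 3:
                raise InputError(f"{path}:{lineno}: malformed row {row!r}")
            u, v = row[0], row[1]
            try:
                wt = float(row[2])
            except ValueError:
                raise InputError(
                    f"{path}:{lineno}: weight {row[2]!r} is not a number"
                ) from None
            if not math.isfinite(wt) or wt < 0:
                raise InputError(f"{path}:{lineno}: invalid weight {wt}")
            nodes.update((u, v))
            key = (u, v) if u <= v else (v, u)
            if key in edges:
                raise InputError(f"{path}:{lineno}: duplicate edge {key}")
            edges[key] = wt
    return WeightedGraph.from_edge_weights(nodes, edges)


def write_graph(
    graph: WeightedGraph, path: str | Path, fmt: str | None = None
) -> None:
    path = Path(path)
    fmt = _detect_format(path, fmt)
    if fmt == "graphml":
        nx.write_graphml(graph.to_networkx(), path)
        return
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["node_u", "node_v", "weight"])
        for u, v, wt in zip(graph.iu, graph.iv, graph.w):
            writer.writerow([graph.nodes[u], graph.nodes[v], repr(float(wt))])
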