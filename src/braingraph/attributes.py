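"""The subject x attribute table.

Per resolution, each brain yields 120 attributes named
``{Scope}_{Property}_{Weight}``: seven properties (Sum, AdjLMaxDivD,
PGEigengap, HoffmanBound, LogSpanningForestN, MinCutBalDivSum,
MinVertexCover) under all five weight schemes, MinVertexCoverBinary under
the unweighted scheme only, and MinSpanningForest under the four weighted
schemes, each for the Left and Right hemisphere subgraphs and the whole
graph: (7*5 + 1 + 4) * 3 = 120.  Over the five standard resolutions a brain
carries 600 attributes.

Attribute values that are undefined on a given graph (e.g. spectral ratios
of an edgeless hemisphere) are stored as NaN; solver failures likewise
degrade to NaN with a logged reason rather than aborting a cohort run.
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from . import graph_metrics, solvers
from .graph_core import (
    InputError,
    Parcellation,
    Scope,
    WeightScheme,
    build_graph,
    subgraph_by_scope,
)

logger = logging.getLogger(__name__)

__all__ = [
    "PROPERTY_SCHEMES",
    "SPECTRAL_PROPERTIES",
    "attribute_names",
    "compute_subject_attributes",
    "compute_attribute_table",
    "METADATA_COLUMNS",
]

_ALL = tuple(WeightScheme)
_WEIGHTED = tuple(s for s in WeightScheme if s is not WeightScheme.UNWEIGHTED)

#: property name -> weight schemes it is computed under
PROPERTY_SCHEMES: dict[str, tuple[WeightScheme, ...]] = {
    "Sum": _ALL,
    "AdjLMaxDivD": _ALL,
    "PGEigengap": _ALL,
    "HoffmanBound": _ALL,
    "LogSpanningForestN": _ALL,
    "MinCutBalDivSum": _ALL,
    "MinVertexCover": _ALL,
    "MinVertexCoverBinary": (WeightScheme.UNWEIGHTED,),
    "MinSpanningForest": _WEIGHTED,
}

SPECTRAL_PROPERTIES = frozenset(
    {"AdjLMaxDivD", "PGEigengap", "HoffmanBound", "LogSpanningForestN"}
)

METADATA_COLUMNS = ("subject_id", "sex", "resolution")

SCOPES = (Scope.LEFT, Scope.RIGHT, Scope.ALL)


def attribute_names(
    properties: Iterable[str] | None = None,
    schemes: Iterable[WeightScheme | str] | None = None,
    scopes: Iterable[Scope | str] | None = None,
) -> list[str]:
    """Deterministically ordered attribute names, optionally restricted.

    With no restriction this enumerates exactly the 120-attribute schema.
    """
    props = list(PROPERTY_SCHEMES) if properties is None else list(properties)
    unknown = [p for p in props if p not in PROPERTY_SCHEMES]
    if unknown:
        raise InputError(f"unknown properties: {unknown}")
    scheme_filter = (
        None if schemes is None else {WeightScheme.coerce(s) for s in schemes}
    )
    scope_list = SCOPES if scopes is None else [Scope.coerce(s) for s in scopes]
    names = []
    for scope in scope_list:
        for prop in props:
            for scheme in PROPERTY_SCHEMES[prop]:
                if scheme_filter is None or scheme in scheme_filter:
                    names.append(f"{scope.value}_{prop}_{scheme.value}")
    return names


def _compute_property(prop, graph, summary_cache, solver_opts):
    """One attribute value on one scope-graph; NaN when undefined."""
    if prop == "Sum":
        return graph_metrics.sum_weights(graph)
    if prop in SPECTRAL_PROPERTIES:
        if graph.n == 0:
            return float("nan")
        if "summary" not in summary_cache:
            summary_cache["summary"] = graph_metrics.spectral_summary(graph)
        summary = summary_cache["summary"]
        if prop == "AdjLMaxDivD":
            return graph_metrics.adj_lmax_div_d(graph, summary)
        if prop == "PGEigengap":
            return float("nan") if graph.n < 2 else graph_metrics.pg_eigengap(
                graph, summary
            )
        if prop == "HoffmanBound":
            return graph_metrics.hoffman_bound(graph, summary)
        return graph_metrics.log_spanning_forest_count(graph, summary)
    if prop == "MinCutBalDivSum":
        if graph.n < 2 or graph.n_edges == 0:
            return float("nan")
        return solvers.min_cut_bal_div_sum(graph, **solver_opts)
    if prop == "MinVertexCover":
        return solvers.min_fractional_vertex_cover(graph).objective
    if prop == "MinVertexCoverBinary":
        return float(
            solvers.min_binary_vertex_cover(
                graph, time_limit=solver_opts.get("time_limit",
                                                 solvers.DEFAULT_TIME_LIMIT)
            )
        )
    if prop == "MinSpanningForest":
        return solvers.min_spanning_forest_cost(graph)
    raise InputError(f"unknown property {prop!r}")


def compute_subject_attributes(
    fiber_table: pd.DataFrame,
    parcellation: Parcellation,
    properties: Iterable[str] | None = None,
    schemes: Iterable[WeightScheme | str] | None = None,
    scopes: Iterable[Scope | str] | None = None,
    solver_opts: Mapping | None = None,
    strict: bool = False,
) -> dict[str, float]:
    """All requested attributes for one subject at one resolution.

    Per-attribute computational failures become NaN with a logged reason
    unless ``strict`` is set.
    """
    names = attribute_names(properties, schemes, scopes)
    solver_opts = dict(solver_opts or {})
    # group requested work by (scope, scheme) so each graph is built once
    wanted: dict[tuple[str, str], list[str]] = {}
    for name in names:
        scope, prop, scheme = name.split("_")
        wanted.setdefault((scope, scheme), []).append(prop)

    out: dict[str, float] = {}
    graphs_by_scheme: dict[str, object] = {}
    for (scope, scheme), props in wanted.items():
        if scheme not in graphs_by_scheme:
            graphs_by_scheme[scheme] = build_graph(fiber_table, parcellation, scheme)
        graph = subgraph_by_scope(graphs_by_scheme[scheme], parcellation, scope)
        summary_cache: dict = {}
        for prop in props:
            name = f"{scope}_{prop}_{scheme}"
            try:
                out[name] = float(_compute_property(prop, graph, summary_cache,
                                                    solver_opts))
            except Exception as exc:
                if strict:
                    raise
                logger.warning("attribute %s failed (%s); recording NaN",
                               name, exc)
                out[name] = float("nan")
    return {name: out[name] for name in names}


def compute_attribute_table(
    cohort,
    resolutions: Sequence[int] | None = None,
    properties: Iterable[str] | None = None,
    schemes: Iterable[WeightScheme | str] | None = None,
    scopes: Iterable[Scope | str] | None = None,
    solver_opts: Mapping | None = None,
) -> pd.DataFrame:
    """Assemble the subject x attribute table.

    ``cohort`` is a :class:`braingraph.synth.Cohort` (or any object with the
    same ``subjects`` / ``parcellations`` shape).  One row per
    (subject, resolution); columns are ``subject_id``, ``sex``,
    ``resolution`` and the requested attributes (all 120 by default).
    """
    resolutions = list(resolutions or cohort.resolutions)
    gaps = [
        (s.subject_id, r)
        for s in cohort.subjects
        for r in resolutions
        if r not in s.fiber_tables
    ]
    if gaps:
        raise InputError(f"missing fiber tables for (subject, resolution): {gaps[:10]}")
    missing_parc = [r for r in resolutions if r not in cohort.parcellations]
    if missing_parc:
        raise InputError(f"missing parcellations for resolutions: {missing_parc}")

    rows = []
    for subject in cohort.subjects:
        for resolution in resolutions:
            values = compute_subject_attributes(
                subject.fiber_tables[resolution],
                cohort.parcellations[resolution],
                properties=properties,
                schemes=schemes,
                scopes=scopes,
                solver_opts=solver_opts,
            )
            rows.append(
                {"subject_id": subject.subject_id, "sex": subject.sex,
                 "resolution": resolution, **values}
            )
    return pd.DataFrame(rows)
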