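"""Precision-weighted chemical -> gene/protein knowledge graphs.

Predicted relations from one or more system runs are assembled into a
directed, typed, weighted graph: chemicals and genes/proteins are nodes, and
each unique (chemical, gene, relation type) identity is one edge.  An edge's
support is the list of (team, run, precision) records that predicted it; its
weight combines those run precisions, by default with noisy-OR
(``1 - prod(1 - p_i)``), treating runs as independent evidence.

Two node-identity modes are supported:

* ``mention`` — node id is ``pmid:term_id``; counts mention instances and is
  the mode in which node totals match per-mention corpus statistics;
* ``surface`` — node id is the role-qualified surface string
  (``CEM:...`` / ``GPRO:...``), which merges mentions across documents and
  yields the cross-document connectivity needed for component/diameter
  analyses.  Role qualification keeps the graph strictly bipartite, so
  clustering and transitivity are exactly zero in this mode.

Topology statistics are computed on the undirected simple projection of the
graph (parallel typed edges collapsed), as the standard definitions of
clustering, transitivity and degree assortativity require simple graphs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import networkx as nx
import pandas as pd

from .corpus_io import (
    EntityMention,
    PathLike,
    PredictionRecord,
    RELATION_TYPES,
    entity_index,
)

Support = tuple[str, Union[str, int], float]  # (team, run, precision)


def combine_precisions(ps: Sequence[float], mode: str = "noisy_or") -> float:
    """Combine run precisions into one edge weight.

    ``noisy_or`` = ``1 - prod(1 - p_i)`` (monotone, bounded by [max p, 1]);
    ``max`` and ``mean`` are provided as alternatives.  A single precision is
    returned unchanged in every mode.
    """
    if not ps:
        raise ValueError("combine_precisions requires at least one precision")
    for p in ps:
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"precision {p} outside [0, 1]")
    if mode == "noisy_or":
        return 1.0 - math.prod(1.0 - p for p in ps)
    if mode == "max":
        return max(ps)
    if mode == "mean":
        return sum(ps) / len(ps)
    raise ValueError(f"unknown combiner mode {mode!r}")


@dataclass
class KGEdge:
    """One unique (chemical, gene, type) edge with its run support."""

    chem_node: str
    gene_node: str
    rel_type: str
    weight: float
    support: list[Support] = field(default_factory=list)

    @property
    def identity(self) -> tuple[str, str, str]:
        return (self.chem_node, self.gene_node, self.rel_type)


@dataclass
class KnowledgeGraph:
    """Directed CEM -> GPRO multigraph keyed by typed edge identity."""

    node_roles: dict[str, str]  # node id -> "CEM" | "GPRO"
    edges: dict[tuple[str, str, str], KGEdge]
    node_mode: str = "surface"

    @property
    def n_nodes(self) -> int:
        return len(self.node_roles)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def to_networkx(self) -> nx.MultiDiGraph:
        g = nx.MultiDiGraph()
        for node, role in self.node_roles.items():
            g.add_node(node, role=role)
        for edge in self.edges.values():
            g.add_edge(
                edge.chem_node,
                edge.gene_node,
                key=edge.rel_type,
                rel_type=edge.rel_type,
                weight=edge.weight,
                n_support=len(edge.support),
            )
        return g

    def undirected_projection(self) -> nx.Graph:
        """Simple undirected projection: parallel typed edges collapse."""
        g = nx.Graph()
        g.add_nodes_from(self.node_roles)
        g.add_edges_from((e.chem_node, e.gene_node) for e in self.edges.values())
        return g


@dataclass
class GraphStats:
    """Topology summary of a knowledge graph's undirected projection."""

    n_nodes: int
    n_edges: int
    avg_clustering: float
    transitivity: float
    degree_assortativity: Optional[float]
    n_components: int
    giant_size: int
    diameter_giant: Optional[int]


def _node_id(entity: EntityMention, node_mode: str) -> str:
    if node_mode == "mention":
        return f"{entity.pmid}:{entity.term_id}"
    if node_mode == "surface":
        role = "CEM" if entity.is_chemical else "GPRO"
        return f"{role}:{entity.text}"
    raise ValueError(f"node_mode must be 'mention' or 'surface', got {node_mode!r}")


def build_kg(
    preds: Iterable[PredictionRecord],
    entities: Sequence[EntityMention],
    node_mode: str = "surface",
    combiner: str = "noisy_or",
) -> KnowledgeGraph:
    """Aggregate prediction records into a knowledge graph.

    Exact duplicate records (same relation, team and run) are dropped; each
    remaining record contributes one support entry to its edge.  The sum of
    support sizes over all edges therefore equals the number of
    deduplicated input predictions.
    """
    index = entity_index(entities)
    node_roles: dict[str, str] = {}
    edges: dict[tuple[str, str, str], KGEdge] = {}
    seen: set[tuple] = set()
    for rec in preds:
        rel = rec.relation
        dedup_key = (rel, rec.team, rec.run)
        if dedup_key in seen:
            continue
        seen.add(dedup_key)
        try:
            chem = index[(rel.pmid, rel.arg1)]
            gene = index[(rel.pmid, rel.arg2)]
        except KeyError as exc:
            raise ValueError(
                f"prediction argument does not resolve to an entity: {exc}"
            ) from exc
        cnode, gnode = _node_id(chem, node_mode), _node_id(gene, node_mode)
        node_roles[cnode] = "CEM"
        node_roles[gnode] = "GPRO"
        identity = (cnode, gnode, rel.rel_type)
        edge = edges.get(identity)
        if edge is None:
            edge = KGEdge(cnode, gnode, rel.rel_type, 0.0, [])
            edges[identity] = edge
        edge.support.append((rec.team, rec.run, rec.precision))
    for edge in edges.values():
        edge.weight = combine_precisions([p for _, _, p in edge.support], combiner)
    return KnowledgeGraph(node_roles=node_roles, edges=edges, node_mode=node_mode)


def _restrict(kg: KnowledgeGraph, edges: dict) -> KnowledgeGraph:
    incident = {n for ident in edges for n in ident[:2]}
    return KnowledgeGraph(
        node_roles={n: r for n, r in kg.node_roles.items() if n in incident},
        edges=edges,
        node_mode=kg.node_mode,
    )


def subgraph_by_type(kg: KnowledgeGraph, rel_type: str) -> KnowledgeGraph:
    """Edges of one relation type plus their incident nodes only."""
    if rel_type not in RELATION_TYPES:
        raise ValueError(f"unknown relation type {rel_type!r}")
    return _restrict(kg, {i: e for i, e in kg.edges.items() if i[2] == rel_type})


def filter_by_weight(kg: KnowledgeGraph, min_weight: float) -> KnowledgeGraph:
    """Keep edges with weight >= ``min_weight``; isolated nodes are dropped.

    ``min_weight=0`` is the identity (up to isolated-node removal of nodes
    that had no edges to begin with)."""
    if not 0.0 <= min_weight <= 1.0:
        raise ValueError(f"min_weight must be in [0, 1], got {min_weight}")
    if min_weight == 0.0:
        return KnowledgeGraph(dict(kg.node_roles), dict(kg.edges), kg.node_mode)
    return _restrict(kg, {i: e for i, e in kg.edges.items() if e.weight >= min_weight})


def graph_stats(kg: KnowledgeGraph) -> GraphStats:
    """Topology statistics on the undirected simple projection.

    ``n_edges`` counts typed edge identities of the graph itself;
    clustering, transitivity, assortativity, components and the giant
    component's diameter are computed on the projection.  Assortativity is
    None when degree variance is zero (it is undefined there); the diameter
    is None for an empty graph.
    """
    proj = kg.undirected_projection()
    if proj.number_of_nodes() == 0:
        return GraphStats(0, 0, 0.0, 0.0, None, 0, 0, None)
    avg_clust = nx.average_clustering(proj)
    trans = nx.transitivity(proj)
    degrees = [d for _, d in proj.degree()]
    if len(set(degrees)) <= 1 or proj.number_of_edges() == 0:
        assort: Optional[float] = None
    else:
        assort = float(nx.degree_assortativity_coefficient(proj))
        if math.isnan(assort):
            assort = None
    components = sorted(nx.connected_components(proj), key=len, reverse=True)
    giant = proj.subgraph(components[0])
    diameter = nx.diameter(giant) if giant.number_of_nodes() > 0 else None
    return GraphStats(
        n_nodes=kg.n_nodes,
        n_edges=kg.n_edges,
        avg_clustering=avg_clust,
        transitivity=trans,
        degree_assortativity=assort,
        n_components=len(components),
        giant_size=giant.number_of_nodes(),
        diameter_giant=diameter,
    )


def prediction_volume_summary(type_counts: pd.DataFrame) -> dict[str, float]:
    """Totals and mean support from a per-type prediction/edge count table.

    ``type_counts`` has one row per relation type with integer columns
    ``predictions`` (all individual run predictions) and ``unique_edges``
    (distinct knowledge-graph edge identities).  Returns the two totals and
    the mean number of predictions per unique edge.
    """
    for col in ("predictions", "unique_edges"):
        if col not in type_counts.columns:
            raise ValueError(f"missing column {col!r}")
    total_preds = int(type_counts["predictions"].sum())
    total_edges = int(type_counts["unique_edges"].sum())
    return {
        "total_predictions": total_preds,
        "total_unique_edges": total_edges,
        "mean_predictions_per_edge": total_preds / total_edges if total_edges else 0.0,
    }


# ---------------------------------------------------------------------------
# Export / import

_TSV_HEADER = "chem\tgene\ttype\tweight\tn_support"


def export_edges(kg: KnowledgeGraph, path: PathLike, format: str = "tsv") -> None:
    """Write the edge list as TSV or GraphML (attributes preserved)."""
    if format == "tsv":
        with open(path, "w", encoding="utf-8", newline="") as fh:
            fh.write(_TSV_HEADER + "\n")
            for ident in sorted(kg.edges):
                e = kg.edges[ident]
                fh.write(
                    f"{e.chem_node}\t{e.gene_node}\t{e.rel_type}\t"
                    f"{e.weight!r}\t{len(e.support)}\n"
                )
    elif format == "graphml":
        nx.write_graphml(kg.to_networkx(), str(path))
    else:
        raise ValueError(f"format must be 'tsv' or 'graphml', got {format!r}")


def read_edges(path: PathLike, format: str = "tsv") -> KnowledgeGraph:
    """Re-import an exported edge list.

    Per-run support provenance is not serialized in either format, so
    imported edges carry a single synthetic support entry whose precision is
    the stored weight; identity, weight and support size round-trip exactly.
    """
    node_roles: dict[str, str] = {}
    edges: dict[tuple[str, str, str], KGEdge] = {}

    def add(chem: str, gene: str, rel_type: str, weight: float, n_support: int) -> None:
        node_roles.setdefault(chem, "CEM")
        node_roles.setdefault(gene, "GPRO")
        edges[(chem, gene, rel_type)] = KGEdge(
            chem, gene, rel_type, weight,
            [("import", i, weight) for i in range(n_support)],
        )

    if format == "tsv":
        lines = Path(path).read_text(encoding="utf-8").splitlines()
        if not lines or lines[0] != _TSV_HEADER:
            raise ValueError(f"{path}: missing edge-list header")
        for line in lines[1:]:
            chem, gene, rel_type, weight, n_support = line.split("\t")
            add(chem, gene, rel_type, float(weight), int(n_support))
    elif format == "graphml":
        g = nx.read_graphml(str(path), force_multigraph=True)
        for u, v, _, data in g.edges(keys=True, data=True):
            add(u, v, data["rel_type"], float(data["weight"]), int(data["n_support"]))
    else:
        raise ValueError(f"format must be 'tsv' or 'graphml', got {format!r}")
    return KnowledgeGraph(node_roles=node_roles, edges=edges)
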