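"""Typed knowledge graphs and reconstructed associative gene networks.

A knowledge graph is a heterogeneous undirected multigraph: vertices are
molecular entities (genes, proteins, metabolites, microRNAs) or higher-level
factors (biological processes, traits, diseases), edges carry a relation
label and a provenance tag (literature-mined vs. curated factual database).
Relation directionality, where a source asserts one, is kept only as a
label: every centrality computation here treats edges as undirected.

An :class:`AssociativeGeneNetwork` is the per-seed-process subnetwork of
gene/protein vertices together with the edges among them.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import networkx as nx

logger = logging.getLogger("agnet")

VERTEX_KINDS = frozenset(
    {"gene", "protein", "metabolite", "microRNA", "process", "trait", "disease", "other"}
)
PROVENANCE_VALUES = frozenset({"literature", "factual_database"})
#: vertex kinds eligible for network membership
MOLECULAR_KINDS = frozenset({"gene", "protein"})


class GraphFormatError(ValueError):
    """Malformed knowledge-graph or network file."""


class UnknownVertexError(KeyError):
    """A vertex id was looked up that is not present in the graph."""


@dataclass(frozen=True)
class Vertex:
    """A typed vertex of the knowledge graph."""

    id: str
    kind: str
    name: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("vertex id must be non-empty")
        if self.kind not in VERTEX_KINDS:
            raise ValueError(f"unknown vertex kind {self.kind!r}")


@dataclass(frozen=True)
class TypedEdge:
    """A labelled, provenance-tagged edge between two vertices."""

    source: str
    target: str
    relation: str
    provenance: str = "literature"

    def __post_init__(self) -> None:
        if not self.relation:
            raise ValueError("relation label must be non-empty")
        if self.provenance not in PROVENANCE_VALUES:
            raise ValueError(f"unknown provenance {self.provenance!r}")

    @property
    def pair(self) -> frozenset[str]:
        return frozenset((self.source, self.target))


@dataclass
class LoadSummary:
    """Per-file load diagnostics: counts and rejected records."""

    n_records: int = 0
    n_edges: int = 0
    n_duplicates: int = 0
    rejected_self_loops: list[int] = field(default_factory=list)
    unknown_kinds: dict[str, int] = field(default_factory=dict)


class KnowledgeGraph:
    """Undirected heterogeneous multigraph of typed vertices and labelled edges.

    Backed by a :class:`networkx.MultiGraph`; parallel edges between the same
    pair (different relation or provenance) are retained, but all degree /
    adjacency queries count distinct neighbouring vertices, because the
    prioritization score is defined over vertices, not edge multiplicities.
    Self-loops are rejected: a vertex's centrality reflects connections with
    *other* vertices.
    """

    def __init__(self) -> None:
        self._g = nx.MultiGraph()

    # -- construction -----------------------------------------------------

    def add_vertex(self, vertex: Vertex) -> None:
        if vertex.id in self._g:
            existing = self._g.nodes[vertex.id]["kind"]
            if existing != vertex.kind:
                logger.warning(
                    "vertex %s re-declared with kind %s (keeping %s)",
                    vertex.id, vertex.kind, existing,
                )
            return
        self._g.add_node(vertex.id, kind=vertex.kind, name=vertex.name or vertex.id)

    def add_edge(self, edge: TypedEdge) -> None:
        if edge.source == edge.target:
            raise ValueError(f"self-loop on {edge.source!r} rejected")
        for endpoint in (edge.source, edge.target):
            if endpoint not in self._g:
                raise UnknownVertexError(endpoint)
        key = (edge.relation, edge.provenance)
        # identical records collapse to one edge
        if not self._g.has_edge(edge.source, edge.target, key=key):
            self._g.add_edge(
                edge.source, edge.target, key=key,
                relation=edge.relation, provenance=edge.provenance,
            )

    # -- queries ----------------------------------------------------------

    def __contains__(self, vertex_id: str) -> bool:
        return vertex_id in self._g

    def __len__(self) -> int:
        return self._g.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self._g.number_of_edges()

    def vertex(self, vertex_id: str) -> Vertex:
        if vertex_id not in self._g:
            raise UnknownVertexError(vertex_id)
        data = self._g.nodes[vertex_id]
        return Vertex(vertex_id, data["kind"], data["name"])

    def vertices(self) -> Iterator[Vertex]:
        for vid in self._g.nodes:
            yield self.vertex(vid)

    def vertices_of_kind(self, *kinds: str) -> list[str]:
        wanted = set(kinds)
        return [v for v, d in self._g.nodes(data="kind") if d in wanted]

    def edges(self) -> Iterator[TypedEdge]:
        for u, v, data in self._g.edges(data=True):
            yield TypedEdge(u, v, data["relation"], data["provenance"])

    def kind_of(self, vertex_id: str) -> str:
        if vertex_id not in self._g:
            raise UnknownVertexError(vertex_id)
        return self._g.nodes[vertex_id]["kind"]

    def neighbors(self, vertex_id: str, provenance: str | None = None) -> set[str]:
        """Distinct neighbours of ``vertex_id``.

        With ``provenance`` set, only neighbours reachable through at least
        one edge of that provenance are returned.
        """
        if vertex_id not in self._g:
            raise UnknownVertexError(vertex_id)
        if provenance is None:
            return set(self._g.neighbors(vertex_id))
        out: set[str] = set()
        for _, nbr, data in self._g.edges(vertex_id, data=True):
            if data["provenance"] == provenance:
                out.add(nbr)
        return out

    def degree_of(self, vertex_id: str) -> int:
        """Number of distinct neighbouring vertices (parallel edges count once)."""
        return len(self.neighbors(vertex_id))

    def edges_between(self, members: set[str]) -> list[TypedEdge]:
        """All edges with both endpoints in ``members``."""
        sub = self._g.subgraph(members)
        return [
            TypedEdge(u, v, d["relation"], d["provenance"])
            for u, v, d in sub.edges(data=True)
        ]


@dataclass
class AssociativeGeneNetwork:
    """Reconstructed per-seed-process network of gene/protein vertices.

    ``M`` — the network size used as the denominator of the cross-talk
    centrality — is the number of member vertices.  The seed process itself
    is never a member.
    """

    seed_process: str
    members: frozenset[str]
    internal_edges: tuple[TypedEdge, ...]
    member_kinds: dict[str, str] = field(default_factory=dict)
    member_names: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.members) < 1:
            raise ValueError("empty network: an associative gene network needs M >= 1")
        if self.seed_process in self.members:
            raise ValueError("seed process cannot be a network member")
        for e in self.internal_edges:
            if e.source not in self.members or e.target not in self.members:
                raise ValueError(f"internal edge {e} leaves the member set")

    @property
    def M(self) -> int:
        return len(self.members)

    def degree_of(self, vertex_id: str) -> int:
        """Distinct-neighbour degree of a member within the network."""
        if vertex_id not in self.members:
            raise UnknownVertexError(vertex_id)
        nbrs = set()
        for e in self.internal_edges:
            if vertex_id in (e.source, e.target):
                nbrs.add(e.target if e.source == vertex_id else e.source)
        return len(nbrs)


def degree_of(graph: KnowledgeGraph | AssociativeGeneNetwork, vertex_id: str) -> int:
    """Distinct-neighbour degree of ``vertex_id`` in either container."""
    return graph.degree_of(vertex_id)


# -- readers / writers ----------------------------------------------------

_EDGE_COLUMNS = "source_id\tsource_kind\trelation\ttarget_id\ttarget_kind\tprovenance"


def _coerce_kind(kind: str, summary: LoadSummary) -> str:
    if kind in VERTEX_KINDS:
        return kind
    summary.unknown_kinds[kind] = summary.unknown_kinds.get(kind, 0) + 1
    logger.warning("unknown vertex kind %r mapped to 'other'", kind)
    return "other"


def read_knowledge_graph(
    path: str | Path, *, return_summary: bool = False
) -> KnowledgeGraph | tuple[KnowledgeGraph, LoadSummary]:
    """Read a knowledge graph from a tab-separated edge list.

    Columns: ``source_id source_kind relation target_id target_kind
    [provenance]``; lines starting with ``#`` are comments.  Duplicate
    identical records collapse to one edge; self-loops are rejected and
    reported in the load summary; unknown kinds map to ``other`` with a
    warning.
    """
    path = Path(path)
    graph = KnowledgeGraph()
    summary = LoadSummary()
    seen: set[tuple[str, ...]] = set()
    with path.open() as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 5:
                raise GraphFormatError(
                    f"{path}:{lineno}: expected >=5 tab-separated fields, got {len(fields)}"
                )
            src, src_kind, relation, tgt, tgt_kind = (f.strip() for f in fields[:5])
            provenance = fields[5].strip() if len(fields) > 5 and fields[5].strip() else "literature"
            summary.n_records += 1
            if not src or not tgt or not relation:
                raise GraphFormatError(f"{path}:{lineno}: empty identifier or relation")
            if provenance not in PROVENANCE_VALUES:
                raise GraphFormatError(
                    f"{path}:{lineno}: provenance must be one of {sorted(PROVENANCE_VALUES)}"
                )
            if src == tgt:
                summary.rejected_self_loops.append(lineno)
                logger.warning("%s:%d: self-loop on %r rejected", path, lineno, src)
                continue
            record = (src, src_kind, relation, tgt, tgt_kind, provenance)
            if record in seen:
                summary.n_duplicates += 1
                continue
            seen.add(record)
            graph.add_vertex(Vertex(src, _coerce_kind(src_kind, summary)))
            graph.add_vertex(Vertex(tgt, _coerce_kind(tgt_kind, summary)))
            graph.add_edge(TypedEdge(src, tgt, relation, provenance))
    summary.n_edges = graph.n_edges
    if return_summary:
        return graph, summary
    return graph


def write_knowledge_graph(graph: KnowledgeGraph, path: str | Path) -> None:
    """Write a knowledge graph back to the TSV edge-list dialect."""
    path = Path(path)
    lines = [f"# {_EDGE_COLUMNS}"]
    for e in sorted(graph.edges(), key=lambda e: (e.source, e.target, e.relation, e.provenance)):
        src_kind = graph.kind_of(e.source)
        tgt_kind = graph.kind_of(e.target)
        lines.append(
            f"{e.source}\t{src_kind}\t{e.relation}\t{e.target}\t{tgt_kind}\t{e.provenance}"
        )
    path.write_text("\n".join(lines) + "\n")


def _network_to_nx(net: AssociativeGeneNetwork) -> nx.MultiGraph:
    g = nx.MultiGraph(seed_process=net.seed_process)
    for m in sorted(net.members):
        g.add_node(
            m,
            kind=net.member_kinds.get(m, "gene"),
            name=net.member_names.get(m, m),
        )
    for e in net.internal_edges:
        g.add_edge(
            e.source, e.target, key=(e.relation, e.provenance),
            relation=e.relation, provenance=e.provenance,
        )
    return g


def write_network(
    net: AssociativeGeneNetwork, path: str | Path, format: str = "graphml"
) -> None:
    """Serialise a reconstructed network as GraphML or TSV.

    Both formats round-trip through :func:`read_network`: the read-back
    network has identical members, kinds and edge multiset.
    """
    path = Path(path)
    if format == "graphml":
        nx.write_graphml(_network_to_nx(net), path)
    elif format == "tsv":
        lines = [f"# seed_process\t{net.seed_process}"]
        for m in sorted(net.members):
            lines.append(
                f"V\t{m}\t{net.member_kinds.get(m, 'gene')}\t{net.member_names.get(m, m)}"
            )
        for e in sorted(
            net.internal_edges, key=lambda e: (e.source, e.target, e.relation, e.provenance)
        ):
            lines.append(f"E\t{e.source}\t{e.target}\t{e.relation}\t{e.provenance}")
        path.write_text("\n".join(lines) + "\n")
    else:
        raise ValueError(f"unknown network format {format!r}")


def read_network(path: str | Path, format: str | None = None) -> AssociativeGeneNetwork:
    """Read a network written by :func:`write_network` (format inferred from suffix)."""
    path = Path(path)
    if format is None:
        format = "graphml" if path.suffix == ".graphml" else "tsv"
    if format == "graphml":
        g = nx.read_graphml(path, force_multigraph=True)
        seed = g.graph.get("seed_process", "")
        members = frozenset(g.nodes)
        edges = tuple(
            TypedEdge(u, v, d["relation"], d["provenance"]) for u, v, d in g.edges(data=True)
        )
        kinds = {n: d.get("kind", "gene") for n, d in g.nodes(data=True)}
        names = {n: d.get("name", n) for n, d in g.nodes(data=True)}
        return AssociativeGeneNetwork(seed, members, edges, kinds, names)
    seed = ""
    members: set[str] = set()
    kinds: dict[str, str] = {}
    names: dict[str, str] = {}
    edges_list: list[TypedEdge] = []
    with path.open() as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if fields[0] == "# seed_process":
                seed = fields[1]
            elif fields[0] == "V":
                members.add(fields[1])
                kinds[fields[1]] = fields[2]
                names[fields[1]] = fields[3]
            elif fields[0] == "E":
                edges_list.append(TypedEdge(fields[1], fields[2], fields[3], fields[4]))
            elif fields[0].startswith("#"):
                continue
            else:
                raise GraphFormatError(f"{path}:{lineno}: unknown record type {fields[0]!r}")
    return AssociativeGeneNetwork(seed, frozenset(members), tuple(edges_list), kinds, names)
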