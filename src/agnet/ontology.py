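"""Biological-process ontology parsing and graph-based semantic similarity.

Similarity between two ontology terms follows the graph-based measure of
Wang et al.: each term's meaning is represented by its ancestor closure,
every ancestor contributing a *semantic value* (S-value) that decays along
the path by a per-relation weight (default 0.8 for ``is_a``, 0.6 for
``part_of``, the measure's standard constants).  The similarity of terms A
and B is the summed S-value mass on their common ancestors, normalised by
the total semantic value of each term:

    sim(A, B) = sum_{t in T_A ∩ T_B} (S_A(t) + S_B(t)) / (SV(A) + SV(B))

where T_X = {X} ∪ ancestors(X), S_X(X) = 1, S_X(t) = max over children c
of t on paths toward X of w_e · S_X(c), and SV(X) = Σ_t S_X(t).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import obonet

logger = logging.getLogger("agnet")

#: standard contribution weights of the measure; configurable per call
DEFAULT_WEIGHTS: dict[str, float] = {"is_a": 0.8, "part_of": 0.6}
SEMANTIC_RELATIONS = frozenset(DEFAULT_WEIGHTS)


class OntologyCycleError(ValueError):
    """The ontology relation graph contains a cycle."""


class UnknownTermError(KeyError):
    """A term id was looked up that is not in the ontology."""


@dataclass(frozen=True)
class OntologyTerm:
    term_id: str
    name: str = ""
    namespace: str = ""


class OntologyDAG:
    """Ontology as a DAG with typed child→parent edges (``is_a`` / ``part_of``)."""

    def __init__(self, graph: nx.MultiDiGraph) -> None:
        self._g = graph
        if not nx.is_directed_acyclic_graph(graph):
            cycle = nx.find_cycle(graph)
            raise OntologyCycleError(f"ontology relations contain a cycle: {cycle}")

    def __contains__(self, term_id: str) -> bool:
        return term_id in self._g

    def __len__(self) -> int:
        return self._g.number_of_nodes()

    @property
    def n_relations(self) -> int:
        return self._g.number_of_edges()

    def term(self, term_id: str) -> OntologyTerm:
        if term_id not in self._g:
            raise UnknownTermError(term_id)
        d = self._g.nodes[term_id]
        return OntologyTerm(term_id, d.get("name", ""), d.get("namespace", ""))

    def terms(self) -> list[str]:
        return sorted(self._g.nodes)

    def parents(self, term_id: str) -> list[tuple[str, str]]:
        """(parent, relation_type) pairs for a term."""
        if term_id not in self._g:
            raise UnknownTermError(term_id)
        return [(p, key) for _, p, key in self._g.out_edges(term_id, keys=True)]

    def ancestors(self, term_id: str) -> set[str]:
        """All terms reachable from ``term_id`` through child→parent relations."""
        if term_id not in self._g:
            raise UnknownTermError(term_id)
        return nx.descendants(self._g, term_id)

    @classmethod
    def from_relations(
        cls,
        relations: list[tuple[str, str, str]],
        terms: dict[str, str] | None = None,
    ) -> "OntologyDAG":
        """Build from (child, parent, relation_type) triples; handy for tests."""
        g = nx.MultiDiGraph()
        for term_id, name in (terms or {}).items():
            g.add_node(term_id, name=name)
        for child, parent, rel in relations:
            if rel not in SEMANTIC_RELATIONS:
                raise ValueError(f"unsupported relation type {rel!r}")
            g.add_node(child)
            g.add_node(parent)
            g.add_edge(child, parent, key=rel)
        return cls(g)


def read_obo(path: str | Path) -> OntologyDAG:
    """Parse an OBO 1.2/1.4 flat file into an :class:`OntologyDAG`.

    Only ``is_a`` and ``part_of`` relations participate in similarity;
    other relation types are dropped with a logged count.  Obsolete terms
    are excluded.  Cyclic input raises :class:`OntologyCycleError`.
    """
    raw = obonet.read_obo(str(path))  # excludes obsolete terms by default
    g = nx.MultiDiGraph()
    dropped = 0
    for node, data in raw.nodes(data=True):
        g.add_node(node, name=data.get("name", ""), namespace=data.get("namespace", ""))
    for child, parent, key in raw.edges(keys=True):
        if key in SEMANTIC_RELATIONS:
            g.add_edge(child, parent, key=key)
        else:
            dropped += 1
    if dropped:
        logger.info("read_obo: ignored %d relations of unsupported types", dropped)
    return OntologyDAG(g)


@dataclass
class SValueMap:
    """Ancestor contributions of one anchor term and their sum SV."""

    anchor: str
    svalues: dict[str, float] = field(default_factory=dict)

    @property
    def SV(self) -> float:
        return sum(self.svalues.values())


def svalues(
    dag: OntologyDAG, term: str, weights: dict[str, float] | None = None
) -> SValueMap:
    """S-values of ``term`` and all its ancestors by dynamic programming.

    Processed in topological order of the ancestor subgraph, so each
    ancestor's value is the max over its contributing children's values
    times the relation weight — equivalent to maximising the product of
    edge weights over all child→parent paths from the anchor.
    """
    if term not in dag:
        raise UnknownTermError(term)
    w = dict(DEFAULT_WEIGHTS if weights is None else weights)
    nodes = {term} | dag.ancestors(term)
    sub = dag._g.subgraph(nodes)
    values: dict[str, float] = {term: 1.0}
    for node in nx.topological_sort(sub):
        if node == term:
            continue
        best = 0.0
        for child, _, rel in sub.in_edges(node, keys=True):
            if child in values and rel in w:
                best = max(best, w[rel] * values[child])
        values[node] = best
    return SValueMap(term, values)


def wang_similarity(
    dag: OntologyDAG, a: str, b: str, weights: dict[str, float] | None = None
) -> float:
    """Semantic similarity of two terms in [0, 1]; symmetric; sim(a, a) = 1."""
    sa = svalues(dag, a, weights)
    sb = svalues(dag, b, weights)
    common = sa.svalues.keys() & sb.svalues.keys()
    if not common:
        return 0.0
    shared = sum(sa.svalues[t] + sb.svalues[t] for t in common)
    return shared / (sa.SV + sb.SV)


def write_similarity_matrix(
    ids: list[str], values, path: str | Path
) -> None:
    """Export a symmetric similarity matrix as TSV with term-id row/col labels."""
    import pandas as pd

    pd.DataFrame(values, index=ids, columns=ids).to_csv(path, sep="\t", float_format="%.6g")
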