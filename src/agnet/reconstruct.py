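"""Reconstruction of the associative gene network around a seed process.

The network for a seed biological process consists of every gene/protein
vertex directly linked to that process in the knowledge graph (one hop, any
relation type, optionally restricted by edge provenance), plus all
knowledge-graph edges among those members.  Process vertices are never
members themselves; they enter later only as scored candidates.
"""

from __future__ import annotations

from .graph import (
    AssociativeGeneNetwork,
    KnowledgeGraph,
    MOLECULAR_KINDS,
    UnknownVertexError,
)


class EmptyNetworkError(ValueError):
    """The seed process has no adjacent gene/protein vertices."""


def reconstruct(
    graph: KnowledgeGraph,
    seed: str,
    provenance: str | None = None,
) -> AssociativeGeneNetwork:
    """Build the associative gene network for ``seed``.

    Parameters
    ----------
    graph : KnowledgeGraph
    seed : str
        Id of a vertex with kind ``process``.
    provenance : str, optional
        ``"literature"`` or ``"factual_database"`` to keep only seed links
        of that provenance; ``None`` (default) uses both.

    Raises
    ------
    UnknownVertexError if the seed is absent; ValueError if it is not a
    process; EmptyNetworkError if no gene/protein is linked to it.
    """
    if seed not in graph:
        raise UnknownVertexError(seed)
    if graph.kind_of(seed) != "process":
        raise ValueError(f"seed vertex {seed!r} has kind {graph.kind_of(seed)!r}, not process")
    members = {
        v
        for v in graph.neighbors(seed, provenance=provenance)
        if graph.kind_of(v) in MOLECULAR_KINDS
    }
    if not members:
        raise EmptyNetworkError(
            f"empty network: no gene/protein vertex linked to {seed!r}"
            + (f" with provenance {provenance!r}" if provenance else "")
        )
    internal = tuple(graph.edges_between(members))
    kinds = {m: graph.kind_of(m) for m in members}
    names = {m: graph.vertex(m).name for m in members}
    return AssociativeGeneNetwork(seed, frozenset(members), internal, kinds, names)


def candidate_links(
    graph: KnowledgeGraph, net: AssociativeGeneNetwork, candidate: str
) -> int:
    """N_i: number of distinct network members adjacent to ``candidate``.

    Bounded by 0 <= N_i <= M; the candidate may be the seed itself, in
    which case N_i = M by construction of the member set.
    """
    if candidate not in graph:
        raise UnknownVertexError(candidate)
    return len(graph.neighbors(candidate) & net.members)
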