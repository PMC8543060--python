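"""Shared fixtures: tiny hand-built graphs and random generators."""

import random

import pytest

from agnet import KnowledgeGraph, TypedEdge, Vertex


def build_graph(vertices, edges):
    """KnowledgeGraph from (id, kind) pairs and (src, tgt, rel[, prov]) tuples."""
    kg = KnowledgeGraph()
    for vid, kind in vertices:
        kg.add_vertex(Vertex(vid, kind, vid))
    for e in edges:
        kg.add_edge(TypedEdge(*e))
    return kg


def random_kg(rng: random.Random, n_genes=20, n_processes=8, link_p=0.2, gg_p=0.1):
    """Random heterogeneous graph; returns (graph, gene ids, process ids)."""
    genes = [f"g{i}" for i in range(n_genes)]
    procs = [f"P{i}" for i in range(n_processes)]
    vertices = [(g, "gene") for g in genes] + [(p, "process") for p in procs]
    edges = []
    for g in genes:
        for p in procs:
            if rng.random() < link_p:
                edges.append((g, p, "association"))
    for i in range(n_genes):
        for j in range(i + 1, n_genes):
            if rng.random() < gg_p:
                edges.append((genes[i], genes[j], "interaction"))
    return build_graph(vertices, edges), genes, procs


@pytest.fixture
def toy_graph():
    """g1, g2, g3 annotated to process P0; extra gene g4 off-network; one g1-g2 edge."""
    return build_graph(
        [("g1", "gene"), ("g2", "gene"), ("g3", "gene"), ("g4", "gene"),
         ("P0", "process"), ("P1", "process")],
        [("g1", "P0", "participation"), ("g2", "P0", "participation"),
         ("g3", "P0", "participation"), ("g1", "g2", "interaction"),
         ("g4", "g1", "interaction"), ("g1", "P1", "association"),
         ("g2", "P1", "association")],
    )


@pytest.fixture
def rng():
    return random.Random(20240917)
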