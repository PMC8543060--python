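"""Synthetic knowledge graphs and toy ontologies with planted structure.

Real associative gene networks come from proprietary literature-mined
knowledge bases, so every stage of the pipeline is exercised instead on
generated graphs whose ground truth is known by construction: designated
seed processes annotate a Bernoulli-sampled fraction of the genes, planted
candidate processes link to a chosen fraction of each seed's members
(their expected cross-talk centrality), and decoy processes link to genes
at a low background rate.  A companion generator emits a toy ontology —
a complete ``is_a`` tree with a sprinkling of acyclicity-preserving
``part_of`` cross-links — whose leaf terms double as the knowledge-graph
process ids, so semantic clustering is exercised on the same identifiers.

All randomness flows from one integer seed; identical seeds give
byte-identical serialisations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .graph import KnowledgeGraph, TypedEdge, Vertex
from .ontology import OntologyDAG, read_obo


@dataclass
class FixtureSpec:
    """Parameters of one synthetic knowledge graph + ontology.

    ``planted_ctc`` maps a process id to the probability that it links to
    each member of the first seed's network (its expected CTC there);
    processes not listed are decoys linking to any gene with probability
    ``background_link_prob``.
    """

    n_genes: int = 100
    n_processes: int = 24
    seed_processes: tuple[str, ...] = ("GO:S0000001",)
    seed_process_fraction: float = 0.5
    planted_ctc: dict[str, float] = field(default_factory=dict)
    background_link_prob: float = 0.05
    gene_gene_edge_prob: float = 0.02
    ontology_depth: int = 3
    ontology_branching: int = 3
    part_of_fraction: float = 0.1
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("seed_process_fraction", "background_link_prob",
                     "gene_gene_edge_prob", "part_of_fraction"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name}={v} outside [0, 1]")
        for proc, f in self.planted_ctc.items():
            if not 0 <= f <= 1:
                raise ValueError(f"planted_ctc[{proc!r}]={f} outside [0, 1]")
        if self.n_genes < 1 or self.n_processes < 1:
            raise ValueError("counts must be >= 1")
        if self.ontology_depth < 1 or self.ontology_branching < 1:
            raise ValueError("ontology depth and branching must be >= 1")


def _gene_ids(n: int) -> list[str]:
    return [f"g{i:05d}" for i in range(1, n + 1)]


def process_ids(spec: FixtureSpec) -> list[str]:
    """Decoy/planted process ids: the first ``n_processes`` ontology leaves."""
    leaves = ontology_leaf_ids(spec)
    if spec.n_processes > len(leaves):
        raise ValueError(
            f"n_processes={spec.n_processes} exceeds the {len(leaves)} ontology leaves"
        )
    return leaves[: spec.n_processes]


def ontology_leaf_ids(spec: FixtureSpec) -> list[str]:
    depth, branching = spec.ontology_depth, spec.ontology_branching
    n_leaves = branching**depth
    first = sum(branching**d for d in range(depth)) + 1
    return [f"GO:T{first + i:07d}" for i in range(n_leaves)]


def make_knowledge_graph(spec: FixtureSpec) -> KnowledgeGraph:
    """Generate a knowledge graph with planted link structure.

    Seed processes annotate each gene independently with probability
    ``seed_process_fraction``.  Planted processes link to members of the
    *first* seed's network with their ``planted_ctc`` probability and to
    other genes at background rate; decoys use the background rate
    everywhere.  Gene–gene interaction edges are Bernoulli at
    ``gene_gene_edge_prob``.
    """
    rng = np.random.default_rng(spec.rng_seed)
    genes = _gene_ids(spec.n_genes)
    procs = process_ids(spec)
    unknown = set(spec.planted_ctc) - set(procs) - set(spec.seed_processes)
    if unknown:
        raise ValueError(f"planted_ctc names unknown processes: {sorted(unknown)}")

    kg = KnowledgeGraph()
    for g in genes:
        kg.add_vertex(Vertex(g, "gene", g))
    for s in spec.seed_processes:
        kg.add_vertex(Vertex(s, "process", s))
    for p in procs:
        kg.add_vertex(Vertex(p, "process", p))

    # seed annotations; every seed network is kept non-empty by forcing one link
    members: dict[str, list[str]] = {}
    for s in spec.seed_processes:
        draws = rng.random(spec.n_genes) < spec.seed_process_fraction
        chosen = [g for g, d in zip(genes, draws) if d]
        if not chosen:
            chosen = [genes[rng.integers(spec.n_genes)]]
        members[s] = chosen
        for g in chosen:
            kg.add_edge(TypedEdge(g, s, "participation", "literature"))
    first_members = set(members[spec.seed_processes[0]])

    for p in procs:
        target = spec.planted_ctc.get(p)
        for g in genes:
            prob = (
                target
                if target is not None and g in first_members
                else spec.background_link_prob
            )
            if rng.random() < prob:
                kg.add_edge(TypedEdge(g, p, "association", "literature"))

    draws = rng.random((spec.n_genes, spec.n_genes))
    for i in range(spec.n_genes):
        for j in range(i + 1, spec.n_genes):
            if draws[i, j] < spec.gene_gene_edge_prob:
                kg.add_edge(TypedEdge(genes[i], genes[j], "interaction", "factual_database"))
    return kg


def make_ontology(spec: FixtureSpec, path: str | Path | None = None) -> OntologyDAG:
    """Generate a toy ontology: complete ``is_a`` tree plus ``part_of`` cross-links.

    Term ids are assigned breadth-first (``GO:T0000001`` is the root).  Every
    ``part_of`` cross-link points from a term to a strictly shallower term
    that is not one of its ancestors, so acyclicity holds by construction.
    Seed-process terms are attached directly under the root.  If ``path``
    is given the ontology is also written there in OBO format.
    """
    rng = np.random.default_rng(spec.rng_seed + 1)
    depth, branching = spec.ontology_depth, spec.ontology_branching
    levels: list[list[str]] = [["GO:T0000001"]]
    counter = 1
    for _ in range(depth):
        nxt = []
        for _parent in levels[-1]:
            for _ in range(branching):
                counter += 1
                nxt.append(f"GO:T{counter:07d}")
        levels.append(nxt)

    relations: list[tuple[str, str, str]] = []
    for d in range(1, depth + 1):
        for i, term in enumerate(levels[d]):
            relations.append((term, levels[d - 1][i // branching], "is_a"))
    # part_of cross-links to a shallower, non-parent term
    all_terms = [t for lvl in levels for t in lvl]
    for d in range(2, depth + 1):
        for term in levels[d]:
            if rng.random() < spec.part_of_fraction:
                shallow = [t for lvl in levels[: d - 1] for t in lvl]
                target = shallow[rng.integers(len(shallow))]
                relations.append((term, target, "part_of"))
    for s in spec.seed_processes:
        relations.append((s, levels[0][0], "is_a"))
        all_terms.append(s)

    if path is not None:
        write_obo(all_terms, relations, path)
        return read_obo(path)
    return OntologyDAG.from_relations(relations, {t: t for t in all_terms})


def write_obo(
    terms: list[str], relations: list[tuple[str, str, str]], path: str | Path
) -> None:
    """Serialise terms and (child, parent, type) relations as an OBO flat file."""
    by_child: dict[str, list[tuple[str, str]]] = {}
    for child, parent, rel in relations:
        by_child.setdefault(child, []).append((parent, rel))
    chunks = ["format-version: 1.2", "ontology: synthetic-bp", ""]
    for t in terms:
        chunks.append("[Term]")
        chunks.append(f"id: {t}")
        chunks.append(f"name: {t}")
        chunks.append("namespace: biological_process")
        for parent, rel in sorted(by_child.get(t, [])):
            if rel == "is_a":
                chunks.append(f"is_a: {parent} ! {parent}")
            else:
                chunks.append(f"relationship: part_of {parent} ! {parent}")
        chunks.append("")
    Path(path).write_text("\n".join(chunks))


@dataclass
class ThreeConditionTruth:
    """Planted ground truth of the three-condition comparison fixture."""

    seeds: tuple[str, str, str]
    common: set[str]
    specific: dict[str, set[str]]


def make_three_condition_fixture(
    rng_seed: int = 0,
    *,
    n_shared: int = 24,
    n_private: int = 32,
    n_background_genes: int = 300,
    n_decoys: int = 18,
    membership_prob: float = 0.8,
    planted_link_prob: float = 0.8,
    background: float = 0.02,
) -> tuple[KnowledgeGraph, FixtureSpec, ThreeConditionTruth]:
    """Knowledge graph emulating the three-condition study design.

    Genes fall into a shared pool (candidate members of every seed
    network), three private pools (one per seed) and an unannotated
    background pool that widens the hypergeometric universe.  Three
    planted processes link strongly to every seed's members (the expected
    common core); one planted process per condition links strongly only to
    that seed's private members (the expected condition-specific finds);
    decoys link everywhere at background rate.  The seed processes
    themselves are excluded from scoring downstream: their saturated
    centrality in their own network is tautological.
    """
    seeds = ("GO:S0000001", "GO:S0000002", "GO:S0000003")
    n_genes = n_shared + 3 * n_private + n_background_genes
    spec = FixtureSpec(
        n_genes=n_genes,
        n_processes=n_decoys + 6,
        seed_processes=seeds,
        seed_process_fraction=membership_prob,
        background_link_prob=background,
        gene_gene_edge_prob=0.02,
        ontology_depth=3,
        ontology_branching=3,
        rng_seed=rng_seed,
    )
    procs = process_ids(spec)
    common = set(procs[:3])
    spec_ids = procs[3:6]
    truth = ThreeConditionTruth(
        seeds, common, {seeds[i]: {spec_ids[i]} for i in range(3)}
    )

    rng = np.random.default_rng(rng_seed)
    genes = _gene_ids(n_genes)
    shared_pool = set(genes[:n_shared])
    private_pool = [
        set(genes[n_shared + i * n_private : n_shared + (i + 1) * n_private])
        for i in range(3)
    ]
    kg = KnowledgeGraph()
    for g in genes:
        kg.add_vertex(Vertex(g, "gene", g))
    for pid in (*seeds, *procs):
        kg.add_vertex(Vertex(pid, "process", pid))

    members: dict[str, set[str]] = {}
    for i, s in enumerate(seeds):
        pool = shared_pool | private_pool[i]
        chosen = {g for g in sorted(pool) if rng.random() < membership_prob}
        if not chosen:
            chosen = {sorted(pool)[0]}
        members[s] = chosen
        for g in sorted(chosen):
            kg.add_edge(TypedEdge(g, s, "participation", "literature"))

    def link(process: str, strong_pool: set[str]) -> None:
        for g in genes:
            p = planted_link_prob if g in strong_pool else background
            if rng.random() < p:
                kg.add_edge(TypedEdge(g, process, "association", "literature"))

    all_members = set.union(*members.values())
    for p in sorted(common):
        link(p, all_members)
    for i, s in enumerate(seeds):
        link(spec_ids[i], members[s] & private_pool[i])
    for p in procs[6:]:
        link(p, set())

    for i in range(n_genes):
        for j in range(i + 1, n_genes):
            if rng.random() < spec.gene_gene_edge_prob:
                kg.add_edge(TypedEdge(genes[i], genes[j], "interaction", "factual_database"))
    return kg, spec, truth
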