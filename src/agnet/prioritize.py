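"""Cross-talk centrality prioritization of candidate biological processes.

Every candidate process is scored against a reconstructed network of M
gene/protein members:

* **CTC** (cross-talk centrality) = N_i / M, where N_i is the number of
  distinct network members the candidate is linked to in the knowledge
  graph.  CTC ranges over [0, 1]; 0 means the candidate touches no member.
* **p-value**: the upper-tail (inclusive) hypergeometric probability of
  observing N_i or more links by chance, drawing M genes from a universe of
  N_U annotated genes of which K are annotated to the candidate.
* **q-value**: Benjamini–Yekutieli FDR adjustment across all scored
  candidates of one run — the step-up procedure with the harmonic-sum
  factor c(m), valid under arbitrary dependence among the tests.

Candidates are ranked by CTC descending, ties broken by q-value ascending
then id lexicographic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .graph import AssociativeGeneNetwork, KnowledgeGraph, MOLECULAR_KINDS
from .reconstruct import candidate_links


@dataclass(frozen=True)
class ProcessScore:
    """One candidate process's score against one network."""

    process: str
    Ni: int
    M: int
    ctc: float
    p_value: float
    q_value: float
    rank: int
    name: str = ""


@dataclass
class UniverseSpec:
    """Sampling frame of the hypergeometric test.

    ``universe_size`` (N_U) — distinct gene/protein vertices in the whole
    knowledge graph that carry at least one process annotation;
    ``annotation_counts`` — per process, the number of distinct gene/protein
    vertices linked to it anywhere in the graph (K).
    """

    universe_size: int
    annotation_counts: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for proc, k in self.annotation_counts.items():
            if k > self.universe_size:
                raise ValueError(
                    f"annotation count {k} of {proc!r} exceeds universe size "
                    f"{self.universe_size}"
                )


def universe_from_graph(graph: KnowledgeGraph) -> UniverseSpec:
    """Derive the default sampling frame from the knowledge graph."""
    processes = graph.vertices_of_kind("process")
    annotated: set[str] = set()
    counts: dict[str, int] = {}
    for p in processes:
        genes = {v for v in graph.neighbors(p) if graph.kind_of(v) in MOLECULAR_KINDS}
        counts[p] = len(genes)
        annotated |= genes
    return UniverseSpec(len(annotated), counts)


def ctc(Ni: int, M: int) -> float:
    """Cross-talk centrality N_i / M."""
    if M < 1:
        raise ValueError("M must be >= 1")
    if not 0 <= Ni <= M:
        raise ValueError(f"Ni={Ni} outside [0, M={M}]")
    return Ni / M


def hypergeom_pvalue(Ni: int, M: int, K: int, N_U: int) -> float:
    """P(X >= Ni) with X ~ Hypergeometric(N_U population, K successes, M draws).

    Upper tail is inclusive: the chance of N_i *or more* links.
    """
    if not (0 <= K <= N_U and 1 <= M <= N_U):
        raise ValueError(f"inconsistent counts: K={K}, M={M}, N_U={N_U}")
    if Ni < 0 or Ni > min(M, K):
        raise ValueError(f"Ni={Ni} outside [0, min(M={M}, K={K})]")
    return float(stats.hypergeom.sf(Ni - 1, N_U, K, M))


def benjamini_yekutieli(pvalues) -> list[float]:
    """Benjamini–Yekutieli step-up q-values, in the input's original order.

    q_(i) = min_{j >= i} p_(j) * m * c(m) / j capped at 1, with
    c(m) = sum_{k=1..m} 1/k.  Monotone in p and always >= the
    Benjamini–Hochberg adjustment on the same input.
    """
    p = np.asarray(list(pvalues), dtype=float)
    if p.size == 0:
        return []
    if np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_by")[1].tolist()


def prioritize(
    graph: KnowledgeGraph,
    net: AssociativeGeneNetwork,
    candidates: list[str] | None = None,
    universe: UniverseSpec | None = None,
) -> list[ProcessScore]:
    """Score and rank candidate processes against a reconstructed network.

    ``candidates`` defaults to every process vertex of the graph; the
    sampling frame defaults to :func:`universe_from_graph`.  Candidates
    with zero annotated genes are skipped (they cannot be drawn), and the
    BY correction runs across all scored candidates of this call.
    """
    if candidates is None:
        candidates = graph.vertices_of_kind("process")
    if not candidates:
        raise ValueError("candidate list is empty")
    if len(set(candidates)) != len(candidates):
        raise ValueError("candidate list contains duplicates")
    if universe is None:
        universe = universe_from_graph(graph)

    scored: list[tuple[str, int, float, float]] = []
    for cand in candidates:
        K = universe.annotation_counts.get(cand, 0)
        if K == 0:
            continue
        Ni = candidate_links(graph, net, cand)
        p = hypergeom_pvalue(Ni, net.M, K, universe.universe_size)
        scored.append((cand, Ni, ctc(Ni, net.M), p))
    if not scored:
        raise ValueError("no scorable candidate (all annotation counts are zero)")

    qvals = benjamini_yekutieli([s[3] for s in scored])
    order = sorted(
        range(len(scored)),
        key=lambda i: (-scored[i][2], qvals[i], scored[i][0]),
    )
    out = [None] * len(scored)
    for rank, i in enumerate(order, start=1):
        cand, Ni, c, p = scored[i]
        name = graph.vertex(cand).name if cand in graph else cand
        out[i] = ProcessScore(cand, Ni, net.M, c, p, qvals[i], rank, name)
    return sorted(out, key=lambda s: s.rank)


def significant(scores: list[ProcessScore], alpha: float = 0.05) -> list[ProcessScore]:
    """Subset of scores with q-value below ``alpha``, ranking order preserved."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    return [s for s in sorted(scores, key=lambda s: s.rank) if s.q_value < alpha]


def scores_to_frame(scores: list[ProcessScore]):
    """Ranking as a DataFrame with the TSV output column layout."""
    import pandas as pd

    rows = [
        {
            "process_id": s.process,
            "process_name": s.name,
            "Ni": s.Ni,
            "M": s.M,
            "ctc": s.ctc,
            "p_value": s.p_value,
            "q_value": s.q_value,
            "rank": s.rank,
        }
        for s in sorted(scores, key=lambda s: s.rank)
    ]
    return pd.DataFrame(rows)


def write_ranking(scores: list[ProcessScore], path) -> None:
    scores_to_frame(scores).to_csv(path, sep="\t", index=False, float_format="%.8g")


def read_ranking(path) -> list[ProcessScore]:
    """Read a ranking TSV back into :class:`ProcessScore` records."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype={"process_id": str, "process_name": str})
    df["process_name"] = df["process_name"].fillna("")
    return [
        ProcessScore(
            r.process_id, int(r.Ni), int(r.M), float(r.ctc),
            float(r.p_value), float(r.q_value), int(r.rank), r.process_name,
        )
        for r in df.itertuples()
    ]
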