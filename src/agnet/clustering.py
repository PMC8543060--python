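"""Markov clustering of significant processes by semantic similarity.

The pairwise Wang similarity matrix of the significant processes is fed to
the Markov Cluster algorithm (MCL): the matrix, with unit self-loops, is
column-normalised into a stochastic flow matrix, then *expansion* (matrix
squaring) and *inflation* (element-wise power followed by column
renormalisation) alternate until the flow stabilises.  Rows that retain
flow on their own diagonal are attractors; each attractor together with
the columns flowing into it forms a cluster, and attractor systems that
share nodes merge.  Inflation (default 2.0) controls granularity: higher
values give more, smaller clusters.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .ontology import OntologyDAG, wang_similarity

logger = logging.getLogger("agnet")


@dataclass
class SimilarityMatrix:
    """Symmetric process-by-process similarity with unit diagonal."""

    ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if v.shape != (n, n):
            raise ValueError(f"matrix shape {v.shape} does not match {n} ids")
        if not np.allclose(v, v.T):
            raise ValueError("similarity matrix must be symmetric")
        if np.any(v < 0) or np.any(v > 1 + 1e-9):
            raise ValueError("similarities must lie in [0, 1]")
        if not np.allclose(np.diag(v), 1.0):
            raise ValueError("similarity matrix must have unit diagonal")
        self.values = v


@dataclass
class ClusterAssignment:
    """Partition of processes into clusters labelled 1..n_clusters."""

    mapping: dict[str, int]
    n_clusters: int


def similarity_matrix(
    dag: OntologyDAG,
    processes: list[str],
    weights: dict[str, float] | None = None,
) -> SimilarityMatrix:
    """Pairwise Wang similarity of ``processes``.

    Processes absent from the ontology get similarity 0 to everything
    except themselves (knowledge-base dictionaries and ontology releases
    drift), with a warning.
    """
    if not processes:
        raise ValueError("process list is empty")
    n = len(processes)
    missing = [p for p in processes if p not in dag]
    if missing:
        logger.warning(
            "%d of %d processes missing from ontology; their similarities are 0",
            len(missing), n,
        )
    resolvable = set(processes) - set(missing)
    mat = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            a, b = processes[i], processes[j]
            if a in resolvable and b in resolvable:
                mat[i, j] = mat[j, i] = wang_similarity(dag, a, b, weights)
    return SimilarityMatrix(list(processes), mat)


def _normalize_columns(m: np.ndarray) -> np.ndarray:
    sums = m.sum(axis=0)
    sums[sums == 0] = 1.0
    return m / sums


def mcl_cluster(
    sim: SimilarityMatrix,
    inflation: float = 2.0,
    *,
    expansion: int = 2,
    self_loop: float = 1.0,
    pruning_threshold: float = 1e-5,
    tolerance: float = 1e-8,
    max_iterations: int = 200,
    sim_threshold: float = 0.0,
) -> ClusterAssignment:
    """Cluster processes with the Markov Cluster algorithm.

    Deterministic for fixed input and parameters.  On non-convergence
    within ``max_iterations`` a warning is logged and the last iterate is
    clustered.  Nodes left without an attractor join the cluster of their
    highest-similarity neighbour (singleton if they have none).
    """
    if inflation <= 1:
        raise ValueError("inflation must exceed 1")
    n = len(sim.ids)
    m = sim.values.copy()
    if sim_threshold > 0:
        m = np.where(m >= sim_threshold, m, 0.0)
    np.fill_diagonal(m, self_loop)
    m = _normalize_columns(m)

    converged = False
    for _ in range(max_iterations):
        expanded = np.linalg.matrix_power(m, expansion)
        inflated = _normalize_columns(np.power(expanded, inflation))
        inflated[inflated < pruning_threshold] = 0.0
        inflated = _normalize_columns(inflated)
        if np.abs(inflated - m).max() < tolerance:
            m = inflated
            converged = True
            break
        m = inflated
    if not converged:
        logger.warning("MCL did not converge in %d iterations; clustering last iterate",
                       max_iterations)

    # attractors: rows keeping flow on their own diagonal
    attractors = [i for i in range(n) if m[i, i] > 0]
    # merge attractor systems that claim common nodes (union-find)
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(a: int, b: int) -> None:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[max(ra, rb)] = min(ra, rb)

    claimed: dict[int, int] = {}
    for a in attractors:
        union(a, a)
        for j in np.nonzero(m[a] > 0)[0]:
            if j in claimed:
                union(a, claimed[j])
            else:
                claimed[int(j)] = a
            union(a, int(j))

    # orphans: nodes no attractor row reaches
    for j in range(n):
        if j in claimed:
            continue
        nbrs = np.argsort(-sim.values[j])
        attached = False
        for k in nbrs:
            if k != j and sim.values[j, k] > 0 and int(k) in claimed:
                union(int(j), int(k))
                attached = True
                break
        if not attached:
            parent[j] = j  # singleton

    roots = sorted({find(i) for i in range(n)})
    label_of_root = {r: lab for lab, r in enumerate(roots, start=1)}
    mapping = {sim.ids[i]: label_of_root[find(i)] for i in range(n)}
    return ClusterAssignment(mapping, len(roots))


def write_clusters(assignment: ClusterAssignment, path) -> None:
    """TSV export: process_id, cluster_label."""
    lines = ["process_id\tcluster"]
    for pid in sorted(assignment.mapping):
        lines.append(f"{pid}\t{assignment.mapping[pid]}")
    from pathlib import Path

    Path(path).write_text("\n".join(lines) + "\n")
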