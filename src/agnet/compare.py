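"""Comparison of significant-process sets across several networks.

Given per-condition rankings, the processes with q-value below the
threshold form one set per condition; the comparison reports the common
core (significant in every condition), all pairwise intersections, and the
condition-specific remainders (significant in exactly one condition).
Processes are matched across conditions by term id, never by name string.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from pathlib import Path

import pandas as pd

from .prioritize import ProcessScore, significant


@dataclass
class ComparisonResult:
    condition_names: list[str]
    per_condition_significant: dict[str, set[str]]
    common_all: set[str]
    pairwise_common: dict[tuple[str, str], set[str]]
    specific: dict[str, set[str]]


def compare(
    rankings: dict[str, list[ProcessScore]], alpha: float = 0.05
) -> ComparisonResult:
    """Compute common and condition-specific significant processes.

    Requires at least two conditions.  Deterministic and invariant to the
    order in which conditions are supplied (up to key names).
    """
    if len(rankings) < 2:
        raise ValueError("comparison requires at least two conditions")
    names = list(rankings)
    sets = {
        cond: {s.process for s in significant(scores, alpha)}
        for cond, scores in rankings.items()
    }
    common_all = set.intersection(*sets.values())
    pairwise = {
        (a, b): sets[a] & sets[b] for a, b in combinations(names, 2)
    }
    spec = {
        cond: {
            p for p in sets[cond]
            if not any(p in sets[o] for o in names if o != cond)
        }
        for cond in names
    }
    return ComparisonResult(names, sets, common_all, pairwise, spec)


def _category(result: ComparisonResult, process: str) -> str:
    if process in result.common_all:
        return "common_all"
    conds = [c for c in result.condition_names if process in result.per_condition_significant[c]]
    if len(conds) == 1:
        return f"specific:{conds[0]}"
    if len(conds) >= 2:
        return "pairwise"
    return "other"


def comparison_frame(result: ComparisonResult) -> pd.DataFrame:
    """Membership table: one row per process significant anywhere."""
    processes = sorted(set.union(*result.per_condition_significant.values()))
    rows = []
    for p in processes:
        row: dict[str, object] = {"process_id": p}
        for cond in result.condition_names:
            row[cond] = (
                "significant" if p in result.per_condition_significant[cond] else "not"
            )
        row["category"] = _category(result, p)
        rows.append(row)
    return pd.DataFrame(rows, columns=["process_id", *result.condition_names, "category"])


def report(result: ComparisonResult, path: str | Path) -> None:
    """Write the membership table as TSV; processes significant nowhere are absent."""
    comparison_frame(result).to_csv(path, sep="\t", index=False)
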