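"""CTC, hypergeometric significance, BY correction and ranking."""

import itertools
import math
import random

import numpy as np
import pytest
from statsmodels.stats.multitest import multipletests

from agnet import (
    UniverseSpec,
    benjamini_yekutieli,
    ctc,
    hypergeom_pvalue,
    prioritize,
    read_ranking,
    reconstruct,
    significant,
    universe_from_graph,
    write_ranking,
)

from conftest import build_graph, random_kg


def hypergeom_by_enumeration(Ni, M, K, N_U):
    """Oracle: count draws of size M with >= Ni successes among C(N_U, M)."""
    population = range(N_U)
    successes = set(range(K))
    hits = sum(
        1 for draw in itertools.combinations(population, M)
        if len(successes.intersection(draw)) >= Ni
    )
    return hits / math.comb(N_U, M)


def by_from_definition(pvalues):
    """Oracle: BY step-up straight from the definition."""
    m = len(pvalues)
    c_m = sum(1.0 / k for k in range(1, m + 1))
    order = sorted(range(m), key=lambda i: pvalues[i])
    q = [0.0] * m
    running = 1.0
    for pos in range(m - 1, -1, -1):
        i = order[pos]
        running = min(running, pvalues[i] * m * c_m / (pos + 1))
        q[i] = running
    return q


class TestCtc:
    @pytest.mark.parametrize("Ni,M,expected", [(0, 292, 0.0), (10, 10, 1.0), (3, 10, 0.3)])
    def test_ratio(self, Ni, M, expected):
        assert ctc(Ni, M) == expected

    def test_contract_violations(self):
        with pytest.raises(ValueError):
            ctc(11, 10)
        with pytest.raises(ValueError):
            ctc(0, 0)


class TestHypergeomPvalue:
    def test_zero_links_is_certain(self):
        assert hypergeom_pvalue(0, 5, 3, 10) == 1.0

    def test_small_worked_example(self):
        # all C(10,5)=252 draws; 186 contain >= 2 of the 4 successes
        assert hypergeom_pvalue(2, 5, 4, 10) == pytest.approx(186 / 252, abs=1e-12)
        assert hypergeom_by_enumeration(2, 5, 4, 10) == pytest.approx(186 / 252)

    def test_saturated_universe_is_certain(self):
        assert hypergeom_pvalue(5, 5, 10, 10) == 1.0

    def test_inconsistent_counts_rejected(self):
        with pytest.raises(ValueError):
            hypergeom_pvalue(3, 5, 2, 10)
        with pytest.raises(ValueError):
            hypergeom_pvalue(1, 5, 11, 10)

    def test_matches_enumeration_on_small_frames(self):
        for N_U in (4, 7, 9):
            for K in range(N_U + 1):
                for M in range(1, N_U + 1):
                    for Ni in range(min(M, K) + 1):
                        assert hypergeom_pvalue(Ni, M, K, N_U) == pytest.approx(
                            hypergeom_by_enumeration(Ni, M, K, N_U), abs=1e-12)


class TestBenjaminiYekutieli:
    def test_single_p_unchanged(self):
        assert benjamini_yekutieli([0.03]) == pytest.approx([0.03])

    def test_hand_worked_triple(self):
        # c(3) = 11/6; step-up gives (0.055, 0.055, 1.0)
        assert benjamini_yekutieli([0.01, 0.02, 0.9]) == pytest.approx(
            [0.055, 0.055, 1.0])

    def test_empty_and_invalid(self):
        assert benjamini_yekutieli([]) == []
        with pytest.raises(ValueError):
            benjamini_yekutieli([0.0, 0.5])
        with pytest.raises(ValueError):
            benjamini_yekutieli([1.5])

    def test_matches_definition_and_dominates_bh(self):
        rng = np.random.default_rng(42)
        for _ in range(200):
            m = int(rng.integers(1, 200))
            p = rng.uniform(1e-12, 1.0, size=m)
            q = benjamini_yekutieli(p)
            assert q == pytest.approx(by_from_definition(list(p)), abs=1e-12)
            bh = multipletests(p, method="fdr_bh")[1]
            assert np.all(np.asarray(q) >= bh - 1e-12)

    def test_order_preserving(self):
        rng = np.random.default_rng(3)
        p = rng.uniform(0.001, 1.0, size=50)
        q = benjamini_yekutieli(p)
        for i in range(50):
            for j in range(50):
                if p[i] <= p[j]:
                    assert q[i] <= q[j] + 1e-12


class TestPrioritize:
    @staticmethod
    def _kg_with_extremes():
        vertices = [(f"g{i}", "gene") for i in range(6)] + [
            ("P0", "process"), ("Pfull", "process"), ("Pnone", "process"),
            ("Pother", "process")]
        edges = [(f"g{i}", "P0", "participation") for i in range(4)]
        edges += [(f"g{i}", "Pfull", "association") for i in range(4)]
        edges += [("g4", "Pnone", "association"), ("g5", "Pnone", "association")]
        edges += [("g0", "Pother", "association")]
        return build_graph(vertices, edges)

    def test_extremes_rank_correctly(self):
        kg = self._kg_with_extremes()
        net = reconstruct(kg, "P0")
        scores = {s.process: s for s in prioritize(kg, net, ["Pnone", "Pfull"])}
        assert scores["Pfull"].rank == 1 and scores["Pfull"].ctc == 1.0
        assert scores["Pnone"].rank == 2 and scores["Pnone"].ctc == 0.0

    def test_tie_break_by_qvalue_then_id(self):
        kg = self._kg_with_extremes()
        net = reconstruct(kg, "P0")
        # Pnone and Pother: Pnone has ctc 0; Pother ctc 0.25
        out = prioritize(kg, net, ["Pnone", "Pother", "Pfull"])
        assert [s.process for s in out] == ["Pfull", "Pother", "Pnone"]

    def test_ranks_are_permutation_and_order_invariant(self, rng):
        kg, genes, procs = random_kg(rng, n_genes=30, n_processes=10, link_p=0.3)
        net = reconstruct(kg, "P0")
        out1 = prioritize(kg, net, procs)
        shuffled = procs[:]
        rng.shuffle(shuffled)
        out2 = prioritize(kg, net, shuffled)
        assert sorted(s.rank for s in out1) == list(range(1, len(out1) + 1))
        assert {s.process: s.rank for s in out1} == {s.process: s.rank for s in out2}

    def test_unannotated_candidates_skipped(self):
        kg = self._kg_with_extremes()
        kg_vertices = [("Porphan", "process")]
        from agnet import Vertex
        kg.add_vertex(Vertex("Porphan", "process", "Porphan"))
        net = reconstruct(kg, "P0")
        out = prioritize(kg, net, ["Pfull", "Porphan"])
        assert [s.process for s in out] == ["Pfull"]

    def test_empty_candidates_error(self):
        kg = self._kg_with_extremes()
        net = reconstruct(kg, "P0")
        with pytest.raises(ValueError):
            prioritize(kg, net, [])

    def test_pvalue_never_exceeds_qvalue(self, rng):
        kg, genes, procs = random_kg(rng, n_genes=30, n_processes=12, link_p=0.2)
        net = reconstruct(kg, "P0")
        for s in prioritize(kg, net, procs):
            assert 0 < s.p_value <= s.q_value <= 1
            assert s.ctc == s.Ni / s.M

    def test_universe_consistency_enforced(self):
        with pytest.raises(ValueError):
            UniverseSpec(5, {"P": 6})


class TestSignificant:
    def test_all_ones_filtered_out(self):
        kg = TestPrioritize._kg_with_extremes()
        net = reconstruct(kg, "P0")
        scores = prioritize(kg, net, ["Pnone"])
        assert significant(scores, 0.05) == []

    def test_alpha_near_one_keeps_everything(self, rng):
        kg, genes, procs = random_kg(rng, n_genes=20, n_processes=8)
        net = reconstruct(kg, "P0")
        scores = prioritize(kg, net, procs)
        assert significant(scores, 0.999999) == [
            s for s in scores if s.q_value < 0.999999]

    def test_matches_linear_scan(self, rng):
        kg, genes, procs = random_kg(rng, n_genes=30, n_processes=12, link_p=0.3)
        net = reconstruct(kg, "P0")
        scores = prioritize(kg, net, procs)
        for alpha in (0.01, 0.05, 0.5):
            expected = [s for s in scores if s.q_value < alpha]
            assert significant(scores, alpha) == expected


class TestRankingIO:
    def test_round_trip(self, tmp_path, rng):
        kg, genes, procs = random_kg(rng, n_genes=25, n_processes=10, link_p=0.3)
        net = reconstruct(kg, "P0")
        scores = prioritize(kg, net, procs)
        path = tmp_path / "ranking.tsv"
        write_ranking(scores, path)
        back = read_ranking(path)
        assert [s.process for s in back] == [s.process for s in scores]
        assert [s.rank for s in back] == [s.rank for s in scores]
        for a, b in zip(back, scores):
            assert a.q_value == pytest.approx(b.q_value, rel=1e-6)
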