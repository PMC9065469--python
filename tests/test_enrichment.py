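"""Hypergeometric over-representation, BH-FDR, and the evidence filter."""

from itertools import combinations
from math import comb

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from fibronet.enrichment import (
    EnrichmentResult,
    GeneSet,
    apply_evidence_filter,
    bh_fdr,
    enrich_sets,
    hypergeometric_test,
    read_gmt,
    write_gmt,
)
from fibronet.errors import ContractError, InputError


def exhaustive_upper_tail(k, n, K, N):
    """Oracle: enumerate all C(N, n) draws from an explicit urn."""
    urn = list(range(N))
    successes = set(range(K))
    hits = sum(1 for draw in combinations(urn, n) if len(successes & set(draw)) >= k)
    return hits / comb(N, n)


class TestHypergeometric:
    def test_zero_overlap_is_one(self):
        assert hypergeometric_test(0, 5, 4, 10) == 1.0

    def test_forced_full_draw(self):
        assert hypergeometric_test(4, 10, 4, 10) == pytest.approx(1.0)

    def test_worked_urn(self):
        # N=10, K=4, n=5: P(X>=3) = (C(4,3)C(6,2)+C(4,4)C(6,1))/C(10,5) = 66/252
        assert hypergeometric_test(3, 5, 4, 10) == pytest.approx(66 / 252, abs=1e-12)

    def test_matches_enumeration_on_small_urns(self):
        for N in (4, 7, 9):
            for K in range(0, N + 1, 2):
                for n in range(1, N + 1, 2):
                    for k in range(0, min(n, K) + 1):
                        assert hypergeometric_test(k, n, K, N) == pytest.approx(
                            exhaustive_upper_tail(k, n, K, N), abs=1e-12
                        )

    def test_tail_is_non_increasing_in_k(self):
        p_prev = 1.0
        for k in range(0, 5):
            p = hypergeometric_test(k, 6, 5, 12)
            assert p <= p_prev + 1e-15
            p_prev = p

    def test_bounds_violation_rejected(self):
        with pytest.raises(ContractError):
            hypergeometric_test(5, 4, 4, 10)
        with pytest.raises(ContractError):
            hypergeometric_test(1, 4, 11, 10)


class TestBH:
    def test_single_p(self):
        assert bh_fdr([0.03]) == pytest.approx([0.03])

    def test_hand_stepup(self):
        # ranks 1..3, q_i = min over j>=i of p_j*m/rank_j -> all 0.03
        assert bh_fdr([0.01, 0.02, 0.03]) == pytest.approx([0.03, 0.03, 0.03])

    def test_all_ones(self):
        assert bh_fdr([1.0, 1.0, 1.0]) == pytest.approx([1.0, 1.0, 1.0])

    @given(st.permutations(list(range(6))))
    def test_order_invariance(self, perm):
        p = [0.001, 0.2, 0.04, 0.5, 0.04, 0.9]
        shuffled = [p[i] for i in perm]
        q_shuffled = bh_fdr(shuffled)
        q_direct = bh_fdr(p)
        for pos, i in enumerate(perm):
            assert q_shuffled[pos] == pytest.approx(q_direct[i])


class TestGMT:
    def test_read_two_sets(self, tmp_path):
        path = tmp_path / "sets.gmt"
        path.write_text("S1\tdesc;category=pathway\tA\tB\nS2\tdesc;category=disease\tC\tD\tD\n")
        sets = read_gmt(path)
        assert len(sets) == 2
        assert sets[1].members == {"C", "D"}  # duplicates collapsed
        assert sets[0].category == "pathway" and sets[1].category == "disease"

    def test_malformed_and_empty_lines_dropped(self, tmp_path):
        path = tmp_path / "sets.gmt"
        path.write_text("only_one_field\nS1\tdesc\tA\n\n")
        sets = read_gmt(path)
        assert [s.set_id for s in sets] == ["S1"]

    def test_roundtrip(self, tmp_path):
        sets = [
            GeneSet("S1", "alpha;category=pathway", "pathway", frozenset({"A", "B"})),
            GeneSet("S2", "beta;category=disease", "disease", frozenset({"C"})),
        ]
        back = read_gmt(write_gmt(sets, tmp_path / "x.gmt"))
        assert {(s.set_id, s.category, s.members) for s in back} == {
            (s.set_id, s.category, s.members) for s in sets
        }


class TestEnrichSets:
    def setup_method(self):
        self.sets = [
            GeneSet("HIT", "x;category=pathway", "pathway", frozenset({"A", "B", "C", "D"})),
            GeneSet("MISS", "y;category=pathway", "pathway",
                    frozenset({f"Z{i}" for i in range(10)})),
        ]
        self.background = {"A", "B", "C", "D"} | {f"Z{i}" for i in range(10)}

    def test_disjoint_set_not_significant(self):
        results = {r.set_id: r for r in enrich_sets(["A", "B", "C"], self.sets)}
        assert results["MISS"].n_overlap == 0
        assert results["MISS"].p_value == 1.0
        assert not results["MISS"].significant

    def test_overlap_matches_naive_intersection(self):
        targets = ["A", "B", "Z1"]
        for res in enrich_sets(targets, self.sets):
            members = next(s.members for s in self.sets if s.set_id == res.set_id)
            assert res.n_overlap == len(members & set(targets))
            assert res.overlap_ids == members & set(targets)

    def test_empty_background_fatal(self):
        with pytest.raises(InputError):
            enrich_sets(["A"], [], background=[])

    def test_planted_set_is_significant(self, synthetic_data, pipeline_run):
        _, manifest = synthetic_data
        summary, _ = pipeline_run
        assert manifest.planted_enriched_sets[0] in summary["enrichment"]["kept_set_ids"]


class TestEvidenceFilter:
    def make_result(self, n_overlap, ids=None):
        ids = ids or frozenset(f"G{i}" for i in range(n_overlap))
        return EnrichmentResult(
            set_id="S", set_name="s", category="pathway",
            n_overlap=n_overlap, overlap_ids=frozenset(ids), p_value=0.001,
        )

    def test_worked_pathway_example(self):
        # 19-target overlap with 4 known and 6 DE members passes all three rules
        overlap = frozenset(f"G{i}" for i in range(19))
        known = set(list(sorted(overlap))[:4])
        de = set(list(sorted(overlap))[4:10])
        res = self.make_result(19, overlap)
        kept = apply_evidence_filter([res], known, de)
        assert kept == [res]
        assert res.n_known_targets == 4 and res.n_known_de_genes == 6
        assert res.de_fraction == pytest.approx(6 / 19)

    def test_small_overlap_dropped_regardless(self):
        res = self.make_result(9)
        assert apply_evidence_filter([res], set(res.overlap_ids), set(res.overlap_ids)) == []

    def test_de_fraction_boundary_is_strict(self):
        overlap = frozenset(f"G{i}" for i in range(20))
        known = set(list(sorted(overlap))[:2])
        de = set(list(sorted(overlap))[:2])  # 2/20 = 0.10 exactly -> not > 0.10
        assert apply_evidence_filter([self.make_result(20, overlap)], known, de) == []

    def test_tightening_thresholds_never_adds_sets(self):
        overlap = frozenset(f"G{i}" for i in range(15))
        known = set(list(sorted(overlap))[:3])
        de = set(list(sorted(overlap))[:5])
        res = [self.make_result(15, overlap)]
        base = {r.set_id for r in apply_evidence_filter(res, known, de)}
        for kwargs in ({"min_overlap": 16}, {"min_known": 4}, {"min_de_frac": 0.5}):
            tight = {r.set_id for r in apply_evidence_filter(res, known, de, **kwargs)}
            assert tight <= base
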