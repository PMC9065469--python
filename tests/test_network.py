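"""Fingerprints, Tanimoto similarity, and the seed-anchored network build."""

import networkx as nx
import numpy as np
import pytest
from rdkit.DataStructs.cDataStructs import ExplicitBitVect

from fibronet.errors import ContractError, InputError
from fibronet.library import library_from_records
from fibronet.network import (
    Fingerprint,
    build_activity_network,
    compute_fingerprint,
    export_network,
    network_summary,
    pairwise_similarity_matrix,
    tanimoto_similarity,
)


def bitvec(on_bits, n_bits=16):
    vec = ExplicitBitVect(n_bits)
    for b in on_bits:
        vec.SetBit(b)
    return Fingerprint(bits=vec)


class TestFingerprint:
    def test_notation_invariance(self):
        assert compute_fingerprint("CCO").on_bits == compute_fingerprint("OCC").on_bits

    def test_methane_has_set_bits(self):
        assert compute_fingerprint("C").n_on >= 1

    def test_parse_failure_names_compound(self):
        from fibronet.library import Compound

        bad = Compound(
            compound_id="badmol", name="b", smiles="C1CC", compound_class="other", is_seed=False
        )
        with pytest.raises(InputError, match="badmol"):
            compute_fingerprint(bad)


class TestTanimoto:
    def test_self_similarity_is_one(self):
        fp = compute_fingerprint("CC(=O)Oc1ccccc1C(=O)O")
        assert tanimoto_similarity(fp, fp) == 1.0

    def test_disjoint_is_zero(self):
        assert tanimoto_similarity(bitvec({1, 2}), bitvec({5, 6})) == 0.0

    def test_known_overlap(self):
        # |{2,3}| / |{1,2,3,4}| = 0.5 by direct set arithmetic
        assert tanimoto_similarity(bitvec({1, 2, 3}), bitvec({2, 3, 4})) == 0.5

    def test_empty_pair_convention(self):
        assert tanimoto_similarity(bitvec(set()), bitvec(set())) == 1.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ContractError):
            tanimoto_similarity(bitvec({1}, 16), bitvec({1}, 32))


class TestSimilarityMatrix:
    def test_single_compound(self):
        lib = library_from_records([("a", "a", "CCO", "other", True)])
        mat = pairwise_similarity_matrix(lib)
        assert mat.shape == (1, 1) and mat.iloc[0, 0] == 1.0

    def test_symmetric_unit_diagonal_and_pairwise_oracle(self):
        lib = library_from_records(
            [("a", "a", "CCO", "other", True), ("b", "b", "CCCO", "other", False),
             ("c", "c", "c1ccccc1O", "other", False), ("d", "d", "CC(=O)O", "other", False)]
        )
        mat = pairwise_similarity_matrix(lib)
        assert np.allclose(mat.values, mat.values.T)
        assert np.allclose(np.diag(mat.values), 1.0)
        for x in lib.ids:
            for y in lib.ids:
                expected = tanimoto_similarity(
                    compute_fingerprint(lib.get(x)), compute_fingerprint(lib.get(y))
                )
                assert mat.loc[x, y] == pytest.approx(expected, abs=1e-12)


class TestNetworkBuild:
    def test_candidates_match_matrix_oracle(self, synthetic_library):
        lib, _ = synthetic_library
        tau = 0.5
        net = build_activity_network(lib, tau=tau)
        mat = pairwise_similarity_matrix(lib)
        seeds = sorted(lib.seed_ids)
        expected = {
            cid for cid in lib.ids
            if cid not in lib.seed_ids and max(mat.loc[cid, s] for s in seeds) > tau
        }
        assert set(net.candidate_ids) == expected
        # every stored edge involves a seed and strictly exceeds tau
        for edge in net.edges:
            assert edge.source_id in lib.seed_ids or edge.target_id in lib.seed_ids
            assert edge.similarity > tau
        # every candidate has at least one seed edge
        linked = set()
        for edge in net.edges:
            linked.update((edge.source_id, edge.target_id))
        assert set(net.candidate_ids) <= linked

    def test_raising_tau_shrinks_network(self, synthetic_library):
        lib, _ = synthetic_library
        prev_nodes, prev_edges = None, None
        for tau in (0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9):
            net = build_activity_network(lib, tau=tau)
            nodes, edges = set(net.node_ids), set(net.edges and {(e.source_id, e.target_id) for e in net.edges} or set())
            if prev_nodes is not None:
                assert nodes <= prev_nodes
                assert edges <= prev_edges
            prev_nodes, prev_edges = nodes, edges

    def test_tau_one_keeps_only_seeds(self, synthetic_library):
        lib, _ = synthetic_library
        net = build_activity_network(lib, tau=1.0)
        assert set(net.node_ids) == lib.seed_ids
        assert net.n_edges == 0

    def test_planted_family_recovery(self, synthetic_library):
        """Candidates at tau=0.5 recover planted family members with high fidelity."""
        lib, manifest = synthetic_library
        net = build_activity_network(lib, tau=0.5)
        truth = set(manifest.network_compound_ids) - set(manifest.planted_seed_ids)
        found = set(net.candidate_ids)
        tp = len(found & truth)
        precision = tp / len(found)
        recall = tp / len(truth)
        assert precision >= 0.9 and recall >= 0.9

    def test_zero_seeds_fatal(self):
        lib = library_from_records([("a", "a", "CCO", "other", False)])
        with pytest.raises(InputError):
            build_activity_network(lib)

    def test_candidate_edge_policy_only_adds_edges(self, synthetic_library):
        lib, _ = synthetic_library
        base = build_activity_network(lib, tau=0.5, include_candidate_edges=False)
        full = build_activity_network(lib, tau=0.5, include_candidate_edges=True)
        assert set(base.node_ids) == set(full.node_ids)  # node set is policy-invariant
        assert set(base.edges) <= set(full.edges)


class TestSummaryAndExport:
    def test_summary_conservation(self, synthetic_library):
        lib, _ = synthetic_library
        net = build_activity_network(lib, tau=0.5)
        summary = network_summary(net, lib)
        assert summary["n_nodes"] == summary["n_seeds"] + summary["n_candidates"]
        assert sum(summary["candidate_class_counts"].values()) == summary["n_candidates"]

    def test_graphml_roundtrip(self, synthetic_library, tmp_path):
        lib, _ = synthetic_library
        net = build_activity_network(lib, tau=0.5)
        path = export_network(net, tmp_path / "net.graphml", "graphml", lib)
        back = nx.read_graphml(path)
        assert set(back.nodes) == set(net.node_ids)
        assert back.number_of_edges() == net.n_edges
        for _, _, data in back.edges(data=True):
            assert data["similarity"] > net.tau

    def test_sif_line_count(self, synthetic_library, tmp_path):
        lib, _ = synthetic_library
        net = build_activity_network(lib, tau=0.5)
        path = export_network(net, tmp_path / "net.sif", "sif")
        lines = path.read_text().strip().splitlines()
        linked = set()
        for edge in net.edges:
            linked.update((edge.source_id, edge.target_id))
        isolated = [n for n in net.node_ids if n not in linked]
        assert len(lines) == net.n_edges + len(isolated)

    def test_edge_tsv_format(self, synthetic_library, tmp_path):
        lib, _ = synthetic_library
        net = build_activity_network(lib, tau=0.5)
        path = export_network(net, tmp_path / "edges.tsv", "edge_tsv")
        lines = path.read_text().strip().splitlines()
        assert lines[0] == "source\ttarget\tsimilarity"
        assert len(lines) == net.n_edges + 1

    def test_unknown_format_rejected(self, synthetic_library, tmp_path):
        from fibronet.errors import ConfigError

        lib, _ = synthetic_library
        net = build_activity_network(lib, tau=0.5)
        with pytest.raises(ConfigError):
            export_network(net, tmp_path / "x", "xlsx")
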