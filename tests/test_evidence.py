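"""Affinity filtering and differential-expression calling."""

import numpy as np
import pandas as pd
import pytest

from fibronet.errors import InputError
from fibronet.evidence import (
    ExpressionMatrix,
    InteractionRecord,
    call_differential_genes,
    differential_expression_table,
    filter_known_interactions,
    map_evidence_to_targets,
    read_expression_matrix,
    read_interaction_table,
)


def make_matrix(values: dict, n_ctrl=3, n_trt=3, compound="cpd1"):
    """values: gene -> (control levels, treated levels); symbols upper-cased
    to match the reader's convention."""
    genes = [g.upper() for g in values]
    values = {g.upper(): v for g, v in values.items()}
    samples = [f"C{i}" for i in range(n_ctrl)] + [f"T{i}" for i in range(n_trt)]
    data = [list(values[g][0]) + list(values[g][1]) for g in genes]
    frame = pd.DataFrame(data, index=genes, columns=samples, dtype=float)
    groups = pd.DataFrame(
        {
            "group": ["control"] * n_ctrl + ["treated"] * n_trt,
            "compound_id": [""] * n_ctrl + [compound] * n_trt,
        },
        index=samples,
    )
    return ExpressionMatrix(values=frame, sample_groups=groups)


class TestInteractions:
    def test_read_rejects_non_numeric_values(self, tmp_path):
        path = tmp_path / "i.tsv"
        path.write_text(
            "compound_id\ttarget_id\tmeasure\tvalue_nm\tsource\n"
            "c1\tT1\tIC50\t4600\tx\n"
            "c2\tT2\tIC50\tabc\tx\n"
        )
        records = read_interaction_table(path)
        assert len(records) == 1 and records[0].target_id == "T1"

    def test_roundtrip_preserves_records(self, tmp_path):
        path = tmp_path / "i.tsv"
        path.write_text(
            "compound_id\ttarget_id\tmeasure\tvalue_nm\tsource\n"
            "c1\tT1\tKd\t120.5\tchembl\n"
        )
        rec = read_interaction_table(path)[0]
        assert rec == InteractionRecord("c1", "T1", "Kd", 120.5, "chembl")

    @pytest.mark.parametrize(
        "measure,value,kept",
        [
            ("IC50", 4600.0, True),   # sub-10-µM IC50 retained
            ("IC50", 10000.0, False), # boundary is strict
            ("Kd", 9999.9, True),
            ("Ki", 500.0, False),     # measure not credited
            ("EC50", 10.0, False),
        ],
    )
    def test_credibility_filter(self, measure, value, kept):
        rec = InteractionRecord("c", "T", measure, value)
        assert (filter_known_interactions([rec]) == [rec]) is kept

    def test_filter_is_idempotent(self):
        records = [
            InteractionRecord("c", "T1", "IC50", 4600.0),
            InteractionRecord("c", "T2", "Ki", 100.0),
            InteractionRecord("c", "T3", "Kd", 20000.0),
        ]
        once = filter_known_interactions(records)
        assert filter_known_interactions(once) == once


class TestExpressionIO:
    def test_read_two_by_two(self, tmp_path):
        (tmp_path / "e.tsv").write_text(
            "gene\ts1\ts2\ts3\ts4\ng1\t1\t2\t3\t4\ng2\t5\t6\t7\t8\n"
        )
        (tmp_path / "m.tsv").write_text(
            "sample_id\tgroup\tcompound_id\ns1\tcontrol\t\ns2\tcontrol\t\n"
            "s3\ttreated\tc1\ns4\ttreated\tc1\n"
        )
        mat = read_expression_matrix(tmp_path / "e.tsv", tmp_path / "m.tsv")
        assert mat.values.shape == (2, 4)
        assert mat.samples_for("control") == ["s1", "s2"]
        assert mat.treated_compounds == ["c1"]

    def test_duplicate_genes_collapsed_by_mean(self, tmp_path):
        (tmp_path / "e.tsv").write_text("gene\ts1\ts2\ng1\t1\t2\ng1\t3\t4\n")
        (tmp_path / "m.tsv").write_text(
            "sample_id\tgroup\tcompound_id\ns1\tcontrol\t\ns2\ttreated\tc1\n"
        )
        mat = read_expression_matrix(tmp_path / "e.tsv", tmp_path / "m.tsv")
        assert mat.values.loc["G1"].tolist() == [2.0, 3.0]

    def test_unmapped_sample_is_fatal(self, tmp_path):
        (tmp_path / "e.tsv").write_text("gene\ts1\ts2\ng1\t1\t2\n")
        (tmp_path / "m.tsv").write_text("sample_id\tgroup\tcompound_id\ns1\tcontrol\t\n")
        with pytest.raises(InputError):
            read_expression_matrix(tmp_path / "e.tsv", tmp_path / "m.tsv")


class TestDECalling:
    def test_planted_four_fold_up_called(self):
        rng = np.random.default_rng(0)
        base = 100 + rng.normal(0, 2, size=3)
        mat = make_matrix({"g1": (base, base * 4), "g2": (base, base * 1.02)})
        calls = call_differential_genes(mat)
        by_gene = {c.gene: c for c in calls}
        assert "G1" in by_gene and by_gene["G1"].direction == "up"
        assert "G2" not in by_gene

    def test_exact_two_fold_is_inclusive(self):
        ctrl = np.array([100.0, 101.0, 99.0])
        trt = ctrl * 2.0  # fold change exactly 2.0
        mat = make_matrix({"g": (ctrl, trt)})
        calls = call_differential_genes(mat)
        assert len(calls) == 1
        assert calls[0].direction == "up"
        assert calls[0].fold_change == pytest.approx(2.0)

    def test_strong_down_regulation_direction(self):
        ctrl = np.array([1000.0, 1010.0, 990.0])
        mat = make_matrix({"g": (ctrl, ctrl * 0.09)})
        calls = call_differential_genes(mat)
        assert calls[0].direction == "down"
        assert calls[0].fold_change == pytest.approx(0.09, rel=1e-6)

    def test_missing_values_drop_gene(self):
        ctrl = np.array([100.0, 101.0, 99.0])
        mat = make_matrix({"g1": (ctrl, ctrl * 4), "g2": ([np.nan, 100, 100], ctrl * 4)})
        table = differential_expression_table(mat, "cpd1")
        assert set(table["gene"]) == {"G1"}

    def test_zero_variance_equal_means_not_de(self):
        mat = make_matrix({"g": ([5.0, 5.0, 5.0], [5.0, 5.0, 5.0])})
        table = differential_expression_table(mat, "cpd1")
        assert table["p_value"].iloc[0] == 1.0
        assert call_differential_genes(mat) == []

    def test_sample_column_order_invariance(self):
        rng = np.random.default_rng(1)
        base = 100 + rng.normal(0, 2, size=3)
        mat = make_matrix({"g1": (base, base * 4), "g2": (base * 3, base)})
        shuffled = ExpressionMatrix(
            values=mat.values[["T2", "C0", "T0", "C2", "T1", "C1"]],
            sample_groups=mat.sample_groups.loc[["T2", "C0", "T0", "C2", "T1", "C1"]],
        )
        a = differential_expression_table(mat, "cpd1").set_index("gene")
        b = differential_expression_table(shuffled, "cpd1").set_index("gene")
        assert np.allclose(a["p_value"], b.loc[a.index, "p_value"])
        assert np.allclose(a["fold_change"], b.loc[a.index, "fold_change"])

    def test_fold_change_gate_never_adds_calls(self):
        rng = np.random.default_rng(2)
        values = {}
        for i in range(200):
            base = 100 + rng.normal(0, 5, size=3)
            values[f"g{i}"] = (base, 100 + rng.normal(0, 5, size=3))
        mat = make_matrix(values)
        table = differential_expression_table(mat, "cpd1")
        p_only = int((table["p_value"] < 0.05).sum())
        assert len(call_differential_genes(mat)) <= p_only


class TestEvidenceMapping:
    def test_flags(self):
        interactions = [
            InteractionRecord("c1", "PTPN11", "IC50", 3940.0),
            InteractionRecord("c2", "PTPN11", "IC50", 2570.0),
            InteractionRecord("c3", "PTPN11", "IC50", 2590.0),
        ]
        from fibronet.evidence import DifferentialGene

        de = [
            DifferentialGene("PTPN11", "c3", 2.06, 0.01, "up"),
            DifferentialGene("PIM1", "c3", 2.21, 0.01, "up"),
        ]
        evidence = map_evidence_to_targets(interactions, de, ["PTPN11", "PIM1", "JAK1"])
        assert evidence["PTPN11"].has_affinity_evidence and evidence["PTPN11"].has_de_evidence
        assert not evidence["PIM1"].has_affinity_evidence and evidence["PIM1"].has_de_evidence
        assert not evidence["JAK1"].has_affinity_evidence and not evidence["JAK1"].has_de_evidence
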