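import numpy as np
import pytest

from mammokg.corpus_io import Demographics
from mammokg.fusion import Finding, assemble_findings
from mammokg.graph import (
    AssociationResult,
    GraphError,
    ReportRecord,
    build_graph,
    edge_counts,
    export_graph,
    feature_category_association,
    import_graphml,
    query_patients,
    validate_graph,
)


@pytest.fixture(scope="module")
def records(clean_bundle, schema, lexicon):
    return [
        ReportRecord(
            r.report_id, r.demographics,
            assemble_findings(r, schema, lexicon).findings,
            r.birads_category,
        )
        for r in clean_bundle.reports
    ]


@pytest.fixture(scope="module")
def kg(records, schema):
    return build_graph(records, schema)


class TestSkeleton:
    def test_empty_report_still_builds_full_skeleton(self, schema):
        rec = ReportRecord("r0", None, [], None)
        g = build_graph([rec], schema)
        counts = edge_counts(g)
        assert counts.get("has_a") == 3
        assert counts.get("instance_of") == 4
        assert counts.get("part_of") == 15
        assert "select" not in counts

    @pytest.mark.parametrize("n", [1, 7, 40])
    def test_structural_counts_scale_linearly(self, records, schema, n):
        g = build_graph(records[:n], schema)
        counts = edge_counts(g)
        assert counts["has_a"] == 3 * n
        assert counts["instance_of"] == 4 * n
        assert counts["part_of"] == 15 * n

    def test_predicate_closure(self, kg, schema):
        assert set(edge_counts(kg)) <= schema.predicates

    def test_every_edge_validates_against_schema(self, kg, schema):
        validate_graph(kg, schema)

    def test_unlicensed_slot_rejected(self, schema):
        bad = Finding("Structure", "结构扭曲", {"Shape": ("圆形",)}, False)
        rec = ReportRecord("r0", None, [bad], None)
        with pytest.raises(GraphError, match="not licensed"):
            build_graph([rec], schema)


class TestExports:
    def test_graphml_round_trip(self, records, schema, tmp_path):
        g = build_graph(records[:5], schema)
        path = tmp_path / "kg.graphml"
        export_graph(g, "graphml", str(path))
        back = import_graphml(str(path))
        assert back.number_of_nodes() == g.number_of_nodes()
        assert back.number_of_edges() == g.number_of_edges()
        assert edge_counts(back) == edge_counts(g)
        assert {d["label"] for _, d in back.nodes(data=True)} == \
               {d["label"] for _, d in g.nodes(data=True)}

    def test_cypher_one_statement_per_element(self, records, schema, tmp_path):
        g = build_graph(records[:2], schema)
        path = tmp_path / "kg.cypher"
        export_graph(g, "cypher", str(path))
        lines = path.read_text(encoding="utf-8").splitlines()
        assert len(lines) == g.number_of_nodes() + g.number_of_edges()
        assert all(l.count("CREATE") == 1 for l in lines)

    def test_csv_tables(self, records, schema, tmp_path):
        g = build_graph(records[:2], schema)
        node_path = export_graph(g, "csv", str(tmp_path / "kg"))
        import csv

        with open(node_path, encoding="utf-8") as fh:
            rows = list(csv.reader(fh))
        assert len(rows) == g.number_of_nodes() + 1  # header
        with open(str(tmp_path / "kg") + "_edges.csv", encoding="utf-8") as fh:
            rows = list(csv.reader(fh))
        assert len(rows) == g.number_of_edges() + 1

    def test_empty_graph_exports(self, schema, tmp_path):
        import networkx as nx

        g = nx.MultiDiGraph()
        export_graph(g, "cypher", str(tmp_path / "e.cypher"))
        assert (tmp_path / "e.cypher").read_text() == ""

    def test_unknown_format_rejected(self, kg, tmp_path):
        with pytest.raises(GraphError, match="format"):
            export_graph(kg, "parquet", str(tmp_path / "x"))


class TestQueries:
    def test_age_category_query_equals_linear_scan(self, kg, clean_bundle):
        got = query_patients(kg, (46, 50), "3")
        oracle = sorted(
            r.report_id for r in clean_bundle.reports
            if 46 <= r.demographics.age <= 50 and r.birads_category == "3"
        )
        assert got == oracle
        assert got  # the study's example query is non-empty at this size

    def test_bounds_inclusive(self, schema):
        recs = [
            ReportRecord("a", Demographics("女", 46), [], "3"),
            ReportRecord("b", Demographics("女", 50), [], "3"),
            ReportRecord("c", Demographics("女", 51), [], "3"),
            ReportRecord("d", Demographics("女", 45), [], "3"),
        ]
        g = build_graph(recs, schema)
        assert query_patients(g, (46, 50), "3") == ["a", "b"]

    def test_out_of_support_range_empty(self, kg):
        assert query_patients(kg, (90, 95), "3") == []

    def test_invalid_range_rejected(self, kg):
        with pytest.raises(GraphError):
            query_patients(kg, (50, 46), "3")


class TestAssociation:
    def test_single_matching_report_concentrates_distribution(self, schema):
        finding = Finding("Mass", "肿块",
                          {"Shape": ("不规则形",), "Margin": ("毛刺状",)}, False)
        rec = ReportRecord("r0", Demographics("女", 50), [finding], "4C")
        g = build_graph([rec], schema)
        res = feature_category_association(
            g, [("Shape", "不规则形"), ("Margin", "毛刺状")])
        assert res.support == 1
        assert res.category_distribution == {"4C": 1.0}
        assert res.top_category == "4C"

    def test_condition_never_generated(self, kg):
        res = feature_category_association(kg, [("Distribute", "区域性分布"),
                                                ("Shape", "分叶状")])
        if res.support == 0:
            assert res.category_distribution == {}
            assert res.top_category is None

    def test_unknown_feature_type_rejected(self, kg):
        with pytest.raises(GraphError, match="feature type"):
            feature_category_association(kg, [("Colour", "红")])

    def test_non_canonical_value_rejected_with_lexicon(self, kg, lexicon):
        with pytest.raises(GraphError, match="canonical"):
            feature_category_association(kg, [("Shape", "毛刺")], lexicon=lexicon)

    def test_negated_findings_do_not_match(self, schema):
        finding = Finding("Calcification", "钙化", {"Location": ("双乳",)}, True)
        rec = ReportRecord("r0", Demographics("女", 50), [finding], "1")
        g = build_graph([rec], schema)
        res = feature_category_association(g, [("Calcification", None)])
        assert res.support == 0

    def test_recovered_distribution_matches_gold_scan(self, kg, clean_bundle):
        res = feature_category_association(kg, [("Shape", "不规则形")])
        oracle = [
            r.birads_category
            for r, fs in zip(clean_bundle.reports, clean_bundle.gold_findings)
            if any(not f.negated and ("Shape", "不规则形") in f.attributes
                   for f in fs)
        ]
        assert res.support == len(oracle)
        for cat, p in res.category_distribution.items():
            assert p == pytest.approx(oracle.count(cat) / len(oracle))
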