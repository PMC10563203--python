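import pytest

from mammokg.corpus_io import AnnotatedReport, EntitySpan
from mammokg.fusion import (
    Lexicon,
    assemble_findings,
    normalize_entity,
    similarity,
    split_sentences,
)


def gold_key(finding):
    """Comparable view of a gold finding (attributes as sorted pairs)."""
    return (finding.kind, finding.value, tuple(sorted(finding.attributes)),
            finding.negated)


def fused_key(finding):
    pairs = tuple(sorted(
        (slot, v) for slot, vs in finding.attributes.items() for v in vs
    ))
    return (finding.kind, finding.value, pairs, finding.negated)


class TestSimilarity:
    def test_identical_strings(self):
        assert similarity("毛刺状", "毛刺状") == 1.0

    def test_one_insertion_over_three_characters(self):
        assert similarity("毛刺", "毛刺状") == pytest.approx(2 / 3, abs=1e-9)

    def test_disjoint_single_characters(self):
        assert similarity("左", "右") == 0.0

    def test_empty_strings_identical(self):
        assert similarity("", "") == 1.0

    def test_symmetric(self):
        assert similarity("钙化灶", "钙化") == similarity("钙化", "钙化灶")


class TestNormalization:
    def test_canonical_maps_to_itself(self, lexicon):
        span = EntitySpan(0, 3, "Margin", "毛刺状")
        assert normalize_entity(span, lexicon) == ("毛刺状", True)

    def test_variant_resolves_by_similarity(self):
        lex = Lexicon({"Margin": {"毛刺": []}})
        span = EntitySpan(0, 3, "Margin", "毛刺状")
        assert normalize_entity(span, lex, threshold=0.6) == ("毛刺", True)

    def test_replacement_table_wins_before_similarity(self, lexicon):
        span = EntitySpan(0, 2, "Margin", "欠清")
        assert normalize_entity(span, lexicon) == ("模糊", True)

    def test_gibberish_below_threshold_kept_unmatched(self, lexicon):
        span = EntitySpan(0, 4, "Margin", "随机文本")
        surface, matched = normalize_entity(span, lexicon, threshold=0.6)
        assert surface == "随机文本" and not matched

    def test_unknown_feature_type_rejected(self):
        lex = Lexicon({"Margin": {"毛刺": []}})
        with pytest.raises(KeyError):
            normalize_entity(EntitySpan(0, 2, "Shape", "圆形"), lex)

    def test_idempotent_on_all_canonicals(self, lexicon):
        for ftype in lexicon.types():
            for canon in lexicon.canonicals(ftype):
                span = EntitySpan(0, len(canon), ftype, canon)
                assert normalize_entity(span, lexicon) == (canon, True)

    def test_every_fixture_variant_normalizes_to_its_canonical(self, lexicon):
        for ftype in lexicon.types():
            for canon in lexicon.canonicals(ftype):
                for variant in lexicon.variants(ftype, canon):
                    span = EntitySpan(0, len(variant), ftype, variant)
                    assert normalize_entity(span, lexicon, threshold=0.6) == \
                        (canon, True), (ftype, variant)

    def test_raising_threshold_never_gains_matches(self, lexicon):
        variants = [
            (ftype, v)
            for ftype in lexicon.types()
            for c in lexicon.canonicals(ftype)
            for v in lexicon.variants(ftype, c)
        ]
        matched = []
        for thr in (0.3, 0.6, 0.9):
            n = sum(
                normalize_entity(EntitySpan(0, len(v), t, v), lexicon, thr)[1]
                for t, v in variants
            )
            matched.append(n)
        assert matched[0] >= matched[1] >= matched[2]


class TestAssembleFindings:
    def test_positive_mass_sentence(self, schema, lexicon):
        text = "左乳外上象限见一卵圆形肿块。"
        report = AnnotatedReport("r", text, [
            EntitySpan(0, 6, "Location", "左乳外上象限"),
            EntitySpan(7, 8, "Number", "一"),
            EntitySpan(8, 11, "Shape", "卵圆形"),
            EntitySpan(11, 13, "Mass", "肿块"),
        ])
        res = assemble_findings(report, schema, lexicon)
        assert len(res.findings) == 1
        f = res.findings[0]
        assert (f.kind, f.value, f.negated) == ("Mass", "肿块", False)
        assert f.attributes == {"Location": ("左乳外上象限",),
                                "Number": ("一",), "Shape": ("卵圆形",)}
        assert not res.unattached

    def test_negated_calcification_sentence(self, schema, lexicon):
        text = "双乳未见钙化。"
        report = AnnotatedReport("r", text, [
            EntitySpan(0, 2, "Location", "双乳"),
            EntitySpan(2, 4, "Negation", "未见"),
            EntitySpan(4, 6, "Calcification", "钙化"),
        ])
        res = assemble_findings(report, schema, lexicon)
        f, = res.findings
        assert (f.kind, f.negated) == ("Calcification", True)
        assert f.attributes == {"Location": ("双乳",)}

    def test_zero_anchors_reports_unattached_attributes(self, schema, lexicon):
        report = AnnotatedReport("r", "左乳。", [
            EntitySpan(0, 2, "Location", "左乳"),
        ])
        res = assemble_findings(report, schema, lexicon)
        assert res.findings == []
        assert len(res.unattached) == 1

    def test_attachment_respects_sentence_boundaries(self, schema, lexicon):
        # the Shape sits in the second sentence: it must not attach to the
        # first sentence's mass
        text = "左乳见肿块。右乳见点状钙化。"
        report = AnnotatedReport("r", text, [
            EntitySpan(0, 2, "Location", "左乳"),
            EntitySpan(3, 5, "Mass", "肿块"),
            EntitySpan(6, 8, "Location", "右乳"),
            EntitySpan(9, 11, "Shape", "点状"),
            EntitySpan(11, 13, "Calcification", "钙化"),
        ])
        res = assemble_findings(report, schema, lexicon)
        mass, calc = res.findings
        assert "Shape" not in mass.attributes
        assert calc.attributes["Shape"] == ("点状",)
        assert mass.attributes["Location"] == ("左乳",)
        assert calc.attributes["Location"] == ("右乳",)

    def test_unlicensed_attribute_left_unattached(self, schema, lexicon):
        # Structure's only slot is Describe, so a Location cannot attach
        text = "双乳结构扭曲。"
        report = AnnotatedReport("r", text, [
            EntitySpan(0, 2, "Location", "双乳"),
            EntitySpan(2, 6, "Structure", "结构扭曲"),
        ])
        res = assemble_findings(report, schema, lexicon)
        f, = res.findings
        assert f.attributes == {}
        assert res.unattached == [EntitySpan(0, 2, "Location", "双乳")]

    def test_sentence_splitting(self):
        assert split_sentences("甲。乙。") == [(0, 2), (2, 4)]
        assert split_sentences("甲。尾巴") == [(0, 2), (2, 4)]
        assert split_sentences("") == []


class TestGoldReproduction:
    def test_clean_corpus_reproduced_exactly(self, clean_bundle, schema, lexicon):
        for report, gold in zip(clean_bundle.reports, clean_bundle.gold_findings):
            res = assemble_findings(report, schema, lexicon)
            assert not res.unattached and not res.unmatched
            assert [fused_key(f) for f in res.findings] == \
                   [gold_key(f) for f in gold]

    def test_variant_corpus_normalizes_back_to_gold(self, small_bundle,
                                                    schema, lexicon):
        for report, gold in zip(small_bundle.reports, small_bundle.gold_findings):
            res = assemble_findings(report, schema, lexicon)
            assert [fused_key(f) for f in res.findings] == \
                   [gold_key(f) for f in gold]
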