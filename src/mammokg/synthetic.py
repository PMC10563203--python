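"""Synthetic Chinese mammography report generator with gold annotations.

The hospital corpus behind the study conditions (1,171 reports) is not
public, so this module emulates its statistical structure: per-type
mention proportions shaped by the published annotation counts (Location
most frequent, Distribute rarest), one finding per 句号-terminated
sentence, surface-form variants to exercise knowledge fusion, per-report
demographics, and a BI-RADS category sampled from feature-conditional
rules (irregular shape with spiculated margins is overwhelmingly 4C).

The generator is the oracle for the downstream stages: every report
carries its gold entity spans and the structured findings used to render
the text.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .corpus_io import AnnotatedReport, Demographics, EntitySpan, write_corpus_dir
from .fusion import Lexicon, default_lexicon
from .schema import FEATURE_TYPES

__all__ = [
    "GeneratorConfig",
    "GoldFinding",
    "GoldBundle",
    "CategoryRule",
    "TABLE_MENTION_COUNTS",
    "default_type_proportions",
    "default_category_rules",
    "generate_corpus",
    "corpus_stats",
    "write_bundle",
]

#: Published annotation counts per feature type over the 1,171-report
#: corpus; their normalized shares are the default mention proportions.
TABLE_MENTION_COUNTS: dict[str, int] = {
    "Calcification": 1824,
    "Density": 630,
    "Distribute": 144,
    "Location": 6038,
    "Mass": 1169,
    "Lymph Node": 1163,
    "Margin": 507,
    "Merge": 1154,
    "Number": 1082,
    "Shape": 1270,
    "Size": 562,
    "Special": 1217,
    "Structure": 1934,
    "Category descriptions": 1162,
    "Negation": 3288,
}

BREAST_LOCATIONS = (
    "左乳外上象限", "左乳外下象限", "左乳内上象限", "左乳内下象限",
    "右乳外上象限", "右乳外下象限", "右乳内上象限", "右乳内下象限",
    "左乳", "右乳", "双乳",
)
AXILLARY_LOCATIONS = ("左腋下", "右腋下")
MASS_SHAPES = ("不规则形", "卵圆形", "圆形", "分叶状")
MASS_SHAPE_PROBS = (0.4, 0.3, 0.2, 0.1)
CALC_SHAPES = ("点状", "沙砾样")
MARGINS = ("清晰", "模糊", "毛刺状")
MARGIN_PROBS = (0.55, 0.35, 0.10)
MARGIN_PROBS_IRREGULAR = (0.10, 0.25, 0.65)


def default_type_proportions() -> dict[str, float]:
    total = sum(TABLE_MENTION_COUNTS.values())
    return {t: c / total for t, c in TABLE_MENTION_COUNTS.items()}


@dataclass(frozen=True)
class CategoryRule:
    """First-match-wins rule: a finding-level feature predicate and the
    BI-RADS category distribution it induces.

    Each condition is ``(feature type, canonical value or None)``; a rule
    fires when one non-negated finding satisfies every condition.
    """

    conditions: tuple[tuple[str, str | None], ...]
    distribution: dict[str, float]


def default_category_rules() -> list[CategoryRule]:
    return [
        CategoryRule(
            (("Shape", "不规则形"), ("Margin", "毛刺状")),
            {"4C": 0.9, "5": 0.05, "4B": 0.05},
        ),
        CategoryRule((("Margin", "模糊"),), {"4A": 0.40, "4B": 0.35, "3": 0.25}),
        CategoryRule((("Mass", None),), {"3": 0.45, "2": 0.40, "4A": 0.15}),
        CategoryRule((("Calcification", None),), {"2": 0.55, "3": 0.35, "4A": 0.10}),
        CategoryRule((), {"1": 0.50, "2": 0.50}),
    ]


def _default_age_weights() -> dict[int, float]:
    # Screening-age profile over 30-80 with mass in the 46-55 band so that
    # age-window queries (e.g. 46-50 with category 3) are well populated.
    w = {}
    for a in range(30, 81):
        if 46 <= a <= 55:
            w[a] = 3.0
        elif 40 <= a <= 65:
            w[a] = 2.0
        else:
            w[a] = 1.0
    z = sum(w.values())
    return {a: v / z for a, v in w.items()}


@dataclass(frozen=True)
class GoldFinding:
    """Structured finding used to render one sentence (the fusion oracle)."""

    kind: str
    value: str
    attributes: tuple[tuple[str, str], ...] = ()
    negated: bool = False

    def attribute_dict(self) -> dict[str, tuple[str, ...]]:
        out: dict[str, tuple[str, ...]] = {}
        for slot, v in self.attributes:
            out[slot] = out.get(slot, ()) + (v,)
        return out


@dataclass
class GeneratorConfig:
    n_reports: int = 1171
    seed: int = 7
    type_proportions: dict[str, float] = field(default_factory=default_type_proportions)
    variant_rate: float = 0.15
    category_rules: list[CategoryRule] = field(default_factory=default_category_rules)
    age_distribution: dict[int, float] = field(default_factory=_default_age_weights)
    sex: str = "女"
    #: negation propensity weights per finding kind (rescaled to match the
    #: configured Negation share)
    negation_weights: dict[str, float] = field(
        default_factory=lambda: {
            "Mass": 0.30, "Calcification": 0.45, "Structure": 0.50,
            "Lymph Node": 0.35, "Special": 0.30, "Merge": 0.30,
        }
    )
    #: margin behaviour conditional on an irregular-shape mass
    irregular_margin_include: float = 0.8
    spiculated_given_irregular: float = 0.65

    def validate(self) -> "GeneratorConfig":
        if self.n_reports < 0:
            raise ValueError("n_reports must be non-negative")
        if not 0.0 <= self.variant_rate <= 1.0:
            raise ValueError("variant_rate must lie in [0, 1]")
        if set(self.type_proportions) != set(FEATURE_TYPES):
            raise ValueError("type_proportions must cover exactly the 15 feature types")
        s = sum(self.type_proportions.values())
        if abs(s - 1.0) > 1e-9:
            raise ValueError(f"type_proportions sums to {s}, expected 1")
        for rule in self.category_rules:
            ds = sum(rule.distribution.values())
            if abs(ds - 1.0) > 1e-9:
                raise ValueError(f"category rule distribution sums to {ds}")
        if abs(sum(self.age_distribution.values()) - 1.0) > 1e-6:
            raise ValueError("age_distribution must sum to 1")
        return self


@dataclass
class GoldBundle:
    reports: list[AnnotatedReport]
    gold_findings: list[list[GoldFinding]]
    config: GeneratorConfig


def _derive_rates(cfg: GeneratorConfig) -> dict:
    """Turn target mention proportions into per-sentence inclusion rates.

    Expected mentions per report are measured in units of the Mass share
    (one mass finding per report); anchor sentence counts follow
    floor + Bernoulli(fraction), attribute inclusion probabilities are
    scaled so expected realized shares match the configured proportions.
    """
    p = cfg.type_proportions
    e = {t: p[t] / p["Mass"] for t in FEATURE_TYPES}

    w = cfg.negation_weights
    anchor_e = {
        "Mass": e["Mass"], "Calcification": e["Calcification"],
        "Structure": e["Structure"], "Lymph Node": e["Lymph Node"],
        "Special": e["Special"], "Merge": e["Merge"],
        "Category descriptions": e["Category descriptions"],
    }
    neg_base = sum(w[k] * anchor_e[k] for k in w)
    s_neg = e["Negation"] / neg_base if neg_base > 0 else 0.0
    p_neg = {k: float(np.clip(s_neg * w[k], 0.0, 0.85)) for k in w}

    pos = {k: anchor_e[k] * (1.0 - p_neg.get(k, 0.0)) for k in anchor_e}

    shape_base = 0.8 * pos["Mass"] + 0.6 * pos["Calcification"]
    s_shape = e["Shape"] / shape_base if shape_base > 0 else 0.0
    p_shape_mass = float(np.clip(0.8 * s_shape, 0.0, 1.0))
    p_shape_calc = float(np.clip(0.6 * s_shape, 0.0, 1.0))

    num_base = 0.9 * pos["Mass"] + 0.45 * pos["Lymph Node"]
    s_num = e["Number"] / num_base if num_base > 0 else 0.0
    p_num_mass = float(np.clip(0.9 * s_num, 0.0, 1.0))
    p_num_lymph = float(np.clip(0.45 * s_num, 0.0, 1.0))

    p_density = float(np.clip(e["Density"] / max(pos["Mass"], 1e-12), 0.0, 1.0))
    p_size = float(np.clip(e["Size"] / max(pos["Mass"], 1e-12), 0.0, 1.0))
    p_distribute = float(
        np.clip(e["Distribute"] / max(pos["Calcification"], 1e-12), 0.0, 1.0)
    )

    irr_mass = pos["Mass"] * p_shape_mass * MASS_SHAPE_PROBS[0]
    margin_irr = irr_mass * cfg.irregular_margin_include
    rest = max(pos["Mass"] - irr_mass, 1e-12)
    p_margin_rest = float(np.clip((e["Margin"] - margin_irr) / rest, 0.0, 1.0))

    loc_sent = sum(anchor_e[k] for k in
                   ("Mass", "Calcification", "Lymph Node", "Special", "Merge"))
    p_loc_other = float(
        np.clip((e["Location"] - anchor_e["Mass"]) / max(loc_sent - anchor_e["Mass"], 1e-12),
                0.0, 1.0)
    )

    return {
        "anchor_e": anchor_e, "p_neg": p_neg,
        "p_shape_mass": p_shape_mass, "p_shape_calc": p_shape_calc,
        "p_num_mass": p_num_mass, "p_num_lymph": p_num_lymph,
        "p_density": p_density, "p_size": p_size,
        "p_distribute": p_distribute, "p_margin_rest": p_margin_rest,
        "p_loc_other": p_loc_other,
    }


class _Lexemes:
    """Surface-form chooser: canonical term, or one of its variants."""

    def __init__(self, lexicon: Lexicon, variant_rate: float):
        self.lexicon = lexicon
        self.rate = variant_rate
        # variant pool per (type, canonical): listed variants plus any
        # replacement-table spellings that map to this canonical
        self.pools: dict[tuple[str, str], list[str]] = {}
        for ftype in lexicon.types():
            repl = lexicon.replacements.get(ftype, {})
            for canon in lexicon.canonicals(ftype):
                pool = list(lexicon.variants(ftype, canon))
                pool += [v for v, c in repl.items() if c == canon]
                self.pools[(ftype, canon)] = pool

    def surface(self, rng: np.random.Generator, ftype: str, canon: str) -> str:
        pool = self.pools.get((ftype, canon), [])
        if pool and self.rate > 0 and rng.random() < self.rate:
            return pool[rng.integers(len(pool))]
        return canon


class _SentenceBuilder:
    def __init__(self):
        self.parts: list[str] = []
        self.len = 0
        self.spans: list[tuple[str, int, int, str]] = []

    def lit(self, text: str):
        self.parts.append(text)
        self.len += len(text)

    def ent(self, ftype: str, surface: str):
        self.spans.append((ftype, self.len, self.len + len(surface), surface))
        self.lit(surface)

    def render(self) -> tuple[str, list[tuple[str, int, int, str]]]:
        return "".join(self.parts), self.spans


def _count(rng: np.random.Generator, expected: float) -> int:
    base = int(np.floor(expected))
    frac = expected - base
    return base + (1 if rng.random() < frac else 0)


def _choose(rng: np.random.Generator, items: Sequence[str],
            probs: Sequence[float] | None = None) -> str:
    idx = rng.choice(len(items), p=None if probs is None else np.asarray(probs))
    return items[int(idx)]


def _pick_category(rng, findings: Sequence[GoldFinding],
                   rules: Sequence[CategoryRule]) -> str:
    def satisfies(f: GoldFinding, cond) -> bool:
        ftype, value = cond
        if f.negated:
            return False
        if ftype in ("Mass", "Calcification", "Structure", "Lymph Node",
                     "Special", "Merge", "Category descriptions"):
            return f.kind == ftype and (value is None or f.value == value)
        return value in f.attribute_dict().get(ftype, ())

    for rule in rules:
        if not rule.conditions:
            fired = True
        else:
            fired = any(
                all(satisfies(f, c) for c in rule.conditions) for f in findings
            )
        if fired:
            cats = sorted(rule.distribution)
            probs = np.array([rule.distribution[c] for c in cats])
            return cats[int(rng.choice(len(cats), p=probs / probs.sum()))]
    raise RuntimeError("category_rules has no fallback rule")


def generate_corpus(config: GeneratorConfig | None = None,
                    lexicon: Lexicon | None = None) -> GoldBundle:
    """Render ``config.n_reports`` reports with gold spans and findings.

    Deterministic given the seed: two runs with the same config produce
    identical bundles.
    """
    cfg = (config or GeneratorConfig()).validate()
    lex = lexicon or default_lexicon()
    rng = np.random.default_rng(cfg.seed)
    rates = _derive_rates(cfg)
    lexemes = _Lexemes(lex, cfg.variant_rate)

    ages = sorted(cfg.age_distribution)
    age_p = np.array([cfg.age_distribution[a] for a in ages])
    age_p = age_p / age_p.sum()

    reports: list[AnnotatedReport] = []
    gold: list[list[GoldFinding]] = []
    for i in range(cfg.n_reports):
        sentences: list[tuple[str, list[tuple[str, int, int, str]]]] = []
        findings: list[GoldFinding] = []

        def surface(ftype, canon):
            return lexemes.surface(rng, ftype, canon)

        def sample_locations(pool, n):
            pool = list(pool)
            idx = rng.permutation(len(pool))
            return [pool[int(j)] for j in idx[:n]]

        def emit(builder, finding):
            sentences.append(builder.render())
            findings.append(finding)

        def anchor_sentence(kind, value_pool, loc_pool, n, *, force_loc_first,
                            body):
            locs = sample_locations(loc_pool, n)
            values = sample_locations(value_pool, min(n, len(value_pool)))
            for j in range(n):
                loc = locs[j % len(locs)]
                value = values[j % len(values)] if values else None
                has_loc = force_loc_first or rng.random() < rates["p_loc_other"]
                body(kind, value, loc if has_loc else None,
                     rng.random() < rates["p_neg"].get(kind, 0.0))

        # ---- mass (always exactly one finding) --------------------------
        def mass_body(kind, value, loc, negated):
            b = _SentenceBuilder()
            attrs = []
            if loc:
                b.ent("Location", surface("Location", loc))
                attrs.append(("Location", loc))
            if negated:
                b.ent("Negation", surface("Negation", _choose(rng, ("未见", "无"))))
                b.ent("Mass", surface("Mass", value))
            else:
                b.lit("见")
                shape = None
                if rng.random() < rates["p_num_mass"]:
                    num = _choose(rng, ("一", "两", "多发"))
                    b.ent("Number", surface("Number", num))
                    attrs.append(("Number", num))
                if rng.random() < rates["p_shape_mass"]:
                    shape = _choose(rng, MASS_SHAPES, MASS_SHAPE_PROBS)
                    b.ent("Shape", surface("Shape", shape))
                    attrs.append(("Shape", shape))
                b.ent("Mass", surface("Mass", value))
                if shape == "不规则形":
                    include = rng.random() < cfg.irregular_margin_include
                    probs = MARGIN_PROBS_IRREGULAR
                else:
                    include = rng.random() < rates["p_margin_rest"]
                    probs = MARGIN_PROBS
                if include:
                    margin = _choose(rng, MARGINS, probs)
                    b.lit("，边缘")
                    b.ent("Margin", surface("Margin", margin))
                    attrs.append(("Margin", margin))
                if rng.random() < rates["p_size"]:
                    size = _choose(rng, tuple(lex.canonicals("Size")))
                    b.lit("，大小")
                    b.ent("Size", surface("Size", size))
                    attrs.append(("Size", size))
                if rng.random() < rates["p_density"]:
                    dens = _choose(rng, ("高密度", "等密度", "低密度"))
                    b.lit("，呈")
                    b.ent("Density", surface("Density", dens))
                    attrs.append(("Density", dens))
            b.lit("。")
            emit(b, GoldFinding(kind, value, tuple(attrs), negated))

        anchor_sentence("Mass", ("肿块", "结节"), BREAST_LOCATIONS,
                        _count(rng, rates["anchor_e"]["Mass"]),
                        force_loc_first=True, body=mass_body)

        # ---- calcification ----------------------------------------------
        def calc_body(kind, value, loc, negated):
            b = _SentenceBuilder()
            attrs = []
            if loc:
                b.ent("Location", surface("Location", loc))
                attrs.append(("Location", loc))
            if negated:
                b.ent("Negation", surface("Negation", _choose(rng, ("未见", "无"))))
                b.ent("Calcification", surface("Calcification", value))
            else:
                b.lit("见")
                if rng.random() < rates["p_shape_calc"]:
                    shape = _choose(rng, CALC_SHAPES)
                    b.ent("Shape", surface("Shape", shape))
                    attrs.append(("Shape", shape))
                b.ent("Calcification", surface("Calcification", value))
                if rng.random() < rates["p_distribute"]:
                    dist = _choose(rng, tuple(lex.canonicals("Distribute")))
                    b.lit("，呈")
                    b.ent("Distribute", surface("Distribute", dist))
                    attrs.append(("Distribute", dist))
            b.lit("。")
            emit(b, GoldFinding(kind, value, tuple(attrs), negated))

        anchor_sentence("Calcification", ("钙化",), BREAST_LOCATIONS,
                        _count(rng, rates["anchor_e"]["Calcification"]),
                        force_loc_first=False, body=calc_body)

        # ---- structure (no location slot: Describe-only owner) ----------
        n_struct = _count(rng, rates["anchor_e"]["Structure"])
        struct_values = sample_locations(("结构扭曲", "结构紊乱"), n_struct)
        for j in range(n_struct):
            value = struct_values[j % len(struct_values)]
            negated = rng.random() < rates["p_neg"]["Structure"]
            b = _SentenceBuilder()
            b.lit("乳腺")
            if negated:
                b.ent("Negation", surface("Negation", _choose(rng, ("未见", "无"))))
            b.ent("Structure", surface("Structure", value))
            b.lit("。")
            emit(b, GoldFinding("Structure", value, (), negated))

        # ---- axillary lymph nodes ---------------------------------------
        def lymph_body(kind, value, loc, negated):
            b = _SentenceBuilder()
            attrs = []
            if loc:
                b.ent("Location", surface("Location", loc))
                attrs.append(("Location", loc))
            if negated:
                b.ent("Negation", surface("Negation", _choose(rng, ("未见", "无"))))
            else:
                b.lit("见")
                if rng.random() < rates["p_num_lymph"]:
                    num = _choose(rng, ("数个", "多发"))
                    b.ent("Number", surface("Number", num))
                    attrs.append(("Number", num))
            b.ent("Lymph Node", surface("Lymph Node", value))
            b.lit("。")
            emit(b, GoldFinding(kind, value, tuple(attrs), negated))

        anchor_sentence("Lymph Node", ("淋巴结",), AXILLARY_LOCATIONS,
                        _count(rng, rates["anchor_e"]["Lymph Node"]),
                        force_loc_first=False, body=lymph_body)

        # ---- special and merge signs ------------------------------------
        def plain_body_for(ftype):
            def body(kind, value, loc, negated):
                b = _SentenceBuilder()
                attrs = []
                if loc:
                    b.ent("Location", surface("Location", loc))
                    attrs.append(("Location", loc))
                if negated:
                    b.ent("Negation", surface("Negation", _choose(rng, ("未见", "无"))))
                b.ent(ftype, surface(ftype, value))
                b.lit("。")
                emit(b, GoldFinding(kind, value, tuple(attrs), negated))
            return body

        anchor_sentence("Special", tuple(lex.canonicals("Special")),
                        BREAST_LOCATIONS,
                        _count(rng, rates["anchor_e"]["Special"]),
                        force_loc_first=False, body=plain_body_for("Special"))
        anchor_sentence("Merge", tuple(lex.canonicals("Merge")),
                        BREAST_LOCATIONS,
                        _count(rng, rates["anchor_e"]["Merge"]),
                        force_loc_first=False, body=plain_body_for("Merge"))

        # ---- breast-composition category statement (always last) --------
        n_cat = max(1, _count(rng, rates["anchor_e"]["Category descriptions"]))
        cat_values = sample_locations(tuple(lex.canonicals("Category descriptions")),
                                      n_cat)
        for j in range(n_cat):
            value = cat_values[j % len(cat_values)]
            b = _SentenceBuilder()
            b.lit("乳腺分型为")
            b.ent("Category descriptions", surface("Category descriptions", value))
            b.lit("。")
            emit(b, GoldFinding("Category descriptions", value, (), False))

        # ---- assemble the report ----------------------------------------
        text_parts: list[str] = []
        spans: list[EntitySpan] = []
        offset = 0
        for sent_text, sent_spans in sentences:
            text_parts.append(sent_text)
            for ftype, s, t, surf in sent_spans:
                spans.append(EntitySpan(offset + s, offset + t, ftype, surf))
            offset += len(sent_text)
        text = "".join(text_parts)

        age = ages[int(rng.choice(len(ages), p=age_p))]
        category = _pick_category(rng, findings, cfg.category_rules)
        reports.append(
            AnnotatedReport(
                report_id=f"r{i:05d}",
                text=text,
                entities=spans,
                demographics=Demographics(cfg.sex, int(age)),
                birads_category=category,
            )
        )
        gold.append(findings)
    return GoldBundle(reports, gold, cfg)


def corpus_stats(bundle: GoldBundle) -> dict:
    """Per-type mention counts and the BI-RADS category histogram."""
    counts = {t: 0 for t in FEATURE_TYPES}
    categories: dict[str, int] = {}
    for r in bundle.reports:
        for sp in r.entities:
            counts[sp.label] += 1
        if r.birads_category is not None:
            categories[r.birads_category] = categories.get(r.birads_category, 0) + 1
    return {
        "n_reports": len(bundle.reports),
        "mention_counts": counts,
        "total_mentions": sum(counts.values()),
        "category_histogram": dict(sorted(categories.items())),
    }


def write_bundle(bundle: GoldBundle, out_dir) -> None:
    """Emit .txt/.ann pairs, a demographics table and gold findings."""
    os.makedirs(out_dir, exist_ok=True)
    write_corpus_dir(bundle.reports, out_dir)
    rows = [
        {
            "report_id": r.report_id,
            "sex": r.demographics.sex if r.demographics else "",
            "age": r.demographics.age if r.demographics else "",
            "birads": r.birads_category or "",
        }
        for r in bundle.reports
    ]
    pd.DataFrame(rows).to_csv(os.path.join(out_dir, "demographics.csv"), index=False)
    with open(os.path.join(out_dir, "gold_findings.jsonl"), "w", encoding="utf-8") as fh:
        for r, findings in zip(bundle.reports, bundle.gold_findings):
            fh.write(json.dumps({
                "report_id": r.report_id,
                "findings": [
                    {"kind": f.kind, "value": f.value,
                     "attributes": [list(a) for a in f.attributes],
                     "negated": f.negated}
                    for f in findings
                ],
            }, ensure_ascii=False) + "\n")
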