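"""Knowledge fusion: surface-form normalization and finding assembly.

Free-text reports describe the same finding in many ways (毛刺 / 毛刺状 /
毛刺状边缘).  Fusion maps every extracted entity to the canonical lexicon
term of its type — explicit semantic replacements first, then
edit-distance similarity — and then groups entities into structured
findings: each anchor entity (mass, calcification, …) seeds one finding,
attribute entities attach to the nearest anchor in the same sentence
whose concept-layer slots license them, and negation cues flip the
nearest anchor's polarity.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import edlib
import yaml

from .corpus_io import AnnotatedReport, EntitySpan
from .schema import ConceptLayer

__all__ = [
    "Lexicon",
    "Finding",
    "FusionResult",
    "ANCHOR_TYPES",
    "ATTRIBUTE_TYPES",
    "ANCHOR_OWNER_MAP",
    "default_lexicon",
    "load_lexicon",
    "similarity",
    "normalize_entity",
    "split_sentences",
    "assemble_findings",
]

#: Feature types that seed a finding.
ANCHOR_TYPES = (
    "Mass", "Calcification", "Structure", "Lymph Node",
    "Special", "Merge", "Category descriptions",
)
#: Feature types that attach to an anchor as attribute slots.
ATTRIBUTE_TYPES = ("Location", "Shape", "Size", "Number", "Density",
                   "Distribute", "Margin")

#: Concept-layer owner whose attribute slots license each anchor type.
ANCHOR_OWNER_MAP = {
    "Mass": "Mass",
    "Calcification": "Calcification",
    "Structure": "Structure",
    "Lymph Node": "Axillary lymph nodes",
    "Special": "Asymmetrical",
    "Merge": "Association anomaly",
    "Category descriptions": "Category descriptions",
}


class Lexicon:
    """Canonical terms per feature type plus an explicit replacement table."""

    def __init__(self, types: Mapping[str, Mapping[str, Sequence[str]]],
                 replacements: Mapping[str, Mapping[str, str]] | None = None):
        self._types = {t: {c: list(v) for c, v in terms.items()}
                       for t, terms in types.items()}
        self.replacements = {t: dict(m) for t, m in (replacements or {}).items()}
        for ftype, table in self.replacements.items():
            canon = set(self._types.get(ftype, ()))
            for variant, target in table.items():
                if target not in canon:
                    raise ValueError(
                        f"replacement {variant!r} -> {target!r} does not target a "
                        f"canonical {ftype} term"
                    )

    def types(self) -> list[str]:
        return list(self._types)

    def canonicals(self, ftype: str) -> list[str]:
        if ftype not in self._types:
            raise KeyError(f"unknown feature type {ftype!r}")
        return list(self._types[ftype])

    def variants(self, ftype: str, canonical: str) -> list[str]:
        return list(self._types[ftype].get(canonical, ()))


def load_lexicon(path) -> Lexicon:
    with open(path, "r", encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    return Lexicon(doc["types"], doc.get("replacements"))


def default_lexicon() -> Lexicon:
    ref = importlib.resources.files("mammokg.data").joinpath("lexicon.yaml")
    doc = yaml.safe_load(ref.read_text(encoding="utf-8"))
    return Lexicon(doc["types"], doc.get("replacements"))


def similarity(a: str, b: str) -> float:
    """Edit-distance similarity: ``1 - levenshtein(a, b) / max(|a|, |b|)``.

    Two empty strings are identical (similarity 1).
    """
    if not a and not b:
        return 1.0
    if not a or not b:
        return 0.0
    dist = edlib.align(a, b, task="distance")["editDistance"]
    return 1.0 - dist / max(len(a), len(b))


def normalize_entity(span: EntitySpan, lexicon: Lexicon,
                     threshold: float = 0.6) -> tuple[str, bool]:
    """Map a span's surface to its canonical term.

    Exact canonical or replacement-table hits win outright; otherwise the
    most similar canonical term of the same type is chosen if its
    similarity reaches ``threshold`` (first-listed canonical wins ties).
    Below threshold the original surface is kept, flagged unmatched.
    """
    surface = span.surface
    canon = lexicon.canonicals(span.label)  # raises KeyError for unknown type
    if surface in canon:
        return surface, True
    repl = lexicon.replacements.get(span.label, {})
    if surface in repl:
        return repl[surface], True
    best, best_sim = None, -1.0
    for c in canon:
        sim = similarity(surface, c)
        if sim > best_sim:
            best, best_sim = c, sim
    if best is not None and best_sim >= threshold:
        return best, True
    return surface, False


@dataclass
class Finding:
    """One normalized finding: an anchor entity with attached attributes."""

    kind: str
    value: str
    attributes: dict[str, tuple[str, ...]] = field(default_factory=dict)
    negated: bool = False
    source_spans: list[EntitySpan] = field(default_factory=list)
    conflicts: list[tuple[str, tuple[str, ...]]] = field(default_factory=list)

    def key(self):
        return (self.kind, self.value,
                tuple(sorted((s, tuple(sorted(v))) for s, v in self.attributes.items())),
                self.negated)


@dataclass
class FusionResult:
    findings: list[Finding]
    unattached: list[EntitySpan]
    unmatched: list[EntitySpan]


def split_sentences(text: str) -> list[tuple[int, int]]:
    """Character ranges of 句号-terminated sentences (remainder included)."""
    out = []
    start = 0
    for i, ch in enumerate(text):
        if ch == "。":
            out.append((start, i + 1))
            start = i + 1
    if start < len(text):
        out.append((start, len(text)))
    return out


def _distance(a: EntitySpan, b: EntitySpan) -> int:
    if a.end <= b.start:
        return b.start - a.end
    if b.end <= a.start:
        return a.start - b.end
    return 0


def assemble_findings(
    report: AnnotatedReport,
    schema: ConceptLayer,
    lexicon: Lexicon | None = None,
    threshold: float = 0.6,
    entities: Sequence[EntitySpan] | None = None,
) -> FusionResult:
    """Group a report's entities into findings.

    Entities default to ``report.entities`` (pass predicted spans via
    ``entities``).  When a lexicon is given every surface is normalized
    first.  Attribute entities attach to the nearest same-sentence anchor
    whose owner licenses the slot (ties to the left); negation cues flip
    the nearest anchor.  Unattachable attributes are returned, not
    silently dropped.  Duplicate findings — same kind, same canonical
    value and the same non-empty Location — are merged, union-ing their
    attributes and flagging conflicting slot values.
    """
    spans = sorted(entities if entities is not None else report.entities)
    norm: dict[EntitySpan, str] = {}
    unmatched: list[EntitySpan] = []
    for sp in spans:
        if lexicon is not None and sp.label in lexicon.types():
            value, ok = normalize_entity(sp, lexicon, threshold)
            if not ok:
                unmatched.append(sp)
        else:
            value = sp.surface
        norm[sp] = value

    sentences = split_sentences(report.text)
    findings: list[Finding] = []
    unattached: list[EntitySpan] = []
    for lo, hi in sentences:
        in_sent = [sp for sp in spans if lo <= sp.start and sp.end <= hi]
        anchors = [sp for sp in in_sent if sp.label in ANCHOR_TYPES]
        by_anchor: dict[EntitySpan, Finding] = {
            a: Finding(a.label, norm[a], {}, False, [a]) for a in anchors
        }

        def nearest(sp, candidates):
            best, best_d = None, None
            for a in candidates:
                d = _distance(sp, a)
                if best_d is None or d < best_d or (d == best_d and a.start < best.start):
                    best, best_d = a, d
            return best

        for sp in in_sent:
            if sp.label in ANCHOR_TYPES:
                continue
            if sp.label == "Negation":
                target = nearest(sp, anchors)
                if target is not None:
                    by_anchor[target].negated = True
                    by_anchor[target].source_spans.append(sp)
                else:
                    unattached.append(sp)
                continue
            # attribute entity: restrict to anchors licensing this slot
            licensed = [
                a for a in anchors
                if sp.label in schema.licensed_slots(ANCHOR_OWNER_MAP[a.label])
            ]
            target = nearest(sp, licensed)
            if target is None:
                unattached.append(sp)
                continue
            f = by_anchor[target]
            f.attributes[sp.label] = f.attributes.get(sp.label, ()) + (norm[sp],)
            f.source_spans.append(sp)
        findings.extend(by_anchor[a] for a in anchors)

    return FusionResult(_merge_duplicates(findings), unattached, unmatched)


def _merge_duplicates(findings: Iterable[Finding]) -> list[Finding]:
    merged: list[Finding] = []
    index: dict[tuple, int] = {}
    for f in findings:
        loc = f.attributes.get("Location", ())
        key = (f.kind, f.value, loc) if loc else None
        if key is not None and key in index:
            tgt = merged[index[key]]
            for slot, values in f.attributes.items():
                combined = tgt.attributes.get(slot, ())
                new = combined + tuple(v for v in values if v not in combined)
                if len(set(new)) > 1:
                    tgt.conflicts.append((slot, new))
                tgt.attributes[slot] = new
            tgt.negated = tgt.negated or f.negated
            tgt.source_spans.extend(f.source_spans)
        else:
            if key is not None:
                index[key] = len(merged)
            merged.append(f)
    return merged
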