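"""Report corpus I/O: BRAT standoff files, character-level BIO tags, splits.

Reports are Chinese free text; annotation offsets are 0-based,
end-exclusive and counted in characters (code points), the BRAT
convention.  Tagging is character-level: a three-character entity such
as 卵圆形 annotated as Shape becomes ``B-Shape I-Shape I-Shape``.

BRAT entity labels may not contain spaces, so the two spaced feature
types are written as ``Lymph_Node`` and ``Category_descriptions`` in
``.ann`` files and mapped back on read.
"""

from __future__ import annotations

import os
import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .schema import FEATURE_TYPES

__all__ = [
    "EntitySpan",
    "Demographics",
    "AnnotatedReport",
    "TagSet",
    "BratError",
    "BIRADS_CATEGORIES",
    "read_brat",
    "write_brat",
    "read_corpus_dir",
    "write_corpus_dir",
    "encode_bio",
    "decode_bio",
    "split_corpus",
    "to_conll",
    "from_conll",
]

BIRADS_CATEGORIES = ("1", "2", "3", "4A", "4B", "4C", "5")

_LABEL_TO_FILE = {t: t.replace(" ", "_") for t in FEATURE_TYPES}
_FILE_TO_LABEL = {v: k for k, v in _LABEL_TO_FILE.items()}


class BratError(ValueError):
    """Raised for malformed or inconsistent standoff annotations."""


@dataclass(frozen=True, order=True)
class EntitySpan:
    """A gold or predicted entity: feature-type label over [start, end)."""

    start: int
    end: int
    label: str
    surface: str = field(compare=False, default="")

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise BratError(f"invalid span offsets [{self.start}, {self.end})")
        if self.label not in FEATURE_TYPES:
            raise BratError(f"unknown feature type {self.label!r}")


@dataclass(frozen=True)
class Demographics:
    sex: str
    age: int


@dataclass
class AnnotatedReport:
    """One report: text, non-overlapping entity spans, optional metadata."""

    report_id: str
    text: str
    entities: list[EntitySpan] = field(default_factory=list)
    demographics: Demographics | None = None
    birads_category: str | None = None

    def __post_init__(self):
        if self.birads_category is not None and self.birads_category not in BIRADS_CATEGORIES:
            raise BratError(f"unknown BI-RADS category {self.birads_category!r}")
        self.entities = sorted(self.entities)
        n = len(self.text)
        prev = None
        for sp in self.entities:
            if sp.end > n:
                raise BratError(
                    f"{self.report_id}: span [{sp.start},{sp.end}) exceeds text length {n}"
                )
            if sp.surface and self.text[sp.start : sp.end] != sp.surface:
                raise BratError(
                    f"{self.report_id}: surface {sp.surface!r} does not match "
                    f"text[{sp.start}:{sp.end}]={self.text[sp.start:sp.end]!r}"
                )
            if prev is not None and sp.start < prev.end:
                raise BratError(
                    f"{self.report_id}: overlapping spans "
                    f"[{prev.start},{prev.end}) and [{sp.start},{sp.end})"
                )
            prev = sp


class TagSet:
    """O plus B-X/I-X for each feature type (31 tags for the 15 types)."""

    def __init__(self, types: Sequence[str] = FEATURE_TYPES):
        self.types = tuple(types)
        self.tags = ["O"]
        for t in self.types:
            self.tags.append(f"B-{t}")
            self.tags.append(f"I-{t}")
        self.index = {tag: i for i, tag in enumerate(self.tags)}

    def __len__(self) -> int:
        return len(self.tags)

    def __iter__(self):
        return iter(self.tags)


_T_LINE = re.compile(r"^(T\d+)\t(\S+) (\d+) (\d+)\t(.*)$")


def read_brat(text_path, ann_path) -> AnnotatedReport:
    """Parse a ``.txt``/``.ann`` BRAT pair into an :class:`AnnotatedReport`.

    Only entity (T) lines are read; relation/attribute/note lines are
    ignored.  Offsets and surfaces are cross-checked against the text and
    overlapping spans are rejected with the two offending annotation ids.
    """
    with open(text_path, "r", encoding="utf-8") as fh:
        text = fh.read()
    spans: list[tuple[str, EntitySpan]] = []
    with open(ann_path, "r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line or not line.startswith("T"):
                continue
            m = _T_LINE.match(line)
            if m is None:
                raise BratError(f"{ann_path}:{lineno}: malformed T line: {line!r}")
            tid, label, start, end, surface = m.groups()
            label = _FILE_TO_LABEL.get(label, label)
            start, end = int(start), int(end)
            if end > len(text):
                raise BratError(
                    f"{ann_path}:{lineno}: {tid} offsets [{start},{end}) out of "
                    f"bounds for text of length {len(text)}"
                )
            if text[start:end] != surface:
                raise BratError(
                    f"{ann_path}:{lineno}: {tid} surface {surface!r} does not "
                    f"match text[{start}:{end}]={text[start:end]!r}"
                )
            spans.append((tid, EntitySpan(start, end, label, surface)))
    spans.sort(key=lambda p: (p[1].start, p[1].end))
    for (ida, a), (idb, b) in zip(spans, spans[1:]):
        if b.start < a.end:
            raise BratError(f"{ann_path}: overlapping annotations {ida} and {idb}")
    rid = os.path.splitext(os.path.basename(str(text_path)))[0]
    return AnnotatedReport(rid, text, [sp for _, sp in spans])


def write_brat(report: AnnotatedReport, text_path, ann_path) -> None:
    """Write canonical BRAT T-lines; inverse of :func:`read_brat`."""
    with open(text_path, "w", encoding="utf-8") as fh:
        fh.write(report.text)
    with open(ann_path, "w", encoding="utf-8") as fh:
        for i, sp in enumerate(sorted(report.entities), 1):
            label = _LABEL_TO_FILE[sp.label]
            surface = report.text[sp.start : sp.end]
            fh.write(f"T{i}\t{label} {sp.start} {sp.end}\t{surface}\n")


def write_corpus_dir(reports: Iterable[AnnotatedReport], out_dir) -> None:
    os.makedirs(out_dir, exist_ok=True)
    for r in reports:
        base = os.path.join(out_dir, r.report_id)
        write_brat(r, base + ".txt", base + ".ann")


def read_corpus_dir(in_dir) -> list[AnnotatedReport]:
    reports = []
    for name in sorted(os.listdir(in_dir)):
        if name.endswith(".txt"):
            base = os.path.join(in_dir, name[:-4])
            reports.append(read_brat(base + ".txt", base + ".ann"))
    return reports


def encode_bio(report: AnnotatedReport) -> list[str]:
    """One tag per character: B-label at entity starts, I-label inside, else O."""
    tags = ["O"] * len(report.text)
    for sp in report.entities:
        tags[sp.start] = f"B-{sp.label}"
        for i in range(sp.start + 1, sp.end):
            tags[i] = f"I-{sp.label}"
    return tags


def decode_bio(text: str, tags: Sequence[str]) -> list[EntitySpan]:
    """Turn a character tag sequence back into spans (lenient repair).

    An I-tag with no open span of the same label starts a new span
    (I-as-B); any label change closes the previous span.
    """
    if len(tags) != len(text):
        raise ValueError(f"{len(tags)} tags for {len(text)} characters")
    spans: list[EntitySpan] = []
    start = None
    label = None

    def close(end):
        nonlocal start, label
        if start is not None:
            spans.append(EntitySpan(start, end, label, text[start:end]))
        start, label = None, None

    for i, tag in enumerate(tags):
        if tag == "O":
            close(i)
        elif tag.startswith("B-"):
            close(i)
            start, label = i, tag[2:]
        elif tag.startswith("I-"):
            if label != tag[2:]:
                close(i)
                start, label = i, tag[2:]
        else:
            raise ValueError(f"unknown tag {tag!r}")
    close(len(tags))
    return spans


def split_corpus(
    reports: Sequence[AnnotatedReport],
    sizes: tuple[float, float, float],
    seed: int,
) -> tuple[list[AnnotatedReport], list[AnnotatedReport], list[AnnotatedReport]]:
    """Seeded random partition into train/validation/test.

    ``sizes`` is either integer counts summing to the corpus size (the
    study split is 820/116/235 over 1171 reports) or ratios summing to 1.
    """
    n = len(reports)
    if all(isinstance(s, (int, np.integer)) for s in sizes):
        counts = [int(s) for s in sizes]
        if sum(counts) != n:
            raise ValueError(f"split counts {counts} do not sum to corpus size {n}")
    else:
        if abs(sum(sizes) - 1.0) > 1e-9:
            raise ValueError(f"split ratios {sizes} do not sum to 1")
        counts = [int(round(s * n)) for s in sizes[:2]]
        counts.append(n - sum(counts))
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    a, b = counts[0], counts[0] + counts[1]
    train = [reports[i] for i in order[:a]]
    val = [reports[i] for i in order[a:b]]
    test = [reports[i] for i in order[b:]]
    return train, val, test


def to_conll(reports: Iterable[AnnotatedReport]) -> str:
    """Two-column character/tag export, blank line between reports."""
    blocks = []
    for r in reports:
        tags = encode_bio(r)
        blocks.append("\n".join(f"{c}\t{t}" for c, t in zip(r.text, tags)))
    return "\n\n".join(blocks) + "\n"


def from_conll(payload: str) -> list[tuple[str, list[str]]]:
    """Parse the two-column export into (text, tags) pairs."""
    out = []
    for block in payload.strip("\n").split("\n\n"):
        chars, tags = [], []
        for line in block.splitlines():
            c, t = line.split("\t")
            chars.append(c)
            tags.append(t)
        out.append(("".join(chars), tags))
    return out
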