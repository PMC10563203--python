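"""Shared tagger interface: every architecture decodes BIO tags per character."""

from __future__ import annotations

from typing import Protocol, Sequence, runtime_checkable

from ..corpus_io import AnnotatedReport, EntitySpan, TagSet, decode_bio, encode_bio

__all__ = ["TaggerModel", "TaggedCorpus", "predict", "as_tagged", "ARCHITECTURES"]

ARCHITECTURES = ("hmm", "crf", "bilstm_crf", "bilstm_highway_crf")

#: (text, tags) training pairs
TaggedCorpus = list[tuple[str, list[str]]]


@runtime_checkable
class TaggerModel(Protocol):
    architecture: str
    tagset: TagSet
    hyperparameters: dict

    def predict_tags(self, text: str) -> list[str]: ...


def as_tagged(reports: Sequence[AnnotatedReport]) -> TaggedCorpus:
    """Character/BIO-tag pairs for a list of annotated reports."""
    return [(r.text, encode_bio(r)) for r in reports]


def predict(model: TaggerModel, text: str) -> list[EntitySpan]:
    """Decode a trained tagger's BIO output into entity spans."""
    if not text:
        return []
    return decode_bio(text, model.predict_tags(text))
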