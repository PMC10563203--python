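"""Entity-level precision / recall / F1, per feature type and overall.

A predicted span counts as a true positive only when its (start, end,
label) triple exactly matches a gold span — the strict convention for
character-level BIO tagging.  Overall scores are micro-averaged from the
pooled per-type counts; zero denominators score 0 (worst value).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

from .corpus_io import EntitySpan
from .schema import FEATURE_TYPES

__all__ = ["PRF", "EvaluationResult", "entity_prf", "format_table"]


@dataclass(frozen=True)
class PRF:
    precision: float
    recall: float
    f1: float


@dataclass
class EvaluationResult:
    per_type: dict[str, PRF]
    overall: PRF
    counts: dict[str, tuple[int, int, int]]  # type -> (TP, FP, FN)


def _prf(tp: int, fp: int, fn: int) -> PRF:
    p = 100.0 * tp / (tp + fp) if tp + fp else 0.0
    r = 100.0 * tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * p * r / (p + r) if p + r else 0.0
    return PRF(p, r, f1)


def entity_prf(
    gold: Mapping[str, Sequence[EntitySpan]],
    predicted: Mapping[str, Sequence[EntitySpan]],
) -> EvaluationResult:
    """Score predictions against gold spans over a common report set.

    Both arguments map report id -> spans; the id sets must coincide.
    """
    if set(gold) != set(predicted):
        only_g = set(gold) - set(predicted)
        only_p = set(predicted) - set(gold)
        raise ValueError(
            f"mismatched report sets (gold-only={sorted(only_g)[:3]}, "
            f"predicted-only={sorted(only_p)[:3]})"
        )
    counts = {t: [0, 0, 0] for t in FEATURE_TYPES}
    for rid in gold:
        gset = {(sp.start, sp.end, sp.label) for sp in gold[rid]}
        pset = {(sp.start, sp.end, sp.label) for sp in predicted[rid]}
        for item in pset:
            counts[item[2]][0 if item in gset else 1] += 1
        for item in gset - pset:
            counts[item[2]][2] += 1
    per_type = {t: _prf(*c) for t, c in counts.items()}
    tp = sum(c[0] for c in counts.values())
    fp = sum(c[1] for c in counts.values())
    fn = sum(c[2] for c in counts.values())
    return EvaluationResult(
        per_type=per_type,
        overall=_prf(tp, fp, fn),
        counts={t: tuple(c) for t, c in counts.items()},
    )


def format_table(result: EvaluationResult) -> str:
    """Render the per-type score table (unit: %)."""
    lines = [f"{'Entity Type':<24}{'Precision':>10}{'Recall':>10}{'F1':>10}"]
    for t in FEATURE_TYPES:
        s = result.per_type[t]
        lines.append(f"{t:<24}{s.precision:>10.2f}{s.recall:>10.2f}{s.f1:>10.2f}")
    o = result.overall
    lines.append(f"{'Overall':<24}{o.precision:>10.2f}{o.recall:>10.2f}{o.f1:>10.2f}")
    return "\n".join(lines)
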