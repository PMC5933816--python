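"""Overlap-based matching of predictions to annotations, PR curves and max-F1.

A prediction is a true positive when it overlaps an annotation of the same
superfamily by at least ``min_overlap`` nucleotides, or when either interval
completely contains the other. Strand is ignored. Each annotation counts
once toward recall no matter how many predictions hit it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

from .classify import NONE_LABEL, PredictionRecord
from .errors import ConsistencyError, LtrForestError
from .io import AnnotationRecord

DEFAULT_MIN_OVERLAP = 100


@dataclass(frozen=True)
class MatchResult:
    tp_predictions: frozenset[str]
    fp_predictions: frozenset[str]
    found_annotations: frozenset[str]
    annotation_total: int
    matched: dict = field(default_factory=dict, compare=False)


@dataclass(frozen=True)
class PRPoint:
    threshold: float
    precision: float
    recall: float

    @property
    def f1(self) -> float:
        if self.precision + self.recall == 0:
            return 0.0
        return 2 * self.precision * self.recall / (self.precision + self.recall)


@dataclass(frozen=True)
class PRCurve:
    points: tuple[PRPoint, ...]
    annotation_total: int


def _is_match(p_start: int, p_end: int, a_start: int, a_end: int,
              min_overlap: int) -> bool:
    # half-open intervals: overlap equals the 1-based inclusive count
    overlap = min(p_end, a_end) - max(p_start, a_start)
    if overlap >= min_overlap:
        return True
    if p_start <= a_start and a_end <= p_end:  # prediction contains annotation
        return True
    if a_start <= p_start and p_end <= a_end:  # annotation contains prediction
        return True
    return False


def match(
    predictions: Sequence[PredictionRecord],
    annotations: Sequence[AnnotationRecord],
    label: str,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
) -> MatchResult:
    """Match one superfamily's predictions against its annotations."""
    anns = [a for a in annotations if a.label == label]
    tps, fps, found = set(), set(), set()
    matched: dict[str, list[str]] = {}
    for p in predictions:
        hits = [
            a.annotation_id
            for a in anns
            if a.seq_id == p.seq_id
            and _is_match(p.start, p.end, a.start, a.end, min_overlap)
        ]
        if hits:
            tps.add(p.candidate_id)
            matched[p.candidate_id] = hits
            found.update(hits)
        else:
            fps.add(p.candidate_id)
    return MatchResult(
        tp_predictions=frozenset(tps),
        fp_predictions=frozenset(fps),
        found_annotations=frozenset(found),
        annotation_total=len(anns),
        matched=matched,
    )


def pr_curve(
    predictions: Sequence[PredictionRecord],
    annotations: Sequence[AnnotationRecord],
    label: str,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
) -> PRCurve:
    """Sweep the probability threshold from high to low, one point per value."""
    anns = [a for a in annotations if a.label == label]
    if not anns:
        raise LtrForestError(f"no annotations for {label!r}: recall is undefined")
    result = match(predictions, annotations, label, min_overlap)
    scored = sorted(
        predictions, key=lambda p: p.probabilities[label], reverse=True
    )
    points: list[PRPoint] = []
    tp = fp = 0
    found: set[str] = set()
    i = 0
    n = len(scored)
    while i < n:
        t = scored[i].probabilities[label]
        while i < n and scored[i].probabilities[label] == t:
            p = scored[i]
            if p.candidate_id in result.tp_predictions:
                tp += 1
                found.update(result.matched[p.candidate_id])
            else:
                fp += 1
            i += 1
        points.append(PRPoint(t, tp / (tp + fp), len(found) / len(anns)))
    return PRCurve(tuple(points), len(anns))


def max_f1(curve: PRCurve) -> float:
    if not curve.points:
        raise LtrForestError("empty PR curve")
    return max(p.f1 for p in curve.points)


def combined_pr(
    records: Sequence[PredictionRecord],
    annotations: Sequence[AnnotationRecord],
    min_overlap: int = DEFAULT_MIN_OVERLAP,
) -> PRCurve:
    """Multi-superfamily PR curve with a None category at each threshold.

    At threshold t a candidate is labelled with its argmax superfamily when
    that probability exceeds t, else None. A non-None prediction is correct
    iff it matches an annotation of its predicted superfamily. Precision
    counts all non-None predictions in its denominator; recall counts every
    annotation (all superfamilies). Thresholds where every prediction is
    None are omitted.
    """
    if not annotations:
        raise LtrForestError("no annotations: recall is undefined")
    families = sorted({a.label for a in annotations} | {
        f for r in records for f in r.probabilities
    })
    per_family = {
        f: match(records, annotations, f, min_overlap) for f in families
    }
    thresholds = sorted({r.max_probability for r in records}, reverse=True)
    points: list[PRPoint] = []
    total = len(annotations)
    for t in thresholds:
        correct = 0
        non_none = 0
        found: set[str] = set()
        for r in records:
            if r.max_probability < t:  # point stands for thresholds just below t
                continue
            best_p = r.max_probability
            label = None  # argmax with fixed-order tie-break
            for f in ("Copia", "Gypsy", "Bel-Pao"):
                if r.probabilities.get(f) == best_p:
                    label = f
                    break
            if label is None:
                label = max(r.probabilities, key=r.probabilities.get)
            non_none += 1
            mres = per_family.get(label)
            if mres is not None and r.candidate_id in mres.tp_predictions:
                correct += 1
                found.update(mres.matched[r.candidate_id])
        if non_none == 0:
            continue
        points.append(PRPoint(t, correct / non_none, len(found) / total))
    return PRCurve(tuple(points), total)


def exclusive_comparison(
    matches_a: MatchResult, matches_b: MatchResult
) -> tuple[int, int, int]:
    """Partition found annotations into (only A, both, only B)."""
    if matches_a.annotation_total != matches_b.annotation_total:
        raise ConsistencyError(
            "the two match results were computed against different annotation sets"
        )
    a, b = matches_a.found_annotations, matches_b.found_annotations
    both = a & b
    return (len(a - b), len(both), len(b - a))


def curve_table(curve: PRCurve) -> str:
    """Tab-separated (threshold, precision, recall, F1) rendering of a curve."""
    lines = ["threshold\tprecision\trecall\tf1"]
    for p in curve.points:
        lines.append(f"{p.threshold:.4f}\t{p.precision:.4f}\t{p.recall:.4f}\t{p.f1:.4f}")
    return "\n".join(lines) + "\n"
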