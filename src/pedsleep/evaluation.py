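"""Evaluation arithmetic for note-level and span-level performance.

Note-level: a 2x2 confusion matrix over positive/negative note labels and
the derived precision (TP / predicted positive), recall (TP / gold
positive) and F1 (harmonic mean of the two).  Metrics with an empty
denominator are *undefined* (``None``), never silently zero.

Span-level: the fraction of gold annotation spans — each tagged with one
of nine sleep-health dimensions — that contain at least one tier-1 keyword
match.  "Contains" defaults to full containment of the match interval
inside the annotation interval; an any-overlap mode is available.

Display rounding follows the conventions of the published tables: metrics
to 3 decimals, percentages to 1 decimal, half rounded away from zero.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Optional, Sequence

from .matcher import Match

__all__ = [
    "DIMENSIONS",
    "ConfusionMatrix",
    "Metrics",
    "AnnotationSpan",
    "CoverageRow",
    "CoverageTable",
    "confusion",
    "compute_metrics",
    "recall_delta",
    "span_coverage",
    "cohen_kappa",
    "round_half_up",
]

DIMENSIONS = (
    "sleep_behavior",
    "sleep_satisfaction",
    "alertness_daytime_sleepiness",
    "sleep_timing",
    "sleep_efficiency",
    "sleep_duration",
    "sleep_medication",
    "sleep_disorder",
    "sleep_intervention",
)


def round_half_up(x: float, decimals: int) -> float:
    """Round with ties away from zero (0.8525 -> 0.853), as tables print."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion matrix cells must be non-negative")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class Metrics:
    """Precision/recall/F1 held at full float precision; ``None`` = undefined."""

    precision: Optional[float]
    recall: Optional[float]
    f1: Optional[float]

    def rounded(self, decimals: int = 3) -> "Metrics":
        rnd = lambda v: None if v is None else round_half_up(v, decimals)
        return Metrics(rnd(self.precision), rnd(self.recall), rnd(self.f1))


@dataclass(frozen=True)
class AnnotationSpan:
    """A gold-standard standoff span tagged with one sleep-health dimension."""

    note_id: str
    dimension: str
    char_start: int
    char_end: int

    def __post_init__(self) -> None:
        if self.dimension not in DIMENSIONS:
            raise ValueError(f"unknown dimension {self.dimension!r}")
        if not self.char_start < self.char_end:
            raise ValueError(
                f"annotation span must be non-empty, got "
                f"[{self.char_start}, {self.char_end})"
            )


@dataclass(frozen=True)
class CoverageRow:
    dimension: str  # a dimension name, or "ALL"
    total_tags: int
    tags_containing_keyword: int
    percentage: Optional[float]  # 1 decimal; None when total_tags == 0
    most_present_keyword: Optional[str]
    most_present_count: int


@dataclass(frozen=True)
class CoverageTable:
    rows: tuple[CoverageRow, ...]  # per-dimension rows followed by the ALL row

    @property
    def all_row(self) -> CoverageRow:
        return self.rows[-1]

    def row(self, dimension: str) -> CoverageRow:
        for r in self.rows:
            if r.dimension == dimension:
                return r
        raise KeyError(dimension)


def confusion(
    predictions: Mapping[str, str], gold: Mapping[str, str]
) -> ConfusionMatrix:
    """Tally the 2x2 note-level confusion matrix.

    Raises :class:`ValueError` unless both maps cover the same note ids.
    """
    if set(predictions) != set(gold):
        missing = set(gold) ^ set(predictions)
        raise ValueError(f"prediction/gold note id mismatch: {sorted(missing)[:5]}...")
    tp = fp = fn = tn = 0
    for nid, pred in predictions.items():
        g = gold[nid]
        if pred == "positive" and g == "positive":
            tp += 1
        elif pred == "positive" and g == "negative":
            fp += 1
        elif pred == "negative" and g == "positive":
            fn += 1
        else:
            tn += 1
    return ConfusionMatrix(tp=tp, fp=fp, fn=fn, tn=tn)


def compute_metrics(cm: ConfusionMatrix) -> Metrics:
    """Precision, recall and F1 from a confusion matrix.

    >>> compute_metrics(ConfusionMatrix(tp=242, fp=42, fn=2, tn=14)).rounded()
    Metrics(precision=0.852, recall=0.992, f1=0.917)
    """
    precision = cm.tp / (cm.tp + cm.fp) if cm.tp + cm.fp > 0 else None
    recall = cm.tp / (cm.tp + cm.fn) if cm.tp + cm.fn > 0 else None
    f1 = None
    if precision is not None and recall is not None and precision + recall > 0:
        f1 = 2 * precision * recall / (precision + recall)
    return Metrics(precision=precision, recall=recall, f1=f1)


def recall_delta(m_a: Metrics, m_b: Metrics) -> float:
    """Recall difference (a minus b) in percentage points, 1 decimal."""
    if m_a.recall is None or m_b.recall is None:
        raise ValueError("recall_delta requires both recalls to be defined")
    delta = (m_a.recall - m_b.recall) * 100.0
    # quantize on the magnitude so ties round away from zero symmetrically
    return -round_half_up(-delta, 1) if delta < 0 else round_half_up(delta, 1)


def _contains(match: Match, span: AnnotationSpan, mode: str) -> bool:
    if mode == "containment":
        return span.char_start <= match.char_start and match.char_end <= span.char_end
    if mode == "any-overlap":
        return match.char_start < span.char_end and span.char_start < match.char_end
    raise ValueError(f"unknown overlap mode {mode!r}")


def span_coverage(
    matches_by_note: Mapping[str, Sequence[Match]],
    annotations: Iterable[AnnotationSpan],
    overlap: str = "containment",
) -> CoverageTable:
    """Keyword coverage of gold annotation spans, by dimension plus ALL.

    Only tier-1 matches count.  An annotation "contains a keyword" iff at
    least one tier-1 match interval lies fully inside it (default), or
    overlaps it at all in ``overlap="any-overlap"`` mode.  The most-present
    keyword of a row is the entry surface found inside the largest number
    of that row's annotations, ties broken lexicographically.
    """
    anns = list(annotations)
    for a in anns:
        if a.note_id not in matches_by_note:
            raise ValueError(f"annotation references unknown note id {a.note_id!r}")

    # per annotation: the set of tier-1 surfaces found inside it
    per_ann_surfaces: list[set[str]] = []
    for a in anns:
        surfaces = {
            m.entry_surface
            for m in matches_by_note[a.note_id]
            if 1 in m.tiers and _contains(m, a, overlap)
        }
        per_ann_surfaces.append(surfaces)

    def make_row(name: str, idxs: list[int]) -> CoverageRow:
        total = len(idxs)
        contained = sum(1 for i in idxs if per_ann_surfaces[i])
        pct = round_half_up(100.0 * contained / total, 1) if total else None
        counts: Counter[str] = Counter()
        for i in idxs:
            for s in per_ann_surfaces[i]:
                counts[s] += 1
        best: Optional[str] = None
        best_n = 0
        for s in sorted(counts):
            if counts[s] > best_n:
                best, best_n = s, counts[s]
        return CoverageRow(
            dimension=name,
            total_tags=total,
            tags_containing_keyword=contained,
            percentage=pct,
            most_present_keyword=best,
            most_present_count=best_n,
        )

    rows = [
        make_row(dim, [i for i, a in enumerate(anns) if a.dimension == dim])
        for dim in DIMENSIONS
    ]
    rows.append(make_row("ALL", list(range(len(anns)))))
    return CoverageTable(rows=tuple(rows))


def cohen_kappa(labels_a: Sequence, labels_b: Sequence) -> float:
    """Cohen's kappa: chance-corrected agreement between two labelings.

    kappa = (p_o - p_e) / (1 - p_e), with expected agreement p_e computed
    from the two marginal label distributions.  When p_e = 1 (both
    annotators constant), returns 1.0 for identical labelings and 0.0
    otherwise.
    """
    if len(labels_a) != len(labels_b):
        raise ValueError("labelings must have equal length")
    n = len(labels_a)
    if n == 0:
        raise ValueError("labelings must be non-empty")
    p_o = sum(1 for a, b in zip(labels_a, labels_b) if a == b) / n
    ca, cb = Counter(labels_a), Counter(labels_b)
    p_e = sum(ca[k] * cb.get(k, 0) for k in ca) / (n * n)
    if p_e == 1.0:
        return 1.0 if p_o == 1.0 else 0.0
    return (p_o - p_e) / (1.0 - p_e)
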