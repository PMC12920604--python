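"""Note-level identification rule.

A note is labeled positive when it contains at least one tier-1 keyword or
pattern match; tier-2 matches are reported but never trigger a positive
label.  A match whose surface belongs to both a tier-1 and a tier-2
category counts as tier-1.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from .matcher import Match, Matcher, find_matches

__all__ = ["NoteClassification", "classify_note", "classify_corpus", "CorpusSummary"]

POSITIVE = "positive"
NEGATIVE = "negative"


@dataclass(frozen=True)
class NoteClassification:
    note_id: str
    label: str  # "positive" | "negative"
    tier1_matches: tuple[Match, ...]
    tier2_matches: tuple[Match, ...]

    @property
    def matches(self) -> tuple[Match, ...]:
        return tuple(
            sorted(
                self.tier1_matches + self.tier2_matches,
                key=lambda m: (m.char_start, m.char_end),
            )
        )


@dataclass(frozen=True)
class CorpusSummary:
    n_notes: int
    n_positive: int
    n_negative: int


def classify_note(m: Matcher, note_id: str, raw: str) -> NoteClassification:
    """Classify one note: positive iff any match carries a tier-1 category."""
    tier1: list[Match] = []
    tier2: list[Match] = []
    for match in find_matches(m, raw):
        (tier1 if 1 in match.tiers else tier2).append(match)
    label = POSITIVE if tier1 else NEGATIVE
    return NoteClassification(
        note_id=note_id,
        label=label,
        tier1_matches=tuple(tier1),
        tier2_matches=tuple(tier2),
    )


def classify_corpus(
    m: Matcher, notes: Iterable[tuple[str, str]]
) -> tuple[list[NoteClassification], CorpusSummary]:
    """Order-preserving classification of a corpus of (id, text) pairs.

    Raises :class:`ValueError` on duplicate note ids.
    """
    seen: set[str] = set()
    out: list[NoteClassification] = []
    for note_id, text in notes:
        if note_id in seen:
            raise ValueError(f"duplicate note id {note_id!r}")
        seen.add(note_id)
        out.append(classify_note(m, note_id, text))
    n_pos = sum(1 for c in out if c.label == POSITIVE)
    return out, CorpusSummary(n_notes=len(out), n_positive=n_pos, n_negative=len(out) - n_pos)
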