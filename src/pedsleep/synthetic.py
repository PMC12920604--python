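"""Seeded synthetic well-child-visit note corpus with gold labels and spans.

Real pediatric clinical notes cannot be shared, so this module fabricates
note text with known ground truth: each gold-positive note embeds one or
more sleep-mention sentences (rendered either from a keyword-bearing
template containing a verbatim tier-1 surface, or from a keyword-free
paraphrase that describes the same dimension without any bank surface),
and each gold-negative note contains only filler prose plus, optionally,
the two distractor families the rule-based approach is known to trip on:
negated sleep phrases ("denies snoring") and tier-2-only symptom text
("mild wheezing").

Every template is screened against the vocabulary at generation time:
paraphrases and filler must produce zero matches, tier-2 distractors no
tier-1 match, and every pooled keyword surface must actually fire — so the
classifier's recall on a corpus generated with ``keyword_free_mention_rate
= 0`` is 1.0 by construction, and false positives arise only from
distractors.

A single ``random.Random(seed)`` stream drives all choices, consumed in a
fixed documented order (per note: label draw, then mention draws, then
distractor draws, then filler draws, then sentence placement), so a config
and seed reproduce a corpus byte for byte.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Union

from .classifier import NEGATIVE, POSITIVE
from .evaluation import DIMENSIONS, AnnotationSpan
from .io import write_jsonl
from .matcher import compile_matcher, find_matches
from .vocabulary import Vocabulary

__all__ = ["GeneratorConfig", "SyntheticCorpus", "generate_corpus", "corpus_to_files"]


# --- template bank -----------------------------------------------------------
# Keyword pools: verbatim tier-1 surfaces from the packaged bank, grouped by
# the annotation dimension a mention of that surface typically falls under.
DIMENSION_SURFACES: dict[str, tuple[str, ...]] = {
    "sleep_behavior": ("snores", "snoring", "sleepwalking", "teeth grinding", "nightmares", "restless sleep"),
    "sleep_satisfaction": ("poor sleep", "sleep quality", "trouble sleeping", "sleep issues", "difficulty sleeping"),
    "alertness_daytime_sleepiness": ("sleepy", "drowsy", "tired", "fatigue", "sleepiness", "dozing"),
    "sleep_timing": ("bedtime", "bedtime routine", "goes to bed", "sleeps late", "inconsistent bedtime"),
    "sleep_efficiency": ("sleep disturbance", "interrupted sleep", "wakes up at night", "fragmented sleep", "nighttime awakenings"),
    "sleep_duration": ("insufficient sleep", "sleep duration", "short sleep", "not getting enough sleep", "sleep deprivation"),
    "sleep_medication": ("melatonin", "clonidine", "sleep aid", "tylenol pm", "hypnotics"),
    "sleep_disorder": ("insomnia", "obstructive sleep apnea", "sleep apnea", "narcolepsy", "night terrors", "restless leg"),
    "sleep_intervention": ("sleep hygiene", "bedtime routine", "tonsillectomy", "adenoidectomy"),
}

# Sentence frames for keyword-bearing mentions; {kw} is the surface slot.
MENTION_FRAMES: tuple[str, ...] = (
    "Mom reports {kw} most nights.",
    "Patient endorses {kw} per parent.",
    "Discussed {kw} with the family today.",
    "History notable for {kw} on review.",
)

# Keyword-free paraphrases: a sleep mention a clinician annotates, phrased
# without any bank surface. Screened at generation time.
PARAPHRASES: dict[str, tuple[str, ...]] = {
    "sleep_behavior": (
        "Parents describe loud mouth breathing and frequent tossing overnight.",
        "He calls out and sits upright overnight without recalling it.",
    ),
    "sleep_satisfaction": (
        "Family feels his nights are not restful lately.",
        "She says mornings feel unrefreshing despite a full night in bed.",
    ),
    "alertness_daytime_sleepiness": (
        "Struggles to keep his eyes open during afternoon classes.",
        "Teachers note him nodding off at his desk after lunch.",
    ),
    "sleep_timing": (
        "Lights out around nine, up for school at six.",
        "On weekends the whole schedule drifts several time slots later.",
    ),
    "sleep_efficiency": (
        "Is up two or three times overnight before settling again.",
        "Takes nearly an hour of lying in bed before drifting off.",
    ),
    "sleep_duration": (
        "Gets about six hours on school nights per parent report.",
        "Parent estimates well under the recommended amount for his age overnight.",
    ),
    "sleep_medication": (
        "Takes a small chewable from the pharmacy aisle to help him settle in the evening.",
        "Family gives an over the counter gummy before bed on rough weeks.",
    ),
    "sleep_disorder": (
        "Has a formal nighttime breathing diagnosis followed by pulmonology.",
        "Carries a chronic diagnosis affecting how he rests, managed by specialty care.",
    ),
    "sleep_intervention": (
        "Counseled family on screens off an hour before bed and a consistent evening wind down.",
        "Reviewed a calming pre bed routine with the family.",
    ),
}

# Distractors for gold-negative notes: negated/absent sleep phrasing that
# still contains tier-1 surfaces (the false-positive mode), and tier-2-only
# symptom text (correctly ignored by the rule).
NEGATION_DISTRACTORS: tuple[str, ...] = (
    "Parent denies snoring or trouble sleeping.",
    "No sleep concerns reported today.",
    "Patient doesn't snore often per mom.",
    "Denies nightmares or bedwetting.",
)

TIER2_DISTRACTORS: tuple[str, ...] = (
    "Mild wheezing noted on lung exam.",
    "Mother describes him as irritable and hyper in the afternoons.",
    "Reports occasional dizziness with standing.",
)

FILLER_SENTENCES: tuple[str, ...] = (
    "Well child visit for routine health maintenance.",
    "Growth parameters tracking along the 50th percentile.",
    "Immunizations reviewed and updated per schedule.",
    "Diet includes fruits, vegetables, and whole grains.",
    "Physical activity most days of the week.",
    "Heart regular rate and rhythm without murmur.",
    "Abdomen soft, nontender, no organomegaly.",
    "Vision and hearing screens within normal limits.",
    "Anticipatory guidance provided regarding helmet use.",
    "Skin without rashes or concerning lesions.",
    "Denies headaches, chest pain, or palpitations.",
    "Follow up at the next annual visit or sooner as needed.",
)

# Annotation mix observed in manually tagged well-child notes (total tags
# per dimension); used as default sampling weights for mention dimensions.
DEFAULT_DIMENSION_WEIGHTS: dict[str, float] = {
    "sleep_behavior": 96.0,
    "sleep_satisfaction": 124.0,
    "alertness_daytime_sleepiness": 143.0,
    "sleep_timing": 87.0,
    "sleep_efficiency": 164.0,
    "sleep_duration": 40.0,
    "sleep_medication": 199.0,
    "sleep_disorder": 204.0,
    "sleep_intervention": 99.0,
}


@dataclass(frozen=True)
class GeneratorConfig:
    """Knobs of the synthetic corpus; defaults mirror the annotated study
    corpus: 300 notes of which 244 are positive, 1-3 mentions per positive
    note, mention dimensions drawn with the observed tag-count weights, and
    roughly one annotated span in five phrased without any bank keyword."""

    n_notes: int = 300
    prevalence: float = 244 / 300
    mentions_per_positive_note: tuple[int, int] = (1, 3)
    dimension_weights: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_DIMENSION_WEIGHTS)
    )
    keyword_free_mention_rate: float = 0.2
    negation_distractor_rate: float = 0.5
    tier2_only_rate: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_notes < 0:
            raise ValueError("n_notes must be >= 0")
        for name in ("prevalence", "keyword_free_mention_rate",
                     "negation_distractor_rate", "tier2_only_rate"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {p}")
        lo, hi = self.mentions_per_positive_note
        if not 1 <= lo <= hi:
            raise ValueError("mentions_per_positive_note must satisfy 1 <= lo <= hi")
        if set(self.dimension_weights) - set(DIMENSIONS):
            raise ValueError("dimension_weights contains unknown dimensions")
        weights = [self.dimension_weights.get(d, 0.0) for d in DIMENSIONS]
        if any(w < 0 for w in weights) or sum(weights) == 0:
            raise ValueError("dimension weights must be non-negative, not all zero")

    def to_dict(self) -> dict:
        return {
            "n_notes": self.n_notes,
            "prevalence": self.prevalence,
            "mentions_per_positive_note": list(self.mentions_per_positive_note),
            "dimension_weights": dict(self.dimension_weights),
            "keyword_free_mention_rate": self.keyword_free_mention_rate,
            "negation_distractor_rate": self.negation_distractor_rate,
            "tier2_only_rate": self.tier2_only_rate,
            "seed": self.seed,
        }


@dataclass(frozen=True)
class SyntheticCorpus:
    notes: tuple[tuple[str, str], ...]  # (note_id, text)
    gold_labels: dict[str, str]
    gold_spans: tuple[AnnotationSpan, ...]
    config_echo: GeneratorConfig


def _screen_templates(vocab: Vocabulary) -> None:
    """Assert the template bank is consistent with the vocabulary."""
    m = compile_matcher(vocab)
    for dim, surfaces in DIMENSION_SURFACES.items():
        for s in surfaces:
            hits = [h for h in find_matches(m, s) if 1 in h.tiers]
            if not hits:
                raise ValueError(
                    f"pooled surface {s!r} ({dim}) yields no tier-1 match "
                    "under the supplied vocabulary"
                )
    clean = [t for ts in PARAPHRASES.values() for t in ts]
    clean += list(FILLER_SENTENCES)
    clean += [f.format(kw="placeholder") for f in MENTION_FRAMES]
    for t in clean:
        hits = find_matches(m, t)
        if hits:
            raise ValueError(f"template {t!r} unexpectedly matches {hits[0].entry_surface!r}")
    for t in TIER2_DISTRACTORS:
        t1 = [h for h in find_matches(m, t) if 1 in h.tiers]
        if t1:
            raise ValueError(f"tier-2 distractor {t!r} contains tier-1 surface {t1[0].entry_surface!r}")


def _weighted_choice(rng: random.Random, items: list[str], weights: list[float]) -> str:
    return rng.choices(items, weights=weights, k=1)[0]


def generate_corpus(config: GeneratorConfig, vocab: Vocabulary) -> SyntheticCorpus:
    """Generate a corpus; deterministic given ``config`` (incl. its seed).

    Gold invariant: a note is labeled positive iff it carries at least one
    gold annotation span, and every gold span comes from a mention template
    (keyword-bearing or paraphrase), never from a distractor.
    """
    _screen_templates(vocab)
    rng = random.Random(config.seed)
    dims = [d for d in DIMENSIONS if config.dimension_weights.get(d, 0.0) > 0]
    dim_weights = [config.dimension_weights[d] for d in dims]
    lo, hi = config.mentions_per_positive_note

    notes: list[tuple[str, str]] = []
    labels: dict[str, str] = {}
    spans: list[AnnotationSpan] = []

    for i in range(config.n_notes):
        note_id = f"note-{i:04d}"
        positive = rng.random() < config.prevalence
        # (sentence text, dimension or None) — dimension marks a gold mention
        mention_sents: list[tuple[str, str]] = []
        distractor_sents: list[str] = []
        if positive:
            k = rng.randint(lo, hi)
            for _ in range(k):
                dim = _weighted_choice(rng, dims, dim_weights)
                if rng.random() < config.keyword_free_mention_rate:
                    sent = rng.choice(PARAPHRASES[dim])
                else:
                    frame = rng.choice(MENTION_FRAMES)
                    kw = rng.choice(DIMENSION_SURFACES[dim])
                    sent = frame.format(kw=kw)
                mention_sents.append((sent, dim))
        else:
            if rng.random() < config.negation_distractor_rate:
                distractor_sents.append(rng.choice(NEGATION_DISTRACTORS))
            if rng.random() < config.tier2_only_rate:
                distractor_sents.append(rng.choice(TIER2_DISTRACTORS))

        n_filler = rng.randint(3, 6)
        filler = [rng.choice(FILLER_SENTENCES) for _ in range(n_filler)]

        # place mention/distractor sentences at random slots among filler
        tagged: list[tuple[str, str | None]] = [(s, None) for s in filler]
        inserts: list[tuple[str, str | None]] = [(s, d) for s, d in mention_sents]
        inserts += [(s, None) for s in distractor_sents]
        for item in inserts:
            pos = rng.randint(0, len(tagged))
            tagged.insert(pos, item)

        pieces: list[str] = []
        cursor = 0
        for sent, dim in tagged:
            if pieces:
                cursor += 1  # the joining space
            start = cursor
            pieces.append(sent)
            cursor += len(sent)
            if dim is not None:
                spans.append(
                    AnnotationSpan(note_id=note_id, dimension=dim,
                                   char_start=start, char_end=cursor)
                )
        text = " ".join(pieces)
        notes.append((note_id, text))
        labels[note_id] = POSITIVE if positive else NEGATIVE

    return SyntheticCorpus(
        notes=tuple(notes),
        gold_labels=labels,
        gold_spans=tuple(spans),
        config_echo=replace(config),
    )


def corpus_to_files(corpus: SyntheticCorpus, dir: Union[str, Path]) -> None:
    """Write notes, gold labels, and gold annotations as JSONL files.

    Produces ``notes.jsonl``, ``gold_labels.jsonl`` and
    ``gold_annotations.jsonl`` in the formats the evaluation pipeline
    reads; offsets in the annotation file slice the written note texts to
    the original mention sentences.
    """
    d = Path(dir)
    try:
        write_jsonl(d / "notes.jsonl",
                    ({"note_id": nid, "text": text} for nid, text in corpus.notes))
        write_jsonl(d / "gold_labels.jsonl",
                    ({"note_id": nid, "label": corpus.gold_labels[nid]}
                     for nid, _ in corpus.notes))
        write_jsonl(d / "gold_annotations.jsonl",
                    ({"note_id": s.note_id, "dimension": s.dimension,
                      "start": s.char_start, "end": s.char_end}
                     for s in corpus.gold_spans))
    except OSError as exc:
        raise OSError(f"cannot write corpus files under {d}: {exc}") from exc
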