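"""The two-tier pediatric sleep keyword bank.

A :class:`Vocabulary` is an ordered list of named categories, each holding
literal phrases and/or regular-expression patterns and assigned to one of
two tiers: tier-1 categories drive note identification, tier-2 categories
are matched and reported but deliberately excluded from the note rule
because their surfaces (e.g. "wheezing", "irritable") are too ambiguous in
general clinical text.

The packaged asset ``dse_vocabulary.json`` is a verbatim transcription of
the published DSE (Davenport–Sirrianni Expanded) bank: 30 tier-1 and 7
tier-2 categories.  Transcription fidelity is deliberate — apparent
misspellings ("bendryl", "trazadone", "waking up a night") and repeated
entries are preserved exactly as printed; the validator flags them, the
matcher de-duplicates them at compile time.
"""

from __future__ import annotations

import json
import re
from collections import Counter
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Literal, Union

__all__ = [
    "KeywordEntry",
    "Category",
    "Vocabulary",
    "VocabStats",
    "ValidationReport",
    "Finding",
    "VocabularyError",
    "load_vocabulary",
    "save_vocabulary",
    "validate_vocabulary",
    "vocab_stats",
    "BUILTIN_DSE",
]

BUILTIN_DSE = "dse"

# Characters that carry special meaning in a regex; a *literal* entry
# containing one of these (other than the apostrophe-free hyphen set below)
# is suspicious but not fatal — literals are matched on token sequences,
# never compiled.
_REGEX_META = set(".^$*+?{}[]|()\\")


class VocabularyError(ValueError):
    """Raised for malformed vocabulary files or invalid vocabulary structure."""


@dataclass(frozen=True)
class KeywordEntry:
    """One literal phrase or regex pattern belonging to a category."""

    surface: str
    kind: Literal["literal", "regex"]
    category_name: str
    tier: int

    def __post_init__(self) -> None:
        if not self.surface.strip():
            raise VocabularyError(
                f"empty {self.kind} entry in category {self.category_name!r}"
            )
        if self.tier not in (1, 2):
            raise VocabularyError(
                f"tier must be 1 or 2, got {self.tier!r} "
                f"(category {self.category_name!r})"
            )
        if self.kind == "regex":
            try:
                re.compile(self.surface)
            except re.error as exc:
                raise VocabularyError(
                    f"regex {self.surface!r} in category "
                    f"{self.category_name!r} does not compile: {exc}"
                ) from exc
        elif self.kind != "literal":
            raise VocabularyError(f"unknown entry kind {self.kind!r}")


@dataclass(frozen=True)
class Category:
    """A named high-level concept with its entries, all on one tier."""

    name: str
    tier: int
    entries: tuple[KeywordEntry, ...]

    def __post_init__(self) -> None:
        if not self.entries:
            raise VocabularyError(f"category {self.name!r} has no entries")
        for e in self.entries:
            if e.tier != self.tier or e.category_name != self.name:
                raise VocabularyError(
                    f"entry {e.surface!r} does not belong to category "
                    f"{self.name!r} (tier {self.tier})"
                )

    @property
    def literals(self) -> tuple[str, ...]:
        return tuple(e.surface for e in self.entries if e.kind == "literal")

    @property
    def regexes(self) -> tuple[str, ...]:
        return tuple(e.surface for e in self.entries if e.kind == "regex")


@dataclass(frozen=True)
class Vocabulary:
    """An ordered collection of categories with a version tag."""

    categories: tuple[Category, ...]
    version: str = "unversioned"

    def __post_init__(self) -> None:
        if not self.categories:
            raise VocabularyError("vocabulary has no categories")
        names = [c.name for c in self.categories]
        dupes = [n for n, k in Counter(names).items() if k > 1]
        if dupes:
            raise VocabularyError(f"duplicate category names: {dupes}")

    def entries(self) -> Iterable[KeywordEntry]:
        for cat in self.categories:
            yield from cat.entries

    def tier_categories(self, tier: int) -> tuple[Category, ...]:
        return tuple(c for c in self.categories if c.tier == tier)


@dataclass(frozen=True)
class Finding:
    """One validation observation; ``fatal`` findings make the bank unusable."""

    code: str
    message: str
    fatal: bool = False


@dataclass(frozen=True)
class ValidationReport:
    findings: tuple[Finding, ...]

    @property
    def ok(self) -> bool:
        return not any(f.fatal for f in self.findings)

    def by_code(self, code: str) -> tuple[Finding, ...]:
        return tuple(f for f in self.findings if f.code == code)


@dataclass(frozen=True)
class VocabStats:
    n_categories_total: int
    n_categories_tier1: int
    n_categories_tier2: int
    n_literals: int
    n_regexes: int
    per_category_counts: dict[str, int] = field(default_factory=dict)


def _category_from_record(rec: dict, idx: int) -> Category:
    try:
        name = rec["name"]
        tier = rec["tier"]
        literals = rec.get("literals", [])
        regexes = rec.get("regexes", [])
    except (KeyError, TypeError) as exc:
        raise VocabularyError(f"malformed category record #{idx}: {rec!r}") from exc
    if not isinstance(name, str) or not isinstance(literals, list) or not isinstance(regexes, list):
        raise VocabularyError(f"malformed category record #{idx} ({name!r})")
    entries = [
        KeywordEntry(surface=s, kind="literal", category_name=name, tier=tier)
        for s in literals
    ] + [
        KeywordEntry(surface=s, kind="regex", category_name=name, tier=tier)
        for s in regexes
    ]
    return Category(name=name, tier=tier, entries=tuple(entries))


def load_vocabulary(source: Union[str, Path] = BUILTIN_DSE) -> Vocabulary:
    """Load a vocabulary from the packaged DSE asset or a JSON file.

    ``source`` is either the builtin identifier ``"dse"`` or a path to a
    file in the documented schema::

        {"version": "...",
         "categories": [{"name": ..., "tier": 1|2,
                         "literals": [...], "regexes": [...]}, ...]}

    All regex entries are compiled during loading; a malformed file raises
    :class:`VocabularyError` naming the offending record.
    """
    if isinstance(source, str) and source == BUILTIN_DSE:
        payload = (
            resources.files("pedsleep").joinpath("data/dse_vocabulary.json").read_text("utf-8")
        )
    else:
        path = Path(source)
        if str(path) == "":
            raise VocabularyError("empty vocabulary path")
        try:
            payload = path.read_text("utf-8")
        except OSError as exc:
            raise VocabularyError(f"cannot read vocabulary file {path}: {exc}") from exc
    try:
        doc = json.loads(payload)
    except json.JSONDecodeError as exc:
        raise VocabularyError(f"vocabulary source is not valid JSON: {exc}") from exc
    if not isinstance(doc, dict) or "categories" not in doc:
        raise VocabularyError("vocabulary JSON must be an object with a 'categories' list")
    cats = tuple(
        _category_from_record(rec, i) for i, rec in enumerate(doc["categories"])
    )
    return Vocabulary(categories=cats, version=str(doc.get("version", "unversioned")))


def save_vocabulary(v: Vocabulary, dest: Union[str, Path]) -> None:
    """Write ``v`` in the canonical JSON schema; round-trips losslessly."""
    if str(dest) == "":
        raise VocabularyError("empty destination path")
    doc = {
        "version": v.version,
        "categories": [
            {
                "name": c.name,
                "tier": c.tier,
                "literals": list(c.literals),
                "regexes": list(c.regexes),
            }
            for c in v.categories
        ],
    }
    Path(dest).write_text(
        json.dumps(doc, indent=2, ensure_ascii=False) + "\n", encoding="utf-8"
    )


def validate_vocabulary(v: Vocabulary) -> ValidationReport:
    """Audit a vocabulary without mutating it.

    Reports within-category duplicate surfaces, surfaces shared across
    categories (informational — the published bank contains e.g. "trouble
    sleeping" under two categories), literals containing regex
    metacharacters, and blank surfaces.  Non-compiling regexes cannot occur
    in a constructed :class:`Vocabulary` (entry construction compiles them),
    but raw surfaces are re-checked for completeness.
    """
    findings: list[Finding] = []
    surface_to_cats: dict[tuple[str, str], list[str]] = {}
    for cat in v.categories:
        seen: Counter[tuple[str, str]] = Counter()
        for e in cat.entries:
            if not e.surface.strip():
                findings.append(
                    Finding("empty-surface", f"blank entry in {cat.name!r}", fatal=True)
                )
                continue
            seen[(e.kind, e.surface)] += 1
            surface_to_cats.setdefault((e.kind, e.surface), []).append(cat.name)
            if e.kind == "literal" and _REGEX_META & set(e.surface):
                findings.append(
                    Finding(
                        "literal-metachar",
                        f"literal {e.surface!r} in {cat.name!r} contains regex "
                        "metacharacters",
                    )
                )
            if e.kind == "regex":
                try:
                    re.compile(e.surface)
                except re.error as exc:
                    findings.append(
                        Finding(
                            "regex-no-compile",
                            f"regex {e.surface!r} in {cat.name!r}: {exc}",
                            fatal=True,
                        )
                    )
        for (kind, surface), k in seen.items():
            if k > 1:
                findings.append(
                    Finding(
                        "within-category-duplicate",
                        f"{kind} {surface!r} appears {k}x in {cat.name!r}",
                    )
                )
    for (kind, surface), cats in surface_to_cats.items():
        distinct = sorted(set(cats))
        if len(distinct) > 1:
            findings.append(
                Finding(
                    "cross-category-duplicate",
                    f"{kind} {surface!r} appears in categories {distinct}",
                )
            )
    return ValidationReport(findings=tuple(findings))


def vocab_stats(v: Vocabulary) -> VocabStats:
    """Exact entry and category counts (duplicates counted as printed)."""
    tier1 = v.tier_categories(1)
    tier2 = v.tier_categories(2)
    n_lit = sum(len(c.literals) for c in v.categories)
    n_re = sum(len(c.regexes) for c in v.categories)
    return VocabStats(
        n_categories_total=len(v.categories),
        n_categories_tier1=len(tier1),
        n_categories_tier2=len(tier2),
        n_literals=n_lit,
        n_regexes=n_re,
        per_category_counts={c.name: len(c.entries) for c in v.categories},
    )
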