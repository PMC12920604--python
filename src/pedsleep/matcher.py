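"""Multi-pattern keyword matching over normalized token streams.

Literal phrases from the vocabulary are tokenized and inserted into a
token-sequence trie; a single left-to-right scan over a note's token stream
enumerates literal hits with longest-leftmost, non-overlapping resolution
(so "difficulty falling asleep" beats the nested "falling asleep").  Regex
entries run independently over the space-joined normalized token string —
anchored to token boundaries — and are mapped back to raw character
offsets; regex hits are never suppressed by overlapping literal hits.

:func:`find_matches_bruteforce` is an intentionally naive per-entry scanner
with the same resolution rule, kept as an equivalence oracle for testing.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from itertools import accumulate
from typing import Iterable

from .textprep import NormalizedText, normalize
from .vocabulary import Vocabulary

__all__ = ["Match", "Matcher", "compile_matcher", "find_matches", "find_matches_bruteforce"]


@dataclass(frozen=True)
class Match:
    """One detected keyword or pattern occurrence in a raw note.

    ``categories`` lists every (category name, tier) pair whose entry
    produced this surface; cross-category duplicate surfaces therefore
    yield a single multi-category match.
    """

    matched_text: str
    char_start: int
    char_end: int
    entry_surface: str
    categories: tuple[tuple[str, int], ...]
    kind: str  # "literal" | "regex"

    @property
    def tiers(self) -> frozenset[int]:
        return frozenset(t for _, t in self.categories)

    def to_dict(self) -> dict:
        return {
            "start": self.char_start,
            "end": self.char_end,
            "text": self.matched_text,
            "surface": self.entry_surface,
            "kind": self.kind,
            "categories": [{"name": n, "tier": t} for n, t in self.categories],
        }


class _TrieNode:
    __slots__ = ("children", "terminal")

    def __init__(self) -> None:
        self.children: dict[str, _TrieNode] = {}
        # terminal: None, or the normalized surface key ending here
        self.terminal: str | None = None


@dataclass(frozen=True)
class Matcher:
    """Compiled matcher: a literal trie plus compiled, annotated regexes.

    Compilation is a pure function of the vocabulary; recompiling yields a
    matcher with identical behavior.
    """

    root: _TrieNode
    # normalized surface key -> sorted (category, tier) pairs
    literal_categories: dict[str, tuple[tuple[str, int], ...]]
    # (pattern source, compiled boundary-anchored regex, categories)
    regexes: tuple[tuple[str, "re.Pattern[str]", tuple[tuple[str, int], ...]], ...]


def _anchor(pattern: str) -> "re.Pattern[str]":
    # Token-boundary anchoring on the space-joined token string: a match may
    # not start or end inside a token.
    return re.compile(r"(?<![a-z0-9])(?:" + pattern + r")(?![a-z0-9])")


def compile_matcher(v: Vocabulary) -> Matcher:
    """Compile ``v`` into a :class:`Matcher`.

    Literal surfaces are normalized with :func:`pedsleep.textprep.normalize`;
    duplicate surfaces (within or across categories) are merged with the
    union of their categories.
    """
    lit_cats: dict[str, set[tuple[str, int]]] = {}
    re_cats: dict[str, set[tuple[str, int]]] = {}
    for entry in v.entries():
        if entry.kind == "literal":
            key = " ".join(normalize(entry.surface).tokens)
            if not key:
                continue
            lit_cats.setdefault(key, set()).add((entry.category_name, entry.tier))
        else:
            re_cats.setdefault(entry.surface, set()).add((entry.category_name, entry.tier))

    root = _TrieNode()
    literal_categories: dict[str, tuple[tuple[str, int], ...]] = {}
    for key in sorted(lit_cats):
        node = root
        for tok in key.split(" "):
            node = node.children.setdefault(tok, _TrieNode())
        node.terminal = key
        literal_categories[key] = tuple(sorted(lit_cats[key]))

    regexes = tuple(
        (src, _anchor(src), tuple(sorted(re_cats[src]))) for src in sorted(re_cats)
    )
    return Matcher(root=root, literal_categories=literal_categories, regexes=regexes)


def _scan_literals_trie(m: Matcher, nt: NormalizedText) -> list[tuple[int, int, str]]:
    """Longest-leftmost non-overlapping literal hits as (tok_start, tok_end, key)."""
    hits: list[tuple[int, int, str]] = []
    tokens = nt.tokens
    i, n = 0, len(tokens)
    while i < n:
        node = m.root
        best: tuple[int, str] | None = None  # (tok_end inclusive, key)
        j = i
        while j < n:
            node = node.children.get(tokens[j])
            if node is None:
                break
            if node.terminal is not None:
                best = (j, node.terminal)
            j += 1
        if best is not None:
            hits.append((i, best[0], best[1]))
            i = best[0] + 1
        else:
            i += 1
    return hits


def _regex_hits(
    regexes: Iterable[tuple[str, "re.Pattern[str]", tuple[tuple[str, int], ...]]],
    nt: NormalizedText,
) -> list[Match]:
    if not nt.tokens:
        return []
    joined = nt.joined
    # joined-string start offset of each token
    starts = [0] + list(accumulate(len(t) + 1 for t in nt.tokens))[:-1]
    start_to_tok = {s: k for k, s in enumerate(starts)}
    end_to_tok = {s + len(t): k for k, (s, t) in enumerate(zip(starts, nt.tokens))}
    out: list[Match] = []
    for src, pat, cats in regexes:
        for hit in pat.finditer(joined):
            a, b = hit.span()
            if a == b:
                continue
            first = start_to_tok.get(a)
            last = end_to_tok.get(b)
            if first is None or last is None:
                continue  # anchoring guarantees alignment; guard regardless
            cs = nt.token_offsets[first][0]
            ce = nt.token_offsets[last][1]
            out.append(
                Match(
                    matched_text=nt.raw[cs:ce],
                    char_start=cs,
                    char_end=ce,
                    entry_surface=src,
                    categories=cats,
                    kind="regex",
                )
            )
    return out


def _finalize(matches: list[Match]) -> list[Match]:
    seen: set[tuple] = set()
    out: list[Match] = []
    for m in sorted(
        matches, key=lambda m: (m.char_start, m.char_end, m.kind, m.entry_surface)
    ):
        key = (m.char_start, m.char_end, m.kind, m.entry_surface, m.categories)
        if key not in seen:
            seen.add(key)
            out.append(m)
    return out


def find_matches(m: Matcher, raw: str) -> list[Match]:
    """Enumerate all matches in ``raw``, sorted by (start, end)."""
    nt = normalize(raw)
    matches: list[Match] = []
    for ti, tj, key in _scan_literals_trie(m, nt):
        cs, ce = nt.token_offsets[ti][0], nt.token_offsets[tj][1]
        matches.append(
            Match(
                matched_text=raw[cs:ce],
                char_start=cs,
                char_end=ce,
                entry_surface=key,
                categories=m.literal_categories[key],
                kind="literal",
            )
        )
    matches.extend(_regex_hits(m.regexes, nt))
    return _finalize(matches)


def find_matches_bruteforce(v: Vocabulary, raw: str) -> list[Match]:
    """Oracle implementation: per-entry naive scan, identical resolution.

    For every literal entry independently, every token position is tested
    for whole-token-sequence equality; candidates then pass through the same
    longest-leftmost, non-overlapping resolution as the trie scanner.
    Contract: equal output to :func:`find_matches` on every input.
    """
    nt = normalize(raw)
    tokens = nt.tokens

    lit_cats: dict[str, set[tuple[str, int]]] = {}
    re_cats: dict[str, set[tuple[str, int]]] = {}
    for entry in v.entries():
        if entry.kind == "literal":
            key = " ".join(normalize(entry.surface).tokens)
            if key:
                lit_cats.setdefault(key, set()).add((entry.category_name, entry.tier))
        else:
            re_cats.setdefault(entry.surface, set()).add((entry.category_name, entry.tier))

    # all candidate literal occurrences
    candidates: list[tuple[int, int, str]] = []  # (tok_start, tok_end, key)
    for key in lit_cats:
        seq = tuple(key.split(" "))
        L = len(seq)
        for i in range(len(tokens) - L + 1):
            if tokens[i : i + L] == seq:
                candidates.append((i, i + L - 1, key))

    # longest-leftmost, non-overlapping resolution
    candidates.sort(key=lambda c: (c[0], -(c[1] - c[0])))
    resolved: list[tuple[int, int, str]] = []
    cursor = 0
    for i, j, key in candidates:
        if i >= cursor:
            resolved.append((i, j, key))
            cursor = j + 1

    matches: list[Match] = []
    for i, j, key in resolved:
        cs, ce = nt.token_offsets[i][0], nt.token_offsets[j][1]
        matches.append(
            Match(
                matched_text=raw[cs:ce],
                char_start=cs,
                char_end=ce,
                entry_surface=key,
                categories=tuple(sorted(lit_cats[key])),
                kind="literal",
            )
        )
    regex_list = tuple(
        (src, _anchor(src), tuple(sorted(re_cats[src]))) for src in sorted(re_cats)
    )
    matches.extend(_regex_hits(regex_list, nt))
    return _finalize(matches)
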