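"""Text normalization for keyword matching.

Clinical note text is lowercased and split into alphanumeric tokens, while
every token keeps an exact half-open character interval back into the raw
string.  Any non-alphanumeric character (punctuation, whitespace, hyphens,
apostrophes — including the Unicode "smart" variants) acts as a word
boundary, so ``nap`` never fires inside ``naproxen`` and ``low-energy``
tokenizes identically to ``low energy``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = ["NormalizedText", "normalize", "token_span_to_raw"]


def _is_token_char(c: str) -> bool:
    # ASCII letters and digits only; everything else (incl. accented and
    # non-Latin characters) is a boundary.
    return ("a" <= c <= "z") or ("A" <= c <= "Z") or ("0" <= c <= "9")


@dataclass(frozen=True)
class NormalizedText:
    """A raw string plus its lowercase token stream and per-token offsets.

    ``token_offsets[i]`` is the half-open interval ``[start, end)`` in
    ``raw`` from which ``tokens[i]`` was produced; intervals are strictly
    increasing and non-overlapping.
    """

    raw: str
    tokens: tuple[str, ...] = field(default=())
    token_offsets: tuple[tuple[int, int], ...] = field(default=())

    @property
    def joined(self) -> str:
        """The tokens joined by single spaces (the regex-matching surface)."""
        return " ".join(self.tokens)


def normalize(raw: str) -> NormalizedText:
    """Tokenize ``raw`` into lowercase alphanumeric tokens with offsets.

    Deterministic; the empty string yields an empty token list.

    >>> normalize("Can’t Sleep!!").tokens
    ('can', 't', 'sleep')
    >>> normalize("low-energy").token_offsets
    ((0, 3), (4, 10))
    """
    tokens: list[str] = []
    offsets: list[tuple[int, int]] = []
    i, n = 0, len(raw)
    while i < n:
        if _is_token_char(raw[i]):
            j = i + 1
            while j < n and _is_token_char(raw[j]):
                j += 1
            tokens.append(raw[i:j].lower())
            offsets.append((i, j))
            i = j
        else:
            i += 1
    return NormalizedText(raw=raw, tokens=tuple(tokens), token_offsets=tuple(offsets))


def token_span_to_raw(nt: NormalizedText, first_token: int, last_token: int) -> tuple[int, int]:
    """Map an inclusive token index range to raw character coordinates.

    Returns ``[start of first token, end of last token)``.  Raises
    :class:`IndexError` on out-of-range or inverted indices.
    """
    if not (0 <= first_token <= last_token < len(nt.tokens)):
        raise IndexError(
            f"token span [{first_token}, {last_token}] out of range "
            f"for {len(nt.tokens)} tokens"
        )
    return (nt.token_offsets[first_token][0], nt.token_offsets[last_token][1])
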