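"""JSONL reading/writing for note-shaped data.

All on-disk formats are line-delimited JSON: notes ``{note_id, text}``,
gold labels ``{note_id, label}``, annotations
``{note_id, dimension, start, end}``, match records
``{note_id, matches: [...]}``.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Iterator, Union

__all__ = ["read_jsonl", "write_jsonl"]


def read_jsonl(path: Union[str, Path]) -> Iterator[dict]:
    """Yield one parsed object per non-blank line; errors name the line."""
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                obj = json.loads(line)
            except json.JSONDecodeError as exc:
                raise ValueError(f"{path}:{lineno}: malformed JSON line: {exc}") from exc
            if not isinstance(obj, dict):
                raise ValueError(f"{path}:{lineno}: expected a JSON object")
            yield obj


def write_jsonl(path: Union[str, Path], records: Iterable[dict]) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for rec in records:
            fh.write(json.dumps(rec, ensure_ascii=False) + "\n")
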