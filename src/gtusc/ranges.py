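"""Residue-number range arithmetic and formatting.

Binding-site footprints and interface descriptions are conventionally
printed as inclusive residue ranges ("515–536, 617–632"). These helpers
convert between sorted residue-number lists and that notation, and count
the residues a span covers.
"""

from __future__ import annotations

import re
from collections.abc import Iterable, Sequence

# en dash (the typeset convention), hyphen, or minus sign
_SEP = re.compile(r"\s*[–−-]\s*")
_EN_DASH = "–"


def collapse_ranges(numbers: Iterable[int]) -> list[tuple[int, int]]:
    """Collapse residue numbers into sorted maximal inclusive (start, end) runs."""
    uniq = sorted(set(int(n) for n in numbers))
    runs: list[tuple[int, int]] = []
    for n in uniq:
        if runs and n == runs[-1][1] + 1:
            runs[-1] = (runs[-1][0], n)
        else:
            runs.append((n, n))
    return runs


def format_ranges(numbers: Iterable[int]) -> str:
    """Render residue numbers as "246–264, 315–319, 337"."""
    parts = []
    for start, end in collapse_ranges(numbers):
        parts.append(str(start) if start == end else f"{start}{_EN_DASH}{end}")
    return ", ".join(parts)


def parse_ranges(text: str) -> list[int]:
    """Expand "515–536, 617–632" (hyphen or en dash) into residue numbers."""
    numbers: list[int] = []
    for token in text.split(","):
        token = token.strip()
        if not token:
            continue
        pieces = _SEP.split(token)
        if len(pieces) == 1:
            numbers.append(int(pieces[0]))
        elif len(pieces) == 2:
            start, end = int(pieces[0]), int(pieces[1])
            if end < start:
                raise ValueError(f"descending range: {token!r}")
            numbers.extend(range(start, end + 1))
        else:
            raise ValueError(f"unparsable range token: {token!r}")
    return numbers


def span_residue_count(text: str) -> int:
    """Number of residues covered by a printed span, e.g. "328–342" -> 15."""
    return len(set(parse_ranges(text)))


def ranges_to_intervals(numbers: Sequence[int]) -> list[tuple[int, int]]:
    """Alias of :func:`collapse_ranges` kept for interval-table (TSV) export."""
    return collapse_ranges(numbers)
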