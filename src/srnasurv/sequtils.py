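"""Small sequence helpers shared across modules."""

from __future__ import annotations

from typing import Iterator

_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string."""
    return seq.translate(_COMP)[::-1]


def find_all(haystack: str, needle: str) -> Iterator[int]:
    """Yield every start index of ``needle`` in ``haystack`` (overlaps included)."""
    i = haystack.find(needle)
    while i != -1:
        yield i
        i = haystack.find(needle, i + 1)
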