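"""Cardinal-number normalization.

Narrative genetics text writes cohort sizes either as digits (``4``,
``1,204``) or as English number words (``two``, ``twenty-three``,
``three hundred five``).  Pattern matching needs the integer value, so this
module maps both surface forms onto ``int``.  Word numerals are supported up
to 999; digit strings may be arbitrarily large and may carry thousands
separators.
"""

from __future__ import annotations

import re

__all__ = ["normalize_cardinal", "UnparseableNumeralError", "CARDINAL_WORDS"]


class UnparseableNumeralError(ValueError):
    """Raised when a surface form cannot be read as a cardinal number."""


_ONES = {
    "zero": 0, "one": 1, "two": 2, "three": 3, "four": 4, "five": 5,
    "six": 6, "seven": 7, "eight": 8, "nine": 9, "ten": 10,
    "eleven": 11, "twelve": 12, "thirteen": 13, "fourteen": 14,
    "fifteen": 15, "sixteen": 16, "seventeen": 17, "eighteen": 18,
    "nineteen": 19,
}
_TENS = {
    "twenty": 20, "thirty": 30, "forty": 40, "fifty": 50,
    "sixty": 60, "seventy": 70, "eighty": 80, "ninety": 90,
}

#: every word that can participate in a written cardinal (used by the
#: tokenizer to merge multi-word numerals into a single token)
CARDINAL_WORDS = frozenset(_ONES) | frozenset(_TENS) | {"hundred"}

_DIGITS_RE = re.compile(r"^\d{1,3}(?:,\d{3})+$|^\d+$")


def normalize_cardinal(surface: str) -> int:
    """Return the integer value of a cardinal surface form.

    Accepts digit strings (optionally with comma thousands separators) and
    English cardinal words or compounds up to 999 ("two", "twenty-three",
    "one hundred and five").  Case-insensitive.

    Raises
    ------
    UnparseableNumeralError
        If the surface form is neither a digit string nor a word numeral.
    """
    s = surface.strip()
    if not s:
        raise UnparseableNumeralError("empty numeral")
    if _DIGITS_RE.match(s):
        return int(s.replace(",", ""))

    words = [w for w in re.split(r"[\s\-–]+", s.lower()) if w and w != "and"]
    if not words:
        raise UnparseableNumeralError(surface)

    total = 0
    current = 0
    seen_hundred = False
    for w in words:
        if w in _ONES:
            current += _ONES[w]
        elif w in _TENS:
            current += _TENS[w]
        elif w == "hundred":
            if current == 0 or seen_hundred:
                raise UnparseableNumeralError(surface)
            current *= 100
            seen_hundred = True
        else:
            raise UnparseableNumeralError(surface)
    total += current
    if total > 999 and not _DIGITS_RE.match(s):
        raise UnparseableNumeralError(surface)
    return total
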