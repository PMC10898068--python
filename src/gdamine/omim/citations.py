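"""Inline citation detection and resolution against a reference list.

Two citation dialects are supported:

* **brace-numbered marks** (canonical): ``{5:Thiffault et al. (2019)}`` —
  resolved directly by reference number; multi-reference marks
  ``{1,2:...}`` carry every number;
* **surface author-year citations** (fallback): ``Smith et al. (2001)`` —
  resolved by first-author surname + year lookup; unresolvable surface
  citations are returned with empty ``ref_numbers`` and ``resolved=False``
  rather than dropped.

Every mention carries its character span in the paragraph and the sentence
index assigned by the linguistic engine, which is what the proximity-based
citation selection consumes.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

from ..nlp.engine import AnalysisEngine, get_engine
from ..nlp.tokens import AnalyzedDoc
from .models import ReferenceRecord

__all__ = ["CitationMention", "resolve_reference_marks"]

_BRACE_RE = re.compile(r"\{(\d+(?:\s*,\s*\d+)*):([^{}]*)\}")
_SURFACE_RE = re.compile(
    r"\b([A-Z][A-Za-z'’\-]+)"               # first-author surname
    r"(?:\s+and\s+[A-Z][A-Za-z'’\-]+)?"     # optional second author
    r"(?:\s+et\s+al\.?)?"                   # optional 'et al.'
    r"\s*\((\d{4})\)"                       # (year)
)


@dataclass(frozen=True)
class CitationMention:
    """One inline citation occurrence within a paragraph."""

    ref_numbers: tuple[int, ...]
    char_span: tuple[int, int]
    sentence_index: int
    surface: str
    resolved: bool = True

    @property
    def start(self) -> int:
        return self.char_span[0]


def resolve_reference_marks(
    paragraph: str,
    references: list[ReferenceRecord],
    doc: AnalyzedDoc | None = None,
    engine: AnalysisEngine | None = None,
) -> list[CitationMention]:
    """Return every inline citation of a paragraph in document order.

    ``doc`` supplies sentence segmentation; when omitted the paragraph is
    analyzed with the default engine.  Mentions whose reference numbers are
    not present in ``references`` (or whose author/year pair has no match)
    come back flagged ``resolved=False`` with empty ``ref_numbers``.
    """
    if doc is None:
        doc = (engine or get_engine()).analyze(paragraph)

    known = {r.ref_number for r in references}
    by_author_year = {(r.first_author.lower(), r.year): r.ref_number for r in references}

    mentions: list[CitationMention] = []
    brace_spans: list[tuple[int, int]] = []

    for m in _BRACE_RE.finditer(paragraph):
        nums = tuple(int(x) for x in re.split(r"\s*,\s*", m.group(1)))
        ok = all(n in known for n in nums)
        mentions.append(
            CitationMention(
                ref_numbers=nums if ok else (),
                char_span=(m.start(), m.end()),
                sentence_index=doc.sentence_index_at(m.start()),
                surface=m.group(0),
                resolved=ok,
            )
        )
        brace_spans.append((m.start(), m.end()))

    for m in _SURFACE_RE.finditer(paragraph):
        if any(s <= m.start() < e for s, e in brace_spans):
            continue  # inside a brace mark; already captured
        author, year = m.group(1), int(m.group(2))
        ref = by_author_year.get((author.lower(), year))
        mentions.append(
            CitationMention(
                ref_numbers=(ref,) if ref is not None else (),
                char_span=(m.start(), m.end()),
                sentence_index=doc.sentence_index_at(m.start()),
                surface=m.group(0),
                resolved=ref is not None,
            )
        )

    mentions.sort(key=lambda c: c.char_span)
    return mentions
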