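"""Proximity-based selection of the publication evidencing a match.

Given an anchor token's sentence, candidate citations are ranked by
proximity first and publication year second:

1. the anchor sentence itself;
2. preceding sentences, scanned in reverse order (nearest first);
3. following sentences, nearest first, up to the end of the paragraph.

Each sentence is its own proximity rank; within the first rank holding any
non-blacklisted citation, the mention whose resolved reference has the
earliest year wins, with year ties broken by the smaller reference number.
Citations flagged as phenotype-only describing studies are blacklisted and
skipped entirely, which can push the selection to a farther sentence but
never to a nearer one.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Literal, Optional

from .nlp.patterns import ExclusionMatch
from .nlp.tokens import AnalyzedDoc
from .omim.citations import CitationMention
from .omim.models import ReferenceRecord

__all__ = [
    "ResolutionResult",
    "phenotype_only_references",
    "select_citation",
    "earliest_across_sections",
]

Tier = Literal["same_sentence", "preceding", "following", "none"]


@dataclass
class ResolutionResult:
    mention: Optional[CitationMention]
    reference: Optional[ReferenceRecord]
    tier: Tier
    excluded_refs: frozenset[int] = frozenset()
    #: candidates considered, for the audit trace: (rank, year, ref_number)
    trace: list[tuple[int, int, int]] = field(default_factory=list)

    @property
    def found(self) -> bool:
        return self.reference is not None

    def to_trace_json(self) -> str:
        return json.dumps(
            {
                "tier": self.tier,
                "selected": self.reference.ref_number if self.reference else None,
                "year": self.reference.year if self.reference else None,
                "excluded": sorted(self.excluded_refs),
                "candidates": [
                    {"rank": r, "year": y, "ref": n} for r, y, n in self.trace
                ],
            }
        )


def phenotype_only_references(
    doc: AnalyzedDoc,
    mentions: list[CitationMention],
    exclusions: list[ExclusionMatch],
) -> frozenset[int]:
    """Reference numbers of every citation co-sentential with an exclusion
    match (studies that merely describe the phenotype/patients)."""
    excluded_sentences = {e.sentence_index for e in exclusions}
    return frozenset(
        n
        for m in mentions
        if m.sentence_index in excluded_sentences
        for n in m.ref_numbers
    )


def select_citation(
    doc: AnalyzedDoc,
    anchor_sentence: int,
    mentions: list[CitationMention],
    blacklist: frozenset[int] | set[int],
    references: list[ReferenceRecord],
) -> ResolutionResult:
    """Pick the citation evidencing an anchor, by proximity then year.

    Multi-reference mentions expand to one candidate per reference.  Returns
    ``tier='none'`` when every mention is blacklisted or the paragraph has
    no resolvable citation.
    """
    by_num = {r.ref_number: r for r in references}
    n_sent = max(doc.sentence_count, anchor_sentence + 1)

    candidates: list[tuple[int, int, int, CitationMention]] = []
    for m in mentions:
        for num in m.ref_numbers:
            if num in blacklist or num not in by_num:
                continue
            d = m.sentence_index - anchor_sentence
            if d == 0:
                rank = 0
            elif d < 0:
                rank = -d               # preceding, nearest first
            else:
                rank = n_sent + d       # following, after all preceding
            candidates.append((rank, by_num[num].year, num, m))

    trace = sorted((r, y, n) for r, y, n, _ in candidates)
    if not candidates:
        return ResolutionResult(None, None, "none", frozenset(blacklist), trace)

    rank, year, num, mention = min(candidates, key=lambda c: c[:3])
    if rank == 0:
        tier: Tier = "same_sentence"
    elif mention.sentence_index < anchor_sentence:
        tier = "preceding"
    else:
        tier = "following"
    return ResolutionResult(mention, by_num[num], tier, frozenset(blacklist), trace)


def earliest_across_sections(results: list[ResolutionResult]) -> ResolutionResult:
    """Combine per-section resolutions: the first section (in priority
    order) that found anything wins, regardless of its proximity tier."""
    for r in results:
        if r.tier != "none":
            return r
    return ResolutionResult(None, None, "none")
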