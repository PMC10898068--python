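"""Token and document containers shared by every pattern matcher."""

from __future__ import annotations

from bisect import bisect_right
from dataclasses import dataclass, field


@dataclass
class Token:
    """One analyzed token.

    ``head`` is the index of the governing token within the document (a
    sentence root governs itself).  ``char_span`` is a 0-based half-open
    span into the source paragraph.
    """

    index: int
    text: str
    lemma: str
    pos: str
    dep: str
    head: int
    sentence_index: int
    char_span: tuple[int, int]

    @property
    def lower(self) -> str:
        return self.text.lower()


@dataclass
class AnalyzedDoc:
    """A paragraph with its token stream and sentence segmentation."""

    text: str
    tokens: list[Token] = field(default_factory=list)
    sentence_count: int = 0

    def sentence(self, i: int) -> list[Token]:
        return [t for t in self.tokens if t.sentence_index == i]

    def children(self, i: int) -> list[Token]:
        """Dependents of token ``i`` (excluding the token itself)."""
        return [t for t in self.tokens if t.head == i and t.index != i]

    def sentence_index_at(self, char_pos: int) -> int:
        """Sentence index of the token covering (or nearest before) a
        character position; 0 for an empty document."""
        if not self.tokens:
            return 0
        starts = [t.char_span[0] for t in self.tokens]
        k = bisect_right(starts, char_pos) - 1
        return self.tokens[max(k, 0)].sentence_index

    def subtree(self, i: int) -> list[Token]:
        """Token ``i`` plus all transitive dependents."""
        out, queue, seen = [], [i], set()
        while queue:
            j = queue.pop()
            if j in seen:
                continue
            seen.add(j)
            out.append(self.tokens[j])
            queue.extend(t.index for t in self.children(j))
        return sorted(out, key=lambda t: t.index)
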