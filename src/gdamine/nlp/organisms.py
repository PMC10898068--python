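"""Model-organism mention detection.

A configurable lexicon maps surface forms (mice, zebrafish, Drosophila,
...) to canonical species keys.  A mention is any nominal token (common or
proper noun) whose surface or lemma is in the lexicon; duplicate mentions of
one species within a sentence collapse to the first.
"""

from __future__ import annotations

from dataclasses import dataclass

from .patterns import _load_lexicons
from .tokens import AnalyzedDoc

__all__ = ["OrganismMention", "SpeciesLexicon", "default_species_lexicon", "detect_organisms"]


@dataclass(frozen=True)
class OrganismMention:
    species: str
    token_index: int
    sentence_index: int


class SpeciesLexicon:
    """Maps lower-cased surface forms to canonical species keys."""

    def __init__(self, table: dict[str, list[str]]):
        self.table = dict(table)
        self._surface = {
            form.lower(): key for key, forms in table.items() for form in forms
        }

    def lookup(self, surface_or_lemma: str) -> str | None:
        return self._surface.get(surface_or_lemma.lower())

    @property
    def species_keys(self) -> list[str]:
        return sorted(self.table)


def default_species_lexicon() -> SpeciesLexicon:
    return SpeciesLexicon(_load_lexicons()["species"])


def detect_organisms(
    doc: AnalyzedDoc, lexicon: SpeciesLexicon | None = None
) -> list[OrganismMention]:
    """One mention per species per sentence, in document order."""
    lex = lexicon or default_species_lexicon()
    seen: set[tuple[str, int]] = set()
    out: list[OrganismMention] = []
    for t in doc.tokens:
        if t.pos not in {"NOUN", "PROPN"}:
            continue
        species = lex.lookup(t.text) or lex.lookup(t.lemma)
        if species is None:
            continue
        key = (species, t.sentence_index)
        if key in seen:
            continue
        seen.add(key)
        out.append(OrganismMention(species, t.index, t.sentence_index))
    return out
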