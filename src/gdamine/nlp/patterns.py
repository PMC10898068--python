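"""Dependency patterns for cohort sizes and phenotype-only study exclusion.

Three patterns run over an :class:`~gdamine.nlp.tokens.AnalyzedDoc`:

* **P1** — an anchor noun (patient, family, ...) carrying a direct numeric
  modifier: "variants were identified in *6 unrelated patients*".
* **P2** — the partitive geometry, where the numeral heads a prepositional
  phrase that reaches the anchor: "*three* of the unrelated *patients*".
* **Exclusion** — an adverb–verb–adposition–number chain marking sentences
  that merely re-describe previously reported patients ("was *previously
  reported in 4* patients"); citations in such sentences must not be taken
  as discovery evidence.

Anchor lemmas are configuration (``data/lexicons.yaml``); a declarative
description of the patterns ships as ``data/patterns.json``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources

import yaml

from .numbers import UnparseableNumeralError, normalize_cardinal
from .tokens import AnalyzedDoc, Token

__all__ = [
    "CohortMatch",
    "ExclusionMatch",
    "match_cohort_patterns",
    "match_exclusion_pattern",
    "default_anchor_lemmas",
    "load_pattern_spec",
]


@dataclass(frozen=True)
class CohortMatch:
    anchor_index: int
    count: int | None
    unrelated: bool
    pattern_id: str  # "P1" | "P2"
    sentence_index: int


@dataclass(frozen=True)
class ExclusionMatch:
    span: tuple[int, int]  # token index range, half-open
    sentence_index: int


def _load_lexicons() -> dict:
    with resources.files("gdamine.data").joinpath("lexicons.yaml").open() as fh:
        return yaml.safe_load(fh)


def default_anchor_lemmas() -> frozenset[str]:
    """The shipped anchor-lemma set (nouns that denote studied humans)."""
    return frozenset(_load_lexicons()["anchor_lemmas"])


def load_pattern_spec() -> dict:
    """The declarative JSON description of the shipped patterns."""
    with resources.files("gdamine.data").joinpath("patterns.json").open() as fh:
        return json.load(fh)


def _count_of(token: Token) -> int | None:
    try:
        return normalize_cardinal(token.text)
    except UnparseableNumeralError:
        return None


def match_cohort_patterns(
    doc: AnalyzedDoc, anchor_lemmas: frozenset[str] | None = None
) -> list[CohortMatch]:
    """Run P1 and P2 over an analyzed paragraph.

    Returns at most one match per anchor token; when both geometries fire,
    the direct attachment (P1) wins, and among several numeric modifiers the
    syntactically closest (then leftmost) is used.
    """
    anchors = anchor_lemmas or default_anchor_lemmas()
    out: list[CohortMatch] = []
    for t in doc.tokens:
        if t.pos not in {"NOUN", "PROPN"} or t.lemma.lower() not in anchors:
            continue
        children = doc.children(t.index)
        unrelated = any(c.dep == "amod" and c.lemma == "unrelated" for c in children)

        nummods = [c for c in children if c.dep == "nummod" and c.pos == "NUM"]
        if nummods:
            best = min(nummods, key=lambda c: (abs(c.index - t.index), c.index))
            out.append(CohortMatch(t.index, _count_of(best), unrelated, "P1", t.sentence_index))
            continue

        # P2: anchor is pobj of an ADP whose governor is a NUM in-sentence
        if t.dep == "pobj":
            adp = doc.tokens[t.head]
            gov = doc.tokens[adp.head]
            if (
                adp.pos == "ADP"
                and gov.pos == "NUM"
                and gov.sentence_index == t.sentence_index
            ):
                out.append(
                    CohortMatch(t.index, _count_of(gov), unrelated, "P2", t.sentence_index)
                )
    return out


def match_exclusion_pattern(doc: AnalyzedDoc) -> list[ExclusionMatch]:
    """Find adverb-verb-adposition-number chains (phenotype-only studies)."""
    out: list[ExclusionMatch] = []
    for v in doc.tokens:
        if v.pos != "VERB":
            continue
        children = doc.children(v.index)
        advs = [c for c in children if c.dep == "advmod" and c.pos == "ADV"]
        if not advs:
            continue
        for p in (c for c in children if c.dep == "prep" and c.pos == "ADP"):
            nums = [u for u in doc.subtree(p.index) if u.pos == "NUM"]
            if nums:
                involved = [advs[0], v, p, nums[0]]
                lo = min(t.index for t in involved)
                hi = max(t.index for t in involved) + 1
                out.append(ExclusionMatch((lo, hi), v.sentence_index))
                break
    return out
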