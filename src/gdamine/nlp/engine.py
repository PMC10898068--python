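"""Deterministic rule-based linguistic engine.

The pattern matchers in this package need, for every token: a lemma, a
universal POS tag, a dependency relation and a sentence index.  Engines are
pluggable through the :class:`AnalysisEngine` protocol; the shipped
implementation, :class:`RuleEngine`, is a deterministic cascade built for
curated biomedical narrative (OMIM-style prose):

1. regex tokenization (inline numbered citation marks such as
   ``{5:Smith et al. (2001)}`` are kept as single opaque tokens so they never
   disturb sentence segmentation or attachment),
2. abbreviation-aware sentence splitting,
3. lexicon-driven POS tagging with suffix fallbacks,
4. lemmatization from an exception table plus inflection rules,
5. a shallow chunk-and-attach dependency pass that produces the relations
   the matchers consume: ``det``, ``amod``, ``nummod``, ``compound``,
   ``nsubj``/``dobj``, ``prep``/``pobj``, ``advmod``, ``aux``.

The engine is fully deterministic: the same paragraph always yields the same
analysis, and the engine name/version pair identifies the rule set so fixture
manifests can pin it.
"""

from __future__ import annotations

import re
from typing import Protocol, runtime_checkable

from .numbers import CARDINAL_WORDS
from .tokens import AnalyzedDoc, Token

__all__ = ["AnalysisEngine", "RuleEngine", "get_engine", "EngineUnavailableError"]


class EngineUnavailableError(RuntimeError):
    """Raised when a requested analysis engine cannot be constructed."""


@runtime_checkable
class AnalysisEngine(Protocol):
    """Contract every linguistic engine must satisfy."""

    name: str
    version: str

    def analyze(self, paragraph: str) -> AnalyzedDoc:  # pragma: no cover
        ...


# --------------------------------------------------------------------------
# lexicons
# --------------------------------------------------------------------------

_CITE_RE = r"\{\d+(?:\s*,\s*\d+)*:[^{}]*\}"
_TOKEN_RE = re.compile(
    _CITE_RE
    + r"|\d{1,3}(?:,\d{3})+"        # 1,204
    + r"|\d+(?:\.\d+)?"             # 42, 3.5
    + r"|[A-Za-z][A-Za-z0-9'’\-]*"  # words, gene symbols, twenty-three
    + r"|[().,;:?!\[\]{}%/]"
)
_CITE_FULL = re.compile(_CITE_RE)

_ABBREV = {"al", "et", "dr", "fig", "figs", "st", "vs", "cf", "no", "e.g", "i.e"}

_DET = {
    "a", "an", "the", "this", "these", "those", "its", "their", "his",
    "her", "each", "either", "both", "all", "some", "several", "few",
    "many", "most", "any", "another", "such",
}
_ADP = {
    "in", "of", "on", "at", "by", "from", "with", "within", "among",
    "amongst", "for", "to", "into", "through", "during", "between",
    "after", "before", "over", "under", "without", "as",
}
_PRON = {"he", "she", "it", "they", "we", "i", "you", "them", "him", "us", "who", "which"}
_AUX = {
    "is", "are", "was", "were", "be", "been", "being", "has", "have",
    "had", "can", "could", "may", "might", "will", "would", "should",
    "must", "do", "does", "did",
}
_CCONJ = {"and", "or", "but", "nor"}
_SCONJ = {"that", "because", "although", "while", "whereas", "if", "when"}

_ADV = {
    "previously", "originally", "initially", "subsequently", "later",
    "earlier", "first", "also", "then", "independently", "recently",
    "further", "thus", "moreover", "however", "separately",
    "simultaneously", "already", "only", "not",
}

_ADJ = {
    "unrelated", "affected", "related", "consanguineous", "homozygous",
    "heterozygous", "compound", "novel", "severe", "mild", "pathogenic",
    "causative", "clinical", "functional", "additional", "similar",
    "same", "de", "novo", "genetic", "molecular", "primary", "recessive",
    "dominant", "autosomal", "mitochondrial", "combined", "deficient",
    "knockout", "mutant", "transgenic", "null", "wild-type", "early",
    "late", "new", "unknown", "possible", "neurodevelopmental",
    "biallelic", "truncating", "missense",
}

# verb form -> lemma; covers the reporting verbs of curated genetics prose
_VERB_FORMS: dict[str, str] = {}
for _lemma, _forms in {
    "identify": ["identify", "identifies", "identified", "identifying"],
    "report": ["report", "reports", "reported", "reporting"],
    "describe": ["describe", "describes", "described", "describing"],
    "find": ["find", "finds", "found", "finding"],
    "study": ["study", "studies", "studied", "studying"],
    "observe": ["observe", "observes", "observed", "observing"],
    "note": ["note", "notes", "noted", "noting"],
    "detect": ["detect", "detects", "detected", "detecting"],
    "perform": ["perform", "performs", "performed", "performing"],
    "demonstrate": ["demonstrate", "demonstrates", "demonstrated"],
    "show": ["show", "shows", "showed", "shown"],
    "reveal": ["reveal", "reveals", "revealed"],
    "confirm": ["confirm", "confirms", "confirmed", "confirming"],
    "establish": ["establish", "establishes", "established"],
    "associate": ["associate", "associates", "associated"],
    "implicate": ["implicate", "implicates", "implicated"],
    "carry": ["carry", "carries", "carried", "carrying"],
    "display": ["display", "displays", "displayed"],
    "exhibit": ["exhibit", "exhibits", "exhibited"],
    "review": ["review", "reviews", "reviewed"],
    "lack": ["lack", "lacks", "lacked", "lacking"],
    "cause": ["cause", "causes", "caused", "causing"],
    "map": ["map", "maps", "mapped", "mapping"],
    "discover": ["discover", "discovers", "discovered"],
    "delineate": ["delineate", "delineates", "delineated"],
    "localize": ["localize", "localizes", "localized"],
    "screen": ["screen", "screens", "screened"],
    "present": ["present", "presents", "presented"],
    "involve": ["involve", "involves", "involved"],
    "harbor": ["harbor", "harbors", "harbored"],
    "develop": ["develop", "develops", "developed"],
    "include": ["include", "includes", "included", "including"],
}.items():
    for _f in _forms:
        _VERB_FORMS[_f] = _lemma

# forms that double as common nouns: prefer NOUN after a determiner-ish left
# context ("the first report", "functional studies")
_NOUNISH_VERBS = {
    "study", "studies", "report", "reports", "screen", "map", "cause",
    "find", "display", "review", "present", "lack", "note",
}

_NOUN_IRREG = {
    "mice": "mouse", "children": "child", "women": "woman", "men": "man",
    "people": "people", "feet": "foot", "flies": "fly", "species": "species",
    "analyses": "analysis", "sheep": "sheep", "cattle": "cattle",
    "siblings": "sibling", "fishes": "fish", "progenies": "progeny",
}

_PROPER_SPECIES = {"drosophila", "xenopus"}

# nouns the '-ly' adverb suffix heuristic must not capture
_LY_NOUNS = {
    "family", "families", "fly", "flies", "anomaly", "anomalies",
    "assembly", "assemblies", "supply", "supplies", "reply", "replies",
    "butterfly", "monopoly",
}


def _lemma_noun(lower: str) -> str:
    if lower in _NOUN_IRREG:
        return _NOUN_IRREG[lower]
    if lower.endswith("ies") and len(lower) > 4:
        return lower[:-3] + "y"
    if lower.endswith(("ses", "xes", "zes", "ches", "shes")):
        return lower[:-2]
    if lower.endswith("s") and not lower.endswith(("ss", "us", "is")):
        return lower[:-1]
    return lower


def _lemma_verb(lower: str) -> str:
    if lower in _VERB_FORMS:
        return _VERB_FORMS[lower]
    if lower.endswith("ied"):
        return lower[:-3] + "y"
    if lower.endswith("ed"):
        base = lower[:-2]
        if len(base) > 2 and base[-1] == base[-2]:  # mapped -> map
            return base[:-1]
        return base
    return lower


class RuleEngine:
    """Deterministic lexicon/rule analyzer for OMIM-style prose."""

    name = "rulepipe-en"
    version = "1.0"

    def analyze(self, paragraph: str) -> AnalyzedDoc:
        raw = [(m.group(0), m.start(), m.end()) for m in _TOKEN_RE.finditer(paragraph)]
        raw = self._merge_cardinals(paragraph, raw)
        if not raw:
            return AnalyzedDoc(text=paragraph, tokens=[], sentence_count=0)

        sent_ids = self._split_sentences(raw)
        tokens: list[Token] = []
        for i, ((surface, s, e), sid) in enumerate(zip(raw, sent_ids)):
            tokens.append(
                Token(index=i, text=surface, lemma=surface.lower(), pos="NOUN",
                      dep="dep", head=i, sentence_index=sid, char_span=(s, e))
            )
        self._tag(tokens)
        self._attach(tokens)
        return AnalyzedDoc(text=paragraph, tokens=tokens,
                           sentence_count=sent_ids[-1] + 1 if sent_ids else 0)

    # -- tokenization ------------------------------------------------------

    @staticmethod
    def _merge_cardinals(text: str, raw: list[tuple[str, int, int]]):
        """Merge adjacent cardinal-word tokens ('three hundred five')."""
        out: list[tuple[str, int, int]] = []
        for tok in raw:
            if (
                out
                and tok[0].lower() in CARDINAL_WORDS
                and out[-1][0].split()[-1].lower() in CARDINAL_WORDS
                and text[out[-1][2]:tok[1]].isspace()
            ):
                prev = out.pop()
                out.append((text[prev[1]:tok[2]], prev[1], tok[2]))
            else:
                out.append(tok)
        return out

    @staticmethod
    def _split_sentences(raw: list[tuple[str, int, int]]) -> list[int]:
        ids = []
        sid = 0
        for i, (surface, _s, _e) in enumerate(raw):
            ids.append(sid)
            if surface in {".", "?", "!"}:
                prev = raw[i - 1][0].lower() if i else ""
                nxt = raw[i + 1][0] if i + 1 < len(raw) else None
                if prev in _ABBREV:
                    continue
                if nxt is None or nxt[0].isupper() or nxt[0].isdigit() or nxt.startswith("{"):
                    sid += 1
        return ids

    # -- tagging -----------------------------------------------------------

    def _tag(self, tokens: list[Token]) -> None:
        sent_start = {t.sentence_index: t.index for t in reversed(tokens)}
        for t in tokens:
            lower = t.lower
            first_in_sentence = sent_start[t.sentence_index] == t.index
            prev = tokens[t.index - 1] if t.index else None

            if _CITE_FULL.fullmatch(t.text):
                t.pos, t.lemma = "X", t.text
            elif t.text[0].isdigit():
                t.pos, t.lemma = "NUM", t.text
            elif not t.text[0].isalnum() and len(t.text) == 1:
                t.pos, t.lemma = "PUNCT", t.text
            elif lower != "and" and all(
                w in CARDINAL_WORDS or w == "and" for w in re.split(r"[\s\-–]+", lower)
            ):
                t.pos, t.lemma = "NUM", lower
            elif lower in _DET:
                t.pos, t.lemma = "DET", lower
            elif lower in _ADP:
                t.pos, t.lemma = "ADP", lower
            elif lower in _PRON:
                t.pos, t.lemma = "PRON", lower
            elif lower in _AUX:
                t.pos, t.lemma = "AUX", _lemma_verb(lower) if lower not in {"is", "are", "was", "were", "been", "being"} else "be"
            elif lower in _CCONJ:
                t.pos, t.lemma = "CCONJ", lower
            elif lower in _SCONJ:
                t.pos, t.lemma = "SCONJ", lower
            elif lower in _ADV and not (prev is not None and prev.pos == "DET"):
                t.pos, t.lemma = "ADV", lower
            elif lower in _ADJ:
                t.pos, t.lemma = "ADJ", lower
            elif lower in _VERB_FORMS and not (
                lower in _NOUNISH_VERBS
                and prev is not None
                and prev.pos in {"DET", "ADJ", "NUM", "ADP", "NOUN", "PROPN"}
            ):
                t.pos, t.lemma = "VERB", _lemma_verb(lower)
            elif lower.endswith("ly") and lower not in _LY_NOUNS:
                t.pos, t.lemma = "ADV", lower
            elif lower.endswith("ed"):
                t.pos, t.lemma = "VERB", _lemma_verb(lower)
            elif any(c.isdigit() for c in t.text) or (len(t.text) > 1 and t.text.isupper()):
                t.pos, t.lemma = "PROPN", t.text  # gene symbols / acronyms
            elif t.text[0].isupper() and not first_in_sentence:
                t.pos, t.lemma = "PROPN", t.text
            elif lower in _PROPER_SPECIES:
                t.pos, t.lemma = "PROPN", lower
            else:
                t.pos, t.lemma = "NOUN", _lemma_noun(lower)

    # -- attachment --------------------------------------------------------

    def _attach(self, tokens: list[Token]) -> None:
        n_sent = tokens[-1].sentence_index + 1
        for sid in range(n_sent):
            sent = [t for t in tokens if t.sentence_index == sid]
            if sent:
                self._attach_sentence(sent)

    @staticmethod
    def _attach_sentence(sent: list[Token]) -> None:
        np_member = {"DET", "ADJ", "NUM", "NOUN", "PROPN"}

        # chunk noun phrases; record each chunk's head token
        chunks: list[list[Token]] = []
        cur: list[Token] = []
        for t in sent:
            if t.pos in np_member:
                cur.append(t)
            else:
                if cur:
                    chunks.append(cur)
                cur = []
        if cur:
            chunks.append(cur)

        chunk_heads: list[Token] = []
        for chunk in chunks:
            nominal = [t for t in chunk if t.pos in {"NOUN", "PROPN"}]
            head = nominal[-1] if nominal else chunk[-1]
            chunk_heads.append(head)
            for t in chunk:
                if t is head:
                    continue
                t.head = head.index
                if t.pos == "DET":
                    t.dep = "det"
                elif t.pos == "ADJ":
                    t.dep = "amod"
                elif t.pos == "NUM":
                    t.dep = "nummod" if head.pos in {"NOUN", "PROPN"} else "dep"
                else:
                    t.dep = "compound"

        is_head = {t.index for t in chunk_heads}
        verbs = [t for t in sent if t.pos == "VERB"]
        if verbs:
            root = verbs[0]
        elif any(t.pos == "AUX" for t in sent):
            root = next(t for t in sent if t.pos == "AUX")
        elif chunk_heads:
            root = chunk_heads[0]
        else:
            root = sent[0]
        root.dep, root.head = "ROOT", root.index
        for v in verbs:
            if v is not root:
                v.dep, v.head = "conj", root.index

        for t in sent:
            if t is root or (t.index in is_head and t.dep in {"det", "amod", "nummod", "compound"}):
                continue
            if t.pos == "AUX" and t is not root:
                nxt_verb = next((v for v in verbs if v.index > t.index), root)
                t.dep, t.head = "aux", nxt_verb.index
            elif t.pos == "ADV":
                nxt = next((v for v in verbs if v.index > t.index), None)
                prv = next((v for v in reversed(verbs) if v.index < t.index), None)
                t.dep, t.head = "advmod", (nxt or prv or root).index
            elif t.pos in {"SCONJ", "PART"}:
                t.dep, t.head = "mark", root.index
            elif t.pos == "CCONJ":
                t.dep, t.head = "cc", root.index
            elif t.pos == "PUNCT":
                t.dep, t.head = "punct", root.index

        # prepositions: head = nearest preceding verb or chunk head;
        # object = next chunk head or citation token
        for t in sent:
            if t.pos != "ADP":
                continue
            gov = None
            for u in reversed(sent[: sent.index(t)]):
                if u.pos == "VERB" or u.index in is_head or u.pos == "X":
                    gov = u
                    break
            t.dep, t.head = "prep", (gov or root).index
            for u in sent[sent.index(t) + 1:]:
                if u.pos == "VERB" or u.pos == "ADP":
                    break
                if u.index in is_head or u.pos == "X":
                    if u.dep in {"dep", "meta"} or (u.index in is_head and u.dep == "dep"):
                        u.dep, u.head = "pobj", t.index
                    break

        # remaining chunk heads and pronouns: subject before root, object after
        for t in sent:
            unattached_head = t.index in is_head and t.dep == "dep"
            if (unattached_head or (t.pos == "PRON" and t.dep == "dep")) and t is not root:
                if t.index < root.index:
                    passive = any(
                        u.pos == "AUX" and u.lemma == "be" and u.head == root.index
                        for u in sent
                    )
                    t.dep = "nsubjpass" if passive else "nsubj"
                else:
                    t.dep = "dobj"
                t.head = root.index

        # citation marks default to the sentence root
        for t in sent:
            if t.pos == "X" and t.dep == "dep":
                t.dep, t.head = "meta", root.index


_DEFAULT: RuleEngine | None = None


def get_engine(name: str = "rulepipe-en") -> AnalysisEngine:
    """Return the shared engine instance for ``name``."""
    global _DEFAULT
    if name != RuleEngine.name:
        raise EngineUnavailableError(
            f"unknown analysis engine {name!r}; expected {RuleEngine.name!r}"
        )
    if _DEFAULT is None:
        _DEFAULT = RuleEngine()
    return _DEFAULT
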