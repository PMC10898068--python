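"""Proximity citation selection against a brute-force sentence-scan oracle."""

import random

import pytest

from gdamine.nlp.patterns import ExclusionMatch
from gdamine.nlp.tokens import AnalyzedDoc
from gdamine.omim.citations import CitationMention
from gdamine.omim.models import ReferenceRecord
from gdamine.resolve import (
    earliest_across_sections,
    phenotype_only_references,
    select_citation,
)


def _doc(n_sentences: int) -> AnalyzedDoc:
    return AnalyzedDoc(text="", tokens=[], sentence_count=n_sentences)


def _mention(sentence, *refs):
    return CitationMention(
        ref_numbers=tuple(refs), char_span=(0, 1), sentence_index=sentence, surface="x"
    )


def _refs(years: dict[int, int]):
    return [
        ReferenceRecord(ref_number=n, first_author=f"A{n}", year=y, pubmed_id=n)
        for n, y in years.items()
    ]


def oracle(n_sent, anchor, mentions, blacklist, refs):
    """Independent formulation: walk sentences in proximity order, then
    pick (earliest year, lowest ref number) within the first non-empty one."""
    year = {r.ref_number: r.year for r in refs}
    order = [anchor]
    for d in range(1, n_sent):
        if anchor - d >= 0:
            order.append(anchor - d)
    for d in range(1, n_sent):
        if anchor + d < n_sent:
            order.append(anchor + d)
    for s in order:
        cands = sorted(
            (year[r], r)
            for m in mentions
            if m.sentence_index == s
            for r in m.ref_numbers
            if r not in blacklist and r in year
        )
        if cands:
            return s, cands[0][1]
    return None


class TestSelectCitation:
    def test_same_sentence_beats_everything(self):
        refs = _refs({1: 1990, 2: 2015})
        res = select_citation(
            _doc(3), 1, [_mention(0, 1), _mention(1, 2)], frozenset(), refs
        )
        assert res.tier == "same_sentence" and res.reference.ref_number == 2

    def test_preceding_searched_before_following(self):
        refs = _refs({1: 2010, 2: 1990})
        res = select_citation(
            _doc(5), 2, [_mention(0, 1), _mention(3, 2)], frozenset(), refs
        )
        assert res.tier == "preceding" and res.reference.ref_number == 1

    def test_following_when_nothing_before(self):
        refs = _refs({1: 2010, 2: 1990})
        res = select_citation(
            _doc(5), 0, [_mention(2, 1), _mention(4, 2)], frozenset(), refs
        )
        assert res.tier == "following" and res.reference.ref_number == 1

    def test_year_then_ref_number_tie_break_within_sentence(self):
        refs = _refs({1: 2013, 2: 2013, 3: 2012})
        res = select_citation(_doc(1), 0, [_mention(0, 1, 2, 3)], frozenset(), refs)
        assert res.reference.ref_number == 3
        res = select_citation(_doc(1), 0, [_mention(0, 1, 2)], frozenset(), refs)
        assert res.reference.ref_number == 1  # year tie: lower number

    def test_no_mentions_gives_none(self):
        res = select_citation(_doc(2), 0, [], frozenset(), _refs({1: 2000}))
        assert res.tier == "none" and res.reference is None

    def test_all_blacklisted_gives_none(self):
        res = select_citation(
            _doc(2), 0, [_mention(0, 1)], frozenset({1}), _refs({1: 2000})
        )
        assert res.tier == "none"

    def test_blacklist_never_moves_result_nearer(self):
        rng = random.Random(41)
        refs = _refs({n: rng.randint(1950, 2020) for n in range(1, 6)})
        mentions = [_mention(rng.randrange(5), n) for n in range(1, 6)]
        tier_rank = {"same_sentence": 0, "preceding": 1, "following": 2, "none": 3}
        base = select_citation(_doc(5), 2, mentions, frozenset(), refs)
        for k in range(1, 6):
            bigger = select_citation(_doc(5), 2, mentions, frozenset(range(1, k + 1)), refs)
            assert tier_rank[bigger.tier] >= tier_rank[base.tier]

    def test_agrees_with_brute_force_oracle_on_randomized_paragraphs(self):
        rng = random.Random(20240101)
        for _ in range(1000):
            n_sent = rng.randint(1, 8)
            anchor = rng.randrange(n_sent)
            refs = _refs({n: rng.randint(1950, 2022) for n in range(1, rng.randint(2, 7))})
            nums = [r.ref_number for r in refs]
            mentions = []
            for _ in range(rng.randint(0, 6)):
                chosen = rng.sample(nums, rng.randint(1, min(2, len(nums))))
                mentions.append(_mention(rng.randrange(n_sent), *chosen))
            blacklist = frozenset(n for n in nums if rng.random() < 0.3)
            res = select_citation(_doc(n_sent), anchor, mentions, blacklist, refs)
            expected = oracle(n_sent, anchor, mentions, blacklist, refs)
            if expected is None:
                assert res.tier == "none"
            else:
                sent, ref_num = expected
                assert res.reference.ref_number == ref_num
                assert res.mention.sentence_index == sent


class TestPhenotypeOnlyReferences:
    def test_co_sentential_refs_returned(self):
        mentions = [_mention(2, 1), _mention(4, 2)]
        excl = [ExclusionMatch(span=(0, 4), sentence_index=2)]
        assert phenotype_only_references(_doc(5), mentions, excl) == {1}

    def test_no_exclusions_empty(self):
        assert phenotype_only_references(_doc(3), [_mention(0, 1)], []) == frozenset()


class TestEarliestAcrossSections:
    def _res(self, tier, ref=None):
        from gdamine.resolve import ResolutionResult

        reference = (
            ReferenceRecord(ref_number=ref, first_author="A", year=2000, pubmed_id=ref)
            if ref
            else None
        )
        mention = _mention(0, ref) if ref else None
        return ResolutionResult(mention, reference, tier)

    def test_first_non_none_wins(self):
        none, hit = self._res("none"), self._res("same_sentence", 1)
        assert earliest_across_sections([none, hit]) is hit

    def test_section_priority_dominates_tier(self):
        far, near = self._res("preceding", 1), self._res("same_sentence", 2)
        assert earliest_across_sections([far, near]) is far

    def test_empty_input_gives_none(self):
        assert earliest_across_sections([]).tier == "none"
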