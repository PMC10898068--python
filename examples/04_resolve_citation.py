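"""Proximity-based citation selection with exclusion blacklisting.

Walks a two-sentence paragraph in which an early study (1965) merely
described patients and a later study (2003) made the gene-disease
association.  The early citation shares the anchor sentence, so naive
proximity would pick it; the exclusion pattern blacklists it and the
resolver falls through to the later study.
"""

from gdamine.nlp import get_engine, match_exclusion_pattern
from gdamine.omim import ReferenceRecord, resolve_reference_marks
from gdamine.resolve import phenotype_only_references, select_citation

paragraph = (
    "Coagulation defects associated with KLKB1 were previously reported "
    "in 3 patients by {1:Hathaway et al. (1965)}. In a patient with "
    "prekallikrein deficiency, {2:Lombardi et al. (2003)} identified a "
    "homozygous mutation in the KLKB1 gene."
)
references = [
    ReferenceRecord(ref_number=1, first_author="Hathaway", year=1965, pubmed_id=91000021),
    ReferenceRecord(ref_number=2, first_author="Lombardi", year=2003, pubmed_id=91000022),
]

engine = get_engine()
doc = engine.analyze(paragraph)
mentions = resolve_reference_marks(paragraph, references, doc)
exclusions = match_exclusion_pattern(doc)
blacklist = phenotype_only_references(doc, mentions, exclusions)
print(f"citations found      : {[(m.surface, m.sentence_index) for m in mentions]}")
print(f"blacklisted refs     : {sorted(blacklist)}  (phenotype-only studies)")

anchor_sentence = next(t.sentence_index for t in doc.tokens if t.text == "KLKB1")
result = select_citation(doc, anchor_sentence, mentions, blacklist, references)
print(f"selected             : ref {result.reference.ref_number}, "
      f"{result.reference.first_author} {result.reference.year} (tier={result.tier})")
# Without the blacklist the 1965 study would win on same-sentence
# proximity; with it, the 2003 association-making study is selected.
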