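# Methods

`gdamine` turns curated OMIM-style narrative into structured
gene-disease-association (GDA) discovery records. This note describes the
procedure, the choices behind it, and what the synthetic test corpora do
and do not show about real catalogue text.

## Pipeline overview

For each gene entry the pipeline:

1. **enumerates candidates** from the gene-phenotype relationships table
   (one candidate per row, with the mapping key and label markers);
2. **filters** them into confirmed / provisional / rejected streams;
3. for each surviving association, **extracts** the discovery
   publication, cohort metadata and model-organism evidence from the
   narrative sections of the phenotype and gene entries;
4. **aggregates** records into trend tables and benchmark-concordance
   reports.

### Filtration ladder

A candidate is **rejected** when its mapping key is not 3 (molecular basis
not known), when its label carries a non-disease `[...]` or susceptibility
`{...}` wrapper, when it contains the word "susceptibility" or "modifier"
(matched case-insensitively as whole words), or when it has no phenotype
MIM number — without a phenotype entry there is no narrative to mine, so
such rows can never be confirmed; they are kept in the rejected stream so
the three streams always partition the input. Key-3 survivors whose label
begins with `?` are **provisional** (typically single-patient evidence)
and are tracked as their own stream rather than discarded, because trend
analyses plot them separately; the rest are **confirmed**.

## The linguistic engine

Pattern matching needs lemmas, universal POS tags, dependency relations
and sentence boundaries. The engine contract is pluggable
(`gdamine.nlp.AnalysisEngine`); the shipped implementation,
`RuleEngine` ("rulepipe-en" 1.0), is a deterministic cascade written for
curated biomedical narrative:

* **Tokenization** by regex. Inline numbered citation marks
  (`{5:Smith et al. (2001)}`) are kept as single opaque tokens so their
  internal punctuation can never split a sentence or disturb attachment.
  Adjacent cardinal words merge into one numeral token
  ("three hundred five").
* **Sentence splitting** at `.?!` with an abbreviation guard
  (et al., e.g., Fig., ...).
* **POS tagging** from closed-class lexicons (determiners, adpositions,
  auxiliaries, reporting verbs of genetics prose) with suffix fallbacks
  (`-ly` → adverb, with a noun exception list so "family" and "flies"
  stay nominal; `-ed` → verb). All-caps alphanumeric tokens (gene
  symbols) tag as proper nouns.
* **Dependency attachment** by noun-phrase chunking plus a shallow
  attach pass producing exactly the relations the matchers consume:
  `det`, `amod`, `nummod`, `compound`, `nsubj(pass)`, `dobj`,
  `prep`/`pobj`, `advmod`, `aux`.

The engine is pinned by name/version in every fixture manifest: POS and
dependency output is rule-set-dependent, so tests and generated corpora
record which engine produced them. It is a purpose-built rule engine, not
a general parser: it covers the sentence geometries of curated catalogue
prose and the fixture grammars, and the generator's verification loop
(below) makes that coverage explicit rather than assumed.

## Patterns

* **P1** — an anchor noun with a direct numeric modifier
  ("variants in **6** unrelated **patients**"). When several numerals
  attach to one anchor, the syntactically closest wins, ties to the left.
* **P2** — the partitive geometry: the numeral heads a prepositional
  phrase whose object is the anchor ("**three** of the unrelated
  **patients**").
* **Unrelatedness** — an adjectival modifier of the anchor lemmatizing to
  "unrelated".
* **Exclusion** — an adverb-verb-adposition-number chain over dependency
  links ("was **previously reported in 4** patients"). It is purely
  POS-structural; no verb-lemma constraint is imposed, so "described",
  "observed", "noted" all trigger it. Any sentence carrying an exclusion
  match contributes no cohort match downstream, and its citations are
  blacklisted as phenotype-only studies.
* **Organisms** — nominal tokens (common or proper noun) whose surface or
  lemma is in the species lexicon, collapsed to one mention per species
  per sentence.

The **anchor lemma set** (configuration, `data/lexicons.yaml`) contains
family, patient, child, boy, girl, parent, individual, people, infant,
woman, man — plus **sibling** and **proband**, because curated text
routinely counts cohorts with those nouns ("found the variant in two
siblings"). The **species lexicon** ships 14 canonical keys (mouse,
zebrafish, drosophila, worm, yeast, rat, xenopus, rabbit, pig, sheep,
cattle, chicken, dog, monkey) with their surface forms; both lists are
data, not code, and can be replaced per run. Cardinal numerals are
normalized from digits (with thousands separators) or English number
words up to 999; an unparseable numeral yields a match with the count
absent rather than an error.

## Citation handling

Two dialects are recognized: brace-numbered marks (canonical; resolved by
reference number, multi-reference marks expand to one candidate per
number) and surface author-year citations (resolved by first-author +
year; unresolvable ones are flagged, never fatal).

The **proximity resolver** ranks candidate citations per sentence:
the anchor sentence first, then preceding sentences nearest-first, then
following sentences nearest-first to the paragraph end. Within the first
sentence that holds any non-blacklisted citation, the earliest publication
year wins; year ties break to the smaller reference number. This makes
proximity the coarse key and year the fine key, and it makes simultaneous
same-year discoveries resolve deterministically (the lower-numbered
reference) — enlarging the blacklist can only push the result farther,
never nearer. Search never crosses a paragraph boundary.

When several source sections are searched, section priority dominates
proximity tier: the first section (in the configured order) that resolves
anything wins. Discovery and cohort use the phenotype entry's
molecularGenetics first, then the gene entry's allelicVariants; organisms
use the phenotype entry's animalModel first, then the same fallbacks.
Missing sections degrade to absent fields with the miss noted in the
record's provenance.

`cohort_same_study` compares the PubMed IDs of the cohort and discovery
resolutions (falling back to reference-number equality only when both
resolved inside the same entry) — the two resolutions may live in
different entries, where reference numbers are not comparable.

The cohort field reports the **earliest cohort-bearing study** among the
surviving matches, which may differ from the discovery study; when no
cohort citation resolves, the first match still supplies the count with
the publication fields absent.

## Fetching and quota

The entry client caches raw API responses on disk (cache hits are free)
and persists the remaining daily request budget (default 250) in a JSON
sidecar keyed by UTC date, raising a quota error instead of issuing a
request once the budget is spent — a multi-day harvest resumes where it
stopped. The HTTP transport is an injectable `url -> bytes` callable, so
the client is fully testable offline.

## Synthetic corpora

The fixture generator emulates the statistical structure of a curated GDA
catalogue: small cohorts dominate (default bin mix 0.35 / 0.45 / 0.12 /
0.06 / 0.02 over 1, 2–5, 6–10, 11–100, >100, mirroring the reporting
granularity of cohort-size analyses), the mouse is the most common model
organism (0.55, then zebrafish 0.20), most discovery citations sit in the
anchor sentence (tier mix 0.6 / 0.25 / 0.15), 15% of associations are
provisional, and 20% of entries carry an **exclusion decoy**: an earlier
phenotype-describing citation placed in the anchor sentence itself, the
exact configuration in which a purely proximity-driven resolver would
pick the wrong study.

Every realized sentence is re-analyzed with the pinned engine and
verified to parse to its intended pattern (the planned cohort match,
exclusion firing only on the decoy sentence, the planted organism, the
planned anchor and citation sentence indices); a sentence that fails
verification is re-realized from an alternative template, and the
resample count is recorded in the corpus manifest. Verification is
sentence-level only: the end-to-end behaviours — blacklisting, tier
selection, earliest-study choice, section priority — are *not* used
during generation, so corpus-scale recovery tests exercise them
genuinely. Generation is byte-deterministic for a fixed spec.

What passing on these corpora does **not** show: robustness to the full
heterogeneity of decades of human curation (free-form delineation
histories, legacy phenotype entries not yet split by gene, in-vitro/iPSC
evidence, citation styles outside the two dialects). Those are the known
failure modes of rule-based extraction on real catalogue text, and the
synthetic grammars deliberately do not imitate them.

Four hand-written worked fixtures complement the generator, each
reproducing one documented behaviour: a five-citation paragraph whose
co-sentential citation must win; a two-sibling 2012 discovery with yeast
evidence; an early phenotype-describing study that must be skipped in
favour of the 2003 association-maker; and two simultaneous 2013 studies
that must resolve deterministically. Their text and PubMed IDs are
synthetic stand-ins mirroring the structure, not the licensed content, of
the corresponding real entries.

## Problem sizes and checks

The test suite and the acceptance script use: a 500-candidate planted
catalog for the filtration ladder; the full generated sentence banks
(112 in-grammar, 12 adversarial) for pattern recall/precision; 1,000
randomized paragraphs against a brute-force sentence-scan oracle for the
proximity resolver; a 200-entry generated corpus for end-to-end recovery
and decoy avoidance; all 999 word cardinals against an independent
constructive speller; and 1,000 randomized trials comparing every trend
and benchmark aggregation with brute-force recomputation. All
aggregations are exact integer arithmetic; the only tolerances in the
package are none — equality is asserted everywhere.

## Known limitations

* The rule engine's grammar coverage is curated-prose-deep, not
  English-wide; out-of-grammar sentences degrade to absent fields, never
  to crashes.
* Only the earliest publication of simultaneous discoveries is reported.
* Phenotypic-series and legacy unsplit phenotype entries are processed
  as-is, with no splitting heuristic.
* Cross-paragraph citation search and PubMed year validation are out of
  scope by design.
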