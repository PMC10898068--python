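# gdamine

Rule-based mining of **gene-disease-association (GDA) discovery
metadata** from OMIM-style narrative entries.

Curated Mendelian-disease catalogues record *when* a gene was first
associated with a phenotype, *how many* unrelated individuals or families
the discovery study examined, and *which model organisms* supplied
supporting evidence — but they record it in free prose, not queryable
fields. `gdamine` extracts those fields syntactically: it enumerates
gene-phenotype candidates from the phenotype map, filters them by mapping
key and label markers, runs dependency patterns over the narrative
sections, and resolves each finding to the publication that evidences it.

It is a library first (with `examples/` walking through each capability)
plus a thin `gdamine` command-line layer for batch runs.

## The method in brief

* **Filtration.** A candidate survives only with mapping key 3 (molecular
  basis known) and a clean label; `[...]` non-disease, `{...}`/
  "susceptibility", and "modifier" markers reject it, and a leading `?`
  routes it to a separate *provisional* stream (single-patient evidence).
* **Patterns.** Over tokens with lemma/POS/dependency structure
  (deterministic rule engine, pluggable contract):
  * **P1** — numeric modifier directly on a cohort anchor noun
    ("… in **6 unrelated patients**");
  * **P2** — partitive numeral reaching the anchor
    ("**Three of** the unrelated **patients** …");
  * **exclusion** — an adverb-verb-adposition-number chain
    ("was **previously reported in 4** patients") marking sentences that
    merely re-describe known patients: their cohort matches are dropped
    and their citations blacklisted;
  * **organisms** — nominal mentions from a 14-species lexicon.
* **Citation proximity.** A match is evidenced by the citation in its own
  sentence, else the nearest preceding, else the nearest following
  sentence; within the first sentence holding any non-blacklisted
  citation, the earliest year wins, ties to the lower reference number.
  Sections are searched in priority order (phenotype molecularGenetics,
  then gene allelicVariants; animalModel first for organisms), and
  section priority dominates proximity tier.

The result is one `GdaDiscoveryRecord` per association: discovery year +
PubMed ID, cohort count/unrelatedness (and whether the cohort study *is*
the discovery study), organisms with their evidence years, provenance per
field, and the confirmed/provisional stream tag. Aggregations turn record
sets into yearly discovery counts per stream, cohort-size histograms
(default bins 1, 2–5, 6–10, 11–100, >100) with the small-cohort share,
organism shares over a year window, and PubMed-ID concordance against a
benchmark table.

## Worked example

```bash
python examples/05_extract_record.py
```

```text
association         : gene 603136 -> phenotype 619239
discovery           : 2019 (PMID 91000002)
cohort              : 6 (unrelated), same study as discovery: True
organisms           : none
discovery provenance: {'entry': 619239, 'section': 'molecularGenetics', 'sentence': 2, 'tier': 'same_sentence', 'ref_number': 2}
```

The fixture paragraph holds five citations; the 2019 study is selected
because it is the only one sharing a sentence with the gene anchor, and
the same sentence's "6 unrelated patients" supplies the cohort — from the
same study, hence `same study: True`. The other examples cover parsing
(`01`), filtration (`02`), the patterns (`03`), exclusion-aware citation
resolution (`04`), and corpus-scale trends (`06`).

Batch use mirrors the library:

```bash
gdamine fixtures --out corpus/                      # synthetic corpus + truth
gdamine extract  --entries corpus/ --out records.jsonl
gdamine trends   --records records.jsonl --out tables/
gdamine benchmark --records records.jsonl --truth benchmark.csv --report report.json
```

Live fetching (`gdamine extract --mims mims.txt --config cfg.yaml`) needs
an API key; responses are cached and a persisted daily request budget
(default 250) lets multi-day harvests resume safely.

## Layout

```
src/gdamine/
  omim/        entry parsing, citation marks, quota-aware cached client
  nlp/         rule engine, cohort/exclusion patterns, organisms, numerals
  filters.py   candidate enumeration + filtration ladder
  resolve.py   proximity-based citation selection
  extract.py   per-association workflow and batch driver
  fixtures/    synthetic corpus generator + worked-example entries
  trends.py    trend tables and benchmark concordance
  cli.py       thin command-line layer
docs/methods.md       model, parameters, design choices, limitations
docs/omim_dialect.md  annotated entry-JSON fixture and benchmark CSV schema
```
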