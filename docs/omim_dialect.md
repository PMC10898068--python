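# The entry JSON dialect

`gdamine.omim.parse_entry` reads the OMIM API JSON dialect. The annotated
fixture below shows every field the parser consumes; unknown fields are
ignored, unknown *section names* are preserved verbatim.

```jsonc
{
  "omim": {
    "entryList": [                      // exactly one entry per document
      {
        "entry": {
          "mimNumber": 603136,          // required, 6 digits
          "prefix": "*",                // one of  # * + % ^  or absent
                                        // ('^' = moved/removed: parsed but inactive)
          "titles": {
            // gene symbols follow the long name after ';'
            "preferredTitle": "CULLIN 3; CUL3"
          },
          "textSectionList": [
            {
              "textSection": {
                "textSectionName": "molecularGenetics",
                // paragraphs are separated by blank lines
                "textSectionContent": "First paragraph.\n\nSecond paragraph."
              }
            }
          ],
          "referenceList": [
            {
              "reference": {
                "referenceNumber": 1,   // unique within the entry, >= 1
                "authors": "Thiffault, I., Smith, J.",  // first author used
                "pubDate": "2019",      // any string containing a 4-digit year
                "pubmedID": 91000002    // optional
              }
            }
          ],
          "geneMap": {                  // gene entries only; may be absent
            "phenotypeMapList": [
              {
                "phenotypeMap": {
                  "phenotypeMimNumber": 619239,   // may be absent
                  "phenotype": "?Some disorder",  // label with markers as printed
                  "phenotypeMappingKey": 3,       // 1..4
                  "phenotypeInheritance": "Autosomal dominant"
                }
              }
            ]
          }
        }
      }
    ]
  }
}
```

Inline citations inside `textSectionContent` use brace-numbered marks,
`{5:Thiffault et al. (2019)}`, resolved against `referenceList` by
number; plain surface citations, `Thiffault et al. (2019)`, resolve by
first author + year. `emit_entry` writes this same dialect back
(round-trip safe).

The benchmark CSV consumed by `gdamine benchmark` and
`gdamine.trends.compare_to_benchmark` has the header
`gene_mim,phenotype_mim,pmid` with one row per association; duplicate
`(gene_mim, phenotype_mim)` keys are rejected.
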