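{
  "engine": {"name": "rulepipe-en", "version": "1.0"},
  "patterns": [
    {
      "id": "P1",
      "purpose": "cohort size, direct attachment",
      "anchor": {"pos": ["NOUN"], "lemma_set": "anchor_lemmas"},
      "elements": [
        {"role": "count", "pos": "NUM", "dep": "nummod", "head": "anchor"},
        {"role": "unrelated", "pos": "ADJ", "dep": "amod", "lemma": "unrelated",
         "head": "anchor", "optional": true}
      ]
    },
    {
      "id": "P2",
      "purpose": "cohort size, partitive attachment ('N of the ... <anchor>')",
      "anchor": {"pos": ["NOUN"], "lemma_set": "anchor_lemmas", "dep": "pobj"},
      "elements": [
        {"role": "link", "pos": "ADP", "dep": "prep", "child": "anchor"},
        {"role": "count", "pos": "NUM", "head_of": "link"},
        {"role": "unrelated", "pos": "ADJ", "dep": "amod", "lemma": "unrelated",
         "head": "anchor", "optional": true}
      ]
    },
    {
      "id": "EXCLUSION",
      "purpose": "phenotype-only describing study (adverb-verb-adposition-number)",
      "anchor": {"pos": ["VERB"]},
      "elements": [
        {"role": "adverb", "pos": "ADV", "dep": "advmod", "head": "anchor"},
        {"role": "adposition", "pos": "ADP", "dep": "prep", "head": "anchor"},
        {"role": "number", "pos": "NUM", "within_subtree_of": "adposition"}
      ]
    }
  ]
}
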