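# Anchor lemmas for cohort patterns and the model-organism lexicon.
# Both are configuration: edit or pass an alternative file to the matchers.
#
# The anchor set covers the nouns OMIM curators use for studied humans;
# "sibling" and "proband" are included because curated text frequently
# counts cohorts with them.
anchor_lemmas:
  - family
  - patient
  - child
  - boy
  - girl
  - parent
  - individual
  - people
  - infant
  - woman
  - man
  - sibling
  - proband

# canonical species key -> surface forms (lower-cased; matched against the
# token surface or lemma when the token is a common or proper noun)
species:
  mouse: [mouse, mice, murine]
  zebrafish: [zebrafish]
  drosophila: [drosophila, fly, flies]
  worm: [worm, worms, elegans]
  yeast: [yeast]
  rat: [rat, rats]
  xenopus: [xenopus, frog, frogs]
  rabbit: [rabbit, rabbits]
  pig: [pig, pigs, porcine]
  sheep: [sheep]
  cattle: [cattle, cow, cows, bull, bulls]
  chicken: [chicken, chickens]
  dog: [dog, dogs, canine]
  monkey: [monkey, monkeys, macaque]
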