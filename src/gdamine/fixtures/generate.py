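"""Seeded generator of synthetic entry corpora with planted ground truth.

Every generated gene/phenotype entry pair realizes its cohort, exclusion
and organism sentences from the same grammars the pattern matchers are
built for, places the discovery citation according to a configurable
proximity-tier mix, and records the intended values in a
:class:`GroundTruth` row.  A generation-then-verification loop analyses
each produced sentence with the pinned engine and re-realizes it from an
alternative template if it does not parse to the intended pattern, so the
truth table holds unconditionally; the resample count is recorded in the
corpus manifest.

Decoy entries plant an earlier phenotype-describing citation in the anchor
sentence itself — the configuration in which a purely proximity-driven
resolver would pick the wrong study — so downstream exclusion handling is
genuinely exercised.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field as dc_field
from typing import Any, Optional

from pydantic import BaseModel, Field, model_validator

from ..nlp.engine import AnalysisEngine, get_engine
from ..nlp.organisms import default_species_lexicon, detect_organisms
from ..nlp.patterns import (
    default_anchor_lemmas,
    match_cohort_patterns,
    match_exclusion_pattern,
)

__all__ = [
    "FixtureSpec",
    "GroundTruth",
    "CorpusFixture",
    "FixtureGenerationError",
    "generate_corpus",
    "generate_candidate_catalog",
    "pattern_sentence_bank",
    "adversarial_sentence_bank",
]

COHORT_BINS = ("1", "2-5", "6-10", "11-100", ">100")
_BIN_RANGES = {"1": (1, 1), "2-5": (2, 5), "6-10": (6, 10), "11-100": (11, 100), ">100": (101, 400)}

TIERS = ("same_sentence", "preceding", "following")


class FixtureGenerationError(RuntimeError):
    pass


class FixtureSpec(BaseModel):
    """Study conditions for one synthetic corpus.

    Defaults emulate the statistical structure of curated gene-disease
    catalogues: small cohorts dominate, the mouse is the most common model
    organism, and most discovery citations sit in the anchor sentence.
    """

    seed: int = 7
    n_entries: int = Field(default=200, ge=1)
    cohort_count_distribution: dict[str, float] = Field(
        default_factory=lambda: {
            "1": 0.35, "2-5": 0.45, "6-10": 0.12, "11-100": 0.06, ">100": 0.02
        }
    )
    organism_mix: dict[str, float] = Field(
        default_factory=lambda: {
            "mouse": 0.55, "zebrafish": 0.20, "drosophila": 0.08, "worm": 0.05,
            "yeast": 0.04, "rat": 0.03, "xenopus": 0.02, "dog": 0.01,
            "cattle": 0.01, "chicken": 0.01,
        }
    )
    fraction_with_exclusion_decoy: float = Field(default=0.2, ge=0.0, le=1.0)
    fraction_provisional: float = Field(default=0.15, ge=0.0, le=1.0)
    fraction_cohort_same_study: float = Field(default=0.5, ge=0.0, le=1.0)
    citation_tier_mix: dict[str, float] = Field(
        default_factory=lambda: {"same_sentence": 0.6, "preceding": 0.25, "following": 0.15}
    )

    @model_validator(mode="after")
    def _mixes_sum_to_one(self) -> "FixtureSpec":
        for name, mix, keys in (
            ("cohort_count_distribution", self.cohort_count_distribution, COHORT_BINS),
            ("citation_tier_mix", self.citation_tier_mix, TIERS),
            ("organism_mix", self.organism_mix, None),
        ):
            if keys is not None and set(mix) - set(keys):
                raise ValueError(f"{name}: unknown keys {set(mix) - set(keys)}")
            if any(not 0.0 <= v <= 1.0 for v in mix.values()):
                raise ValueError(f"{name}: proportions must lie in [0, 1]")
            if abs(sum(mix.values()) - 1.0) > 1e-9:
                raise ValueError(f"{name}: proportions must sum to 1")
        return self


class GroundTruth(BaseModel):
    """Planted expected values for one generated association."""

    gene_mim: int
    phenotype_mim: int
    gene_symbol: str
    stream: str  # confirmed | provisional
    tier: str
    decoy: bool
    discovery_year: int
    discovery_pmid: int
    decoy_pmid: Optional[int] = None
    cohort_count: int
    cohort_unrelated: bool
    cohort_same_study: bool
    organisms: list[tuple[str, int]] = Field(default_factory=list)


@dataclass
class CorpusFixture:
    entries: list[dict[str, Any]]
    truth: list[GroundTruth]
    manifest: dict[str, Any] = dc_field(default_factory=dict)


# -- sentence realization ---------------------------------------------------

_NOUNS = {  # anchor lemma -> plural surface
    "patient": "patients", "family": "families", "individual": "individuals",
    "child": "children", "sibling": "siblings", "proband": "probands",
}
_NOUNS_SG = {"patient": "patient", "family": "family", "individual": "individual",
             "child": "child", "sibling": "sibling", "proband": "proband"}

_SPECIES_SURFACE = {
    "mouse": "mice", "zebrafish": "zebrafish", "drosophila": "Drosophila",
    "worm": "worms", "yeast": "yeast", "rat": "rats", "xenopus": "Xenopus",
    "rabbit": "rabbits", "pig": "pigs", "sheep": "sheep", "cattle": "cattle",
    "chicken": "chickens", "dog": "dogs", "monkey": "monkeys",
}

_SURNAMES = (
    "Almeida", "Baker", "Chen", "Dubois", "Eriksen", "Fujita", "Garcia",
    "Hoffmann", "Ivanov", "Jansen", "Kumar", "Larsen", "Moreau", "Nakata",
    "Okafor", "Petrov", "Quinn", "Rossi", "Sato", "Tanaka", "Ueda",
    "Varga", "Weber", "Xu", "Yamada", "Zhou",
)

_WORD_NUMBERS = {
    1: "one", 2: "two", 3: "three", 4: "four", 5: "five", 6: "six",
    7: "seven", 8: "eight", 9: "nine", 10: "ten", 11: "eleven", 12: "twelve",
}

_FILLERS = (
    "The encoded protein is highly conserved across vertebrates.",
    "Expression analysis revealed broad tissue distribution.",
    "The gene product participates in an essential signaling pathway.",
)


def _cite(ref_num: int, author: str, year: int) -> str:
    return f"{{{ref_num}:{author} et al. ({year})}}"


def _numeral(rng: random.Random, n: int) -> str:
    if n in _WORD_NUMBERS and rng.random() < 0.5:
        return _WORD_NUMBERS[n]
    return f"{n:,}" if n >= 1000 else str(n)


def _discovery_sentences(variant, tier, symbol, cite):
    """Return the discovery block as a list of sentences, plus the index
    (within the block) of the anchor sentence."""
    anchor_with_cite = [
        f"Using exome sequencing, {cite} identified heterozygous variants in the {symbol} gene.",
        f"{cite} identified biallelic variants in the {symbol} gene.",
        f"Pathogenic variants in the {symbol} gene were identified by {cite}.",
    ]
    anchor_plain = [
        f"Variants in the {symbol} gene segregate with the disorder.",
        f"Molecular analysis implicated the {symbol} gene in this disorder.",
    ]
    cite_plain = [
        f"The causative variants were identified by {cite}.",
        f"{cite} described the molecular findings.",
    ]
    if tier == "same_sentence":
        return [anchor_with_cite[variant % len(anchor_with_cite)]], 0
    if tier == "preceding":
        return [cite_plain[variant % len(cite_plain)],
                anchor_plain[variant % len(anchor_plain)]], 1
    return [anchor_plain[variant % len(anchor_plain)],
            cite_plain[variant % len(cite_plain)]], 0


def _decoy_sentence(variant, symbol, count_surface, noun_pl, cite):
    forms = [
        f"A disorder associated with {symbol} was previously reported in "
        f"{count_surface} {noun_pl} by {cite}.",
        f"The phenotype linked to {symbol} was originally described in "
        f"{count_surface} {noun_pl} by {cite}.",
    ]
    return forms[variant % len(forms)]


def _cohort_sentence(variant, pattern, count_surface, noun_pl, unrelated, cite):
    adj = "unrelated " if unrelated else "affected "
    if pattern == "P1":
        forms = [
            f"Causative variants were found in {count_surface} {adj}{noun_pl} {cite}.",
            f"Disease variants were detected in {count_surface} {adj}{noun_pl} {cite}.",
        ]
    else:  # P2: partitive geometry
        cap = count_surface[0].upper() + count_surface[1:]
        forms = [
            f"{cap} of the {adj}{noun_pl} carried biallelic variants {cite}.",
            f"{cap} of the {adj}{noun_pl} harbored the recurrent variant {cite}.",
        ]
    return forms[variant % len(forms)]


def _organism_sentence(variant, species, cite):
    surface = _SPECIES_SURFACE[species]
    cap = surface[0].upper() + surface[1:]
    if species in {"zebrafish", "xenopus"}:
        forms = [
            f"Morpholino knockdown of the ortholog in {surface} embryos reproduced the phenotype {cite}.",
            f"Mutant {surface} embryos displayed the corresponding phenotype {cite}.",
        ]
    elif species == "yeast":
        forms = [
            f"Complementation assays in yeast demonstrated a conserved function {cite}.",
            f"Functional studies in yeast confirmed the deleterious effect {cite}.",
        ]
    else:
        forms = [
            f"{cap} lacking the ortholog displayed a similar phenotype {cite}.",
            f"Targeted disruption of the ortholog in {surface} reproduced the disease phenotype {cite}.",
        ]
    return forms[variant % len(forms)]


# -- verification -----------------------------------------------------------

def _verify_entry(engine, anchors, lexicon, mg_plan, am_plan) -> bool:
    """Check that the realized paragraphs parse to the planned patterns."""
    doc = engine.analyze(mg_plan["paragraph"])
    if doc.sentence_count != mg_plan["n_sentences"]:
        return False
    cohort = [m for m in match_cohort_patterns(doc, anchors)
              if m.sentence_index == mg_plan["cohort_sentence"]]
    if len(cohort) != 1:
        return False
    m = cohort[0]
    if (m.count, m.unrelated, m.pattern_id) != (
        mg_plan["count"], mg_plan["unrelated"], mg_plan["pattern"]
    ):
        return False
    excl = {e.sentence_index for e in match_exclusion_pattern(doc)}
    if mg_plan["decoy"]:
        if excl != {0}:
            return False
    elif excl:
        return False
    # stray cohort matches outside the planned sentences break the truth
    stray = [m for m in match_cohort_patterns(doc, anchors)
             if m.sentence_index not in {mg_plan["cohort_sentence"], 0 if mg_plan["decoy"] else -1}]
    if stray:
        return False
    if not any(t.text == mg_plan["symbol"] for t in doc.tokens):
        return False
    anchor_tok = next(t for t in doc.tokens if t.text == mg_plan["symbol"])
    if anchor_tok.sentence_index != mg_plan["anchor_sentence"]:
        return False
    if detect_organisms(doc, lexicon):
        return False

    am_doc = engine.analyze(am_plan["paragraph"])
    orgs = detect_organisms(am_doc, lexicon)
    if {o.species for o in orgs} != {am_plan["species"]}:
        return False
    if match_exclusion_pattern(am_doc) or match_cohort_patterns(am_doc, anchors):
        return False
    return True


# -- generator --------------------------------------------------------------

def _weighted(rng: random.Random, mix: dict[str, float]) -> str:
    items = sorted(mix.items())
    return rng.choices([k for k, _ in items], weights=[w for _, w in items], k=1)[0]


def generate_corpus(
    spec: FixtureSpec, engine: AnalysisEngine | None = None
) -> CorpusFixture:
    """Generate a corpus of gene/phenotype entry pairs plus its truth table.

    Deterministic for a fixed spec (including the seed): two calls return
    byte-identical corpora.
    """
    engine = engine or get_engine()
    anchors = default_anchor_lemmas()
    lexicon = default_species_lexicon()
    rng = random.Random(spec.seed)

    entries: list[dict] = []
    truths: list[GroundTruth] = []
    resampled = 0
    pmid_counter = 10_000_000

    for i in range(spec.n_entries):
        gene_mim = 600000 + 3 * i
        phen_mim = gene_mim + 1
        symbol = f"GX{i:04d}"
        provisional = rng.random() < spec.fraction_provisional
        decoy = rng.random() < spec.fraction_with_exclusion_decoy
        tier = "following" if decoy else _weighted(rng, spec.citation_tier_mix)
        cbin = _weighted(rng, spec.cohort_count_distribution)
        lo, hi = _BIN_RANGES[cbin]
        count = rng.randint(lo, hi)
        unrelated = count > 1 and rng.random() < 0.8
        noun = rng.choice(sorted(_NOUNS))
        noun_pl = _NOUNS[noun] if count != 1 else _NOUNS_SG[noun]
        # the partitive geometry only reads naturally for plural cohorts
        pattern = rng.choice(("P1", "P2")) if count > 1 else "P1"
        same_study = rng.random() < spec.fraction_cohort_same_study
        species = _weighted(rng, spec.organism_mix)

        discovery_year = rng.randint(1990, 2021)
        cohort_year = discovery_year if same_study else rng.randint(discovery_year, 2022)
        organism_year = rng.randint(discovery_year, 2022)
        decoy_year = max(1850, discovery_year - rng.randint(3, 15))

        refs: list[tuple[int, str, int, int]] = []

        def new_ref(year: int) -> tuple[int, str, int]:
            nonlocal pmid_counter
            pmid_counter += 1
            num = len(refs) + 1
            author = _SURNAMES[(pmid_counter + num) % len(_SURNAMES)]
            refs.append((num, author, year, pmid_counter))
            return num, author, year

        decoy_ref = new_ref(decoy_year) if decoy else None
        disc_ref = new_ref(discovery_year)
        cohort_ref = disc_ref if same_study else new_ref(cohort_year)
        org_ref = new_ref(organism_year)

        for attempt in range(20):
            variant = attempt  # advance through template variants on resample
            block, anchor_in_block = _discovery_sentences(
                variant, tier, symbol, _cite(*disc_ref)
            )
            sentences: list[str] = []
            if decoy:
                sentences.append(
                    _decoy_sentence(
                        variant, symbol, _numeral(rng, rng.randint(2, 9)),
                        "patients", _cite(*decoy_ref),
                    )
                )
                # decoy owns the anchor; discovery block supplies only the
                # true citation sentence(s)
                block = [s for j, s in enumerate(block) if j != anchor_in_block]
                anchor_sentence = 0
                sentences.extend(block)
            else:
                anchor_sentence = len(sentences) + anchor_in_block
                sentences.extend(block)
            cohort_sentence = len(sentences)
            sentences.append(
                _cohort_sentence(
                    variant, pattern, _numeral(rng, count), noun_pl,
                    unrelated, _cite(*cohort_ref),
                )
            )
            if rng.random() < 0.4:
                sentences.append(rng.choice(_FILLERS))
            mg_paragraph = " ".join(sentences)

            am_paragraph = _organism_sentence(variant, species, _cite(*org_ref))

            mg_plan = {
                "paragraph": mg_paragraph,
                "n_sentences": len(sentences),
                "cohort_sentence": cohort_sentence,
                "count": count,
                "unrelated": unrelated,
                "pattern": pattern,
                "decoy": decoy,
                "symbol": symbol,
                "anchor_sentence": anchor_sentence,
            }
            am_plan = {"paragraph": am_paragraph, "species": species}
            if _verify_entry(engine, anchors, lexicon, mg_plan, am_plan):
                break
            resampled += 1
        else:
            raise FixtureGenerationError(
                f"entry {i}: no template variant parsed to the planned patterns"
            )

        label = ("?" if provisional else "") + f"Syndromic disorder {i + 1}"
        gene_raw = {
            "mimNumber": gene_mim,
            "prefix": "*",
            "titles": {"preferredTitle": f"SYNTHETIC GENE {i + 1}; {symbol}"},
            "textSectionList": [],
            "referenceList": [],
            "geneMap": {
                "phenotypeMapList": [
                    {
                        "phenotypeMap": {
                            "phenotypeMimNumber": phen_mim,
                            "phenotype": label,
                            "phenotypeMappingKey": 3,
                            "phenotypeInheritance": "Autosomal recessive",
                        }
                    }
                ]
            },
        }
        phen_raw = {
            "mimNumber": phen_mim,
            "prefix": "#",
            "titles": {"preferredTitle": label.upper().lstrip("?")},
            "textSectionList": [
                {
                    "textSection": {
                        "textSectionName": "molecularGenetics",
                        "textSectionContent": mg_paragraph,
                    }
                },
                {
                    "textSection": {
                        "textSectionName": "animalModel",
                        "textSectionContent": am_paragraph,
                    }
                },
            ],
            "referenceList": [
                {
                    "reference": {
                        "referenceNumber": n,
                        "authors": f"{author}, A. B.",
                        "pubDate": str(year),
                        "pubmedID": pmid,
                    }
                }
                for n, author, year, pmid in refs
            ],
        }
        entries.append({"omim": {"entryList": [{"entry": gene_raw}]}})
        entries.append({"omim": {"entryList": [{"entry": phen_raw}]}})

        pmid_of = {n: p for n, _, _, p in refs}
        truths.append(
            GroundTruth(
                gene_mim=gene_mim,
                phenotype_mim=phen_mim,
                gene_symbol=symbol,
                stream="provisional" if provisional else "confirmed",
                tier=tier,
                decoy=decoy,
                discovery_year=discovery_year,
                discovery_pmid=pmid_of[disc_ref[0]],
                decoy_pmid=pmid_of[decoy_ref[0]] if decoy else None,
                cohort_count=count,
                cohort_unrelated=unrelated,
                cohort_same_study=same_study,
                organisms=[(species, organism_year)],
            )
        )

    manifest = {
        "seed": spec.seed,
        "n_entries": spec.n_entries,
        "engine": {"name": engine.name, "version": engine.version},
        "resampled_sentences": resampled,
    }
    return CorpusFixture(entries=entries, truth=truths, manifest=manifest)


# -- auxiliary planted fixtures --------------------------------------------

def generate_candidate_catalog(seed: int, n: int):
    """A synthetic gene-phenotype candidate catalog with planted mapping
    keys and marker symbols, plus the planted stream assignment.

    Returns ``(candidates, planted)`` where ``planted`` maps candidate
    index to its intended stream ("confirmed" / "provisional" /
    "rejected").
    """
    from ..filters import GdaCandidate, classify_phenotype_markers

    rng = random.Random(seed)
    candidates: list[GdaCandidate] = []
    planted: list[str] = []
    for i in range(n):
        key = rng.choices([1, 2, 3, 4], weights=[0.05, 0.08, 0.80, 0.07])[0]
        base = f"Disorder catalog item {i + 1}"
        style = rng.random()
        if style < 0.60:
            label = base
        elif style < 0.70:
            label = f"?{base}"
        elif style < 0.78:
            label = f"[{base}]"
        elif style < 0.88:
            label = f"{{{base}, susceptibility to}}"
        elif style < 0.94:
            label = f"{base}, modifier of"
        else:
            label = f"{{?{base}, susceptibility to}}"
        missing_mim = rng.random() < 0.03
        cand = GdaCandidate(
            gene_mim=600000 + i,
            phenotype_mim=None if missing_mim else 500000 + i,
            phenotype_label=label,
            mapping_key=key,
            markers=classify_phenotype_markers(label),
        )
        m = cand.markers
        if key != 3 or m.nondisease or m.susceptibility or m.modifier or missing_mim:
            planted.append("rejected")
        elif m.provisional:
            planted.append("provisional")
        else:
            planted.append("confirmed")
        candidates.append(cand)
    return candidates, planted


def pattern_sentence_bank() -> list[dict]:
    """In-grammar sentences with their expected match, one per row.

    ``kind`` is one of P1/P2/exclusion/organism; the remaining keys give
    the expected extraction for that sentence.
    """
    bank: list[dict] = []
    for count, word in [(6, "6"), (3, "three"), (23, "twenty-three"), (1204, "1,204")]:
        for noun in sorted(_NOUNS):
            pl = _NOUNS[noun]
            bank.append({
                "kind": "P1", "count": count, "unrelated": True, "anchor": noun,
                "text": f"De novo variants were identified in {word} unrelated {pl}.",
            })
            bank.append({
                "kind": "P1", "count": count, "unrelated": False, "anchor": noun,
                "text": f"Causative variants were found in {word} affected {pl}.",
            })
            cap = word[0].upper() + word[1:]
            bank.append({
                "kind": "P2", "count": count, "unrelated": True, "anchor": noun,
                "text": f"{cap} of the unrelated {pl} carried the variant.",
            })
    for verb in ("reported", "described", "observed", "noted"):
        for adv in ("previously", "originally", "initially"):
            bank.append({
                "kind": "exclusion",
                "text": f"This phenotype was {adv} {verb} in 4 patients by other groups.",
            })
    for species, surface in sorted(_SPECIES_SURFACE.items()):
        cap = surface[0].upper() + surface[1:]
        bank.append({
            "kind": "organism", "species": species,
            "text": f"{cap} carrying the variant displayed a similar phenotype.",
        })
        bank.append({
            "kind": "organism", "species": species,
            "text": f"Experiments in {surface} confirmed the gene function.",
        })
    return bank


def adversarial_sentence_bank() -> list[str]:
    """Sentences containing anchor lemmas or numbers but no valid
    attachment: none may produce a cohort or exclusion match."""
    return [
        "The patients were grateful for the diagnosis.",
        "Several patients were examined over many years.",
        "The family history was unremarkable.",
        "Most individuals remained undiagnosed.",
        "The parents declined further testing.",
        "All children in the cohort attended school.",
        "The proband's siblings were healthy.",
        "Affected individuals were described in the literature.",
        "In 1998 the gene was mapped to chromosome 4.",
        "The study enrolled many unrelated volunteers.",
        "Chromosome 12 carries the locus.",
        "Exon 7 of the gene was sequenced in the proband.",
    ]
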