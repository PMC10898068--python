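"""Per-association extraction workflow.

For one gene-phenotype association the extractor assembles a discovery
record from three searches, each over a prioritized list of source
sections:

* **discovery publication** — the gene symbol is the anchor token; the
  phenotype entry's molecularGenetics section is searched first, then the
  gene entry's allelicVariants.  Citations co-sentential with an exclusion
  match (phenotype-only studies) are blacklisted before the proximity
  selection runs.
* **cohort** — the cohort patterns (P1/P2) provide anchors and counts;
  matches inside exclusion sentences are discarded; among the remaining
  matches the one whose citation resolves to the earliest study is
  reported, which may or may not be the discovery study.
* **model organisms** — the phenotype entry's animalModel section has the
  highest priority, falling back to molecularGenetics and allelicVariants;
  per species, the first mention anchors a proximity resolution whose
  reference supplies the evidence year.

Missing sections degrade to absent fields, with the miss noted in the
record's provenance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Literal, Optional

from pydantic import BaseModel, Field, model_validator

from .filters import GdaCandidate, extract_gda_candidates, partition_candidates
from .nlp.engine import AnalysisEngine, get_engine
from .nlp.organisms import SpeciesLexicon, default_species_lexicon, detect_organisms
from .nlp.patterns import (
    CohortMatch,
    default_anchor_lemmas,
    match_cohort_patterns,
    match_exclusion_pattern,
)
from .omim.citations import resolve_reference_marks
from .omim.models import OmimEntry
from .resolve import (
    ResolutionResult,
    earliest_across_sections,
    phenotype_only_references,
    select_citation,
)

logger = logging.getLogger(__name__)

__all__ = ["GdaDiscoveryRecord", "OrganismEvidence", "CorpusResult", "Extractor",
           "extract_discovery", "extract_corpus"]

DISCOVERY_SECTIONS = (("phenotype", "molecularGenetics"), ("gene", "allelicVariants"))
COHORT_SECTIONS = DISCOVERY_SECTIONS
ORGANISM_SECTIONS = (
    ("phenotype", "animalModel"),
    ("phenotype", "molecularGenetics"),
    ("gene", "allelicVariants"),
)


class OrganismEvidence(BaseModel):
    species: str
    year: Optional[int] = None


class GdaDiscoveryRecord(BaseModel):
    """The extraction product for one gene-phenotype association."""

    gene_mim: int
    phenotype_mim: Optional[int] = None
    discovery_year: Optional[int] = None
    discovery_pmid: Optional[int] = None
    cohort_count: Optional[int] = None
    cohort_unrelated: Optional[bool] = None
    cohort_same_study: Optional[bool] = None
    organisms: list[OrganismEvidence] = Field(default_factory=list)
    provenance: dict[str, dict] = Field(default_factory=dict)
    stream: Literal["confirmed", "provisional"] = "confirmed"

    @model_validator(mode="after")
    def _pmid_needs_year(self) -> "GdaDiscoveryRecord":
        if self.discovery_year is None and self.discovery_pmid is not None:
            raise ValueError("discovery_pmid set without discovery_year")
        return self


@dataclass
class _Analyzed:
    """One analyzed paragraph with its citations and exclusion blacklist."""

    entry: OmimEntry
    section: str
    doc: object
    mentions: list
    blacklist: frozenset[int]


@dataclass
class CorpusResult:
    records: list[GdaDiscoveryRecord] = field(default_factory=list)
    errors: list[tuple[int, str]] = field(default_factory=list)  # (gene_mim, message)


class Extractor:
    def __init__(
        self,
        engine: AnalysisEngine | None = None,
        anchor_lemmas: frozenset[str] | None = None,
        species_lexicon: SpeciesLexicon | None = None,
    ):
        self.engine = engine or get_engine()
        self.anchor_lemmas = anchor_lemmas or default_anchor_lemmas()
        self.species_lexicon = species_lexicon or default_species_lexicon()

    # -- shared helpers ----------------------------------------------------

    def _analyzed_paragraphs(self, entry: OmimEntry | None, section: str) -> list[_Analyzed]:
        if entry is None:
            return []
        sec = entry.section(section)
        if sec is None:
            return []
        out = []
        for para in sec.paragraphs:
            doc = self.engine.analyze(para)
            mentions = resolve_reference_marks(para, entry.references, doc)
            exclusions = match_exclusion_pattern(doc)
            blacklist = phenotype_only_references(doc, mentions, exclusions)
            out.append(_Analyzed(entry, section, doc, mentions, blacklist))
        return out

    def _sections(self, role_sections, gene: OmimEntry, phenotype: OmimEntry | None):
        for role, name in role_sections:
            entry = gene if role == "gene" else phenotype
            yield from self._analyzed_paragraphs(entry, name)

    # -- discovery publication ---------------------------------------------

    def _resolve_discovery(self, gene: OmimEntry, phenotype: OmimEntry | None):
        symbols = set(gene.gene_symbols)
        results: list[tuple[ResolutionResult, _Analyzed, int]] = []
        for ana in self._sections(DISCOVERY_SECTIONS, gene, phenotype):
            anchor = next((t for t in ana.doc.tokens if t.text in symbols), None)
            if anchor is None:
                continue
            res = select_citation(
                ana.doc, anchor.sentence_index, ana.mentions, ana.blacklist,
                ana.entry.references,
            )
            results.append((res, ana, anchor.sentence_index))
        combined = earliest_across_sections([r for r, _, _ in results])
        for res, ana, sent in results:
            if res is combined and combined.tier != "none":
                return combined, ana, sent
        return combined, None, None

    # -- cohort -------------------------------------------------------------

    def _resolve_cohort(self, gene: OmimEntry, phenotype: OmimEntry | None):
        for role, name in COHORT_SECTIONS:
            entry = gene if role == "gene" else phenotype
            paragraphs = self._analyzed_paragraphs(entry, name)
            candidates: list[tuple[CohortMatch, ResolutionResult, _Analyzed]] = []
            for ana in paragraphs:
                excl_sents = {
                    e.sentence_index for e in match_exclusion_pattern(ana.doc)
                }
                for match in match_cohort_patterns(ana.doc, self.anchor_lemmas):
                    if match.sentence_index in excl_sents:
                        continue  # exclusion precedence
                    res = select_citation(
                        ana.doc, match.sentence_index, ana.mentions,
                        ana.blacklist, ana.entry.references,
                    )
                    candidates.append((match, res, ana))
            if not candidates:
                continue
            resolved = [c for c in candidates if c[1].found]
            if resolved:
                return min(
                    resolved,
                    key=lambda c: (c[1].reference.year, c[1].reference.ref_number),
                )
            return candidates[0]
        return None

    # -- organisms -----------------------------------------------------------

    def _resolve_organisms(self, gene: OmimEntry, phenotype: OmimEntry | None):
        for role, name in ORGANISM_SECTIONS:
            entry = gene if role == "gene" else phenotype
            paragraphs = self._analyzed_paragraphs(entry, name)
            found: dict[str, tuple] = {}
            for ana in paragraphs:
                for mention in detect_organisms(ana.doc, self.species_lexicon):
                    if mention.species in found:
                        continue
                    res = select_citation(
                        ana.doc, mention.sentence_index, ana.mentions,
                        ana.blacklist, ana.entry.references,
                    )
                    found[mention.species] = (res, ana, mention)
            if found:
                return found
        return {}

    # -- record assembly -----------------------------------------------------

    def extract_discovery(
        self,
        gene_entry: OmimEntry,
        phenotype_entry: OmimEntry | None,
        gda: GdaCandidate,
    ) -> GdaDiscoveryRecord:
        provenance: dict[str, dict] = {}

        discovery, disc_ana, disc_sent = self._resolve_discovery(gene_entry, phenotype_entry)
        discovery_year = discovery_pmid = None
        if discovery.found:
            discovery_year = discovery.reference.year
            discovery_pmid = discovery.reference.pubmed_id
            provenance["discovery"] = {
                "entry": disc_ana.entry.mim_number,
                "section": disc_ana.section,
                "sentence": disc_sent,
                "tier": discovery.tier,
                "ref_number": discovery.reference.ref_number,
            }
        else:
            provenance["discovery"] = {"note": "no resolvable citation"}

        cohort = self._resolve_cohort(gene_entry, phenotype_entry)
        cohort_count = cohort_unrelated = cohort_same_study = None
        if cohort is not None:
            match, res, ana = cohort
            cohort_count = match.count
            cohort_unrelated = match.unrelated
            provenance["cohort"] = {
                "entry": ana.entry.mim_number,
                "section": ana.section,
                "sentence": match.sentence_index,
                "pattern": match.pattern_id,
            }
            if res.found and discovery.found:
                if res.reference.pubmed_id is not None and discovery_pmid is not None:
                    cohort_same_study = res.reference.pubmed_id == discovery_pmid
                elif ana.entry.mim_number == provenance["discovery"].get("entry"):
                    cohort_same_study = (
                        res.reference.ref_number == discovery.reference.ref_number
                    )
        else:
            provenance["cohort"] = {"note": "no cohort pattern matched"}

        organisms = []
        org_prov = {}
        for species, (res, ana, mention) in sorted(
            self._resolve_organisms(gene_entry, phenotype_entry).items()
        ):
            organisms.append(
                OrganismEvidence(
                    species=species,
                    year=res.reference.year if res.found else None,
                )
            )
            org_prov[species] = {
                "entry": ana.entry.mim_number,
                "section": ana.section,
                "sentence": mention.sentence_index,
            }
        provenance["organisms"] = org_prov or {"note": "no organism mention"}

        return GdaDiscoveryRecord(
            gene_mim=gda.gene_mim,
            phenotype_mim=gda.phenotype_mim,
            discovery_year=discovery_year,
            discovery_pmid=discovery_pmid,
            cohort_count=cohort_count,
            cohort_unrelated=cohort_unrelated,
            cohort_same_study=cohort_same_study,
            organisms=organisms,
            provenance=provenance,
            stream="provisional" if gda.markers.provisional else "confirmed",
        )

    def extract_corpus(self, entries: list[OmimEntry]) -> CorpusResult:
        """Batch driver: one record per confirmed/provisional association.

        Never aborts the batch; per-entry failures are aggregated in
        ``CorpusResult.errors``.  Output is sorted by (gene_mim,
        phenotype_mim).
        """
        by_mim = {e.mim_number: e for e in entries}
        result = CorpusResult()
        for entry in entries:
            if not entry.phenotype_map or not entry.active:
                continue
            try:
                part = partition_candidates(extract_gda_candidates(entry))
                for gda in part.confirmed + part.provisional:
                    phenotype = by_mim.get(gda.phenotype_mim)
                    result.records.append(
                        self.extract_discovery(entry, phenotype, gda)
                    )
            except Exception as exc:  # noqa: BLE001 - batch must survive
                logger.exception("extraction failed for entry %s", entry.mim_number)
                result.errors.append((entry.mim_number, str(exc)))
        result.records.sort(key=lambda r: (r.gene_mim, r.phenotype_mim or 0))
        return result


def extract_discovery(
    gene_entry: OmimEntry,
    phenotype_entry: OmimEntry | None,
    gda: GdaCandidate,
    **kwargs,
) -> GdaDiscoveryRecord:
    """Module-level convenience wrapper around :class:`Extractor`."""
    return Extractor(**kwargs).extract_discovery(gene_entry, phenotype_entry, gda)


def extract_corpus(entries: list[OmimEntry], **kwargs) -> CorpusResult:
    return Extractor(**kwargs).extract_corpus(entries)
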