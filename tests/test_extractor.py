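"""End-to-end extraction on worked examples and generated corpora."""

import pytest

from gdamine.extract import Extractor, extract_corpus
from gdamine.filters import extract_gda_candidates, partition_candidates
from gdamine.fixtures import FixtureSpec, generate_corpus, worked_example_cases
from gdamine.omim import parse_entry


def _case(name):
    return next(c for c in worked_example_cases() if c.name == name)


def _record_for(case, extractor):
    gene = parse_entry(case.gene_raw)
    phenotype = parse_entry(case.phenotype_raw)
    gda = next(
        c for c in extract_gda_candidates(gene)
        if c.phenotype_mim == phenotype.mim_number
    )
    return extractor.extract_discovery(gene, phenotype, gda)


class TestWorkedExamples:
    def test_cul3_discovery_is_cosentential_2019_study(self, extractor):
        rec = _record_for(_case("CUL3"), extractor)
        assert (rec.discovery_year, rec.discovery_pmid) == (2019, 91000002)
        assert rec.provenance["discovery"]["tier"] == "same_sentence"

    def test_mto1_year_cohort_and_yeast(self, extractor):
        rec = _record_for(_case("MTO1"), extractor)
        assert rec.discovery_year == 2012
        assert rec.cohort_count == 2 and rec.cohort_unrelated is False
        assert [o.species for o in rec.organisms] == ["yeast"]
        assert rec.cohort_same_study is True

    def test_klkb1_skips_early_phenotype_describing_study(self, extractor):
        rec = _record_for(_case("KLKB1"), extractor)
        assert (rec.discovery_year, rec.discovery_pmid) == (2003, 91000022)

    def test_ccdc65_simultaneous_studies_resolved_deterministically(self, extractor):
        case = _case("CCDC65")
        picks = {(r.discovery_year, r.discovery_pmid)
                 for r in (_record_for(case, extractor) for _ in range(5))}
        assert picks == {(2013, 91000031)}


class TestDegradation:
    def test_entry_without_citations_yields_absent_fields(self, extractor):
        gene = parse_entry({
            "mimNumber": 600100, "prefix": "*",
            "titles": {"preferredTitle": "SOME GENE; SG1"},
            "geneMap": {"phenotypeMapList": [{"phenotypeMap": {
                "phenotypeMimNumber": 600101, "phenotype": "Some disorder",
                "phenotypeMappingKey": 3, "phenotypeInheritance": ""}}]},
        })
        phenotype = parse_entry({
            "mimNumber": 600101, "prefix": "#",
            "textSectionList": [{"textSection": {
                "textSectionName": "molecularGenetics",
                "textSectionContent": "Variants in SG1 segregate with the disorder."}}],
        })
        gda = extract_gda_candidates(gene)[0]
        rec = extractor.extract_discovery(gene, phenotype, gda)
        assert rec.discovery_year is None and rec.discovery_pmid is None
        assert rec.cohort_count is None and rec.organisms == []
        assert "note" in rec.provenance["organisms"]

    def test_missing_phenotype_entry_degrades(self, extractor):
        case = _case("CUL3")
        gene = parse_entry(case.gene_raw)
        gda = extract_gda_candidates(gene)[0]
        rec = extractor.extract_discovery(gene, None, gda)
        assert rec.discovery_year is None


class TestCorpus:
    def test_empty_corpus(self):
        assert extract_corpus([]).records == []

    def test_deterministic_sorted_output(self, seed7_entries, extractor):
        a = extractor.extract_corpus(seed7_entries)
        b = extractor.extract_corpus(seed7_entries)
        assert [r.model_dump() for r in a.records] == [r.model_dump() for r in b.records]
        keys = [(r.gene_mim, r.phenotype_mim) for r in a.records]
        assert keys == sorted(keys)

    def test_ground_truth_recovery(self, seed7_corpus, seed7_entries, extractor):
        result = extractor.extract_corpus(seed7_entries)
        truth = {(t.gene_mim, t.phenotype_mim): t for t in seed7_corpus.truth}
        assert len(result.records) == len(truth)
        for rec in result.records:
            t = truth[(rec.gene_mim, rec.phenotype_mim)]
            assert rec.discovery_pmid == t.discovery_pmid
            assert rec.discovery_year == t.discovery_year
            assert rec.cohort_count == t.cohort_count
            assert rec.cohort_unrelated == t.cohort_unrelated
            assert rec.cohort_same_study == t.cohort_same_study
            assert [(o.species, o.year) for o in rec.organisms] == t.organisms
            assert rec.stream == t.stream

    def test_decoy_citation_never_selected(self, seed7_corpus, seed7_entries, extractor):
        """Planted earlier phenotype-describing studies must always lose to
        the later association-making study."""
        decoy_pmids = {t.decoy_pmid for t in seed7_corpus.truth if t.decoy}
        assert decoy_pmids  # the default decoy fraction plants some
        records = extractor.extract_corpus(seed7_entries).records
        assert decoy_pmids.isdisjoint({r.discovery_pmid for r in records})

    def test_provisional_stream_tracked_separately(self, seed7_entries):
        gene_entries = [e for e in seed7_entries if e.phenotype_map]
        streams = []
        for g in gene_entries:
            part = partition_candidates(extract_gda_candidates(g))
            streams.extend(["confirmed"] * len(part.confirmed))
            streams.extend(["provisional"] * len(part.provisional))
        assert "provisional" in streams and "confirmed" in streams


def test_cohort_same_study_iff_references_coincide(extractor):
    """cohort_same_study is exactly PMID identity of the two resolutions."""
    fx = generate_corpus(FixtureSpec(seed=13, n_entries=40))
    entries = [parse_entry(raw) for raw in fx.entries]
    records = extractor.extract_corpus(entries).records
    truth = {(t.gene_mim, t.phenotype_mim): t for t in fx.truth}
    for rec in records:
        assert rec.cohort_same_study == truth[(rec.gene_mim, rec.phenotype_mim)].cohort_same_study
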