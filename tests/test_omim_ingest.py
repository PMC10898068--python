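"""Entry parsing, serialization round-trips, citation marks, and the
quota-aware cached client."""

import datetime
import json

import pytest

from gdamine.fixtures import FixtureSpec, generate_corpus, worked_example_cases
from gdamine.omim import (
    ClientConfig,
    InvalidMimError,
    MalformedResponseError,
    OmimClient,
    OmimSchemaError,
    Prefix,
    QuotaExhaustedError,
    ReferenceRecord,
    emit_entry,
    parse_entry,
    resolve_reference_marks,
)


@pytest.fixture()
def cul3_raw():
    return worked_example_cases()[0].gene_raw


class TestParse:
    def test_cul3_gene_entry(self, cul3_raw):
        entry = parse_entry(cul3_raw)
        assert entry.mim_number == 603136
        assert entry.prefix is Prefix.asterisk
        assert entry.gene_symbols == ["CUL3"]
        assert [row.phenotype_mim for row in entry.phenotype_map] == [619239, 614496]

    def test_empty_sections_allowed(self):
        entry = parse_entry({"mimNumber": 100100, "prefix": "#", "textSectionList": []})
        assert entry.sections == []

    def test_missing_mim_number_names_field(self):
        with pytest.raises(OmimSchemaError, match="mimNumber"):
            parse_entry({"prefix": "#"})

    def test_duplicate_reference_numbers_rejected(self):
        raw = {
            "mimNumber": 100100,
            "referenceList": [
                {"reference": {"referenceNumber": 1, "authors": "A", "pubDate": "1999"}},
                {"reference": {"referenceNumber": 1, "authors": "B", "pubDate": "2000"}},
            ],
        }
        with pytest.raises(OmimSchemaError, match="duplicate"):
            parse_entry(raw)

    def test_caret_entry_parsed_but_inactive(self):
        entry = parse_entry({"mimNumber": 100200, "prefix": "^"})
        assert not entry.active

    def test_unknown_section_names_preserved(self):
        raw = {
            "mimNumber": 100300,
            "textSectionList": [
                {"textSection": {"textSectionName": "biochemicalFeatures",
                                 "textSectionContent": "Some text."}}
            ],
        }
        assert parse_entry(raw).section("biochemicalFeatures") is not None

    @pytest.mark.parametrize("case_index", range(4))
    def test_round_trip_worked_entries(self, case_index):
        case = worked_example_cases()[case_index]
        for raw in (case.gene_raw, case.phenotype_raw):
            entry = parse_entry(raw)
            assert parse_entry(emit_entry(entry)) == entry

    def test_round_trip_generated_corpus(self):
        fx = generate_corpus(FixtureSpec(seed=3, n_entries=10))
        for raw in fx.entries:
            entry = parse_entry(raw)
            assert parse_entry(emit_entry(entry)) == entry


class TestCitationMentions:
    REFS = [
        ReferenceRecord(ref_number=5, first_author="Thiffault", year=2019, pubmed_id=1),
        ReferenceRecord(ref_number=6, first_author="Smith", year=2001, pubmed_id=2),
        ReferenceRecord(ref_number=7, first_author="Jones", year=2002, pubmed_id=3),
    ]

    def test_brace_mark_resolution(self):
        para = "{5:Thiffault et al. (2019)} identified de novo variants."
        (m,) = resolve_reference_marks(para, self.REFS)
        assert m.ref_numbers == (5,) and m.sentence_index == 0 and m.resolved

    def test_surface_citations_in_order(self):
        para = "Smith et al. (2001) and Jones et al. (2002) reported cases."
        mentions = resolve_reference_marks(para, self.REFS)
        assert [m.ref_numbers for m in mentions] == [(6,), (7,)]

    def test_no_citation_syntax(self):
        assert resolve_reference_marks("No citations here.", self.REFS) == []

    def test_unresolvable_surface_flagged_not_fatal(self):
        para = "Garcia et al. (1993) reported a family."
        (m,) = resolve_reference_marks(para, self.REFS)
        assert m.ref_numbers == () and not m.resolved

    def test_multi_reference_mark(self):
        para = "Variants were reported {5,6:Thiffault et al. (2019); Smith (2001)}."
        (m,) = resolve_reference_marks(para, self.REFS)
        assert m.ref_numbers == (5, 6)

    def test_offsets_index_exact_surface(self):
        para = (
            "An early report came from Smith et al. (2001). Later, "
            "{7:Jones et al. (2002)} confirmed the association."
        )
        for m in resolve_reference_marks(para, self.REFS):
            s, e = m.char_span
            assert para[s:e] == m.surface

    def test_sentence_indices_follow_segmentation(self):
        para = (
            "The gene was mapped early. {6:Smith et al. (2001)} cloned it. "
            "{7:Jones et al. (2002)} found variants."
        )
        mentions = resolve_reference_marks(para, self.REFS)
        assert [m.sentence_index for m in mentions] == [1, 2]


def _fake_transport(payload_map):
    calls = []

    def transport(url):
        calls.append(url)
        for mim, payload in payload_map.items():
            if str(mim) in url:
                return payload
        raise AssertionError(f"unexpected url {url}")

    transport.calls = calls
    return transport


def _raw_payload(mim):
    return json.dumps(
        {"omim": {"entryList": [{"entry": {"mimNumber": mim, "prefix": "*",
                                           "titles": {"preferredTitle": f"GENE; G{mim}"}}}]}}
    ).encode()


class TestClient:
    def test_invalid_mim_rejected(self, tmp_path):
        client = OmimClient(ClientConfig(cache_dir=tmp_path))
        with pytest.raises(InvalidMimError):
            client.fetch_entry(12)

    def test_live_fetch_decrements_budget_and_caches(self, tmp_path):
        transport = _fake_transport({603136: _raw_payload(603136)})
        client = OmimClient(ClientConfig(cache_dir=tmp_path, daily_budget=2), transport)
        entry = client.fetch_entry(603136)
        assert entry.mim_number == 603136
        assert client.remaining_budget() == 1
        # second fetch is a cache hit: no transport call, budget unchanged
        again = client.fetch_entry(603136)
        assert again == entry
        assert len(transport.calls) == 1
        assert client.remaining_budget() == 1

    def test_cached_entry_served_at_zero_budget(self, tmp_path):
        transport = _fake_transport({603136: _raw_payload(603136)})
        client = OmimClient(ClientConfig(cache_dir=tmp_path, daily_budget=1), transport)
        client.fetch_entry(603136)
        assert client.remaining_budget() == 0
        assert client.fetch_entry(603136).mim_number == 603136

    def test_uncached_fetch_at_zero_budget_raises(self, tmp_path):
        transport = _fake_transport({})
        client = OmimClient(ClientConfig(cache_dir=tmp_path, daily_budget=0), transport)
        with pytest.raises(QuotaExhaustedError):
            client.fetch_entry(603136)
        assert transport.calls == []

    def test_budget_resets_on_new_utc_date(self, tmp_path):
        day = [datetime.date(2024, 1, 1)]
        transport = _fake_transport({603136: _raw_payload(603136), 603137: _raw_payload(603137)})
        client = OmimClient(
            ClientConfig(cache_dir=tmp_path, daily_budget=1), transport, today=lambda: day[0]
        )
        client.fetch_entry(603136)
        with pytest.raises(QuotaExhaustedError):
            client.fetch_entry(603137)
        day[0] = datetime.date(2024, 1, 2)  # harvest resumes next day
        assert client.fetch_entry(603137).mim_number == 603137

    def test_malformed_response(self, tmp_path):
        transport = _fake_transport({603136: b"this is not json"})
        client = OmimClient(ClientConfig(cache_dir=tmp_path), transport)
        with pytest.raises(MalformedResponseError):
            client.fetch_entry(603136)

    def test_cache_determinism(self, tmp_path):
        transport = _fake_transport({603136: _raw_payload(603136)})
        client = OmimClient(ClientConfig(cache_dir=tmp_path), transport)
        a = client.fetch_entry(603136)
        b = client.fetch_entry(603136)
        assert a.model_dump_json() == b.model_dump_json()
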