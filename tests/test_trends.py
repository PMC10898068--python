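"""Trend tables and benchmark concordance against brute-force recomputation."""

import random
from collections import Counter

import pandas as pd
import pytest

from gdamine.extract import GdaDiscoveryRecord, OrganismEvidence
from gdamine.trends import (
    BenchmarkKeyError,
    DEFAULT_COHORT_BINS,
    cohort_size_distribution,
    compare_to_benchmark,
    organism_share,
    yearly_counts,
)

_SPECIES = ["mouse", "zebrafish", "yeast", "worm"]


def _rand_records(rng, n):
    out = []
    for i in range(n):
        year = rng.choice([None] + list(range(1990, 2023)))
        out.append(
            GdaDiscoveryRecord(
                gene_mim=600000 + i,
                phenotype_mim=500000 + i,
                discovery_year=year,
                discovery_pmid=rng.randrange(10**6) if year else None,
                cohort_count=rng.choice([None, 1, 2, 3, 4, 5, 6, 7, 12, 50, 150, 400]),
                organisms=[
                    OrganismEvidence(species=s, year=year)
                    for s in rng.sample(_SPECIES, rng.randint(0, 2))
                ],
                stream=rng.choice(["confirmed", "provisional"]),
            )
        )
    return out


def test_yearly_counts_example():
    recs = [
        GdaDiscoveryRecord(gene_mim=600001, discovery_year=y, discovery_pmid=1)
        for y in (2013, 2013, 2014)
    ]
    table = yearly_counts(recs).table
    assert dict(zip(table["year"], table["count"])) == {2013: 2, 2014: 1}


def test_yearly_counts_empty():
    t = yearly_counts([])
    assert len(t) == 0 and t.n_missing == 0


def test_cohort_bins_example():
    recs = [GdaDiscoveryRecord(gene_mim=600001, cohort_count=c) for c in (1, 2, 3, 7)]
    t = cohort_size_distribution(recs, bins=(1, 5, 10))
    assert dict(zip(t.table["bin"], t.table["count"])) == {
        "1": 1, "2-5": 2, "6-10": 1, ">10": 0
    }


def test_cohort_bins_all_missing():
    recs = [GdaDiscoveryRecord(gene_mim=600001)] * 3
    t = cohort_size_distribution(recs)
    assert t.n_missing == 3 and t.table["count"].sum() == 0


def test_organism_share_example():
    recs = [
        GdaDiscoveryRecord(
            gene_mim=600000 + i, discovery_year=2015, discovery_pmid=1,
            organisms=[OrganismEvidence(species=s)],
        )
        for i, s in enumerate(["mouse", "mouse", "mouse", "zebrafish"])
    ]
    t = organism_share(recs, window=(2011, 2021)).table
    shares = dict(zip(t["species"], t["share"]))
    assert shares == {"mouse": 0.75, "zebrafish": 0.25}


def test_organism_share_empty_window():
    assert len(organism_share([], window=(2011, 2021))) == 0


def test_randomized_tables_equal_brute_force():
    rng = random.Random(99)
    for _ in range(300):
        recs = _rand_records(rng, rng.randint(0, 25))

        t = yearly_counts(recs, stream="both")
        brute = Counter(
            (r.discovery_year, r.stream) for r in recs if r.discovery_year is not None
        )
        got = {
            (row.year, row.stream): row.count for row in t.table.itertuples()
        }
        assert got == dict(brute)
        assert t.n_missing == sum(1 for r in recs if r.discovery_year is None)

        # stream disjointness: confirmed + provisional = both
        c = yearly_counts(recs, "confirmed").table["count"].sum()
        p = yearly_counts(recs, "provisional").table["count"].sum()
        assert c + p == t.table["count"].sum()

        d = cohort_size_distribution(recs)
        sized = [r.cohort_count for r in recs if r.cohort_count is not None]
        edges = DEFAULT_COHORT_BINS
        brute_bins = Counter()
        for v in sized:
            if v <= edges[0]:
                brute_bins["1"] += 1
            elif v <= edges[1]:
                brute_bins["2-5"] += 1
            elif v <= edges[2]:
                brute_bins["6-10"] += 1
            elif v <= edges[3]:
                brute_bins["11-100"] += 1
            else:
                brute_bins[">100"] += 1
        assert dict(zip(d.table["bin"], d.table["count"])) == {
            b: brute_bins.get(b, 0) for b in d.table["bin"]
        }
        if sized:
            assert d.stats["share_under_5"] == sum(1 for v in sized if v < 5) / len(sized)

        s = organism_share(recs, window=(2000, 2015))
        brute_org = Counter(
            o.species
            for r in recs
            if r.organisms and r.discovery_year is not None and 2000 <= r.discovery_year <= 2015
            for o in r.organisms
        )
        assert dict(zip(s.table["species"], s.table["count"])) == dict(brute_org)


def _benchmark_frame(rows):
    return pd.DataFrame(rows, columns=["gene_mim", "phenotype_mim", "pmid"])


class TestBenchmark:
    def _recs(self, pmids):
        return [
            GdaDiscoveryRecord(
                gene_mim=600000 + i, phenotype_mim=500000 + i,
                discovery_year=2000, discovery_pmid=p,
            )
            for i, p in enumerate(pmids)
        ]

    def test_identical_tables_match_fully(self):
        recs = self._recs(range(100, 110))
        bench = _benchmark_frame(
            [(r.gene_mim, r.phenotype_mim, r.discovery_pmid) for r in recs]
        )
        rep = compare_to_benchmark(recs, bench)
        assert rep.match_share == 1.0 and rep.n_conflicting == 0

    def test_one_conflict_of_thirteen(self):
        recs = self._recs(range(100, 113))
        rows = [(r.gene_mim, r.phenotype_mim, r.discovery_pmid) for r in recs]
        rows[4] = (rows[4][0], rows[4][1], 999999)
        rep = compare_to_benchmark(recs, _benchmark_frame(rows))
        assert (rep.n_matched, rep.n_conflicting) == (12, 1)
        assert rep.conflicts[0]["benchmark_pmid"] == 999999

    def test_absent_records_counted_separately(self):
        recs = self._recs([100, 101])
        bench = _benchmark_frame([(recs[0].gene_mim, recs[0].phenotype_mim, 100)])
        rep = compare_to_benchmark(recs, bench)
        assert rep.n_compared == 1 and rep.n_absent_in_benchmark == 1

    def test_duplicate_benchmark_keys_rejected(self):
        bench = _benchmark_frame([(600000, 500000, 1), (600000, 500000, 2)])
        with pytest.raises(BenchmarkKeyError):
            compare_to_benchmark([], bench)

    def test_randomized_reports_equal_brute_force(self):
        rng = random.Random(123)
        for _ in range(300):
            recs = self._recs(rng.randrange(10**4) for _ in range(rng.randint(0, 15)))
            rows = []
            for r in recs:
                if rng.random() < 0.7:
                    pmid = r.discovery_pmid if rng.random() < 0.6 else rng.randrange(10**4)
                    rows.append((r.gene_mim, r.phenotype_mim, pmid))
            rep = compare_to_benchmark(recs, _benchmark_frame(rows))
            lookup = {(g, p): m for g, p, m in rows}
            matched = conflicting = absent = 0
            for r in recs:
                k = (r.gene_mim, r.phenotype_mim)
                if k not in lookup:
                    absent += 1
                elif lookup[k] == r.discovery_pmid:
                    matched += 1
                else:
                    conflicting += 1
            assert (rep.n_matched, rep.n_conflicting, rep.n_absent_in_benchmark) == (
                matched, conflicting, absent,
            )
            assert rep.n_matched + rep.n_conflicting == rep.n_compared
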