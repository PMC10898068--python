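"""Trend aggregation and benchmark concordance over discovery records.

All aggregations are plain pandas arithmetic over
:class:`~gdamine.extract.GdaDiscoveryRecord` lists: yearly discovery counts
per stream, cohort-size histograms over configurable bins, model-organism
shares within a year window, and per-association PubMed-ID concordance
against an independently curated benchmark table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Optional, Sequence

import pandas as pd

from .extract import GdaDiscoveryRecord

__all__ = [
    "TrendTable",
    "MatchReport",
    "DEFAULT_COHORT_BINS",
    "yearly_counts",
    "cohort_size_distribution",
    "organism_share",
    "compare_to_benchmark",
    "BenchmarkKeyError",
]

#: bin breakpoints producing the categories 1, 2-5, 6-10, 11-100, >100
DEFAULT_COHORT_BINS: tuple[int, ...] = (1, 5, 10, 100)


@dataclass
class TrendTable:
    """A small result table plus bookkeeping counts."""

    table: pd.DataFrame
    n_missing: int = 0
    stats: dict[str, float] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.table)


class BenchmarkKeyError(ValueError):
    """Duplicate (gene, phenotype) keys in the benchmark table."""


@dataclass
class MatchReport:
    n_compared: int
    n_matched: int
    n_conflicting: int
    n_absent_in_benchmark: int
    conflicts: list[dict] = field(default_factory=list)

    @property
    def match_share(self) -> float:
        return self.n_matched / self.n_compared if self.n_compared else float("nan")


def yearly_counts(
    records: Iterable[GdaDiscoveryRecord],
    stream: Literal["confirmed", "provisional", "both"] = "both",
) -> TrendTable:
    """Discovery counts per calendar year (and per stream for 'both').

    Records without a resolved discovery year are tallied in
    ``n_missing`` rather than under any year.
    """
    records = list(records)
    if stream != "both":
        records = [r for r in records if r.stream == stream]
    dated = [r for r in records if r.discovery_year is not None]
    n_missing = len(records) - len(dated)
    if not dated:
        return TrendTable(pd.DataFrame(columns=["year", "stream", "count"]), n_missing)
    df = pd.DataFrame(
        {"year": [r.discovery_year for r in dated], "stream": [r.stream for r in dated]}
    )
    out = (
        df.groupby(["year", "stream"]).size().rename("count").reset_index()
        .sort_values(["year", "stream"], ignore_index=True)
    )
    return TrendTable(out, n_missing)


def _bin_labels(bins: Sequence[int]) -> list[str]:
    labels = []
    prev = None
    for b in bins:
        if prev is None:
            labels.append(str(b) if b == 1 else f"1-{b}")
        else:
            labels.append(str(prev + 1) if prev + 1 == b else f"{prev + 1}-{b}")
        prev = b
    labels.append(f">{bins[-1]}")
    return labels


def cohort_size_distribution(
    records: Iterable[GdaDiscoveryRecord],
    bins: Sequence[int] = DEFAULT_COHORT_BINS,
) -> TrendTable:
    """Histogram of cohort sizes over right-closed bins.

    ``stats['share_under_5']`` reports the fraction of sized records with
    fewer than five individuals/families — the small-cohort share.
    """
    if list(bins) != sorted(set(bins)):
        raise ValueError("bins must be strictly increasing")
    counts = [r.cohort_count for r in records if r.cohort_count is not None]
    n_missing = sum(1 for r in records if r.cohort_count is None)
    labels = _bin_labels(bins)
    if not counts:
        table = pd.DataFrame({"bin": labels, "count": 0})
        return TrendTable(table, n_missing)
    edges = [0, *bins, float("inf")]
    cat = pd.cut(pd.Series(counts), bins=edges, labels=labels, right=True)
    tally = cat.value_counts().reindex(labels, fill_value=0)
    table = pd.DataFrame({"bin": labels, "count": tally.to_numpy()})
    table["share"] = table["count"] / len(counts)
    stats = {"share_under_5": sum(1 for c in counts if c < 5) / len(counts)}
    return TrendTable(table, n_missing, stats)


def organism_share(
    records: Iterable[GdaDiscoveryRecord],
    window: tuple[int, int] = (2011, 2021),
) -> TrendTable:
    """Per-species counts/shares among organism-backed records whose
    discovery year falls in the closed ``window``."""
    lo, hi = window
    if lo > hi:
        raise ValueError("window start must not exceed its end")
    hits: list[str] = []
    for r in records:
        if not r.organisms or r.discovery_year is None:
            continue
        if lo <= r.discovery_year <= hi:
            hits.extend(o.species for o in r.organisms)
    if not hits:
        return TrendTable(pd.DataFrame(columns=["species", "count", "share"]))
    tally = pd.Series(hits).value_counts().sort_index()
    table = pd.DataFrame(
        {"species": tally.index, "count": tally.to_numpy()}
    )
    table["share"] = table["count"] / table["count"].sum()
    return TrendTable(table)


def compare_to_benchmark(
    records: Iterable[GdaDiscoveryRecord],
    benchmark: pd.DataFrame,
) -> MatchReport:
    """PubMed-ID concordance against a benchmark of
    (gene_mim, phenotype_mim, pmid) rows.

    Records whose key is absent from the benchmark are counted separately;
    records without a resolved PMID compare as conflicting.  The conflict
    list is retained for manual review.
    """
    required = {"gene_mim", "phenotype_mim", "pmid"}
    if not required <= set(benchmark.columns):
        raise ValueError(f"benchmark table must have columns {sorted(required)}")
    keys = list(zip(benchmark["gene_mim"], benchmark["phenotype_mim"]))
    if len(keys) != len(set(keys)):
        raise BenchmarkKeyError("duplicate (gene_mim, phenotype_mim) rows in benchmark")
    lookup = dict(zip(keys, benchmark["pmid"]))

    n_compared = n_matched = n_absent = 0
    conflicts: list[dict] = []
    for r in records:
        key = (r.gene_mim, r.phenotype_mim)
        if key not in lookup:
            n_absent += 1
            continue
        n_compared += 1
        expected = int(lookup[key])
        if r.discovery_pmid is not None and int(r.discovery_pmid) == expected:
            n_matched += 1
        else:
            conflicts.append(
                {
                    "gene_mim": r.gene_mim,
                    "phenotype_mim": r.phenotype_mim,
                    "extracted_pmid": r.discovery_pmid,
                    "benchmark_pmid": expected,
                }
            )
    return MatchReport(
        n_compared=n_compared,
        n_matched=n_matched,
        n_conflicting=n_compared - n_matched,
        n_absent_in_benchmark=n_absent,
        conflicts=conflicts,
    )
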