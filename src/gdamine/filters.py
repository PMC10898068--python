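"""Gene-phenotype candidate enumeration and the filtration ladder.

OMIM marks the certainty of a gene-phenotype link with the mapping key
(1-4; only key 3 means the molecular basis is known) and with label
symbols: ``[...]`` non-disease trait, ``{...}`` susceptibility, leading
``?`` provisional, and the words "susceptibility"/"modifier" inside the
label.  The ladder partitions candidates into three streams:

* **rejected** — mapping key != 3, or non-disease / susceptibility /
  modifier markers, or no phenotype MIM to mine;
* **provisional** — key-3 survivors flagged ``?`` (typically single-patient
  evidence), tracked separately rather than discarded;
* **confirmed** — the remaining key-3 survivors.

The three streams always partition the input exactly.
"""

from __future__ import annotations

import json
import re
from typing import NamedTuple, Optional

from pydantic import BaseModel, Field

from .omim.models import OmimEntry

__all__ = [
    "MarkerFlags",
    "GdaCandidate",
    "Partition",
    "classify_phenotype_markers",
    "extract_gda_candidates",
    "partition_candidates",
    "partition_to_jsonl",
]


class MarkerFlags(BaseModel):
    nondisease: bool = False       # label wrapped in [ ]
    susceptibility: bool = False   # label wrapped in { } or word "susceptibility"
    provisional: bool = False      # label begins with ?
    modifier: bool = False         # label contains word "modifier"


class GdaCandidate(BaseModel):
    gene_mim: int
    phenotype_mim: Optional[int] = None
    phenotype_label: str
    mapping_key: int
    markers: MarkerFlags = Field(default_factory=MarkerFlags)


class Partition(NamedTuple):
    confirmed: list[GdaCandidate]
    provisional: list[GdaCandidate]
    rejected: list[GdaCandidate]


_SUSCEPT_RE = re.compile(r"\bsusceptibility\b", re.IGNORECASE)
_MODIFIER_RE = re.compile(r"\bmodifier\b", re.IGNORECASE)


def classify_phenotype_markers(label: str) -> MarkerFlags:
    """Decode the marker symbols and keywords of a phenotype label."""
    stripped = label.strip()
    return MarkerFlags(
        nondisease=stripped.startswith("[") and stripped.endswith("]"),
        susceptibility=(stripped.startswith("{") and stripped.endswith("}"))
        or bool(_SUSCEPT_RE.search(stripped)),
        provisional=stripped.lstrip("[{ ").startswith("?"),
        modifier=bool(_MODIFIER_RE.search(stripped)),
    )


def extract_gda_candidates(gene_entry: OmimEntry) -> list[GdaCandidate]:
    """One candidate per phenotype-map row of a gene entry."""
    return [
        GdaCandidate(
            gene_mim=gene_entry.mim_number,
            phenotype_mim=row.phenotype_mim,
            phenotype_label=row.phenotype_label,
            mapping_key=row.mapping_key,
            markers=classify_phenotype_markers(row.phenotype_label),
        )
        for row in gene_entry.phenotype_map
    ]


def partition_candidates(candidates: list[GdaCandidate]) -> Partition:
    """Split candidates into confirmed / provisional / rejected streams."""
    confirmed: list[GdaCandidate] = []
    provisional: list[GdaCandidate] = []
    rejected: list[GdaCandidate] = []
    for c in candidates:
        m = c.markers
        if (
            c.mapping_key != 3
            or m.nondisease
            or m.susceptibility
            or m.modifier
            or c.phenotype_mim is None  # nothing to mine; can never confirm
        ):
            rejected.append(c)
        elif m.provisional:
            provisional.append(c)
        else:
            confirmed.append(c)
    return Partition(confirmed, provisional, rejected)


def partition_to_jsonl(partition: Partition) -> tuple[str, dict[str, int]]:
    """Serialize a partition as stream-tagged JSONL plus a counts summary."""
    lines = []
    for stream in partition._fields:
        for c in getattr(partition, stream):
            lines.append(json.dumps({"stream": stream, **c.model_dump()}))
    counts = {stream: len(getattr(partition, stream)) for stream in partition._fields}
    counts["total"] = sum(counts.values())
    return "\n".join(lines) + ("\n" if lines else ""), counts
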