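"""Parse and emit the OMIM API JSON dialect.

The dialect (documented with an annotated fixture under ``examples/``)
wraps each entry as::

    {"omim": {"entryList": [{"entry": {
        "mimNumber": 603136,
        "prefix": "*",
        "titles": {"preferredTitle": "CULLIN 3; CUL3"},
        "textSectionList": [{"textSection": {
            "textSectionName": "molecularGenetics",
            "textSectionContent": "para1\\n\\npara2"}}],
        "referenceList": [{"reference": {
            "referenceNumber": 1, "authors": "Smith, J. B., ...",
            "pubDate": "2001", "pubmedID": 11111111}}],
        "geneMap": {"phenotypeMapList": [{"phenotypeMap": {
            "phenotypeMimNumber": 619239,
            "phenotype": "Neurodevelopmental disorder ...",
            "phenotypeMappingKey": 3,
            "phenotypeInheritance": "Autosomal dominant"}}]}
    }}]}}

``parse_entry`` accepts the full wrapper or a bare ``entry`` object and
returns an :class:`~gdamine.omim.models.OmimEntry`; ``emit_entry`` is its
inverse (round-trip safe for every field the domain model captures).
"""

from __future__ import annotations

import re
from typing import Any

from pydantic import ValidationError

from .models import (
    PREFIX_SYMBOLS,
    SYMBOL_OF_PREFIX,
    OmimEntry,
    PhenotypeMapRow,
    ReferenceRecord,
    TextSection,
)

__all__ = ["parse_entry", "emit_entry", "OmimSchemaError"]


class OmimSchemaError(ValueError):
    """The raw document does not follow the expected dialect."""


_YEAR_RE = re.compile(r"(18[5-9]\d|19\d\d|20\d\d)")


def _unwrap(raw: dict[str, Any]) -> dict[str, Any]:
    if "omim" in raw:
        entries = raw["omim"].get("entryList") or []
        if len(entries) != 1:
            raise OmimSchemaError(
                f"expected a single-entry document, got {len(entries)} entries"
            )
        raw = entries[0]
    if "entry" in raw:
        raw = raw["entry"]
    return raw


def _first_author(authors: str) -> str:
    return authors.split(",")[0].strip() if authors else ""


def _ref_year(ref: dict[str, Any]) -> int | None:
    if isinstance(ref.get("year"), int):
        return ref["year"]
    m = _YEAR_RE.search(str(ref.get("pubDate", "")))
    return int(m.group(0)) if m else None


def parse_entry(raw: dict[str, Any]) -> OmimEntry:
    """Parse one OMIM-dialect JSON document into the domain model.

    Raises :class:`OmimSchemaError` naming the first missing required field
    or violated invariant.
    """
    entry = _unwrap(raw)
    if "mimNumber" not in entry:
        raise OmimSchemaError("missing required field: mimNumber")

    titles = entry.get("titles", {})
    title = titles.get("preferredTitle", "")
    # gene symbols follow the long name after ';' in the preferred title
    symbols = [s.strip() for s in title.split(";")[1:] if s.strip()]

    sections = []
    for item in entry.get("textSectionList", []):
        ts = item.get("textSection", item)
        name = ts.get("textSectionName")
        if not name:
            raise OmimSchemaError("missing required field: textSectionName")
        content = ts.get("textSectionContent", "")
        paragraphs = [p.strip() for p in content.split("\n\n") if p.strip()]
        sections.append(TextSection(name=name, paragraphs=paragraphs))

    references = []
    for item in entry.get("referenceList", []):
        ref = item.get("reference", item)
        if "referenceNumber" not in ref:
            raise OmimSchemaError("missing required field: referenceNumber")
        year = _ref_year(ref)
        if year is None:
            raise OmimSchemaError(
                f"reference {ref['referenceNumber']}: missing or unparseable year"
            )
        references.append(
            ReferenceRecord(
                ref_number=ref["referenceNumber"],
                first_author=_first_author(ref.get("authors", "")),
                year=year,
                pubmed_id=ref.get("pubmedID"),
            )
        )

    phenotype_map = []
    gene_map = entry.get("geneMap", {})
    for item in gene_map.get("phenotypeMapList", []):
        pm = item.get("phenotypeMap", item)
        if "phenotypeMappingKey" not in pm:
            raise OmimSchemaError("missing required field: phenotypeMappingKey")
        phenotype_map.append(
            PhenotypeMapRow(
                phenotype_mim=pm.get("phenotypeMimNumber"),
                phenotype_label=pm.get("phenotype", ""),
                mapping_key=pm["phenotypeMappingKey"],
                inheritance=pm.get("phenotypeInheritance", "") or "",
            )
        )

    prefix_symbol = entry.get("prefix", "")
    if prefix_symbol not in PREFIX_SYMBOLS:
        raise OmimSchemaError(f"unknown entry prefix {prefix_symbol!r}")

    try:
        return OmimEntry(
            mim_number=entry["mimNumber"],
            prefix=PREFIX_SYMBOLS[prefix_symbol],
            title=title,
            gene_symbols=symbols,
            sections=sections,
            references=references,
            phenotype_map=phenotype_map,
        )
    except ValidationError as exc:
        first = exc.errors()[0]
        raise OmimSchemaError(
            f"{'.'.join(str(p) for p in first['loc'])}: {first['msg']}"
        ) from exc


def emit_entry(entry: OmimEntry) -> dict[str, Any]:
    """Serialize an :class:`OmimEntry` back to the OMIM JSON dialect."""
    raw: dict[str, Any] = {
        "mimNumber": entry.mim_number,
        "prefix": SYMBOL_OF_PREFIX[entry.prefix],
        "titles": {"preferredTitle": entry.title},
        "textSectionList": [
            {
                "textSection": {
                    "textSectionName": s.name,
                    "textSectionContent": "\n\n".join(s.paragraphs),
                }
            }
            for s in entry.sections
        ],
        "referenceList": [
            {
                "reference": {
                    "referenceNumber": r.ref_number,
                    "authors": r.first_author,
                    "pubDate": str(r.year),
                    **({"pubmedID": r.pubmed_id} if r.pubmed_id is not None else {}),
                }
            }
            for r in entry.references
        ],
    }
    if entry.phenotype_map:
        raw["geneMap"] = {
            "phenotypeMapList": [
                {
                    "phenotypeMap": {
                        **(
                            {"phenotypeMimNumber": row.phenotype_mim}
                            if row.phenotype_mim is not None
                            else {}
                        ),
                        "phenotype": row.phenotype_label,
                        "phenotypeMappingKey": row.mapping_key,
                        "phenotypeInheritance": row.inheritance,
                    }
                }
                for row in entry.phenotype_map
            ]
        }
    return {"omim": {"entryList": [{"entry": raw}]}}
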