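"""Domain model for OMIM-style entries.

An entry is one record of the catalogue: a 6-digit MIM number, a status
prefix, named narrative text sections, a numbered reference list, and (for
gene entries) a phenotype map linking the gene to its phenotypes via a
mapping key (1-4; key 3 means the molecular basis of the association is
known).
"""

from __future__ import annotations

import datetime
import enum
from typing import Optional

from pydantic import BaseModel, Field, field_validator, model_validator

#: canonical section keys the extractor knows about; entries may carry
#: additional section names, which are preserved verbatim
CANONICAL_SECTIONS = {
    "description",
    "molecularGenetics",
    "animalModel",
    "allelicVariants",
    "clinicalFeatures",
    "inheritance",
    "mapping",
}


class Prefix(str, enum.Enum):
    """OMIM entry status symbol."""

    hash = "hash"          # '#': phenotype, molecular basis known
    asterisk = "asterisk"  # '*': gene
    plus = "plus"          # '+': gene and phenotype combined
    percent = "percent"    # '%': phenotype, mendelian basis unknown
    caret = "caret"        # '^': moved or removed entry
    none = "none"          # unprefixed


PREFIX_SYMBOLS = {
    "#": Prefix.hash,
    "*": Prefix.asterisk,
    "+": Prefix.plus,
    "%": Prefix.percent,
    "^": Prefix.caret,
    "": Prefix.none,
    None: Prefix.none,
}
SYMBOL_OF_PREFIX = {v: k for k, v in PREFIX_SYMBOLS.items() if k is not None}


class ReferenceRecord(BaseModel):
    """One numbered entry of an entry's reference list."""

    ref_number: int = Field(ge=1)
    first_author: str
    year: int
    pubmed_id: Optional[int] = None

    @field_validator("year")
    @classmethod
    def _year_range(cls, v: int) -> int:
        if not 1850 <= v <= datetime.date.today().year:
            raise ValueError(f"reference year {v} out of range")
        return v


class TextSection(BaseModel):
    """A named narrative section, split into paragraphs."""

    name: str = Field(min_length=1)
    paragraphs: list[str] = Field(default_factory=list)


class PhenotypeMapRow(BaseModel):
    """One row of a gene entry's gene-phenotype relationships table."""

    phenotype_mim: Optional[int] = None
    phenotype_label: str
    mapping_key: int
    inheritance: str = ""

    @field_validator("mapping_key")
    @classmethod
    def _key_range(cls, v: int) -> int:
        if v not in {1, 2, 3, 4}:
            raise ValueError(f"mapping key must be 1-4, got {v}")
        return v


class OmimEntry(BaseModel):
    """One parsed OMIM-style record."""

    mim_number: int
    prefix: Prefix = Prefix.none
    title: str = ""
    gene_symbols: list[str] = Field(default_factory=list)
    sections: list[TextSection] = Field(default_factory=list)
    references: list[ReferenceRecord] = Field(default_factory=list)
    phenotype_map: list[PhenotypeMapRow] = Field(default_factory=list)

    @field_validator("mim_number")
    @classmethod
    def _six_digits(cls, v: int) -> int:
        if not 100000 <= v <= 999999:
            raise ValueError(f"MIM number must be 6 digits, got {v}")
        return v

    @model_validator(mode="after")
    def _unique_refs(self) -> "OmimEntry":
        nums = [r.ref_number for r in self.references]
        if len(nums) != len(set(nums)):
            raise ValueError("duplicate reference numbers within entry")
        return self

    @property
    def active(self) -> bool:
        """Moved/removed entries ('^') are parsed but inactive."""
        return self.prefix is not Prefix.caret

    def section(self, name: str) -> Optional[TextSection]:
        for s in self.sections:
            if s.name == name:
                return s
        return None

    def reference(self, ref_number: int) -> Optional[ReferenceRecord]:
        for r in self.references:
            if r.ref_number == ref_number:
                return r
        return None
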