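"""Hand-written synthetic worked-example entries.

Four miniature gene/phenotype entry pairs, each reproducing one documented
behaviour of the extraction workflow on a well-known association.  All
narrative text, reference lists and PubMed IDs here are synthetic
stand-ins written for this package — they mirror the *structure* of the
real OMIM entries (citation placement, years, section layout), not their
licensed content.

* **CUL3 / NEDAUS** — five citations in the molecularGenetics paragraph;
  the discovery citation is co-sentential with the gene anchor and must be
  selected over the other four.
* **MTO1 / COXPD10** — a 2012 two-sibling discovery with yeast
  complementation evidence in the animalModel section.
* **KLKB1 / prekallikrein deficiency** — an early phenotype-describing
  study shares the anchor sentence; the exclusion pattern must blacklist
  it so the 2003 association-making study wins.
* **CCDC65 / primary ciliary dyskinesia** — two simultaneous 2013 studies
  in one sentence; the tie breaks deterministically to the lower reference
  number.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Any

__all__ = ["worked_example_entries", "worked_example_cases", "WorkedCase"]


def _entry(
    mim: int,
    prefix: str,
    title: str,
    sections: dict[str, str] | None = None,
    references: list[tuple[int, str, int, int]] | None = None,
    phenotype_map: list[dict] | None = None,
) -> dict[str, Any]:
    raw: dict[str, Any] = {
        "mimNumber": mim,
        "prefix": prefix,
        "titles": {"preferredTitle": title},
        "textSectionList": [
            {"textSection": {"textSectionName": name, "textSectionContent": content}}
            for name, content in (sections or {}).items()
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
            for n, author, year, pmid in (references or [])
        ],
    }
    if phenotype_map:
        raw["geneMap"] = {"phenotypeMapList": [{"phenotypeMap": pm} for pm in phenotype_map]}
    return {"omim": {"entryList": [{"entry": raw}]}}


def _cul3() -> list[dict]:
    gene = _entry(
        603136, "*", "CULLIN 3; CUL3",
        phenotype_map=[
            {
                "phenotypeMimNumber": 619239,
                "phenotype": "Neurodevelopmental disorder with or without autism or seizures",
                "phenotypeMappingKey": 3,
                "phenotypeInheritance": "Autosomal dominant",
            },
            {
                "phenotypeMimNumber": 614496,
                "phenotype": "Pseudohypoaldosteronism, type IIE",
                "phenotypeMappingKey": 3,
                "phenotypeInheritance": "Autosomal dominant",
            },
        ],
    )
    phenotype = _entry(
        619239, "#",
        "NEURODEVELOPMENTAL DISORDER WITH OR WITHOUT AUTISM OR SEIZURES",
        sections={
            "molecularGenetics": (
                "Neurodevelopmental disorders with autism and seizures have been "
                "described in several cohorts. The clinical spectrum was reviewed "
                "by {1:Nakashima et al. (2020)}. In 6 unrelated patients with a "
                "neurodevelopmental disorder, {2:Thiffault et al. (2019)} "
                "identified de novo heterozygous mutations in the CUL3 gene. "
                "Functional consequences of the variants were reported by "
                "{3:Dubey et al. (2020)}. Additional affected individuals were "
                "described by {4:Blackburn et al. (2020)} and "
                "{5:Iwafuchi et al. (2021)}."
            )
        },
        references=[
            (1, "Nakashima", 2020, 91000001),
            (2, "Thiffault", 2019, 91000002),
            (3, "Dubey", 2020, 91000003),
            (4, "Blackburn", 2020, 91000004),
            (5, "Iwafuchi", 2021, 91000005),
        ],
    )
    return [gene, phenotype]


def _mto1() -> list[dict]:
    gene = _entry(
        614667, "*", "MITOCHONDRIAL tRNA TRANSLATION OPTIMIZATION 1; MTO1",
        phenotype_map=[
            {
                "phenotypeMimNumber": 614702,
                "phenotype": "Combined oxidative phosphorylation deficiency 10",
                "phenotypeMappingKey": 3,
                "phenotypeInheritance": "Autosomal recessive",
            }
        ],
    )
    phenotype = _entry(
        614702, "#", "COMBINED OXIDATIVE PHOSPHORYLATION DEFICIENCY 10",
        sections={
            "molecularGenetics": (
                "In two siblings with combined oxidative phosphorylation "
                "deficiency, {1:Ghezzi et al. (2012)} identified a homozygous "
                "missense mutation in the MTO1 gene. The variant segregated "
                "with the disorder in the family."
            ),
            "animalModel": (
                "Functional studies in yeast demonstrated that the mutant "
                "protein failed to restore respiratory growth "
                "{1:Ghezzi et al. (2012)}."
            ),
        },
        references=[(1, "Ghezzi", 2012, 91000011)],
    )
    return [gene, phenotype]


def _klkb1() -> list[dict]:
    gene = _entry(
        229000, "*", "KALLIKREIN B, PLASMA; KLKB1",
        phenotype_map=[
            {
                "phenotypeMimNumber": 612423,
                "phenotype": "Prekallikrein deficiency",
                "phenotypeMappingKey": 3,
                "phenotypeInheritance": "Autosomal recessive",
            }
        ],
    )
    phenotype = _entry(
        612423, "#", "PREKALLIKREIN DEFICIENCY",
        sections={
            "molecularGenetics": (
                "Coagulation defects associated with KLKB1 were previously "
                "reported in 3 patients by {1:Hathaway et al. (1965)}. In a "
                "patient with prekallikrein deficiency, "
                "{2:Lombardi et al. (2003)} identified a homozygous mutation "
                "in the KLKB1 gene."
            )
        },
        references=[
            (1, "Hathaway", 1965, 91000021),
            (2, "Lombardi", 2003, 91000022),
        ],
    )
    return [gene, phenotype]


def _ccdc65() -> list[dict]:
    gene = _entry(
        611088, "*", "COILED-COIL DOMAIN-CONTAINING PROTEIN 65; CCDC65",
        phenotype_map=[
            {
                "phenotypeMimNumber": 615504,
                "phenotype": "Ciliary dyskinesia, primary, 27",
                "phenotypeMappingKey": 3,
                "phenotypeInheritance": "Autosomal recessive",
            }
        ],
    )
    phenotype = _entry(
        615504, "#", "CILIARY DYSKINESIA, PRIMARY, 27",
        sections={
            "molecularGenetics": (
                "In patients with primary ciliary dyskinesia, mutations in the "
                "CCDC65 gene were identified by {1:Austin-Tse et al. (2013)} "
                "and {2:Horani et al. (2013)}. Both studies used exome "
                "sequencing to establish the association."
            )
        },
        references=[
            (1, "Austin-Tse", 2013, 91000031),
            (2, "Horani", 2013, 91000032),
        ],
    )
    return [gene, phenotype]


@dataclass(frozen=True)
class WorkedCase:
    name: str
    gene_raw: dict
    phenotype_raw: dict
    expected_ref_number: int
    expected_year: int
    expected_pmid: int


def worked_example_entries() -> list[dict]:
    """All worked-example entries as raw OMIM-dialect documents."""
    return [*_cul3(), *_mto1(), *_klkb1(), *_ccdc65()]


def worked_example_cases() -> list[WorkedCase]:
    """The same entries paired with the expected discovery resolution."""
    cul3, mto1, klkb1, ccdc65 = _cul3(), _mto1(), _klkb1(), _ccdc65()
    return [
        WorkedCase("CUL3", cul3[0], cul3[1], 2, 2019, 91000002),
        WorkedCase("MTO1", mto1[0], mto1[1], 1, 2012, 91000011),
        WorkedCase("KLKB1", klkb1[0], klkb1[1], 2, 2003, 91000022),
        WorkedCase("CCDC65", ccdc65[0], ccdc65[1], 1, 2013, 91000031),
    ]
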