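"""End-to-end extraction of one discovery record.

Runs the full workflow on the CUL3-style worked fixture: candidate
enumeration from the phenotype map, discovery-publication resolution with
the gene symbol as anchor, cohort pattern matching, and organism search.
"""

from gdamine.extract import Extractor
from gdamine.filters import extract_gda_candidates
from gdamine.fixtures import worked_example_cases
from gdamine.omim import parse_entry

case = worked_example_cases()[0]  # CUL3 / neurodevelopmental disorder
gene = parse_entry(case.gene_raw)
phenotype = parse_entry(case.phenotype_raw)

gda = next(c for c in extract_gda_candidates(gene)
           if c.phenotype_mim == phenotype.mim_number)
record = Extractor().extract_discovery(gene, phenotype, gda)

print(f"association         : gene {record.gene_mim} -> phenotype {record.phenotype_mim}")
print(f"discovery           : {record.discovery_year} (PMID {record.discovery_pmid})")
print(f"cohort              : {record.cohort_count} "
      f"({'unrelated' if record.cohort_unrelated else 'related'}), "
      f"same study as discovery: {record.cohort_same_study}")
print(f"organisms           : {[(o.species, o.year) for o in record.organisms] or 'none'}")
print(f"discovery provenance: {record.provenance['discovery']}")
# The paragraph holds five citations; the 2019 study wins because it is
# the only one co-sentential with the gene anchor (tier=same_sentence).
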