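"""Common-interval detection on the packaged published tables.

Loads the transcribed summary tables (19 trait-matched rows, 40 pleiotropic
rows), re-runs Class1 detection and the gene overlay, and classifies the
Class2 data resources — reproducing the published counts.
"""

from earmeta import classify_resource, find_class1, load_fixtures, overlay_known_genes
from earmeta.core import DataResource

fixtures = load_fixtures()

class1 = find_class1(fixtures.table1_qtl_clusters(), fixtures.table1_qtn_clusters())
annotated = overlay_known_genes(class1, fixtures.table1_known_gene_models())
with_gene = sum(bool(ci.known_genes) for ci in annotated)
print(f"Class1 common intervals (KRN, QTL×QTN): {len(class1)}")
print(f"  ... containing a known cloned gene : {with_gene}")

cis2 = fixtures.table2_cis()
both = sum(classify_resource(ci) is DataResource.BOTH for ci in cis2)
arity3 = sum(len(ci.traits) == 3 for ci in cis2)
print(f"Class2 pleiotropic intervals           : {len(cis2)}")
print(f"  ... from both data resources         : {both}  (single: {len(cis2) - both})")
print(f"  ... spanning three traits            : {arity3}  (two: {len(cis2) - arity3})")
# 19 / 5 / 13 / 6: the environmentally stable loci and the pleiotropic loci a
# breeder would prioritize, with the gene-bearing subset already cloned.
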