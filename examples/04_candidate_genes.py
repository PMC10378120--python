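"""Candidate-gene prioritization inside a cluster.

Screens a mini gene annotation against one QTL cluster: only genes that
overlap the cluster, are expressed in the female inflorescence meristem, and
match the pathway vocabulary are assigned.
"""

from earmeta import assign_candidates, default_vocabulary
from earmeta.core import GeneModel, GenomicInterval, QtlCluster

cluster = QtlCluster("qEL7_like", "EL", "7", GenomicInterval.from_mb("7", 120.0, 125.0))

genes = [
    GeneModel("g_aco", "7", GenomicInterval.from_mb("7", 121.0, 121.01),
              annotation="1-aminocyclopropane-1-carboxylate ACC oxidase",
              im_expressed=True),
    GeneModel("g_silent", "7", GenomicInterval.from_mb("7", 122.0, 122.01),
              annotation="ACC oxidase", im_expressed=False),      # fails expression gate
    GeneModel("g_neutral", "7", GenomicInterval.from_mb("7", 123.0, 123.01),
              annotation="hypothetical protein", im_expressed=True),  # no pathway hit
    GeneModel("g_outside", "7", GenomicInterval.from_mb("7", 180.0, 180.01),
              annotation="ACC oxidase", im_expressed=True),       # outside the cluster
]

for a in assign_candidates([cluster], genes, default_vocabulary()):
    print(f"candidate {a.gene_id} in {a.cluster_id}: "
          f"pathways={sorted(a.matched_pathways)} keywords={list(a.keyword_hits)}")
# Only g_aco passes all three gates — the ethylene-pathway pattern by which
# ACO2 was recognized as the causal gene of the qEL7 ear-length locus.
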