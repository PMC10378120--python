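"""Cluster calling on a small hand-built dataset.

Three studies report overlapping KRN QTLs around 10–12 Mb on Chr1 (a
cluster), two more report an isolated locus (no cluster); a GWAS panel has
three KRN QTNs within 0.2 Mb (a hotspot) plus scattered background.
"""

from earmeta import call_qtl_clusters, call_qtn_clusters
from earmeta.core import GenomicInterval, QtlRecord, QtnRecord

MB = 1_000_000


def qtl(rid, study, start_mb, end_mb):
    iv = GenomicInterval.from_mb("1", start_mb, end_mb)
    return QtlRecord(rid, study, "KRN", "1", iv)


records = [
    qtl("q1", "StudyA", 10.0, 11.2),
    qtl("q2", "StudyB", 10.5, 11.8),
    qtl("q3", "StudyC", 11.0, 12.0),   # 3 distinct studies -> cluster
    qtl("q4", "StudyA", 40.0, 41.0),
    qtl("q5", "StudyB", 40.5, 41.5),   # only 2 studies -> no cluster
]
for c in call_qtl_clusters(records):
    print(f"QTL cluster {c.cluster_id}: {c.interval} "
          f"({c.n_studies} studies: {sorted(c.supporting_studies)})")

qtns = [
    QtnRecord(f"n{i}", "GwasA", "KRN", "1", pos)
    for i, pos in enumerate([10_000_000, 10_100_000, 10_200_000, 50_000_000])
]
for c in call_qtn_clusters(qtns):
    print(f"QTN cluster {c.cluster_id}: {c.interval} ({c.qtn_count} QTNs, "
          f"width {c.interval.length_mb:.2f} Mb)")
# Exactly one cluster of each kind is called; the QTN cluster is exactly one
# window (0.5 Mb) wide because a single anchored window qualifies.
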