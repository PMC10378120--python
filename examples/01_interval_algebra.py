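"""Interval algebra on published cluster coordinates.

Builds the Chr5 TD1-locus pair — a QTL cluster (60.99–67.09 Mb) and a QTN
cluster (65.79–66.29 Mb) — and computes their overlap, the common
intersection, and a window merge.  All coordinates are integer base pairs in
half-open [start, end) convention.
"""

from earmeta import GenomicInterval, intersection, merge_overlapping, overlaps, union_span

qtl = GenomicInterval.from_mb("5", 60.99, 67.09)
qtn = GenomicInterval.from_mb("5", 65.79, 66.29)

print(f"QTL cluster : {qtl}  ({qtl.length_mb:.2f} Mb)")
print(f"QTN cluster : {qtn}  ({qtn.length_mb:.2f} Mb)")
print(f"overlap?    : {overlaps(qtl, qtn)}")
print(f"intersection: {intersection([qtl, qtn])}")
print(f"union span  : {union_span([qtl, qtn])}")

windows = [GenomicInterval("5", 0, 500_000), GenomicInterval("5", 400_000, 900_000)]
print(f"merged windows: {merge_overlapping(windows)}")
# The intersection (65.79–66.29 Mb) is the common interval both mapping
# strategies point at — the region a fine-mapping effort would target.
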