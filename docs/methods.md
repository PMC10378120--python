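# Methods

## The problem

Maize ear traits — kernel row number (KRN), ear length (EL), ear diameter
(ED), kernel number per row (KNPR), ear weight (EW), cob diameter (CD),
kernel weight per ear (KWPE), cob weight (CW) — are quantitatively inherited
components of grain yield. Decades of linkage mapping (QTL studies) and
genome-wide association studies (GWAS, yielding trait-associated SNPs, here
called QTNs) have produced hundreds of published loci on heterogeneous
marker systems and assembly versions. `earmeta` implements the meta-analysis
that turns such a curated compendium into actionable loci: hotspot regions
supported by multiple independent studies, regions seen by both mapping
strategies (environmentally stable loci), regions affecting several traits
(pleiotropic loci), and prioritized candidate genes inside them.

## Coordinate model

All loci live on integer base-pair coordinates in half-open `[start, end)`
convention (BED-compatible), 0-based. Published tables print megabases to
two decimals; conversion is `bp = round(Mb × 10⁶)`, which makes the
Mb → bp → Mb round trip exact for printed values. Chromosomes are opaque
string labels; the natural numeric order of "1".."10" is used only for
sorting reports. Strand is carried on gene models but ignored by all
interval logic, since mapped loci are strandless. Abutting intervals
(`a.end == b.start`) do not overlap.

## Normalization

The original resolution of flanking-marker sequences and cross-assembly
positions used sequence search and remote remap services; `earmeta`
replaces both with deterministic offline lookup tables: a `MarkerMap`
(marker name → single position; multi-mapping markers are an explicit
simplification, first exact name match wins) and a `PositionLookup`
((chrom, source position) → target position, with an optional identity
fallback). Design points:

* a marker pair in reversed order is reordered (marker order in source
  tables is unreliable); coincident markers yield the minimal 1 bp interval
  `[p, p+1)` so the record stays usable;
* a pair on two different chromosomes is rejected as a "trans-marker pair";
* unresolvable records are never dropped silently — they go to a rejects
  report, and resolved + rejected always equals the input count.

## QTL clusters

Within one (trait, chromosome) group, records are grouped into connected
components of the interval-overlap graph (single sweep over sorted starts).
A component is emitted as a cluster when its members come from ≥ 3 distinct
studies ("independent studies" = distinct `study_id` values; the curation
dialect makes the unit explicit). Because long intervals chain easily, a
cluster whose region exceeds 30 Mb requires ≥ 5 distinct studies; a large
component failing that is discarded whole rather than recursively split —
the simplest reading of the escalated criterion (the treatment of failing
large components is not documented in the source analyses; splitting is a
possible alternative we deliberately did not implement).

The cluster region defaults to the **union span** of the component: reported
cluster extents reach tens of Mb, which is incompatible with member
intersection, while the ~0.02 Mb lower end is consistent with tightly
co-located fine-mapped members. A `coverage` region mode is provided for
sensitivity analysis: maximal runs where the number of distinct studies
covering a point (each study counted once per point, its own intervals
merged first) reaches the threshold. Both modes are oracle-tested.

Note the escalation rule makes cluster calling non-monotone in the record
set (an added record can push a component past 30 Mb); the monotonicity
property "adding records never removes support" holds exactly when the
escalation is disabled, and the tests check it in that regime.

## QTN clusters

A QTN cluster is a region holding ≥ 3 same-trait QTNs within a 0.5 Mb
sliding window. Windows are **anchored at QTN positions**: for each position
`p`, the full-width window `[p, p + w)` qualifies iff it contains ≥ 3
same-trait positions. Qualifying windows are merged; each merged extent is
one cluster, and every same-trait QTN inside the extent is a member. The
anchored choice is deliberate: reported cluster boundaries are not on a
fixed grid (excluding tiling), and many reported widths are exactly 0.50 Mb,
which anchored full-width windows reproduce while a continuous-sliding union
generically widens the extent backwards past the first member. The
continuous variant (`window_mode="continuous"`) is available for sensitivity
checks and is tested against an exhaustive window-start scan.

Consequences, both enforced by tests: no cluster is ever narrower than the
window (the reported 0.5 Mb floor), and a cluster exceeds the window width
only when at least two qualifying windows chain. QTNs from different studies
at the identical position count separately (they are distinct association
evidence); `dedup_pos` collapses them on request. Traits never mix within a
window.

## Common intervals

**Class1** (environmentally stable): every (QTL cluster, QTN cluster) pair
with equal trait and chromosome whose intervals overlap; the reported region
is the intersection. Counting is pair-level — one QTL cluster overlapping
two QTN clusters yields two common intervals — because the published
pair table repeats a QTL cluster against distinct QTN clusters. Class1 is
computed for every trait; that only KRN survives in the published data is a
data property, not a code restriction.

**Class2** (pleiotropic): on the pooled QTL + QTN clusters per chromosome,
maximal sets of *mutually* overlapping intervals covering ≥ 2 distinct
traits. For interval graphs, every maximal clique is the stabbing set at a
point just left of some right endpoint, so cliques are found by stabbing and
pruning subsets; by the Helly property, pairwise overlap guarantees a
non-empty common intersection, which is the reported region (published
pleiotropic regions are far narrower than any plausible member cluster,
consistent with intersection). Member sets that are subsets of other kept
sets are pruned so nested cliques are not double-reported. The data-resource
label is `both` iff members include at least one cluster of each kind.
Whether the original analysis required mutual overlap or only pairwise
chaining cannot be discriminated from the published rows; mutual overlap is
the default, and `class2_mode="chain"` uses connected components instead
(when a chained component shares no common point, the spanning interval is
reported — such regions are wider than any clique region and should be read
as a sensitivity check, not a locus).

**Gene overlay.** A known gene marks a common interval when its span
overlaps the CI's common region (the QTL∩QTN intersection for Class1, the
member intersection for Class2). We match against the common region rather
than either member interval because the common region is what "the CI
possesses a gene" means, and because sibling pair-rows sharing one QTL
cluster would otherwise inherit each other's genes.

## Candidate genes

A gene is assigned as a candidate for a cluster when it (a) overlaps the
cluster interval (any-overlap, consistent with the rest of the pipeline),
(b) is expressed in the female inflorescence meristem (IM) — the expression
universe is an input ID list; no quantification is performed — and (c)
matches the pathway vocabulary, via pre-computed tags or a case-insensitive
substring hit in its annotation text. The packaged vocabulary distils the
molecular modules known to regulate female-inflorescence development (auxin,
TALE, CLV-WUS, ROS, RAMOSA, ethylene, miR172, WD40); it is a curatorial
reading, shipped as YAML and fully user-overridable. Substring matching is
deliberately plain — reproducible and auditable — at the cost of occasional
over-matching on short keywords; removing a keyword can never increase the
assignment count (tested anti-monotonicity).

## Fixtures

The packaged tables transcribe the published summaries: 19 trait-matched
common intervals and 40 pleiotropic intervals, with printed 2-decimal Mb
endpoints converted exactly to bp and SHA-256 checksums guarding the files.
One row's chromosome cell is blank in the printed source and is recorded as
Chr5 with a provenance note (its neighbours and interval continue the Chr5
series). The source prints gene names without coordinates, so known-gene
records are synthetic 1 kb point genes placed at the midpoint of their host
common interval (placement documented in the file and docstrings); where one
cell lists two genes shared by two sibling rows, one gene is placed per row.
These placements make the gene-overlay worked examples exact without
inventing real coordinates.

## Synthetic data

The generator's defaults define the study conditions used throughout the
tests: 10 chromosomes of 250 Mb (uniform; real maize lengths are irrelevant
to the algorithms), a pool of 8 studies, 8 traits, 6 planted QTL sites
(3–6 supporting studies each, member half-spans of 1–8 Mb around the site
center), one background QTL per study per trait (1–10 Mb long, uniform), 6
planted QTN hotspots (3–5 QTNs within 0.2–0.4 Mb), Poisson(3) background
QTNs per trait per chromosome, 150 neutral background genes with
Bernoulli(0.5) IM expression, and 3 planted pathway genes. These sizes are
desk-scale: large enough that every code path (chaining, escalation,
multi-trait pooling) is exercised, small enough that the whole suite runs in
seconds.

Guarantees, enforced rather than hoped for:

* planted QTL members all contain their site center, so each site is one
  overlap component with the configured distinct-study support;
* background QTL of a trait never touch that trait's planted intervals, and
  the background-only distinct-study support is re-checked to stay below the
  calling threshold at every point — a violating draw is redrawn, and an
  infeasible regime raises an explicit error after bounded retries;
* background QTN density is checked against the analytic spurious-triple
  bound `n·C(n−1,2)·(w/L)² < 0.01` per (trait, chromosome) and draws are
  additionally rejection-sampled so no background triple fits one window and
  no background QTN lands within a window of a same-trait hotspot center;
* planted genes sit at site centers with a vocabulary keyword in their
  annotation; background gene annotations are drawn from a neutral list that
  matches no vocabulary keyword.

Everything is deterministic under (config, seed): each generator draws from
its own seeded substream, and outputs are byte-identical across runs.

What the generator does **not** emulate: linkage disequilibrium, effect
sizes, phenotypes, uneven chromosome lengths, assembly errors, or curation
noise beyond inverted marker pairs. Passing recovery tests therefore shows
the algorithms are correct on data with the assumed structure, not that the
thresholds are well-calibrated for any particular real compendium.

## Numerical and degenerate-input choices

* Inverted printed intervals (start > end) are swapped with a warning, not
  rejected; printed point intervals (start = end) are widened to 1 bp.
* Duplicate records are retained by default (distinct-study counting happens
  at study level); deduplication is an explicit flag.
* Unknown trait codes are kept, upper-cased, and registered with a warning —
  the trait registry is extensible.
* All outputs are deterministically sorted (chromosome natural order, then
  start); re-running the pipeline on identical inputs is byte-identical.
* Empty inputs yield empty outputs (empty BED file, all-zero summary), never
  errors.

## Problem sizes used in the checks

The acceptance script recomputes: the Class1 pair count, gene-overlay count
and Class2 resource split on the packaged 19- and 40-row tables, and the
minimum QTN-cluster width over 50 synthetic panels (~300 clusters) seeded
from the command-line seed. The randomized oracle-equivalence suites run on
instances of ≤ 60 records against brute-force implementations (transitive
closure over the pairwise-overlap matrix, double-loop window counting,
quadratic all-pairs scans, exhaustive subset enumeration for cliques on
≤ 12 clusters), and planted-structure recovery runs over seeds 1–20.

## Known limitations

* Marker resolution is single-position; multi-mapping markers and chain-file
  liftover are out of scope.
* The >30 Mb escalation discards failing components whole; no sub-region
  rescue is attempted.
* The vocabulary screen is keyword-based; it neither scores matches nor
  disambiguates gene families.
* Appendix-scale compendium counts (hundreds of clusters from thousands of
  records) require the external curated tables, expression data and genome
  annotation; the pipeline supports that scale but the packaged checks are
  desk-scale by design.
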