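# Methods

## Coordinates and conventions

All in-memory coordinates are 0-based half-open on the forward strand of a
single contig; GFF3 output converts to 1-based closed at the writer and
nowhere else. Features never span contigs: assembly gaps inside
pseudochromosomes appear as N-runs within one sequence and are handled by
the locus merge rule, not by cross-contig logic. Strain is the unit of
aggregation; species, phylotype, location and biome groupings come only
from the metadata table and are never inferred from sequence.

## Array detection

The detector finds repeat-spacer arrays de novo in four phases per contig:

1. **Seeding.** Exact k-mers (`seed_k`, default 16) recurring at distances
   compatible with a repeat period — repeat length plus spacer length,
   bounded by the configured repeat-length window and spacer-length
   fractions — are chained.
2. **Boundary extension.** The shared k-mer of a chain is extended left
   and right while the aligned columns of the putative repeat occurrences
   keep a majority base at ≥ 0.7 frequency, up to the maximum repeat
   length. The majority consensus of the extended windows becomes the
   provisional repeat.
3. **Walk and fill-in.** Starting from the chained occurrences, the
   contig is scanned outward at spacer-compatible distances for further
   windows whose identity to the consensus is at least
   `repeat_identity_min`; this recovers mutated repeat copies that exact
   seeding missed and heals chains broken by a mutated middle repeat.
   Edges are then re-refined over *all* occurrences: with only two or
   three seed anchors a boundary column can agree by chance (probability
   ~1/4 per column), so the column-majority test is repeated on the full
   occurrence set, where it is sharp.
4. **Acceptance.** Occurrence runs are split wherever a gap leaves the
   spacer-length window; runs of ≥ 2 repeats become candidate loci.
   Overlapping candidates are resolved deterministically: more repeats,
   then longer span, then leftmost.

A locus is **confirmed** when it has at least `min_repeats_confirmed`
(default 3) occurrences, all within `repeat_identity_min` (default 0.8) of
the consensus, and its spacers' mean pairwise ungapped identity is at most
`max_spacer_self_identity` (default 0.8) — the last condition rejects
tandem repeats, whose "spacers" are copies of one another. Everything
weaker is *questionable* and excluded from downstream analysis. The
confidence rule is an explicit approximation of the "confirmed" category
of interactive repeat finders, whose exact criteria are not published;
defaults (repeat window 21–48 nt, spacer bounds 0.6×–2.5× repeat length)
are this package's choices, anchored to observed repeat lengths of 29 nt
(I-E, I-B) and 37 nt (I-C, I-U) and overridable in configuration.

Locus size is measured from the first repeat start to the last repeat end;
no flanking leader sequence is included. Adjacent loci are merged when
separated by ≤ `merge_gap_max` (default 2000 nt) consisting of an N-run
(up to 10 non-N bases tolerated at each edge) and their consensus repeats
are identical or exact reverse complements; the gap becomes a spacer
interval of the merged locus so the tiling invariant
(spacers = repeats − 1) is preserved.

**Orientation.** The leader end is placed adjacent to an associated cas
cluster when one exists; otherwise opposite the most degenerate terminal
repeat (the decayed repeat marks the trailer); otherwise unknown. Loci are
always reported on the forward strand — orientation is metadata, never a
coordinate flip. With unknown orientation, trailer indices default to
forward-strand order, a deterministic convention that keeps homologous
arrays comparable when they were planted or sequenced in the same
orientation.

**Paired loci.** Two confirmed arrays flanking one cas cluster within the
association distance are reported as a pair when one consensus is the
exact reverse complement of the other.

## Cas typing

Cas clusters are maximal runs of cas-vocabulary genes with intergenic gaps
≤ 500 nt; an intervening non-cas gene splits a run. Classification is
purely set-based over normalized gene names (case-insensitive, aliases
such as cas8e→cse1, csd1→cas8c, cas8b→cst1 applied from an editable YAML):
the highest-priority signature whose required set is present and forbidden
set absent wins; clusters without *cas3* are never classified, since
*cas3* defines type I. The shipped table encodes I-E {cas3, cse1, cse2},
I-C {cas3, cas8c}, I-B {cas3, cst1} (the canonical cas8b position is
occupied by a larger cst1-related gene in this genus), I-U_csb3
{cas3, csb3}, I-U_csx17 {cas3, csx17; cas1 forbidden} and I-U_Sa
{cas3, csb1, csb2; csb3, csx17, cas1 forbidden}. The exact gene orders of
the three I-U subtypes are known only from operon diagrams, so the table
is deliberately editable rather than hard-coded. A cluster is *complete*
when it carries the cas1–cas2 adaptation module on top of its required
set; subtypes whose definition forbids *cas1* are complete on their
required set alone. Loci associate with the nearest cluster on the same
contig within 1000 nt edge-to-edge.

GC contrast computes (G+C)/(A+C+G+T) over a region and over the whole
genome (N excluded from denominators), reported to 0.1 percentage points;
a markedly lower operon GC than the genomic background indicates
horizontal acquisition.

## Spacer catalogue

Spacers are deduplicated by exact identity of their canonical form — the
lexicographic minimum of the sequence and its reverse complement — because
array strand is not always known and strand ambiguity must not split
identical spacers; the raw-strand grouping is retained alongside for
comparison with strand-aware workflows. A canonical sequence is *shared*
when carried by at least two distinct strains; multiple copies within one
strain count once. No mismatch tolerance exists at catalogue level;
near-identical spacers are the business of the variant analysis.

## Protospacer matching

Only 100%-identity spans are considered. A *perfect* hit covers the
entire spacer; a *partial* hit is a maximal exact common substring of at
least 18 nt — two-thirds of the average repeat length, the suggested
minimum for a functioning spacer. Seeded local alignment with word size 7,
post-filtered to ungapped 100%-identity hits of length ≥ 18, reports
exactly these maximal exact substrings (every exact span of ≥ 18 contains
a 7-word seed, and 100% identity forbids extension across a mismatch), so
exact substring search is the faithful, dependency-free equivalent; the
equivalence is property-tested against a sliding-window comparator.
Partial hits are computed for every target class but summarized as
headline numbers only for the known-MGE database. In summaries a spacer
counts once per target class however many targets it hits.

The self-targeting scan matches each strain's spacers against its own
contigs, excluding hits overlapping any detected locus ± 100 nt (the
margin is this package's choice); hits inside annotated prophage regions
are flagged, since self-targeting of a resident prophage is biologically
distinct from targeting a housekeeping gene. Encounter history reports the
trailer→leader positions of matches within each array, their index span,
and a `recent_only` flag when all matches sit in the leader-proximal
quarter.

## Array comparison

Homologous loci are grouped when their consensus repeats are identical (or
exact reverse complements) *and* they share at least one canonical spacer
— an operationalization chosen here, since no published criterion exists.
Alignment operates on spacer tokens rather than concatenated nucleotides:
identical spacers align in single columns, which is exactly the signal the
analysis interprets, and token LCS (longest common subsequence) is exact
for those columns while avoiding nucleotide-aligner heuristics; a
concatenated-nucleotide export is provided for external replication.
Progressive alignment orders arrays by descending length, ties by
strain_id, with a fixed traceback preference, so results are
deterministic. Group-specific blocks are maximal column runs occupied by
all members of exactly one declared group and no others; they are reported
as "deletion or insertion" events without polarity, which the alignment
cannot determine. Variant groups are equal-length canonical spacers
single-linked at Hamming distance ≤ 3 (matching the observed ≤ 3
polymorphic sites in a conserved 41-nt spacer), with ≥ 2 distinct
variants; a variant is location-exclusive when it occurs at exactly one
location.

## Statistics

Counts are normalized per Mb of genome or per gene count. The pipeline
screens groups with tie-corrected Kruskal-Wallis (chi-square p, k−1 df)
and runs pairwise Wilcoxon rank-sum tests only after a significant omnibus
result (p < 0.05), though each operation is callable independently. The
rank-sum test enumerates all rank assignments exactly when
n₁ + n₂ ≤ 10 — reproducible small-sample behaviour — and otherwise uses a
tie-corrected normal approximation with continuity correction.
Prophage-presence contrasts use the pooled-variance two-sample t-test
(df = n₁+n₂−2); count correlations use ordinary least squares with R²
equal to the squared Pearson correlation (R² defined as 0 for a constant
response). All tests are two-sided; no multiple-testing correction is
applied. The location-restriction fraction counts shared spacers confined
to one location *or* one biome (both components also reported
separately).

## Synthetic data generator

The generator emulates the statistical structure the analysis assumes.
Background sequence is i.i.d. at the configured GC (default 0.70, the
genus's genomic GC); repeats and spacers are drawn uniform-random and
frozen in the manifest, so at the simulated scale (≤ ~1 Mb per genome) no
unintended repeat structure arises. Defaults mirror the observed corpus:
4.4 arrays per strain (Poisson, minimum 1), subtype repeats of 29/37 nt,
60% of arrays cas-associated with operons drawn from all six subtype gene
orders, 1.3 prophages per strain of 12 kb, a 20-record known-MGE database,
12% of spacers given a planted protospacer (90% in prophages, 10% in the
MGE database; 20% of plantings partial, as a centred ≥ 18 nt fragment so
the partial rule is exercised away from spacer ends), 1% self-targeting
spacers (30% of them inside the strain's own prophage), 8–24 spacers of
34–41 nt per array, and a 20-spacer shared pool of which 40% is
location-restricted. Planted features are placed non-overlapping with
≥ 2.5 kb separation so cas association is unambiguous; clade-specific
blocks are planted by omitting a contiguous token run from every strain
outside the clade, making deletion and insertion indistinguishable by
construction, as in real subclade comparisons. Rounding of planted counts
is deterministic, so tests can assert exact fractions. Spacer turnover
over time is not modelled; placements are static.

What passing tests on this generator do show: lossless recovery of exact
planted structure, correct threshold behaviour, correct bookkeeping of
sharing, restriction and category fractions, and robustness to per-base
repeat mutation. What they do not show: performance on diverged real
repeats with indels, on low-complexity or repeat-rich genomic backgrounds,
on fragmented assemblies, or on databases where near-identical (not
identical) protospacers matter.

## Problem sizes and numerical choices

The shipped test suites run the full pipeline on 8–10 strains of 0.25–1 Mb
each — sizes chosen so every stage, including two determinism reruns,
completes comfortably on a single CPU while still containing ~50 arrays
and ~800 spacers. Matching is pure string search and scales linearly in
target size; detection is dominated by k-mer indexing (~2 s per Mb).
Ties are broken by fixed rules throughout (base order A<C<G<T in
consensus votes; more repeats / longer span / leftmost in overlap
resolution; sorted processing in single-linkage), so every output is
byte-identical across reruns with the same seed.

## Known limitations

- The detector targets direct-repeat arrays with ungapped repeat copies;
  repeat variants with indels shift the column grid and can truncate a
  locus at the indel.
- Subtype signatures are set-based; gene order and pseudogenization are
  not examined.
- The homologous-locus criterion (identical consensus + one shared
  spacer) can merge loci that share a repeat family and a single mobile
  spacer, and can split true homologs whose consensus decayed.
- Exact matching cannot find protospacers that have diverged by even one
  substitution within every ≥ 18 nt window; fractions on real, diverged
  MGE databases are therefore lower bounds.
- The Wilcoxon exact enumeration is limited to n₁+n₂ ≤ 10 by
  combinatorial cost; beyond that the continuity-corrected approximation
  is used.
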