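# Methods

## Problem setting

A splice-switching antisense oligonucleotide (AON) is delivered together
with a scrambled control; RNA-seq of treated cells is analyzed for
differential splicing between the scrambled and each targeting condition.
The package answers two questions downstream of the splicing tools: which
predicted AON binding sites could explain which splicing events
(hybridization-dependent off-targets), and which events deserve priority
because their effect exceeds the intended one.

## Binding-site search

**Search space.**  One pre-spliced record per gene: the genomic span of the
gene's exon union, reverse-complemented for minus-strand genes so the stored
sequence is the sense pre-mRNA.  A per-gene (rather than per-transcript)
database deduplicates transcript redundancy and makes gene attribution
direct; a locus inside two overlapping genes yields one site per gene
record.  Only this sense strand is searched — the strand an antisense
oligonucleotide base-pairs with.

**Query.**  The AON target sequence: reverse complement of the RNA sequence
with U→T.

**Distance model.**  Unit-cost Levenshtein distance; "mismatches" therefore
include substitutions, insertions and deletions, with no affine gap cost.
`N` or any non-ACGT genome base mismatches every query base, so ambiguous
sequence can never produce an artificially perfect hit.

**Algorithm.**  Semi-global alignment (full query, free text ends).  The
minimal distance for every alignment end position is computed by a
vectorized dynamic program over the query rows; the within-row dependency
`D[i][j] = min(..., D[i][j-1]+1)` is resolved exactly by a prefix-minimum
scan of `candidate[j] − j`.  End positions with distance ≤ k are refined by
a small tuple-cost DP (distance, then indel count, then leftmost start —
the deterministic tie-break) that also yields the alignment trace.
Overlapping candidate alignments are deduplicated to one hit per locus:
intervals are chain-merged and the minimal (distance, indels, start, end)
representative kept.  `max_distance` defaults to 3 and is configurable
(binding sites with more mismatches can still act; they are simply not
predicted by default).

**Oracle.**  `brute_force_oracle` computes the same per-end-position
distances by a plain column-major DP in pure Python and shares only the
locus-refinement/dedup policy, giving an independent route for equivalence
tests.  A third route (edlib infix alignment over each hit's context) is
used in tests to confirm reported distances.  The dedup policy is a stated
convention of this package, not a claim of bit-compatibility with any
public search engine.

## Event handling

**Coordinates.**  Internally everything is 0-based half-open.  GTF (1-based
inclusive), rMATS (`*_0base` starts with half-open ends) and Whippet
(`chrom:start-end`, 1-based inclusive) are converted at their readers.

**Filters.**  rMATS: an event survives iff *every* replicate in *both*
groups has IJC+SJC ≥ 10 and FDR < 0.05 (strict).  Whippet: probability
≥ 0.90 and |ΔΨ| ≥ 0.10.  The Whippet cutoffs are common practice rather
than universal; both are configurable and logged.

**Orientation.**  ΔΨ = Ψ(scrambled) − Ψ(targeting) everywhere, so a
positive ΔΨ is the induced skip fraction.  rMATS `IncLevelDifference`
(group1 − group2) is used as-is when group 1 is the scrambled condition and
negated otherwise; Whippet `DeltaPsi` is flipped when group A is the
targeting condition.

**Standardized region.**  SE → the skipped exon; RI → the retained intron
(between the flanking exons); A5SS/A3SS → the set difference between the
long and short exon variants.  Whippet node coordinates already denote this
region.  Degenerate alternative-splice-site events (long = short) are
errors.

**Consensus.**  A match requires same gene, event type and strand plus
standardized-region overlap (default) or equality (`exact` mode, since the
cross-comparison identity keys are exact).  One consensus row per matched
rMATS event: rMATS distinguishes flanking regions, so one Whippet event may
legitimately back several consensus rows.  If several Whippet events match
one rMATS event, the largest-overlap (then closest-ΔΨ, then leftmost) one
is kept.  The consensus effect size is the arithmetic mean of the two
oriented ΔΨ values; the identity key is the tuple (event type, contig,
rMATS primary coordinates, rMATS flanking coordinates, Whippet
coordinates).

## Classification

**Linkage window.**  From the furthest ends of the flanking exons (plus the
event region itself) extended by `pad` = 200 bp on *both* sides — the
phrasing "plus 200 bp" is one-sided-ambiguous and the symmetric window is
the conservative superset.  A5SS/A3SS events carry a single annotated
flank; their windows still extend `pad` beyond the event region on the
unannotated side and the row is flagged `single_flank`.  Windows are
clamped at position 0.

**Matching.**  A site matches an event iff the start *or* end coordinate of
its closed genomic footprint lies inside the half-open window.  Matches are
kept separately for targeting-AON and scrambled-AON sites; scrambled
matches are reported but never exclude an event from other categories.

**Specificity.**  An event is AON-specific iff its identity key occurs in
exactly one targeting comparison of the experiment (evaluated within the
experiment; cross-experiment agreement is a separate replication report).

**Flags.**  `hybridization_dependent` = matched-to-targeting AND
AON-specific.  The intended event (unique consensus event matching the
AON's declared target gene/type/region; ambiguity is an error, absence is
legal) is included in the matched and specific counts but excluded from the
larger-than-intended count; when no intended event exists,
`larger_than_intended` is emitted as NA rather than false.

## Synthetic data

The generator emulates the study design, not the sequencing: no reads, no
alignment — junction-count tables and `.diff` files directly.

* **Genome**: uniform-random bases; non-overlapping multi-exon genes
  (default 5–7 exons of 80–200 bp, introns 250–450 bp — comfortably above
  twice the AON length so any intron can host a binding site), intergenic
  gaps of 600–1000 bp so that decoy genes stay well clear of every linkage
  window, two contigs.
* **Sites**: for each planted site a variant of the AON target sequence at
  an exact edit distance (rejection-sampled until the Levenshtein distance
  matches) is written into the gene — inside a planted event's linkage
  window for linked sites (including an exon-border placement mode), in
  dedicated decoy genes for unlinked sites.  Every planted locus is
  re-verified by scanning its gene; accidental background matches anywhere
  in the genome are removed by mutating a matched base of the offending
  alignment away from both genome and query (guaranteed progress), so the
  finished genome scans to exactly the planted truth.
* **Counts**: with planted inclusion ψ and fixed length-normalization
  constants IncFormLen = 198, SkipFormLen = 99, inclusion reads are
  IJC ~ Binomial(depth, 2ψ/(1+ψ)) and SJC = depth − IJC per replicate, so
  the length-normalized Ψ reproduces ψ in expectation.  The default is pure
  binomial; a beta-binomial overdispersion knob exists but is off.
* **Significance fields**: rMATS p-values are two-sided Fisher exact tests
  on pooled group counts with Benjamini–Hochberg FDR within each event-type
  file — an emulation of the file semantics, *not* of rMATS's
  likelihood-ratio framework.  The Whippet probability is the fraction of
  100 seeded bootstrap resamples of the pooled counts whose ΔΨ keeps the
  planted sign — a stand-in for Whippet's posterior; downstream code only
  thresholds it.
* **Default scenario**: three targeting AONs (the published 18–20-mer
  sequences) plus one scrambled control; one intended exon skip per AON at
  ΔΨ = 0.40 with scrambled-group Ψ ≈ 1; per comparison 3 linked and 4
  unlinked specific off-targets, 2 scrambled-linked events, 5 shared
  background events present in all comparisons, 3 rMATS-only and 3
  Whippet-only false positives, 1 low-coverage event; one deliberately
  "toxic" AON (the ATXN3 analog) carries 8 extra events; 6 replicates per
  group at depth 100 (the classification tests use depth 200).  Planted
  effect sizes keep ≥ 0.1 margin from the intended 0.40 so the
  larger-than-intended truth labels are stable against counting noise.
  Negative-ΔΨ events start from a mirrored low scrambled baseline so both
  group Ψ values stay in [0, 1].
* **Manifest**: a JSON file (schema-versioned) recording every planted site
  (coordinates, distance, linkage) and event (coordinates, Ψ per group,
  tool membership, kind), the single source of truth for recovery tests.

Everything is deterministic given (config, seed): the file tree is
byte-identical across runs, with independent child seeds per stage.

**What passing tests show — and what they do not.**  The generator writes
idealized tool output: binomial counts with no overdispersion, no
mapping/coverage structure, no shared reads between the two tools
(their counts are drawn independently, which if anything understates their
real correlation), no annotation errors, and planted effects well separated
from the decision thresholds.  Recovery with precision = recall = 1 on this
material validates the *bookkeeping* — coordinate conventions, filters,
linkage and specificity logic — not the statistical power or error control
of rMATS/Whippet on real reads, which are outside this package's scope.

## Numerical and problem-size choices

Test and acceptance runs use desk-scale sizes chosen to make the checks
sharp: genomes of ~30–300 genes (a few hundred kb), 200 scanner/oracle
pairs of 10 kb, 50-event calibration sets at depths 100 and 2000 (binomial
standard errors put the expected |ΔΨ| error near 0.013 and 0.003,
comfortably inside the asserted 0.05 and 0.01), and 200-event null sets.
Fisher p-values are discrete and conservative, so the null BH fraction sits
well below 0.05.  All report floats are written with fixed formats so runs
are byte-reproducible.

## Known limitations

* The per-gene pre-spliced database is an approximation of curated
  per-transcript databases; counts of "genes involved" are exact, but sites
  in regions covered only by unannotated transcripts are missed.
* Locus deduplication of overlapping approximate matches has no universal
  definition; ours is deterministic and shared by scanner and oracle, but
  other tools may count overlapping hits differently.
* The Whippet probability cutoff (0.90) and the overlap-vs-exact consensus
  mode are analysis choices; both are exposed as parameters.
* MXE (mutually exclusive exon) events and spliced-mRNA (mature transcript)
  binding sites are out of scope.
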