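# spliceoff

Off-target splicing analysis for splice-switching antisense oligonucleotides
(AONs) from short-read RNA-seq differential-splicing results.

Splice-switching AONs are fully modified, RNase-H-resistant oligonucleotides
that alter pre-mRNA splicing by base-pairing to the primary transcript.
Besides the designed (intended) exon skip, an AON can hybridize at partially
complementary loci elsewhere in the transcriptome and perturb splicing there
— *hybridization-dependent off-target events*.  `spliceoff` implements the
identification and prioritization of such events from the outputs of two
differential-splicing tools:

1. **Binding-site prediction.**  The AON *target sequence* (the reverse
   complement of the AON, U→T) is searched against the pre-spliced RNA of
   every gene — the sense-orientation genomic span — by exhaustive
   semi-global alignment under unit-cost Levenshtein distance (substitutions,
   insertions, deletions), reporting every deduplicated locus within a
   maximum distance *k* (default 3).  Only the sense strand is searched: it
   is the strand an antisense oligonucleotide hybridizes to.
2. **Event consensus.**  rMATS junction-count tables (SE/A5SS/A3SS/RI) are
   filtered (every replicate in both groups with ≥ 10 informative reads
   IJC+SJC; FDR < 0.05) and Whippet `.diff` tables are filtered (probability
   ≥ 0.90, |ΔΨ| ≥ 0.10); events of the two tools are matched by gene, type,
   strand and a *standardized region* (skipped exon, retained intron, or
   alternative splice-site segment), and each matched pair carries the mean
   ΔΨ of the two tools.  ΔΨ is oriented as Ψ(scrambled) − Ψ(targeting), so
   positive ΔΨ means the targeting AON induced a skip.
3. **Linkage and classification.**  A binding site is *linked* to an event
   when either endpoint of the site falls inside the event's linkage window
   — the flank-to-flank span of the event padded by 200 bp on both sides.
   An event is *AON-specific* when its exact-coordinate identity key appears
   in only one targeting-AON comparison of the experiment.  An event is
   called **hybridization-dependent** when it is linked to a targeting-AON
   site *and* AON-specific; events with |mean ΔΨ| larger than the intended
   event are flagged for prioritization.

Because the analysis consumes only tool output formats, the package includes
a deterministic synthetic-data generator that plants binding sites at exact
edit distances (verified against a brute-force alignment oracle) and
differential-splicing events with binomial junction counts around planted
group Ψ values — so the whole pipeline is testable offline with known truth.

## Worked example

Generate a synthetic study (3 targeting AONs + 1 scrambled control, intended
exon skips at ΔΨ ≈ 0.4, planted linked/unlinked off-target events, shared
background events, tool-specific false positives), then classify:

```sh
spliceoff simulate --seed 7 --out demo/study
spliceoff classify \
    --genome demo/study/genome.fa --gtf demo/study/annotation.gtf \
    --aons demo/study/aons.tsv --comparisons demo/comparisons.yaml \
    --out demo/results --seed 7
```

(`demo/comparisons.yaml` maps each comparison name to its rMATS directory,
Whippet `.diff`, and the targeting/scrambled AON names.)

`demo/results/site_summary.tsv` counts predicted binding sites per AON by
edit distance, with the intended site recovered at 0 mismatches:

```
aon            mismatches_0  mismatches_1  mismatches_2  mismatches_3  total_sites  total_genes_involved  intended_sites
APP-AON        1             1             3             5             10           10                    1
ATXN3-AON      1             1             3             5             10           10                    1
HTT-AON        1             1             3             5             10           10                    1
Scrambled-AON  0             1             2             9             12           12                    0
```

`demo/results/classification_summary.tsv` gives the all/AON-specific counts
per comparison; the ATXN3 analog is configured as the "toxic" AON with many
more events, and each comparison recovers its 4 planted
hybridization-dependent events (1 intended + 3 linked off-targets):

```
comparison  total_all  total_specific  matched_scrambled_all  matched_scrambled_specific  matched_targeting_all  matched_targeting_specific  hybridization_dependent  larger_than_intended  n_SE  n_A5SS  n_A3SS  n_RI
APP-AON     15         10              2                      2                           4                      4                           4                        2                     9     2       2       2
ATXN3-AON   23         18              2                      2                           4                      4                           4                        4                     13    4       3       3
HTT-AON     15         10              2                      2                           4                      4                           4                        2                     9     2       2       2
```

Per-event detail (flags, matching sites, identity keys) is in each
comparison's `classified.tsv`; `spliceoff report` builds a cross-experiment
replication table of shared events with their per-experiment mean ΔΨ.

## Library layout

| module                 | contents |
| ---------------------- | -------- |
| `spliceoff.annotation` | FASTA/GTF reading, gene/transcript models, pre-spliced sequence extraction, coordinate mapping |
| `spliceoff.scanner`    | AON records, target sequences, semi-global approximate search + brute-force oracle, transcriptome scan, site summaries |
| `spliceoff.events`     | rMATS/Whippet readers, filters, standardized regions, two-tool consensus, cross-comparison overlap |
| `spliceoff.classify`   | linkage windows, site→event matching, AON specificity, intended events, classification and summaries |
| `spliceoff.simulate`   | scenario configs, genome/site/event generators, truth manifest |
| `spliceoff.pipeline`   | end-to-end orchestration behind the CLI |
| `spliceoff.cli`        | `spliceoff simulate / scan / classify / report` |

See `docs/methods.md` for the model, parameter and design details.
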