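# Methods

## Scope and model

srnakit annotates three pools of small-RNA reads against a reference
genome. The pipeline's statistical content is deliberately rule-based
rather than probabilistic: a read is a miRNA candidate if and only if at
least one of its genomic placements folds into a qualifying hairpin; a
read is repeat-associated if any placement overlaps a repeat by at least
one base; the mirror-motif statistic is a per-window count with an
empirical permutation p-value. No per-call score or p-value is attached
to hairpin predictions — downstream validation is expected to come from
reference comparison and experiment, so the filters are transparent and
exactly testable.

All coordinates are 0-based half-open internally; GFF3 and RepeatMasker
rows are converted at the I/O boundary. Sequences live in the DNA
alphabet (U→T at ingest) and G·T is treated as the wobble pair when
folding. N never matches anything: it is a mismatch in alignment, pairs
with no base, never complements its mirror position, and 3-mers
containing N do not count toward window complexity.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `min_adapter_match` | 5 nt | shortest exact adapter substring that clips |
| `size_ranges` | 18–22 / 28–32 / 35–42 nt | inclusive insert windows for miRNA / piRNA / crasiRNA |
| `max_mismatches` | 1 | Hamming budget per placement; all placements reported |
| `hairpin_flank` | 50 bp | window extension on each side of a placement before folding |
| `min_loop` | 3 nt | minimum hairpin loop the folder may close |
| `min_stem_paired_frac` | 0.75 | paired fraction of stem-arm bases required |
| `loop_overhang` | 0 nt | read bases tolerated inside the terminal loop |
| `gene_flank` | 1000 bp | expansion of gene ends lacking an annotated UTR |
| `ref_min_seed` | 15 nt | exact shared substring required to consider a reference hairpin |
| `ref_min_identity` | 0.95 | ungapped mature identity required for a reference hit |
| `motif_flank` | 50 bp | mirror-motif window extension |
| `motif_min_distinct_3mers` | 5 | window complexity gate |
| `motif_n_shuffles` | 100 | composition-preserving permutations per window |
| `motif_share_threshold` | 1/3 | match fraction defining cohort membership |
| `peak_min_reads` / `peak_max_gap` | 2 / 0 | peak clustering (explicit stand-ins; see below) |
| `index_k` | 9 | seed length of the k-mer genome index |

The preprocessing size windows are the post-sequencing selection windows,
not the wider gel-excision ranges used at the bench; both are plain
config values. The two clipping descriptions in circulation ("alignment
of 5 or more bases" vs "exact substrings of length 5 nt or more") are
reconciled in favour of exactness, the more specific statement, with the
longest qualifying match removed. Only a missing 3' adapter discards a
read; the 5' clip, when configured, is non-discarding, since the discard
rule is only ever stated for the 3' end.

## Alignment

`map_read` enumerates exactly the set of ungapped placements within the
mismatch budget on both strands. The read is split into
`max_mismatches + 1` contiguous near-equal parts; by pigeonhole, any
qualifying placement matches at least one part exactly, so exact part
occurrences (found via a k-mer seed table and verified by string
comparison) nominate candidate placements, each fully verified by
Hamming count. Reads too short to carry k-mer-length parts fall back to
a full window scan. Minus-strand hits keep forward-genome coordinates
with the read equal to the reverse complement of the window (BED/SAM
convention). No cap is placed on placements per read — multi-mappers are
essential for the repeat-derived pools. `brute_force_map`, a quadratic
scan, defines ground truth in the tests; the suite asserts exact hit-set
equality on hundreds of randomized instances.

## Folding and hairpin validation

The folding backend is a deterministic maximum-base-pair dynamic program
over nested structures with three constraints: minimum loop length,
allowed pair set {A·T, G·C, G·T}, and no lonely pairs (every helix
carries ≥ 2 stacked pairs). The no-lonely-pair optimum uses the grammar

    M[i,j] = max(M[i+1,j], max_k H[i,k] + M[k+1,j])
    H[i,j] = 1 + E[i+1,j-1]        (both (i,j) and (i+1,j-1) pairable)
    E[a,b] = 1 + max(M[a+1,b-1], E[a+1,b-1] if pairable)

which generates exactly the no-lonely-pair structures because every
helix must begin with two stacked pairs (H) and may then either continue
(E) or close over an arbitrary sub-structure (M). Traceback ties are
broken deterministically: prefer pairing the leftmost undecided base,
then the smallest partner, then helix continuation. The test suite
checks the DP against exhaustive enumeration of all constrained nested
structures for sequences up to 12 nt. A thermodynamic folder can be
substituted through the `backend` argument; all validation operates on
the resulting dot-bracket only.

Stem-loops are parsed one per hairpin loop, extending outward through
enclosing pairs until the first multiloop branch point. The 75% rule is
read as *paired bases over all bases of the two arms* of the selected
stem-loop — bulges and internal loops count against the denominator, the
terminal loop does not. Candidate stem-loops are those whose full span
touches the read (so a read sitting in the terminal loop selects its
hairpin and then fails the read-in-stem verdict); among candidates the
one with most pairs wins, ties to the 5'-most. The read must lie
entirely within the two arm spans, with `loop_overhang` (default 0)
bases of tolerance inside the loop. "Unpaired loop present" requires
loop length ≥ 1 at validation; the folder itself already forces ≥
`min_loop` for closed loops, but the validation threshold is independent
so substituted backends are judged by the same rule.

Reference comparison replaces a general aligner with the two conditions
the accept/reject decision actually depends on: an exact shared
substring of ≥ 15 nt between candidate hairpin (either strand) and
reference hairpin, then the best ungapped identity of the mature
sequence slid along the reference hairpin, accepted at ≥ 95%. Ties break
on longer seed, then lexicographic reference id.

### A note on false positives

Maximum-base-pair folding is permissive: in random flanking sequence the
optimum is typically a long, low-bulge quasi-helix (branching costs loop
bases), and such chains can exceed the 75% paired threshold while
spanning the read. Windows of unstructured sequence therefore pass the
three criteria at a low but non-zero rate, which is why called loci can
outnumber planted hairpins on simulated data and why occasional calls
appear at shuffled decoy loci. Recovery of true planted stems is
unaffected (recall 1.0 in the simulations the tests and the acceptance
script run). A thermodynamic backend would lower this false-positive
rate; with the built-in folder the reference-comparison and
classification stages play that refining role, mirroring the original
design in which loose mapping was refined by downstream steps.

## Annotation semantics

* Target support counts **unique read sequences** per (gene, pool) —
  identical sequences collapse so duplicates cannot inflate support.
* The repeat-class distribution counts one assignment per (read, class);
  a multi-class read contributes to each class it touches and the
  percentage column sums to 100 over assignments.
* Pool comparison reports read pairs whose placements share ≥ 1 bp on
  the same contig and strand — the only comparison two independently
  mapped pools share.
* Peak clustering is single-linkage with gap ≤ `peak_max_gap` and
  minimum membership `peak_min_reads`. The original peak definition was
  never published; these defaults are explicit stand-ins and fully
  configurable. Peaks are strand-agnostic coverage pile-ups.
* Gene expansion is strand-aware: the transcriptional 5'/3' side lacking
  an annotated UTR grows by `gene_flank`, clamped to the contig.

## Mirror-motif statistic

Windows are taken on the strand the read mapped to; the score itself is
strand-invariant (`score(W) == score(revcomp(W))`), always even (no base
is self-complementary, so matches come in symmetric pairs), and equals
the window length exactly when the window is its own reverse complement.
Each alignment of a multi-mapping read contributes its own window.
Significance permutes the window as a whole (Fisher–Yates), preserving
base composition; `p = n_ge / n_shuffles` with the "greater or equal"
convention. Because the score is lattice-valued (step 2), shuffle ties
are common (~10% mass at typical window lengths) and the ≥ convention
makes the p-value conservative — its null mean sits near 0.55 rather
than 0.5, a property the calibration test quantifies. An add-one
corrected `(n_ge+1)/(n_shuffles+1)` estimate is a documented alternative
but the raw proportion is the default. Per-window RNG seeds derive
deterministically from (global seed, contig, start, strand), so results
do not depend on processing order. The cohort share is reported with
both denominators: non-skipped loci (primary) and all loci.

## Synthetic data

The generator plants every signal the pipeline is meant to detect into a
uniform-composition background genome (default 60 kb over two contigs,
GC 0.5), with non-overlapping placement at an 80 bp margin so each
planted truth is unambiguous; overlap scenarios are exercised with
hand-written fixtures instead.

* **Hairpins**: arm + loop + revcomp(arm), default 25 bp stem / 6 nt
  loop. The loop and the two loop-adjacent arm bases are drawn from
  {A, C}, which cannot pair among themselves, so the designed stem is
  the unique pair-count optimum and the fold cannot nibble into the
  loop on a tie.
* **Decoys**: shuffled hairpin loci (structure destroyed, composition —
  including its self-complementarity — preserved).
* **Repeats**: per-class consensus sequences with 2% per-instance
  divergence, so class members multi-map realistically.
* **Genes**: spans with per-gene planted target read counts (distinct
  insert sequences; duplicate copies share strand so uniqueness
  collapses them back to the planted count).
* **Mirror loci**: read-plus-flank windows built with an exact designed
  count of mirror-matching symmetric pairs (the odd-window middle base
  never matches, matching the scoring rule). The default cohort is 60%
  designed loci at match fraction 0.5 plus 40% fully random windows.
* **Reads**: sampled from planted loci with uniform strand, adapter
  suffix of ≥ 5 nt (a configurable fraction receives < 5 nt to exercise
  the discard rule), and substitution errors at a configurable rate.
  Errors are placed in the insert only — an adapter error would silently
  turn a clip into a discard and break truth traceability. If a mutated
  insert happens to end in a ≥ 5 nt adapter prefix the read is emitted
  from the opposite strand, keeping clipping unambiguous.

What the generator does **not** emulate: expression-level structure
(depth is uniform per locus), sequencing quality variation (constant Q),
indel errors (the mapper is ungapped, so indels would only delete
reads), chimeras, and real repeat family phylogenies. Passing the
planted-recovery tests therefore demonstrates correctness of the
pipeline's logic under its own model, not performance on real libraries.

## Problem sizes and determinism

Simulated runs in the tests and acceptance script use 30–70 kb genomes,
10–60 loci per signal class and read depths of 1–20 — sizes chosen so a
full run takes seconds while every code path (multi-mapping, merging,
skipping, discarding) is exercised. Everything is seeded: one global
seed drives genome construction, read sampling, and per-window shuffle
seeds; two runs with the same configuration produce byte-identical
outputs, and the run manifest records config digest, input digests and
per-stage counts. Stage caching reuses outputs when the configuration
digest matches.

## Known limitations

* Maximum-base-pair folding over-pairs random sequence (see above); the
  structural filter is faithful to its rules but not to thermodynamics.
* Identity thresholds in reference comparison are ungapped; a reference
  ortholog reachable only through a gapped alignment is missed.
* The GFF3 reader keeps gene spans and UTR/exon children but does not
  validate attribute ontology; RepeatMasker parsing expects the standard
  15-column layout.
* The empirical p-value's resolution is 1/`motif_n_shuffles`; findings
  at p = 0 mean "no shuffle scored as high", not a continuous tail
  probability.
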