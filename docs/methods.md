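# Methods

## Problem setting

Consensus assembly of short-read RNA-Seq alignments yields transcript
models whose exon–intron structures are mostly right but whose boundaries
inherit artifacts of read bleed-through between closely spaced genes.
`txpolish` takes three inputs — an annotation (GTF), per-base read depth
(bedGraph, as produced by `bedtools genomecov -d`-style counting), and the
genome (FASTA) — and applies three repair operators: redundancy removal,
merged-gene splitting, and antisense end trimming. All internal
coordinates are 1-based inclusive; bedGraph and BED are converted on read.

## Changepoint model

Within a coverage segment, per-base depth is treated as i.i.d.
exponential. The exponential family is a pragmatic choice for RNA-Seq
depth: non-negative, right-skewed, variance growing with the mean, and its
likelihood depends on the data only through the segment mean, which makes
segment costs O(1) given prefix sums. The segment cost is twice the
negative log-likelihood at the MLE rate with the segmentation-invariant
constant dropped, `C(x) = 2 n ln(mean(x))`. Observed depth contains zeros,
which an exponential likelihood cannot score, so a pseudocount (default
1.0) is added to every base before scoring; a constant shift preserves the
location of level changes and compresses ratios only mildly at the depths
where the operators act.

### Segmentation: growth then pruning

`binary_segmentation` first grows a split tree greedily: every segment is
split at its best single changepoint while that split yields any cost
improvement, subject to a minimum segment length and a recursion-depth
cap. It then prunes: the adjacent segment pair whose merge increases total
cost least is merged repeatedly, while that increase is at most the
penalty `β = penalty_multiplier · ln(n)`.

The two-phase form, rather than accepting each split only when its own
gain exceeds `β`, is deliberate. For a narrow trough between long flanks
the *first* split's marginal gain is diluted — splitting
`[61]*120 | [3]*40+[61]*120` changes the pooled means only slightly, for a
gain of ~5 against a penalty of ~17 — while in the fully grown tree each
trough boundary carries a contextual gain of ~145. Pruning judges every
changepoint against its final neighbours, which is the comparison that
matters. The merge sequence does not depend on `β`, so increasing the
penalty can only remove more changepoints: changepoint counts are monotone
in the penalty, and flat coverage yields none (growth never fires, since a
constant vector's best gain is numerically zero).

### Parameters

| parameter | default | role |
|---|---|---|
| `penalty_multiplier` | 3.0 | pruning threshold `β = 3 ln n`; BIC-flavoured, conservative on flat coverage |
| `min_segment_length` | 10 bases | shortest admissible segment; also the boundary-localization resolution |
| `pseudocount` | 1.0 | shift applied before likelihood scoring |
| `max_depth_of_recursion` | 10 | cap on growth-tree depth (2^10 segments ≫ any exon in practice) |
| `trough_drop_ratio` | 0.2 | a trough/outer-side segment must fall to ≤ 20% of its flank mean |

`min_segment_length = 10` balances two pressures. Larger values suppress
spurious micro-segments, but a boundary cannot be placed more finely than
one segment: with a 20-base minimum, a mixed "transition" segment
straddling a trough edge both displaces the inferred boundary by up to
~20 bases and sits between the trough and its true flank, defeating a
naive adjacent-segment drop test. At 10 bases, planted boundaries are
recovered exactly on noise-free plateaus and within ±10 bases under
exponential noise at the simulated depths (50 versus 2).

### Trough qualification

`detect_trough` takes the minimum-mean interior segment (never the first
or last), absorbs adjacent interior segments that are also low relative to
the outermost (flank-level) segments, and accepts the call only if the
trough mean is ≤ `trough_drop_ratio` times both segment means immediately
outside the run. The run extension makes the call robust to noise slicing
the gap into several low segments. Ratios are evaluated on
pseudocount-shifted means, consistently with everything else.

## Repair operators

**Candidate screening.** Only internal exons whose strand-oriented
sequence contains a stop codon in all three reading frames are probed for
troughs. A genuine fused exon spans an intergenic gap, so no frame stays
open across it; screening first keeps the trough search off ordinary
coding exons and bounds runtime. Codons containing N never match. The
screen uses the bare exon sequence, not the spliced transcript frame: the
signal sought is local to the exon, and the spliced frame is unknown
before CDS prediction anyway.

**Splitting.** A qualifying trough splits the transcript; the trough bases
belong to neither child, modelling the intergenic gap. Children take
`.split1`/`.split2` suffixes on both transcript and gene ids — a split
separates two genes, not two isoforms. A transcript is split at most once
per pass at the leftmost qualifying trough; the children re-enter the
queue, so loci with more than two merged genes resolve over successive
passes without recursive bookkeeping. A trough touching an exon boundary
is rejected (that geometry is an end-trim case). Retained CDS rows are
dropped from children, as their frames no longer apply; CDS re-prediction
is downstream of this tool.

**Trimming.** Only terminal exons implicated by an antisense overlap
(≥ 1 shared base with an exon of an opposite-strand transcript, or within
`antisense_max_gap`) are eligible — coverage-based trimming of arbitrary
ends would invite false modifications. Walking from the outer end inward
over the exon's segmentation, the outermost changepoint whose outer-side
segment mean has collapsed to ≤ `trough_drop_ratio` of its inner neighbour
marks the real transcript end; outer bases are removed and the old
coordinates are recorded in a `trimmed` attribute. Uniform coverage, or a
neighbour whose own coverage never collapses, leaves the transcript
unchanged — which is also why the symmetric overlap record for the
*un-extended* partner of an antisense pair is a natural no-op.

**Redundancy removal.** Transcript A is redundant to a same-chromosome,
same-strand transcript B when (i) their intron chains are equal and A's
span lies within B's (longer span wins; ties by smaller id), (ii) A's
chain is a proper contiguous subsequence of B's with span containment, or
(iii) mono-exonic A lies within one exon of B or within mono-exonic B's
interval (equal intervals: smaller id wins). The relation is evaluated
pairwise against the original set and applied in one step; the tie-breaks
make it antisymmetric, so exactly one member of a duplicate pair survives
and the operation is idempotent.

**Pipeline order** is dedupe → split → trim → dedupe: splitting and
trimming can expose new redundancy among previously distinct models.

## Evaluation conventions

Base-level counting is stranded and unioned per side (a base covered by
two isoforms counts once). Exon and intron levels compare de-duplicated
exact-coordinate sets. Transcript recognition uses complete intron-chain
identity for multi-exonic models — terminal extents do not matter — and a
symmetric ≥ 80% reciprocal overlap (shared bases over the longer length)
for mono-exonic models; the symmetric denominator stops tiny fragments
inside long references from counting. Sensitivity is computed over
reference features (a reference matched by several predictions counts
once) and specificity over predicted features, so at the transcript and
gene levels the two numerators differ. A gene is recognized when at least
one of its transcripts is. AED of a prediction is `1 − max (SN+SP)/2`
over base-level fractions against each same-strand overlapping reference
transcript; no overlap gives 1.

## Confidence and tissue association

Three independent evidence flags — expressed in RNA-Seq, predicted
ab initio, protein-supported — are supplied as transcript-id lists; a gene
carries a flag when any of its transcripts does. A gene is high confidence
when at least two of the three flags hold; this reproduces both anchor
cases of the rule set (all three ⇒ high; ab-initio-only ⇒ low) and fills
the remaining combinations symmetrically. Note that under this rule an
expressed-only gene (no prediction, no protein) is *low* confidence. A
gene whose exonic base union is ≥ 50% covered by repeat intervals
(threshold exposed) is demoted to low regardless of other evidence, since
transposon-derived ORFs routinely imitate genes. Coverage depth is not
used as a scoring input: no principled threshold exists without a
background model, and the evidence flags already encode expression.

The tissue matrix applies the same two matching rules between the
consolidated annotation and each per-sample annotation; the row-wise OR
over samples equals "expressed somewhere".

## Synthetic data

The generators emulate the failure geometries, not real genomes. Defaults:
exonic plateau depth 50, inter-gene gap depth 2, gap width 40 bases,
200-base exons, 100-base introns, exponential per-base noise (floored to
integer depth). Exponential noise matches the detector's model family;
Poisson is available to test misspecification. Sequence content is an
`AAC` tiling (no stop in any frame) with `TAAA` tilings planted in fused
exons (a stop in every frame), so the candidate screen fires exactly on
planted fusion exons. The merged-gene generator rejects gaps narrower than
20 bases — one admissible segment — as undetectable by construction.

What the fixtures do *not* model: mappability variation, spliced-read edge
effects at exon boundaries, overdispersion beyond exponential, isoform
mixtures over a shared locus, and GC-dependent coverage bias. Passing the
fixture suites therefore demonstrates correctness of the operators under
their stated model, not performance on real libraries, where depth ratios
between neighbouring genes are often less favourable than 25:1.

The annotation-pair generator corrupts a random reference (drop, +3-base
intron shift, 10–90-base end truncation, spurious additions) and computes
its truth metrics by naive set arithmetic — explicit position sets and
quadratic loops — kept deliberately independent of the evaluator so it can
serve as an oracle.

## Problem sizes and determinism

The test suite and the acceptance script use 200 replicates for boundary
recovery suites, 100 for redundancy and end-to-end improvement, 50 for
evaluator agreement, and 1000 random 300-mers for the stop screen; loci
are a few kilobases, which keeps the full suite under a minute while
leaving each statistical bar (≥ 95% recovery within ±10 bases) far from
its sampling noise floor. Everything is seeded: identical seeds give
byte-identical fixture files and bit-identical segmentations. Ties are
broken deterministically throughout (smallest split offset, leftmost
segment, lexicographically smaller transcript id).

## Known limitations

* Splitting assigns trough bases to neither child; true gene ends inside
  the trough are unrecoverable at depth ~2.
* Intron-chain matching is exact; a one-base splice-site shift breaks
  recognition, as intended by the convention, but real aligners produce
  such shifts.
* The trimmer only acts on antisense-implicated ends; same-strand
  read-through past a 3′ end is out of scope.
* GTF is the only annotation dialect; GFF3 is not parsed.
* CDS/UTR inference is out of scope; retained CDS rows are carried
  verbatim and dropped on split.
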