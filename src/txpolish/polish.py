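"""Structure repair for assembled transcript models.

Three error classes produced by meta-assembly of RNA-Seq data are repaired
here:

1. **Redundant transcripts** — models that are proper structural subsets of
   other models are removed so only unique structures remain.
2. **Merged genes** — two closely spaced genes on the same strand whose
   reads bleed into each other get assembled as one transcript with a
   single fused exon.  Internal exons whose sequence carries premature stop
   codons in all three reading frames are probed for a coverage trough; a
   qualifying trough splits the transcript into two gene models.
3. **Antisense overrun** — a terminal exon extended across a neighbouring
   gene on the opposite strand is trimmed back to the changepoint where its
   own coverage collapses.
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Set, Tuple

from .changepoint import (
    SegmentationConfig,
    TroughCall,
    binary_segmentation,
    detect_trough,
)
from .models import (
    Annotation,
    CoverageTrack,
    GenomicInterval,
    GenomeSequence,
    TranscriptModel,
    ValidationError,
    exon_sequence,
)

log = logging.getLogger(__name__)

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})

LEFT = "left"
RIGHT = "right"


@dataclass(frozen=True)
class PolishConfig:
    segmentation: SegmentationConfig = field(default_factory=SegmentationConfig)
    min_exons_for_internal: int = 3
    antisense_max_gap: int = 0
    stop_codons: frozenset = STOP_CODONS

    def __post_init__(self) -> None:
        if self.min_exons_for_internal < 3:
            raise ValueError(
                "min_exons_for_internal must be >= 3 (a transcript needs at "
                "least 3 exons to have an internal exon)"
            )
        if self.antisense_max_gap < 0:
            raise ValueError("antisense_max_gap must be >= 0")


@dataclass
class PolishReport:
    """Event counts and per-event records from one polishing run."""

    n_redundant_removed: int = 0
    n_candidate_exons: int = 0
    n_troughs_found: int = 0
    n_transcripts_split: int = 0
    n_ends_trimmed: int = 0
    events: List[Dict[str, object]] = field(default_factory=list)

    def summary(self) -> Dict[str, int]:
        return {
            "n_redundant_removed": self.n_redundant_removed,
            "n_candidate_exons": self.n_candidate_exons,
            "n_troughs_found": self.n_troughs_found,
            "n_transcripts_split": self.n_transcripts_split,
            "n_ends_trimmed": self.n_ends_trimmed,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as handle:
            json.dump({"summary": self.summary(), "events": self.events}, handle,
                      indent=2)
            handle.write("\n")

    def to_tsv(self, path) -> None:
        keys = ["kind", "transcript_id", "detail"]
        with open(path, "w") as handle:
            handle.write("\t".join(keys) + "\n")
            for event in self.events:
                detail = {k: v for k, v in event.items()
                          if k not in ("kind", "transcript_id")}
                handle.write(
                    f"{event.get('kind')}\t{event.get('transcript_id')}\t"
                    + json.dumps(detail, sort_keys=True)
                    + "\n"
                )


@dataclass(frozen=True)
class SplitEvent:
    parent_id: str
    left_child_id: str
    right_child_id: str
    trough: GenomicInterval


def has_premature_stops_all_frames(
    seq: str, stop_codons: frozenset = STOP_CODONS
) -> bool:
    """True iff every one of the three frames contains a stop codon.

    The sequence is assumed to be strand-oriented (reverse-complemented
    already for minus-strand exons).  Codons containing N never match.
    Sequences shorter than 3 bases cannot hold a codon in any frame.
    """
    n = len(seq)
    if n < 3:
        return False
    for frame in range(3):
        if not any(
            seq[i : i + 3] in stop_codons for i in range(frame, n - 2, 3)
        ):
            return False
    return True


def select_candidate_exons(
    transcript: TranscriptModel,
    genome: GenomeSequence,
    stop_codons: frozenset = STOP_CODONS,
) -> List[int]:
    """Internal exons worth probing for a merged-gene trough.

    Returns 0-based indices (genomic order) of exons that are neither first
    nor last and whose strand-oriented sequence has premature stop codons in
    all three frames — the signature of a fused exon spanning an inter-gene
    gap, where no reading frame stays open.  Transcripts with fewer than 3
    exons have no internal exon and return an empty list.
    """
    if len(transcript.exons) < 3:
        return []
    candidates = []
    for i in range(1, len(transcript.exons) - 1):
        seq = exon_sequence(transcript.exons[i], genome)
        if has_premature_stops_all_frames(seq, stop_codons):
            candidates.append(i)
    return candidates


def split_transcript_at_trough(
    transcript: TranscriptModel, exon_index: int, trough: TroughCall
) -> Optional[Tuple[TranscriptModel, TranscriptModel]]:
    """Split a transcript into two gene models at a coverage trough.

    The trough offsets are 1-based within the exon; trough bases belong to
    neither child (they model the inter-genic gap).  Children receive
    ``.split1``/``.split2`` suffixes on both transcript and gene ids — a
    split separates two genes, not two isoforms.  Retained CDS features are
    dropped from the children, since their frames no longer apply.

    Returns ``None`` when the trough touches an exon boundary: that
    geometry is an end-trimming scenario, not a merged-gene split.
    """
    if exon_index <= 0 or exon_index >= len(transcript.exons) - 1:
        raise ValueError(
            f"exon_index {exon_index} is not internal for "
            f"{transcript.transcript_id}"
        )
    exon = transcript.exons[exon_index]
    if trough.left <= 1 or trough.right >= exon.length:
        return None
    left_fragment = replace(exon, end=exon.start + trough.left - 2)
    right_fragment = replace(exon, start=exon.start + trough.right)
    left_child = TranscriptModel(
        transcript_id=transcript.transcript_id + ".split1",
        gene_id=transcript.gene_id + ".split1",
        exons=transcript.exons[:exon_index] + (left_fragment,),
        attributes=dict(transcript.attributes),
        source=transcript.source,
    )
    right_child = TranscriptModel(
        transcript_id=transcript.transcript_id + ".split2",
        gene_id=transcript.gene_id + ".split2",
        exons=(right_fragment,) + transcript.exons[exon_index + 1 :],
        attributes=dict(transcript.attributes),
        source=transcript.source,
    )
    return left_child, right_child


def find_antisense_end_overlaps(
    annotation: Annotation, max_gap: int = 0
) -> List[Tuple[str, str, str]]:
    """Terminal exons that overlap an exon of an opposite-strand transcript.

    Returns ``(transcript_id, which_end, opposing_transcript_id)`` records,
    ``which_end`` being ``"left"`` (outermost-left exon) or ``"right"``.
    Overlap requires at least one shared base when ``max_gap`` is 0;
    otherwise a gap of up to ``max_gap`` bases also qualifies.  Unstranded
    transcripts are never eligible.
    """
    by_chrom: Dict[str, List[TranscriptModel]] = {}
    for t in annotation.transcripts_sorted():
        by_chrom.setdefault(t.chrom, []).append(t)

    records: List[Tuple[str, str, str]] = []
    for chrom in sorted(by_chrom):
        transcripts = by_chrom[chrom]
        for t in transcripts:
            if t.strand not in ("+", "-"):
                continue
            for which_end, terminal in ((LEFT, t.exons[0]), (RIGHT, t.exons[-1])):
                for other in transcripts:
                    if other.transcript_id == t.transcript_id:
                        continue
                    if other.strand not in ("+", "-") or other.strand == t.strand:
                        continue
                    if any(
                        terminal.start <= ex.end + max_gap
                        and ex.start <= terminal.end + max_gap
                        for ex in other.exons
                    ):
                        records.append(
                            (t.transcript_id, which_end, other.transcript_id)
                        )
    return records


def trim_end_exon(
    transcript: TranscriptModel,
    which_end: str,
    coverage: CoverageTrack,
    config: PolishConfig = PolishConfig(),
) -> TranscriptModel:
    """Trim an antisense-implicated terminal exon back to its own coverage.

    Binary segmentation runs on the terminal exon's depth; walking from the
    outer end inward, the outermost changepoint whose outer-side segment
    mean has collapsed to at most ``trough_drop_ratio`` times its inner
    neighbour marks the actual transcript end, and everything outside it is
    removed.  If no changepoint qualifies (e.g. uniform coverage) the
    transcript is returned unchanged.
    """
    if which_end not in (LEFT, RIGHT):
        raise ValueError(f"which_end must be 'left' or 'right', got {which_end!r}")
    seg_cfg = config.segmentation
    exon = transcript.exons[0] if which_end == LEFT else transcript.exons[-1]
    if exon.length < 2 * seg_cfg.min_segment_length:
        log.debug(
            "skipping trim of %s (%s end): exon too short (%d bases)",
            transcript.transcript_id, which_end, exon.length,
        )
        return transcript
    depth = coverage.interval_depth(exon)
    seg = binary_segmentation(depth, seg_cfg)
    if not seg.changepoints:
        return transcript
    bounds, means = seg.segment_bounds, seg.segment_means
    ratio = seg_cfg.trough_drop_ratio
    new_exon = None
    if which_end == RIGHT:
        for j in range(len(bounds) - 1, 0, -1):
            outer, inner = means[j], means[j - 1]
            if outer <= ratio * inner:
                cut = bounds[j - 1][1]  # keep offsets 1..cut
                new_exon = replace(exon, end=exon.start + cut - 1)
                break
    else:
        for j in range(len(bounds) - 1):
            outer, inner = means[j], means[j + 1]
            if outer <= ratio * inner:
                cut = bounds[j][1]  # drop offsets 1..cut
                new_exon = replace(exon, start=exon.start + cut)
                break
    if new_exon is None:
        return transcript
    attributes = dict(transcript.attributes)
    note = f"{which_end}:{exon.start}-{exon.end}"
    attributes["trimmed"] = (
        attributes["trimmed"] + "," + note if "trimmed" in attributes else note
    )
    exons = (
        (new_exon,) + transcript.exons[1:]
        if which_end == LEFT
        else transcript.exons[:-1] + (new_exon,)
    )
    return replace(transcript, exons=exons, attributes=attributes)


def _is_contiguous_subchain(
    sub: Sequence[Tuple[int, int]], chain: Sequence[Tuple[int, int]]
) -> bool:
    k = len(sub)
    if k >= len(chain):
        return False
    sub = tuple(sub)
    return any(tuple(chain[j : j + k]) == sub for j in range(len(chain) - k + 1))


def _dominates(keeper: TranscriptModel, candidate: TranscriptModel) -> bool:
    """True if ``candidate`` is redundant relative to ``keeper``.

    Rules (same chromosome and strand throughout):

    * equal intron chains with candidate's span inside keeper's — the longer
      span wins, ties go to the lexicographically smaller transcript_id;
    * candidate's chain is a proper contiguous subsequence of keeper's and
      its span lies within keeper's span;
    * mono-exonic candidate contained in a single exon of keeper, or in
      mono-exonic keeper's interval (equal intervals: smaller id wins).
    """
    a, b = candidate, keeper
    if a.chrom != b.chrom or a.strand != b.strand:
        return False
    span_within = b.start <= a.start and a.end <= b.end
    if not a.is_mono_exonic:
        if b.is_mono_exonic or not span_within:
            return False
        if a.introns == b.introns:
            if (a.start, a.end) != (b.start, b.end):
                return True  # b's span strictly contains a's
            return b.transcript_id < a.transcript_id
        return _is_contiguous_subchain(a.introns, b.introns)
    if b.is_mono_exonic:
        if not span_within:
            return False
        if (a.start, a.end) == (b.start, b.end):
            return b.transcript_id < a.transcript_id
        return True
    return any(
        ex.start <= a.start and a.end <= ex.end for ex in b.exons
    )


def remove_redundant_transcripts(
    annotation: Annotation,
) -> Tuple[Annotation, List[str]]:
    """Drop transcripts that are structural subsets of other transcripts.

    Redundancy is evaluated pairwise against the original transcript set,
    then applied in one step, so the outcome does not depend on removal
    order.  The tie-break rules in :func:`_dominates` make the relation
    antisymmetric, so one member of every duplicate pair always survives,
    and the operation is idempotent.
    """
    transcripts = list(annotation)
    removed: Set[str] = set()
    for a in transcripts:
        for b in transcripts:
            if a.transcript_id == b.transcript_id:
                continue
            if _dominates(b, a):
                removed.add(a.transcript_id)
                break
    kept = [t for t in transcripts if t.transcript_id not in removed]
    return Annotation.from_transcripts(kept), sorted(removed)


def polish_annotation(
    annotation: Annotation,
    coverage: CoverageTrack,
    genome: GenomeSequence,
    config: PolishConfig = PolishConfig(),
) -> Tuple[Annotation, PolishReport]:
    """Full polishing pass: dedupe, split merged genes, trim ends, dedupe.

    Splitting runs once per transcript per pass at the leftmost qualifying
    trough; the two children re-enter the queue so loci with more than two
    merged genes resolve over successive passes.  Deduplication runs again
    at the end because splitting and trimming can expose new redundancy.
    """
    chroms = {t.chrom for t in annotation}
    missing_cov = sorted(c for c in chroms if c not in coverage)
    if missing_cov:
        raise ValidationError(
            "coverage missing chromosome(s): " + ", ".join(missing_cov)
        )
    missing_seq = sorted(c for c in chroms if c not in genome)
    if missing_seq:
        raise ValidationError(
            "genome missing chromosome(s): " + ", ".join(missing_seq)
        )

    report = PolishReport()

    deduped, removed = remove_redundant_transcripts(annotation)
    for tid in removed:
        report.events.append({"kind": "redundant_removed", "transcript_id": tid})

    queue = list(deduped.transcripts_sorted())
    kept: List[TranscriptModel] = []
    while queue:
        t = queue.pop(0)
        candidates = select_candidate_exons(t, genome, config.stop_codons)
        report.n_candidate_exons += len(candidates)
        split_done = False
        for i in candidates:
            depth = coverage.interval_depth(t.exons[i])
            trough = detect_trough(depth, config.segmentation)
            if trough is None:
                continue
            report.n_troughs_found += 1
            children = split_transcript_at_trough(t, i, trough)
            if children is None:
                log.debug(
                    "trough in %s exon %d touches the exon boundary; "
                    "treating as a trim scenario",
                    t.transcript_id, i,
                )
                continue
            left_child, right_child = children
            exon = t.exons[i]
            trough_iv = GenomicInterval(
                t.chrom,
                exon.start + trough.left - 1,
                exon.start + trough.right - 1,
                t.strand,
            )
            report.n_transcripts_split += 1
            report.events.append(
                {
                    "kind": "split",
                    "transcript_id": t.transcript_id,
                    "exon_index": i,
                    "trough_start": trough_iv.start,
                    "trough_end": trough_iv.end,
                    "left_child": left_child.transcript_id,
                    "right_child": right_child.transcript_id,
                }
            )
            queue.append(left_child)
            queue.append(right_child)
            split_done = True
            break
        if not split_done:
            kept.append(t)
    after_split = Annotation.from_transcripts(kept)

    overlaps = find_antisense_end_overlaps(after_split, config.antisense_max_gap)
    targets: List[Tuple[str, str]] = []
    for tid, which_end, _other in overlaps:
        if (tid, which_end) not in targets:
            targets.append((tid, which_end))
    current = dict(after_split.transcripts)
    for tid, which_end in targets:
        before = current[tid]
        after = trim_end_exon(before, which_end, coverage, config)
        if (after.start, after.end) != (before.start, before.end):
            report.n_ends_trimmed += 1
            report.events.append(
                {
                    "kind": "trim",
                    "transcript_id": tid,
                    "which_end": which_end,
                    "old_start": before.start,
                    "old_end": before.end,
                    "new_start": after.start,
                    "new_end": after.end,
                }
            )
            current[tid] = after
    after_trim = Annotation.from_transcripts(current.values())

    final, removed2 = remove_redundant_transcripts(after_trim)
    for tid in removed2:
        report.events.append({"kind": "redundant_removed", "transcript_id": tid})
    report.n_redundant_removed = len(removed) + len(removed2)
    return final, report
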