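"""Annotation comparison: multi-level sensitivity/specificity/F1 and AED.

A predicted annotation is compared against a reference at five levels —
base, exon, intron, transcript and gene.  Following the convention of
annotation benchmarking (Mikado-style), *sensitivity* is the fraction of
reference features recovered and *specificity* is the fraction of predicted
features that are correct (precision, in machine-learning vocabulary).

Transcript recognition uses the intron-chain rule: a multi-exonic
prediction is recognized when its complete intron chain matches a reference
transcript (terminal-exon extents do not matter); a mono-exonic prediction
is recognized when it shares at least 80% of nucleotides with a mono-exonic
reference, measured against the longer of the two.

The annotation edit distance (AED) of a predicted transcript is
``1 - max over overlapping reference transcripts of (SN + SP) / 2`` where
SN/SP are base-level fractions against that reference: 0 means complete
agreement, 1 means no reference transcript overlaps the prediction.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Set, Tuple

from .models import Annotation, TranscriptModel

LEVELS = ("base", "exon", "intron", "transcript", "gene")


def harmonic_f1(sensitivity: float, specificity: float) -> float:
    """Harmonic mean of two percentages; 0 when either component is 0."""
    if sensitivity <= 0 or specificity <= 0:
        return 0.0
    return 2.0 * sensitivity * specificity / (sensitivity + specificity)


@dataclass(frozen=True)
class LevelMetrics:
    """Counts and percentage metrics at one comparison level.

    At the symmetric levels (base/exon/intron) ``tp`` counts features
    present on both sides.  At the transcript and gene levels ``tp`` counts
    recognized *reference* features (used for sensitivity); ``fp`` counts
    unrecognized predictions, so specificity is computed from the predicted
    total rather than from ``tp`` (several predictions may match one
    reference).
    """

    level: str
    tp: int
    fp: int
    fn: int
    sensitivity: float
    specificity: float
    f1: float

    @classmethod
    def symmetric(cls, level: str, tp: int, fp: int, fn: int) -> "LevelMetrics":
        sn = 100.0 * tp / (tp + fn) if tp + fn else 0.0
        sp = 100.0 * tp / (tp + fp) if tp + fp else 0.0
        return cls(level, tp, fp, fn, sn, sp, harmonic_f1(sn, sp))


@dataclass
class ComparisonReport:
    metrics: Dict[str, LevelMetrics]
    aed: Dict[str, float]

    def levels_tsv(self, path) -> None:
        with open(path, "w") as handle:
            handle.write("level\ttp\tfp\tfn\tsensitivity\tspecificity\tf1\n")
            for level in LEVELS:
                m = self.metrics[level]
                handle.write(
                    f"{m.level}\t{m.tp}\t{m.fp}\t{m.fn}\t{m.sensitivity:.2f}"
                    f"\t{m.specificity:.2f}\t{m.f1:.2f}\n"
                )

    def aed_tsv(self, path) -> None:
        with open(path, "w") as handle:
            handle.write("transcript_id\taed\n")
            for tid in sorted(self.aed):
                handle.write(f"{tid}\t{self.aed[tid]:.4f}\n")


def intron_chain_match(pred: TranscriptModel, ref: TranscriptModel) -> bool:
    """Exact intron-chain identity (multi-exonic transcripts only)."""
    if pred.is_mono_exonic or ref.is_mono_exonic:
        raise ValueError("intron_chain_match requires multi-exonic transcripts")
    return (
        pred.chrom == ref.chrom
        and pred.strand == ref.strand
        and pred.introns == ref.introns
    )


def mono_overlap_match(
    pred: TranscriptModel, ref: TranscriptModel, threshold: float = 0.8
) -> bool:
    """Reciprocal overlap rule for mono-exonic transcripts.

    Shared bases divided by the longer of the two lengths must reach the
    threshold; the symmetric denominator stops tiny fragments inside long
    references from counting as matches.
    """
    if not pred.is_mono_exonic or not ref.is_mono_exonic:
        raise ValueError("mono_overlap_match requires mono-exonic transcripts")
    if pred.chrom != ref.chrom or pred.strand != ref.strand:
        return False
    shared = pred.exons[0].overlap_length(ref.exons[0])
    longer = max(pred.exonic_length, ref.exonic_length)
    return shared / longer >= threshold


def transcripts_match(
    pred: TranscriptModel, ref: TranscriptModel, mono_threshold: float = 0.8
) -> bool:
    """Route to the chain rule or the mono-exonic overlap rule."""
    if pred.is_mono_exonic != ref.is_mono_exonic:
        return False
    if pred.is_mono_exonic:
        return mono_overlap_match(pred, ref, mono_threshold)
    return intron_chain_match(pred, ref)


def _base_set(annotation: Annotation) -> Set[Tuple[str, str, int]]:
    # union per side: a base covered by several isoforms counts once
    out: Set[Tuple[str, str, int]] = set()
    for t in annotation:
        for ex in t.exons:
            for pos in range(ex.start, ex.end + 1):
                out.add((t.chrom, t.strand, pos))
    return out


def _exon_set(annotation: Annotation) -> Set[Tuple[str, str, int, int]]:
    return {
        (t.chrom, t.strand, ex.start, ex.end) for t in annotation for ex in t.exons
    }


def _intron_set(annotation: Annotation) -> Set[Tuple[str, str, int, int]]:
    return {
        (t.chrom, t.strand, s, e) for t in annotation for s, e in t.introns
    }


def _matched_transcripts(
    pred: Annotation, ref: Annotation, mono_threshold: float
) -> Tuple[Set[str], Set[str]]:
    """Ids of matched predictions and matched references."""
    multi_index: Dict[Tuple[str, str, Tuple[Tuple[int, int], ...]], List[str]] = {}
    mono_by_loc: Dict[Tuple[str, str], List[TranscriptModel]] = {}
    for r in ref:
        if r.is_mono_exonic:
            mono_by_loc.setdefault((r.chrom, r.strand), []).append(r)
        else:
            multi_index.setdefault((r.chrom, r.strand, r.introns), []).append(
                r.transcript_id
            )
    matched_pred: Set[str] = set()
    matched_ref: Set[str] = set()
    for p in pred:
        if p.is_mono_exonic:
            for r in mono_by_loc.get((p.chrom, p.strand), []):
                if mono_overlap_match(p, r, mono_threshold):
                    matched_pred.add(p.transcript_id)
                    matched_ref.add(r.transcript_id)
        else:
            hits = multi_index.get((p.chrom, p.strand, p.introns), [])
            if hits:
                matched_pred.add(p.transcript_id)
                matched_ref.update(hits)
    return matched_pred, matched_ref


def compute_aed(pred: TranscriptModel, ref: Annotation) -> float:
    """Annotation edit distance of one predicted transcript.

    Only reference transcripts on the same chromosome and strand that share
    at least one exonic base are considered; with no overlapping reference
    the AED is 1.
    """
    pred_bases = {
        pos for ex in pred.exons for pos in range(ex.start, ex.end + 1)
    }
    best = None
    for r in ref:
        if r.chrom != pred.chrom or r.strand != pred.strand:
            continue
        ref_bases = {
            pos for ex in r.exons for pos in range(ex.start, ex.end + 1)
        }
        shared = len(pred_bases & ref_bases)
        if shared == 0:
            continue
        sn = shared / len(ref_bases)
        sp = shared / len(pred_bases)
        congruence = (sn + sp) / 2.0
        if best is None or congruence > best:
            best = congruence
    return 1.0 if best is None else 1.0 - best


def compare_annotations(
    pred: Annotation, ref: Annotation, mono_threshold: float = 0.8
) -> ComparisonReport:
    """Five-level comparison of a prediction against a reference.

    Base level counts stranded exonic positions (unioned per side); exon
    and intron levels count exact coordinate matches over de-duplicated
    feature sets; transcript level applies the recognition rules; a gene is
    recognized when at least one of its transcripts is.  Raises
    ``ValueError`` on an empty side, where sensitivity or specificity is
    undefined.
    """
    if len(ref) == 0:
        raise ValueError("empty reference annotation: sensitivity undefined")
    if len(pred) == 0:
        raise ValueError("empty predicted annotation: specificity undefined")

    metrics: Dict[str, LevelMetrics] = {}
    for level, getter in (
        ("base", _base_set),
        ("exon", _exon_set),
        ("intron", _intron_set),
    ):
        p_set, r_set = getter(pred), getter(ref)
        tp = len(p_set & r_set)
        metrics[level] = LevelMetrics.symmetric(
            level, tp, len(p_set) - tp, len(r_set) - tp
        )

    matched_pred, matched_ref = _matched_transcripts(pred, ref, mono_threshold)
    n_pred, n_ref = len(pred), len(ref)
    sn = 100.0 * len(matched_ref) / n_ref
    sp = 100.0 * len(matched_pred) / n_pred
    metrics["transcript"] = LevelMetrics(
        "transcript",
        tp=len(matched_ref),
        fp=n_pred - len(matched_pred),
        fn=n_ref - len(matched_ref),
        sensitivity=sn,
        specificity=sp,
        f1=harmonic_f1(sn, sp),
    )

    ref_genes_hit = {
        ref.transcripts[tid].gene_id for tid in matched_ref
    }
    pred_genes_hit = {
        pred.transcripts[tid].gene_id for tid in matched_pred
    }
    n_ref_genes, n_pred_genes = len(ref.genes), len(pred.genes)
    gene_sn = 100.0 * len(ref_genes_hit) / n_ref_genes
    gene_sp = 100.0 * len(pred_genes_hit) / n_pred_genes
    metrics["gene"] = LevelMetrics(
        "gene",
        tp=len(ref_genes_hit),
        fp=n_pred_genes - len(pred_genes_hit),
        fn=n_ref_genes - len(ref_genes_hit),
        sensitivity=gene_sn,
        specificity=gene_sp,
        f1=harmonic_f1(gene_sn, gene_sp),
    )

    aed = {t.transcript_id: compute_aed(t, ref) for t in pred}
    return ComparisonReport(metrics=metrics, aed=aed)
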