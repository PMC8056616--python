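"""Evidence-based confidence classes and tissue association.

A gene assembled or predicted by several independent lines of evidence —
expression in RNA-Seq data, an ab-initio gene prediction, a protein hit —
deserves more trust than one seen by a single method.  Genes supported by
at least two of the three evidence types are classed *high* confidence;
genes overlapping repeat regions are always demoted to *low*, since
transposon-derived ORFs routinely masquerade as genes.

The tissue/condition association records, for every transcript of the
consolidated annotation, which per-sample assemblies contain a structurally
matching transcript (intron-chain identity for multi-exonic transcripts,
reciprocal 80% overlap for mono-exonic ones).
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Set, Tuple

import numpy as np

from .evaluate import mono_overlap_match
from .models import Annotation, GenomicInterval, TranscriptModel


@dataclass(frozen=True)
class EvidenceFlags:
    expressed: bool = False
    predicted_ab_initio: bool = False
    protein_supported: bool = False
    in_repeat_region: bool = False


@dataclass(frozen=True)
class ConfidenceCall:
    gene_id: str
    confidence: str  # "high" | "low"
    evidence_count: int
    repeat_flagged: bool


def assign_confidence(
    flags: EvidenceFlags, gene_id: str = "", high_min_evidence: int = 2
) -> ConfidenceCall:
    """Classify a gene from its evidence flags.

    A repeat-region gene is always low confidence.  Otherwise the gene is
    high confidence when at least ``high_min_evidence`` of {expressed,
    predicted_ab_initio, protein_supported} hold; the default of 2
    reproduces both boundary cases of the rule set: all three evidence
    types give high confidence, and an ab-initio prediction with no
    expression or protein support gives low.
    """
    count = sum(
        (flags.expressed, flags.predicted_ab_initio, flags.protein_supported)
    )
    if flags.in_repeat_region:
        confidence = "low"
    else:
        confidence = "high" if count >= high_min_evidence else "low"
    return ConfidenceCall(
        gene_id=gene_id,
        confidence=confidence,
        evidence_count=count,
        repeat_flagged=flags.in_repeat_region,
    )


def _gene_exonic_positions(
    annotation: Annotation,
) -> Dict[str, Set[Tuple[str, int]]]:
    positions: Dict[str, Set[Tuple[str, int]]] = {}
    for t in annotation:
        bucket = positions.setdefault(t.gene_id, set())
        for ex in t.exons:
            bucket.update((t.chrom, pos) for pos in range(ex.start, ex.end + 1))
    return positions


def annotate_repeat_overlap(
    annotation: Annotation,
    repeats: Mapping[str, Iterable[GenomicInterval]],
    threshold: float = 0.5,
) -> Dict[str, bool]:
    """Flag genes whose exonic bases fall mostly within repeat intervals.

    The exonic base union over all of a gene's transcripts is intersected
    with the repeat intervals; the gene is flagged when the covered
    fraction reaches ``threshold`` (boundary inclusive).
    """
    repeat_positions: Dict[str, Set[int]] = {}
    for chrom, ivs in repeats.items():
        bucket = repeat_positions.setdefault(chrom, set())
        for iv in ivs:
            bucket.update(range(iv.start, iv.end + 1))
    flags: Dict[str, bool] = {}
    for gene_id, positions in _gene_exonic_positions(annotation).items():
        covered = sum(
            1 for chrom, pos in positions if pos in repeat_positions.get(chrom, ())
        )
        flags[gene_id] = covered / len(positions) >= threshold
    return flags


def score_annotation(
    annotation: Annotation,
    expressed_ids: Set[str],
    predicted_ids: Set[str],
    protein_ids: Set[str],
    repeats: Mapping[str, Iterable[GenomicInterval]] = (),
    repeat_threshold: float = 0.5,
    high_min_evidence: int = 2,
) -> Dict[str, ConfidenceCall]:
    """Confidence calls for every gene from transcript-level evidence lists.

    The id lists name transcripts; a gene carries a flag when any of its
    transcripts does.
    """
    repeat_flags = (
        annotate_repeat_overlap(annotation, repeats, repeat_threshold)
        if repeats
        else {}
    )
    calls: Dict[str, ConfidenceCall] = {}
    for gene_id, tids in annotation.genes.items():
        flags = EvidenceFlags(
            expressed=any(t in expressed_ids for t in tids),
            predicted_ab_initio=any(t in predicted_ids for t in tids),
            protein_supported=any(t in protein_ids for t in tids),
            in_repeat_region=repeat_flags.get(gene_id, False),
        )
        calls[gene_id] = assign_confidence(flags, gene_id, high_min_evidence)
    return calls


@dataclass
class TissueExpressionMatrix:
    """Boolean transcript x sample matrix of structural presence."""

    transcript_ids: Tuple[str, ...]
    labels: Tuple[str, ...]
    values: np.ndarray  # bool, shape (transcripts, labels)

    def cell(self, transcript_id: str, label: str) -> bool:
        i = self.transcript_ids.index(transcript_id)
        j = self.labels.index(label)
        return bool(self.values[i, j])

    def expressed_anywhere(self) -> Dict[str, bool]:
        return {
            tid: bool(self.values[i].any())
            for i, tid in enumerate(self.transcript_ids)
        }

    def to_tsv(self, path) -> None:
        with open(path, "w") as handle:
            handle.write("transcript_id\t" + "\t".join(self.labels) + "\n")
            for i, tid in enumerate(self.transcript_ids):
                row = "\t".join(str(int(v)) for v in self.values[i])
                handle.write(f"{tid}\t{row}\n")


def tissue_association(
    consolidated: Annotation,
    per_sample: Mapping[str, Annotation],
    mono_threshold: float = 0.8,
) -> TissueExpressionMatrix:
    """Mark, per sample, which consolidated transcripts it contains.

    A cell is true when the sample holds a transcript matching the
    consolidated one by intron-chain identity (multi-exonic) or by the
    mono-exonic reciprocal-overlap rule.
    """
    if not per_sample:
        raise ValueError("per_sample map must not be empty")
    labels = tuple(sorted(per_sample))
    tids = tuple(t.transcript_id for t in consolidated.transcripts_sorted())
    values = np.zeros((len(tids), len(labels)), dtype=bool)

    for j, label in enumerate(labels):
        sample = per_sample[label]
        chains: Set[Tuple[str, str, Tuple[Tuple[int, int], ...]]] = set()
        monos: Dict[Tuple[str, str], List[TranscriptModel]] = {}
        for s in sample:
            if s.is_mono_exonic:
                monos.setdefault((s.chrom, s.strand), []).append(s)
            else:
                chains.add((s.chrom, s.strand, s.introns))
        for i, tid in enumerate(tids):
            t = consolidated.transcripts[tid]
            if t.is_mono_exonic:
                values[i, j] = any(
                    mono_overlap_match(t, s, mono_threshold)
                    for s in monos.get((t.chrom, t.strand), [])
                )
            else:
                values[i, j] = (t.chrom, t.strand, t.introns) in chains
    return TissueExpressionMatrix(tids, labels, values)
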