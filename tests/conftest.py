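"""Shared helpers for the test suite."""
from __future__ import annotations

from typing import Sequence, Tuple

from txpolish import Annotation, GenomicInterval, TranscriptModel


def make_transcript(
    tid: str,
    exons: Sequence[Tuple[int, int]],
    strand: str = "+",
    gene: str | None = None,
    chrom: str = "chr1",
) -> TranscriptModel:
    return TranscriptModel(
        transcript_id=tid,
        gene_id=gene or tid.rsplit(".", 1)[0],
        exons=tuple(GenomicInterval(chrom, s, e, strand) for s, e in exons),
    )


def make_annotation(*transcripts: TranscriptModel) -> Annotation:
    return Annotation.from_transcripts(transcripts)
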