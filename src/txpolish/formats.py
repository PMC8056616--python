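"""Readers and writers for GTF, bedGraph, FASTA and BED.

GTF is read and written in 1-based inclusive coordinates.  bedGraph and BED
records are 0-based half-open on disk and converted to the internal 1-based
inclusive convention on read.
"""
from __future__ import annotations

import re
from pathlib import Path
from typing import Dict, List, Optional, Tuple, Union

import numpy as np
from Bio import SeqIO

from .models import (
    Annotation,
    CoverageTrack,
    GenomicInterval,
    GenomeSequence,
    TranscriptModel,
    ValidationError,
)

PathLike = Union[str, Path]

_ATTR_RE = re.compile(r'(\S+)\s+"([^"]*)"\s*;?')

# feature rows that are fully derivable from the exon rows and are therefore
# not round-tripped
_SKIPPED_FEATURES = {"transcript", "gene"}


class GtfParseError(ValueError):
    """Malformed GTF input; the message carries the offending line number."""


def _parse_attributes(field: str, lineno: int) -> Dict[str, str]:
    attrs = dict(_ATTR_RE.findall(field))
    if "gene_id" not in attrs or "transcript_id" not in attrs:
        raise GtfParseError(
            f"line {lineno}: attributes must contain gene_id and transcript_id"
        )
    return attrs


def parse_gtf(path: PathLike) -> Annotation:
    """Read a GTF file into an :class:`Annotation`.

    Exon rows define the transcript structures; CDS/start_codon/stop_codon
    rows are retained verbatim on the owning transcript but play no role in
    polishing.  ``transcript``/``gene`` summary rows are skipped (they are
    derivable).  Malformed rows raise :class:`GtfParseError` with the line
    number; structural problems (exon with start > end, overlapping exons,
    one transcript_id under two genes) raise :class:`ValidationError`.
    """
    order: List[str] = []
    exons: Dict[str, List[GenomicInterval]] = {}
    gene_of: Dict[str, str] = {}
    attrs_of: Dict[str, Dict[str, str]] = {}
    source_of: Dict[str, str] = {}
    extra_of: Dict[str, List[str]] = {}

    with open(path) as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise GtfParseError(
                    f"line {lineno}: expected 9 tab-delimited fields, "
                    f"got {len(fields)}"
                )
            chrom, source, feature, start_s, end_s, _score, strand, _frame, attr_s = (
                fields
            )
            if feature in _SKIPPED_FEATURES:
                continue
            attrs = _parse_attributes(attr_s, lineno)
            tid = attrs["transcript_id"]
            gid = attrs["gene_id"]
            if tid in gene_of and gene_of[tid] != gid:
                raise ValidationError(
                    f"transcript_id {tid!r} appears under two genes "
                    f"({gene_of[tid]!r} and {gid!r})"
                )
            if tid not in gene_of:
                gene_of[tid] = gid
                order.append(tid)
                exons[tid] = []
                extra_of[tid] = []
            if feature != "exon":
                extra_of[tid].append(line)
                continue
            try:
                start, end = int(start_s), int(end_s)
            except ValueError:
                raise GtfParseError(
                    f"line {lineno}: non-integer coordinates "
                    f"{start_s!r}/{end_s!r}"
                ) from None
            if start > end:
                raise ValidationError(
                    f"line {lineno}: exon start {start} > end {end} "
                    f"(transcript {tid})"
                )
            exons[tid].append(GenomicInterval(chrom, start, end, strand))
            source_of.setdefault(tid, source)
            if tid not in attrs_of:
                attrs_of[tid] = {
                    k: v
                    for k, v in attrs.items()
                    if k not in ("gene_id", "transcript_id")
                }

    transcripts = []
    for tid in order:
        if not exons[tid]:
            raise ValidationError(f"transcript {tid} has no exon features")
        sorted_exons = sorted(exons[tid], key=lambda e: e.start)
        try:
            model = TranscriptModel(
                transcript_id=tid,
                gene_id=gene_of[tid],
                exons=tuple(sorted_exons),
                attributes=attrs_of.get(tid, {}),
                source=source_of.get(tid, "."),
                extra_features=tuple(extra_of[tid]),
            )
        except ValidationError as exc:
            raise ValidationError(f"transcript {tid}: {exc}") from None
        transcripts.append(model)
    return Annotation.from_transcripts(transcripts)


def _format_attributes(transcript: TranscriptModel) -> str:
    parts = [
        f'gene_id "{transcript.gene_id}";',
        f'transcript_id "{transcript.transcript_id}";',
    ]
    for key, value in transcript.attributes.items():
        parts.append(f'{key} "{value}";')
    return " ".join(parts)


def write_gtf(annotation: Annotation, path: PathLike) -> None:
    """Write one exon row per exon, transcripts ordered by (chrom, start).

    Retained non-exon rows (CDS etc.) are emitted verbatim after their
    transcript's exons, so ``parse_gtf(write_gtf(A)) == A``.
    """
    with open(path, "w") as handle:
        for t in annotation.transcripts_sorted():
            attr_s = _format_attributes(t)
            for ex in t.exons:
                handle.write(
                    f"{t.chrom}\t{t.source}\texon\t{ex.start}\t{ex.end}\t."
                    f"\t{t.strand}\t.\t{attr_s}\n"
                )
            for line in t.extra_features:
                handle.write(line + "\n")


def parse_bedgraph(
    path: PathLike, genome: Optional[GenomeSequence] = None
) -> CoverageTrack:
    """Expand a 4-column bedGraph into per-base depth.

    Records are 0-based half-open; the returned track is 1-based.  Positions
    not covered by any record get depth 0; overlapping records are summed
    (the output of ``bedtools genomecov`` never overlaps, but sums are the
    only consistent semantics for general input).  When a genome is given,
    every chromosome present in it gets a vector of the full chromosome
    length, and records past the chromosome end are errors.
    """
    records: Dict[str, List[Tuple[int, int, float]]] = {}
    with open(path) as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split()
            if len(fields) < 4:
                raise ValidationError(
                    f"line {lineno}: bedGraph needs 4 columns, got {len(fields)}"
                )
            chrom = fields[0]
            start, end = int(fields[1]), int(fields[2])
            value = float(fields[3])
            if value < 0:
                raise ValidationError(f"line {lineno}: negative depth {value}")
            if end <= start:
                raise ValidationError(
                    f"line {lineno}: end {end} must exceed start {start}"
                )
            if start < 0:
                raise ValidationError(f"line {lineno}: negative start {start}")
            records.setdefault(chrom, []).append((start, end, value))

    depth: Dict[str, np.ndarray] = {}
    chroms = set(records)
    if genome is not None:
        chroms |= set(genome.seq)
    for chrom in sorted(chroms):
        recs = records.get(chrom, [])
        if genome is not None and chrom in genome:
            n = genome.length(chrom)
            for start, end, _value in recs:
                if end > n:
                    raise ValidationError(
                        f"bedGraph record {chrom}:{start}-{end} exceeds "
                        f"chromosome length {n}"
                    )
        else:
            n = max((end for _s, end, _v in recs), default=0)
        vec = np.zeros(n, dtype=float)
        for start, end, value in recs:
            vec[start:end] += value
        depth[chrom] = vec
    return CoverageTrack(depth)


def write_bedgraph(track: CoverageTrack, path: PathLike) -> None:
    """Write runs of constant non-zero depth as 0-based half-open records."""
    with open(path, "w") as handle:
        for chrom in sorted(track.depth):
            vec = track.depth[chrom]
            if len(vec) == 0:
                continue
            boundaries = np.flatnonzero(np.diff(vec)) + 1
            starts = np.concatenate(([0], boundaries))
            ends = np.concatenate((boundaries, [len(vec)]))
            for start, end in zip(starts, ends):
                value = vec[start]
                if value == 0:
                    continue
                text = f"{int(value)}" if float(value).is_integer() else f"{value}"
                handle.write(f"{chrom}\t{start}\t{end}\t{text}\n")


def read_fasta(path: PathLike) -> GenomeSequence:
    seqs = {
        record.id: str(record.seq).upper()
        for record in SeqIO.parse(str(path), "fasta")
    }
    return GenomeSequence(seqs)


def write_fasta(genome: GenomeSequence, path: PathLike, width: int = 60) -> None:
    with open(path, "w") as handle:
        for chrom in sorted(genome.seq):
            handle.write(f">{chrom}\n")
            seq = genome.seq[chrom]
            for i in range(0, len(seq), width):
                handle.write(seq[i : i + width] + "\n")


def read_bed(path: PathLike) -> Dict[str, List[GenomicInterval]]:
    """Read BED intervals (e.g. repeat regions) into 1-based inclusive form."""
    intervals: Dict[str, List[GenomicInterval]] = {}
    with open(path) as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split()
            if len(fields) < 3:
                raise ValidationError(
                    f"line {lineno}: BED needs at least 3 columns"
                )
            chrom = fields[0]
            start, end = int(fields[1]), int(fields[2])
            if end <= start or start < 0:
                raise ValidationError(
                    f"line {lineno}: invalid BED interval {start}-{end}"
                )
            intervals.setdefault(chrom, []).append(
                GenomicInterval(chrom, start + 1, end)
            )
    return intervals
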