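"""Core domain objects for transcript-model polishing.

All coordinates are 1-based and inclusive (the GTF convention).  Formats
that use other conventions (bedGraph, BED) are converted on read, so the
rest of the package never has to think about coordinate systems.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, Iterator, List, Mapping, Tuple

import numpy as np

VALID_STRANDS = ("+", "-", ".")

_RC_TABLE = str.maketrans("ACGTN", "TGCAN")


class ValidationError(ValueError):
    """Raised when a domain object violates one of its invariants."""


@dataclass(frozen=True)
class GenomicInterval:
    """A stranded, closed interval on a chromosome.

    ``start`` and ``end`` are 1-based inclusive; ``length`` is therefore
    ``end - start + 1`` and is always at least 1.
    """

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValidationError("chromosome name must be non-empty")
        if self.start < 1:
            raise ValidationError(f"start must be >= 1, got {self.start}")
        if self.end < self.start:
            raise ValidationError(
                f"end ({self.end}) < start ({self.start}) on {self.chrom}"
            )
        if self.strand not in VALID_STRANDS:
            raise ValidationError(
                f"strand must be one of {VALID_STRANDS}, got {self.strand!r}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def overlap_length(self, other: "GenomicInterval") -> int:
        """Number of shared bases with ``other`` (0 if different chromosome)."""
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start) + 1)

    def contains(self, other: "GenomicInterval") -> bool:
        """True if ``other`` lies entirely within this interval (same chrom)."""
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )


@dataclass(frozen=True)
class IntronChain:
    """Ordered intron coordinates of a transcript.

    Empty for mono-exonic transcripts.  Two multi-exonic transcripts with
    equal chains are structurally identical up to their terminal-exon
    extents, which is the matching rule used throughout evaluation.
    """

    introns: Tuple[Tuple[int, int], ...]

    def __len__(self) -> int:
        return len(self.introns)

    def __iter__(self) -> Iterator[Tuple[int, int]]:
        return iter(self.introns)

    def __bool__(self) -> bool:
        return bool(self.introns)


@dataclass(frozen=True)
class TranscriptModel:
    """A stranded multi-exon gene model: the unit being polished and scored.

    Invariants enforced at construction:

    * exons are sorted by start, strictly non-overlapping, and separated by
      at least one base (so every intron has length >= 1);
    * all exons share chromosome and strand.

    ``extra_features`` holds verbatim non-exon GTF lines (CDS, start/stop
    codon) attached to the transcript; they are carried through I/O but
    never consulted by polishing.
    """

    transcript_id: str
    gene_id: str
    exons: Tuple[GenomicInterval, ...]
    attributes: Mapping[str, str] = field(default_factory=dict)
    source: str = "txpolish"
    extra_features: Tuple[str, ...] = ()

    def __post_init__(self) -> None:
        exons = tuple(self.exons)
        object.__setattr__(self, "exons", exons)
        object.__setattr__(self, "attributes", dict(self.attributes))
        object.__setattr__(self, "extra_features", tuple(self.extra_features))
        if not self.transcript_id:
            raise ValidationError("transcript_id must be non-empty")
        if not self.gene_id:
            raise ValidationError("gene_id must be non-empty")
        if not exons:
            raise ValidationError(
                f"transcript {self.transcript_id}: must have at least one exon"
            )
        chrom = exons[0].chrom
        strand = exons[0].strand
        for ex in exons[1:]:
            if ex.chrom != chrom or ex.strand != strand:
                raise ValidationError(
                    f"transcript {self.transcript_id}: exons span multiple "
                    "chromosomes or strands"
                )
        for prev, cur in zip(exons, exons[1:]):
            if cur.start <= prev.end + 1:
                raise ValidationError(
                    f"transcript {self.transcript_id}: exons "
                    f"{prev.start}-{prev.end} and {cur.start}-{cur.end} "
                    "overlap or touch"
                )

    @property
    def chrom(self) -> str:
        return self.exons[0].chrom

    @property
    def strand(self) -> str:
        return self.exons[0].strand

    @property
    def start(self) -> int:
        return self.exons[0].start

    @property
    def end(self) -> int:
        return self.exons[-1].end

    @property
    def interval(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.end, self.strand)

    @property
    def is_mono_exonic(self) -> bool:
        return len(self.exons) == 1

    @property
    def introns(self) -> Tuple[Tuple[int, int], ...]:
        return tuple(
            (prev.end + 1, cur.start - 1)
            for prev, cur in zip(self.exons, self.exons[1:])
        )

    @property
    def exonic_length(self) -> int:
        return sum(ex.length for ex in self.exons)


def derive_intron_chain(transcript: TranscriptModel) -> IntronChain:
    """Intron chain implied by the transcript's exons (empty if mono-exonic)."""
    return IntronChain(transcript.introns)


@dataclass
class Annotation:
    """A collection of transcripts with a derived gene -> transcripts map."""

    transcripts: Dict[str, TranscriptModel] = field(default_factory=dict)
    genes: Dict[str, List[str]] = field(default_factory=dict)

    @classmethod
    def from_transcripts(cls, transcripts: Iterable[TranscriptModel]) -> "Annotation":
        tmap: Dict[str, TranscriptModel] = {}
        genes: Dict[str, List[str]] = {}
        for t in transcripts:
            if t.transcript_id in tmap:
                raise ValidationError(
                    f"duplicate transcript_id {t.transcript_id!r}"
                )
            tmap[t.transcript_id] = t
            genes.setdefault(t.gene_id, []).append(t.transcript_id)
        return cls(tmap, genes)

    def __len__(self) -> int:
        return len(self.transcripts)

    def __iter__(self) -> Iterator[TranscriptModel]:
        return iter(self.transcripts.values())

    def __contains__(self, transcript_id: str) -> bool:
        return transcript_id in self.transcripts

    def transcripts_sorted(self) -> List[TranscriptModel]:
        """Transcripts ordered by (chrom, start, transcript_id)."""
        return sorted(
            self.transcripts.values(),
            key=lambda t: (t.chrom, t.start, t.transcript_id),
        )

    def chroms(self) -> List[str]:
        return sorted({t.chrom for t in self})


@dataclass
class CoverageTrack:
    """Per-base read depth, one vector per chromosome.

    ``depth[chrom][i]`` is the depth at 1-based position ``i + 1``.
    Positions beyond the stored vector are treated as depth 0.
    """

    depth: Dict[str, np.ndarray] = field(default_factory=dict)

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.depth

    def chrom_depth(self, chrom: str) -> np.ndarray:
        try:
            return self.depth[chrom]
        except KeyError:
            raise ValidationError(f"no coverage for chromosome {chrom!r}") from None

    def interval_depth(self, interval: GenomicInterval) -> np.ndarray:
        """Depth vector over ``interval`` (zero-padded past the track end)."""
        vec = self.chrom_depth(interval.chrom)
        out = np.zeros(interval.length, dtype=float)
        hi = min(interval.end, len(vec))
        if hi >= interval.start:
            out[: hi - interval.start + 1] = vec[interval.start - 1 : hi]
        return out

    def equals(self, other: "CoverageTrack") -> bool:
        if set(self.depth) != set(other.depth):
            return False
        return all(np.array_equal(self.depth[c], other.depth[c]) for c in self.depth)


@dataclass
class GenomeSequence:
    """Uppercase nucleotide sequences keyed by chromosome name."""

    seq: Dict[str, str] = field(default_factory=dict)

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.seq

    def length(self, chrom: str) -> int:
        try:
            return len(self.seq[chrom])
        except KeyError:
            raise ValidationError(f"no sequence for chromosome {chrom!r}") from None

    def fetch(self, chrom: str, start: int, end: int) -> str:
        """Subsequence in 1-based inclusive coordinates; out of bounds is an error."""
        n = self.length(chrom)
        if start < 1 or end > n or end < start:
            raise ValidationError(
                f"coordinates {start}-{end} out of bounds for {chrom} (length {n})"
            )
        return self.seq[chrom][start - 1 : end]


def reverse_complement(seq: str) -> str:
    return seq.translate(_RC_TABLE)[::-1]


def exon_sequence(exon: GenomicInterval, genome: GenomeSequence) -> str:
    """Strand-oriented exon sequence.

    Plus-strand (and unstranded) exons return the genome substring as-is;
    minus-strand exons return its reverse complement.  Unstranded exons are
    read on the plus strand by convention.
    """
    raw = genome.fetch(exon.chrom, exon.start, exon.end).upper()
    if exon.strand == "-":
        return reverse_complement(raw)
    return raw
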