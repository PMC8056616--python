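"""Seeded generators of genomes, annotations and coverage with known truth.

Every generator emulates a failure mode of meta-assembled transcript
models so the repair operators can be tested without any sequencing data:

* **merged-gene fixture** — two closely spaced same-strand genes whose
  terminal exons are fused into one exon across a low-coverage inter-gene
  gap;
* **antisense fixture** — two closely spaced opposite-strand genes where
  one terminal exon has been extended across the neighbour, up to the
  neighbour's nearest intron;
* **combined fixture** — one merged locus, one antisense pair and two
  planted redundant transcripts, for end-to-end polishing tests;
* **annotation pair** — a reference annotation plus a prediction with
  controlled corruption (dropped transcripts, shifted introns, truncated
  ends, spurious additions) and independently computed truth metrics.

Sequence content is synthetic: the background tiles ``AAC`` (no stop codon
in any frame) and fused exons tile ``TAAA`` (a stop codon in every frame),
so the premature-stop candidate screen fires exactly on the planted fusion
exons.  Real sequence statistics are irrelevant to the operators under
test.  Coverage noise defaults to exponential, matching the detector's
model family; Poisson noise is available to test model misspecification.
"""
from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np

from .evaluate import ComparisonReport, LevelMetrics
from .formats import write_bedgraph, write_fasta, write_gtf
from .models import (
    Annotation,
    CoverageTrack,
    GenomicInterval,
    GenomeSequence,
    TranscriptModel,
)

NOISE_MODELS = ("none", "exponential", "poisson")

_MIN_DETECTABLE_GAP = 20  # a trough narrower than one admissible segment
                          # cannot be recovered by the default detector


def simulate_exon_coverage(
    segments: Sequence[Tuple[int, float]],
    noise: str = "none",
    seed: int = 0,
    rng: Optional[np.random.Generator] = None,
) -> np.ndarray:
    """Piecewise-constant depth with optional per-base noise.

    ``segments`` is a list of (length, mean_depth).  ``none`` gives exact
    rounded plateaus; ``exponential`` draws each base from an exponential
    with the segment mean (floored to integer depth); ``poisson`` draws
    Poisson counts at the segment mean.
    """
    if noise not in NOISE_MODELS:
        raise ValueError(f"unknown noise model {noise!r}; use one of {NOISE_MODELS}")
    if rng is None:
        rng = np.random.default_rng(seed)
    parts = []
    for length, mean in segments:
        if length < 1:
            raise ValueError(f"segment length must be >= 1, got {length}")
        if mean < 0:
            raise ValueError(f"segment mean must be >= 0, got {mean}")
        if noise == "none" or mean == 0:
            parts.append(np.full(length, round(mean), dtype=np.int64))
        elif noise == "exponential":
            parts.append(np.floor(rng.exponential(mean, length)).astype(np.int64))
        else:
            parts.append(rng.poisson(mean, length).astype(np.int64))
    return np.concatenate(parts) if parts else np.zeros(0, dtype=np.int64)


@dataclass
class FixtureTruth:
    true_annotation: Annotation
    input_annotation: Annotation
    events: List[Dict[str, object]]
    seed: int
    params: object


@dataclass
class SimulatedFixture:
    genome: GenomeSequence
    annotation: Annotation  # the deliberately corrupted input
    coverage: CoverageTrack
    truth: FixtureTruth

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_fasta(self.genome, outdir / "genome.fa")
        write_gtf(self.annotation, outdir / "input.gtf")
        write_gtf(self.truth.true_annotation, outdir / "truth.gtf")
        write_bedgraph(self.coverage, outdir / "coverage.bedgraph")
        with open(outdir / "truth.json", "w") as handle:
            json.dump(
                {
                    "seed": self.truth.seed,
                    "params": dataclasses.asdict(self.truth.params)
                    if dataclasses.is_dataclass(self.truth.params)
                    else self.truth.params,
                    "events": self.truth.events,
                },
                handle,
                indent=2,
            )
            handle.write("\n")


def _gene_exons(
    chrom: str,
    strand: str,
    start: int,
    exon_lengths: Sequence[int],
    intron_length: int,
) -> Tuple[GenomicInterval, ...]:
    exons = []
    pos = start
    for length in exon_lengths:
        exons.append(GenomicInterval(chrom, pos, pos + length - 1, strand))
        pos += length + intron_length
    return tuple(exons)


def _background_genome(chrom: str, length: int) -> Dict[str, str]:
    # AAC tiling: frames read AAC/ACA/CAA, never a stop codon
    return {chrom: ("AAC" * (length // 3 + 1))[:length]}


def _plant_stop_rich(seq: Dict[str, str], chrom: str, region: Tuple[int, int]) -> None:
    # TAAA tiling: every frame contains TAA within any 6-base window
    start, end = region
    length = end - start + 1
    patch = ("TAAA" * (length // 4 + 1))[:length]
    s = seq[chrom]
    seq[chrom] = s[: start - 1] + patch + s[end:]


def _fill_coverage(
    length: int,
    regions: Sequence[Tuple[int, int, float]],
    noise: str,
    rng: np.random.Generator,
) -> np.ndarray:
    vec = np.zeros(length, dtype=float)
    for start, end, mean in regions:
        vec[start - 1 : end] = simulate_exon_coverage(
            [(end - start + 1, mean)], noise=noise, rng=rng
        )
    return vec


# ---------------------------------------------------------------------------
# merged-gene fixture


@dataclass(frozen=True)
class MergedGeneParams:
    exon_length: int = 200
    intron_length: int = 100
    gap: int = 40
    exon_mean: float = 50.0
    trough_mean: float = 2.0
    noise: str = "exponential"
    offset: int = 100
    chrom: str = "chr1"


def simulate_merged_gene_fixture(
    seed: int = 0, params: MergedGeneParams = MergedGeneParams()
) -> SimulatedFixture:
    """Two same-strand genes fused across a coverage trough.

    The input annotation carries a single transcript whose middle exon
    spans gene A's last exon, the inter-gene gap, and gene B's first exon;
    the truth holds the two separate genes.  The fused exon sequence is
    stop-rich in all frames, so it is the unique split candidate.
    """
    if params.gap < _MIN_DETECTABLE_GAP:
        raise ValueError(
            f"inter-gene gap {params.gap} is narrower than the shortest "
            f"admissible trough segment ({_MIN_DETECTABLE_GAP} bases)"
        )
    chrom, el, il = params.chrom, params.exon_length, params.intron_length
    a_exons = _gene_exons(chrom, "+", params.offset + 1, [el, el, el], il)
    b_start = a_exons[-1].end + params.gap + 1
    b_exons = _gene_exons(chrom, "+", b_start, [el, el, el], il)
    gap_region = (a_exons[-1].end + 1, b_exons[0].start - 1)
    fused = GenomicInterval(chrom, a_exons[-1].start, b_exons[0].end, "+")
    length = b_exons[-1].end + params.offset

    true_ann = Annotation.from_transcripts(
        [
            TranscriptModel("geneA.1", "geneA", a_exons),
            TranscriptModel("geneB.1", "geneB", b_exons),
        ]
    )
    merged = TranscriptModel(
        "merged.1", "merged", a_exons[:2] + (fused,) + b_exons[1:]
    )
    input_ann = Annotation.from_transcripts([merged])

    seq = _background_genome(chrom, length)
    _plant_stop_rich(seq, chrom, (fused.start, fused.end))
    genome = GenomeSequence(seq)

    rng = np.random.default_rng(seed)
    regions = [(ex.start, ex.end, params.exon_mean) for ex in a_exons + b_exons]
    regions.append((gap_region[0], gap_region[1], params.trough_mean))
    coverage = CoverageTrack(
        {chrom: _fill_coverage(length, regions, params.noise, rng)}
    )

    truth = FixtureTruth(
        true_annotation=true_ann,
        input_annotation=input_ann,
        events=[
            {
                "kind": "merge",
                "transcript_id": "merged.1",
                "fused_exon_index": 2,
                "trough_start": gap_region[0],
                "trough_end": gap_region[1],
                "left_true_end": a_exons[-1].end,
                "right_true_start": b_exons[0].start,
            }
        ],
        seed=seed,
        params=params,
    )
    return SimulatedFixture(genome, input_ann, coverage, truth)


# ---------------------------------------------------------------------------
# antisense fixture


@dataclass(frozen=True)
class AntisenseParams:
    exon_length: int = 200
    terminal_exon_length: int = 300
    intron_length: int = 100
    gap: int = 60
    exon_mean: float = 50.0
    gap_mean: float = 2.0
    noise: str = "exponential"
    offset: int = 100
    chrom: str = "chr1"


def simulate_antisense_fixture(
    seed: int = 0, params: AntisenseParams = AntisenseParams()
) -> SimulatedFixture:
    """Opposite-strand neighbours with one terminal exon extended too far.

    The plus-strand gene's last exon is extended across the gap and the
    minus-strand gene's near exon, stopping at that gene's nearest intron —
    the geometry a meta-assembler produces when antisense reads bleed
    together.  Coverage drops to ``gap_mean`` over the true inter-gene gap.
    """
    if params.gap < _MIN_DETECTABLE_GAP:
        raise ValueError(
            f"inter-gene gap {params.gap} is narrower than the shortest "
            f"admissible segment ({_MIN_DETECTABLE_GAP} bases)"
        )
    chrom = params.chrom
    a_exons = _gene_exons(
        chrom, "+", params.offset + 1,
        [params.exon_length, params.terminal_exon_length], params.intron_length,
    )
    b_start = a_exons[-1].end + params.gap + 1
    b_exons = _gene_exons(
        chrom, "-", b_start, [params.exon_length, params.exon_length],
        params.intron_length,
    )
    length = b_exons[-1].end + params.offset
    gap_region = (a_exons[-1].end + 1, b_exons[0].start - 1)

    true_ann = Annotation.from_transcripts(
        [
            TranscriptModel("geneA.1", "geneA", a_exons),
            TranscriptModel("geneB.1", "geneB", b_exons),
        ]
    )
    extended_terminal = GenomicInterval(
        chrom, a_exons[-1].start, b_exons[0].end, "+"
    )
    input_ann = Annotation.from_transcripts(
        [
            TranscriptModel("geneA.1", "geneA", a_exons[:-1] + (extended_terminal,)),
            TranscriptModel("geneB.1", "geneB", b_exons),
        ]
    )

    genome = GenomeSequence(_background_genome(chrom, length))
    rng = np.random.default_rng(seed)
    regions = [(ex.start, ex.end, params.exon_mean) for ex in a_exons + b_exons]
    regions.append((gap_region[0], gap_region[1], params.gap_mean))
    coverage = CoverageTrack(
        {chrom: _fill_coverage(length, regions, params.noise, rng)}
    )

    truth = FixtureTruth(
        true_annotation=true_ann,
        input_annotation=input_ann,
        events=[
            {
                "kind": "antisense_overlap",
                "transcript_id": "geneA.1",
                "which_end": "right",
                "true_end": a_exons[-1].end,
                "opposing": "geneB.1",
            }
        ],
        seed=seed,
        params=params,
    )
    return SimulatedFixture(genome, input_ann, coverage, truth)


# ---------------------------------------------------------------------------
# combined fixture


@dataclass(frozen=True)
class CombinedParams:
    exon_mean: float = 50.0
    trough_mean: float = 2.0
    noise: str = "exponential"
    chrom: str = "chr1"


def simulate_combined_fixture(
    seed: int = 0, params: CombinedParams = CombinedParams()
) -> SimulatedFixture:
    """One merged locus, one antisense pair and two redundant transcripts.

    The input annotation holds five transcripts: a fused two-gene model, an
    opposite-strand pair with one over-extended terminal exon, a multi-
    exonic transcript whose chain is a proper subchain of the fused model,
    and a mono-exonic transcript inside one of its exons.  The truth holds
    the four real genes.
    """
    chrom = params.chrom
    g1 = _gene_exons(chrom, "+", 101, [200, 200, 200], 100)      # ends 900
    g2 = _gene_exons(chrom, "+", 941, [200, 200, 200], 100)      # ends 1740
    fused = GenomicInterval(chrom, g1[-1].start, g2[0].end, "+")  # 701-1140
    g3 = _gene_exons(chrom, "+", 3101, [200, 300], 100)          # ends 3700
    g4 = _gene_exons(chrom, "-", 3761, [200, 200], 100)          # ends 4260
    g3_extended = GenomicInterval(chrom, g3[-1].start, g4[0].end, "+")
    length = 4400

    true_ann = Annotation.from_transcripts(
        [
            TranscriptModel("G1.1", "G1", g1),
            TranscriptModel("G2.1", "G2", g2),
            TranscriptModel("G3.1", "G3", g3),
            TranscriptModel("G4.1", "G4", g4),
        ]
    )
    input_ann = Annotation.from_transcripts(
        [
            TranscriptModel("merged.1", "merged", g1[:2] + (fused,) + g2[1:]),
            TranscriptModel("G3.1", "G3", g3[:-1] + (g3_extended,)),
            TranscriptModel("G4.1", "G4", g4),
            TranscriptModel("dupA.1", "dupA", g1[:2]),           # proper subchain
            TranscriptModel(
                "dupB.1", "dupB",
                (GenomicInterval(chrom, 450, 550, "+"),),         # inside an exon
            ),
        ]
    )

    seq = _background_genome(chrom, length)
    _plant_stop_rich(seq, chrom, (fused.start, fused.end))
    genome = GenomeSequence(seq)

    rng = np.random.default_rng(seed)
    regions = [(ex.start, ex.end, params.exon_mean) for ex in g1 + g2 + g3 + g4]
    regions.append((g1[-1].end + 1, g2[0].start - 1, params.trough_mean))
    regions.append((g3[-1].end + 1, g4[0].start - 1, params.trough_mean))
    coverage = CoverageTrack(
        {chrom: _fill_coverage(length, regions, params.noise, rng)}
    )

    truth = FixtureTruth(
        true_annotation=true_ann,
        input_annotation=input_ann,
        events=[
            {
                "kind": "merge",
                "transcript_id": "merged.1",
                "fused_exon_index": 2,
                "trough_start": g1[-1].end + 1,
                "trough_end": g2[0].start - 1,
                "left_true_end": g1[-1].end,
                "right_true_start": g2[0].start,
            },
            {
                "kind": "antisense_overlap",
                "transcript_id": "G3.1",
                "which_end": "right",
                "true_end": g3[-1].end,
                "opposing": "G4.1",
            },
            {"kind": "duplicate", "transcript_id": "dupA.1"},
            {"kind": "duplicate", "transcript_id": "dupB.1"},
        ],
        seed=seed,
        params=params,
    )
    return SimulatedFixture(genome, input_ann, coverage, truth)


# ---------------------------------------------------------------------------
# prediction/reference pair with independently computed truth metrics


@dataclass(frozen=True)
class PairParams:
    n_genes: int = 30
    mono_fraction: float = 0.2
    p_two_isoforms: float = 0.3
    p_drop: float = 0.15
    p_intron_shift: float = 0.15
    p_truncate: float = 0.25
    n_spurious: int = 3
    mono_threshold: float = 0.8
    chrom: str = "chr1"


@dataclass
class AnnotationPair:
    pred: Annotation
    ref: Annotation
    truth: ComparisonReport
    dropped_ids: List[str]
    shifted_ids: List[str]
    truncated_ids: List[str]
    spurious_ids: List[str]
    seed: int
    params: PairParams


def _random_transcript(
    rng: np.random.Generator,
    chrom: str,
    start: int,
    gene_id: str,
    transcript_id: str,
    mono: bool,
) -> TranscriptModel:
    strand = "+" if rng.random() < 0.5 else "-"
    if mono:
        length = int(rng.integers(250, 401))
        exons = (GenomicInterval(chrom, start, start + length - 1, strand),)
    else:
        n_exons = int(rng.integers(2, 5))
        lengths = [int(rng.integers(150, 301)) for _ in range(n_exons)]
        introns = [int(rng.integers(80, 201)) for _ in range(n_exons - 1)]
        exons = []
        pos = start
        for i, length in enumerate(lengths):
            exons.append(GenomicInterval(chrom, pos, pos + length - 1, strand))
            pos += length
            if i < n_exons - 1:
                pos += introns[i]
        exons = tuple(exons)
    return TranscriptModel(transcript_id, gene_id, exons)


def _second_isoform(
    rng: np.random.Generator, base: TranscriptModel
) -> Optional[TranscriptModel]:
    tid = base.transcript_id.rsplit(".", 1)[0] + ".2"
    if len(base.exons) >= 3:
        drop = int(rng.integers(1, len(base.exons) - 1))
        exons = base.exons[:drop] + base.exons[drop + 1 :]
        return TranscriptModel(tid, base.gene_id, exons)
    if len(base.exons) == 2:
        first = base.exons[0]
        shifted = dataclasses.replace(first, end=first.end + 12)
        if shifted.end + 2 <= base.exons[1].start:
            return TranscriptModel(tid, base.gene_id, (shifted, base.exons[1]))
    return None


def simulate_annotation_pair(
    seed: int = 0, params: PairParams = PairParams()
) -> AnnotationPair:
    """A reference annotation and a corrupted prediction with truth metrics.

    Corruptions are applied independently per reference transcript: drop,
    intron-boundary shift (+3 bases, breaking the chain), or end truncation
    (10-90 bases off the first exon, preserving the chain for multi-exonic
    transcripts but sometimes breaking the 80% rule for mono-exonic ones).
    Spurious transcripts are added in otherwise empty regions.  The truth
    report is computed by naive set arithmetic inside this generator,
    independent of the evaluator.
    """
    rng = np.random.default_rng(seed)
    chrom = params.chrom
    ref_transcripts: List[TranscriptModel] = []
    cursor = 1000
    for g in range(params.n_genes):
        mono = rng.random() < params.mono_fraction
        gene_id = f"g{g:03d}"
        base = _random_transcript(rng, chrom, cursor, gene_id, f"{gene_id}.1", mono)
        ref_transcripts.append(base)
        if not mono and rng.random() < params.p_two_isoforms:
            iso = _second_isoform(rng, base)
            if iso is not None:
                ref_transcripts.append(iso)
        cursor = base.end + int(rng.integers(500, 1501))
    ref = Annotation.from_transcripts(ref_transcripts)

    pred_transcripts: List[TranscriptModel] = []
    dropped, shifted, truncated = [], [], []
    for t in ref_transcripts:
        if rng.random() < params.p_drop:
            dropped.append(t.transcript_id)
            continue
        out = t
        if not t.is_mono_exonic and rng.random() < params.p_intron_shift:
            j = int(rng.integers(0, len(t.exons) - 1))
            bumped = dataclasses.replace(t.exons[j], end=t.exons[j].end + 3)
            out = TranscriptModel(
                t.transcript_id, t.gene_id,
                t.exons[:j] + (bumped,) + t.exons[j + 1 :],
            )
            shifted.append(t.transcript_id)
        elif rng.random() < params.p_truncate:
            d = int(rng.integers(10, 91))
            first = out.exons[0]
            if first.length > d + 10:
                trimmed = dataclasses.replace(first, start=first.start + d)
                out = TranscriptModel(
                    out.transcript_id, out.gene_id, (trimmed,) + out.exons[1:]
                )
                truncated.append(t.transcript_id)
        pred_transcripts.append(out)

    spurious = []
    for i in range(params.n_spurious):
        gene_id = f"spur{i:02d}"
        t = _random_transcript(
            rng, chrom, cursor, gene_id, f"{gene_id}.1",
            mono=rng.random() < params.mono_fraction,
        )
        spurious.append(t.transcript_id)
        pred_transcripts.append(t)
        cursor = t.end + int(rng.integers(500, 1501))
    pred = Annotation.from_transcripts(pred_transcripts)

    truth = naive_compare(pred, ref, params.mono_threshold)
    return AnnotationPair(
        pred=pred,
        ref=ref,
        truth=truth,
        dropped_ids=dropped,
        shifted_ids=shifted,
        truncated_ids=truncated,
        spurious_ids=spurious,
        seed=seed,
        params=params,
    )


# ---------------------------------------------------------------------------
# naive set-arithmetic comparison (test oracle for the evaluator)


def _naive_match(p: TranscriptModel, r: TranscriptModel, threshold: float) -> bool:
    if p.chrom != r.chrom or p.strand != r.strand:
        return False
    if p.is_mono_exonic != r.is_mono_exonic:
        return False
    if p.is_mono_exonic:
        lo = max(p.start, r.start)
        hi = min(p.end, r.end)
        shared = max(0, hi - lo + 1)
        return shared / max(p.exonic_length, r.exonic_length) >= threshold
    return p.introns == r.introns


def naive_compare(
    pred: Annotation, ref: Annotation, mono_threshold: float = 0.8
) -> ComparisonReport:
    """Straight-line set-arithmetic comparison used as a truth oracle.

    Deliberately unoptimized: explicit position sets and quadratic loops,
    so its correctness is auditable at a glance.
    """
    def bases(ann: Annotation) -> Set[Tuple[str, str, int]]:
        out = set()
        for t in ann:
            for ex in t.exons:
                for pos in range(ex.start, ex.end + 1):
                    out.add((t.chrom, t.strand, pos))
        return out

    def level(name: str, p: Set, r: Set) -> LevelMetrics:
        tp = len(p & r)
        fp = len(p - r)
        fn = len(r - p)
        sn = 100.0 * tp / (tp + fn) if tp + fn else 0.0
        sp = 100.0 * tp / (tp + fp) if tp + fp else 0.0
        f1 = 2 * sn * sp / (sn + sp) if sn > 0 and sp > 0 else 0.0
        return LevelMetrics(name, tp, fp, fn, sn, sp, f1)

    metrics = {"base": level("base", bases(pred), bases(ref))}
    p_exons = {(t.chrom, t.strand, e.start, e.end) for t in pred for e in t.exons}
    r_exons = {(t.chrom, t.strand, e.start, e.end) for t in ref for e in t.exons}
    metrics["exon"] = level("exon", p_exons, r_exons)
    p_introns = {(t.chrom, t.strand, s, e) for t in pred for s, e in t.introns}
    r_introns = {(t.chrom, t.strand, s, e) for t in ref for s, e in t.introns}
    metrics["intron"] = level("intron", p_introns, r_introns)

    matched_pred = {
        p.transcript_id
        for p in pred
        if any(_naive_match(p, r, mono_threshold) for r in ref)
    }
    matched_ref = {
        r.transcript_id
        for r in ref
        if any(_naive_match(p, r, mono_threshold) for p in pred)
    }
    sn = 100.0 * len(matched_ref) / len(ref)
    sp = 100.0 * len(matched_pred) / len(pred)
    f1 = 2 * sn * sp / (sn + sp) if sn > 0 and sp > 0 else 0.0
    metrics["transcript"] = LevelMetrics(
        "transcript", len(matched_ref), len(pred) - len(matched_pred),
        len(ref) - len(matched_ref), sn, sp, f1,
    )

    ref_genes_hit = {ref.transcripts[tid].gene_id for tid in matched_ref}
    pred_genes_hit = {pred.transcripts[tid].gene_id for tid in matched_pred}
    gsn = 100.0 * len(ref_genes_hit) / len(ref.genes)
    gsp = 100.0 * len(pred_genes_hit) / len(pred.genes)
    gf1 = 2 * gsn * gsp / (gsn + gsp) if gsn > 0 and gsp > 0 else 0.0
    metrics["gene"] = LevelMetrics(
        "gene", len(ref_genes_hit), len(pred.genes) - len(pred_genes_hit),
        len(ref.genes) - len(ref_genes_hit), gsn, gsp, gf1,
    )

    aed: Dict[str, float] = {}
    for p in pred:
        p_bases = {pos for e in p.exons for pos in range(e.start, e.end + 1)}
        best = None
        for r in ref:
            if r.chrom != p.chrom or r.strand != p.strand:
                continue
            r_bases = {pos for e in r.exons for pos in range(e.start, e.end + 1)}
            shared = len(p_bases & r_bases)
            if shared == 0:
                continue
            c = (shared / len(r_bases) + shared / len(p_bases)) / 2
            if best is None or c > best:
                best = c
        aed[p.transcript_id] = 1.0 if best is None else 1.0 - best
    return ComparisonReport(metrics=metrics, aed=aed)


# ---------------------------------------------------------------------------
# random annotations with planted redundancy


def random_redundant_annotation(
    seed: int = 0, n_base: int = 6, n_subsets: int = 4
) -> Tuple[Annotation, List[str]]:
    """An annotation of unique base transcripts plus planted proper subsets.

    Each subset is strictly dominated by its base transcript: a same-chain
    copy with a strictly shorter span, a proper contiguous subchain, or a
    mono-exonic transcript inside one exon.  Returns the annotation and the
    ids that redundancy removal must delete.
    """
    rng = np.random.default_rng(seed)
    chrom = "chr1"
    bases: List[TranscriptModel] = []
    cursor = 1000
    for i in range(n_base):
        t = _random_transcript(
            rng, chrom, cursor, f"base{i:02d}", f"base{i:02d}.1", mono=False
        )
        while len(t.exons) < 3:  # subsets need room; force >= 3 exons
            t = _random_transcript(
                rng, chrom, cursor, f"base{i:02d}", f"base{i:02d}.1", mono=False
            )
        bases.append(t)
        cursor = t.end + int(rng.integers(500, 1501))

    subsets: List[TranscriptModel] = []
    for i in range(n_subsets):
        parent = bases[int(rng.integers(0, len(bases)))]
        kind = ("shrunk", "subchain", "mono")[int(rng.integers(0, 3))]
        tid, gid = f"sub{i:02d}.1", f"sub{i:02d}"
        if kind == "shrunk":
            d1 = int(rng.integers(1, 31))
            d2 = int(rng.integers(1, 31))
            first = dataclasses.replace(
                parent.exons[0], start=parent.exons[0].start + d1
            )
            last = dataclasses.replace(
                parent.exons[-1], end=parent.exons[-1].end - d2
            )
            exons = (first,) + parent.exons[1:-1] + (last,)
        elif kind == "subchain":
            exons = parent.exons[1:] if rng.random() < 0.5 else parent.exons[:-1]
        else:
            ex = parent.exons[int(rng.integers(0, len(parent.exons)))]
            exons = (
                dataclasses.replace(ex, start=ex.start + 5, end=ex.end - 5),
            )
        subsets.append(TranscriptModel(tid, gid, exons))
    ann = Annotation.from_transcripts(bases + subsets)
    return ann, sorted(t.transcript_id for t in subsets)
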