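"""Domain types, coordinate conventions and file round-trips."""
import tempfile
from pathlib import Path

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from conftest import make_annotation, make_transcript

from txpolish import (
    Annotation,
    GenomicInterval,
    GenomeSequence,
    TranscriptModel,
    ValidationError,
    derive_intron_chain,
    exon_sequence,
    parse_bedgraph,
    parse_gtf,
    write_gtf,
)
from txpolish.formats import GtfParseError, read_bed, read_fasta, write_fasta


class TestGenomicInterval:
    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(chrom="", start=1, end=5),
            dict(chrom="chr1", start=0, end=5),
            dict(chrom="chr1", start=10, end=5),
            dict(chrom="chr1", start=1, end=5, strand="x"),
        ],
    )
    def test_invalid_intervals_rejected(self, kwargs):
        with pytest.raises(ValidationError):
            GenomicInterval(**kwargs)

    def test_length_is_inclusive(self):
        assert GenomicInterval("chr1", 5, 5).length == 1
        assert GenomicInterval("chr1", 101, 200).length == 100


class TestTranscriptModel:
    def test_overlapping_exons_rejected(self):
        with pytest.raises(ValidationError, match="t1"):
            make_transcript("t1.1", [(1, 100), (50, 150)])

    def test_touching_exons_rejected(self):
        # adjacent exons would imply a zero-length intron
        with pytest.raises(ValidationError):
            make_transcript("t1.1", [(1, 100), (101, 200)])

    def test_mixed_strand_exons_rejected(self):
        with pytest.raises(ValidationError):
            TranscriptModel(
                "t1.1",
                "t1",
                (
                    GenomicInterval("chr1", 1, 100, "+"),
                    GenomicInterval("chr1", 200, 300, "-"),
                ),
            )

    def test_interval_spans_exons(self):
        t = make_transcript("t1.1", [(101, 200), (301, 400)])
        assert (t.start, t.end) == (101, 400)
        assert t.exonic_length == 200

    @pytest.mark.parametrize(
        "exons,expected",
        [
            ([(101, 200), (301, 400)], ((201, 300),)),
            ([(101, 400)], ()),
            ([(1, 10), (12, 20), (30, 40)], ((11, 11), (21, 29))),
        ],
    )
    def test_intron_chain_derivation(self, exons, expected):
        chain = derive_intron_chain(make_transcript("t1.1", exons))
        assert chain.introns == expected


class TestExonSequence:
    genome = GenomeSequence({"chr1": "ATGTAA", "chr2": "ACGNNT"})

    def test_plus_strand_identity(self):
        assert exon_sequence(GenomicInterval("chr1", 1, 6, "+"), self.genome) == "ATGTAA"

    def test_minus_strand_reverse_complement(self):
        assert exon_sequence(GenomicInterval("chr1", 1, 6, "-"), self.genome) == "TTACAT"

    def test_unstranded_read_as_plus(self):
        assert exon_sequence(GenomicInterval("chr1", 2, 4, "."), self.genome) == "TGT"

    def test_n_bases_pass_through(self):
        assert exon_sequence(GenomicInterval("chr2", 3, 5, "+"), self.genome) == "GNN"

    def test_out_of_bounds_names_coordinates(self):
        with pytest.raises(ValidationError, match="chr1"):
            exon_sequence(GenomicInterval("chr1", 2, 9, "+"), self.genome)


class TestGtfRoundTrip:
    def test_two_line_gtf(self, tmp_path):
        path = tmp_path / "a.gtf"
        path.write_text(
            'chr1\tsrc\texon\t101\t200\t.\t+\t.\tgene_id "g1"; transcript_id "g1.1";\n'
            'chr1\tsrc\texon\t301\t400\t.\t+\t.\tgene_id "g1"; transcript_id "g1.1";\n'
        )
        ann = parse_gtf(path)
        assert len(ann) == 1
        t = ann.transcripts["g1.1"]
        assert [(e.start, e.end) for e in t.exons] == [(101, 200), (301, 400)]
        assert t.introns == ((201, 300),)

    def test_round_trip_identity(self, tmp_path):
        t1 = TranscriptModel(
            "g1.1", "g1",
            (GenomicInterval("chr1", 101, 200, "+"),
             GenomicInterval("chr1", 301, 400, "+")),
            attributes={"note": "hello world"},
            source="asm",
            extra_features=(
                'chr1\tasm\tCDS\t120\t200\t.\t+\t0\tgene_id "g1"; transcript_id "g1.1";',
            ),
        )
        t2 = make_transcript("g2.1", [(50, 90)], strand="-", chrom="chr2")
        ann = make_annotation(t1, t2)
        path = tmp_path / "rt.gtf"
        write_gtf(ann, path)
        again = parse_gtf(path)
        assert again == ann
        # second pass is byte-stable
        path2 = tmp_path / "rt2.gtf"
        write_gtf(again, path2)
        assert path.read_text() == path2.read_text()

    def test_empty_annotation_writes_empty_file(self, tmp_path):
        path = tmp_path / "empty.gtf"
        write_gtf(Annotation(), path)
        assert path.read_text() == ""

    def test_line_count_equals_exon_count(self, tmp_path):
        ann = make_annotation(
            make_transcript("a.1", [(1, 10), (20, 30), (40, 50)]),
            make_transcript("b.1", [(100, 150)]),
        )
        path = tmp_path / "count.gtf"
        write_gtf(ann, path)
        lines = [l for l in path.read_text().splitlines() if not l.startswith("#")]
        assert len(lines) == 4

    def test_malformed_line_reports_line_number(self, tmp_path):
        path = tmp_path / "bad.gtf"
        path.write_text("chr1\texon\t1\t10\n")
        with pytest.raises(GtfParseError, match="line 1"):
            parse_gtf(path)

    def test_exon_start_after_end_rejected(self, tmp_path):
        path = tmp_path / "bad.gtf"
        path.write_text(
            'chr1\ts\texon\t200\t100\t.\t+\t.\tgene_id "g"; transcript_id "g.1";\n'
        )
        with pytest.raises(ValidationError):
            parse_gtf(path)

    def test_transcript_under_two_genes_rejected(self, tmp_path):
        path = tmp_path / "dup.gtf"
        path.write_text(
            'chr1\ts\texon\t1\t10\t.\t+\t.\tgene_id "g1"; transcript_id "t.1";\n'
            'chr1\ts\texon\t30\t40\t.\t+\t.\tgene_id "g2"; transcript_id "t.1";\n'
        )
        with pytest.raises(ValidationError, match="t.1"):
            parse_gtf(path)


class TestBedgraph:
    def test_single_record_expansion(self, tmp_path):
        path = tmp_path / "a.bedgraph"
        path.write_text("chr1\t0\t5\t7\n")
        track = parse_bedgraph(path)
        vec = track.depth["chr1"]
        assert list(vec) == [7.0] * 5

    def test_empty_file_with_genome(self, tmp_path):
        path = tmp_path / "a.bedgraph"
        path.write_text("")
        genome = GenomeSequence({"chr1": "A" * 100})
        track = parse_bedgraph(path, genome)
        assert len(track.depth["chr1"]) == 100
        assert not track.depth["chr1"].any()

    def test_overlapping_records_sum(self, tmp_path):
        path = tmp_path / "a.bedgraph"
        path.write_text("chr1\t0\t10\t3\nchr1\t5\t15\t2\n")
        track = parse_bedgraph(path)
        assert track.depth["chr1"][5] == 5.0  # 1-based position 6

    @pytest.mark.parametrize("line", ["chr1\t0\t5\t-1\n", "chr1\t5\t5\t3\n"])
    def test_invalid_records_rejected(self, tmp_path, line):
        path = tmp_path / "a.bedgraph"
        path.write_text(line)
        with pytest.raises(ValidationError):
            parse_bedgraph(path)

    def test_expansion_conserves_mass(self, tmp_path):
        rng = np.random.default_rng(11)
        records, mass = [], 0.0
        for _ in range(50):
            start = int(rng.integers(0, 900))
            end = start + int(rng.integers(1, 80))
            value = int(rng.integers(0, 40))
            records.append(f"chr1\t{start}\t{end}\t{value}")
            mass += value * (end - start)
        path = tmp_path / "m.bedgraph"
        path.write_text("\n".join(records) + "\n")
        track = parse_bedgraph(path)
        assert track.depth["chr1"].sum() == pytest.approx(mass)


class TestFastaAndBed:
    def test_fasta_round_trip(self, tmp_path):
        genome = GenomeSequence({"chr1": "ACGT" * 40, "chr2": "TTTT"})
        path = tmp_path / "g.fa"
        write_fasta(genome, path)
        assert read_fasta(path).seq == genome.seq

    def test_bed_converted_to_one_based(self, tmp_path):
        path = tmp_path / "r.bed"
        path.write_text("chr1\t0\t10\nchr1\t99\t200\trepeat1\n")
        ivs = read_bed(path)["chr1"]
        assert [(iv.start, iv.end) for iv in ivs] == [(1, 10), (100, 200)]


@st.composite
def annotations(draw):
    transcripts = []
    n = draw(st.integers(1, 4))
    cursor = 1
    for i in range(n):
        strand = draw(st.sampled_from("+-."))
        exons = []
        start = cursor + draw(st.integers(0, 20))
        for _ in range(draw(st.integers(1, 4))):
            end = start + draw(st.integers(0, 40))
            exons.append((start, end))
            start = end + 2 + draw(st.integers(0, 30))
        cursor = exons[-1][1] + 2
        transcripts.append(make_transcript(f"t{i}.1", exons, strand=strand))
    return make_annotation(*transcripts)


class TestRoundTripProperty:
    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(annotations())
    def test_write_then_parse_is_identity(self, ann):
        with tempfile.TemporaryDirectory() as tmp:
            path = Path(tmp) / "rt.gtf"
            write_gtf(ann, path)
            assert parse_gtf(path) == ann


class TestAnnotation:
    def test_duplicate_transcript_id_rejected(self):
        t = make_transcript("t.1", [(1, 10)])
        with pytest.raises(ValidationError):
            Annotation.from_transcripts([t, t])

    def test_gene_map_derived(self):
        ann = make_annotation(
            make_transcript("g1.1", [(1, 10)]),
            make_transcript("g1.2", [(1, 10)], gene="g1"),
            make_transcript("g2.1", [(50, 60)]),
        )
        assert ann.genes == {"g1": ["g1.1", "g1.2"], "g2": ["g2.1"]}
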