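"""Structure-repair operators: stop screen, splitting, trimming, dedup."""
import numpy as np
import pytest
from conftest import make_annotation, make_transcript

from txpolish import (
    CoverageTrack,
    GenomicInterval,
    GenomeSequence,
    PolishConfig,
    TroughCall,
    ValidationError,
    find_antisense_end_overlaps,
    has_premature_stops_all_frames,
    polish_annotation,
    remove_redundant_transcripts,
    select_candidate_exons,
    split_transcript_at_trough,
    trim_end_exon,
)
from txpolish.synthetic import (
    MergedGeneParams,
    random_redundant_annotation,
    simulate_combined_fixture,
    simulate_merged_gene_fixture,
)

STOPS = frozenset({"TAA", "TAG", "TGA"})


def brute_force_all_frames(seq):
    """Oracle: enumerate every codon in every frame, check for a stop."""
    hit = [False, False, False]
    for i in range(len(seq) - 2):
        if seq[i : i + 3] in STOPS:
            hit[i % 3] = True
    return all(hit)


class TestStopScreen:
    def test_stop_rich_sequence_hits_all_frames(self):
        assert has_premature_stops_all_frames("TAAATAAATAAA")

    def test_stopless_sequence_is_negative(self):
        assert not has_premature_stops_all_frames("AAAAAAAAA")

    def test_too_short_for_a_codon(self):
        assert not has_premature_stops_all_frames("TA")

    def test_n_codons_never_match(self):
        assert not has_premature_stops_all_frames("TNATNATNATNA")

    def test_matches_bruteforce_on_random_sequences(self):
        rng = np.random.default_rng(7)
        bases = np.array(list("ACGT"))
        for _ in range(200):
            seq = "".join(rng.choice(bases, 300))
            assert has_premature_stops_all_frames(seq) == brute_force_all_frames(seq)


class TestCandidateSelection:
    def test_two_exon_transcript_has_no_internal_exons(self):
        genome = GenomeSequence({"chr1": "TAAA" * 100})
        t = make_transcript("t.1", [(1, 100), (201, 300)])
        assert select_candidate_exons(t, genome) == []

    def test_stop_rich_middle_exon_selected(self):
        seq = "AAC" * 40 + "TAAATAAATAAA" + "AAC" * 40
        genome = GenomeSequence({"chr1": seq})
        t = make_transcript("t.1", [(1, 100), (121, 132), (150, 250)])
        assert select_candidate_exons(t, genome) == [1]

    def test_stopless_middle_exon_not_selected(self):
        genome = GenomeSequence({"chr1": "AAC" * 200})
        t = make_transcript("t.1", [(1, 100), (121, 180), (200, 300)])
        assert select_candidate_exons(t, genome) == []

    def test_merged_fixture_selects_planted_fusion_exon(self):
        fx = simulate_merged_gene_fixture(0, MergedGeneParams(noise="none"))
        t = fx.annotation.transcripts["merged.1"]
        planted = fx.truth.events[0]["fused_exon_index"]
        assert select_candidate_exons(t, fx.genome) == [planted]


class TestSplit:
    trough = TroughCall(121, 160, 3.0, 51.0, 51.0)

    def test_coordinate_arithmetic(self):
        t = make_transcript("p.1", [(1, 100), (1001, 1400), (2001, 2100)])
        left, right = split_transcript_at_trough(t, 1, self.trough)
        assert [(e.start, e.end) for e in left.exons] == [(1, 100), (1001, 1120)]
        assert [(e.start, e.end) for e in right.exons] == [(1161, 1400), (2001, 2100)]
        assert left.transcript_id == "p.1.split1"
        assert right.gene_id == "p.split2"
        assert left.strand == right.strand == "+"

    def test_base_conservation(self):
        t = make_transcript("p.1", [(1, 100), (1001, 1400), (2001, 2100)])
        left, right = split_transcript_at_trough(t, 1, self.trough)
        trough_width = self.trough.right - self.trough.left + 1
        assert left.exonic_length + right.exonic_length == t.exonic_length - trough_width

    def test_children_partition_parent_chain(self):
        t = make_transcript("p.1", [(1, 100), (1001, 1400), (2001, 2100)])
        left, right = split_transcript_at_trough(t, 1, self.trough)
        assert left.introns == ((101, 1000),)
        assert right.introns == ((1401, 2000),)

    def test_boundary_trough_rejected(self):
        t = make_transcript("p.1", [(1, 100), (1001, 1400), (2001, 2100)])
        assert split_transcript_at_trough(t, 1, TroughCall(1, 40, 3, 51, 51)) is None
        assert split_transcript_at_trough(t, 1, TroughCall(380, 400, 3, 51, 51)) is None

    def test_terminal_exon_index_rejected(self):
        t = make_transcript("p.1", [(1, 100), (1001, 1400), (2001, 2100)])
        with pytest.raises(ValueError):
            split_transcript_at_trough(t, 0, self.trough)


class TestAntisenseOverlaps:
    def test_opposite_strand_terminal_overlap_reported(self):
        ann = make_annotation(
            make_transcript("a.1", [(100, 300), (500, 700)], strand="+"),
            make_transcript("b.1", [(650, 900), (1000, 1100)], strand="-"),
        )
        records = find_antisense_end_overlaps(ann)
        assert ("a.1", "right", "b.1") in records
        assert ("b.1", "left", "a.1") in records
        assert len({(a, c) for a, _e, c in records}) == 2  # one unordered pair

    def test_same_strand_overlap_not_reported(self):
        ann = make_annotation(
            make_transcript("a.1", [(100, 300), (500, 700)], strand="+"),
            make_transcript("b.1", [(650, 900)], strand="+"),
        )
        assert find_antisense_end_overlaps(ann) == []

    def test_unstranded_excluded(self):
        ann = make_annotation(
            make_transcript("a.1", [(100, 700)], strand="."),
            make_transcript("b.1", [(650, 900)], strand="-"),
        )
        assert find_antisense_end_overlaps(ann) == []

    def test_gap_tolerance(self):
        ann = make_annotation(
            make_transcript("a.1", [(100, 300), (500, 700)], strand="+"),
            make_transcript("b.1", [(705, 900)], strand="-"),
        )
        assert find_antisense_end_overlaps(ann) == []
        assert find_antisense_end_overlaps(ann, max_gap=5) != []


class TestTrim:
    def _coverage(self, vec):
        return CoverageTrack({"chr1": np.asarray(vec, float)})

    def test_collapsed_outer_coverage_trimmed(self):
        # inner 150 bases at depth 40, outer 50 bases at depth 4
        cov = self._coverage([40.0] * 150 + [4.0] * 50)
        t = make_transcript("t.1", [(1, 200)])
        out = trim_end_exon(t, "right", cov)
        assert out.exons[0].end == 150
        assert out.attributes["trimmed"] == "right:1-200"

    def test_left_end_trim(self):
        cov = self._coverage([4.0] * 50 + [40.0] * 150)
        t = make_transcript("t.1", [(1, 200)])
        out = trim_end_exon(t, "left", cov)
        assert out.exons[0].start == 51

    def test_uniform_coverage_unchanged(self):
        cov = self._coverage([30.0] * 200)
        t = make_transcript("t.1", [(1, 200)])
        assert trim_end_exon(t, "right", cov) is t

    def test_short_exon_skipped(self):
        cov = self._coverage([30.0] * 15)
        t = make_transcript("t.1", [(1, 15)])
        assert trim_end_exon(t, "right", cov) is t

    def test_high_outer_plateau_not_trimmed_past_gap(self):
        # own gene 200 @ 50, gap 60 @ 2, neighbour 200 @ 50: cut at the gap start
        cov = self._coverage([50.0] * 200 + [2.0] * 60 + [50.0] * 200)
        t = make_transcript("t.1", [(1, 460)])
        out = trim_end_exon(t, "right", cov)
        assert out.exons[0].end == 200


def containment_oracle(annotation):
    """Literal restatement of the redundancy rules as an independent check."""
    ts = list(annotation)
    removed = set()
    for a in ts:
        for b in ts:
            if a.transcript_id == b.transcript_id:
                continue
            if a.chrom != b.chrom or a.strand != b.strand:
                continue
            within = b.start <= a.start and a.end <= b.end
            if not a.is_mono_exonic and not b.is_mono_exonic and within:
                if a.introns == b.introns:
                    if (a.start, a.end) != (b.start, b.end):
                        removed.add(a.transcript_id)
                    elif b.transcript_id < a.transcript_id:
                        removed.add(a.transcript_id)
                elif len(a.introns) < len(b.introns):
                    k = len(a.introns)
                    for j in range(len(b.introns) - k + 1):
                        if b.introns[j : j + k] == a.introns:
                            removed.add(a.transcript_id)
                            break
            elif a.is_mono_exonic and b.is_mono_exonic and within:
                if (a.start, a.end) != (b.start, b.end):
                    removed.add(a.transcript_id)
                elif b.transcript_id < a.transcript_id:
                    removed.add(a.transcript_id)
            elif a.is_mono_exonic and not b.is_mono_exonic:
                for ex in b.exons:
                    if ex.start <= a.start and a.end <= ex.end:
                        removed.add(a.transcript_id)
                        break
    return sorted(removed)


class TestRedundancyRemoval:
    def test_subchain_within_span_removed(self):
        a = make_transcript("a.1", [(150, 200), (301, 350)])
        b = make_transcript("b.1", [(100, 200), (301, 400), (501, 600)])
        out, removed = remove_redundant_transcripts(make_annotation(a, b))
        assert removed == ["a.1"]
        assert set(out.transcripts) == {"b.1"}

    def test_identical_pair_keeps_smaller_id(self):
        a = make_transcript("zzz.1", [(100, 200), (301, 400)])
        b = make_transcript("aaa.1", [(100, 200), (301, 400)])
        out, removed = remove_redundant_transcripts(make_annotation(a, b))
        assert removed == ["zzz.1"]

    def test_mono_inside_exon_removed(self):
        a = make_transcript("mono.1", [(320, 380)])
        b = make_transcript("multi.1", [(100, 200), (301, 400)])
        _out, removed = remove_redundant_transcripts(make_annotation(a, b))
        assert removed == ["mono.1"]

    def test_different_strand_never_redundant(self):
        a = make_transcript("a.1", [(150, 200), (301, 350)], strand="-")
        b = make_transcript("b.1", [(100, 200), (301, 400), (501, 600)])
        _out, removed = remove_redundant_transcripts(make_annotation(a, b))
        assert removed == []

    def test_planted_subsets_exactly_removed_and_idempotent(self):
        for seed in range(30):
            ann, planted = random_redundant_annotation(seed)
            out, removed = remove_redundant_transcripts(ann)
            assert removed == planted
            assert removed == containment_oracle(ann)
            again, removed2 = remove_redundant_transcripts(out)
            assert removed2 == []
            assert set(again.transcripts) == set(out.transcripts)


class TestPolishAnnotation:
    def test_clean_annotation_is_fixed_point(self):
        ann = make_annotation(
            make_transcript("a.1", [(101, 200), (301, 400)]),
            make_transcript("b.1", [(1001, 1100)], strand="-"),
        )
        genome = GenomeSequence({"chr1": "AAC" * 500})
        cov = CoverageTrack({"chr1": np.full(1500, 30.0)})
        out, report = polish_annotation(ann, cov, genome)
        assert set(out.transcripts) == {"a.1", "b.1"}
        assert report.summary() == {
            "n_redundant_removed": 0,
            "n_candidate_exons": 0,
            "n_troughs_found": 0,
            "n_transcripts_split": 0,
            "n_ends_trimmed": 0,
        }

    def test_missing_coverage_chromosome_is_hard_error(self):
        ann = make_annotation(make_transcript("a.1", [(1, 100)]))
        genome = GenomeSequence({"chr1": "A" * 200})
        with pytest.raises(ValidationError, match="chr1"):
            polish_annotation(ann, CoverageTrack({}), genome)

    def test_merged_fixture_split_into_two_genes(self):
        fx = simulate_merged_gene_fixture(2, MergedGeneParams(noise="none"))
        out, report = polish_annotation(fx.annotation, fx.coverage, fx.genome)
        assert report.n_transcripts_split == 1
        truth = {
            tuple((e.start, e.end) for e in t.exons)
            for t in fx.truth.true_annotation
        }
        got = {tuple((e.start, e.end) for e in t.exons) for t in out}
        assert got == truth

    def test_combined_fixture_event_counts(self):
        fx = simulate_combined_fixture(0)
        out, report = polish_annotation(fx.annotation, fx.coverage, fx.genome)
        assert report.n_redundant_removed == 2
        assert report.n_transcripts_split == 1
        assert report.n_ends_trimmed >= 1
        assert report.n_transcripts_split <= report.n_troughs_found
        assert report.n_troughs_found <= report.n_candidate_exons

    def test_polish_preserves_chrom_and_strand(self):
        fx = simulate_combined_fixture(1)
        before = {t.transcript_id: (t.chrom, t.strand) for t in fx.annotation}
        out, _report = polish_annotation(fx.annotation, fx.coverage, fx.genome)
        for t in out:
            parent = t.transcript_id.split(".split")[0]
            if parent in before:
                assert (t.chrom, t.strand) == before[parent]
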