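"""Prefix trimming and unique paired-end alignment."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import pbscreen as pb
from pbscreen.genome import revcomp


def mk_pairs(*read1s):
    return [pb.ReadPair(r1, "ACGT" * 10, "s1") for r1 in read1s]


class TestTrimPrefix:
    def test_matching_prefix_removed(self):
        trimmed, stats = pb.trim_prefix(mk_pairs("TAGGGTTAAACGTACGT"))
        assert [p.read1_seq for p in trimmed] == ["ACGTACGT"]
        assert stats.discarded == 0

    def test_nonmatching_discarded(self):
        trimmed, stats = pb.trim_prefix(mk_pairs("TTGGGTTAAACGT"))
        assert trimmed == []
        assert (stats.total, stats.discarded) == (1, 1)

    def test_empty_stream(self):
        trimmed, stats = pb.trim_prefix([])
        assert trimmed == [] and stats.total == 0 and stats.fraction == 0.0

    def test_bad_prefix_rejected(self):
        with pytest.raises(ValueError):
            pb.trim_prefix([], prefix="acgt")

    @given(st.text(alphabet="ACGT", min_size=10, max_size=40))
    @settings(max_examples=50, deadline=None)
    def test_idempotent_on_own_output(self, tail):
        trimmed, _ = pb.trim_prefix(mk_pairs("TAGGGTTAA" + tail))
        again, stats2 = pb.trim_prefix(trimmed)
        # retained read 1s that still begin with the prefix are re-trimmed,
        # which only happens when the genomic tail itself starts with it
        if not tail.startswith("TAGGGTTAA"):
            assert stats2.discarded == len(trimmed)

    def test_discard_fraction_matches_simulation(self, small_config):
        cfg = pb.SimConfig(**{**small_config.to_dict(), "contaminant_frac": 0.03,
                              "pcr_dup_mean": 2.0})
        genome, transcripts = pb.gen_reference(cfg)
        truth = pb.plant_insertions(genome, transcripts, cfg)
        sim = pb.simulate_read_pairs(genome, truth, cfg)
        pairs = [pb.ReadPair(p.read1, p.read2, s)
                 for s, pl in sim.items() for p in pl]
        _, stats = pb.trim_prefix(pairs)
        truth_frac = sum(p.is_contaminant for pl in sim.values() for p in pl) / len(pairs)
        assert stats.fraction == pytest.approx(truth_frac, abs=1e-9)


def read_pair_from_locus(genome, chrom, pos, frag=120, read_len=40):
    """Construct a + strand pair whose junction read starts at ``pos``."""
    seq = genome[chrom]
    fragment = seq[pos:pos + frag]
    return pb.ReadPair(fragment[:read_len], revcomp(fragment)[:read_len], "s1")


class TestBuiltinAligner:
    def test_unique_locus_recovers_truth(self, toy_genome):
        pair = read_pair_from_locus(toy_genome, "chrT", 104)
        aligned, stats = pb.align_pairs([pair], toy_genome)
        assert stats.aligned == 1
        ap = aligned[0]
        assert (ap.chrom, ap.strand, ap.r1_start) == ("chrT", "+", 104)
        assert ap.shear_end == 104 + 120

    def test_minus_strand_coordinates(self, toy_genome):
        # fragment running leftwards from the TTAA at [200, 204)
        seq = toy_genome["chrT"]
        coord = 200
        fragment = revcomp(seq[coord - 120:coord])
        pair = pb.ReadPair(fragment[:40], revcomp(fragment)[:40], "s1")
        aligned, _ = pb.align_pairs([pair], toy_genome)
        assert len(aligned) == 1
        ap = aligned[0]
        assert (ap.strand, ap.r1_start, ap.shear_end) == ("-", coord, coord - 120)

    def test_duplicated_sequence_is_multimapper(self):
        core = "ATGGACCATGACCTGAGGACCATTACCGGATCAGGACCATG"
        pad1 = "C" * 60
        pad2 = "G" * 60
        genome = pb.ReferenceGenome({"c1": pad1 + core + pad1,
                                     "c2": pad2 + core + pad2})
        frag = core
        pair = pb.ReadPair(frag[:25], revcomp(frag)[:25], "s1")
        aligned, stats = pb.align_pairs([pair], genome)
        assert aligned == [] and stats.multimapped == 1

    def test_distant_mate_excluded(self, small_config):
        genome, _ = pb.gen_reference(small_config)
        seq = genome["chr1"]
        read1 = seq[5000:5040]
        read2 = revcomp(seq[6460:6500])  # fragment span 1500 bp
        aligned, stats = pb.align_pairs(
            [pb.ReadPair(read1, read2, "s1")], genome, max_insert=1000)
        assert aligned == [] and stats.unmapped == 1

    def test_one_mismatch_tolerated_two_rejected(self, small_config):
        genome, _ = pb.gen_reference(small_config)
        seq = genome["chr1"]
        frag = seq[9000:9140]
        read1 = list(frag[:40])
        read1[30] = "A" if read1[30] != "A" else "C"  # outside the 20-nt seed
        pair = pb.ReadPair("".join(read1), revcomp(frag)[:40], "s1")
        aligned, _ = pb.align_pairs([pair], genome)
        assert len(aligned) == 1 and aligned[0].r1_start == 9000
        read1[35] = "A" if read1[35] != "A" else "C"
        pair2 = pb.ReadPair("".join(read1), revcomp(frag)[:40], "s1")
        aligned2, stats2 = pb.align_pairs([pair2], genome)
        assert aligned2 == [] and stats2.unmapped == 1

    def test_short_read_dropped(self, toy_genome):
        aligned, stats = pb.align_pairs(
            [pb.ReadPair("ACGTACGTAC", "ACGTACGTAC", "s1")], toy_genome)
        assert aligned == [] and stats.too_short == 1

    def test_alignment_count_matches_fragments_no_noise(self, small_config):
        cfg = pb.SimConfig(**{**small_config.to_dict(), "pcr_dup_mean": 0.0})
        genome, transcripts = pb.gen_reference(cfg)
        truth = pb.plant_insertions(genome, transcripts, cfg)
        sim = pb.simulate_read_pairs(genome, truth, cfg)
        pairs = [pb.ReadPair(p.read1, p.read2, s)
                 for s, pl in sim.items() for p in pl]
        trimmed, _ = pb.trim_prefix(pairs)
        aligned, stats = pb.align_pairs(trimmed, genome)
        assert len(aligned) == sum(r.true_diversity for r in truth)


class TestSamRoundTrip:
    def test_roundtrip_identity(self, small_screen, tmp_path):
        cfg = small_screen.config
        genome = small_screen.genome
        sim = pb.simulate_read_pairs(genome, small_screen.truth, cfg)
        pairs = [pb.ReadPair(p.read1, p.read2, s)
                 for s, pl in sim.items() for p in pl]
        trimmed, _ = pb.trim_prefix(pairs)
        aligned, _ = pb.align_pairs(trimmed, genome)
        sam = tmp_path / "out.sam"
        pb.write_sam(aligned, genome, sam)
        back, orphans = pb.read_alignments(sam)
        assert orphans == 0
        key = lambda ap: (ap.sample_id, ap.chrom, ap.strand, ap.r1_start,
                          ap.shear_end, ap.insert_size)
        assert sorted(map(key, back)) == sorted(map(key, aligned))

    def test_coordinate_conversion_and_secondary_filter(self, tmp_path):
        sam = tmp_path / "mini.sam"
        sam.write_text(
            "@HD\tVN:1.6\n@SQ\tSN:chr1\tLN:1000\n"
            "s|1\t99\tchr1\t101\t60\t30M\t=\t301\t230\t" + "A" * 30 + "\t*\n"
            "s|1\t147\tchr1\t301\t60\t30M\t=\t101\t-230\t" + "A" * 30 + "\t*\n"
            "s|2\t355\tchr1\t501\t60\t30M\t=\t601\t130\t" + "A" * 30 + "\t*\n"
            "s|2\t403\tchr1\t601\t60\t30M\t=\t501\t-130\t" + "A" * 30 + "\t*\n")
        pairs, orphans = pb.read_alignments(sam)
        assert len(pairs) == 1  # the secondary pair (flags 355/403) is ignored
        ap = pairs[0]
        assert ap.r1_start == 100  # POS 101 (1-based) -> 100 (0-based)
        assert ap.shear_end == 330
        assert ap.sample_id == "s"
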