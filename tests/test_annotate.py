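"""Classification hierarchy, gene grouping, regulatory-domain association
and ranked-list intersection — each checked against an independent
brute-force oracle."""

import numpy as np
import pytest

import pbscreen as pb
from pbscreen.annotate import NO_FLANK, Annotator, TranscriptModel
from _oracles import oracle_classify, oracle_domains


def T(gene, tx, chrom, strand, start, end, exons, cds=None):
    return TranscriptModel(gene_id=gene, transcript_id=tx, chrom=chrom,
                           strand=strand, tx_start=start, tx_end=end,
                           exons=tuple(exons),
                           cds_start=cds[0] if cds else None,
                           cds_end=cds[1] if cds else None)


@pytest.fixture(scope="module")
def overlapping_models():
    """10-kb toy chromosome: two coding transcripts (opposite strands,
    partially overlapping) and one non-coding transcript inside an
    intron of the first."""
    return [
        T("gA", "gA.t1", "c", "+", 3000, 6000,
          [(3000, 3400), (4200, 4800), (5500, 6000)], cds=(3200, 5800)),
        T("gB", "gB.t1", "c", "-", 5200, 8200,
          [(5200, 5900), (7000, 8200)], cds=(5400, 8000)),
        T("gN", "gN.t1", "c", "+", 3600, 4100, [(3600, 4100)]),  # ncRNA
    ]


class TestClassifySite:
    def test_exonic_site_upstream_of_cds_is_5utr(self, overlapping_models):
        ann = Annotator(overlapping_models).classify("c", 3100, "+")
        assert (ann.category, ann.gene_id) == ("5UTR", "gA")

    def test_promoter_upstream_of_minus_strand_tss(self, overlapping_models):
        # gB is on -, TSS at tx_end=8200; 1,500 bp upstream = 9700
        ann = Annotator(overlapping_models).classify("c", 9700, "+")
        assert (ann.category, ann.gene_id) == ("promoter", "gB")
        assert ann.orientation == "opposite"

    def test_orientation_reported(self, overlapping_models):
        ann = Annotator(overlapping_models).classify("c", 3100, "+")
        assert ann.orientation == "same"
        ann2 = Annotator(overlapping_models).classify("c", 3100, "-")
        assert ann2.orientation == "opposite"

    def test_exhaustive_per_base_oracle(self, overlapping_models):
        """Classification agrees with the brute-force checker at every
        position of the toy chromosome, on both strands."""
        annot = Annotator(overlapping_models)
        for pos in range(0, 10_000):
            for strand in "+-":
                ann = annot.classify("c", pos, strand)
                cat, gene = oracle_classify(overlapping_models, pos, strand)
                assert (ann.category, ann.gene_id) == (cat, gene), pos

    def test_input_order_invariance(self, overlapping_models):
        a1 = Annotator(overlapping_models)
        a2 = Annotator(list(reversed(overlapping_models)))
        for pos in range(2500, 9000, 37):
            assert a1.classify("c", pos, "+") == a2.classify("c", pos, "+")


class TestGroupByGene:
    def test_promoter_and_intron_share_group(self, overlapping_models):
        annot = Annotator(overlapping_models)
        promoter = annot.classify("c", 2500, "+")  # gA promoter window
        intron = annot.classify("c", 3450, "+")  # gA intron
        assert promoter.category == "promoter" and intron.category == "intron"
        groups = pb.group_by_gene([promoter, intron])
        assert set(groups) == {"gA"} and len(groups["gA"]) == 2

    def test_intergenic_flanking_key(self, overlapping_models):
        annot = Annotator(overlapping_models)
        between = annot.classify("c", 8800, "+")  # past gB end, before window?
        left_end = annot.classify("c", 500, "+")
        assert left_end.category in ("intergenic", "promoter")
        ann = annot.classify("c", 100, "+")
        if ann.category == "intergenic":
            assert ann.flanking[0] == NO_FLANK

    def test_partition(self, overlapping_models):
        annot = Annotator(overlapping_models)
        anns = [annot.classify("c", p, "+") for p in range(0, 10_000, 111)]
        groups = pb.group_by_gene(anns)
        assert sum(len(v) for v in groups.values()) == len(anns)


class TestGreatAssociate:
    def test_peak_within_basal(self):
        genes = [T("g1", "g1.t1", "c", "+", 50_000, 55_000, [(50_000, 55_000)],
                   cds=(50_100, 54_900))]
        peaks = [("c", 46_900, 47_100)]  # midpoint 3,000 bp upstream of TSS
        assoc = pb.great_associate(peaks, genes)
        assert assoc[("c", 46_900, 47_100)] == {"g1"}

    def test_peak_beyond_basal_plus_extension(self):
        genes = [T("g1", "g1.t1", "c", "+", 50_000, 55_000, [(50_000, 55_000)],
                   cds=(50_100, 54_900))]
        # max association reach upstream is basal_up + max_ext = 15,000 bp:
        # a midpoint 14,000 bp upstream associates, 16,000 bp does not
        assoc = pb.great_associate([("c", 35_900, 36_100),
                                    ("c", 33_900, 34_100)], genes)
        assert assoc[("c", 35_900, 36_100)] == {"g1"}
        assert assoc[("c", 33_900, 34_100)] == set()

    def test_two_close_genes_extension_stops(self):
        # TSSs 8 kb apart on +: each basal is [tss-5000, tss+1000)
        genes = [
            T("gL", "gL.t1", "c", "+", 50_000, 52_000, [(50_000, 52_000)],
              cds=(50_100, 51_900)),
            T("gR", "gR.t1", "c", "+", 58_000, 60_000, [(58_000, 60_000)],
              cds=(58_100, 59_900)),
        ]
        # gL extension stops at gR's basal start (53,000), so the point
        # midway between the two TSSs (54,000) maps to gR alone; in the
        # gap between the basal domains the extensions overlap
        assoc = pb.great_associate([("c", 53_900, 54_100),
                                    ("c", 51_900, 52_100)], genes)
        assert assoc[("c", 53_900, 54_100)] == {"gR"}
        assert assoc[("c", 51_900, 52_100)] == {"gL", "gR"}

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_bruteforce_on_random_toys(self, seed):
        rng = np.random.default_rng(seed)
        n_genes = int(rng.integers(3, 20))
        genes = []
        for i in range(n_genes):
            start = int(rng.integers(0, 400_000))
            length = int(rng.integers(500, 20_000))
            strand = "+" if rng.random() < 0.5 else "-"
            genes.append(T(f"g{i}", f"g{i}.t1", "c", strand, start,
                           start + length, [(start, start + length)]))
        dom = oracle_domains(genes, 5000, 1000, 10_000)
        peaks = [("c", int(p), int(p) + 200)
                 for p in rng.integers(0, 420_000, 300)]
        assoc = pb.great_associate(peaks, genes)
        for (chrom, s, e), hits in assoc.items():
            mid = (s + e) // 2
            expect = {g for g, (c, lo, hi) in dom.items()
                      if c == chrom and lo <= mid < hi}
            assert hits == expect, (s, e)


class TestIntersectTop:
    def test_single_common_gene(self):
        a = ["g1", "g2", "g3"]
        b = ["g9", "g2", "g4"]
        target = {"g2", "g7"}
        common, venn = pb.intersect_top(a, b, target, n=3)
        assert common == {"g2"}

    def test_disjoint_lists(self):
        common, _ = pb.intersect_top(["a"], ["b"], {"c"}, n=1)
        assert common == set()

    def test_venn_counts_sum_to_union(self):
        a, b, t = ["g1", "g2", "g3"], ["g2", "g4"], {"g3", "g4", "g5"}
        common, venn = pb.intersect_top(a, b, t, n=10)
        assert sum(venn.values()) == len(set(a) | set(b) | t)

    def test_n_too_large_warns(self):
        with pytest.warns(UserWarning):
            pb.intersect_top(["a"], ["b"], set(), n=5)


class TestGtfRoundTrip:
    def test_roundtrip(self, small_config, tmp_path):
        _, transcripts = pb.gen_reference(small_config)
        pb.write_gtf(transcripts, tmp_path / "t.gtf")
        back = pb.read_gtf(tmp_path / "t.gtf")
        key = lambda t: t.transcript_id
        assert sorted(back, key=key) == sorted(transcripts, key=key)
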