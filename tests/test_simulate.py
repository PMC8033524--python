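"""Synthetic-screen generator: determinism, planted-truth invariants and
the statistical structure of simulated libraries."""

import numpy as np
import pytest

import pbscreen as pb
from pbscreen.genome import revcomp


def naive_ttaa_count(seq: str) -> int:
    # independent sliding-window scan
    return sum(1 for i in range(len(seq) - 3) if seq[i:i + 4] == "TTAA")


@pytest.fixture(scope="module")
def reference(small_config):
    return pb.gen_reference(small_config)


class TestGenReference:
    def test_deterministic_bytes(self, small_config, tmp_path):
        for run in ("a", "b"):
            genome, transcripts = pb.gen_reference(small_config)
            genome.write_fasta(tmp_path / f"{run}.fa")
            pb.write_gtf(transcripts, tmp_path / f"{run}.gtf")
        assert (tmp_path / "a.fa").read_bytes() == (tmp_path / "b.fa").read_bytes()
        assert (tmp_path / "a.gtf").read_bytes() == (tmp_path / "b.gtf").read_bytes()

    def test_ttaa_count_matches_naive_scan(self, reference):
        genome, _ = reference
        for chrom in genome.names():
            assert len(genome.ttaa_sites(chrom)) == naive_ttaa_count(genome[chrom])
            assert len(genome.ttaa_sites(chrom)) >= 50

    def test_transcripts_within_chromosomes(self, reference):
        genome, transcripts = reference
        assert transcripts, "expected genes"
        for t in transcripts:
            assert 0 <= t.tx_start < t.tx_end <= genome.length(t.chrom)

    def test_noncoding_fraction_present(self, reference):
        _, transcripts = reference
        kinds = {t.is_noncoding for t in transcripts}
        assert kinds == {True, False}

    def test_too_small_chromosome_raises(self):
        with pytest.raises(pb.ConfigError):
            pb.gen_reference(pb.SimConfig(chrom_length=5000, n_genes=50,
                                          n_chroms=1))


class TestPlantInsertions:
    def test_truth_sits_on_ttaa(self, reference, small_config):
        genome, transcripts = reference
        truth = pb.plant_insertions(genome, transcripts, small_config)
        assert len(truth) > 0
        for rec in truth:
            seq = genome[rec.chrom]
            if rec.strand == "+":
                assert seq[rec.coord - 4:rec.coord] == "TTAA"
            else:
                assert revcomp(seq[rec.coord:rec.coord + 4]) == "TTAA"
            assert rec.true_diversity >= 1

    def test_truth_tsv_roundtrip(self, reference, small_config, tmp_path):
        genome, transcripts = reference
        truth = pb.plant_insertions(genome, transcripts, small_config)
        truth.write_tsv(tmp_path / "truth.tsv")
        back = pb.TruthTable.read_tsv(tmp_path / "truth.tsv")
        assert back.records == truth.records

    def test_enriched_gene_elevates_diversity(self, small_config):
        """A fold-5 gene gains summed diversity in the enriched group in
        nearly all seeds (Monte-Carlo)."""
        wins = 0
        n_seeds = 60
        for seed in range(n_seeds):
            cfg = pb.SimConfig(**{**small_config.to_dict(), "seed": seed,
                                  "enriched_genes": [["gene0001", "metastatic", 5.0]]})
            genome, transcripts = pb.gen_reference(cfg)
            truth = pb.plant_insertions(genome, transcripts, cfg)
            by_group = {"tumour": 0.0, "metastatic": 0.0}
            for rec in truth:
                if rec.gene_id == "gene0001":
                    by_group[cfg.sample_groups()[rec.sample_id]] += rec.true_diversity
            if by_group["metastatic"] > by_group["tumour"]:
                wins += 1
        assert wins >= 0.95 * n_seeds

    def test_fold_monotonicity(self, small_config):
        """Raising the fold never lowers the expected group difference."""
        means = []
        for fold in (1.0, 2.0, 5.0):
            diffs = []
            for seed in range(20):
                cfg = pb.SimConfig(**{**small_config.to_dict(), "seed": seed,
                                      "enriched_genes": [["gene0001", "metastatic", fold]]})
                genome, transcripts = pb.gen_reference(cfg)
                truth = pb.plant_insertions(genome, transcripts, cfg)
                tot = {"tumour": 0.0, "metastatic": 0.0}
                for rec in truth:
                    if rec.gene_id == "gene0001":
                        tot[cfg.sample_groups()[rec.sample_id]] += rec.true_diversity
                diffs.append(tot["metastatic"] - tot["tumour"])
            means.append(np.mean(diffs))
        assert means[0] <= means[1] <= means[2]

    def test_unknown_enriched_gene_raises(self, reference, small_config):
        genome, transcripts = reference
        cfg_dict = {**small_config.to_dict(),
                    "enriched_genes": [["nope", "metastatic", 5.0]]}
        with pytest.raises(pb.ConfigError):
            pb.plant_insertions(genome, transcripts, pb.SimConfig(**cfg_dict))


class TestSimulateReads:
    def test_no_noise_pair_count_equals_diversity(self, reference, small_config):
        genome, transcripts = reference
        cfg = pb.SimConfig(**{**small_config.to_dict(), "pcr_dup_mean": 0.0,
                              "seq_error_rate": 0.0, "contaminant_frac": 0.0})
        truth = pb.plant_insertions(genome, transcripts, cfg)
        pairs = pb.simulate_read_pairs(genome, truth, cfg)
        for sample in cfg.sample_ids():
            assert len(pairs[sample]) == truth.total_diversity(sample)

    def test_junction_reads_carry_prefix(self, reference, small_config):
        genome, transcripts = reference
        truth = pb.plant_insertions(genome, transcripts, small_config)
        pairs = pb.simulate_read_pairs(genome, truth, small_config)
        for plist in pairs.values():
            for p in plist:
                if not p.is_contaminant:
                    assert p.read1[:9] == "TAGGGTTAA"

    def test_contaminant_fraction_binomial(self, reference, small_config):
        genome, transcripts = reference
        cfg = pb.SimConfig(**{**small_config.to_dict(), "seed": 3,
                              "contaminant_frac": 0.02, "seq_error_rate": 0.0,
                              "pcr_dup_mean": 3.0})
        truth = pb.plant_insertions(genome, transcripts, cfg)
        pairs = [p for plist in pb.simulate_read_pairs(genome, truth, cfg).values()
                 for p in plist]
        n = len(pairs)
        frac = sum(not p.read1.startswith("TAGGGTTAA") for p in pairs) / n
        # 4-sigma binomial band around the configured rate
        tol = 4 * np.sqrt(0.02 * 0.98 / n)
        assert abs(frac - 0.02) <= tol

    def test_fastq_output_deterministic(self, reference, small_config, tmp_path):
        genome, transcripts = reference
        truth = pb.plant_insertions(genome, transcripts, small_config)
        sample = small_config.sample_ids()[0]
        out = {}
        for run in ("a", "b"):
            paths = pb.simulate_reads(genome, truth, small_config, tmp_path / run)
            out[run] = tuple(p.read_bytes() for p in paths[sample])
        assert out["a"] == out["b"]

    def test_fastq_files_parse_as_pairs(self, reference, small_config, tmp_path):
        genome, transcripts = reference
        truth = pb.plant_insertions(genome, transcripts, small_config)
        paths = pb.simulate_reads(genome, truth, small_config, tmp_path)
        sample = small_config.sample_ids()[0]
        pairs = list(pb.read_fastq_pairs(*paths[sample], sample))
        assert len(pairs) > 0
        assert all(len(p.read1_seq) <= small_config.read_length for p in pairs)
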