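"""Synthetic splinkerette-screen generator.

Emulates the data-generating process the analysis assumes: a small
reference genome with transcript models, transposon insertions planted at
TTAA tetranucleotides per sample, sonication shear points around 250 bp,
PCR duplication, sequencing errors, and a small contaminant fraction of
read pairs lacking the transposon junction.  Every stage is deterministic
given the configuration seed, and the planted truth table is returned so
downstream calls can be scored exactly.

Coordinate convention (used consistently across the package): an insertion
coordinate ``coord`` is the boundary just 3' of the duplicated TTAA in the
orientation of the junction read.  On the + strand the TTAA occupies
``genome[coord-4:coord]`` and the trimmed junction read starts at ``coord``
running rightwards; on the − strand the TTAA occupies
``genome[coord:coord+4]`` (TTAA is its own reverse complement) and the
trimmed read starts at ``coord - 1`` running leftwards, i.e. ``coord`` is
the half-open end of the aligned read interval.
"""

from __future__ import annotations

import gzip
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np

from .annotate import TranscriptModel, write_gtf
from .config import TRANSPOSON_PREFIX, ConfigError, SimConfig
from .genome import ReferenceGenome, revcomp

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class TruthRecord:
    """One planted insertion: where it is and how clonal it is."""

    sample_id: str
    chrom: str
    strand: str
    coord: int
    true_diversity: int
    gene_id: Optional[str] = None


class TruthTable:
    """Planted-insertion ground truth for a simulated screen."""

    COLUMNS = ("sample_id", "chrom", "strand", "coord", "true_diversity", "gene_id")

    def __init__(self, records: list[TruthRecord]):
        self.records = sorted(
            records, key=lambda r: (r.sample_id, r.chrom, r.coord, r.strand)
        )

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def for_sample(self, sample_id: str) -> list[TruthRecord]:
        return [r for r in self.records if r.sample_id == sample_id]

    def total_diversity(self, sample_id: str) -> int:
        return sum(r.true_diversity for r in self.for_sample(sample_id))

    def write_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("\t".join(self.COLUMNS) + "\n")
            for r in self.records:
                fh.write(f"{r.sample_id}\t{r.chrom}\t{r.strand}\t{r.coord}\t"
                         f"{r.true_diversity}\t{r.gene_id or '.'}\n")

    @classmethod
    def read_tsv(cls, path) -> "TruthTable":
        records = []
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")
            assert tuple(header) == cls.COLUMNS, "unexpected truth-table header"
            for line in fh:
                s, c, st, co, d, g = line.rstrip("\n").split("\t")
                records.append(TruthRecord(s, c, st, int(co), int(d),
                                           None if g == "." else g))
        return cls(records)


# ---------------------------------------------------------------------------
# Reference generation
# ---------------------------------------------------------------------------

def _random_sequence(rng: np.random.Generator, length: int) -> str:
    return _BASES[rng.integers(0, 4, length)].tobytes().decode()


_MIN_TTAA_PER_CHROM = 50
_MIN_EXON = 50


def gen_reference(config: SimConfig):
    """Generate a reference genome and transcript models.

    Returns ``(ReferenceGenome, [TranscriptModel])``.  Deterministic given
    the seed.  Each chromosome carries at least 50 TTAA occurrences (random
    sequence already does at the configured lengths; short test chromosomes
    are seeded with extra motifs at deterministic positions).  A
    ``noncoding_frac`` share of genes has no CDS.
    """
    rng = np.random.default_rng([config.seed, 0])
    chroms: dict[str, str] = {}
    transcripts: list[TranscriptModel] = []

    genes_per_chrom = [config.n_genes // config.n_chroms] * config.n_chroms
    for i in range(config.n_genes % config.n_chroms):
        genes_per_chrom[i] += 1

    gene_counter = 0
    for ci in range(config.n_chroms):
        name = f"chr{ci + 1}"
        seq = _random_sequence(rng, config.chrom_length)
        seq = _ensure_ttaa(seq)
        n_here = genes_per_chrom[ci]
        if n_here:
            slot = config.chrom_length // n_here
            margin = 2500  # promoter window + spacing between genes
            if slot <= 2 * margin + 3 * _MIN_EXON:
                raise ConfigError(
                    f"chrom_length {config.chrom_length} too small to host "
                    f"{n_here} genes per chromosome")
            for gi in range(n_here):
                gene_counter += 1
                lo, hi = gi * slot + margin, (gi + 1) * slot - margin
                max_len = hi - lo
                glen = int(rng.integers(min(2000, max_len // 2), max_len))
                start = int(rng.integers(lo, hi - glen))
                strand = "+" if rng.random() < 0.5 else "-"
                coding = rng.random() >= config.noncoding_frac
                transcripts.append(
                    _make_transcript(rng, f"gene{gene_counter:04d}", name,
                                     strand, start, start + glen, coding))
        chroms[name] = seq
    return ReferenceGenome(chroms), transcripts


def _ensure_ttaa(seq: str) -> str:
    from .genome import find_ttaa

    n = len(find_ttaa(seq))
    if n >= _MIN_TTAA_PER_CHROM:
        return seq
    out = bytearray(seq.encode())
    stride = max(8, len(seq) // (_MIN_TTAA_PER_CHROM + 10))
    for p in range(stride, len(seq) - 4, stride):
        out[p:p + 4] = b"TTAA"
    return out.decode()


def _make_transcript(rng, gene_id, chrom, strand, tx_start, tx_end, coding):
    glen = tx_end - tx_start
    k = int(rng.integers(1, 4))  # 1-3 exons
    n_parts = 2 * k - 1
    while n_parts * _MIN_EXON > glen:
        k -= 1
        n_parts = 2 * k - 1
    w = rng.dirichlet(np.ones(n_parts))
    extra = glen - n_parts * _MIN_EXON
    lengths = (_MIN_EXON + np.floor(w * extra)).astype(int)
    lengths[-1] += glen - int(lengths.sum())
    bounds = np.concatenate([[0], np.cumsum(lengths)]) + tx_start
    exons = tuple((int(bounds[j]), int(bounds[j + 1]))
                  for j in range(0, n_parts, 2))
    cds_start = cds_end = None
    if coding:
        exonic = [p for s, e in exons for p in (s, e)]
        total_ex = sum(e - s for s, e in exons)
        u5 = int(rng.integers(1, max(2, total_ex // 5)))
        u3 = int(rng.integers(1, max(2, total_ex // 5)))
        if u5 + u3 >= total_ex:
            u5 = u3 = max(1, total_ex // 4)
        cds_start = _exonic_to_genomic(exons, u5)
        cds_end = _exonic_to_genomic(exons, total_ex - u3 - 1) + 1
    return TranscriptModel(gene_id=gene_id, transcript_id=f"{gene_id}.t1",
                           chrom=chrom, strand=strand,
                           tx_start=tx_start, tx_end=tx_end, exons=exons,
                           cds_start=cds_start, cds_end=cds_end)


def _exonic_to_genomic(exons, idx):
    for s, e in exons:
        if idx < e - s:
            return s + idx
        idx -= e - s
    raise IndexError("exonic index out of range")


# ---------------------------------------------------------------------------
# Insertion planting
# ---------------------------------------------------------------------------

def _gene_spans(transcripts, promoter_window=2000):
    """Promoter-through-gene-end span per gene (strand-aware upstream)."""
    spans: dict[str, list] = {}
    for t in transcripts:
        s = spans.setdefault(t.gene_id, [t.chrom, t.tx_start, t.tx_end, t.strand])
        s[1] = min(s[1], t.tx_start)
        s[2] = max(s[2], t.tx_end)
    out = {}
    for g, (chrom, s, e, strand) in spans.items():
        if strand == "+":
            out[g] = (chrom, max(0, s - promoter_window), e)
        else:
            out[g] = (chrom, s, e + promoter_window)
    return out


def plant_insertions(genome: ReferenceGenome, transcripts, config: SimConfig,
                     ) -> TruthTable:
    """Plant insertions at TTAA sites per sample and draw their diversities.

    Background insertions are uniform over usable TTAA sites (both strands);
    for each ``(gene_id, group, fold)`` in ``config.enriched_genes``,
    samples of that group receive additional insertions inside the gene's
    promoter-through-end span so the expected summed diversity there is
    ``fold`` times the background expectation.  Per-site diversity is
    ``1 + Poisson(diversity_lambda)``.
    """
    rng = np.random.default_rng([config.seed, 1])
    margin = config.read_length  # keep fragments clear of chromosome ends

    candidates = []  # (chrom, strand, coord)
    for chrom in genome.names():
        L = genome.length(chrom)
        for p in genome.ttaa_sites(chrom):
            if p + 4 + margin <= L:
                candidates.append((chrom, "+", p + 4))
            if p - margin >= 0:
                candidates.append((chrom, "-", p))
    if not candidates:
        raise ConfigError("genome has no usable TTAA sites")
    n_cand = len(candidates)

    spans = _gene_spans(transcripts)
    span_candidates = {
        g: [i for i, (c, _, co) in enumerate(candidates)
            if c == chrom and s <= co < e]
        for g, (chrom, s, e) in spans.items()
    }

    def gene_of(chrom, coord):
        for g, (c, s, e) in spans.items():
            if c == chrom and s <= coord < e:
                return g
        return None

    records = []
    for sample in config.sample_ids():
        group = config.sample_groups()[sample]
        chosen: set[tuple] = set()
        while len(chosen) < config.n_insertions_per_sample:
            need = config.n_insertions_per_sample - len(chosen)
            for i in rng.integers(0, n_cand, need):
                chosen.add(candidates[int(i)])
        for gene_id, egroup, fold in config.enriched_genes:
            if gene_id not in spans:
                raise ConfigError(f"enriched gene {gene_id} not in transcripts")
            if egroup != group:
                continue
            pool = span_candidates[gene_id]
            if not pool:
                warnings.warn(f"gene {gene_id} has no TTAA sites in span; skipped")
                continue
            baseline = config.n_insertions_per_sample * len(pool) / n_cand
            n_extra = int(rng.poisson(max(0.0, (fold - 1.0) * baseline)))
            guard = 0
            added = 0
            while added < n_extra and guard < 50 * n_extra + 100:
                guard += 1
                cand = candidates[int(pool[int(rng.integers(0, len(pool)))])]
                if cand not in chosen:
                    chosen.add(cand)
                    added += 1
        for chrom, strand, coord in sorted(chosen):
            diversity = 1 + int(rng.poisson(config.diversity_lambda))
            records.append(TruthRecord(sample, chrom, strand, coord,
                                       diversity, gene_of(chrom, coord)))
    return TruthTable(records)


# ---------------------------------------------------------------------------
# Read simulation
# ---------------------------------------------------------------------------

@dataclass
class SimulatedPair:
    """One emitted read pair (post-PCR copy)."""

    sample_id: str
    read1: str
    read2: str
    is_contaminant: bool = False


def _mutate(rng, seq: str, rate: float) -> str:
    if rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    hits = np.nonzero(rng.random(len(arr)) < rate)[0]
    for i in hits:
        choices = _BASES[_BASES != arr[i]]
        arr[i] = choices[rng.integers(0, len(choices))]
    return arr.tobytes().decode()


def simulate_read_pairs(genome: ReferenceGenome, truth: TruthTable,
                        config: SimConfig) -> dict[str, list[SimulatedPair]]:
    """Generate read pairs in memory, keyed by sample.

    For each planted insertion, ``true_diversity`` distinct shear ends are
    drawn (fragment length truncated-normal, minimum ``read_length / 2``),
    each unique fragment is emitted ``1 + Poisson(pcr_dup_mean)`` times,
    substitution errors are applied at ``seq_error_rate`` and a
    ``contaminant_frac`` share of pairs is replaced by random non-junction
    sequence.
    """
    rng = np.random.default_rng([config.seed, 2])
    prefix = TRANSPOSON_PREFIX
    core_len = config.read_length - len(prefix)
    min_frag = max(20, config.read_length // 2)

    out: dict[str, list[SimulatedPair]] = {s: [] for s in config.sample_ids()}
    for rec in truth:
        chrom_seq = genome[rec.chrom]
        L = len(chrom_seq)
        room = (L - rec.coord) if rec.strand == "+" else rec.coord
        shear_ends: set[int] = set()
        guard = 0
        while len(shear_ends) < rec.true_diversity and guard < 200 * rec.true_diversity:
            guard += 1
            f = int(round(rng.normal(config.fragment_length_mean,
                                     config.fragment_length_sd)))
            if f < min_frag or f > room:
                continue  # resample fragments falling off the chromosome
            shear_ends.add(rec.coord + f if rec.strand == "+" else rec.coord - f)
        if len(shear_ends) < rec.true_diversity:
            # cramped site near a chromosome end: fall back to consecutive ends
            step = 1 if rec.strand == "+" else -1
            f = min_frag
            while len(shear_ends) < rec.true_diversity and f <= room:
                shear_ends.add(rec.coord + step * f)
                f += 1
        for shear in sorted(shear_ends):
            if rec.strand == "+":
                frag = chrom_seq[rec.coord:shear]
            else:
                frag = revcomp(chrom_seq[shear:rec.coord])
            read1 = (prefix + frag[:core_len])[:config.read_length]
            read2 = revcomp(frag)[:config.read_length]
            copies = 1 + int(rng.poisson(config.pcr_dup_mean))
            for _ in range(copies):
                r1 = _mutate(rng, read1, config.seq_error_rate)
                r2 = _mutate(rng, read2, config.seq_error_rate)
                if rng.random() < config.contaminant_frac:
                    r1 = _random_nonjunction(rng, config.read_length, prefix)
                    r2 = _random_sequence(rng, config.read_length)
                    out[rec.sample_id].append(
                        SimulatedPair(rec.sample_id, r1, r2, True))
                else:
                    out[rec.sample_id].append(
                        SimulatedPair(rec.sample_id, r1, r2, False))
    return out


def _random_nonjunction(rng, length: int, prefix: str) -> str:
    while True:
        s = _random_sequence(rng, length)
        if not s.startswith(prefix):
            return s


def simulate_reads(genome: ReferenceGenome, truth: TruthTable,
                   config: SimConfig, outdir) -> dict[str, tuple[Path, Path]]:
    """Write per-sample gzipped FASTQ pairs ``<sample>_R1/_R2.fastq.gz``.

    Sample barcodes are recorded in read headers (``bc:XXXXXXXX``) unless
    ``config.inline_barcodes`` is set, in which case the barcode is
    prepended to read 1.  Quality strings are constant 'I'.  Output is
    byte-identical for identical configs (gzip timestamps are zeroed).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    pairs = simulate_read_pairs(genome, truth, config)
    bc_rng = np.random.default_rng([config.seed, 3])
    paths: dict[str, tuple[Path, Path]] = {}
    for sample in config.sample_ids():
        barcode = _random_sequence(bc_rng, config.barcode_length)
        p1 = outdir / f"{sample}_R1.fastq.gz"
        p2 = outdir / f"{sample}_R2.fastq.gz"
        with _gz(p1) as f1, _gz(p2) as f2:
            for i, pair in enumerate(pairs[sample]):
                name = f"{sample}:{i + 1} bc:{barcode}"
                r1 = barcode + pair.read1 if config.inline_barcodes else pair.read1
                f1.write(f"@{name}\n{r1}\n+\n{'I' * len(r1)}\n")
                f2.write(f"@{name}\n{pair.read2}\n+\n{'I' * len(pair.read2)}\n")
        paths[sample] = (p1, p2)
    return paths


class _gz:
    """Gzip text writer with zeroed mtime/name for reproducible bytes."""

    def __init__(self, path):
        self.raw = open(path, "wb")
        self.gz = gzip.GzipFile(filename="", mode="wb", fileobj=self.raw, mtime=0)

    def __enter__(self):
        return self

    def write(self, s: str) -> None:
        self.gz.write(s.encode())

    def __exit__(self, *exc):
        self.gz.close()
        self.raw.close()
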