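"""End-to-end screen driver: simulate or load libraries, trim, align,
call and filter sites, annotate, and rank gene enrichment.

This is the orchestration layer the CLI and the examples sit on; each step
is the corresponding library function and can be run independently.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .align import AlignStats, AlignedPair, align_pairs
from .annotate import Annotator, SiteAnnotation, TranscriptModel, group_by_gene
from .config import SimConfig
from .enrich import GeneSampleMatrix, EnrichmentResult, percentage_matrix, rank_enriched
from .genome import ReferenceGenome
from .preprocess import DiscardStats, ReadPair, trim_prefix
from .simulate import (TruthTable, gen_reference, plant_insertions,
                       simulate_read_pairs)
from .sites import IntegrationSite, call_sites, filter_ttaa


@dataclass
class ScreenResult:
    """Everything a simulated screen run produces."""

    config: SimConfig
    genome: ReferenceGenome
    transcripts: list[TranscriptModel]
    truth: TruthTable
    discard_stats: DiscardStats
    align_stats: AlignStats
    kept_sites: dict[str, list[IntegrationSite]]
    rejected_sites: dict[str, list[IntegrationSite]]
    annotations: dict[str, list[SiteAnnotation]] = field(default_factory=dict)
    matrix: GeneSampleMatrix | None = None
    ranking: list[EnrichmentResult] | None = None


def process_sample_pairs(pairs: list[ReadPair], genome: ReferenceGenome,
                         ) -> tuple[dict[str, list[AlignedPair]], DiscardStats, AlignStats]:
    """Trim, align and split aligned pairs by sample."""
    trimmed, discard = trim_prefix(pairs)
    aligned, astats = align_pairs(trimmed, genome)
    by_sample: dict[str, list[AlignedPair]] = {}
    for ap in aligned:
        by_sample.setdefault(ap.sample_id, []).append(ap)
    return by_sample, discard, astats


def run_screen(config: SimConfig, rank: bool = True) -> ScreenResult:
    """Simulate a screen under ``config`` and run the full analysis."""
    genome, transcripts = gen_reference(config)
    truth = plant_insertions(genome, transcripts, config)
    sim = simulate_read_pairs(genome, truth, config)
    all_pairs = [ReadPair(p.read1, p.read2, sample)
                 for sample, plist in sim.items() for p in plist]
    by_sample, discard, astats = process_sample_pairs(all_pairs, genome)

    kept: dict[str, list[IntegrationSite]] = {}
    rejected: dict[str, list[IntegrationSite]] = {}
    for sample in config.sample_ids():
        sites = call_sites(by_sample.get(sample, []), sample, genome)
        kept[sample], rejected[sample] = filter_ttaa(sites, genome)

    result = ScreenResult(config=config, genome=genome, transcripts=transcripts,
                          truth=truth, discard_stats=discard, align_stats=astats,
                          kept_sites=kept, rejected_sites=rejected)
    if rank:
        annotator = Annotator(transcripts)
        grouped = {}
        for sample, sites in kept.items():
            anns = []
            for s in sites:
                ann = annotator.classify(s.chrom, s.coord, s.strand)
                from dataclasses import replace

                anns.append(replace(ann, site=s))
            result.annotations[sample] = anns
            grouped[sample] = group_by_gene(anns)
        result.matrix = percentage_matrix(grouped, config.sample_groups())
        groups = {g for g in config.sample_groups().values()}
        if {"metastatic", "tumour"} <= groups:
            result.ranking = rank_enriched(result.matrix)
    return result


@dataclass(frozen=True)
class RecoveryScore:
    """Agreement between planted truth and called sites."""

    n_planted: int
    n_recovered: int  # planted sites called at exact coordinate + strand
    n_spurious: int  # kept sites not in the truth table
    n_spurious_div2: int  # spurious sites with diversity >= 2
    n_fragments: int  # total unique fragments planted (sum of diversities)

    @property
    def recovery_rate(self) -> float:
        return self.n_recovered / self.n_planted if self.n_planted else 1.0


def score_recovery(truth: TruthTable,
                   kept: dict[str, list[IntegrationSite]]) -> RecoveryScore:
    """Score called sites against the planted truth, exact coordinate and
    strand, per sample."""
    truth_keys = {(r.sample_id, r.chrom, r.strand, r.coord) for r in truth}
    called_keys = {(s.sample_id, s.chrom, s.strand, s.coord)
                   for sites in kept.values() for s in sites}
    spurious = [s for sites in kept.values() for s in sites
                if (s.sample_id, s.chrom, s.strand, s.coord) not in truth_keys]
    return RecoveryScore(
        n_planted=len(truth_keys),
        n_recovered=len(truth_keys & called_keys),
        n_spurious=len(spurious),
        n_spurious_div2=sum(1 for s in spurious if s.diversity >= 2),
        n_fragments=sum(r.true_diversity for r in truth))
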