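"""Integration-site calling and TTAA motif filtering.

Aligned pairs sharing a junction coordinate (chrom, strand, r1_start) are
collapsed into one integration site.  The site's *diversity* is the number
of distinct shear ends among its supporting pairs — identical fragments
produced by PCR duplication collapse to one — which makes it a
PCR-duplicate-robust clonality proxy.  piggyBac duplicates its TTAA target
site, so genuine insertions carry TTAA directly upstream of the junction
on the read strand; sites failing that motif check are removed (but kept
for QC).
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Sequence

from .align import AlignedPair
from .genome import TTAA, ReferenceGenome, revcomp


@dataclass(frozen=True)
class IntegrationSite:
    """A called transposon insertion in one sample."""

    sample_id: str
    chrom: str
    strand: str
    coord: int  # 0-based; TTAA occupies [coord-4, coord) on +, [coord, coord+4) on -
    upstream4: str
    diversity: int
    raw_reads: int

    def __post_init__(self) -> None:
        if self.diversity < 1 or self.diversity > self.raw_reads:
            raise ValueError("need 1 <= diversity <= raw_reads")
        if len(self.upstream4) != 4:
            raise ValueError("upstream4 must be a 4-mer")


def upstream_4mer(genome: ReferenceGenome, chrom: str, strand: str, coord: int) -> str:
    """Genomic 4-mer directly upstream of the junction on the read strand.

    Positions beyond the chromosome edge read as N, so edge sites fail the
    TTAA filter rather than erroring.
    """
    u4 = (genome.fetch(chrom, coord - 4, coord) if strand == "+"
          else revcomp(genome.fetch(chrom, coord, coord + 4)))
    return "NNNN" if "N" in u4 else u4


def call_sites(pairs: Sequence[AlignedPair], sample_id: str,
               genome: ReferenceGenome) -> list[IntegrationSite]:
    """Collapse one sample's aligned pairs into integration sites.

    Diversity counts distinct ``shear_end`` values per (chrom, strand,
    r1_start) group; ``raw_reads`` is the group size.  Output is sorted by
    (chrom, coord, strand) for determinism.
    """
    groups: dict[tuple, list[AlignedPair]] = defaultdict(list)
    for p in pairs:
        if p.sample_id and p.sample_id != sample_id:
            raise ValueError(f"pair from sample {p.sample_id!r}, expected {sample_id!r}")
        groups[(p.chrom, p.strand, p.r1_start)].append(p)
    sites = []
    for (chrom, strand, coord), members in groups.items():
        sites.append(IntegrationSite(
            sample_id=sample_id, chrom=chrom, strand=strand, coord=coord,
            upstream4=upstream_4mer(genome, chrom, strand, coord),
            diversity=len({m.shear_end for m in members}),
            raw_reads=len(members)))
    sites.sort(key=lambda s: (s.chrom, s.coord, s.strand))
    return sites


def filter_ttaa(sites: Iterable[IntegrationSite], genome: ReferenceGenome,
                ) -> tuple[list[IntegrationSite], list[IntegrationSite]]:
    """Split sites into (kept, rejected) on the upstream-TTAA motif.

    The motif is recomputed from the genome (not trusted from the site
    record) so sites read back from BED are filtered identically.
    """
    kept, rejected = [], []
    for s in sites:
        u4 = upstream_4mer(genome, s.chrom, s.strand, s.coord)
        (kept if u4 == TTAA else rejected).append(s)
    return kept, rejected


# ---------------------------------------------------------------------------
# BED6+2 I/O (chrom, start, end, name, score=diversity, strand, upstream4,
# raw_reads)
# ---------------------------------------------------------------------------

def write_bed(sites: Sequence[IntegrationSite], path) -> None:
    with open(path, "w") as fh:
        for i, s in enumerate(sites):
            fh.write(f"{s.chrom}\t{s.coord}\t{s.coord + 1}\t"
                     f"{s.sample_id}:{i + 1}\t{s.diversity}\t{s.strand}\t"
                     f"{s.upstream4}\t{s.raw_reads}\n")


def read_bed(path) -> list[IntegrationSite]:
    sites = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            chrom, start, _end, name, score, strand, u4, raw = \
                line.rstrip("\n").split("\t")
            sites.append(IntegrationSite(
                sample_id=name.rsplit(":", 1)[0], chrom=chrom, strand=strand,
                coord=int(start), upstream4=u4, diversity=int(score),
                raw_reads=int(raw)))
    return sites
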