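"""Transcript models, the insertion-site classification hierarchy, and
regulatory-domain (basal + extension) peak-to-gene association.

An insertion site is annotated against transcript models in a fixed
hierarchy: sites overlapping no transcript are *promoter* sites when they
fall in a 2,000-bp strand-aware window upstream of any transcript start,
otherwise *intergenic*; sites overlapping a transcript take the first
matching region type in the order 5'UTR, CDS, 3'UTR, intron, ncRNA (ncRNA
meaning overlap with a transcript lacking an annotated CDS).  Overlaps are
computed on any strand; the site's orientation relative to the assigned
gene is reported separately.  Where several transcripts overlap, the scan
order (chrom, tx_start, transcript_id) breaks ties deterministically.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

PROMOTER_WINDOW = 2000

#: classification priority once a site overlaps at least one transcript
REGION_ORDER = ("5UTR", "CDS", "3UTR", "intron", "ncRNA")

#: sentinel for a missing flank at a chromosome end
NO_FLANK = "."


@dataclass(frozen=True)
class TranscriptModel:
    """Strand-aware transcript with exon and optional CDS structure.

    Coordinates are 0-based half-open.  ``cds_start``/``cds_end`` are absent
    (None) for non-coding transcripts.
    """

    gene_id: str
    transcript_id: str
    chrom: str
    strand: str
    tx_start: int
    tx_end: int
    exons: tuple[tuple[int, int], ...]
    cds_start: Optional[int] = None
    cds_end: Optional[int] = None

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")
        prev_end = self.tx_start - 1
        for s, e in self.exons:
            if s >= e or s < self.tx_start or e > self.tx_end:
                raise ValueError("exons must be non-empty and within the transcript")
            if s <= prev_end:
                raise ValueError("exons must be sorted and non-overlapping")
            prev_end = e
        if (self.cds_start is None) != (self.cds_end is None):
            raise ValueError("cds_start and cds_end must be both present or absent")

    @property
    def is_noncoding(self) -> bool:
        return self.cds_start is None

    @property
    def tss(self) -> int:
        """TSS as a half-open boundary coordinate (start on +, end on -)."""
        return self.tx_start if self.strand == "+" else self.tx_end

    def promoter_window(self, width: int = PROMOTER_WINDOW) -> tuple[int, int]:
        """Strand-aware upstream window [start, end), clipped at zero."""
        if self.strand == "+":
            return max(0, self.tx_start - width), self.tx_start
        return self.tx_end, self.tx_end + width

    def region_at(self, pos: int) -> Optional[str]:
        """Region type of a single base inside this transcript, else None.

        For a coding transcript exonic bases are 5'UTR / CDS / 3'UTR by
        position relative to the CDS (strand-aware); non-exonic bases inside
        the span are introns.  Every base of a non-coding transcript's span
        is 'ncRNA'.
        """
        if not (self.tx_start <= pos < self.tx_end):
            return None
        if self.is_noncoding:
            return "ncRNA"
        exonic = any(s <= pos < e for s, e in self.exons)
        if not exonic:
            return "intron"
        if self.cds_start <= pos < self.cds_end:
            return "CDS"
        before_cds = pos < self.cds_start
        if self.strand == "+":
            return "5UTR" if before_cds else "3UTR"
        return "3UTR" if before_cds else "5UTR"


@dataclass(frozen=True)
class SiteAnnotation:
    """Classification of one insertion site against the transcriptome."""

    chrom: str
    coord: int
    strand: str
    category: str  # promoter | 5UTR | CDS | 3UTR | intron | ncRNA | intergenic
    gene_id: Optional[str] = None
    flanking: Optional[tuple[str, str]] = None  # (left gene, right gene)
    orientation: Optional[str] = None  # same | opposite | None (intergenic)
    site: object = None  # the IntegrationSite this annotation describes

    @property
    def group_key(self):
        """Gene-level grouping key: gene_id, or the ordered flanking pair."""
        return self.gene_id if self.gene_id is not None else self.flanking


def _scan_order(t: TranscriptModel):
    return (t.chrom, t.tx_start, t.transcript_id)


class Annotator:
    """Classifies genomic positions against a fixed transcript set.

    Precomputes, per chromosome, transcripts in deterministic scan order
    and gene spans (min transcript start to max transcript end) for
    flanking-gene lookup of intergenic sites.
    """

    def __init__(self, transcripts: Iterable[TranscriptModel],
                 promoter_window: int = PROMOTER_WINDOW):
        self.promoter_window = promoter_window
        self._by_chrom: dict[str, list[TranscriptModel]] = defaultdict(list)
        for t in sorted(transcripts, key=_scan_order):
            self._by_chrom[t.chrom].append(t)
        # gene spans per chromosome, sorted by start, for flank lookup
        self._gene_spans: dict[str, list[tuple[int, int, str]]] = {}
        self._span_starts: dict[str, list[int]] = {}
        for chrom, ts in self._by_chrom.items():
            spans: dict[str, list[int]] = {}
            for t in ts:
                s = spans.setdefault(t.gene_id, [t.tx_start, t.tx_end])
                s[0] = min(s[0], t.tx_start)
                s[1] = max(s[1], t.tx_end)
            ordered = sorted((s, e, g) for g, (s, e) in spans.items())
            self._gene_spans[chrom] = ordered
            self._span_starts[chrom] = [s for s, _, _ in ordered]

    def classify(self, chrom: str, coord: int, strand: str) -> SiteAnnotation:
        """Annotate a single position; every position is classifiable."""
        overlapping = [t for t in self._by_chrom.get(chrom, ())
                       if t.tx_start <= coord < t.tx_end]
        if overlapping:
            for category in REGION_ORDER:
                for t in overlapping:  # already in scan order
                    if t.region_at(coord) == category:
                        orientation = "same" if strand == t.strand else "opposite"
                        return SiteAnnotation(chrom, coord, strand, category,
                                              gene_id=t.gene_id,
                                              orientation=orientation)
            raise AssertionError("overlapping transcript yielded no region")
        for t in self._by_chrom.get(chrom, ()):
            ps, pe = t.promoter_window(self.promoter_window)
            if ps <= coord < pe:
                orientation = "same" if strand == t.strand else "opposite"
                return SiteAnnotation(chrom, coord, strand, "promoter",
                                      gene_id=t.gene_id, orientation=orientation)
        return SiteAnnotation(chrom, coord, strand, "intergenic",
                              flanking=self._flanks(chrom, coord))

    def _flanks(self, chrom: str, coord: int) -> tuple[str, str]:
        spans = self._gene_spans.get(chrom, [])
        left, left_end = NO_FLANK, -1
        right, right_start = NO_FLANK, None
        for s, e, g in spans:
            if e <= coord and e > left_end:
                left, left_end = g, e
            if s > coord and (right_start is None or s < right_start):
                right, right_start = g, s
        return (left, right)


def classify_site(site, transcripts: Iterable[TranscriptModel],
                  promoter_window: int = PROMOTER_WINDOW) -> SiteAnnotation:
    """Annotate one IntegrationSite (convenience wrapper over Annotator)."""
    ann = Annotator(transcripts, promoter_window).classify(
        site.chrom, site.coord, site.strand)
    return dataclass_replace(ann, site=site)


def annotate_sites(sites, transcripts: Iterable[TranscriptModel],
                   promoter_window: int = PROMOTER_WINDOW) -> list[SiteAnnotation]:
    """Annotate many sites against one transcript set (index built once)."""
    annot = Annotator(transcripts, promoter_window)
    return [dataclass_replace(annot.classify(s.chrom, s.coord, s.strand), site=s)
            for s in sites]


def dataclass_replace(ann: SiteAnnotation, **kw) -> SiteAnnotation:
    from dataclasses import replace

    return replace(ann, **kw)


def group_by_gene(annotations: Sequence[SiteAnnotation]) -> dict:
    """Partition annotations by gene (promoter sites included) or, for
    intergenic sites, by the ordered (left gene, right gene) flanking pair.

    Returns an insertion-ordered dict key -> list of SiteAnnotation; the
    groups partition the input (no site lost or double-counted).
    """
    groups: dict = {}
    for ann in annotations:
        groups.setdefault(ann.group_key, []).append(ann)
    return groups


# ---------------------------------------------------------------------------
# Basal + extension regulatory domains (GREAT-style association)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RegulatoryDomain:
    gene_id: str
    chrom: str
    strand: str
    basal: tuple[int, int]
    domain: tuple[int, int]


def regulatory_domains(transcripts: Iterable[TranscriptModel],
                       basal_up: int = 5000, basal_down: int = 1000,
                       max_ext: int = 10000) -> list[RegulatoryDomain]:
    """Per-gene basal-plus-extension regulatory domains.

    Each gene's TSS (5'-most transcript boundary) defines a basal domain of
    ``basal_up`` bp upstream and ``basal_down`` bp downstream, strand-aware.
    Each basal domain is then extended on both sides up to the nearest
    neighbouring basal domain on that chromosome, but by at most ``max_ext``
    bp beyond the basal edge; extension never shrinks the basal domain.
    Genes with identical TSS are handled independently.
    """
    per_gene: dict[str, TranscriptModel] = {}
    for t in sorted(transcripts, key=_scan_order):
        cur = per_gene.get(t.gene_id)
        if cur is None:
            per_gene[t.gene_id] = t
        else:
            # 5'-most TSS of the gene defines the domain
            if t.strand == "+":
                if t.tx_start < cur.tx_start:
                    per_gene[t.gene_id] = t
            else:
                if t.tx_end > cur.tx_end:
                    per_gene[t.gene_id] = t

    basal: list[tuple[str, str, str, int, int]] = []
    for g, t in per_gene.items():
        s = t.tss
        if t.strand == "+":
            b = (max(0, s - basal_up), s + basal_down)
        else:
            b = (max(0, s - basal_down), s + basal_up)
        basal.append((t.chrom, g, t.strand, b[0], b[1]))

    out = []
    by_chrom: dict[str, list] = defaultdict(list)
    for rec in basal:
        by_chrom[rec[0]].append(rec)
    for chrom, recs in by_chrom.items():
        for chrom_, g, strand, bs, be in recs:
            left_cap = 0
            right_cap = None
            for _, g2, _, bs2, be2 in recs:
                if g2 == g:
                    continue
                if be2 <= bs and be2 > left_cap:
                    left_cap = be2
                if bs2 >= be and (right_cap is None or bs2 < right_cap):
                    right_cap = bs2
            ds = max(max(0, bs - max_ext), left_cap)
            de = be + max_ext if right_cap is None else min(be + max_ext, right_cap)
            ds = min(ds, bs)  # extension never shrinks the basal domain
            de = max(de, be)
            out.append(RegulatoryDomain(g, chrom, strand, (bs, be), (ds, de)))
    out.sort(key=lambda d: (d.chrom, d.domain[0], d.gene_id))
    return out


def great_associate(peaks: Sequence[tuple], transcripts: Iterable[TranscriptModel],
                    basal_up: int = 5000, basal_down: int = 1000,
                    max_ext: int = 10000) -> dict[tuple, set[str]]:
    """Associate peaks with genes whose regulatory domain contains the
    peak midpoint.

    ``peaks`` are ``(chrom, start, end)`` intervals (half-open); the
    anchoring point is ``(start + end) // 2``.  Returns peak -> set of
    gene_ids (possibly empty).
    """
    domains = regulatory_domains(transcripts, basal_up, basal_down, max_ext)
    by_chrom: dict[str, list[RegulatoryDomain]] = defaultdict(list)
    for d in domains:
        by_chrom[d.chrom].append(d)
    result: dict[tuple, set[str]] = {}
    for peak in peaks:
        chrom, start, end = peak[0], int(peak[1]), int(peak[2])
        mid = (start + end) // 2
        hits = {d.gene_id for d in by_chrom.get(chrom, ())
                if d.domain[0] <= mid < d.domain[1]}
        result[(chrom, start, end)] = hits
    return result


# ---------------------------------------------------------------------------
# Ranked-list intersection (candidate triangulation)
# ---------------------------------------------------------------------------

def intersect_top(ranked_a: Sequence[str], ranked_b: Sequence[str],
                  target_set: Iterable[str], n: int = 200):
    """Intersect the top-``n`` of two significance-ranked gene lists with a
    target gene set.

    Returns ``(common, venn)`` where ``common`` is the set of genes present
    in all three sources and ``venn`` maps each membership pattern (a
    frozenset drawn from {'a', 'b', 'target'}) to its count over the union.
    """
    import warnings

    ta, tb = list(ranked_a), list(ranked_b)
    if n > len(ta) or n > len(tb):
        warnings.warn(f"n={n} exceeds a ranked list length; using full lists")
    a, b, t = set(ta[:n]), set(tb[:n]), set(target_set)
    common = a & b & t
    venn: Counter = Counter()
    for g in a | b | t:
        pattern = frozenset(
            name for name, s in (("a", a), ("b", b), ("target", t)) if g in s
        )
        venn[pattern] += 1
    return common, dict(venn)


# ---------------------------------------------------------------------------
# GTF I/O
# ---------------------------------------------------------------------------

def write_gtf(transcripts: Iterable[TranscriptModel], path) -> None:
    """Write transcripts as GTF (1-based inclusive coordinates on disk)."""
    with open(path, "w") as fh:
        for t in sorted(transcripts, key=_scan_order):
            attrs = f'gene_id "{t.gene_id}"; transcript_id "{t.transcript_id}";'

            def line(feature, s, e):
                return (f"{t.chrom}\tpbscreen\t{feature}\t{s + 1}\t{e}\t.\t"
                        f"{t.strand}\t.\t{attrs}\n")

            fh.write(line("transcript", t.tx_start, t.tx_end))
            for es, ee in t.exons:
                fh.write(line("exon", es, ee))
            if not t.is_noncoding:
                for es, ee in t.exons:
                    cs, ce = max(es, t.cds_start), min(ee, t.cds_end)
                    if cs < ce:
                        fh.write(line("CDS", cs, ce))


def read_gtf(path) -> list[TranscriptModel]:
    """Read transcript models from a GTF file via gffutils."""
    import gffutils

    db = gffutils.create_db(str(path), dbfn=":memory:", force=True,
                            keep_order=True,
                            merge_strategy="create_unique",
                            disable_infer_genes=True,
                            disable_infer_transcripts=True)
    out = []
    for tx in db.features_of_type("transcript"):
        exons = sorted(
            (f.start - 1, f.end)
            for f in db.children(tx, featuretype="exon")
        )
        cds = [(f.start - 1, f.end) for f in db.children(tx, featuretype="CDS")]
        cds_start = min(s for s, _ in cds) if cds else None
        cds_end = max(e for _, e in cds) if cds else None
        out.append(TranscriptModel(
            gene_id=tx.attributes["gene_id"][0],
            transcript_id=tx.attributes["transcript_id"][0],
            chrom=tx.seqid, strand=tx.strand,
            tx_start=tx.start - 1, tx_end=tx.end,
            exons=tuple(exons), cds_start=cds_start, cds_end=cds_end,
        ))
    out.sort(key=_scan_order)
    return out
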