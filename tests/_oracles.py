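"""Independent brute-force oracles shared by the test modules.

These deliberately re-derive each quantity by the most direct method
available (full enumeration, per-base set arithmetic, explicit domain
construction) and never call the implementation paths they check.
"""

from itertools import combinations

import numpy as np
import pandas as pd
from scipy.stats import rankdata

import pbscreen as pb


def enumeration_p(x, y):
    """Exact two-sided Mann-Whitney p by full labeling enumeration."""
    x, y = list(x), list(y)
    nx = len(x)
    vals = np.array(x + y, dtype=float)
    ranks = rankdata(vals)
    base = nx * (nx + 1) / 2
    u_obs = ranks[:nx].sum() - base
    le = ge = total = 0
    for idx in combinations(range(len(vals)), nx):
        u = ranks[list(idx)].sum() - base
        total += 1
        le += u <= u_obs + 1e-9
        ge += u >= u_obs - 1e-9
    return min(1.0, 2.0 * min(le, ge) / total)


def oracle_region(t, pos):
    """Per-base region of one transcript by explicit set arithmetic."""
    if not (t.tx_start <= pos < t.tx_end):
        return None
    if t.cds_start is None:
        return "ncRNA"
    exonic = set()
    for s, e in t.exons:
        exonic.update(range(s, e))
    if pos not in exonic:
        return "intron"
    if t.cds_start <= pos < t.cds_end:
        return "CDS"
    upstream_of_cds = pos < t.cds_start
    if t.strand == "+":
        return "5UTR" if upstream_of_cds else "3UTR"
    return "3UTR" if upstream_of_cds else "5UTR"


def oracle_classify(transcripts, pos, strand):
    """Exhaustive classification of one position (category, gene)."""
    order = sorted(transcripts,
                   key=lambda t: (t.chrom, t.tx_start, t.transcript_id))
    overlapping = [t for t in order if t.tx_start <= pos < t.tx_end]
    if overlapping:
        for cat in ("5UTR", "CDS", "3UTR", "intron", "ncRNA"):
            for t in overlapping:
                if oracle_region(t, pos) == cat:
                    return cat, t.gene_id
        raise AssertionError("unreachable")
    for t in order:
        if t.strand == "+" and t.tx_start - 2000 <= pos < t.tx_start:
            return "promoter", t.gene_id
        if t.strand == "-" and t.tx_end <= pos < t.tx_end + 2000:
            return "promoter", t.gene_id
    return "intergenic", None


def oracle_domains(transcripts, up, down, ext):
    """Brute-force basal+extension regulatory-domain construction."""
    genes = {}
    for t in transcripts:
        tss = t.tx_start if t.strand == "+" else t.tx_end
        cur = genes.get(t.gene_id)
        if cur is None:
            genes[t.gene_id] = (t.chrom, t.strand, tss)
        else:
            _, strand, cur_tss = cur
            if (tss < cur_tss) if strand == "+" else (tss > cur_tss):
                genes[t.gene_id] = (t.chrom, t.strand, tss)
    basal = {}
    for g, (chrom, strand, tss) in genes.items():
        if strand == "+":
            basal[g] = (chrom, max(0, tss - up), tss + down)
        else:
            basal[g] = (chrom, max(0, tss - down), tss + up)
    dom = {}
    for g, (chrom, bs, be) in basal.items():
        lo_cap, hi_cap = 0, None
        for g2, (c2, bs2, be2) in basal.items():
            if g2 == g or c2 != chrom:
                continue
            if be2 <= bs:
                lo_cap = max(lo_cap, be2)
            if bs2 >= be:
                hi_cap = bs2 if hi_cap is None else min(hi_cap, bs2)
        lo = max(bs - ext, lo_cap)
        hi = be + ext if hi_cap is None else min(be + ext, hi_cap)
        dom[g] = (chrom, min(lo, bs), max(hi, be))
    return dom


def matrix_from_diversities(div, groups):
    """GeneSampleMatrix straight from per-gene summed diversities."""
    D = pd.DataFrame(div).fillna(0.0).sort_index()
    T = D.sum(axis=0)
    return pb.GeneSampleMatrix(percentages=100.0 * D / T, diversity=D,
                               totals=T, sample_groups=groups)


def truth_gene_diversities(cfg):
    """Plant insertions under ``cfg`` and sum truth diversities per gene
    and sample (no read simulation)."""
    genome, transcripts = pb.gen_reference(cfg)
    truth = pb.plant_insertions(genome, transcripts, cfg)
    div = {s: {} for s in cfg.sample_ids()}
    for rec in truth:
        g = rec.gene_id or "intergenic"
        div[rec.sample_id][g] = div[rec.sample_id].get(g, 0) + rec.true_diversity
    return div
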