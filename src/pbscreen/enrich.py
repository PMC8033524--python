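"""Gene-level enrichment of insertions in metastatic versus tumour samples.

The screen's quantification unit is the per-sample *percentage of unique
insertions*: each gene's summed shear-end diversity divided by the
sample's total, times 100.  Genes are ranked by the difference of group
means (metastatic − tumour) and tested with a two-tailed Mann–Whitney U
test — exact by full labeling enumeration at small sample sizes, otherwise
a tie- and continuity-corrected normal approximation.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata


def _key_str(key) -> str:
    """Matrix row label: gene_id, or 'left~right' for a flanking pair."""
    if isinstance(key, tuple):
        return "~".join(key)
    return key


@dataclass
class GeneSampleMatrix:
    """Per-gene, per-sample insertion abundance.

    ``percentages`` rows are gene (or flanking-pair) groups, columns are
    samples; each column sums to 100.  ``diversity`` holds the raw summed
    diversities D and ``totals`` the per-sample denominators T, so
    P = 100 * D / T.
    """

    percentages: pd.DataFrame
    diversity: pd.DataFrame
    totals: pd.Series
    sample_groups: dict[str, str] = field(default_factory=dict)


def percentage_matrix(grouped_by_sample: Mapping[str, Mapping[str, object]],
                      sample_groups: Mapping[str, str] | None = None,
                      denominator: str = "summed_diversity") -> GeneSampleMatrix:
    """Build the gene x sample percentage matrix.

    Parameters
    ----------
    grouped_by_sample
        ``sample_id -> {group_key -> [SiteAnnotation, ...]}`` as produced by
        :func:`pbscreen.annotate.group_by_gene` per sample.  Each annotation
        must reference a site with a ``diversity`` attribute.
    denominator
        ``"summed_diversity"`` (default): T[s] is the total summed diversity
        of the sample, consistent with the definition of unique insertions
        per gene.  ``"site_count"``: T[s] is the number of distinct sites,
        the alternative reading of "total number of unique insertions".
    """
    if denominator not in ("summed_diversity", "site_count"):
        raise ValueError(f"unknown denominator {denominator!r}")
    div: dict[str, dict[str, float]] = {}
    totals: dict[str, float] = {}
    for sample, groups in grouped_by_sample.items():
        col: dict[str, float] = {}
        n_sites = 0
        for key, anns in groups.items():
            d = sum(a.site.diversity for a in anns)
            n_sites += len(anns)
            col[_key_str(key)] = col.get(_key_str(key), 0.0) + d
        t = sum(col.values()) if denominator == "summed_diversity" else n_sites
        if t == 0:
            warnings.warn(f"sample {sample} has no insertions; excluded")
            continue
        div[sample] = col
        totals[sample] = float(t)

    D = pd.DataFrame(div).fillna(0.0).sort_index()
    T = pd.Series(totals, dtype=float).reindex(D.columns)
    P = 100.0 * D / T
    groups = dict(sample_groups or {})
    groups = {s: g for s, g in groups.items() if s in D.columns}
    return GeneSampleMatrix(percentages=P, diversity=D, totals=T,
                            sample_groups=groups)


# ---------------------------------------------------------------------------
# Mann-Whitney U
# ---------------------------------------------------------------------------

def mann_whitney_u(x: Sequence[float], y: Sequence[float],
                   exact_max_n: int = 10) -> tuple[float, float]:
    """Two-tailed Mann–Whitney U test.

    U is computed from midranks (ties averaged) for the first sample.  When
    both groups have at most ``exact_max_n`` observations and there are no
    ties, the exact null distribution is obtained by enumerating all
    C(n_x + n_y, n_x) group labelings; otherwise a normal approximation
    with tie correction and continuity correction is used.  The two-sided
    p-value is ``min(1, 2 * one-sided)``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    nx, ny = len(x), len(y)
    if nx == 0 or ny == 0:
        raise ValueError("both samples must be non-empty")
    combined = np.concatenate([x, y])
    ranks = rankdata(combined)
    u_x = float(ranks[:nx].sum() - nx * (nx + 1) / 2)

    _, tie_counts = np.unique(combined, return_counts=True)
    has_ties = bool((tie_counts > 1).any())

    if has_ties and (tie_counts == nx + ny).any():
        # every value identical: no information
        return nx * ny / 2.0, 1.0

    if not has_ties and nx <= exact_max_n and ny <= exact_max_n:
        p = _exact_two_sided(ranks, nx, ny, u_x)
        return u_x, p

    n = nx + ny
    mu = nx * ny / 2.0
    tie_term = float(((tie_counts ** 3 - tie_counts).sum()) / (n * (n - 1)))
    var = nx * ny / 12.0 * ((n + 1) - tie_term)
    if var <= 0:
        return u_x, 1.0
    z = (abs(u_x - mu) - 0.5) / math.sqrt(var)
    p = min(1.0, 2.0 * float(norm.sf(max(z, 0.0))))
    return u_x, p


def _exact_two_sided(ranks: np.ndarray, nx: int, ny: int, u_obs: float) -> float:
    """Exact p over all C(n, nx) equally likely group labelings.

    Without ties the ranks are 1..n, so the labeling enumeration reduces to
    the classic rank-sum null distribution, computed here by dynamic
    programming (counts of size-nx subsets of {1..n} by rank sum).
    """
    n = nx + ny
    max_sum = n * (n + 1) // 2
    # f[k][s]: subsets of size k with rank sum s
    f = np.zeros((nx + 1, max_sum + 1), dtype=float)
    f[0, 0] = 1.0
    for rank in range(1, n + 1):
        f[1:, rank:] += f[:-1, :-rank].copy()  # copy: views overlap
    counts = f[nx]
    total = counts.sum()
    base = nx * (nx + 1) // 2
    u = np.arange(max_sum + 1) - base  # U value per rank sum
    count_le = counts[u <= u_obs + 1e-9].sum()
    count_ge = counts[u >= u_obs - 1e-9].sum()
    one_sided = min(count_le, count_ge) / total
    return min(1.0, 2.0 * one_sided)


# ---------------------------------------------------------------------------
# Ranking
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EnrichmentResult:
    gene_id: str
    mean_pct_met: float
    mean_pct_tum: float
    delta: float
    U: float
    p_two_sided: float
    enriched: bool
    q_bh: float = float("nan")


def rank_enriched(matrix: GeneSampleMatrix,
                  metastatic_group: str = "metastatic",
                  tumour_group: str = "tumour",
                  exact_max_n: int = 10) -> list[EnrichmentResult]:
    """Rank genes by metastatic-vs-tumour difference in insertion percentage.

    Genes are ordered by descending delta (mean metastatic % − mean tumour
    %), ties broken by ascending p then gene id.  Genes with delta <= 0 are
    retained but flagged not-enriched.  A Benjamini–Hochberg column is
    provided as supplementary output; the primary readout is the raw
    two-tailed Mann–Whitney p, as is conventional for a handful of
    candidate genes.
    """
    groups = matrix.sample_groups
    met = [s for s in matrix.percentages.columns if groups.get(s) == metastatic_group]
    tum = [s for s in matrix.percentages.columns if groups.get(s) == tumour_group]
    if not met or not tum:
        raise ValueError(
            f"need samples in both groups {metastatic_group!r} and {tumour_group!r}")

    results = []
    for gene, row in matrix.percentages.iterrows():
        xm = row[met].to_numpy(dtype=float)
        xt = row[tum].to_numpy(dtype=float)
        u, p = mann_whitney_u(xm, xt, exact_max_n=exact_max_n)
        delta = float(xm.mean() - xt.mean())
        results.append(EnrichmentResult(
            gene_id=str(gene), mean_pct_met=float(xm.mean()),
            mean_pct_tum=float(xt.mean()), delta=delta, U=u,
            p_two_sided=p, enriched=delta > 0))

    from statsmodels.stats.multitest import multipletests

    pvals = [r.p_two_sided for r in results]
    if pvals:
        _, q, _, _ = multipletests(pvals, method="fdr_bh")
        results = [EnrichmentResult(**{**r.__dict__, "q_bh": float(qi)})
                   for r, qi in zip(results, q)]
    results.sort(key=lambda r: (-r.delta, r.p_two_sided, r.gene_id))
    return results


def results_frame(results: Sequence[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in results])
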