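# Methods

This note documents the models, conventions and defaults behind
`pbscreen`, what the synthetic-data generator does and does not emulate,
and the design choices made where more than one reading was defensible.

## Coordinate and strand conventions

All coordinates are 0-based half-open internally; 1-based coordinates
appear only at the SAM boundary and in GTF files on disk.

The insertion coordinate `coord` is defined as the boundary immediately 3'
of the duplicated TTAA target site in the orientation of the junction
read (read 1 after trimming):

- **+ strand**: the TTAA occupies `genome[coord-4:coord]`; the trimmed
  read aligns starting at `coord` and runs rightwards. `r1_start = coord`
  is the most-5' aligned base.
- **− strand**: the TTAA occupies `genome[coord:coord+4]` (TTAA is its own
  reverse complement); the trimmed read aligns ending at `coord`
  (half-open) and runs leftwards, so `r1_start = coord` is one past the
  most-5' aligned base. This half-open convention makes the motif-filter
  arithmetic identical on both strands and is the only convention under
  which the filter is satisfiable on simulated truth for both strands.

The shear end is the outer (far) boundary of the mate: `coord + F` on +
and `coord − F` on − for a fragment of length F. Sites on opposite
strands at the same coordinate are distinct sites; whether the original
analyses keyed sites by strand is not documented anywhere we know of, so
the stricter strand-keyed definition is used and stated.

## Synthetic screen generator

The generator emulates the statistical structure the analysis assumes,
stage by stage:

| feature | model | default |
|---|---|---|
| genome | i.i.d. uniform ACGT per chromosome | 1 × 200 kb |
| TTAA density | emergent (~1/256 bp); short test chromosomes are seeded to ≥ 50 per chromosome | — |
| genes | non-overlapping, 1–3 exons, strand-random; a fixed fraction without CDS | 20 genes, 20% non-coding |
| insertions | uniform over usable TTAA sites (both strands), distinct per sample | 100 per sample |
| clonality (diversity) | 1 + Poisson(λ) distinct shear ends per site | λ = 2 |
| shear fragments | Normal(mean, sd) truncated at max(20, read_length/2) bp and at the chromosome end | 250 ± 60 bp |
| PCR duplication | each unique fragment emitted 1 + Poisson(μ) times | μ = 1 |
| sequencing error | i.i.d. per-base substitution | 5 × 10⁻⁴ |
| contaminants | pairs replaced by random non-junction sequence | 1% |
| barcodes | 8 nt, in read headers (inline mode behind a flag) | header |
| qualities | constant 'I'; the pipeline never uses qualities | — |

Group-differential signal: for each `(gene, group, fold)` the generator
plants additional insertions inside the gene's promoter-through-end span
so the *expected* summed diversity there is `fold` times the background
expectation for samples of that group. Everything is a deterministic
function of the single config seed (gzip members are written with zeroed
timestamps so outputs are byte-identical across runs).

What the generator does **not** emulate: splinkerette adaptor-ligation
chemistry, indel errors, reads from non-mobilized transposon copies
(modelled only as the contaminant fraction), local hopping, chromatin-
dependent insertion bias, and per-site clonal dynamics beyond the shifted
Poisson. Passing tests therefore demonstrate correctness of the
*computation* under the stated generative assumptions, not robustness to
every artefact of real libraries. The shifted-Poisson clonality model and
the 60 bp shear-length s.d. are conventions chosen as realistic for
sonication libraries, not reconstructions of any particular dataset.

## Preprocessing and alignment

Trimming removes the expected 9-nt transposon prefix from read 1 and
discards non-matching pairs, reporting the discarded fraction (in real
libraries ~1%; in simulations the expectation is the contaminant fraction
plus the probability of a sequencing error inside the prefix).

The built-in aligner reproduces the uniqueness *contract* of a
`-m 1 --best --strata --maxins 1000` alignment semantically rather than
parameter-for-parameter: exact 20-nt 5' seed, at most one mismatch in the
remainder of each mate, mates on opposite strands in FR orientation
within 1,000 bp, and a pair is reported only when exactly one locus
attains the best total-mismatch stratum. Candidate loci are found by one
forward scan of the genome against the batch's seed set, so cost is
O(genome + reads) per call; this is intended for the megabase-scale
references the package simulates, not for full mammalian genomes — use
the SAM/BAM ingestion path (`read_alignments`) with an external aligner
there. Unmapped pairs are only counted (no secondary alignment against a
donor-plasmid sequence is attempted, since no such reference is shipped).

## Site calling and diversity

Pairs are grouped by `(chrom, strand, r1_start)`; diversity is the number
of distinct shear-end values in the group (exact outer coordinate; no ±1
fuzzy merging, because the quantity counts *distinct alignment pairs*),
`raw_reads` the group size. Diversity is exactly invariant under
replication of input pairs, which the tests assert for k ∈ {2, 10, 100}.
The motif filter recomputes the upstream 4-mer from the genome (so
BED-roundtripped sites filter identically); windows that cross a
chromosome edge read as `NNNN` and fail the filter rather than erroring.
Output order is (chrom, coord, strand) throughout.

## Gene association hierarchy

Overlaps are computed on any strand. A site overlapping no transcript is
`promoter` if inside any 2,000-bp strand-aware window upstream of a
transcript start (transcript-level windows, since annotations list
transcript starts; a gene-level mode is not provided), else `intergenic`
with the ordered flanking-gene pair (sentinel `.` at chromosome ends).
Otherwise the site takes the first matching category in the fixed order
5'UTR → CDS → 3'UTR → intron → ncRNA, where ncRNA means overlap with a
transcript lacking an annotated CDS. "First overlap" among several
transcripts is resolved by the deterministic scan order
(chrom, tx_start, transcript_id). Orientation is `same`/`opposite`
relative to the assigned transcript's strand, `NA` for intergenic. The
tests check the whole hierarchy against an exhaustive per-base oracle.

## Regulatory domains (basal + extension)

Each gene's TSS (5'-most transcript boundary) defines a strand-aware
basal domain [TSS − 5,000, TSS + 1,000); each basal domain is extended on
both sides to the nearest neighbouring basal domain, by at most 10,000 bp
beyond the basal edge, never shrinking below basal. A peak associates
with every gene whose domain contains the peak *midpoint* (so the maximum
upstream reach is 15,000 bp, and extensions of neighbouring genes may
overlap in the gap between their basal domains — a peak there associates
with both). Curated regulatory domains, which require an external
database, are not supported and the option is documented as such. Peak
anchoring by midpoint is the conventional choice; the domain arithmetic
is fixed exactly as above because legend-style descriptions of this rule
are ambiguous about the cap semantics.

## Enrichment statistics

P[g,s] = 100 · D[g,s] / T[s], where D sums diversity over the sites of
gene group g in sample s. The denominator T[s] defaults to the sample's
**total summed diversity** (consistent with defining a gene's "unique
insertions" as summed diversity); the alternative reading — the count of
distinct sites — is available via `denominator="site_count"` rather than
silently chosen. Genes absent from a sample get D = 0; columns sum to
100 exactly.

The Mann–Whitney U uses midranks. With both n ≤ `exact_max_n` (default
10) and no ties, the exact two-sided p is computed over all
C(n_x + n_y, n_x) equally likely labelings; because tie-free ranks are
just 1..n this reduces to the classic rank-sum null distribution,
evaluated by dynamic programming (identical values to full enumeration,
which the tests verify, at polynomial cost). Otherwise a normal
approximation with tie correction and a 0.5 continuity correction is
used; the two branches agree within 0.01 at 8 v 8. Two-sided
p = min(1, 2 · one-sided). All-identical inputs return U = n_x·n_y/2,
p = 1.

Ranking is by descending Δ = mean P(metastatic) − mean P(tumour), ties by
ascending p then gene id; Δ ≤ 0 rows are retained but flagged. No
multiple-testing correction is applied to the primary ranking (raw p on a
handful of candidates is the convention this reproduces); a
Benjamini–Hochberg column is emitted for genome-wide use.

A note on calibration: at 4 v 4 the exact test's smallest attainable
two-sided p is 2/70 ≈ 0.029, so the achieved type-I rate at the 0.05
level is necessarily below nominal; the suite's null-calibration check
therefore runs at 10 v 10 with near-continuous percentage data, where the
achieved level approaches 0.05 (group sizes of that order also match
realistic screen designs such as 16 tumour vs 18 metastatic samples).

## In-vivo quantification

- `tumour_volume`: V = 0.5·L·S² (mm³); swapped diameters are corrected
  with a warning.
- `time_to_threshold`: OLS of log V on t over V > 0 points, natural log
  internally (the estimated time is invariant to the log base; only the
  intercept/slope units depend on it). t* = (ln V* − a)/b with V* = 250
  mm³ by default; b ≤ 0 means the threshold is never reached (None), and
  estimates outside the observed time range are flagged extrapolated.
  Under the reference noise model (σ = 0.2 multiplicative log-normal, 8
  points over 21 days) the median fit R² is ≈ 0.99 and the median
  time-to-threshold error is ≈ 1%; the acceptance script recomputes this.
- `ddct_fold_change`: 2^−(ΔCt_sample − ΔCt_control) with ΔCt = Ct_target −
  Ct_housekeeping; technical replicates are averaged arithmetically
  before the calculation.
- `percent_input`: the standard dilution-adjusted form
  100 · 2^{(Ct_input − log2(1/f)) − Ct_IP} for an input aliquot fraction
  f; the method is conventionally named without its formula, so the
  adopted form is stated here explicitly.
- Student's/Welch's t-tests are bundled as utilities for downstream
  comparisons of estimated times; survival analysis and limiting-dilution
  statistics are out of scope (mature external implementations exist).

## IHC quantification

The recipe is the standard Fiji-style semi-automatic pipeline:
rolling-ball background subtraction (radius 50 px by default, applied to
the inverted light-background image — the morphological equivalent of
"Subtract Background, light background"; radius 0 skips the step, as in
panels quantified without it), colour deconvolution with the published
H-DAB stain vectors (H 0.650/0.704/0.286, DAB 0.269/0.568/0.776,
residual = cross product; overridable), Gaussian blur σ = 5 of the DAB
channel, and a fixed global threshold. The DAB channel is re-rendered as
I = 255·10^(−OD) so 255 = unstained and darker = more stain;
`separate_stains`' internal log(1e-6) normalisation is undone to obtain
true base-10 optical densities (round-trips recover forward-rendered ODs
within 2% away from saturation). Positive pixels are ROI pixels with
DAB value ≤ threshold — the polarity is a flag, since published
thresholds (222 for CD31, 170 for the other panels) are stated without
polarity. Whether the original macros thresholded the raw or blurred
channel is unknowable from the description; the blurred channel is used
and the choice documented rather than asserted. Metastatic burden is
100 × area(union of metastasis ROIs)/area(lung mask), clipping ROI pixels
outside the lung with a warning.

## Problem sizes used in the checks

The end-to-end recovery check simulates 2 groups × 4 samples on a 2-Mb
single-chromosome genome with ~100 insertions per sample, PCR duplication
mean 5, error rate 10⁻³ and 1% contamination (~14,500 read pairs); the
enrichment Monte-Carlo checks use 100 planting seeds, and the null
calibration 2,000 gene-tests. These sizes were chosen so each check
exercises the full code path with comfortable statistical resolution
while the whole suite stays desk-scale.

## Known limitations

- The built-in aligner is for small simulated references; real screens
  should come in through SAM/BAM.
- No common-insertion-site (CIS) statistics, gene-length or TTAA-density
  background correction — the enrichment is the plain percentage ranking
  it reproduces.
- The GREAT-style association omits curated domains.
- Differential-expression input lists are consumed, never produced.
- The IHC module quantifies area fractions only: no nucleus segmentation,
  per-cell scoring, or whole-slide tiling.
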