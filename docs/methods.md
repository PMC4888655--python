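# Methods

## The measurement model

RRHP sequences MspI fragments whose CCGG site carried a glucosylated
5hmC, so the read count at a CCGG site is taken as proportional to that
site's hydroxymethylation level. All analyses in this package start
from per-site count tables (chrom, 0-based position, strand, count).
Sites are strand-collapsed: one record per MspI locus. Coordinates are
0-based half-open internally; GTF is converted on ingest.

### Site calling

The calling threshold is derived from the reference cell type with the
highest global 5hmC: `cutoff = mean + SEM` over **all** of its CCGG
sites, zeros included, with SEM computed from the sample SD (n−1) —
the conventional SEM definition. Replicates of the reference cell type
are pooled before the mean is taken (a per-replicate mode that averages
per-replicate cutoffs is available, `cutoff_mode: per_replicate`). The
call is strict: a site is positive iff `count > cutoff`. No
between-library depth normalisation is applied by default, because the
assay's comparison convention applies one reference-derived cutoff to
all libraries; a counts-per-million mode exists for exploration and is
explicitly labelled as a departure from that convention.

### Gene-body 5hmC

`level = total reads at CCGG sites in [TSS, TTS] / number of CCGG
sites in [TSS, TTS]`, counting every CCGG whether called positive or
not. The gene body is the whole TSS-to-TTS span including introns —
the heatmap analyses that motivate this quantity span the full gene —
with an exon-only mode behind a flag. A gene with no CCGG gets NaN
(missing), never zero: zero would be indistinguishable from "covered
but unmethylated".

## Element maps

Promoter = strand-aware [TSS−1000, TSS+100); TTS region = [TTS−100,
TTS+1000) (mirrored on the minus strand). Every base receives exactly
one label. Where features overlap the precedence is promoter >
TTS_region > 5′UTR > 3′UTR > exon > intron > intergenic: the promoter
and TTS windows are explicit definitions and therefore win over generic
gene structure; the ordering among the remaining labels follows the
usual annotation-hierarchy convention. Overlapping genes resolve
first-by-precedence, then first-gene-wins, so percentages always sum
to 100. When an annotation has isoforms, the longest transcript is the
canonical one. Relative density per element class e is
`n_e · (10⁵ / N_total) / (L_e / 10⁵)` — sites normalised to 10⁵ bp of
element and to a fixed pool of 10⁵ sites — so density is invariant to
proportional rescaling of the site pool; zero-length classes yield NaN.

## Profiles and statistics

**TSS profiles** bin ±5 kb around the TSS in 50-bp bins, oriented in
the direction of transcription. Per-bin enrichment is summed reads
divided by the number of CCGG sites in the bin (normalising the signal
to the genomic CCGG distribution); bins with no CCGG emit NaN rather
than 0 to avoid fake dips. **Scaled-region matrices** divide each
region body into a fixed number of equal genomic spans plus fixed-width
flank bins and average the track over each span (the scale-regions
behaviour of standard coverage-matrix tools, reimplemented here over a
piecewise-constant track with O(log n) window queries). Regions shorter
than the bin count get fractional-bp spans — effectively repeating
bases — rather than failing.

**Spearman permutation test.** ρ uses average ranks for ties. For
n ≤ 8 the full n! null is enumerated and p = #{|ρ*| ≥ |ρ|}/n! (the
identity permutation guarantees p > 0). Otherwise p = (1 + hits) /
(n_perm + 1) over seeded Monte-Carlo permutations (default 10,000),
the +1 correction avoiding p = 0. Two-tailed throughout.

**Kolmogorov–Smirnov.** Two-sample D = sup|ECDF₁ − ECDF₂| with the
asymptotic p (scipy), matching common practice at the sample sizes
involved; occupancy comparisons are flagged significant at the
conservative convention D > 0.45 and p < 10⁻¹⁰.

**Heatmap orderings** use log2(FPKM+1) (pseudocount does not affect
ranks); expression summaries use log2(FPKM) restricted to FPKM > 1.

## Enhancers and TF occupancy

Dual active enhancers are H3K27ac peaks whose bases are ≥ 25 % covered
by the union of H3K4me1 peaks (merged first, so overlapping peaks are
not double-counted; the boundary is inclusive with a 10⁻⁹ float guard)
and that do not overlap any TSS window. The TSS window is half-open
[TSS−1000, TSS+1000), and exclusion triggers on any overlap of the
peak with the window — "lacks a TSS" is read as any-overlap, the
stricter of the two readings. The 5hmC split assigns a region to the
positive group iff it contains at least one called site in
[start, end); the CCGG-matched control additionally requires the
negative group to contain at least one CCGG and drops CCGG-free
regions, so a positive/negative difference cannot be an artefact of
MspI-site content.

The KS comparison runs on **per-region mean occupancy** (one scalar
per region over the scaled body), not on pooled per-bin values: pooled
bins within a region are strongly autocorrelated and would inflate the
effective sample size; the mean profile shapes are reported
descriptively alongside. Swapping the groups leaves D unchanged.

## Clustering and dynamics

Gene-body levels (replicate means per cell type) are transformed
log2(x+1) — the +1 admits zero levels, which a bare log2 would not —
with missing levels imputed as 0 beforehand; clustering is
agglomerative with Euclidean distance and complete linkage
(scipy.cluster.hierarchy), deterministic and invariant to row order.
Two-stage use: cluster all genes (k configurable, default 5), select
the cluster with the highest mean level across all cell types, then
re-cluster it into six (the fixed second-stage k).

Delta analysis filters to genes with FPKM > 1 and gene-body 5hmC > 1
in **at least one** of the two compared cell types: a strict both-sides
filter would remove exactly the genes that lose expression or 5hmC,
the cases the analysis is about (strict mode behind a flag).
LFC = log2(mature/progenitor); "logarithmic fold change ≥ 2" is
interpreted on the log2 scale (≥ 4-fold) — an interpretation, exposed
as `lfc_threshold`. The Δ5hmC vs LFC association uses the permutation
Spearman above; a constant vector (e.g. progenitor = mature) returns
an explicit None instead of a fabricated p.

The joint-state classifier labels a gene *repressed* when gene-body
5hmC is at or below the high-threshold (default: the cell-type
median), otherwise *primed* when promoter methylation ≥ 50 % and
*expressed* when below; missing measurements give *unknown*. Thresholds
are echoed in every result record.

## The synthetic-data generator

The generator emulates the study design the analyses expect: a
multi-chromosome genome with non-overlapping, strand-balanced,
multi-exon genes; a uniform CCGG catalogue (default 2 sites/kb, giving
gene bodies tens of sites); negative-binomial read counts
(var = μ + αμ², default α = 0.1) whose genic mean is
`read_depth_mean × propensity` (default 100 reads — the scale at which
a mean+SEM cutoff lands near 100, as in real RRHP reference
libraries); a fixed per-site lognormal factor (σ = 0.6) shared across
replicates and cell types so replicate concordance sits in the r > 0.75
regime observed in practice; and intergenic background at 5 reads.

Gene 5hmC propensity and expression are coupled through a Gaussian
copula with latent correlation r = 2·sin(πρ/6), which makes the
population Spearman correlation exactly the configured `rho_planted`
(default 0.6). Expression is emitted as the lognormal transform of the
latent itself, so the planted rank correlation is exact by
construction and count noise is the only attenuation the analysis has
to overcome. A TSS-proximal shape (peaks near ±350 bp, dip at the
TSS) is planted on sites within ±2 kb of each TSS. Non-reference cell
types add a per-gene program shift that moves 5hmC and expression
together (σ = 0.8, expression log-gain 2.5), planting the
Δ5hmC–ΔFPKM coupling; the reference cell type keeps the base values so
correlation-recovery checks run against the clean planted ρ.

Enhancers are placed in intergenic slots (≥ 2 kb from genes, so their
high site counts cannot contaminate gene bodies). A configured
fraction is 5hmC-positive (CCGG mean 250 reads, well above any
realistic cutoff); every enhancer is guaranteed at least one CCGG —
injected at the centre when the uniform catalogue missed it, for both
groups alike, keeping CCGG content balanced between groups. H3K27ac
peaks cover all enhancers plus the promoters of the top-expressed
quintile (so TSS exclusion has something to exclude); a configurable
fraction (default 0.8) is fully covered by H3K4me1, the rest 10 % —
below the 25 % rule. TF coverage is gamma noise (shape 4) around
`tf_base_occupancy × tf_factor` in 50-bp bins over enhancers ± 2 kb,
with `tf_factor = tf_effect` (default 3) at 5hmC-positive enhancers.

Truth (propensities, latents, enhancer status, TF factors) is emitted
as a separate object/JSON and never written into any file the analysis
consumes. All randomness derives from the single config seed through
tagged, independent streams, so outputs are byte-identical across runs
and replicates differ only in count noise.

**What the generator does not emulate** — and hence what passing tests
do not establish about real data: sequence-dependent CCGG placement
(CpG islands, repeats), mappability and copy-number artefacts,
isoform complexity (one canonical transcript per gene), peak-calling
noise in the histone inputs, batch/depth differences between libraries,
and any causal link between 5hmC and TF binding (the planted occupancy
effect is associational by construction). Tests demonstrate that the
implementations recover planted parameters under the stated noise
model, not that the biological conclusions transfer.

## Problem sizes and numerical choices

Default study conditions: 2,000 genes on 2 × 12 Mb chromosomes;
correlation-recovery runs use 5,000 genes (4 × 15 Mb) with 10,000
permutations; occupancy comparisons use 1,000 enhancers (500 per
group) with a 200-simulation null calibration; the enhancer-rule
oracle check uses 1,000 random peak configurations. These sizes give
sampling error comfortably inside the tolerances being checked (e.g.
SE(ρ̂) ≈ 0.009 at n = 5000) while keeping a full run to minutes on one
CPU. Permutation chunking caps transient memory at ~4 M floats. Ties
in expression tertiles break by gene id; remainder genes go to the
lower tertiles. Degenerate inputs fail loudly (empty tables, n = 1
SEM, constant vectors, k > n) rather than returning placeholders.
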