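# hmcscan

Analysis toolkit for **reduced representation of 5-hydroxymethylcytosine
profiling (RRHP)** data: calling hydroxymethylated CCGG sites from
per-site read counts, quantifying gene-body 5hmC, relating it to gene
expression, classifying enhancers from histone ChIP peaks, testing
whether transcription-factor occupancy differs between 5hmC-positive
and -negative regulatory regions, and clustering genes by their
gene-body 5hmC programs across cell types.

The intended users are epigenomics groups studying 5hmC as a regulatory
mark — for instance across hematopoietic differentiation, where
gene-body 5hmC tracks lineage-specific expression — who want the whole
integration analysis as a tested, reusable library rather than a chain
of one-off scripts. A synthetic-data generator with planted structure
makes every stage verifiable end to end without any external download.

## Method summary

- **Site calling.** RRHP read counts at MspI CCGG sites are treated as
  proportional to hydroxymethylation. The calling threshold is
  `cutoff = mean + SEM` over *all* CCGG sites of the reference cell
  type (the one with the highest global 5hmC; replicates pooled; SEM
  uses the sample SD, *n*−1). A site is 5hmC-positive iff
  `count > cutoff` (strict).
- **Gene-body 5hmC.** `level = Σ reads at CCGG in [TSS, TTS] / #CCGG in
  [TSS, TTS]` (introns included; exon-only mode available). Genes
  without CCGG are flagged missing, never zero.
- **Element maps.** Promoter = TSS−1 kb..+100 bp, TTS region = TTS−100
  bp..+1 kb (strand-aware); every base gets exactly one label by the
  precedence promoter > TTS > 5′UTR > 3′UTR > exon > intron >
  intergenic. Relative density = `n_e · (10⁵/N_total) / (L_e/10⁵)`.
- **Profiles and statistics.** TSS meta-profiles normalise reads to the
  CCGG distribution (reads per CCGG per 50-bp bin); scaled-region
  matrices implement the scale-regions binning of coverage-matrix
  tools. Spearman ρ gets a seeded two-tailed permutation p (exact
  enumeration for n ≤ 8, +1-corrected Monte Carlo otherwise);
  distribution shifts use the two-sample Kolmogorov–Smirnov *D* with
  the significance convention *D* > 0.45 and *p* < 10⁻¹⁰.
- **Enhancers.** Poised = H3K4me1 peaks; active = H3K27ac peaks; dual
  active = H3K27ac peaks ≥ 25 % covered (inclusive) by merged H3K4me1
  and with no TSS ± 1 kb overlap. Regions split by 5hmC status (≥ 1
  positive site), optionally CCGG-matched so the negative group also
  contains CCGG sites.
- **Clustering and dynamics.** Complete-linkage Euclidean clustering of
  log2(level+1) across cell types, two-stage (select the uniformly-high
  cluster, re-cluster into six); cluster expression summarised as mean
  log2 FPKM ± 95 % CI over genes with FPKM > 1; per-gene Δ5hmC vs
  expression log2 fold change with |LFC| ≥ 2 defining increase/loss.

## Worked example

`examples/` holds one short script per capability. For instance:

```bash
$ python examples/02_genebody_expression_correlation.py
gene-body 5hmC vs log2 FPKM: rho = 0.572, permutation p = 1.00e-04 (planted rho = 0.6)
        high tertile: mean TSS+5kb enrichment 187.5 reads/CCGG
intermediate tertile: mean TSS+5kb enrichment 91.4 reads/CCGG
         low tertile: mean TSS+5kb enrichment 50.0 reads/CCGG
high vs low tertile KS D = 0.56 (above the D > 0.45 convention)
```

The generator planted a rank correlation of 0.6 between gene-body 5hmC
propensity and expression; the pipeline recovers ρ = 0.57 from the
simulated read counts, and TSS-proximal 5hmC enrichment increases
monotonically across expression tertiles with a KS separation above the
significance convention — the qualitative signature expected of an
expression-coupled gene-body mark.

```bash
$ python examples/03_enhancers_and_tf_occupancy.py
H3K27ac peaks: 1020; dual-marked TSS-free active enhancers: 800
5hmC-positive enhancers: 415; negative: 385
TF occupancy KS D = 0.87, p = 4.4e-175 -> significant at the D > 0.45, p < 1e-10 convention (planted effect x3)
```

A thin CLI mirrors the library (`hmcscan simulate|call|genebody|
elements|correlate|cluster|run`); `hmcscan run --config run.yaml`
drives the whole pipeline from a YAML document and writes a manifest
with parameter and file digests for reproducibility.

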