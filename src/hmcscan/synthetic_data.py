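"""Synthetic genomes, RRHP libraries, expression tables and ChIP inputs.

The generator emulates the data a reduced-representation 5hmC profiling
(RRHP) study produces: per-CCGG-site read counts whose mean tracks a
gene's hydroxymethylation propensity, FPKM expression tables coupled to
that propensity through a Gaussian copula (so the planted rank
correlation is exact in population), histone peak sets over intergenic
enhancers, and transcription-factor coverage with a multiplicative
occupancy boost at 5hmC-positive enhancers.

Ground truth (propensities, expression latents, enhancer 5hmC status,
TF factors) is emitted alongside the data and never written into any
file an analysis module consumes.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import Genome, GeneModel, SignalTrack, SiteTable, points_in_intervals

__all__ = [
    "SyntheticConfig",
    "SyntheticTruth",
    "generate_genome",
    "generate_truth",
    "generate_rrhp",
    "generate_expression",
    "generate_chip",
    "simulate",
]


@dataclass
class SyntheticConfig:
    """Study conditions for one synthetic dataset.

    Counts model: negative binomial with mean ``read_depth_mean`` at genic
    CCGG sites (scaled by the gene's propensity) and variance
    ``mu + dispersion * mu**2``. ``rho_planted`` is the target Spearman
    correlation between gene-body 5hmC and expression; ``tf_effect`` the
    occupancy multiplier at 5hmC-positive enhancers.
    """

    n_chroms: int = 2
    chrom_length: int = 12_000_000
    n_genes: int = 2000
    ccgg_rate: float = 2.0                 # sites per kb, genome-wide
    read_depth_mean: float = 100.0         # reads per genic CCGG site
    read_depth_dispersion: float = 0.1     # NB dispersion alpha
    rho_planted: float = 0.6
    frac_positive_enhancers: float = 0.5
    tf_effect: float = 3.0
    seed: int = 0

    # secondary shape parameters (defaults are the package's study conditions)
    cell_types: tuple = ("hESC", "CD34", "Tcell")
    cell_type_scale: dict = field(default_factory=lambda: {"hESC": 1.0, "CD34": 0.8, "Tcell": 0.65})
    gene_length_range: tuple = (4000, 10000)
    propensity_sigma: float = 1.0          # lognormal sd of gene 5hmC propensity
    site_sigma: float = 0.6                # shared per-site lognormal factor
    background_depth: float = 5.0          # reads at intergenic CCGG sites
    expression_sigma: float = 1.5          # lognormal sd of FPKM
    expression_scale: float = 8.0          # median FPKM
    n_enhancers: int = 400
    enhancer_length: int = 1500
    enhancer_depth: float = 250.0          # reads at CCGGs in 5hmC-positive enhancers
    dual_mark_frac: float = 0.8            # H3K27ac peaks also covered >=25% by H3K4me1
    dynamics_sigma: float = 0.8            # per-gene program shift in non-reference cell types
    dynamics_expr_gain: float = 2.5        # expression log-response per unit 5hmC shift
    tf_base_occupancy: float = 10.0
    tf_noise_shape: float = 4.0            # gamma shape of per-bin occupancy noise

    def __post_init__(self) -> None:
        if min(self.n_chroms, self.chrom_length) <= 0:
            raise ValueError("n_chroms and chrom_length must be positive")
        if self.n_genes < 0 or self.n_enhancers < 0:
            raise ValueError("counts must be nonnegative")
        if not 0.0 <= self.frac_positive_enhancers <= 1.0:
            raise ValueError("frac_positive_enhancers must be in [0, 1]")
        if abs(self.rho_planted) > 1.0:
            raise ValueError("|rho_planted| must be <= 1")
        if self.tf_effect < 1.0:
            raise ValueError("tf_effect must be >= 1")


@dataclass
class SyntheticTruth:
    """Planted parameters, aligned to the generated genome."""

    genes: pd.DataFrame       # gene_id, propensity, expression
    enhancers: pd.DataFrame   # enhancer_id, chrom, start, end, hmc_positive, tf_factor
    site_factor: np.ndarray   # shared lognormal factor per CCGG site (genome.ccgg order)

    def propensity_of(self, gene_ids) -> np.ndarray:
        lut = self.genes.set_index("gene_id")["propensity"]
        return lut.reindex(gene_ids).to_numpy()


def _stream(config: SyntheticConfig, *tags) -> np.random.Generator:
    """Independent deterministic RNG stream per (seed, purpose)."""
    ints = [int(config.seed) & 0x7FFFFFFF]
    for t in tags:
        ints.append(zlib.crc32(str(t).encode()) & 0x7FFFFFFF)
    return np.random.default_rng(ints)


def generate_genome(config: SyntheticConfig) -> Genome:
    """Place non-overlapping, strand-balanced genes and a uniform CCGG catalogue.

    Raises ``ValueError`` naming the packing constraint when ``n_genes``
    cannot fit on the configured chromosomes.
    """
    rng = _stream(config, "genome")
    chrom_sizes = {f"chr{i + 1}": config.chrom_length for i in range(config.n_chroms)}
    chroms = list(chrom_sizes)

    per_chrom = np.full(config.n_chroms, config.n_genes // config.n_chroms)
    per_chrom[: config.n_genes % config.n_chroms] += 1

    genes: list[GeneModel] = []
    gidx = 0
    margin = 5000
    lo, hi = config.gene_length_range
    for ci, chrom in enumerate(chroms):
        n = int(per_chrom[ci])
        if n == 0:
            continue
        lengths = rng.integers(lo, hi + 1, size=n)
        slack = config.chrom_length - 2 * margin - int(lengths.sum()) - (n - 1) * 1000
        if slack < 0:
            raise ValueError(
                f"cannot place {n} genes (total {lengths.sum()} bp + margins) "
                f"on {chrom} of length {config.chrom_length}: increase chrom_length"
            )
        offsets = np.sort(rng.uniform(0, slack, size=n)).astype(int)
        for j in range(n):
            start = margin + int(offsets[j]) + int(lengths[:j].sum()) + j * 1000
            end = start + int(lengths[j])
            strand = "+" if gidx % 2 == 0 else "-"
            n_exons = int(rng.integers(2, 6))
            cuts = np.sort(rng.choice(np.arange(start + 50, end - 50), size=2 * n_exons - 2, replace=False))
            bounds = np.concatenate([[start], cuts, [end]])
            exons = [(int(bounds[2 * k]), int(bounds[2 * k + 1])) for k in range(n_exons)]
            genes.append(GeneModel(f"g{gidx:05d}", chrom, strand, start, end, exons))
            gidx += 1

    p = config.ccgg_rate / 1000.0
    frames = []
    for chrom in chroms:
        n_sites = rng.binomial(config.chrom_length, p)
        pos = np.unique(rng.integers(0, config.chrom_length, size=n_sites))
        frames.append(pd.DataFrame({"chrom": chrom, "pos": pos, "strand": "+"}))
    ccgg = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(columns=["chrom", "pos", "strand"])
    return Genome(chrom_sizes=chrom_sizes, genes=genes, ccgg=ccgg)


def _intergenic_slots(genome: Genome, config: SyntheticConfig) -> pd.DataFrame:
    """Candidate enhancer windows in gaps between genes (2 kb buffer)."""
    buffer, length, spacing = 2000, config.enhancer_length, 1000
    slots = []
    for chrom, size in genome.chrom_sizes.items():
        spans = sorted((g.start, g.end) for g in genome.genes if g.chrom == chrom)
        edges = [0] + [x for s, e in spans for x in (s, e)] + [size]
        for gs, ge in zip(edges[::2], edges[1::2]):
            s, e = gs + buffer, ge - buffer
            k = (e - s) // (length + spacing)
            for j in range(max(k, 0)):
                a = s + j * (length + spacing)
                slots.append((chrom, a, a + length))
    return pd.DataFrame(slots, columns=["chrom", "start", "end"])


def generate_truth(genome: Genome, config: SyntheticConfig) -> SyntheticTruth:
    """Draw the planted gene and enhancer parameters for one dataset.

    Gene 5hmC propensity and expression come from a bivariate normal
    copula with latent correlation r = 2*sin(pi*rho/6), which yields a
    population Spearman correlation of exactly ``rho_planted``.
    """
    rng = _stream(config, "truth")
    n = len(genome.genes)
    r = 2.0 * np.sin(np.pi * config.rho_planted / 6.0)
    cov = np.array([[1.0, r], [r, 1.0]])
    z = rng.multivariate_normal([0.0, 0.0], cov, size=n) if n else np.empty((0, 2))
    propensity = np.exp(config.propensity_sigma * z[:, 0] - config.propensity_sigma**2 / 2)
    expression = config.expression_scale * np.exp(config.expression_sigma * z[:, 1])
    genes = pd.DataFrame({
        "gene_id": [g.gene_id for g in genome.genes],
        "propensity": propensity,
        "expression": expression,
    })
    # per-cell-type programs: in non-reference cell types a gene-level shift d
    # moves 5hmC propensity and expression together, planting the coupling
    # between delta-5hmC and expression fold change that the dynamics
    # analysis recovers; the reference (first) cell type keeps the base values
    for i, ct in enumerate(config.cell_types):
        if i == 0 or config.dynamics_sigma == 0:
            genes[f"propensity_{ct}"] = propensity
            genes[f"expression_{ct}"] = expression
        else:
            d = rng.normal(0.0, config.dynamics_sigma, n)
            genes[f"propensity_{ct}"] = propensity * np.exp(d)
            genes[f"expression_{ct}"] = expression * np.exp(config.dynamics_expr_gain * d)

    slots = _intergenic_slots(genome, config)
    if config.n_enhancers > len(slots):
        raise ValueError(
            f"only {len(slots)} intergenic enhancer slots available for "
            f"{config.n_enhancers} requested: enlarge chromosomes or reduce n_genes"
        )
    pick = np.sort(rng.choice(len(slots), size=config.n_enhancers, replace=False))
    enh = slots.iloc[pick].reset_index(drop=True)
    n_pos = int(round(config.frac_positive_enhancers * config.n_enhancers))
    status = np.zeros(config.n_enhancers, dtype=bool)
    status[rng.permutation(config.n_enhancers)[:n_pos]] = True
    enh.insert(0, "enhancer_id", [f"e{i:05d}" for i in range(config.n_enhancers)])
    enh["hmc_positive"] = status
    enh["tf_factor"] = np.where(status, config.tf_effect, 1.0)

    # guarantee >=1 CCGG per enhancer (both groups alike, so content stays
    # balanced) before per-site factors are drawn
    _ensure_ccgg_in_enhancers(genome, enh)

    site_factor = np.exp(
        config.site_sigma * rng.standard_normal(len(genome.ccgg)) - config.site_sigma**2 / 2
    )
    return SyntheticTruth(genes=genes, enhancers=enh, site_factor=site_factor)


def _site_gene_map(genome: Genome) -> np.ndarray:
    """Index of the covering gene per CCGG site (-1 when intergenic)."""
    out = np.full(len(genome.ccgg), -1, dtype=int)
    for chrom in genome.chrom_sizes:
        mask = (genome.ccgg["chrom"] == chrom).to_numpy()
        if not mask.any():
            continue
        pos = genome.ccgg.loc[mask, "pos"].to_numpy()
        gl = [(g.start, g.end, i) for i, g in enumerate(genome.genes) if g.chrom == chrom]
        if not gl:
            continue
        starts = np.array([x[0] for x in gl])
        ends = np.array([x[1] for x in gl])
        idxs = np.array([x[2] for x in gl])
        j = np.searchsorted(starts, pos, side="right") - 1
        jc = np.clip(j, 0, len(starts) - 1)
        hit = (j >= 0) & (pos < ends[jc])
        res = np.where(hit, idxs[jc], -1)
        out[mask] = res
    return out


def _tss_shape(dist: np.ndarray) -> np.ndarray:
    """Planted promoter-proximal 5hmC shape: peaks near TSS+/-350 bp, dip at the TSS."""
    d = dist.astype(float)
    bump = 1.5 * np.exp(-(((np.abs(d) - 350.0) / 250.0) ** 2))
    dip = 0.7 * np.exp(-((d / 120.0) ** 2))
    return np.where(np.abs(d) <= 2000, 1.0 + bump - dip, 1.0)


def generate_rrhp(
    genome: Genome,
    truth: SyntheticTruth,
    config: SyntheticConfig,
    cell_type: str = "hESC",
    replicate: int = 1,
) -> SiteTable:
    """One RRHP library: negative-binomial counts per CCGG site.

    Site means are ``read_depth_mean * propensity`` inside gene bodies
    (modulated by the planted TSS-proximal shape), ``enhancer_depth``
    inside 5hmC-positive enhancers, and ``background_depth`` elsewhere;
    all share a fixed per-site lognormal factor so replicates correlate.
    Replicates share truth and differ only in count noise.
    """
    if len(truth.genes) != len(genome.genes):
        raise ValueError("truth does not match genome: gene tables differ in length")
    if len(truth.site_factor) != len(genome.ccgg):
        raise ValueError("truth does not match genome: site factors missing")

    scale = config.cell_type_scale.get(cell_type, 1.0)
    site_gene = _site_gene_map(genome)
    mu = np.full(len(genome.ccgg), float(config.background_depth))

    if len(genome.genes):
        col = f"propensity_{cell_type}"
        prop = truth.genes[col if col in truth.genes else "propensity"].to_numpy()
        genic = site_gene >= 0
        mu[genic] = config.read_depth_mean * scale * prop[site_gene[genic]]
        # TSS-proximal shape: flanking peaks with a dip right at the TSS,
        # planted on every site within +/-2 kb of a TSS (upstream included)
        pos_all = genome.ccgg["pos"].to_numpy()
        by_chrom = {c: np.flatnonzero((genome.ccgg["chrom"] == c).to_numpy())
                    for c in genome.chrom_sizes}
        for gi, g in enumerate(genome.genes):
            idx = by_chrom[g.chrom]
            p = pos_all[idx]  # sorted within each chromosome
            lo = np.searchsorted(p, g.tss - 2000)
            hi = np.searchsorted(p, g.tss + 2000)
            sel = idx[lo:hi]
            d = pos_all[sel] - g.tss
            mu[sel] = config.read_depth_mean * scale * prop[gi] * _tss_shape(d)

    for _, e in truth.enhancers[truth.enhancers["hmc_positive"]].iterrows():
        m = (
            (genome.ccgg["chrom"] == e["chrom"]).to_numpy()
            & (genome.ccgg["pos"].to_numpy() >= e["start"])
            & (genome.ccgg["pos"].to_numpy() < e["end"])
        )
        mu[m] = config.enhancer_depth * scale

    mu = mu * truth.site_factor
    rng = _stream(config, "rrhp", cell_type, replicate)
    alpha = config.read_depth_dispersion
    if alpha > 0:
        lam = rng.gamma(shape=1.0 / alpha, scale=np.maximum(mu, 0) * alpha)
    else:
        lam = np.maximum(mu, 0)
    counts = rng.poisson(lam)
    df = genome.ccgg.copy()
    df["count"] = counts
    return SiteTable(df, library_id=f"{cell_type}_rep{replicate}", cell_type=cell_type)


def generate_expression(truth: SyntheticTruth, config: SyntheticConfig,
                        cell_type: str = "CD34") -> pd.DataFrame:
    """FPKM table coupled to 5hmC propensity through the truth latents."""
    if truth.genes is None or len(truth.genes) == 0:
        return pd.DataFrame(columns=["gene_id", "fpkm"])
    col = f"expression_{cell_type}"
    vals = truth.genes[col if col in truth.genes else "expression"].to_numpy()
    return pd.DataFrame({"gene_id": truth.genes["gene_id"], "fpkm": vals})


def _ensure_ccgg_in_enhancers(genome: Genome, enhancers: pd.DataFrame) -> None:
    """Inject one CCGG at the centre of any enhancer lacking one.

    Applied to positive and negative enhancers alike, so CCGG content
    stays balanced between the groups.
    """
    add = []
    for _, e in enhancers.iterrows():
        pos = genome.ccgg_positions(e["chrom"])
        lo = np.searchsorted(pos, e["start"])
        hi = np.searchsorted(pos, e["end"])
        if hi == lo:
            add.append((e["chrom"], (e["start"] + e["end"]) // 2, "+"))
    if add:
        extra = pd.DataFrame(add, columns=["chrom", "pos", "strand"])
        genome.ccgg = (
            pd.concat([genome.ccgg, extra], ignore_index=True)
            .drop_duplicates(subset=["chrom", "pos", "strand"])
            .sort_values(["chrom", "pos"], kind="stable")
            .reset_index(drop=True)
        )


def generate_chip(
    genome: Genome,
    truth: SyntheticTruth,
    config: SyntheticConfig,
    noise_seed_offset: int = 0,
) -> tuple[dict[str, pd.DataFrame], SignalTrack]:
    """Histone peak sets and a TF coverage track over the enhancers.

    H3K27ac peaks sit on every enhancer (plus promoter peaks at the most
    expressed genes, to exercise TSS exclusion); a ``dual_mark_frac``
    share of enhancers is covered fully by H3K4me1, the rest only 10 %
    (below the 25 % dual-mark rule). TF occupancy is gamma noise around
    ``tf_base_occupancy`` times the enhancer's planted factor.
    ``noise_seed_offset`` redraws only the occupancy noise, for null
    calibration on a fixed genome.
    """
    rng = _stream(config, "chip", noise_seed_offset)
    enh = truth.enhancers

    k27 = enh[["chrom", "start", "end"]].copy()
    if len(genome.genes):
        expr = truth.genes["expression"].to_numpy()
        top = np.argsort(expr)[::-1][: max(len(expr) // 5, 1)]
        prom = pd.DataFrame({
            "chrom": [genome.genes[i].chrom for i in top],
            "start": [max(genome.genes[i].tss - 500, 0) for i in top],
            "end": [genome.genes[i].tss + 500 for i in top],
        })
        k27 = pd.concat([k27, prom], ignore_index=True)
    k27 = k27.sort_values(["chrom", "start"]).reset_index(drop=True)

    n_dual = int(round(config.dual_mark_frac * len(enh)))
    dual = np.zeros(len(enh), dtype=bool)
    dual[rng.permutation(len(enh))[:n_dual]] = True
    rows = []
    for i, (_, e) in enumerate(enh.iterrows()):
        width = e["end"] - e["start"]
        if dual[i]:
            rows.append((e["chrom"], e["start"], e["end"]))
        else:
            rows.append((e["chrom"], e["start"], e["start"] + width // 10))
    k4 = pd.DataFrame(rows, columns=["chrom", "start", "end"]).sort_values(
        ["chrom", "start"]).reset_index(drop=True)

    # TF coverage: 50-bp bins over each enhancer +/- 2 kb flank
    bin_bp, flank = 50, 2000
    frames = []
    for chrom in genome.chrom_sizes:
        sub = enh[enh["chrom"] == chrom]
        for _, e in sub.iterrows():
            lo = max(int(e["start"]) - flank, 0)
            hi = min(int(e["end"]) + flank, genome.chrom_sizes[chrom])
            edges = np.arange(lo, hi + bin_bp, bin_bp)
            starts, ends = edges[:-1], np.minimum(edges[1:], hi)
            centers = (starts + ends) / 2
            inside = (centers >= e["start"]) & (centers < e["end"])
            base = np.where(inside, config.tf_base_occupancy * e["tf_factor"],
                            0.2 * config.tf_base_occupancy)
            shape = config.tf_noise_shape
            vals = rng.gamma(shape, base / shape)
            frames.append(pd.DataFrame(
                {"chrom": chrom, "start": starts, "end": ends, "value": vals}))
    if frames:
        bg = pd.concat(frames, ignore_index=True)
        bg = bg.drop_duplicates(subset=["chrom", "start"]).sort_values(["chrom", "start"])
        tf = SignalTrack.from_dataframe(bg)
    else:
        tf = SignalTrack({})
    peaks = {"H3K27ac": k27, "H3K4me1": k4}
    return peaks, tf


def simulate(config: SyntheticConfig) -> dict:
    """Full dataset bundle: genome, truth, RRHP tables, expression, ChIP."""
    genome = generate_genome(config)
    truth = generate_truth(genome, config)
    rrhp = {}
    for ct in config.cell_types:
        n_rep = 2 if ct == config.cell_types[0] else 1
        for rep in range(1, n_rep + 1):
            rrhp[(ct, rep)] = generate_rrhp(genome, truth, config, ct, rep)
    expression = {ct: generate_expression(truth, config, ct) for ct in config.cell_types}
    peaks, tf = generate_chip(genome, truth, config)
    return {
        "config": config,
        "genome": genome,
        "truth": truth,
        "rrhp": rrhp,
        "expression": expression,
        "peaks": peaks,
        "tf_track": tf,
    }
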