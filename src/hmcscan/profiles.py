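"""Meta-profiles around genes and the pipeline's statistical tests.

5hmC enrichment in a window is the summed RRHP read count divided by
the number of CCGG sites in the window, i.e. reads normalised to the
genomic CCGG distribution; bins containing no CCGG site are flagged
missing rather than zero. Scaled-region matrices divide each region's
body into a fixed number of equal genomic spans with fixed-width flank
bins, the standard scale-regions behaviour of coverage-matrix tools.

Statistics: Spearman rank correlation with a seeded two-tailed
permutation test (exact enumeration for n <= 8), and the two-sample
Kolmogorov–Smirnov test with asymptotic p.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import SignalTrack, SiteTable, merge_intervals, points_in_intervals
from .rrhp_sites import PositiveSiteSet

__all__ = [
    "TssProfile",
    "ProfileMatrix",
    "SpearmanResult",
    "KSResult",
    "OverlapResult",
    "tss_profile",
    "scaled_region_matrix",
    "expression_tertiles",
    "spearman_perm",
    "ks_two_sample",
    "overlap_fraction",
]


@dataclass
class TssProfile:
    """Per-gene binned reads and CCGG counts around the TSS, strand-oriented."""

    gene_ids: list[str]
    bin_centers: np.ndarray     # bp relative to TSS, upstream negative
    reads: np.ndarray           # genes x bins summed read counts
    ccgg: np.ndarray            # genes x bins CCGG site counts

    def pooled_enrichment(self, row_mask=None) -> np.ndarray:
        """Summed reads over summed CCGG per bin; NaN where no CCGG."""
        reads, ccgg = self.reads, self.ccgg
        if row_mask is not None:
            reads, ccgg = reads[row_mask], ccgg[row_mask]
        tot_c = ccgg.sum(axis=0).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            out = reads.sum(axis=0) / tot_c
        return np.where(tot_c > 0, out, np.nan)

    def per_gene_enrichment(self, rel_lo: int, rel_hi: int) -> np.ndarray:
        """Per-gene reads/CCGG over a relative window [rel_lo, rel_hi)."""
        sel = (self.bin_centers >= rel_lo) & (self.bin_centers < rel_hi)
        c = self.ccgg[:, sel].sum(axis=1).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            out = self.reads[:, sel].sum(axis=1) / c
        return np.where(c > 0, out, np.nan)


@dataclass
class ProfileMatrix:
    """Regions x bins mean-signal matrix (flank | scaled body | flank)."""

    values: np.ndarray
    n_flank_bins: int
    n_body_bins: int
    region_index: pd.Index

    @property
    def n_bins(self) -> int:
        return self.values.shape[1]

    def region_means(self, body_only: bool = True) -> np.ndarray:
        if body_only and self.n_flank_bins:
            v = self.values[:, self.n_flank_bins:-self.n_flank_bins]
        else:
            v = self.values
        return np.nanmean(v, axis=1)


@dataclass(frozen=True)
class SpearmanResult:
    rho: float
    p: float
    n_perm: int
    seed: int
    exact: bool = False


@dataclass(frozen=True)
class KSResult:
    D: float
    p: float
    n1: int
    n2: int


@dataclass(frozen=True)
class OverlapResult:
    fraction_in_peaks: float
    background_fraction: float
    enrichment: float


def tss_profile(table: SiteTable, genes, window: int = 5000, bin_bp: int = 50) -> TssProfile:
    """Binned read and CCGG counts around each gene's TSS.

    Bins advance in the direction of transcription (upstream bins carry
    negative centers), so minus-strand genes are mirrored.
    """
    if window % bin_bp != 0:
        raise ValueError(f"window {window} is not a multiple of bin {bin_bp}")
    rel_edges = np.arange(-window, window + bin_bp, bin_bp)
    n_bins = len(rel_edges) - 1
    reads = np.zeros((len(genes), n_bins))
    ccgg = np.zeros((len(genes), n_bins), dtype=int)
    by_chrom = {}
    for gi, g in enumerate(genes):
        if g.chrom not in by_chrom:
            by_chrom[g.chrom] = table.chrom_arrays(g.chrom)
        pos, counts = by_chrom[g.chrom]
        ccum = np.concatenate([[0], np.cumsum(counts)])
        if g.strand == "+":
            edges = g.tss + rel_edges
        else:
            edges = g.tss + 1 - rel_edges[::-1]
        idx = np.searchsorted(pos, edges, side="left")
        r = ccum[idx[1:]] - ccum[idx[:-1]]
        c = np.diff(idx)
        if g.strand == "-":
            r, c = r[::-1], c[::-1]
        reads[gi] = r
        ccgg[gi] = c
    centers = (rel_edges[:-1] + rel_edges[1:]) / 2.0
    return TssProfile([g.gene_id for g in genes], centers, reads, ccgg)


def scaled_region_matrix(
    track: SignalTrack,
    regions: pd.DataFrame,
    flank_bp: int = 1000,
    n_body_bins: int = 50,
    flank_bin_bp: int = 50,
) -> ProfileMatrix:
    """Mean track signal in scaled-body plus fixed-flank bins per region.

    The body of each region is split into ``n_body_bins`` equal genomic
    spans (fractional-bp spans for regions shorter than the bin count,
    so short regions repeat bases rather than fail); flanks use
    ``flank_bin_bp`` fixed bins.
    """
    if flank_bp % flank_bin_bp != 0:
        raise ValueError("flank_bp must be a multiple of flank_bin_bp")
    if (regions["end"] <= regions["start"]).any():
        raise ValueError("degenerate region (end <= start)")
    n_flank = flank_bp // flank_bin_bp
    total = 2 * n_flank + n_body_bins
    values = np.empty((len(regions), total))
    for i, (_, r) in enumerate(regions.iterrows()):
        s, e = float(r["start"]), float(r["end"])
        up = s - flank_bp + flank_bin_bp * np.arange(n_flank + 1)
        body = np.linspace(s, e, n_body_bins + 1)
        down = e + flank_bin_bp * np.arange(n_flank + 1)
        edges = np.concatenate([up[:-1], body, down[1:]])
        values[i] = track.mean_over(str(r["chrom"]), edges[:-1], edges[1:])
    return ProfileMatrix(values, n_flank, n_body_bins, regions.index)


def expression_tertiles(expr: pd.DataFrame) -> pd.Series:
    """Split genes into low/intermediate/high FPKM tertiles.

    Ranking is by (FPKM, gene_id) so ties resolve deterministically;
    remainder genes go to the lower tertiles.
    """
    if len(expr) < 3:
        raise ValueError("need at least 3 genes to form tertiles")
    ordered = expr.sort_values(["fpkm", "gene_id"], kind="stable")["gene_id"].to_numpy()
    groups = np.array_split(ordered, 3)
    out = {}
    for label, ids in zip(["low", "intermediate", "high"], groups):
        for g in ids:
            out[g] = label
    return pd.Series(out, name="tertile").reindex(expr["gene_id"].to_numpy())


def _rank_corr_against(rx: np.ndarray, ry_rows: np.ndarray) -> np.ndarray:
    rxc = rx - rx.mean()
    ryc = ry_rows - ry_rows.mean(axis=1, keepdims=True)
    denom = np.sqrt((rxc**2).sum() * (ryc**2).sum(axis=1))
    return (ryc @ rxc) / denom


def spearman_perm(x, y, n_perm: int = 10_000, seed: int = 0) -> SpearmanResult:
    """Spearman rho with a two-tailed permutation p-value.

    For n <= 8 the full n! permutation null is enumerated and
    p = #{|rho*| >= |rho|} / n!; otherwise ``n_perm`` seeded Monte-Carlo
    permutations with the +1 correction p = (1+hits)/(n_perm+1).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("x and y must have equal length")
    n = len(x)
    if n < 3:
        raise ValueError("need n >= 3")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("constant vector: Spearman correlation undefined")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rho = float(_rank_corr_against(rx, ry[None, :])[0])
    tol = 1e-12
    if n <= 8:
        perms = np.array(list(itertools.permutations(range(n))))
        rhos = _rank_corr_against(rx, ry[perms])
        hits = int(np.sum(np.abs(rhos) >= abs(rho) - tol))
        return SpearmanResult(rho, hits / math.factorial(n), len(perms), seed, exact=True)
    rng = np.random.default_rng(seed)
    hits = 0
    chunk = max(1, min(n_perm, 4_000_000 // max(n, 1)))
    done = 0
    while done < n_perm:
        k = min(chunk, n_perm - done)
        ry_rows = rng.permuted(np.tile(ry, (k, 1)), axis=1)
        rhos = _rank_corr_against(rx, ry_rows)
        hits += int(np.sum(np.abs(rhos) >= abs(rho) - tol))
        done += k
    return SpearmanResult(rho, (1 + hits) / (n_perm + 1), n_perm, seed, exact=False)


def ks_two_sample(a, b) -> KSResult:
    """Two-sample Kolmogorov–Smirnov: sup ECDF distance and asymptotic p."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    a = a[~np.isnan(a)]
    b = b[~np.isnan(b)]
    if len(a) == 0 or len(b) == 0:
        raise ValueError("KS test needs two non-empty samples")
    res = stats.ks_2samp(a, b, method="asymp")
    return KSResult(float(res.statistic), float(res.pvalue), len(a), len(b))


def overlap_fraction(sites: PositiveSiteSet, peaks: pd.DataFrame,
                     background: SiteTable) -> OverlapResult:
    """Fraction of 5hmC sites inside peaks, vs unmodified-CCGG background.

    ``background`` is the full CCGG catalogue (a superset of the called
    sites); the enrichment is the positive-site in-peak fraction over
    the same fraction among CCGG sites not called positive.
    """
    if len(background) == 0:
        raise ValueError("empty CCGG background")
    key = ["chrom", "pos", "strand"]
    pos_keys = set(map(tuple, sites.sites[key].itertuples(index=False)))
    bg = background.data
    unmod = bg[~bg[key].apply(tuple, axis=1).isin(pos_keys)]

    def _frac(df: pd.DataFrame) -> float:
        if len(df) == 0:
            return float("nan")
        inside = 0
        for chrom, sub in df.groupby("chrom", sort=False):
            p = peaks[peaks["chrom"] == chrom]
            ms, me = merge_intervals(p["start"].to_numpy(), p["end"].to_numpy())
            inside += int(points_in_intervals(sub["pos"].to_numpy(), ms, me).sum())
        return inside / len(df)

    f_pos = _frac(sites.sites)
    f_un = _frac(unmod)
    enrich = f_pos / f_un if (f_un and not np.isnan(f_un)) else float("nan")
    return OverlapResult(f_pos, f_un, enrich)
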