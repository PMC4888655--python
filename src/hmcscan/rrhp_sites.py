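"""RRHP site calling and gene-body 5hmC quantification.

RRHP read counts at MspI CCGG sites are proportional to the site's
hydroxymethylation level. A site is called 5hmC-positive when its read
count strictly exceeds a cutoff derived from the reference cell type
with the highest global 5hmC (mean count + SEM over all its CCGG
sites). Gene-body 5hmC is the summed read count at a gene's CCGG sites
divided by the number of CCGG sites in the gene body (TSS-to-TTS span,
introns included, by default).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import GeneModel, SiteTable

__all__ = [
    "CutoffResult",
    "PositiveSiteSet",
    "GeneBodyLevel",
    "derive_cutoff",
    "call_sites",
    "gene_body_level",
    "gene_body_levels",
    "replicate_correlation",
]


@dataclass(frozen=True)
class CutoffResult:
    mean: float
    sem: float
    cutoff: float
    n_sites: int
    reference_cell_type: str

    def __post_init__(self):
        if self.sem < 0:
            raise ValueError("SEM cannot be negative")


@dataclass
class PositiveSiteSet:
    """Sites whose read count strictly exceeds the calling cutoff."""

    sites: pd.DataFrame  # chrom, pos, strand, count
    cutoff: float

    def __len__(self) -> int:
        return len(self.sites)

    def positions(self, chrom: str) -> np.ndarray:
        sub = self.sites[self.sites["chrom"] == chrom]
        return np.sort(sub["pos"].to_numpy())

    def as_bed(self) -> pd.DataFrame:
        """BED6 with the read count in the score column."""
        s = self.sites
        return pd.DataFrame({
            "chrom": s["chrom"], "start": s["pos"], "end": s["pos"] + 1,
            "name": "5hmC", "score": s["count"], "strand": s["strand"],
        })


@dataclass(frozen=True)
class GeneBodyLevel:
    gene_id: str
    total_reads: int
    n_ccgg: int
    level: float  # NaN when n_ccgg == 0


def derive_cutoff(table: SiteTable, pooled_tables: list[SiteTable] | None = None) -> CutoffResult:
    """Calling threshold: mean read count + SEM over all CCGG sites.

    ``pooled_tables`` lets the reference counts come from pooled
    replicates of the reference cell type. SEM uses the sample standard
    deviation (n-1 denominator). Zero-count sites are included.
    """
    tables = [table] + list(pooled_tables or [])
    counts = np.concatenate([t.counts for t in tables])
    n = len(counts)
    if n == 0:
        raise ValueError("cannot derive a cutoff from an empty site table")
    if n == 1:
        raise ValueError("SEM undefined for a single CCGG site")
    mean = float(np.mean(counts))
    sem = float(np.std(counts, ddof=1) / np.sqrt(n))
    return CutoffResult(mean=mean, sem=sem, cutoff=mean + sem, n_sites=n,
                        reference_cell_type=table.cell_type)


def call_sites(table: SiteTable, cutoff: float) -> PositiveSiteSet:
    """Sites with count strictly greater than ``cutoff``."""
    if cutoff < 0:
        raise ValueError("cutoff must be nonnegative")
    pos = table.data[table.data["count"] > cutoff].reset_index(drop=True)
    return PositiveSiteSet(sites=pos, cutoff=float(cutoff))


def _body_span(gene: GeneModel, exon_only: bool) -> list[tuple[int, int]]:
    if exon_only:
        return gene.exons if gene.exons else [(gene.start, gene.end)]
    return [(gene.start, gene.end)]


def gene_body_level(gene: GeneModel, table: SiteTable, exon_only: bool = False) -> GeneBodyLevel:
    """Summed reads at the gene's CCGG sites over the number of such sites.

    All CCGG sites in the span count, called positive or not. A gene
    with no CCGG site gets a NaN level (flagged missing, never zero).
    """
    pos, counts = table.chrom_arrays(gene.chrom)
    total = 0
    n_ccgg = 0
    for s, e in _body_span(gene, exon_only):
        lo = np.searchsorted(pos, s, side="left")
        hi = np.searchsorted(pos, e, side="left")
        n_ccgg += hi - lo
        total += int(counts[lo:hi].sum())
    level = total / n_ccgg if n_ccgg > 0 else float("nan")
    return GeneBodyLevel(gene.gene_id, total, int(n_ccgg), level)


def gene_body_levels(genes: list[GeneModel], table: SiteTable, exon_only: bool = False) -> pd.DataFrame:
    """Vectorised :func:`gene_body_level` over a gene list."""
    recs = [gene_body_level(g, table, exon_only) for g in genes]
    return pd.DataFrame({
        "gene_id": [r.gene_id for r in recs],
        "total_reads": [r.total_reads for r in recs],
        "n_ccgg": [r.n_ccgg for r in recs],
        "level": [r.level for r in recs],
    })


def replicate_correlation(a: SiteTable, b: SiteTable) -> float:
    """Pearson r between two libraries over the union of their sites.

    Sites absent from one library contribute a zero count there.
    """
    if len(a) == 0 or len(b) == 0:
        raise ValueError("replicate correlation needs two non-empty site tables")
    key = ["chrom", "pos", "strand"]
    merged = a.data.merge(b.data, on=key, how="outer", suffixes=("_a", "_b")).fillna(0)
    x = merged["count_a"].to_numpy(dtype=float)
    y = merged["count_b"].to_numpy(dtype=float)
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero count variance in a library; Pearson r undefined")
    return float(stats.pearsonr(x, y).statistic)
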