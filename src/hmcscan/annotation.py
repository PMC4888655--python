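"""Genomic element partition and per-element 5hmC density.

The genome is decomposed into disjoint labeled elements — promoter
(strand-aware TSS-1 kb .. TSS+100 bp), transcription-termination region
(TTS-100 bp .. TTS+1 kb), 5'/3' UTR, exon, intron and intergenic — so
that every base carries exactly one label. When a base is claimed by
several features the precedence promoter > TTS_region > 5'UTR > 3'UTR >
exon > intron > intergenic applies (the explicitly defined promoter/TTS
windows win over the generic gene structure).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import GeneModel
from .rrhp_sites import PositiveSiteSet

__all__ = ["LABELS", "ElementMap", "build_element_map", "element_proportions", "relative_density"]

# painting order = reversed precedence; the last painted label wins
LABELS = ["promoter", "TTS_region", "utr5", "utr3", "exon", "intron", "intergenic"]
_PRECEDENCE = ["intron", "exon", "utr3", "utr5", "TTS_region", "promoter"]


@dataclass
class ElementMap:
    """Disjoint labeled partition of the genome, per chromosome.

    Stored as elementary segments: ``breaks`` (len k+1) and integer
    ``labels`` (len k) indexing into :data:`LABELS`.
    """

    chroms: dict[str, tuple[np.ndarray, np.ndarray]]

    def label_lengths(self) -> pd.Series:
        totals = pd.Series(0, index=LABELS, dtype=np.int64)
        for breaks, labels in self.chroms.values():
            widths = np.diff(breaks)
            for code in np.unique(labels):
                totals.iloc[code] += int(widths[labels == code].sum())
        return totals

    def assign(self, chrom: str, pos: np.ndarray) -> np.ndarray:
        """Label name per position; raises on unknown chromosome."""
        if chrom not in self.chroms:
            raise KeyError(f"chromosome {chrom!r} not covered by the element map")
        breaks, labels = self.chroms[chrom]
        pos = np.asarray(pos)
        if len(pos) and (pos.min() < breaks[0] or pos.max() >= breaks[-1]):
            raise ValueError(f"position outside {chrom} bounds")
        idx = np.searchsorted(breaks, pos, side="right") - 1
        return np.asarray(LABELS, dtype=object)[labels[idx]]

    def to_bed(self) -> pd.DataFrame:
        rows = []
        for chrom in sorted(self.chroms):
            breaks, labels = self.chroms[chrom]
            for s, e, c in zip(breaks[:-1], breaks[1:], labels):
                rows.append((chrom, int(s), int(e), LABELS[c]))
        return pd.DataFrame(rows, columns=["chrom", "start", "end", "label"])


def _gene_intervals(gene: GeneModel) -> dict[str, list[tuple[int, int]]]:
    t = gene.tss
    if gene.strand == "+":
        promoter = (t - 1000, t + 100)
        tts_region = (gene.tts - 100, gene.tts + 1000)
    else:
        promoter = (t - 100, t + 1000)
        tts_region = (gene.tts - 1000, gene.tts + 100)
    exons = gene.exons if gene.exons else [(gene.start, gene.end)]
    introns = [(e0, s1) for (_, e0), (s1, _) in zip(exons, exons[1:]) if s1 > e0]
    return {
        "promoter": [promoter],
        "TTS_region": [tts_region],
        "utr5": list(gene.utr5),
        "utr3": list(gene.utr3),
        "exon": list(exons),
        "intron": introns,
    }


def build_element_map(genes: list[GeneModel], chrom_sizes: dict[str, int]) -> ElementMap:
    """Partition every chromosome into labeled elements with precedence."""
    per_label: dict[str, dict[str, list]] = {lab: {} for lab in _PRECEDENCE}
    for g in genes:
        if g.chrom not in chrom_sizes:
            raise ValueError(f"gene {g.gene_id} on unknown chromosome {g.chrom}")
        size = chrom_sizes[g.chrom]
        if g.start < 0 or g.end > size:
            raise ValueError(f"gene {g.gene_id} out of bounds for {g.chrom} ({size} bp)")
        for lab, ivs in _gene_intervals(g).items():
            clipped = [(max(s, 0), min(e, size)) for s, e in ivs]
            per_label[lab].setdefault(g.chrom, []).extend(
                (s, e) for s, e in clipped if e > s)

    chrom_maps = {}
    inter_code = LABELS.index("intergenic")
    for chrom, size in chrom_sizes.items():
        bounds = {0, size}
        for lab in _PRECEDENCE:
            for s, e in per_label[lab].get(chrom, []):
                bounds.update((s, e))
        breaks = np.array(sorted(bounds))
        labels = np.full(len(breaks) - 1, inter_code, dtype=np.int8)
        for lab in _PRECEDENCE:  # low precedence first; later paint overwrites
            code = LABELS.index(lab)
            for s, e in per_label[lab].get(chrom, []):
                lo = np.searchsorted(breaks, s, side="left")
                hi = np.searchsorted(breaks, e, side="left")
                labels[lo:hi] = code
        chrom_maps[chrom] = (breaks, labels)
    return ElementMap(chroms=chrom_maps)


def _site_labels(sites: PositiveSiteSet, emap: ElementMap) -> pd.Series:
    parts = []
    for chrom, sub in sites.sites.groupby("chrom", sort=True):
        parts.append(pd.Series(emap.assign(str(chrom), sub["pos"].to_numpy())))
    if not parts:
        raise ValueError("no sites to assign")
    return pd.concat(parts, ignore_index=True)


def element_proportions(sites: PositiveSiteSet, emap: ElementMap) -> pd.Series:
    """Fraction of 5hmC-positive sites per element class (sums to 1)."""
    labels = _site_labels(sites, emap)
    frac = labels.value_counts(normalize=True)
    return frac.reindex(LABELS, fill_value=0.0)


def relative_density(sites: PositiveSiteSet, emap: ElementMap) -> pd.DataFrame:
    """Site density normalised to 1e5 bp of element and 1e5 total sites.

    density = n_e * (1e5 / N_total) / (L_e / 1e5); zero-length elements
    get a NaN density.
    """
    labels = _site_labels(sites, emap)
    n_e = labels.value_counts().reindex(LABELS, fill_value=0)
    lengths = emap.label_lengths()
    n_total = int(n_e.sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        dens = n_e * (1e5 / n_total) / (lengths / 1e5)
    dens = dens.where(lengths > 0)
    return pd.DataFrame({
        "label": LABELS,
        "n_sites": n_e.to_numpy(),
        "length_bp": lengths.to_numpy(),
        "relative_density": dens.to_numpy(dtype=float),
    })
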