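"""Enhancer classification and 5hmC-dependent TF occupancy comparison.

Active enhancers are H3K27ac peaks; putative poised enhancers are
H3K4me1 peaks; dual active enhancers are H3K27ac peaks whose bases are
covered at least 25 % by the union of H3K4me1 peaks and that do not
overlap any TSS +/- 1 kb window. Regulatory regions are then split by
5hmC status (at least one called 5hmC-positive cytosine inside) and
transcription-factor occupancy compared between the groups: scaled
mean-occupancy profiles plus a two-sample KS test on per-region mean
occupancy, flagged significant at the D > 0.45, p < 1e-10 convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import SignalTrack, SiteTable, merge_intervals, covered_length
from .profiles import KSResult, ks_two_sample, scaled_region_matrix
from .rrhp_sites import PositiveSiteSet

__all__ = [
    "EnhancerClasses",
    "SplitRegions",
    "OccupancyComparison",
    "classify_enhancers",
    "split_by_5hmc",
    "split_by_5hmc_ccgg_control",
    "compare_tf_occupancy",
    "KS_D_CONVENTION",
    "KS_P_CONVENTION",
]

KS_D_CONVENTION = 0.45
KS_P_CONVENTION = 1e-10


@dataclass
class EnhancerClasses:
    poised: pd.DataFrame           # H3K4me1 peaks
    active_h3k27ac: pd.DataFrame   # all H3K27ac peaks
    active_dual: pd.DataFrame      # dual-marked, TSS-free H3K27ac peaks
    coverage_frac: float
    tss_excl: int


@dataclass
class SplitRegions:
    positive: pd.DataFrame
    negative: pd.DataFrame
    ccgg_matched: bool = False
    n_excluded: int = 0  # regions with no CCGG, in matched mode


@dataclass
class OccupancyComparison:
    profile_positive: np.ndarray | None
    profile_negative: np.ndarray | None
    ks: KSResult | None
    n_positive: int
    n_negative: int
    significant: bool | None
    status: str = "ok"
    means_positive: np.ndarray = field(default=None, repr=False)
    means_negative: np.ndarray = field(default=None, repr=False)


def _check_sorted(df: pd.DataFrame, name: str) -> None:
    for chrom, sub in df.groupby("chrom", sort=False):
        if not sub["start"].is_monotonic_increasing:
            raise ValueError(f"{name} peaks not sorted by start on {chrom}")


def classify_enhancers(
    h3k27ac: pd.DataFrame,
    h3k4me1: pd.DataFrame,
    tss_list: pd.DataFrame,
    coverage_frac: float = 0.25,
    tss_excl: int = 1000,
) -> EnhancerClasses:
    """Label peaks as poised / active / dual-active enhancers.

    ``tss_list`` needs columns chrom, tss. Dual requires merged-H3K4me1
    coverage >= ``coverage_frac`` of the H3K27ac peak (inclusive at the
    boundary) and no overlap with any half-open [tss - tss_excl,
    tss + tss_excl) window.
    """
    _check_sorted(h3k27ac, "H3K27ac")
    _check_sorted(h3k4me1, "H3K4me1")
    me1 = {chrom: merge_intervals(sub["start"].to_numpy(), sub["end"].to_numpy())
           for chrom, sub in h3k4me1.groupby("chrom", sort=False)}
    tss_win = {}
    for chrom, sub in tss_list.groupby("chrom", sort=False):
        t = sub["tss"].to_numpy()
        tss_win[chrom] = merge_intervals(t - tss_excl, t + tss_excl)

    keep = []
    eps = 1e-9
    for _, r in h3k27ac.iterrows():
        chrom, s, e = r["chrom"], int(r["start"]), int(r["end"])
        ms, me = me1.get(chrom, (np.array([]), np.array([])))
        cov = covered_length(s, e, ms, me) / (e - s)
        if cov + eps < coverage_frac:
            keep.append(False)
            continue
        ws, we = tss_win.get(chrom, (np.array([]), np.array([])))
        keep.append(covered_length(s, e, ws, we) == 0)
    dual = h3k27ac[np.asarray(keep, dtype=bool)].reset_index(drop=True) if len(h3k27ac) else h3k27ac
    return EnhancerClasses(
        poised=h3k4me1.reset_index(drop=True),
        active_h3k27ac=h3k27ac.reset_index(drop=True),
        active_dual=dual,
        coverage_frac=coverage_frac,
        tss_excl=tss_excl,
    )


def _n_sites_in_regions(regions: pd.DataFrame, positions: dict[str, np.ndarray]) -> np.ndarray:
    out = np.zeros(len(regions), dtype=int)
    for i, (_, r) in enumerate(regions.iterrows()):
        pos = positions.get(r["chrom"])
        if pos is None:
            continue
        out[i] = np.searchsorted(pos, r["end"]) - np.searchsorted(pos, r["start"])
    return out


def split_by_5hmc(regions: pd.DataFrame, positive_sites: PositiveSiteSet) -> SplitRegions:
    """Partition regions into 5hmC-positive (>= 1 called site inside) vs negative."""
    pos = {c: positive_sites.positions(c) for c in positive_sites.sites["chrom"].unique()}
    n = _n_sites_in_regions(regions, pos)
    has = n > 0
    return SplitRegions(
        positive=regions[has].reset_index(drop=True),
        negative=regions[~has].reset_index(drop=True),
    )


def split_by_5hmc_ccgg_control(
    regions: pd.DataFrame,
    all_ccgg: SiteTable,
    positive_sites: PositiveSiteSet,
) -> SplitRegions:
    """CCGG-matched split: the negative group must itself contain CCGG.

    Positive = regions with >= 1 called 5hmC site; negative = regions
    with >= 1 CCGG site but no called site; CCGG-free regions drop out,
    so both groups are comparable in MspI-site content.
    """
    pos = {c: positive_sites.positions(c) for c in positive_sites.sites["chrom"].unique()}
    allp = {str(c): np.sort(sub["pos"].to_numpy())
            for c, sub in all_ccgg.data.groupby("chrom", sort=False)}
    n_pos = _n_sites_in_regions(regions, pos)
    n_all = _n_sites_in_regions(regions, allp)
    has_pos = n_pos > 0
    has_ccgg = n_all > 0
    return SplitRegions(
        positive=regions[has_pos].reset_index(drop=True),
        negative=regions[has_ccgg & ~has_pos].reset_index(drop=True),
        ccgg_matched=True,
        n_excluded=int((~has_ccgg).sum()),
    )


def compare_tf_occupancy(
    tf: SignalTrack,
    split: SplitRegions,
    flank_bp: int = 1000,
    n_body_bins: int = 50,
    flank_bin_bp: int = 50,
) -> OccupancyComparison:
    """Scaled occupancy profiles per group + KS on per-region mean occupancy.

    Significance is flagged at the study's convention D > 0.45 and
    p < 1e-10. An empty group skips the comparison with an explicit
    status instead of failing.
    """
    n_p, n_n = len(split.positive), len(split.negative)
    if n_p == 0 or n_n == 0:
        return OccupancyComparison(None, None, None, n_p, n_n, None,
                                   status="skipped: empty group")
    mp = scaled_region_matrix(tf, split.positive, flank_bp, n_body_bins, flank_bin_bp)
    mn = scaled_region_matrix(tf, split.negative, flank_bp, n_body_bins, flank_bin_bp)
    means_p = mp.region_means(body_only=True)
    means_n = mn.region_means(body_only=True)
    ks = ks_two_sample(means_p, means_n)
    sig = bool(ks.D > KS_D_CONVENTION and ks.p < KS_P_CONVENTION)
    return OccupancyComparison(
        profile_positive=np.nanmean(mp.values, axis=0),
        profile_negative=np.nanmean(mn.values, axis=0),
        ks=ks, n_positive=n_p, n_negative=n_n, significant=sig,
        means_positive=means_p, means_negative=means_n,
    )
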