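"""Shared genomic containers and interval primitives.

Coordinates are 0-based half-open everywhere inside the package; 1-based
formats (GTF) are converted on ingest and egress by :mod:`hmcscan.io`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

SITE_COLUMNS = ["chrom", "pos", "strand", "count"]


@dataclass
class GeneModel:
    """Strand-aware gene with a single canonical transcript.

    ``start``/``end`` delimit the genomic span (half-open); ``tss``/``tts``
    are single-base coordinates oriented by ``strand`` (for a minus-strand
    gene the TSS is the last spanned base).
    """

    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int
    exons: list[tuple[int, int]] = field(default_factory=list)
    utr5: list[tuple[int, int]] = field(default_factory=list)
    utr3: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r} for {self.gene_id}")
        if self.end <= self.start:
            raise ValueError(f"empty span for {self.gene_id}")
        self.exons = sorted(tuple(e) for e in self.exons)
        for (s0, e0), (s1, _) in zip(self.exons, self.exons[1:]):
            if s1 < e0:
                raise ValueError(f"overlapping exons in {self.gene_id}")

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end - 1

    @property
    def tts(self) -> int:
        return self.end - 1 if self.strand == "+" else self.start

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class Genome:
    """A gene annotation plus CCGG catalogue over named chromosomes."""

    chrom_sizes: dict[str, int]
    genes: list[GeneModel]
    ccgg: pd.DataFrame  # columns chrom, pos, strand

    def ccgg_positions(self, chrom: str) -> np.ndarray:
        sub = self.ccgg[self.ccgg["chrom"] == chrom]
        return np.sort(sub["pos"].to_numpy())


@dataclass
class SiteTable:
    """Per-CCGG-site read counts for one RRHP library."""

    data: pd.DataFrame  # columns chrom, pos, strand, count
    library_id: str = "lib"
    cell_type: str = "unknown"

    def __post_init__(self) -> None:
        missing = [c for c in SITE_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"site table missing columns {missing}")
        if (self.data["count"] < 0).any():
            raise ValueError("negative read counts")
        dup = self.data.duplicated(subset=["chrom", "pos", "strand"])
        if dup.any():
            raise ValueError("duplicate (chrom, pos, strand) records")
        self.data = (
            self.data[SITE_COLUMNS]
            .sort_values(["chrom", "pos"], kind="stable")
            .reset_index(drop=True)
        )

    def __len__(self) -> int:
        return len(self.data)

    @property
    def counts(self) -> np.ndarray:
        return self.data["count"].to_numpy()

    def chrom_arrays(self, chrom: str) -> tuple[np.ndarray, np.ndarray]:
        """Sorted positions and matching counts for one chromosome."""
        sub = self.data[self.data["chrom"] == chrom]
        return sub["pos"].to_numpy(), sub["count"].to_numpy()


class SignalTrack:
    """Piecewise-constant coverage over chromosomes (bedGraph semantics).

    Intervals must be sorted and non-overlapping per chromosome; gaps read
    as zero. Means over arbitrary spans are computed from a cumulative
    integral, so querying many windows is O(log n) each.
    """

    def __init__(self, per_chrom: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]]):
        self._data = {}
        for chrom, (starts, ends, values) in per_chrom.items():
            starts = np.asarray(starts, dtype=float)
            ends = np.asarray(ends, dtype=float)
            values = np.asarray(values, dtype=float)
            if np.any(ends <= starts):
                raise ValueError(f"degenerate interval on {chrom}")
            if np.any(np.diff(starts) < 0) or np.any(starts[1:] < ends[:-1]):
                raise ValueError(f"intervals on {chrom} not sorted/disjoint")
            cum = np.concatenate([[0.0], np.cumsum((ends - starts) * values)])
            self._data[chrom] = (starts, ends, values, cum)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "SignalTrack":
        per = {}
        for chrom, sub in df.groupby("chrom", sort=True):
            sub = sub.sort_values("start")
            per[chrom] = (
                sub["start"].to_numpy(),
                sub["end"].to_numpy(),
                sub["value"].to_numpy(),
            )
        return cls(per)

    def chroms(self) -> list[str]:
        return list(self._data)

    def _integral_at(self, chrom: str, x: np.ndarray) -> np.ndarray:
        """Integral of the track from -inf to each x."""
        starts, ends, values, cum = self._data[chrom]
        x = np.asarray(x, dtype=float)
        idx = np.searchsorted(starts, x, side="right") - 1
        idx_c = np.clip(idx, 0, len(starts) - 1)
        inside = np.clip(x - starts[idx_c], 0.0, ends[idx_c] - starts[idx_c])
        out = cum[idx_c] + inside * values[idx_c]
        return np.where(idx < 0, 0.0, out)

    def mean_over(self, chrom: str, starts, ends) -> np.ndarray:
        """Mean signal over half-open windows; zero off-track, NaN if empty."""
        starts = np.asarray(starts, dtype=float)
        ends = np.asarray(ends, dtype=float)
        if chrom not in self._data:
            return np.zeros(len(starts))
        width = ends - starts
        with np.errstate(invalid="ignore", divide="ignore"):
            out = (self._integral_at(chrom, ends) - self._integral_at(chrom, starts)) / width
        return np.where(width > 0, out, np.nan)


def merge_intervals(starts, ends) -> tuple[np.ndarray, np.ndarray]:
    """Union of intervals as sorted disjoint arrays."""
    starts = np.asarray(starts)
    ends = np.asarray(ends)
    if len(starts) == 0:
        return starts, ends
    order = np.argsort(starts, kind="stable")
    starts, ends = starts[order], ends[order]
    out_s, out_e = [starts[0]], [ends[0]]
    for s, e in zip(starts[1:], ends[1:]):
        if s <= out_e[-1]:
            out_e[-1] = max(out_e[-1], e)
        else:
            out_s.append(s)
            out_e.append(e)
    return np.asarray(out_s), np.asarray(out_e)


def covered_length(q_start: int, q_end: int, starts: np.ndarray, ends: np.ndarray) -> int:
    """Bases of [q_start, q_end) covered by a merged (disjoint, sorted) set."""
    if len(starts) == 0 or q_end <= q_start:
        return 0
    lo = np.searchsorted(ends, q_start, side="right")
    hi = np.searchsorted(starts, q_end, side="left")
    if hi <= lo:
        return 0
    s = np.maximum(starts[lo:hi], q_start)
    e = np.minimum(ends[lo:hi], q_end)
    return int(np.sum(np.maximum(e - s, 0)))


def points_in_intervals(pos: np.ndarray, starts: np.ndarray, ends: np.ndarray) -> np.ndarray:
    """Boolean mask: which points fall in a merged half-open interval set."""
    pos = np.asarray(pos)
    if len(starts) == 0:
        return np.zeros(len(pos), dtype=bool)
    idx = np.searchsorted(starts, pos, side="right") - 1
    idx_c = np.clip(idx, 0, len(starts) - 1)
    return (idx >= 0) & (pos < ends[idx_c])
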