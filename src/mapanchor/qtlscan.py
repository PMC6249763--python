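"""Bulked-segregant |d(SNP-index)| sliding-window scan.

Per SNP, the SNP-index of a pool is alt depth / total depth; the scan
statistic is the absolute between-pool difference |d(SNP-index)|, averaged
in 1-Mb windows advanced in 20-kb steps.  Windows whose mean reaches the
genome-wide top-fraction quantile (default top 0.5%) are merged into
candidate intervals, which can be projected through an AGP onto the scaffold
pieces they contain.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import AgpRow, PoolDepthTable

DEFAULT_WINDOW = 1_000_000
DEFAULT_STEP = 20_000
DEFAULT_TOP_FRACTION = 0.005


def snp_index(ref_d, alt_d):
    """alt / (alt + ref); NaN where total depth is zero (row excluded later)."""
    ref_d = np.asarray(ref_d, dtype=float)
    alt_d = np.asarray(alt_d, dtype=float)
    total = ref_d + alt_d
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(total > 0, alt_d / np.where(total > 0, total, 1), np.nan)
    return out if out.shape else float(out)


def abs_delta(table: PoolDepthTable) -> pd.DataFrame:
    """Per-SNP |d(SNP-index)|; rows where either pool has zero depth are
    dropped."""
    df = table.frame.copy()
    idx1 = snp_index(df["ref1"], df["alt1"])
    idx2 = snp_index(df["ref2"], df["alt2"])
    df["index1"] = idx1
    df["index2"] = idx2
    df["delta"] = idx1 - idx2
    df["abs_delta"] = np.abs(df["delta"])
    return df.dropna(subset=["abs_delta"]).reset_index(drop=True)


def sliding_windows(chrom_len: int, window: int = DEFAULT_WINDOW,
                    step: int = DEFAULT_STEP) -> list[tuple[int, int]]:
    """1-based inclusive windows anchored at position 1; the tail windows are
    truncated at chrom_len and windows starting beyond it are excluded."""
    if chrom_len < 1:
        raise ValueError("chrom_len must be >= 1")
    if not (window >= step > 0):
        raise ValueError("need window >= step > 0")
    out = []
    start = 1
    while start <= chrom_len:
        out.append((start, min(start + window - 1, chrom_len)))
        start += step
    return out


@dataclass
class WindowStat:
    chrom: str
    start: int
    end: int
    n_snps: int
    mean_abs_delta: float  # NaN when the window holds no SNP


def window_scan(
    table: PoolDepthTable,
    chrom_lengths: dict[str, int],
    window: int = DEFAULT_WINDOW,
    step: int = DEFAULT_STEP,
) -> list[WindowStat]:
    """Mean per-SNP |d(SNP-index)| within each sliding window of every
    chromosome."""
    per_snp = abs_delta(table)
    stats: list[WindowStat] = []
    for chrom, length in chrom_lengths.items():
        sub = per_snp[per_snp["chrom"] == chrom]
        pos = sub["pos"].to_numpy()
        val = sub["abs_delta"].to_numpy()
        for start, end in sliding_windows(length, window, step):
            lo = np.searchsorted(pos, start, side="left")
            hi = np.searchsorted(pos, end, side="right")
            n = hi - lo
            mean = float(val[lo:hi].mean()) if n else float("nan")
            stats.append(WindowStat(chrom, start, end, int(n), mean))
    return stats


def threshold_top(stats: list[WindowStat],
                  fraction: float = DEFAULT_TOP_FRACTION) -> float:
    """(1 - fraction) quantile of the non-missing window means genome-wide."""
    means = np.array([w.mean_abs_delta for w in stats])
    means = means[~np.isnan(means)]
    if means.size == 0:
        raise ValueError("all windows are empty")
    return float(np.quantile(means, 1.0 - fraction))


@dataclass
class CandidateInterval:
    chrom: str
    start: int
    end: int
    peak: float
    pieces: list[tuple[str, int, int, int]] = field(default_factory=list)
    # (scaffold, piece_start, piece_end, piece_len) in scaffold coordinates

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def candidate_intervals(
    stats: list[WindowStat],
    threshold: float,
    agp: list[AgpRow] | None = None,
) -> list[CandidateInterval]:
    """Merge windows whose mean reaches the threshold into candidate
    intervals; overlapping or book-ended windows coalesce.  With an AGP the
    scaffold pieces inside each interval are resolved."""
    hits = [w for w in stats
            if not np.isnan(w.mean_abs_delta) and w.mean_abs_delta >= threshold]
    hits.sort(key=lambda w: (w.chrom, w.start))
    intervals: list[CandidateInterval] = []
    for w in hits:
        if (intervals and intervals[-1].chrom == w.chrom
                and w.start <= intervals[-1].end + 1):
            cur = intervals[-1]
            cur.end = max(cur.end, w.end)
            cur.peak = max(cur.peak, w.mean_abs_delta)
        else:
            intervals.append(CandidateInterval(w.chrom, w.start, w.end,
                                               w.mean_abs_delta))
    if agp is not None:
        for iv in intervals:
            iv.pieces = interval_pieces(iv, agp)
    return intervals


def interval_pieces(interval: CandidateInterval,
                    agp: list[AgpRow]) -> list[tuple[str, int, int, int]]:
    """Scaffold pieces (1-based inclusive scaffold coordinates) covered by a
    chromosome interval, via the AGP tiling; gap rows are skipped."""
    pieces = []
    for row in agp:
        if row.object_id != interval.chrom or row.component_type != "W":
            continue
        lo = max(interval.start, row.object_beg)
        hi = min(interval.end, row.object_end)
        if lo > hi:
            continue
        if row.orientation == "-":
            s = row.component_end - (hi - row.object_beg)
            e = row.component_end - (lo - row.object_beg)
        else:
            s = row.component_beg + (lo - row.object_beg)
            e = row.component_beg + (hi - row.object_beg)
        pieces.append((row.component_id, s, e, e - s + 1))
    return pieces


def windows_to_frame(stats: list[WindowStat]) -> pd.DataFrame:
    return pd.DataFrame(
        [(w.chrom, w.start, w.end, w.n_snps, w.mean_abs_delta) for w in stats],
        columns=["chrom", "start", "end", "n_snps", "mean_abs_delta"],
    )


def intervals_to_frame(intervals: list[CandidateInterval]) -> pd.DataFrame:
    rows = []
    for iv in intervals:
        piece_str = ";".join(f"{s}:{a}-{b}" for s, a, b, _l in iv.pieces) or "."
        rows.append((iv.chrom, iv.start, iv.end, iv.length, iv.peak, piece_str))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "length",
                                       "peak_mean_abs_delta", "scaffold_pieces"])
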