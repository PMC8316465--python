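"""ROSE-style super-enhancer calling.

Enhancer peaks are stitched into regions (peaks fully contained in a
promoter window around any TSS are removed first), regions are scored by
background-subtracted reads-per-million signal, rank-ordered, and the
"hockey stick" is cut where the min-max-scaled curve's forward-difference
slope first exceeds 1 — the discrete analogue of the tangent-slope-1
geometry.  Regions above the cutoff signal are super-enhancers.

Defaults are the published stitching conventions: 12.5 kb stitch distance
and a +/- 2.5 kb TSS exclusion zone.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd

from .core import GenomicInterval, Peak, SignalTrack, merge_intervals, window_sum
from .occupancy import assign_nearest_tss

logger = logging.getLogger(__name__)

DEFAULT_STITCH_DISTANCE = 12_500
DEFAULT_TSS_EXCLUSION = 2_500


@dataclass
class StitchedRegion:
    """A merged enhancer span with its member peaks and signal scores."""

    interval: GenomicInterval
    member_peaks: List[Peak]
    signal_case: float = 0.0
    signal_input: float = 0.0
    net_signal: float = 0.0


@dataclass
class SERanking:
    """Rank-ordered stitched regions with the elbow cutoff.

    ``regions`` are sorted ascending by net signal (ties by chrom, start);
    ``scaled_x``/``scaled_y`` are the min-max-scaled rank/signal vectors;
    ``cutoff_index`` is the first position whose forward slope exceeds 1.
    """

    regions: List[StitchedRegion]
    scaled_x: np.ndarray
    scaled_y: np.ndarray
    cutoff_signal: float
    cutoff_index: Optional[int]
    is_super: np.ndarray

    @property
    def n_super(self) -> int:
        return int(self.is_super.sum())


def stitch(
    peaks: Sequence[Peak],
    annotation: Sequence,
    stitch_distance: int = DEFAULT_STITCH_DISTANCE,
    tss_exclusion: int = DEFAULT_TSS_EXCLUSION,
) -> List[StitchedRegion]:
    """Stitch enhancer peaks into regions, excluding promoter-contained peaks.

    A peak is removed (not stitched) only when it lies *fully* within
    ``[tss - tss_exclusion, tss + tss_exclusion]`` of some TSS; peaks merely
    overlapping a promoter window are kept.  Remaining peaks are merged
    whenever the gap between them is at most ``stitch_distance``.
    """
    if stitch_distance < 0:
        raise ValueError("stitch_distance must be >= 0")
    if tss_exclusion < 0:
        raise ValueError("tss_exclusion must be >= 0")

    tss_by_chrom = {}
    for g in annotation:
        tss_by_chrom.setdefault(g.interval.chrom, []).append(g.tss)
    tss_sorted = {c: np.sort(np.array(v)) for c, v in tss_by_chrom.items()}

    kept: List[Peak] = []
    n_removed = 0
    for p in peaks:
        iv = p.interval
        arr = tss_sorted.get(iv.chrom)
        contained = False
        if arr is not None and len(arr):
            # any TSS with iv fully inside [tss - excl, tss + excl]
            lo = np.searchsorted(arr, iv.start - tss_exclusion, side="left")
            hi = np.searchsorted(arr, iv.end - 1 + tss_exclusion, side="right")
            for t in arr[lo:hi]:
                if iv.start >= t - tss_exclusion and iv.end - 1 <= t + tss_exclusion:
                    contained = True
                    break
        if contained:
            n_removed += 1
        else:
            kept.append(p)
    if n_removed:
        logger.info("removed %d promoter-contained peaks before stitching", n_removed)

    merged = merge_intervals([p.interval for p in kept], max_gap=stitch_distance)
    regions = [StitchedRegion(iv, []) for iv in merged]
    by_chrom = {}
    for r in regions:
        by_chrom.setdefault(r.interval.chrom, []).append(r)
    for p in kept:
        for r in by_chrom.get(p.interval.chrom, []):
            if r.interval.contains(p.interval):
                r.member_peaks.append(p)
                break
    return regions


def score_regions(
    regions: Sequence[StitchedRegion],
    case_track: SignalTrack,
    input_track: Optional[SignalTrack] = None,
) -> List[StitchedRegion]:
    """Score regions by input-subtracted RPM signal, floored at zero."""
    for r in regions:
        r.signal_case = window_sum(case_track, r.interval, as_rpm=True)
        r.signal_input = (
            window_sum(input_track, r.interval, as_rpm=True) if input_track is not None else 0.0
        )
        r.net_signal = max(0.0, r.signal_case - r.signal_input)
    return list(regions)


def rank_and_cut(regions: Sequence[StitchedRegion]) -> SERanking:
    """Rank regions by net signal and cut the hockey stick at the elbow.

    Degenerate inputs (fewer than 3 regions, or all signals equal) yield
    zero super-enhancers.  The scaled curve is invariant under positive
    scaling and constant shifts of the signals, so the is_super set is too.
    """
    regions = sorted(
        regions, key=lambda r: (r.net_signal, r.interval.chrom, r.interval.start)
    )
    signals = np.array([r.net_signal for r in regions], dtype=float)
    if np.any(signals < 0):
        raise ValueError("net signals must be nonnegative")
    n = len(signals)
    if n < 3 or signals.max() == signals.min():
        logger.info("degenerate ranking (n=%d): zero super-enhancers", n)
        x = np.linspace(0, 1, n) if n > 1 else np.zeros(n)
        y = np.zeros(n)
        return SERanking(list(regions), x, y, float("inf"), None, np.zeros(n, bool))
    x = np.arange(n) / (n - 1)
    y = (signals - signals.min()) / (signals.max() - signals.min())
    slopes = (y[1:] - y[:-1]) / (x[1:] - x[:-1])
    above = np.nonzero(slopes > 1)[0]
    if len(above) == 0:
        return SERanking(list(regions), x, y, float("inf"), None, np.zeros(n, bool))
    cut = int(above[0])
    cutoff_signal = float(signals[cut])
    is_super = signals > cutoff_signal
    return SERanking(list(regions), x, y, cutoff_signal, cut, is_super)


def rank_report(ranking: SERanking, annotation: Sequence) -> pd.DataFrame:
    """Per-region report, rank 1 = strongest, with nearest genes.

    Nearest genes are found by nearest-TSS assignment on region midpoints.
    """
    n = len(ranking.regions)
    rows = []
    midpoint_peaks = [
        Peak(r.interval, name=f"region_{i}") for i, r in enumerate(ranking.regions)
    ]
    nearest = assign_nearest_tss(midpoint_peaks, annotation) if annotation else None
    for i, r in enumerate(ranking.regions):
        rank = n - i  # ascending order -> strongest gets rank 1
        gene = None
        if nearest is not None:
            gene = nearest.iloc[i]["gene_id"]
        rows.append(
            {
                "rank": rank,
                "chrom": r.interval.chrom,
                "start": r.interval.start,
                "end": r.interval.end,
                "n_peaks": len(r.member_peaks),
                "net_signal": r.net_signal,
                "is_super": bool(ranking.is_super[i]),
                "nearest_gene": gene,
            }
        )
    df = pd.DataFrame(rows).sort_values("rank").reset_index(drop=True)
    return df


def plot_data(ranking: SERanking) -> pd.DataFrame:
    """(rank, signal) pairs with the cutoff marked, for hockey-stick plots."""
    n = len(ranking.regions)
    return pd.DataFrame(
        {
            "rank": np.arange(n, 0, -1),
            "net_signal": [r.net_signal for r in ranking.regions],
            "scaled_x": ranking.scaled_x,
            "scaled_y": ranking.scaled_y,
            "is_super": ranking.is_super,
            "at_cutoff": [i == ranking.cutoff_index for i in range(n)],
        }
    )
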