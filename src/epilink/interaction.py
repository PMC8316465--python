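"""Viewpoint chromatin-interaction profiling (4C), 3C ratios and ChIP-qPCR.

A 4C profile is per-restriction-fragment read counts around a viewpoint
(bait) locus.  Processing: mask the viewpoint fragment and its +/- k
neighbours (self-ligation artifacts), scale the remaining counts to one
million (cis normalization), fit a power-law distance-decay background
count ~ a * d^(-b) by least squares on log(count + 1) vs log(distance), and
call enriched regions as runs of consecutive fragments whose studentized
log residual exceeds a z threshold.

3C interaction frequencies are reported relative to a neutral control site;
ChIP-qPCR enrichment is expressed as percent input,
PI = 100 * 2^((Ct_input - log2(1 / input_fraction)) - Ct_IP).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import List, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .core import GenomicInterval

logger = logging.getLogger(__name__)

DEFAULT_EXCLUDE_K = 2
DEFAULT_Z_MIN = 2.0
DEFAULT_MIN_RUN = 3
SMOOTH_WINDOW = 5


@dataclass
class FragmentMap:
    """Ordered, contiguous restriction fragments with the viewpoint index."""

    fragments: List[GenomicInterval]
    viewpoint_index: int

    def __post_init__(self) -> None:
        frs = self.fragments
        if not frs:
            raise ValueError("fragment map is empty")
        for a, b in zip(frs, frs[1:]):
            if a.chrom != b.chrom or a.end != b.start:
                raise ValueError("fragments must be contiguous, sorted, non-overlapping")
        if not (0 <= self.viewpoint_index < len(frs)):
            raise ValueError("viewpoint index out of range")

    @property
    def midpoints(self) -> np.ndarray:
        return np.array([f.midpoint for f in self.fragments])


@dataclass
class InteractionProfile:
    """Per-fragment 4C quantities; decay-model fields filled by fit_decay."""

    fragment_map: FragmentMap
    raw_counts: np.ndarray
    masked: np.ndarray            # True for viewpoint-proximal fragments
    normalized: np.ndarray        # cis-normalized to 1e6 over unmasked
    distance: np.ndarray          # |midpoint - viewpoint midpoint|, bp
    smoothed: np.ndarray          # running mean of normalized, w=5
    condition: str = ""
    decay_a: Optional[float] = None
    decay_b: Optional[float] = None
    decay_flagged: bool = False
    expectation: Optional[np.ndarray] = None
    residual_z: Optional[np.ndarray] = None


def digest(sequence: str, recognition_site: str, chrom: str = "chr") -> List[GenomicInterval]:
    """Cut a sequence at every occurrence of the recognition site.

    Cuts are placed at the start of each (case-insensitive) site occurrence;
    the first and last fragments run to the chromosome ends.  A site-free
    sequence yields one whole-chromosome fragment (warned).
    """
    site = recognition_site.upper()
    if len(site) < 4 or set(site) - set("ACGT"):
        raise ValueError("recognition site must be >= 4 bp over A,C,G,T")
    seq = sequence.upper()
    cuts = [m.start() for m in re.finditer(f"(?={re.escape(site)})", seq)]
    cuts = [c for c in cuts if 0 < c < len(seq)]
    if not cuts:
        logger.warning("recognition site %s not found: single fragment", site)
        return [GenomicInterval(chrom, 0, len(seq))]
    bounds = [0] + cuts + [len(seq)]
    return [GenomicInterval(chrom, a, b) for a, b in zip(bounds, bounds[1:]) if b > a]


def profile(
    counts: Sequence[float],
    fragment_map: FragmentMap,
    exclude_k: int = DEFAULT_EXCLUDE_K,
    condition: str = "",
) -> InteractionProfile:
    """Build a cis-normalized viewpoint profile from per-fragment counts."""
    raw = np.asarray(counts, dtype=float)
    if len(raw) != len(fragment_map.fragments):
        raise ValueError("one count per fragment required")
    if np.any(raw < 0):
        raise ValueError("counts must be nonnegative")
    vp = fragment_map.viewpoint_index
    masked = np.zeros(len(raw), dtype=bool)
    masked[max(0, vp - exclude_k) : vp + exclude_k + 1] = True
    total = raw[~masked].sum()
    normalized = np.full(len(raw), np.nan)
    if total > 0:
        normalized[~masked] = raw[~masked] * 1e6 / total
    mids = fragment_map.midpoints
    distance = np.abs(mids - mids[vp]).astype(float)
    smoothed = _running_mean(normalized, SMOOTH_WINDOW)
    return InteractionProfile(fragment_map, raw, masked, normalized, distance, smoothed, condition)


def _running_mean(values: np.ndarray, w: int) -> np.ndarray:
    out = np.full(len(values), np.nan)
    half = w // 2
    for i in range(len(values)):
        lo, hi = max(0, i - half), min(len(values), i + half + 1)
        window = values[lo:hi]
        if np.any(np.isfinite(window)):
            out[i] = np.nanmean(window)
    return out


def fit_decay(prof: InteractionProfile) -> InteractionProfile:
    """Fit count ~ a * d^(-b) on unmasked fragments, storing residual z.

    Least squares on log(count + 1) vs log(d); b is constrained positive —
    a non-decaying profile is clipped to b ~ 0 and flagged.  Residual z is
    (log(obs + 1) - log(exp + 1)) / sd(residuals).
    """
    use = ~prof.masked & (prof.distance > 0)
    if prof.raw_counts[use].sum() == 0:
        raise ValueError("all unmasked counts are zero; cannot fit decay")
    if int(((prof.raw_counts > 0) & use).sum()) < 10:
        raise ValueError("need >= 10 unmasked fragments with positive counts")
    x = np.log(prof.distance[use])
    y = np.log(prof.raw_counts[use] + 1.0)
    slope, intercept = np.polyfit(x, y, 1)
    b = -slope
    flagged = False
    if b <= 1e-2:  # essentially non-decaying (or inverted): boundary case
        b = 1e-6
        flagged = True
        logger.warning("non-decaying profile: b clipped to ~0")
    a = float(np.exp(intercept))
    with np.errstate(divide="ignore"):
        expectation = a * np.where(prof.distance > 0, prof.distance, np.nan) ** (-b)
    log_resid = np.log(prof.raw_counts + 1.0) - np.log(expectation + 1.0)
    sd = float(np.nanstd(log_resid[use], ddof=1))
    if sd == 0:
        sd = 1.0
    z = np.full(len(prof.raw_counts), np.nan)
    z[use] = log_resid[use] / sd
    prof.decay_a = a
    prof.decay_b = float(b)
    prof.decay_flagged = flagged
    prof.expectation = expectation
    prof.residual_z = z
    return prof


def call_interactions(
    prof: InteractionProfile,
    z_min: float = DEFAULT_Z_MIN,
    min_run: int = DEFAULT_MIN_RUN,
) -> List[GenomicInterval]:
    """Maximal runs of >= min_run consecutive fragments with z >= z_min.

    Masked fragments break runs.  Each returned interval spans from the
    first to the last fragment of its run.
    """
    if prof.residual_z is None:
        raise ValueError("fit_decay must run before calling interactions")
    z = prof.residual_z
    frs = prof.fragment_map.fragments
    calls: List[GenomicInterval] = []
    run_start = None
    for i in range(len(frs) + 1):
        hot = i < len(frs) and np.isfinite(z[i]) and z[i] >= z_min and not prof.masked[i]
        if hot and run_start is None:
            run_start = i
        elif not hot and run_start is not None:
            if i - run_start >= min_run:
                calls.append(
                    GenomicInterval(frs[run_start].chrom, frs[run_start].start, frs[i - 1].end)
                )
            run_start = None
    return calls


def relative_interaction_frequency(
    values: Mapping[str, float], control_site_id: str
) -> pd.Series:
    """3C interaction frequencies as ratios to a neutral control site."""
    if control_site_id not in values:
        raise ValueError(f"control site {control_site_id!r} not in table")
    control = float(values[control_site_id])
    if control <= 0:
        raise ValueError("control site value must be > 0")
    return pd.Series({site: float(v) / control for site, v in values.items()})


def percent_input(table: pd.DataFrame) -> pd.DataFrame:
    """ChIP-qPCR percent input per site.

    Requires columns ``ct_ip``, ``ct_input`` and ``input_fraction`` (the
    fraction of chromatin the input aliquot represents, in (0, 1]).
    PI = 100 * 2^((Ct_input - log2(1 / input_fraction)) - Ct_IP).
    """
    for col in ("ct_ip", "ct_input", "input_fraction"):
        if col not in table.columns:
            raise ValueError(f"qPCR table missing column {col!r}")
    frac = table["input_fraction"].to_numpy(dtype=float)
    if np.any(frac <= 0) or np.any(frac > 1):
        raise ValueError("input_fraction must be in (0, 1]")
    ct_ip = table["ct_ip"].to_numpy(dtype=float)
    ct_input = table["ct_input"].to_numpy(dtype=float)
    if not (np.all(np.isfinite(ct_ip)) and np.all(np.isfinite(ct_input))):
        raise ValueError("Ct values must be finite")
    adjusted_input = ct_input - np.log2(1.0 / frac)
    out = table.copy()
    out["percent_input"] = 100.0 * 2.0 ** (adjusted_input - ct_ip)
    return out
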