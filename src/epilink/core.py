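"""Genomic coordinate conventions, interval algebra and standard-format I/O.

Everything downstream (peak-to-TSS assignment, enhancer stitching, window
signal aggregation) is built on three conventions fixed here:

* all internal coordinates are 0-based, half-open (BED convention); GTF's
  1-based inclusive coordinates are converted at the parsing boundary;
* the transcription start site (TSS) of a minus-strand gene is ``end - 1``,
  the last covered base;
* binned signal tracks store signal *mass per bin*; bedGraph files store
  per-bp density, so mass = density x interval length at the I/O boundary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence

import numpy as np

logger = logging.getLogger(__name__)

STRANDS = ("+", "-", ".")


@dataclass(frozen=True)
class GenomicInterval:
    """0-based half-open span on a chromosome."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"require 0 <= start < end, got [{self.start}, {self.end})"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"strand must be one of {STRANDS}, got {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def overlaps(self, other: "GenomicInterval") -> bool:
        return self.chrom == other.chrom and self.start < other.end and other.start < self.end

    def contains(self, other: "GenomicInterval") -> bool:
        return self.chrom == other.chrom and self.start <= other.start and other.end <= self.end


@dataclass(frozen=True)
class Peak:
    """A ChIP-seq peak: an interval plus optional score and summit."""

    interval: GenomicInterval
    name: str = "."
    score: Optional[float] = None
    summit_offset: Optional[int] = None

    def __post_init__(self) -> None:
        if self.score is not None and self.score < 0:
            raise ValueError("peak score must be nonnegative")
        if self.summit_offset is not None and not (
            0 <= self.summit_offset < self.interval.length
        ):
            raise ValueError("summit_offset must lie within the peak")

    @property
    def anchor(self) -> int:
        """Summit position if known, else the interval midpoint."""
        if self.summit_offset is not None:
            return self.interval.start + self.summit_offset
        return self.interval.midpoint


@dataclass(frozen=True)
class GeneAnnotation:
    """One gene with a single representative TSS."""

    gene_id: str
    gene_name: str
    interval: GenomicInterval

    @property
    def tss(self) -> int:
        if self.interval.strand == "-":
            return self.interval.end - 1
        return self.interval.start

    @property
    def strand(self) -> str:
        return self.interval.strand


@dataclass
class SignalTrack:
    """Fixed-bin coverage vectors per chromosome.

    ``data[chrom][i]`` is the signal mass (read count equivalent) in
    ``[i * bin_size, (i + 1) * bin_size)``.  ``library_size`` is the total
    mapped-read equivalent used for reads-per-million (RPM) scaling.
    """

    data: Dict[str, np.ndarray]
    bin_size: int
    library_size: float

    def __post_init__(self) -> None:
        if self.bin_size <= 0:
            raise ValueError("bin_size must be positive")
        if self.library_size <= 0:
            raise ValueError("library_size must be positive")
        for chrom, vec in self.data.items():
            vec = np.asarray(vec, dtype=float)
            if not np.all(np.isfinite(vec)) or np.any(vec < 0):
                raise ValueError(f"track values on {chrom} must be finite and >= 0")
            self.data[chrom] = vec

    @property
    def rpm_factor(self) -> float:
        return 1e6 / self.library_size

    def extent(self, chrom: str) -> int:
        return len(self.data[chrom]) * self.bin_size


# ---------------------------------------------------------------------------
# BED / narrowPeak
# ---------------------------------------------------------------------------

class BedParseError(ValueError):
    pass


def read_bed(path: str | Path) -> List[Peak]:
    """Read BED3/BED6/narrowPeak into peaks, preserving input order.

    narrowPeak column 10 (summit offset) maps to ``summit_offset``;
    the sentinel -1 means absent.
    """
    peaks: List[Peak] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise BedParseError(f"{path}:{lineno}: fewer than 3 columns")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise BedParseError(f"{path}:{lineno}: non-integer coordinates") from exc
            if start >= end:
                raise BedParseError(f"{path}:{lineno}: start >= end ({start} >= {end})")
            name = fields[3] if len(fields) > 3 else "."
            score: Optional[float] = None
            if len(fields) > 4 and fields[4] != ".":
                try:
                    score = float(fields[4])
                except ValueError as exc:
                    raise BedParseError(f"{path}:{lineno}: non-numeric score") from exc
            strand = fields[5] if len(fields) > 5 and fields[5] in STRANDS else "."
            summit: Optional[int] = None
            if len(fields) >= 10:  # narrowPeak
                try:
                    s = int(fields[9])
                except ValueError as exc:
                    raise BedParseError(f"{path}:{lineno}: non-integer summit") from exc
                summit = None if s == -1 else s
            try:
                peaks.append(
                    Peak(GenomicInterval(chrom, start, end, strand), name, score, summit)
                )
            except ValueError as exc:
                raise BedParseError(f"{path}:{lineno}: {exc}") from exc
    return peaks


def write_bed(peaks: Iterable[Peak], path: str | Path, *, score_default: float = 0.0) -> None:
    """Write peaks as canonical BED6 (round-trips byte-identically)."""
    with open(path, "w") as fh:
        for p in peaks:
            iv = p.interval
            score = p.score if p.score is not None else score_default
            score_str = f"{score:g}"
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{p.name}\t{score_str}\t{iv.strand}\n")


# ---------------------------------------------------------------------------
# Gene annotation
# ---------------------------------------------------------------------------

def read_gene_annotation(path: str | Path, dialect: str = "gtf") -> List[GeneAnnotation]:
    """Read gene models from GTF (1-based inclusive) or a TSS TSV (0-based).

    Multi-transcript genes collapse to the first-listed record's TSS with a
    logged warning.  Duplicate gene ids with conflicting strands are an error.
    """
    if dialect == "gtf":
        return _read_gtf(path)
    if dialect == "tsv":
        return _read_tss_tsv(path)
    raise ValueError(f"unknown annotation dialect {dialect!r} (expected 'gtf' or 'tsv')")


def _read_gtf(path: str | Path) -> List[GeneAnnotation]:
    import gffutils.iterators

    by_gene: Dict[str, GeneAnnotation] = {}
    order: List[str] = []
    have_gene_feature: set = set()
    for feat in gffutils.iterators.DataIterator(str(path)):
        if feat.featuretype not in ("gene", "transcript", "mRNA"):
            continue
        gene_id = (feat.attributes.get("gene_id") or [feat.id])[0]
        gene_name = (feat.attributes.get("gene_name") or [gene_id])[0]
        strand = feat.strand if feat.strand in ("+", "-") else "."
        iv = GenomicInterval(feat.seqid, feat.start - 1, feat.end, strand)
        ann = GeneAnnotation(gene_id, gene_name, iv)
        prev = by_gene.get(gene_id)
        if prev is None:
            by_gene[gene_id] = ann
            order.append(gene_id)
            if feat.featuretype == "gene":
                have_gene_feature.add(gene_id)
        else:
            if prev.strand != strand:
                raise ValueError(f"gene {gene_id}: conflicting strands in {path}")
            if feat.featuretype == "gene" and gene_id not in have_gene_feature:
                by_gene[gene_id] = ann  # gene record outranks transcript records
                have_gene_feature.add(gene_id)
            elif prev.tss != ann.tss:
                logger.warning(
                    "gene %s: multiple TSS (%d, %d); keeping first-listed %d",
                    gene_id, prev.tss, ann.tss, prev.tss,
                )
    return [by_gene[g] for g in order]


def _read_tss_tsv(path: str | Path) -> List[GeneAnnotation]:
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    required = {"gene_id", "chrom", "start", "end", "strand"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"annotation TSV missing columns: {sorted(missing)}")
    out: List[GeneAnnotation] = []
    seen: Dict[str, str] = {}
    for row in df.itertuples(index=False):
        gid = str(row.gene_id)
        if gid in seen:
            if seen[gid] != row.strand:
                raise ValueError(f"gene {gid}: conflicting strands in {path}")
            logger.warning("gene %s: duplicate row ignored (first-listed wins)", gid)
            continue
        seen[gid] = row.strand
        name = str(getattr(row, "gene_name", gid))
        out.append(
            GeneAnnotation(gid, name, GenomicInterval(str(row.chrom), int(row.start), int(row.end), str(row.strand)))
        )
    return out


def write_gene_annotation(genes: Sequence[GeneAnnotation], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tgene_name\tchrom\tstart\tend\tstrand\ttss\n")
        for g in genes:
            iv = g.interval
            fh.write(f"{g.gene_id}\t{g.gene_name}\t{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.strand}\t{g.tss}\n")


# ---------------------------------------------------------------------------
# Interval algebra
# ---------------------------------------------------------------------------

def merge_intervals(
    intervals: Sequence[GenomicInterval], max_gap: int = 0
) -> List[GenomicInterval]:
    """Merge intervals whose gap (next.start - prev.end) is <= max_gap.

    Output is sorted by (chrom, start); adjacent output intervals on the same
    chromosome are separated by a gap strictly greater than ``max_gap``.
    With ``max_gap=0`` this is the classic overlap/abutment union.
    """
    if max_gap < 0:
        raise ValueError("max_gap must be >= 0")
    merged: List[GenomicInterval] = []
    for iv in sorted(intervals, key=lambda i: (i.chrom, i.start, i.end)):
        if merged and merged[-1].chrom == iv.chrom and iv.start - merged[-1].end <= max_gap:
            last = merged[-1]
            if iv.end > last.end:
                merged[-1] = GenomicInterval(last.chrom, last.start, iv.end)
        else:
            merged.append(GenomicInterval(iv.chrom, iv.start, iv.end))
    return merged


# ---------------------------------------------------------------------------
# Signal tracks
# ---------------------------------------------------------------------------

def window_sum(track: SignalTrack, interval: GenomicInterval, as_rpm: bool = False) -> float:
    """Sum of track signal over an interval, prorating partial bins linearly.

    Bins beyond the recorded extent contribute zero.  Raises ``KeyError`` if
    the chromosome is not in the track.
    """
    if interval.chrom not in track.data:
        raise KeyError(f"chromosome {interval.chrom!r} not in track")
    vec = track.data[interval.chrom]
    bs = track.bin_size
    lo_bin = interval.start // bs
    hi_bin = (interval.end - 1) // bs
    lo_bin = max(lo_bin, 0)
    hi_bin = min(hi_bin, len(vec) - 1)
    if hi_bin < lo_bin:
        return 0.0
    idx = np.arange(lo_bin, hi_bin + 1)
    bin_starts = idx * bs
    overlap = np.minimum(bin_starts + bs, interval.end) - np.maximum(bin_starts, interval.start)
    total = float(np.dot(vec[lo_bin : hi_bin + 1], overlap / bs))
    if as_rpm:
        total *= track.rpm_factor
    return total


def read_bedgraph(
    path: str | Path, bin_size: int, library_size: float,
    chrom_sizes: Optional[Mapping[str, int]] = None,
) -> SignalTrack:
    """Rasterize a bedGraph (per-bp density values) onto fixed bins.

    Each record contributes ``value x overlap-length`` of mass to every bin it
    touches, so bin-aligned files round-trip exactly through
    :func:`write_bedgraph`.
    """
    data: Dict[str, np.ndarray] = {}
    max_end: Dict[str, int] = {}
    records: List[tuple] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise BedParseError(f"{path}:{lineno}: bedGraph needs 4 columns")
            chrom, start, end, value = fields[0], int(fields[1]), int(fields[2]), float(fields[3])
            if start >= end:
                raise BedParseError(f"{path}:{lineno}: start >= end")
            records.append((chrom, start, end, value))
            max_end[chrom] = max(max_end.get(chrom, 0), end)
    for chrom, end in max_end.items():
        size = chrom_sizes[chrom] if chrom_sizes else end
        data[chrom] = np.zeros(int(np.ceil(size / bin_size)))
    for chrom, start, end, value in records:
        vec = data[chrom]
        lo, hi = start // bin_size, (end - 1) // bin_size
        for b in range(lo, min(hi, len(vec) - 1) + 1):
            bstart = b * bin_size
            overlap = min(bstart + bin_size, end) - max(bstart, start)
            vec[b] += value * overlap
    return SignalTrack(data, bin_size, library_size)


def write_bedgraph(track: SignalTrack, path: str | Path, *, omit_zero: bool = True) -> None:
    """Export a track as bedGraph with per-bp density values."""
    with open(path, "w") as fh:
        for chrom in sorted(track.data):
            vec = track.data[chrom]
            bs = track.bin_size
            for i, mass in enumerate(vec):
                if omit_zero and mass == 0:
                    continue
                fh.write(f"{chrom}\t{i * bs}\t{(i + 1) * bs}\t{mass / bs:.6g}\n")


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> Dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: Mapping[str, str], path: str | Path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
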