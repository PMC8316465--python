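"""Position-weight-matrix motif scanning with a relative-score threshold.

A PWM is built from a JASPAR-style count matrix: column probabilities are
(count + pseudocount * background) / (colsum + pseudocount), entries are
log2(p / background).  Scanning scores every window on both strands and
reports hits whose *relative score* — the min-max-scaled log-odds,
(raw - min_possible) / (max_possible - min_possible) — reaches a threshold;
a 0.95 threshold operationalizes ">95 % consensus" matches, the convention
used by the JASPAR tooling itself.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Sequence

import numpy as np

from .core import GenomicInterval

logger = logging.getLogger(__name__)

ALPHABET = "ACGT"
_CODE = {c: i for i, c in enumerate(ALPHABET)}
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

DEFAULT_PSEUDOCOUNT = 0.8
DEFAULT_MIN_RELATIVE_SCORE = 0.95


@dataclass
class PositionWeightMatrix:
    """Log2-odds matrix over A,C,G,T with its provenance.

    ``log_odds`` has shape (L, 4), column order A, C, G, T.
    """

    motif_id: str
    counts: np.ndarray
    background: np.ndarray
    pseudocount: float
    log_odds: np.ndarray

    @property
    def length(self) -> int:
        return self.log_odds.shape[0]

    @property
    def max_score(self) -> float:
        return float(self.log_odds.max(axis=1).sum())

    @property
    def min_score(self) -> float:
        return float(self.log_odds.min(axis=1).sum())

    @property
    def consensus(self) -> str:
        return "".join(ALPHABET[i] for i in self.log_odds.argmax(axis=1))

    def relative_score(self, raw: float) -> float:
        lo, hi = self.min_score, self.max_score
        return (raw - lo) / (hi - lo)

    def reverse_complement(self) -> "PositionWeightMatrix":
        return PositionWeightMatrix(
            self.motif_id,
            self.counts[::-1, ::-1].copy(),
            self.background[::-1].copy(),
            self.pseudocount,
            self.log_odds[::-1, ::-1].copy(),
        )


@dataclass(frozen=True)
class MotifHit:
    interval: GenomicInterval
    strand: str
    raw_score: float
    relative_score: float


def pwm_from_counts(
    counts: np.ndarray | Sequence[Sequence[float]],
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    background: Sequence[float] | None = None,
    motif_id: str = "motif",
) -> PositionWeightMatrix:
    """Build a PWM from an (L, 4) count matrix (column order A, C, G, T)."""
    mat = np.asarray(counts, dtype=float)
    if mat.ndim != 2 or mat.shape[1] != 4:
        raise ValueError("counts must have shape (L, 4) with columns A,C,G,T")
    if mat.shape[0] < 1:
        raise ValueError("motif length must be >= 1")
    if np.any(mat < 0):
        raise ValueError("counts must be nonnegative")
    bg = np.full(4, 0.25) if background is None else np.asarray(background, dtype=float)
    if not np.isclose(bg.sum(), 1.0) or np.any(bg <= 0):
        raise ValueError("background must be positive and sum to 1")
    if pseudocount <= 0 and np.any(mat.sum(axis=1) == 0):
        raise ValueError("all-zero column requires a positive pseudocount")
    if pseudocount <= 0 and np.any(mat == 0):
        raise ValueError("zero counts require a positive pseudocount")
    colsum = mat.sum(axis=1, keepdims=True)
    probs = (mat + pseudocount * bg) / (colsum + pseudocount)
    log_odds = np.log2(probs / bg)
    return PositionWeightMatrix(motif_id, mat, bg, pseudocount, log_odds)


def encode_sequence(sequence: str) -> np.ndarray:
    """Map A,C,G,T to 0..3 and anything else (N) to -1."""
    seq = sequence.upper()
    arr = np.full(len(seq), -1, dtype=np.int8)
    for base, code in _CODE.items():
        arr[np.frombuffer(seq.encode(), dtype="S1") == base.encode()] = code
    return arr


def reverse_complement(sequence: str) -> str:
    return sequence.upper().translate(_COMPLEMENT)[::-1]


def scan(
    sequence: str,
    pwm: PositionWeightMatrix,
    min_relative_score: float = DEFAULT_MIN_RELATIVE_SCORE,
    both_strands: bool = True,
    chrom: str = "seq",
    offset: int = 0,
) -> List[MotifHit]:
    """Scan a sequence for PWM matches at or above a relative-score threshold.

    Every length-L window is scored on the plus strand and (optionally)
    against the reverse-complemented matrix for minus-strand hits; windows
    containing N are skipped.  Hit coordinates are 0-based half-open on the
    plus strand, shifted by ``offset``.
    """
    if not (0 <= min_relative_score <= 1):
        raise ValueError("min_relative_score must be in [0, 1]")
    L = pwm.length
    codes = encode_sequence(sequence)
    n_win = len(codes) - L + 1
    if n_win <= 0:
        logger.warning("sequence shorter than motif (%d < %d): no windows", len(codes), L)
        return []

    hits: List[MotifHit] = []
    strands = [("+", pwm)] + ([("-", pwm.reverse_complement())] if both_strands else [])
    valid = codes >= 0
    ok = np.ones(n_win, dtype=bool)
    for j in range(L):
        ok &= valid[j : j + n_win]
    span = pwm.max_score - pwm.min_score
    for strand, mat in strands:
        scores = np.zeros(n_win)
        safe = np.where(codes < 0, 0, codes)
        for j in range(L):
            scores += mat.log_odds[j, safe[j : j + n_win]]
        rel = (scores - pwm.min_score) / span
        for i in np.nonzero(ok & (rel >= min_relative_score))[0]:
            hits.append(
                MotifHit(
                    GenomicInterval(chrom, offset + int(i), offset + int(i) + L, strand),
                    strand,
                    float(scores[i]),
                    float(rel[i]),
                )
            )
    hits.sort(key=lambda h: (h.interval.start, h.strand))
    return hits


# ---------------------------------------------------------------------------
# JASPAR PFM I/O (Biopython-backed)
# ---------------------------------------------------------------------------

def read_jaspar(path) -> Dict[str, np.ndarray]:
    """Read JASPAR-format PFMs into {motif_id: (L, 4) count matrix}."""
    from Bio import motifs as bio_motifs

    out: Dict[str, np.ndarray] = {}
    with open(path) as fh:
        for m in bio_motifs.parse(fh, "jaspar"):
            mat = np.column_stack([np.asarray(m.counts[b], dtype=float) for b in ALPHABET])
            key = m.matrix_id or m.name or f"motif_{len(out)}"
            out[key] = mat
    return out


def write_jaspar(matrices: Dict[str, np.ndarray], path) -> None:
    with open(path, "w") as fh:
        for motif_id, mat in matrices.items():
            fh.write(f">{motif_id} {motif_id}\n")
            for bi, base in enumerate(ALPHABET):
                vals = " ".join(f"{v:g}" for v in np.asarray(mat)[:, bi])
                fh.write(f"{base}  [ {vals} ]\n")


def hits_to_bed(hits: Sequence[MotifHit], path) -> None:
    """Write motif hits as BED6 with the relative score in the score column."""
    with open(path, "w") as fh:
        for k, h in enumerate(hits):
            iv = h.interval
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\thit_{k}\t{h.relative_score:.4f}\t{h.strand}\n"
            )
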