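"""Seeded generator of a toy two-condition epigenomic study.

The generator emulates the statistical structure of a patient cohort study
(a small control group vs a small disease/stimulated group) without any
download: negative-binomial RNA counts with planted log2 fold changes;
promoter histone-mark pileups (H3K4me3 / H3K4me1 / H3K27ac active,
H3K27me3 repressive) whose amplitudes move with expression for a configured
fraction of the differential genes; one amplified enhancer cluster destined
to be called a super-enhancer plus constant "decoy" clusters so its rank
rises under amplification; a 4C viewpoint profile with power-law distance
decay and a planted interaction bump; a promoter sequence carrying planted
NF-kB-like consensus motifs; and small 3C / ChIP-qPCR tables.

Every quantity derives from one integer seed through named sub-streams in a
fixed order, so identical configs give byte-identical fixtures.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .core import (
    GeneAnnotation,
    GenomicInterval,
    Peak,
    SignalTrack,
    write_bed,
    write_bedgraph,
    write_fasta,
    write_gene_annotation,
)
from .interaction import FragmentMap
from .motifs import pwm_from_counts, reverse_complement, scan, write_jaspar
from .occupancy import MARKS

logger = logging.getLogger(__name__)

# fixed order of named random sub-streams derived from the global seed
_STREAMS = (
    "layout", "counts", "marks", "tracks", "enhancers",
    "fourc", "sequence", "tables",
)

# per-mark promoter amplitude multipliers (H3K4me3 strongest at promoters)
_MARK_AMPLITUDE = {"H3K4me3": 1.5, "H3K4me1": 0.8, "H3K27ac": 1.0, "H3K27me3": 0.6}


@dataclass
class EnhancerClusterSpec:
    """The planted super-enhancer: member peaks, span, amplification."""

    n_peaks: int = 8
    span: int = 60_000
    peak_width: int = 1_500
    member_amplitude: float = 150.0     # reads per member peak
    amplification: float = 4.0          # condition-2 fold on member amplitudes
    decoy_folds: Tuple[float, ...] = (1.5, 2.0, 2.5)  # constant decoys vs cond-1 total


@dataclass
class FourCSpec:
    """Viewpoint interaction profile: decay plus one planted bump."""

    n_fragments: int = 400
    min_fragment: int = 1_000
    max_fragment: int = 4_000
    decay_b: float = 1.0
    amplitude: float = 2e6              # a in expected count = a * d^(-b)
    bump_fold: float = 5.0
    bump_n_fragments: int = 6
    bump_distance: int = 50_000         # bump start offset from the viewpoint


@dataclass
class MotifSpec:
    """Planted NF-kB-like consensus sites in a promoter sequence."""

    consensus: str = "GGGACTTTCC"
    n_planted: int = 3
    promoter_length: int = 2_000
    consensus_weight: int = 85          # per-column count on the consensus base (of 100)


@dataclass
class SimulationConfig:
    seed: int = 0
    n_genes: int = 2_000
    n_control: int = 4
    n_case: int = 5
    genome_length: int = 20_000_000
    chrom: str = "chrS"
    bin_size: int = 100
    nb_mean: float = 500.0
    nb_dispersion: float = 0.05
    frac_up: float = 0.05
    frac_down: float = 0.05
    planted_lfc: float = 3.0
    congruent_fraction: float = 0.5
    depth_factor_range: Tuple[float, float] = (0.8, 1.25)
    promoter_sigma: float = 300.0
    promoter_amplitude: float = 100.0   # reads per promoter peak (baseline)
    background_rate: float = 0.2        # Poisson mass per bin
    n_background_enhancers: int = 150
    enhancer: EnhancerClusterSpec = field(default_factory=EnhancerClusterSpec)
    fourc: FourCSpec = field(default_factory=FourCSpec)
    motif: MotifSpec = field(default_factory=MotifSpec)

    def validate(self) -> None:
        for name in ("frac_up", "frac_down", "congruent_fraction"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.frac_up + self.frac_down > 1:
            raise ValueError("frac_up + frac_down must be <= 1")
        if self.planted_lfc <= 0:
            raise ValueError("planted_lfc must be > 0")
        if self.nb_dispersion < 0:
            raise ValueError("nb_dispersion must be >= 0")
        if self.fourc.decay_b <= 0:
            raise ValueError("4C decay exponent must be > 0")
        if self.enhancer.span >= self.genome_length:
            raise ValueError("enhancer cluster span exceeds the genome")
        if self.n_genes < 10:
            raise ValueError("n_genes must be >= 10")
        if set(self.motif.consensus) - set("ACGT"):
            raise ValueError("motif consensus must be over A,C,G,T")

    def rng(self, stream: str) -> np.random.Generator:
        """Named sub-stream of the global seed (fixed documented order)."""
        if stream not in _STREAMS:
            raise KeyError(f"unknown stream {stream!r}")
        return np.random.default_rng([self.seed, _STREAMS.index(stream)])


@dataclass
class SyntheticTruth:
    """Ground truth of every planted structure, for recovery tests."""

    gene_status: pd.Series          # +1 up, -1 down, 0 null
    true_lfc: pd.Series
    congruent: pd.Series            # True for DE genes given concordant marks
    mark_log2fold: pd.DataFrame     # genes x marks planted log2 amplitude fold
    se_interval: GenomicInterval
    se_member_intervals: List[GenomicInterval]
    decoy_intervals: List[GenomicInterval]
    fourc_bump_indices: List[int]
    fourc_bump_interval: GenomicInterval
    motif_positions: List[Tuple[str, int, str]]   # (sequence name, start, strand)
    depth_factors: Dict[str, float]
    qpcr_true_percent_input: Dict[str, float]
    threec_true_ratios: Dict[str, float]


@dataclass
class SimulationBundle:
    config: SimulationConfig
    annotation: List[GeneAnnotation]
    counts: pd.DataFrame
    sample_groups: Dict[str, str]
    peaks: Dict[str, Dict[str, List[Peak]]]        # mark -> condition -> peaks
    tracks: Dict[str, Dict[str, List[SignalTrack]]]
    fourc_map: FragmentMap
    fourc_counts: Dict[str, np.ndarray]
    sequences: Dict[str, str]
    pfms: Dict[str, np.ndarray]
    gene_sets: Dict[str, set]
    regulators: Dict[str, Dict[str, int]]
    qpcr: pd.DataFrame
    threec: Dict[str, float]
    truth: SyntheticTruth


def _gaussian_kernel(sigma: float, bin_size: int) -> Tuple[np.ndarray, int]:
    """Discretized unit-mass Gaussian over bins, with its center offset."""
    half = int(np.ceil(4 * sigma / bin_size))
    offsets = np.arange(-half, half + 1)
    centers = offsets * bin_size
    w = np.exp(-0.5 * (centers / sigma) ** 2)
    return w / w.sum(), half


def simulate_study(config: SimulationConfig) -> SimulationBundle:
    """Generate the full synthetic study bundle (deterministic per seed)."""
    config.validate()
    cfg = config
    n_bins = cfg.genome_length // cfg.bin_size

    # ---- layout: reserved zones, gene grid, planted gene status ----
    rng = cfg.rng("layout")
    se_center = int(cfg.genome_length * 0.75)
    se_lo = se_center - cfg.enhancer.span // 2
    reserved = [(se_lo - 50_000, se_lo + cfg.enhancer.span + 50_000)]
    decoy_centers = [
        int(cfg.genome_length * f) for f in (0.55, 0.62, 0.68)[: len(cfg.enhancer.decoy_folds)]
    ]
    for c in decoy_centers:
        reserved.append((c - 40_000, c + 40_000))
    fourc_start = int(cfg.genome_length * 0.20)
    # 4C region overlaps gene territory harmlessly (its own count table)

    spacing = cfg.genome_length // (cfg.n_genes + 120)
    annotation: List[GeneAnnotation] = []
    slot = 1
    while len(annotation) < cfg.n_genes:
        tss = slot * spacing
        slot += 1
        if slot > cfg.n_genes + 119:
            raise ValueError("genome too small for requested gene count")
        if any(lo <= tss <= hi for lo, hi in reserved):
            continue
        strand = "+" if rng.random() < 0.5 else "-"
        gid = f"G{len(annotation):04d}"
        if strand == "+":
            iv = GenomicInterval(cfg.chrom, tss, min(tss + 2_000, cfg.genome_length), "+")
        else:
            iv = GenomicInterval(cfg.chrom, max(tss - 1_999, 0), tss + 1, "-")
        annotation.append(GeneAnnotation(gid, gid, iv))
    gene_ids = [g.gene_id for g in annotation]

    n_up = int(round(cfg.frac_up * cfg.n_genes))
    n_down = int(round(cfg.frac_down * cfg.n_genes))
    status = np.zeros(cfg.n_genes, dtype=int)
    order = rng.permutation(cfg.n_genes)
    status[order[:n_up]] = 1
    status[order[n_up : n_up + n_down]] = -1
    de_idx = np.nonzero(status != 0)[0]
    congruent = np.zeros(cfg.n_genes, dtype=bool)
    n_congruent = int(round(cfg.congruent_fraction * len(de_idx)))
    congruent[rng.permutation(de_idx)[:n_congruent]] = True

    # ---- RNA counts: NB with planted fold changes, varying depth ----
    rng = cfg.rng("counts")
    samples = [f"ctrl_{i}" for i in range(cfg.n_control)] + [
        f"case_{i}" for i in range(cfg.n_case)
    ]
    groups = {s: ("control" if s.startswith("ctrl") else "case") for s in samples}
    lo, hi = cfg.depth_factor_range
    depth = {s: float(rng.uniform(lo, hi)) for s in samples}
    true_lfc = cfg.planted_lfc * status.astype(float)
    mat = np.zeros((cfg.n_genes, len(samples)), dtype=int)
    for j, s in enumerate(samples):
        mean = cfg.nb_mean * depth[s] * (
            2.0 ** true_lfc if groups[s] == "case" else np.ones(cfg.n_genes)
        )
        if cfg.nb_dispersion > 0:
            lam = rng.gamma(1.0 / cfg.nb_dispersion, mean * cfg.nb_dispersion)
        else:
            lam = mean
        mat[:, j] = rng.poisson(lam)
    counts = pd.DataFrame(mat, index=gene_ids, columns=samples)

    # ---- planted mark folds for congruent genes ----
    mark_fold = pd.DataFrame(0.0, index=gene_ids, columns=list(MARKS))
    fc = cfg.planted_lfc
    for gi in np.nonzero(congruent)[0]:
        sign = status[gi]
        for mark in MARKS:
            polarity = -1 if mark == "H3K27me3" else 1
            mark_fold.iloc[gi, mark_fold.columns.get_loc(mark)] = sign * polarity * fc

    # ---- enhancer geometry (planted cluster, decoys, background) ----
    rng = cfg.rng("enhancers")
    enh = cfg.enhancer
    member_starts = se_lo + np.linspace(
        0, enh.span - enh.peak_width, enh.n_peaks
    ).astype(int)
    se_members = [
        GenomicInterval(cfg.chrom, int(s), int(s) + enh.peak_width) for s in member_starts
    ]
    se_interval = GenomicInterval(cfg.chrom, se_members[0].start, se_members[-1].end)
    cluster_total = enh.n_peaks * enh.member_amplitude
    decoys: List[List[Tuple[GenomicInterval, float]]] = []
    decoy_intervals = []
    for center, fold in zip(decoy_centers, enh.decoy_folds):
        n_d = 4
        amp = fold * cluster_total / n_d
        starts = center + np.linspace(0, 20_000 - enh.peak_width, n_d).astype(int)
        members = [
            (GenomicInterval(cfg.chrom, int(s), int(s) + enh.peak_width), amp)
            for s in starts
        ]
        decoys.append(members)
        decoy_intervals.append(
            GenomicInterval(cfg.chrom, members[0][0].start, members[-1][0].end)
        )
    tss_positions = np.sort(np.array([g.tss for g in annotation]))
    background_enh: List[Tuple[GenomicInterval, float]] = []
    while len(background_enh) < cfg.n_background_enhancers:
        pos = int(rng.integers(10_000, cfg.genome_length - 10_000))
        if any(lo_ <= pos <= hi_ for lo_, hi_ in reserved):
            continue
        j = np.searchsorted(tss_positions, pos)
        near = min(
            abs(int(tss_positions[k]) - pos)
            for k in (j - 1, j)
            if 0 <= k < len(tss_positions)
        )
        if near < 4_000:
            continue
        width = int(rng.integers(1_000, 2_001))
        amp = float(rng.uniform(50, 400))
        background_enh.append((GenomicInterval(cfg.chrom, pos, pos + width), amp))

    # ---- tracks: expected bin mass per (mark, condition), Poisson replicates ----
    kernel, khalf = _gaussian_kernel(cfg.promoter_sigma, cfg.bin_size)
    tracks: Dict[str, Dict[str, List[SignalTrack]]] = {}
    peaks: Dict[str, Dict[str, List[Peak]]] = {}
    track_rng = cfg.rng("tracks")
    chip_depth: Dict[str, float] = {}
    for mark in MARKS:
        tracks[mark] = {}
        peaks[mark] = {}
        for cond in ("control", "case"):
            lam = np.full(n_bins, cfg.background_rate)
            cond_peaks: List[Peak] = []
            base_amp = cfg.promoter_amplitude * _MARK_AMPLITUDE[mark]
            tss_bins = np.array([g.tss // cfg.bin_size for g in annotation])
            amps = np.full(cfg.n_genes, base_amp)
            if cond == "case":
                amps = amps * 2.0 ** mark_fold[mark].to_numpy()
            for off_i, w in enumerate(kernel):
                idx = tss_bins + (off_i - khalf)
                ok = (idx >= 0) & (idx < n_bins)
                np.add.at(lam, idx[ok], amps[ok] * w)
            for g, amp in zip(annotation, amps):
                cond_peaks.append(
                    Peak(
                        GenomicInterval(cfg.chrom, max(g.tss - 500, 0), g.tss + 500),
                        name=f"{mark}_{g.gene_id}",
                        score=float(amp),
                    )
                )
            if mark in ("H3K27ac", "H3K4me1"):
                enh_items = [
                    (iv, enh.member_amplitude * (enh.amplification if cond == "case" else 1.0))
                    for iv in se_members
                ]
                for members in decoys:
                    enh_items.extend(members)
                enh_items.extend(background_enh)
                for k, (iv, amp) in enumerate(enh_items):
                    lo_b, hi_b = iv.start // cfg.bin_size, (iv.end - 1) // cfg.bin_size
                    width_bins = hi_b - lo_b + 1
                    lam[lo_b : hi_b + 1] += amp / width_bins
                    cond_peaks.append(
                        Peak(iv, name=f"{mark}_enh_{k}", score=float(amp))
                    )
            peaks[mark][cond] = cond_peaks
            n_rep = cfg.n_control if cond == "control" else cfg.n_case
            reps = []
            for r in range(n_rep):
                f = float(track_rng.uniform(lo, hi))
                chip_depth[f"{mark}_{cond}_{r}"] = f
                vec = track_rng.poisson(lam * f).astype(float)
                reps.append(
                    SignalTrack({cfg.chrom: vec}, cfg.bin_size, float(max(vec.sum(), 1.0)))
                )
            tracks[mark][cond] = reps

    # ---- 4C: fragment map, decay counts, planted bump in the case profile ----
    rng = cfg.rng("fourc")
    fsp = cfg.fourc
    lengths = rng.integers(fsp.min_fragment, fsp.max_fragment + 1, size=fsp.n_fragments)
    bounds = fourc_start + np.concatenate([[0], np.cumsum(lengths)])
    fragments = [
        GenomicInterval(cfg.chrom, int(a), int(b)) for a, b in zip(bounds, bounds[1:])
    ]
    vp = fsp.n_fragments // 2
    fmap = FragmentMap(fragments, vp)
    mids = fmap.midpoints
    dist = np.abs(mids - mids[vp]).astype(float)
    with np.errstate(divide="ignore"):
        lam = fsp.amplitude * np.where(dist > 0, dist, np.nan) ** (-fsp.decay_b)
    lam = np.where(np.isfinite(lam), lam, lam[np.isfinite(lam)].max())
    right_of_vp = np.nonzero((mids - mids[vp]) >= fsp.bump_distance)[0]
    if len(right_of_vp) < fsp.bump_n_fragments:
        raise ValueError("4C span too small for the requested bump placement")
    bump_idx = list(right_of_vp[: fsp.bump_n_fragments])
    fourc_counts = {}
    for cond in ("control", "case"):
        lam_c = lam.copy()
        if cond == "case":
            lam_c[bump_idx] *= fsp.bump_fold
        fourc_counts[cond] = rng.poisson(lam_c)
    bump_interval = GenomicInterval(
        cfg.chrom, fragments[bump_idx[0]].start, fragments[bump_idx[-1]].end
    )

    # ---- promoter sequence with planted consensus motifs ----
    rng = cfg.rng("sequence")
    msp = cfg.motif
    L = len(msp.consensus)
    pfm = np.full((L, 4), (100 - msp.consensus_weight) / 3.0)
    for i, base in enumerate(msp.consensus):
        pfm[i, "ACGT".index(base)] = msp.consensus_weight
    pwm = pwm_from_counts(pfm, motif_id="NFKB_SYNTH")
    target_gene = gene_ids[int(de_idx[0])] if len(de_idx) else gene_ids[0]
    seq_name = f"promoter_{target_gene}"
    planted: List[Tuple[str, int, str]] = []
    for attempt in range(50):
        seq = "".join(rng.choice(list("ACGT"), size=msp.promoter_length))
        # space the planted sites evenly, alternating strands
        positions = np.linspace(100, msp.promoter_length - L - 100, msp.n_planted).astype(int)
        planted = []
        for k, pos in enumerate(positions):
            strand = "+" if k % 2 == 0 else "-"
            site = msp.consensus if strand == "+" else reverse_complement(msp.consensus)
            seq = seq[:pos] + site + seq[pos + L :]
            planted.append((seq_name, int(pos), strand))
        hits = scan(seq, pwm, min_relative_score=0.95)
        if {(h.interval.start, h.strand) for h in hits} == {(p, s) for _, p, s in planted}:
            break
    else:
        raise RuntimeError("could not generate a clean motif-planted sequence")
    sequences = {seq_name: seq}

    # ---- gene sets and regulator models for enrichment ----
    rng = cfg.rng("tables")
    up_ids = [gene_ids[i] for i in np.nonzero(status == 1)[0]]
    down_ids = [gene_ids[i] for i in np.nonzero(status == -1)[0]]
    gene_sets: Dict[str, set] = {}
    if len(up_ids) >= 5:
        gene_sets["PLANTED_UP"] = set(rng.choice(up_ids, size=min(30, len(up_ids)), replace=False))
    if len(down_ids) >= 5:
        gene_sets["PLANTED_DOWN"] = set(
            rng.choice(down_ids, size=min(30, len(down_ids)), replace=False)
        )
    for k in range(3):
        gene_sets[f"RANDOM_{k}"] = set(rng.choice(gene_ids, size=30, replace=False))
    regulators: Dict[str, Dict[str, int]] = {}
    if up_ids and down_ids:
        targets = {g: 1 for g in rng.choice(up_ids, size=min(25, len(up_ids)), replace=False)}
        targets.update(
            {g: -1 for g in rng.choice(down_ids, size=min(5, len(down_ids)), replace=False)}
        )
        regulators["TNFA_LIKE"] = targets

    # ---- qPCR percent-input and 3C tables ----
    true_pi = {"SE_site_control": 0.5, "SE_site_case": 4.0, "neg_site_control": 0.1, "neg_site_case": 0.1}
    qpcr_rows = []
    for site, pi in true_pi.items():
        frac = 0.01
        ct_input = float(rng.uniform(18, 22))
        ct_ip = ct_input - np.log2(1.0 / frac) - np.log2(pi / 100.0)
        qpcr_rows.append(
            {"site": site, "ct_ip": round(ct_ip, 3), "ct_input": round(ct_input, 3), "input_fraction": frac}
        )
    qpcr = pd.DataFrame(qpcr_rows)
    threec_true = {"RASSF6_like": 1.0, "CXCL1_prom": 3.0, "CXCL8_prom": 2.2, "intronic_ctrl": 0.9}
    control_value = 5.0
    threec = {site: control_value * r for site, r in threec_true.items()}

    truth = SyntheticTruth(
        gene_status=pd.Series(status, index=gene_ids),
        true_lfc=pd.Series(true_lfc, index=gene_ids),
        congruent=pd.Series(congruent, index=gene_ids),
        mark_log2fold=mark_fold,
        se_interval=se_interval,
        se_member_intervals=se_members,
        decoy_intervals=decoy_intervals,
        fourc_bump_indices=bump_idx,
        fourc_bump_interval=bump_interval,
        motif_positions=planted,
        depth_factors={**depth, **chip_depth},
        qpcr_true_percent_input=true_pi,
        threec_true_ratios=threec_true,
    )
    return SimulationBundle(
        config=cfg,
        annotation=annotation,
        counts=counts,
        sample_groups=groups,
        peaks=peaks,
        tracks=tracks,
        fourc_map=fmap,
        fourc_counts=fourc_counts,
        sequences=sequences,
        pfms={"NFKB_SYNTH": pfm},
        gene_sets=gene_sets,
        regulators=regulators,
        qpcr=qpcr,
        threec=threec,
        truth=truth,
    )


# ---------------------------------------------------------------------------
# Fixture writing
# ---------------------------------------------------------------------------

def _config_hash(config: SimulationConfig) -> str:
    payload = json.dumps(dataclasses.asdict(config), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_fixture(bundle: SimulationBundle, directory: str | Path) -> Dict[str, object]:
    """Write the bundle as standard-format files plus truth and manifest.

    Returns the manifest (also written as ``manifest.json``): config hash
    and a checksum per file.  Re-writing the same bundle reproduces every
    checksum.
    """
    root = Path(directory)
    (root / "peaks").mkdir(parents=True, exist_ok=True)
    (root / "tracks").mkdir(exist_ok=True)
    cfg = bundle.config
    files: List[str] = []

    bundle.counts.to_csv(root / "counts.tsv", sep="\t")
    files.append("counts.tsv")
    pd.Series(bundle.sample_groups, name="group").rename_axis("sample").to_csv(
        root / "samples.tsv", sep="\t"
    )
    files.append("samples.tsv")
    write_gene_annotation(bundle.annotation, root / "annotation.tsv")
    files.append("annotation.tsv")

    track_rows = []
    for mark, by_cond in bundle.tracks.items():
        for cond, reps in by_cond.items():
            write_bed(bundle.peaks[mark][cond], root / "peaks" / f"{mark}_{cond}.bed")
            files.append(f"peaks/{mark}_{cond}.bed")
            for r, tr in enumerate(reps):
                rel = f"tracks/{mark}_{cond}_rep{r}.bedgraph"
                write_bedgraph(tr, root / rel)
                files.append(rel)
                track_rows.append(
                    {
                        "sample": f"{mark}_{cond}_rep{r}",
                        "condition": cond,
                        "mark": mark,
                        "library_size": tr.library_size,
                        "bin_size": tr.bin_size,
                        "path": rel,
                    }
                )
    pd.DataFrame(track_rows).to_csv(root / "tracks_manifest.tsv", sep="\t", index=False)
    files.append("tracks_manifest.tsv")

    frs = bundle.fourc_map.fragments
    fourc = pd.DataFrame(
        {
            "chrom": [f.chrom for f in frs],
            "start": [f.start for f in frs],
            "end": [f.end for f in frs],
            "control": bundle.fourc_counts["control"],
            "case": bundle.fourc_counts["case"],
            "is_viewpoint": [
                int(i == bundle.fourc_map.viewpoint_index) for i in range(len(frs))
            ],
        }
    )
    fourc.to_csv(root / "fourc_counts.tsv", sep="\t", index=False)
    files.append("fourc_counts.tsv")

    write_fasta(bundle.sequences, root / "sequences.fa")
    files.append("sequences.fa")
    write_jaspar(bundle.pfms, root / "motifs.jaspar")
    files.append("motifs.jaspar")

    from .enrich import write_gmt

    write_gmt(bundle.gene_sets, root / "genesets.gmt")
    files.append("genesets.gmt")
    with open(root / "regulators.tsv", "w") as fh:
        fh.write("regulator\ttarget\tsign\n")
        for reg in sorted(bundle.regulators):
            for target in sorted(bundle.regulators[reg]):
                fh.write(f"{reg}\t{target}\t{bundle.regulators[reg][target]}\n")
    files.append("regulators.tsv")

    bundle.qpcr.to_csv(root / "qpcr.tsv", sep="\t", index=False)
    files.append("qpcr.tsv")
    pd.Series(bundle.threec, name="value").rename_axis("site").to_csv(
        root / "threec.tsv", sep="\t"
    )
    files.append("threec.tsv")

    t = bundle.truth
    truth_payload = {
        "gene_status": t.gene_status.to_dict(),
        "true_lfc": t.true_lfc.to_dict(),
        "congruent": {g: bool(v) for g, v in t.congruent.items()},
        "mark_log2fold": {g: row.to_dict() for g, row in t.mark_log2fold.iterrows()},
        "se_interval": [t.se_interval.chrom, t.se_interval.start, t.se_interval.end],
        "decoy_intervals": [[d.chrom, d.start, d.end] for d in t.decoy_intervals],
        "fourc_viewpoint_index": bundle.fourc_map.viewpoint_index,
        "fourc_bump_indices": t.fourc_bump_indices,
        "fourc_bump_interval": [
            t.fourc_bump_interval.chrom, t.fourc_bump_interval.start, t.fourc_bump_interval.end,
        ],
        "motif_positions": t.motif_positions,
        "depth_factors": t.depth_factors,
        "qpcr_true_percent_input": t.qpcr_true_percent_input,
        "threec_true_ratios": t.threec_true_ratios,
    }
    def _jsonify(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON-serializable: {type(o)}")

    with open(root / "truth.json", "w") as fh:
        json.dump(truth_payload, fh, indent=1, sort_keys=True, default=_jsonify)
    files.append("truth.json")

    manifest = {
        "config_hash": _config_hash(cfg),
        "config": dataclasses.asdict(cfg),
        "files": {f: _sha256(root / f) for f in sorted(files)},
    }
    with open(root / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True, default=str)
    return manifest
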