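"""Configuration-driven end-to-end orchestration.

Stages communicate only through files (each is independently runnable on
its TSV/BED/bedGraph inputs): simulate -> differential expression ->
occupancy -> integration -> enrichment, with super-enhancer calling, motif
scanning, 4C profiling and qPCR/3C quantification as parallel branches.
A run manifest records the config hash, per-stage outputs with checksums
and wall times; identical config + seed reproduces every deterministic
checksum.
"""

from __future__ import annotations

import dataclasses
import difflib
import hashlib
import json
import logging
import os
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .core import SignalTrack, read_bed, read_bedgraph, read_fasta, read_gene_annotation, write_bed
from .diffexpr import classify_de, test_two_group
from .enrich import (
    gsea_rank_from_de,
    gsea_significance,
    overrepresentation,
    read_gmt,
    regulator_z,
)
from .integrate import congruence_classify, summarize_integration
from .interaction import (
    FragmentMap,
    call_interactions,
    fit_decay,
    percent_input,
    profile,
    relative_interaction_frequency,
)
from .motifs import hits_to_bed, pwm_from_counts, read_jaspar, scan
from .occupancy import MARKS, differential_occupancy
from .rose import plot_data, rank_and_cut, rank_report, score_regions, stitch
from .simulate import SimulationConfig, simulate_study, write_fixture
from .core import GenomicInterval

logger = logging.getLogger(__name__)


@dataclass
class Thresholds:
    fdr_max: float = 0.01
    lfc_min: float = 1.5
    occupancy_fdr_max: float = 0.05
    occupancy_halfwidth: int = 2000
    min_supporting_marks: int = 1
    min_relative_score: float = 0.95
    stitch_distance: int = 12_500
    tss_exclusion: int = 2_500
    z_min: float = 2.0
    min_run: int = 3
    exclude_k: int = 2
    n_perm: int = 1000
    threec_control_site: str = "RASSF6_like"

    def validate(self) -> None:
        checks = [
            ("fdr_max", 0 < self.fdr_max <= 1),
            ("lfc_min", self.lfc_min >= 0),
            ("occupancy_fdr_max", 0 < self.occupancy_fdr_max <= 1),
            ("occupancy_halfwidth", self.occupancy_halfwidth > 0),
            ("min_supporting_marks", self.min_supporting_marks >= 1),
            ("min_relative_score", 0 <= self.min_relative_score <= 1),
            ("stitch_distance", self.stitch_distance >= 0),
            ("tss_exclusion", self.tss_exclusion >= 0),
            ("z_min", self.z_min >= 0),
            ("min_run", self.min_run >= 1),
            ("exclude_k", self.exclude_k >= 0),
            ("n_perm", self.n_perm >= 100),
        ]
        for key, ok in checks:
            if not ok:
                raise ConfigError(f"threshold {key!r} out of range: {getattr(self, key)}")


@dataclass
class PipelineConfig:
    output_dir: str
    seed: int = 0
    simulate: Optional[SimulationConfig] = None
    inputs: Dict[str, str] = field(default_factory=dict)
    thresholds: Thresholds = field(default_factory=Thresholds)


class ConfigError(ValueError):
    pass


def _check_keys(given: dict, allowed: List[str], context: str) -> None:
    for key in given:
        if key not in allowed:
            hint = difflib.get_close_matches(key, allowed, n=1)
            suffix = f"; did you mean {hint[0]!r}?" if hint else ""
            raise ConfigError(f"unknown key {key!r} in {context}{suffix}")


def validate_config(path: str | Path) -> PipelineConfig:
    """Load and strictly validate a YAML pipeline configuration.

    Unknown keys are rejected with a closest-match suggestion; thresholds
    are range-checked; referenced input files must exist.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigError("config must be a mapping")
    top_allowed = ["output_dir", "seed", "simulate", "inputs", "thresholds"]
    _check_keys(raw, top_allowed, "config")
    if "output_dir" not in raw:
        raise ConfigError("missing required key 'output_dir'")

    sim = None
    if raw.get("simulate") is not None:
        sim_raw = dict(raw["simulate"])
        sim_fields = {f.name for f in dataclasses.fields(SimulationConfig)}
        _check_keys(sim_raw, sorted(sim_fields), "simulate")
        nested = {}
        for key in ("enhancer", "fourc", "motif"):
            if key in sim_raw:
                sub = sim_raw.pop(key)
                cls = type(getattr(SimulationConfig(), key))
                _check_keys(sub, [f.name for f in dataclasses.fields(cls)], f"simulate.{key}")
                nested[key] = cls(**sub)
        sim_raw.setdefault("seed", raw.get("seed", 0))
        if "depth_factor_range" in sim_raw:
            sim_raw["depth_factor_range"] = tuple(sim_raw["depth_factor_range"])
        sim = SimulationConfig(**sim_raw, **nested)
        sim.validate()

    thresholds = Thresholds()
    if raw.get("thresholds"):
        th_fields = [f.name for f in dataclasses.fields(Thresholds)]
        _check_keys(raw["thresholds"], th_fields, "thresholds")
        thresholds = Thresholds(**raw["thresholds"])
    thresholds.validate()

    inputs = dict(raw.get("inputs") or {})
    for name, p in inputs.items():
        if not Path(p).exists():
            raise ConfigError(f"input {name!r} points to a missing file: {p}")
    if sim is None and not inputs:
        raise ConfigError("either a 'simulate' block or 'inputs' paths are required")

    return PipelineConfig(
        output_dir=str(raw["output_dir"]),
        seed=int(raw.get("seed", 0)),
        simulate=sim,
        inputs=inputs,
        thresholds=thresholds,
    )


# ---------------------------------------------------------------------------
# Individual stages (file in -> file out)
# ---------------------------------------------------------------------------

def stage_de(counts_path, samples_path, out_path, thresholds: Thresholds) -> None:
    counts = pd.read_csv(counts_path, sep="\t", index_col=0)
    samples = pd.read_csv(samples_path, sep="\t", index_col=0)["group"]
    groups = [samples[s] for s in counts.columns]
    de = classify_de(
        test_two_group(counts, groups, control="control"),
        fdr_max=thresholds.fdr_max,
        lfc_min=thresholds.lfc_min,
    )
    de.to_csv(out_path, sep="\t")


def _load_tracks(manifest: pd.DataFrame, base: Path, mark: str, cond: str) -> List[SignalTrack]:
    rows = manifest[(manifest["mark"] == mark) & (manifest["condition"] == cond)]
    return [
        read_bedgraph(base / r.path, int(r.bin_size), float(r.library_size))
        for r in rows.itertuples()
    ]


def stage_occupancy(
    tracks_manifest_path, annotation_path, out_dir, thresholds: Thresholds
) -> Dict[str, Path]:
    manifest = pd.read_csv(tracks_manifest_path, sep="\t")
    base = Path(tracks_manifest_path).parent
    annotation = read_gene_annotation(annotation_path, dialect="tsv")
    out_dir = Path(out_dir)
    outputs = {}
    for mark in sorted(manifest["mark"].unique()):
        case = _load_tracks(manifest, base, mark, "case")
        control = _load_tracks(manifest, base, mark, "control")
        table = differential_occupancy(
            case, control, annotation, mark,
            halfwidth=thresholds.occupancy_halfwidth,
            occupancy_fdr_max=thresholds.occupancy_fdr_max,
        )
        path = out_dir / f"occupancy_{mark}.tsv"
        table.to_csv(path, sep="\t")
        outputs[mark] = path
    return outputs


def stage_integrate(de_path, occupancy_paths: Dict[str, Path], out_dir, thresholds: Thresholds) -> None:
    de = pd.read_csv(de_path, sep="\t", index_col=0)
    occ = {m: pd.read_csv(p, sep="\t", index_col=0) for m, p in occupancy_paths.items()}
    calls, summary = congruence_classify(de, occ, thresholds.min_supporting_marks)
    out_dir = Path(out_dir)
    export = calls.copy()
    if not export.empty:
        export["supporting_marks"] = export["supporting_marks"].map(
            lambda ms: ";".join(f"{m}:{d}" for m, d in ms)
        )
    export.to_csv(out_dir / "integration_calls.tsv", sep="\t")
    report = summarize_integration(calls, occ)
    with open(out_dir / "integration_summary.json", "w") as fh:
        json.dump({"counts": report["counts"], "mark_support_frequency": report["mark_support_frequency"]}, fh, indent=1, sort_keys=True)


def stage_rose(
    peaks_path, tracks: List[SignalTrack], annotation_path, out_prefix, thresholds: Thresholds
) -> None:
    peaks = read_bed(peaks_path)
    annotation = read_gene_annotation(annotation_path, dialect="tsv")
    chroms = {c for t in tracks for c in t.data}
    pooled_data = {}
    for c in chroms:
        vecs = [t.data[c] for t in tracks if c in t.data]
        n = max(len(v) for v in vecs)  # replicates may omit trailing zero bins
        acc = np.zeros(n)
        for v in vecs:
            acc[: len(v)] += v
        pooled_data[c] = acc
    pooled = SignalTrack(pooled_data, tracks[0].bin_size, sum(t.library_size for t in tracks))
    regions = stitch(peaks, annotation, thresholds.stitch_distance, thresholds.tss_exclusion)
    ranking = rank_and_cut(score_regions(regions, pooled))
    report = rank_report(ranking, annotation)
    report.to_csv(f"{out_prefix}_ranking.tsv", sep="\t", index=False)
    plot_data(ranking).to_csv(f"{out_prefix}_plotdata.tsv", sep="\t", index=False)
    supers = [r.interval for r, s in zip(ranking.regions, ranking.is_super) if s]
    from .core import Peak

    write_bed(
        [Peak(iv, name=f"SE_{k}") for k, iv in enumerate(sorted(supers, key=lambda i: i.start))],
        f"{out_prefix}_superenhancers.bed",
    )


def stage_motif(sequences_path, motifs_path, out_path, thresholds: Thresholds) -> None:
    sequences = read_fasta(sequences_path)
    pfms = read_jaspar(motifs_path)
    all_hits = []
    for motif_id, counts in pfms.items():
        pwm = pwm_from_counts(counts, motif_id=motif_id)
        for name, seq in sequences.items():
            all_hits.extend(
                scan(seq, pwm, min_relative_score=thresholds.min_relative_score, chrom=name)
            )
    hits_to_bed(all_hits, out_path)


def stage_enrichment(de_path, genesets_path, regulators_path, out_dir, seed: int, thresholds: Thresholds) -> None:
    de = pd.read_csv(de_path, sep="\t", index_col=0)
    gene_sets = read_gmt(genesets_path)
    ranked = gsea_rank_from_de(de)
    gsea = gsea_significance(ranked, gene_sets, n_perm=thresholds.n_perm, seed=seed)
    out_dir = Path(out_dir)
    gsea.to_csv(out_dir / "gsea.tsv", sep="\t")
    hits = de.index[de["call"] != "ns"].astype(str)
    ora = overrepresentation(hits, de.index.astype(str), gene_sets)
    ora.to_csv(out_dir / "ora.tsv", sep="\t")
    reg = pd.read_csv(regulators_path, sep="\t")
    de_calls = de["call"].to_dict()
    rows = []
    for regulator, grp in reg.groupby("regulator"):
        model = dict(zip(grp["target"].astype(str), grp["sign"].astype(int)))
        z = regulator_z(model, de_calls)
        rows.append({"regulator": regulator, "n_targets": len(model), "z": z})
    pd.DataFrame(rows).to_csv(out_dir / "regulator_z.tsv", sep="\t", index=False)


def stage_fourc(fourc_path, out_dir, thresholds: Thresholds) -> None:
    table = pd.read_csv(fourc_path, sep="\t")
    fragments = [
        GenomicInterval(r.chrom, int(r.start), int(r.end)) for r in table.itertuples()
    ]
    vp = int(table.index[table["is_viewpoint"] == 1][0])
    fmap = FragmentMap(fragments, vp)
    out_dir = Path(out_dir)
    for cond in ("control", "case"):
        prof = fit_decay(
            profile(table[cond].to_numpy(), fmap, exclude_k=thresholds.exclude_k, condition=cond)
        )
        calls = call_interactions(prof, thresholds.z_min, thresholds.min_run)
        pd.DataFrame(
            {
                "chrom": [f.chrom for f in fragments],
                "start": [f.start for f in fragments],
                "end": [f.end for f in fragments],
                "raw": prof.raw_counts,
                "normalized": prof.normalized,
                "distance": prof.distance,
                "expectation": prof.expectation,
                "residual_z": prof.residual_z,
                "masked": prof.masked,
            }
        ).to_csv(out_dir / f"fourc_profile_{cond}.tsv", sep="\t", index=False)
        with open(out_dir / f"fourc_calls_{cond}.bed", "w") as fh:
            for k, iv in enumerate(calls):
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\tinteraction_{k}\n")
        with open(out_dir / f"fourc_decay_{cond}.json", "w") as fh:
            json.dump({"a": prof.decay_a, "b": prof.decay_b, "flagged": prof.decay_flagged}, fh)


def stage_qpcr(qpcr_path, threec_path, out_dir, thresholds: Thresholds) -> None:
    out_dir = Path(out_dir)
    qpcr = pd.read_csv(qpcr_path, sep="\t")
    percent_input(qpcr).to_csv(out_dir / "qpcr_percent_input.tsv", sep="\t", index=False)
    threec = pd.read_csv(threec_path, sep="\t", index_col=0)["value"]
    rif = relative_interaction_frequency(threec.to_dict(), thresholds.threec_control_site)
    rif.rename("relative_frequency").rename_axis("site").to_csv(
        out_dir / "threec_relative_frequency.tsv", sep="\t"
    )


# ---------------------------------------------------------------------------
# run_all
# ---------------------------------------------------------------------------

def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_all(config: PipelineConfig) -> Dict[str, object]:
    """Execute every stage in dependency order, returning the run manifest.

    Stage failures abort the run with the stage name; outputs of completed
    stages are preserved on disk.
    """
    config.thresholds.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: Dict[str, object] = {
        "version": __version__,
        "seed": config.seed,
        "thresholds": dataclasses.asdict(config.thresholds),
        "stages": {},
    }
    inputs = dict(config.inputs)

    def run_stage(name, fn, *args, **kwargs):
        t0 = time.time()
        try:
            fn(*args, **kwargs)
        except Exception as exc:
            raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
        manifest["stages"][name] = {"wall_time_s": round(time.time() - t0, 3)}

    # simulate
    if config.simulate is not None:
        t0 = time.time()
        fixture_dir = out / "fixture"
        bundle = simulate_study(config.simulate)
        fix_manifest = write_fixture(bundle, fixture_dir)
        manifest["stages"]["simulate"] = {
            "wall_time_s": round(time.time() - t0, 3),
            "config_hash": fix_manifest["config_hash"],
        }
        for key in (
            "counts", "samples", "annotation", "tracks_manifest",
            "fourc_counts", "sequences", "motifs", "genesets", "regulators",
            "qpcr", "threec",
        ):
            filename = {
                "counts": "counts.tsv", "samples": "samples.tsv",
                "annotation": "annotation.tsv", "tracks_manifest": "tracks_manifest.tsv",
                "fourc_counts": "fourc_counts.tsv", "sequences": "sequences.fa",
                "motifs": "motifs.jaspar", "genesets": "genesets.gmt",
                "regulators": "regulators.tsv", "qpcr": "qpcr.tsv", "threec": "threec.tsv",
            }[key]
            inputs.setdefault(key, str(fixture_dir / filename))
    manifest["config_hash"] = hashlib.sha256(
        json.dumps(
            {
                "seed": config.seed,
                "thresholds": dataclasses.asdict(config.thresholds),
                "simulate": dataclasses.asdict(config.simulate) if config.simulate else None,
                "inputs": inputs,
            },
            sort_keys=True,
            default=str,
        ).encode()
    ).hexdigest()

    th = config.thresholds
    run_stage("de", stage_de, inputs["counts"], inputs["samples"], out / "de.tsv", th)
    occupancy_paths = {}

    def _occ():
        nonlocal occupancy_paths
        occupancy_paths = stage_occupancy(
            inputs["tracks_manifest"], inputs["annotation"], out, th
        )

    run_stage("occupancy", _occ)
    run_stage("integrate", stage_integrate, out / "de.tsv", occupancy_paths, out, th)

    def _rose():
        track_manifest = pd.read_csv(inputs["tracks_manifest"], sep="\t")
        base = Path(inputs["tracks_manifest"]).parent
        peaks_dir = base / "peaks"
        for cond in sorted(track_manifest["condition"].unique()):
            tracks = _load_tracks(track_manifest, base, "H3K27ac", cond)
            stage_rose(
                peaks_dir / f"H3K27ac_{cond}.bed", tracks, inputs["annotation"],
                out / f"rose_{cond}", th,
            )

    run_stage("rose", _rose)
    run_stage("motif", stage_motif, inputs["sequences"], inputs["motifs"], out / "motif_hits.bed", th)
    run_stage(
        "enrichment", stage_enrichment,
        out / "de.tsv", inputs["genesets"], inputs["regulators"], out, config.seed, th,
    )
    run_stage("fourc", stage_fourc, inputs["fourc_counts"], out, th)
    run_stage("qpcr", stage_qpcr, inputs["qpcr"], inputs["threec"], out, th)

    # checksums of every output file (excluding the manifest itself)
    checksums = {
        str(p.relative_to(out)): _sha256(p)
        for p in sorted(out.rglob("*"))
        if p.is_file() and p.name != "run_manifest.json"
    }
    manifest["output_checksums"] = checksums
    tmp = out / "run_manifest.json.tmp"
    with open(tmp, "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True, default=str)
    os.replace(tmp, out / "run_manifest.json")
    return manifest
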