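"""End-to-end orchestration: simulate -> coverage -> profile -> resection
-> peaks -> overlap for a set of declared samples.

Driven by a YAML run config. Replicates (one per listed seed) are
RPM-normalized individually and averaged for profile/resection work;
raw counts are pooled for peak calling. Every run writes a
machine-readable ``manifest.json`` (config hash, seeds, per-stage record
counts, summary numbers) so downstream checks can assert provenance.
Identical configs give byte-identical manifests and outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import yaml

from .genome import GenomeSpec, HotspotSet
from .peaks import call_peaks, overlap_with_hotspots, write_peaks_bed
from .resection import mean_resection_length, resection_length_distribution
from .signal import (StrandTrack, bin_coverage, cooriented_average, rpm_normalize,
                     smooth_profile)
from .simulate import genotype_preset, simulate_end_reads, simulate_hotspots
from .tracks_io import (AnalysisConfig, write_bedgraph, write_endmap_bed,
                        write_genome, write_hotspots)
from .genome import TOP, BOTTOM

logger = logging.getLogger("dsbend")


def _load_genome(spec: dict | str) -> GenomeSpec:
    if isinstance(spec, str):
        from .tracks_io import read_genome
        return read_genome(spec)
    par = tuple(spec["par"]) if spec.get("par") else None
    return GenomeSpec(chroms={k: int(v) for k, v in spec["chroms"].items()}, par=par)


def _write_profile_tsv(path: Path, distances: np.ndarray, values: np.ndarray) -> None:
    with open(path, "w") as fh:
        fh.write("distance_bp\tvalue\n")
        for d, v in zip(distances, values):
            fh.write(f"{int(d)}\t{v:.10g}\n")


def _write_dist_tsv(path: Path, dist) -> None:
    with open(path, "w") as fh:
        fh.write("bin_start\tbin_end\tfraction\n")
        for a, b, f in zip(dist.bin_edges[:-1], dist.bin_edges[1:], dist.fractions):
            fh.write(f"{int(a)}\t{int(b)}\t{f:.10g}\n")


def run_pipeline(config_path: str | Path, outdir: str | Path | None = None) -> Path:
    """Execute the full pipeline for every sample declared in the config.

    Returns the run directory. Any stage failure aborts with the stage
    name and offending sample in the exception message.
    """
    config_path = Path(config_path)
    raw = config_path.read_bytes()
    config = yaml.safe_load(raw) or {}
    run_dir = Path(outdir or config.get("outdir", "dsbend_run"))
    run_dir.mkdir(parents=True, exist_ok=True)

    cfg = AnalysisConfig.from_mapping(config.get("analysis", {}))
    peak_cfg = config.get("peaks", {})
    samples = config.get("samples", [])
    manifest: dict = {
        "config_sha256": hashlib.sha256(raw).hexdigest(),
        "n_samples": len(samples),
        "samples": {},
    }
    if not samples:
        (run_dir / "manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True) + "\n")
        return run_dir

    genome = _load_genome(config.get("genome", {"chroms": {"chr1": 10_000_000}}))
    write_genome(genome, run_dir / "genome.tsv")

    hs_cfg = config.get("hotspots", {})
    prdm9 = simulate_hotspots(genome, n=int(hs_cfg.get("n_prdm9", 2000)),
                              heat_shape=float(hs_cfg.get("heat_shape", 2.5)),
                              hclass="prdm9",
                              min_spacing=int(hs_cfg.get("min_spacing", 10_000)),
                              seed=int(hs_cfg.get("seed", 11)))
    default = simulate_hotspots(genome, n=int(hs_cfg.get("n_default", 1000)),
                                heat_shape=float(hs_cfg.get("heat_shape", 2.5)),
                                hclass="default",
                                min_spacing=int(hs_cfg.get("min_spacing", 10_000)),
                                seed=int(hs_cfg.get("seed", 11)) + 1)
    catalog = HotspotSet.concat([prdm9, default])
    write_hotspots(prdm9, run_dir / "hotspots_prdm9.tsv")
    write_hotspots(default, run_dir / "hotspots_default.tsv")

    for sample in samples:
        name = sample["name"]
        try:
            params = genotype_preset(sample["preset"])
            overrides = {k: sample[k] for k in ("total_reads",) if k in sample}
            seeds = [int(s) for s in sample.get("seeds", [params.seed])]
            raw_tracks, rpm_tracks = [], []
            n_reads = []
            for seed in seeds:
                p = params.replace(seed=seed, **overrides)
                ends = simulate_end_reads(genome, catalog, p)
                n_reads.append(ends.n_mapped)
                if sample.get("write_ends", False):
                    write_endmap_bed(ends, run_dir / f"{name}.rep{seed}.ends.bed")
                track = bin_coverage(ends, genome, cfg.profile_bin_bp)
                raw_tracks.append(track)
                rpm_tracks.append(rpm_normalize(track))
            avg = StrandTrack.average(rpm_tracks)
            write_bedgraph(avg, TOP, run_dir / f"{name}.top.bedgraph")
            write_bedgraph(avg, BOTTOM, run_dir / f"{name}.bottom.bedgraph")

            profile = cooriented_average(avg, prdm9, cfg, combine=True)
            window_bins = (cfg.hann_window_bp if cfg.profile_bin_bp == 1
                           else cfg.hann_window_bins)
            sm = smooth_profile(profile, window_bins)
            _write_profile_tsv(run_dir / f"{name}.profile.tsv", sm.distances, sm.values)

            dist = resection_length_distribution(sm, cfg)
            _write_dist_tsv(run_dir / f"{name}.resection.tsv", dist)

            pooled = StrandTrack.pool(raw_tracks)
            peaks = call_peaks(pooled, window=int(peak_cfg.get("window", 1000)),
                               q_threshold=float(peak_cfg.get("q", 0.01)),
                               merge_gap=int(peak_cfg.get("merge_gap", 500)))
            write_peaks_bed(peaks, run_dir / f"{name}.peaks.bed")
            overlap = overlap_with_hotspots(peaks, prdm9, default,
                                            halfwidth=cfg.hotspot_halfwidth_bp,
                                            genotype=name)
            manifest["samples"][name] = {
                "preset": sample["preset"],
                "seeds": seeds,
                "n_reads": n_reads,
                "n_profile_hotspots": profile.n_hotspots,
                "resection_degenerate": bool(dist.degenerate),
                "mean_resection_nt": (None if dist.degenerate
                                      else round(mean_resection_length(dist), 3)),
                "n_peaks": overlap.n_peaks,
                "n_overlap_prdm9": overlap.n_overlap_prdm9,
                "n_overlap_default": overlap.n_overlap_default,
                "n_overlap_both": overlap.n_overlap_both,
                "n_neither": overlap.n_neither,
            }
        except Exception as err:
            raise RuntimeError(f"pipeline failed for sample {name!r}: {err}") from err

    (run_dir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    logger.info("run_pipeline: wrote %s", run_dir / "manifest.json")
    return run_dir
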