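"""End-to-end orchestration: genotypes -> windows -> thresholds -> sweeps
-> overlaps -> heat maps, from one declarative configuration.

Every intermediate artifact is written to the output directory and the run
closes with a JSON manifest recording parameter values, the seed, package
versions and a SHA-256 checksum of every output file; rerunning the same
configuration and seed reproduces identical checksums.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from sweepscan.errors import ConfigurationError, SweepscanError
from sweepscan.genome import DEFAULT_WINDOW_BP, GenomeLayout
from sweepscan.overlaps import (
    TURKEY_POPULATION_CLASSES,
    find_overlaps,
    overlap_summary,
    write_overlaps_bed,
)
from sweepscan.plotting import HeatmapSpec, render_heatmap
from sweepscan.sweeps import call_sweeps, sweep_summary, write_sweeps_bed, write_sweeps_tsv
from sweepscan.synthetic import (
    SimulationConfig,
    simulate_genotypes,
    write_population_vcfs,
    write_overlap_regions_tsv,
)
from sweepscan.threshold import permute_and_estimate
from sweepscan.windows import read_vcf_genotypes, track_from_genotypes

log = logging.getLogger("sweepscan")


@dataclass
class RunConfig:
    outdir: Path
    seed: int = 0
    simulation: SimulationConfig | None = None
    vcfs: dict[str, Path] = field(default_factory=dict)
    layout: GenomeLayout | None = None  # required in VCF mode
    window_bp: int = DEFAULT_WINDOW_BP
    run_len: int = 5
    n_reps: int = 7000
    alpha: float = 0.05
    min_depth: int = 5
    max_depth: int = 10
    min_gq: int = 20
    population_classes: dict[str, str] = field(default_factory=dict)
    heatmaps: bool = True

    def __post_init__(self) -> None:
        self.outdir = Path(self.outdir)
        if self.n_reps < 1:
            raise ConfigurationError("n_reps must be >= 1")
        if not 0 < self.alpha < 1:
            raise ConfigurationError("alpha must lie in (0, 1)")
        if self.simulation is None and not self.vcfs:
            raise ConfigurationError("either a simulation or per-population VCFs required")
        if self.simulation is None and self.layout is None:
            raise ConfigurationError("a genome layout is required with VCF input")

    @property
    def populations(self) -> list[str]:
        if self.simulation is not None:
            return [p for p, _ in self.simulation.populations]
        return list(self.vcfs)

    def classes(self) -> dict[str, str]:
        if self.population_classes:
            return self.population_classes
        pops = self.populations
        if all(p in TURKEY_POPULATION_CLASSES for p in pops):
            return {p: TURKEY_POPULATION_CLASSES[p] for p in pops}
        return {p: "unclassified" for p in pops}

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        base = Path(path).parent
        sim = None
        layout = None
        if "simulation" in raw:
            sim = SimulationConfig.from_dict(raw["simulation"], seed=raw.get("seed", 0))
        elif "layout" in raw:
            layout = GenomeLayout.from_tsv(base / raw["layout"])
        filters = raw.get("filters", {})
        return cls(
            outdir=base / raw["outdir"],
            seed=int(raw.get("seed", 0)),
            simulation=sim,
            vcfs={p: base / v for p, v in raw.get("vcfs", {}).items()},
            layout=layout,
            window_bp=int(raw.get("window_bp", DEFAULT_WINDOW_BP)),
            run_len=int(raw.get("run_len", 5)),
            n_reps=int(raw.get("n_reps", 7000)),
            alpha=float(raw.get("alpha", 0.05)),
            min_depth=int(filters.get("min_depth", 5)),
            max_depth=int(filters.get("max_depth", 10)),
            min_gq=int(filters.get("min_gq", 20)),
            population_classes=raw.get("classes", {}),
            heatmaps=bool(raw.get("heatmaps", True)),
        )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _pop_seed(seed: int, index: int) -> int:
    return int(np.random.SeedSequence([seed, 7, index]).generate_state(1)[0])


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage and return the manifest (also written as JSON)."""
    outdir = config.outdir
    outdir.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, Path] = {}
    stage = "setup"
    try:
        if config.simulation is not None:
            stage = "simulate"
            records = simulate_genotypes(config.simulation)
            log.info("simulate: %d genotype records", len(records))
            vcf_paths = write_population_vcfs(records, config.simulation, outdir / "vcf")
            layout = config.simulation.layout
            layout_path = outdir / "layout.tsv"
            layout.to_tsv(layout_path)
            artifacts["layout"] = layout_path
            for pop, p in vcf_paths.items():
                artifacts[f"vcf/{pop}"] = p
        else:
            vcf_paths = dict(config.vcfs)
            layout = config.layout

        stage = "windows"
        tracks = {}
        for pop, vcf_path in vcf_paths.items():
            records, samples = read_vcf_genotypes(vcf_path, pop)
            tracks[pop] = track_from_genotypes(
                records,
                pop,
                layout,
                individuals=samples,
                window_bp=config.window_bp,
                min_depth=config.min_depth,
                max_depth=config.max_depth,
                min_gq=config.min_gq,
            )
            path = outdir / f"{pop}.windows.tsv"
            tracks[pop].to_tsv(path)
            artifacts[f"windows/{pop}"] = path
            log.info("windows: %s, %d retained calls in %d bins",
                     pop, int(tracks[pop].frame["het_count"].sum()), tracks[pop].n_bins)

        stage = "threshold"
        thresholds = {}
        for i, pop in enumerate(vcf_paths):
            res = permute_and_estimate(
                tracks[pop],
                run_len=config.run_len,
                n_reps=config.n_reps,
                alpha=config.alpha,
                seed=_pop_seed(config.seed, i),
            )
            thresholds[pop] = res
            path = outdir / f"{pop}.threshold.json"
            res.to_json(path, include_replicates=False)
            artifacts[f"threshold/{pop}"] = path
            log.info("threshold: %s = %.3g", pop, res.genome_wide_threshold)

        stage = "call"
        sweeps = {}
        for pop in vcf_paths:
            sweeps[pop] = call_sweeps(
                tracks[pop], thresholds[pop].genome_wide_threshold, config.run_len
            )
            bed = outdir / f"{pop}.sweeps.bed"
            write_sweeps_bed(sweeps[pop], bed)
            write_sweeps_tsv(sweeps[pop], outdir / f"{pop}.sweeps.tsv")
            artifacts[f"sweeps/{pop}"] = bed
            log.info("call: %s, %d sweeps", pop, len(sweeps[pop]))

        stage = "overlap"
        overlaps, specifics = find_overlaps(sweeps)
        write_overlap_regions_tsv(overlaps, outdir / "overlaps.tsv")
        write_overlaps_bed(overlaps, outdir / "overlaps.bed")
        summary = {
            "sweeps": sweep_summary(sweeps),
            "overlaps": overlap_summary(overlaps, specifics, config.classes()),
        }
        with open(outdir / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=2)
        artifacts["overlaps"] = outdir / "overlaps.tsv"
        artifacts["overlaps_bed"] = outdir / "overlaps.bed"
        artifacts["summary"] = outdir / "summary.json"
        log.info("overlap: %d overlap regions, %d population-specific sweeps",
                 len(overlaps), len(specifics))

        if config.heatmaps:
            stage = "heatmap"
            track_list = [tracks[p] for p in vcf_paths]
            ann = [(ov.chromosome, ov.start, ov.end) for ov in overlaps]
            path = render_heatmap(
                HeatmapSpec(tracks=track_list, region=None,
                            out=outdir / "genome.heatmap.png", annotations=ann)
            )
            artifacts["heatmap/genome"] = path
    except SweepscanError as exc:
        raise SweepscanError(f"stage {stage!r} failed: {exc}") from exc

    import pandas

    manifest = {
        "tool": "sweepscan",
        "version": __import__("sweepscan").__version__,
        "library_versions": {"numpy": np.__version__, "pandas": pandas.__version__},
        "seed": config.seed,
        "parameters": {
            "window_bp": config.window_bp,
            "run_len": config.run_len,
            "n_reps": config.n_reps,
            "alpha": config.alpha,
            "min_depth": config.min_depth,
            "max_depth": config.max_depth,
            "min_gq": config.min_gq,
        },
        "populations": config.populations,
        "thresholds": {p: t.genome_wide_threshold for p, t in thresholds.items()},
        "n_overlap_regions": len(overlaps),
        "overlap_populations": [sorted(ov.populations) for ov in overlaps],
        "outputs": {k: {"path": str(p.relative_to(outdir)), "sha256": _sha256(p)}
                    for k, p in sorted(artifacts.items())},
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
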