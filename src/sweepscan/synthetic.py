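"""Synthetic genotype-call datasets with planted low-diversity regions.

The generator emulates the downstream product of whole-genome resequencing
plus per-individual SNP genotype calling: for every individual it scatters
heterozygous sites along each chromosome as a homogeneous Poisson process
with rate ``theta`` per bp (about one heterozygous SNP per Kb in domestic
turkey), reduced by a multiplicative factor inside *planted sweeps* —
contiguous intervals that stand in for regions driven toward fixation.
Homozygous non-reference sites are scattered at an independent flat rate.
Each emitted call carries a read depth and a Phred-scaled genotype quality
drawn from configurable discrete distributions whose defaults straddle the
downstream retention filters (depth 5–10, GQ >= 20), so both filter branches
are exercised.

No linkage, recombination or coalescent structure is simulated: every site
and every individual is independent.  That is exactly the structure the
window/permutation analysis assumes under its null.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from sweepscan.errors import ConfigurationError, CoordinateError, FixtureParseError
from sweepscan.genome import GenomeLayout
from sweepscan.overlaps import OverlapRegion

#: Background heterozygosity of domestic turkey: ~1.07 heterozygous SNPs
#: per Kb per individual.
DEFAULT_THETA = 1.07e-3

#: Homozygous non-reference sites per bp; lower than the heterozygous rate,
#: as expected when the reference assembly is itself a domestic bird.
DEFAULT_HOM_NONREF_RATE = 2e-4

GENOTYPE_CLASSES = ("hom_ref", "het", "hom_nonref")

_FIXTURE_COLUMNS = (
    "chrom",
    "sweep_start",
    "sweep_end",
    "overlap_start",
    "overlap_end",
    "populations",
)


@dataclass(frozen=True)
class GenotypeRecord:
    """One genotype call for one individual at one site (1-based position)."""

    chromosome: str
    position: int
    individual: str
    population: str
    genotype_class: str
    depth: int
    genotype_quality: int


class DiscreteDistribution:
    """A finite discrete distribution over integers, sampled with numpy."""

    def __init__(self, values, probs) -> None:
        self.values = np.asarray(values, dtype=np.int64)
        self.probs = np.asarray(probs, dtype=float)
        if self.values.shape != self.probs.shape:
            raise ConfigurationError("values and probs must have equal length")
        if np.any(self.probs < 0) or not np.isclose(self.probs.sum(), 1.0):
            raise ConfigurationError("probabilities must be non-negative and sum to 1")
        self.probs = self.probs / self.probs.sum()

    @classmethod
    def uniform_int(cls, low: int, high: int) -> "DiscreteDistribution":
        """Uniform over the inclusive integer range [low, high]."""
        vals = np.arange(low, high + 1)
        return cls(vals, np.full(len(vals), 1.0 / len(vals)))

    @classmethod
    def mixture(cls, components, weights) -> "DiscreteDistribution":
        values: dict[int, float] = {}
        for comp, w in zip(components, weights):
            for v, p in zip(comp.values, comp.probs):
                values[int(v)] = values.get(int(v), 0.0) + w * float(p)
        vals = sorted(values)
        return cls(vals, [values[v] for v in vals])

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        return rng.choice(self.values, size=n, p=self.probs)

    def mean(self) -> float:
        return float(np.dot(self.values, self.probs))


def default_depth_model() -> DiscreteDistribution:
    # Uniform over 2..12: spans both the retained 5-10x band and depths
    # rejected on either side.
    return DiscreteDistribution.uniform_int(2, 12)


def default_gq_model() -> DiscreteDistribution:
    # 85% of calls at GQ >= 20 (uniform 20..60), 15% below the cutoff.
    return DiscreteDistribution.mixture(
        [DiscreteDistribution.uniform_int(0, 19), DiscreteDistribution.uniform_int(20, 60)],
        [0.15, 0.85],
    )


@dataclass(frozen=True)
class PlantedSweep:
    """A contiguous interval of reduced diversity, planted in one population
    or (``population='shared'``) in every population."""

    population: str
    chromosome: str
    start: int  # 0-based, half-open
    end: int
    reduction: float  # multiplies theta inside [start, end)

    def applies_to(self, population: str) -> bool:
        return self.population == "shared" or self.population == population


@dataclass
class SimulationConfig:
    layout: GenomeLayout
    populations: tuple[tuple[str, int], ...]  # (population id, n individuals)
    theta: float = DEFAULT_THETA
    planted_sweeps: tuple[PlantedSweep, ...] = ()
    depth_model: DiscreteDistribution = field(default_factory=default_depth_model)
    gq_model: DiscreteDistribution = field(default_factory=default_gq_model)
    hom_nonref_rate: float = DEFAULT_HOM_NONREF_RATE
    seed: int = 0

    def __post_init__(self) -> None:
        self.populations = tuple((str(p), int(n)) for p, n in self.populations)
        self.planted_sweeps = tuple(self.planted_sweeps)
        if self.theta < 0 or self.hom_nonref_rate < 0:
            raise ConfigurationError("site rates must be non-negative")
        pop_ids = [p for p, _ in self.populations]
        if len(set(pop_ids)) != len(pop_ids):
            raise ConfigurationError("duplicate population ids")
        for p, n in self.populations:
            if n < 1:
                raise ConfigurationError(f"population {p!r} needs >=1 individual")
        for sw in self.planted_sweeps:
            if sw.population != "shared" and sw.population not in pop_ids:
                raise ConfigurationError(
                    f"planted sweep names unknown population {sw.population!r}"
                )
            self.layout.validate_interval(sw.chromosome, sw.start, sw.end)
            if not 0.0 <= sw.reduction <= 1.0:
                raise ConfigurationError("reduction factor must lie in [0, 1]")

    @classmethod
    def from_dict(cls, raw: dict, seed: int | None = None) -> "SimulationConfig":
        """Build a config from a plain mapping (YAML-friendly).

        ``layout`` may be a mapping of chromosome name to length or a list
        of pairs; ``populations`` a mapping of id to individual count or a
        list of pairs; ``planted_sweeps`` a list of mappings with keys
        population, chromosome, start, end, reduction.
        """
        layout = GenomeLayout(
            list(raw["layout"].items())
            if isinstance(raw["layout"], dict)
            else raw["layout"]
        )
        pops = (
            list(raw["populations"].items())
            if isinstance(raw["populations"], dict)
            else raw["populations"]
        )
        sweeps = tuple(
            PlantedSweep(
                population=str(d["population"]),
                chromosome=str(d["chromosome"]),
                start=int(d["start"]),
                end=int(d["end"]),
                reduction=float(d["reduction"]),
            )
            for d in raw.get("planted_sweeps", [])
        )
        kwargs = dict(
            layout=layout,
            populations=tuple((str(p), int(n)) for p, n in pops),
            planted_sweeps=sweeps,
        )
        for key in ("theta", "hom_nonref_rate"):
            if key in raw:
                kwargs[key] = float(raw[key])
        kwargs["seed"] = int(seed if seed is not None else raw.get("seed", 0))
        return cls(**kwargs)

    def individuals(self, population: str) -> list[str]:
        for p, n in self.populations:
            if p == population:
                return [f"{p}_{i + 1}" for i in range(n)]
        raise ConfigurationError(f"unknown population {population!r}")


def _rate_segments(
    config: SimulationConfig, population: str, chrom: str, length: int
) -> list[tuple[int, int, float]]:
    """Piecewise-constant heterozygosity rate along one chromosome."""
    sweeps = sorted(
        (
            sw
            for sw in config.planted_sweeps
            if sw.chromosome == chrom and sw.applies_to(population)
        ),
        key=lambda s: s.start,
    )
    for a, b in zip(sweeps, sweeps[1:]):
        if b.start < a.end:
            raise ConfigurationError(
                f"planted sweeps overlap on {chrom} for population {population!r}"
            )
    segments: list[tuple[int, int, float]] = []
    cursor = 0
    for sw in sweeps:
        if sw.start > cursor:
            segments.append((cursor, sw.start, config.theta))
        segments.append((sw.start, sw.end, config.theta * sw.reduction))
        cursor = sw.end
    if cursor < length:
        segments.append((cursor, length, config.theta))
    return segments


def _poisson_positions(
    rng: np.random.Generator, segments: list[tuple[int, int, float]]
) -> np.ndarray:
    """1-based unique site positions from a piecewise Poisson process."""
    chunks = []
    for start, end, rate in segments:
        n = rng.poisson(rate * (end - start))
        if n:
            chunks.append(rng.integers(start + 1, end + 1, size=n, dtype=np.int64))
    if not chunks:
        return np.empty(0, dtype=np.int64)
    return np.unique(np.concatenate(chunks))


def simulate_genotypes(config: SimulationConfig) -> pd.DataFrame:
    """Simulate genotype calls for every individual of every population.

    Returns a DataFrame with one row per emitted call, columns
    ``chromosome, position, individual, population, genotype_class, depth,
    genotype_quality``, ordered by (population, individual, chromosome in
    layout order, position).  Only non-reference calls are emitted;
    homozygous-reference sites are implicit.  Identical configs and seeds
    produce identical frames.
    """
    root = np.random.SeedSequence(config.seed)
    pop_seeds = root.spawn(len(config.populations))
    frames: list[pd.DataFrame] = []
    for (pop, n_ind), pop_seed in zip(config.populations, pop_seeds):
        ind_seeds = pop_seed.spawn(n_ind)
        for ind, ind_seed in zip(config.individuals(pop), ind_seeds):
            rng = np.random.default_rng(ind_seed)
            for chrom, length in config.layout.chromosomes:
                het_pos = _poisson_positions(
                    rng, _rate_segments(config, pop, chrom, length)
                )
                hom_pos = _poisson_positions(
                    rng, [(0, length, config.hom_nonref_rate)]
                )
                hom_pos = np.setdiff1d(hom_pos, het_pos, assume_unique=True)
                pos = np.concatenate([het_pos, hom_pos])
                if not len(pos):
                    continue
                cls = np.concatenate(
                    [
                        np.full(len(het_pos), "het"),
                        np.full(len(hom_pos), "hom_nonref"),
                    ]
                )
                order = np.argsort(pos, kind="stable")
                pos, cls = pos[order], cls[order]
                frames.append(
                    pd.DataFrame(
                        {
                            "chromosome": chrom,
                            "position": pos,
                            "individual": ind,
                            "population": pop,
                            "genotype_class": cls,
                            "depth": config.depth_model.sample(rng, len(pos)),
                            "genotype_quality": config.gq_model.sample(rng, len(pos)),
                        }
                    )
                )
    if not frames:
        return pd.DataFrame(
            columns=[
                "chromosome",
                "position",
                "individual",
                "population",
                "genotype_class",
                "depth",
                "genotype_quality",
            ]
        )
    return pd.concat(frames, ignore_index=True)


# --- VCF output ----------------------------------------------------------

_VCF_HEADER_FORMATS = (
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
    '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
    '##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">',
)


def write_population_vcfs(
    records: pd.DataFrame, config: SimulationConfig, outdir: str | Path
) -> dict[str, Path]:
    """Write one plain-text VCFv4.2 per population, one sample column per
    individual; FORMAT GT:DP:GQ.  Only polymorphic sites appear; individuals
    without a call at a site get ``./.``.  Output is byte-deterministic for
    a fixed input frame."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    chrom_order = {c: i for i, c in enumerate(config.layout.names)}
    paths: dict[str, Path] = {}
    for pop, _ in config.populations:
        samples = config.individuals(pop)
        sample_idx = {s: i for i, s in enumerate(samples)}
        path = outdir / f"{pop}.vcf"
        sub = records[records["population"] == pop]
        with open(path, "w") as fh:
            fh.write("##fileformat=VCFv4.2\n")
            fh.write("##source=sweepscan simulate\n")
            for chrom, length in config.layout.chromosomes:
                fh.write(f"##contig=<ID={chrom},length={length}>\n")
            for line in _VCF_HEADER_FORMATS:
                fh.write(line + "\n")
            fh.write(
                "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                + "\t".join(samples)
                + "\n"
            )
            if not len(sub):
                paths[pop] = path
                continue
            # one int64 key per site keeps the site grouping fully vectorized
            rank = sub["chromosome"].map(chrom_order).to_numpy(dtype=np.int64)
            pos = sub["position"].to_numpy(dtype=np.int64)
            key = rank * 10_000_000_000 + pos
            usite, inverse = np.unique(key, return_inverse=True)
            col = sub["individual"].map(sample_idx).to_numpy()
            gts = np.where(sub["genotype_class"].to_numpy() == "het", "0/1", "1/1")
            cells = [
                f"{g}:{d}:{q}"
                for g, d, q in zip(
                    gts, sub["depth"].to_numpy(), sub["genotype_quality"].to_numpy()
                )
            ]
            fields = np.full((len(usite), len(samples)), "./.:.:.", dtype=object)
            fields[inverse, col] = cells
            names = config.layout.names
            for i, site in enumerate(usite):
                chrom = names[site // 10_000_000_000]
                fh.write(
                    f"{chrom}\t{site % 10_000_000_000}\t.\tA\tC\t.\tPASS\t.\tGT:DP:GQ\t"
                    + "\t".join(fields[i])
                    + "\n"
                )
        paths[pop] = path
    return paths


# --- packaged reference overlap regions ----------------------------------


def read_overlap_regions_tsv(path: str | Path) -> list[OverlapRegion]:
    """Parse a TSV of multi-population overlapping sweep regions.

    Expected header: ``chrom  sweep_start  sweep_end  overlap_start
    overlap_end  populations`` (populations comma-separated).
    """
    regions: list[OverlapRegion] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if tuple(header) != _FIXTURE_COLUMNS:
            raise FixtureParseError(f"unexpected header {header!r} in {path}")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 6:
                raise FixtureParseError(f"{path}:{lineno}: expected 6 fields: {line!r}")
            try:
                chrom = parts[0]
                span_start, span_end, start, end = (int(x) for x in parts[1:5])
                pops = frozenset(p.strip() for p in parts[5].split(",") if p.strip())
            except ValueError as exc:
                raise FixtureParseError(f"{path}:{lineno}: {exc}: {line!r}") from None
            if len(pops) < 2:
                raise FixtureParseError(
                    f"{path}:{lineno}: overlap region needs >=2 populations: {line!r}"
                )
            regions.append(
                OverlapRegion(
                    chromosome=chrom,
                    start=start,
                    end=end,
                    populations=pops,
                    span_start=span_start,
                    span_end=span_end,
                )
            )
    return regions


def write_overlap_regions_tsv(regions: list[OverlapRegion], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(_FIXTURE_COLUMNS) + "\n")
        for r in regions:
            pops = ",".join(sorted(r.populations))
            fh.write(
                f"{r.chromosome}\t{r.span_start}\t{r.span_end}\t"
                f"{r.start}\t{r.end}\t{pops}\n"
            )


def load_turkey_overlap_regions() -> list[OverlapRegion]:
    """The 23 published overlapping sweep regions of the ten-population
    domestic-turkey genome scan (seven commercial lines L1–L7, heritage
    varieties BvSW, Nset, RP), as packaged reference data."""
    with resources.as_file(
        resources.files("sweepscan.data") / "multi_population_overlaps.tsv"
    ) as path:
        return read_overlap_regions_tsv(path)
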