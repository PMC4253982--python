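"""Cross-population comparison of called sweeps.

An *overlapping sweep region* is a maximal genomic interval covered by the
called sweeps of at least two populations.  Coverage is computed at bp
resolution with a sorted boundary-event sweep: the chromosome is cut into
atomic intervals on which the set of covering populations is constant,
atoms with >=2 covering populations are kept, and touching atoms whose
population sets share at least two populations are merged into a single
record (published tables list one interval with one population list per
region).  A called sweep that intersects no other population's sweep is
*population-specific*; every input sweep falls in exactly one class.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import TYPE_CHECKING, Iterable, Mapping

from sweepscan.errors import ConfigurationError, StructuralError

if TYPE_CHECKING:  # pragma: no cover
    from sweepscan.sweeps import SweepRegion

#: Population classes of the ten-population turkey panel: seven
#: breeding-company commercial lines and three heritage varieties.
TURKEY_POPULATION_CLASSES: dict[str, str] = {
    **{f"L{i}": "commercial" for i in range(1, 8)},
    "BvSW": "heritage",
    "Nset": "heritage",
    "RP": "heritage",
}


@dataclass(frozen=True)
class OverlapRegion:
    """A maximal interval covered by sweeps from >=2 populations.

    ``[start, end)`` is the overlapping region itself; ``[span_start,
    span_end)`` is the extent of the union of the contributing sweeps.
    """

    chromosome: str
    start: int
    end: int
    populations: frozenset[str]
    span_start: int
    span_end: int

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise StructuralError("overlap region must have start < end")
        if len(self.populations) < 2:
            raise StructuralError("overlap region needs >=2 populations")

    @property
    def n_populations(self) -> int:
        return len(self.populations)


def _coverage_atoms(
    sweeps: list["SweepRegion"],
) -> list[tuple[int, int, frozenset[str]]]:
    """Atomic intervals of one chromosome with their covering-population
    sets (only atoms covered by >=1 sweep are emitted)."""
    events: dict[int, tuple[set[str], set[str]]] = {}
    for sw in sweeps:
        events.setdefault(sw.start, (set(), set()))[0].add(sw.population)
        events.setdefault(sw.end, (set(), set()))[1].add(sw.population)
    atoms = []
    active: set[str] = set()
    positions = sorted(events)
    for pos, nxt in zip(positions, positions[1:] + [None]):
        starts, ends = events[pos]
        for p in ends:
            active.discard(p)
        if starts & active:
            raise StructuralError(
                f"overlapping sweeps within population(s) {sorted(starts & active)}"
            )
        active |= starts
        if nxt is not None and active:
            atoms.append((pos, nxt, frozenset(active)))
    return atoms


def find_overlaps(
    sweeps_by_population: Mapping[str, list["SweepRegion"]],
) -> tuple[list[OverlapRegion], list["SweepRegion"]]:
    """Split sweeps into overlapping regions and population-specific sweeps.

    Returns ``(overlap_regions, population_specific_sweeps)``.  Overlap
    regions are annotated with the exact set of populations whose sweeps
    intersect them and with the union span of those contributing sweeps.
    """
    by_chrom: dict[str, list["SweepRegion"]] = {}
    for pop, sweeps in sweeps_by_population.items():
        for sw in sweeps:
            if sw.population != pop:
                raise StructuralError(
                    f"sweep labelled {sw.population!r} filed under {pop!r}"
                )
            by_chrom.setdefault(sw.chromosome, []).append(sw)

    overlaps: list[OverlapRegion] = []
    for chrom in by_chrom:
        atoms = [a for a in _coverage_atoms(by_chrom[chrom]) if len(a[2]) >= 2]
        merged: list[list] = []  # [start, end, set(populations)]
        for start, end, pops in atoms:
            if merged and merged[-1][1] == start and len(merged[-1][2] & pops) >= 2:
                merged[-1][1] = end
                merged[-1][2] |= pops
            else:
                merged.append([start, end, set(pops)])
        for start, end, pops in merged:
            contributing = [
                sw
                for sw in by_chrom[chrom]
                if sw.population in pops and sw.start < end and sw.end > start
            ]
            overlaps.append(
                OverlapRegion(
                    chromosome=chrom,
                    start=start,
                    end=end,
                    populations=frozenset(pops),
                    span_start=min(sw.start for sw in contributing),
                    span_end=max(sw.end for sw in contributing),
                )
            )

    specifics: list["SweepRegion"] = []
    overlaps_by_chrom: dict[str, list[OverlapRegion]] = {}
    for ov in overlaps:
        overlaps_by_chrom.setdefault(ov.chromosome, []).append(ov)
    for pop in sweeps_by_population:
        for sw in sweeps_by_population[pop]:
            hits = any(
                sw.start < ov.end and sw.end > ov.start
                for ov in overlaps_by_chrom.get(sw.chromosome, [])
            )
            if not hits:
                specifics.append(sw)

    overlaps.sort(key=lambda r: (r.chromosome, r.start))
    return overlaps, specifics


def count_overlaps(
    overlaps: Iterable[OverlapRegion],
    min_populations: int | None = None,
    chromosomes: Iterable[str] | None = None,
) -> int:
    """Count overlap records, optionally restricted to a minimum number of
    contributing populations and/or a chromosome subset."""
    chroms = set(chromosomes) if chromosomes is not None else None
    n = 0
    for ov in overlaps:
        if min_populations is not None and ov.n_populations < min_populations:
            continue
        if chroms is not None and ov.chromosome not in chroms:
            continue
        n += 1
    return n


def _chrom_sort_key(chrom: str):
    return (0, int(chrom)) if chrom.isdigit() else (1, chrom)


def overlap_summary(
    overlaps: list[OverlapRegion],
    specifics: list["SweepRegion"],
    population_classes: Mapping[str, str],
) -> dict:
    """Summary counts over overlap regions and population-specific sweeps.

    ``population_classes`` maps each population to a class label (for the
    turkey panel: ``commercial`` or ``heritage``); a record whose population
    set spans several classes is counted as ``mixed``.
    """
    present = set().union(*(ov.populations for ov in overlaps)) if overlaps else set()
    present |= {sw.population for sw in specifics}
    unknown = present - set(population_classes)
    if unknown:
        raise ConfigurationError(f"populations without a class: {sorted(unknown)}")

    max_k = max((ov.n_populations for ov in overlaps), default=1)
    by_min_pops = {
        k: count_overlaps(overlaps, min_populations=k) for k in range(2, max_k + 1)
    }

    composition = {"mixed": 0}
    for ov in overlaps:
        classes = {population_classes[p] for p in ov.populations}
        key = classes.pop() if len(classes) == 1 else "mixed"
        composition[key] = composition.get(key, 0) + 1

    participation: dict[str, int] = {}
    for ov in overlaps:
        for p in ov.populations:
            participation[p] = participation.get(p, 0) + 1

    specific_by_pop: dict[str, int] = {}
    specific_by_class: dict[str, int] = {}
    for sw in specifics:
        specific_by_pop[sw.population] = specific_by_pop.get(sw.population, 0) + 1
        cls = population_classes[sw.population]
        specific_by_class[cls] = specific_by_class.get(cls, 0) + 1

    chroms = sorted({ov.chromosome for ov in overlaps}, key=_chrom_sort_key)
    return {
        "n_overlap_regions": len(overlaps),
        "n_population_specific": len(specifics),
        "overlap_regions_with_min_populations": by_min_pops,
        "overlap_class_composition": composition,
        "overlap_chromosomes": chroms,
        "n_overlap_chromosomes": len(chroms),
        "overlap_participation_by_population": dict(sorted(participation.items())),
        "population_specific_by_population": dict(sorted(specific_by_pop.items())),
        "population_specific_by_class": dict(sorted(specific_by_class.items())),
    }


# --- I/O -----------------------------------------------------------------


def write_overlaps_bed(overlaps: list[OverlapRegion], path) -> None:
    """BED4+: chrom, start, end, comma-separated populations."""
    with open(path, "w") as fh:
        for ov in sorted(overlaps, key=lambda r: (_chrom_sort_key(r.chromosome), r.start)):
            pops = ",".join(sorted(ov.populations))
            fh.write(f"{ov.chromosome}\t{ov.start}\t{ov.end}\t{pops}\n")
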