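"""Sweep calling: maximal runs of consecutive low-heterozygosity bins.

A candidate selective sweep is a maximal within-chromosome run of at
least ``run_len`` (default 5) consecutive bins whose population
heterozygosity is at or below the genome-wide threshold, reported as the
genomic interval from the first bin's start to the last bin's end.  With
full 300 Kb bins the minimum sweep length is therefore 1.5 Mb.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np

from sweepscan.errors import ConfigurationError
from sweepscan.windows import PopulationWindowTrack


@dataclass(frozen=True)
class SweepRegion:
    """A maximal run of low-heterozygosity bins as a genomic interval
    (0-based half-open)."""

    population: str
    chromosome: str
    start: int
    end: int
    n_bins: int
    mean_het: float

    @property
    def length_bp(self) -> int:
        return self.end - self.start

    def to_1based(self) -> tuple[int, int]:
        """(start, end) printed 1-based inclusive."""
        return self.start + 1, self.end


def call_sweeps(
    track: PopulationWindowTrack,
    threshold: float,
    run_len: int = 5,
    min_informative_sites: int | None = None,
) -> list[SweepRegion]:
    """All maximal runs of >= ``run_len`` consecutive bins with
    ``het_rate <= threshold``, per chromosome, in layout order.

    ``min_informative_sites`` optionally masks bins carrying fewer than
    that many calls (het + hom_nonref) as non-qualifying, so stretches with
    no callable data cannot qualify solely because their rate is zero.
    """
    if threshold < 0:
        raise ConfigurationError("threshold must be >= 0")
    if run_len < 1:
        raise ConfigurationError("run_len must be >= 1")
    sweeps: list[SweepRegion] = []
    for chrom, grp in track.frame.groupby("chrom", sort=False, observed=True):
        rates = grp["het_rate"].to_numpy(dtype=float)
        low = rates <= threshold
        if min_informative_sites is not None:
            informative = (
                grp["het_count"].to_numpy() + grp["hom_nonref_count"].to_numpy()
            ) >= min_informative_sites
            low &= informative
        starts = grp["start"].to_numpy()
        ends = grp["end"].to_numpy()
        i = 0
        while i < len(low):
            if not low[i]:
                i += 1
                continue
            j = i
            while j + 1 < len(low) and low[j + 1]:
                j += 1
            if j - i + 1 >= run_len:
                sweeps.append(
                    SweepRegion(
                        population=track.population,
                        chromosome=str(chrom),
                        start=int(starts[i]),
                        end=int(ends[j]),
                        n_bins=j - i + 1,
                        mean_het=float(np.mean(rates[i : j + 1])),
                    )
                )
            i = j + 1
    return sweeps


def sweep_summary(
    sweeps_by_population: Mapping[str, list[SweepRegion]],
) -> dict:
    """Counts and length statistics over all populations' called sweeps."""
    all_sweeps = [sw for sweeps in sweeps_by_population.values() for sw in sweeps]
    lengths = [sw.length_bp for sw in all_sweeps]
    return {
        "n_sweeps_total": len(all_sweeps),
        "n_sweeps_by_population": {
            pop: len(sweeps) for pop, sweeps in sweeps_by_population.items()
        },
        "chromosomes_with_sweeps": sorted({sw.chromosome for sw in all_sweeps}),
        "n_chromosomes_with_sweeps": len({sw.chromosome for sw in all_sweeps}),
        "min_length_bp": min(lengths) if lengths else None,
        "max_length_bp": max(lengths) if lengths else None,
        "mean_length_bp": float(np.mean(lengths)) if lengths else None,
    }


def write_sweeps_bed(sweeps: list[SweepRegion], path: str | Path) -> None:
    """BED6: chrom, start, end, name=population, score=round(1e6 * mean
    heterozygosity), strand '.'."""
    with open(path, "w") as fh:
        for sw in sweeps:
            score = int(round(1e6 * sw.mean_het))
            fh.write(
                f"{sw.chromosome}\t{sw.start}\t{sw.end}\t{sw.population}\t{score}\t.\n"
            )


def write_sweeps_tsv(sweeps: list[SweepRegion], path: str | Path) -> None:
    """TSV mirror with 1-based inclusive coordinates."""
    with open(path, "w") as fh:
        fh.write("population\tchrom\tstart\tend\tn_bins\tlength_bp\tmean_het\n")
        for sw in sweeps:
            s1, e1 = sw.to_1based()
            fh.write(
                f"{sw.population}\t{sw.chromosome}\t{s1}\t{e1}\t"
                f"{sw.n_bins}\t{sw.length_bp}\t{sw.mean_het:.10g}\n"
            )


def read_sweeps_bed(path: str | Path) -> list[SweepRegion]:
    sweeps: list[SweepRegion] = []
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            chrom, start, end, pop, score, _ = line.rstrip("\n").split("\t")
            sweeps.append(
                SweepRegion(
                    population=pop,
                    chromosome=chrom,
                    start=int(start),
                    end=int(end),
                    n_bins=0,  # not encoded in BED
                    mean_het=int(score) / 1e6,
                )
            )
    return sweeps
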