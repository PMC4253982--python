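"""Depth/quality filtering and windowed heterozygosity.

Genotype calls are retained when their read depth lies in an inclusive
band (default 5–10x; the ceiling doubles as a crude repeat filter) and
their Phred-scaled genotype quality is at least 20.  Retained calls are
counted per individual in 300 Kb bins, each bin's heterozygosity is the
number of heterozygous calls per bp of the bin, and the per-population
track is the arithmetic mean of the individuals' rates per bin.
Homozygous non-reference calls are counted alongside but play no role in
the sweep statistic.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from sweepscan.errors import ConfigurationError, CoordinateError, StructuralError
from sweepscan.genome import DEFAULT_WINDOW_BP, GenomeLayout

DEFAULT_MIN_DEPTH = 5
DEFAULT_MAX_DEPTH = 10
DEFAULT_MIN_GQ = 20

_BIN_KEY = ["chrom", "bin_index", "start", "end"]


def filter_genotypes(
    records: pd.DataFrame,
    min_depth: int = DEFAULT_MIN_DEPTH,
    max_depth: int = DEFAULT_MAX_DEPTH,
    min_gq: int = DEFAULT_MIN_GQ,
) -> pd.DataFrame:
    """Keep calls with ``min_depth <= depth <= max_depth`` (inclusive) and
    ``genotype_quality >= min_gq``; input order is preserved."""
    if min_depth > max_depth:
        raise ConfigurationError("min_depth must not exceed max_depth")
    keep = (
        records["depth"].between(min_depth, max_depth)
        & (records["genotype_quality"] >= min_gq)
    )
    return records[keep]


def bin_individual(
    records: pd.DataFrame,
    layout: GenomeLayout,
    window_bp: int = DEFAULT_WINDOW_BP,
) -> pd.DataFrame:
    """Per-bin site counts for one individual.

    A 1-based position ``p`` belongs to bin ``(p - 1) // window_bp``.  Every
    bin of the layout appears, zero-filled when empty.  Returns columns
    ``chrom, bin_index, start, end, partial, het_count, hom_nonref_count,
    het_rate``.
    """
    if records["individual"].nunique() > 1:
        raise StructuralError("bin_individual expects records of one individual")
    bins = layout.bin_table(window_bp)
    het = np.zeros(len(bins), dtype=np.int64)
    hom = np.zeros(len(bins), dtype=np.int64)
    offsets = {}
    cursor = 0
    for chrom in layout.names:
        offsets[chrom] = cursor
        cursor += layout.n_bins(chrom, window_bp)
    for chrom, grp in records.groupby("chromosome", sort=False, observed=True):
        if chrom not in offsets:
            raise CoordinateError(f"record on chromosome {chrom!r} absent from layout")
        pos = grp["position"].to_numpy()
        if len(pos) and (pos.min() < 1 or pos.max() > layout.length_of(chrom)):
            raise CoordinateError(f"position outside chromosome {chrom!r}")
        idx = (pos - 1) // window_bp + offsets[chrom]
        is_het = (grp["genotype_class"] == "het").to_numpy()
        het += np.bincount(idx[is_het], minlength=len(bins)).astype(np.int64)
        hom += np.bincount(idx[~is_het], minlength=len(bins)).astype(np.int64)
    out = bins.copy()
    out["het_count"] = het
    out["hom_nonref_count"] = hom
    out["het_rate"] = het / (out["end"] - out["start"])
    return out


@dataclass
class PopulationWindowTrack:
    """Ordered per-bin heterozygosity of one population across the genome."""

    population: str
    layout: GenomeLayout
    window_bp: int
    frame: pd.DataFrame  # bin table + het_count, hom_nonref_count, het_rate,
    #                      n_individuals; one row per bin, layout order

    @property
    def het_rates(self) -> np.ndarray:
        return self.frame["het_rate"].to_numpy(dtype=float)

    @property
    def n_bins(self) -> int:
        return len(self.frame)

    def values_by_chromosome(self) -> list[np.ndarray]:
        """Per-chromosome bin heterozygosity arrays, in layout order."""
        grouped = self.frame.groupby("chrom", sort=False, observed=True)["het_rate"]
        rates = {c: g.to_numpy(dtype=float) for c, g in grouped}
        return [rates[c] for c in self.layout.names]

    def chromosome_bin_counts(self) -> list[int]:
        return [self.layout.n_bins(c, self.window_bp) for c in self.layout.names]

    # --- I/O -------------------------------------------------------------

    def to_tsv(self, path: str | Path) -> None:
        cols = [
            "chrom",
            "start",
            "end",
            "het_count",
            "hom_nonref_count",
            "het_rate",
            "n_individuals",
        ]
        self.frame[cols].to_csv(path, sep="\t", index=False, float_format="%.10g")

    @classmethod
    def from_tsv(
        cls,
        path: str | Path,
        population: str,
        window_bp: int = DEFAULT_WINDOW_BP,
    ) -> "PopulationWindowTrack":
        """Rebuild a track from its TSV; the layout is recovered from the
        bin tiling (each chromosome's length is its last bin's end)."""
        df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
        lengths = df.groupby("chrom", sort=False)["end"].max()
        layout = GenomeLayout(lengths.items())
        frame = layout.bin_table(window_bp)
        merged = frame.merge(df, on=["chrom", "start", "end"], how="left")
        if merged["het_rate"].isna().any():
            raise StructuralError(f"{path}: bins do not tile the genome at {window_bp} bp")
        return cls(population=population, layout=layout, window_bp=window_bp, frame=merged)


def average_population(
    individual_tracks: list[pd.DataFrame],
    population: str,
    layout: GenomeLayout,
    window_bp: int = DEFAULT_WINDOW_BP,
) -> PopulationWindowTrack:
    """Average per-individual bin tables into one population track.

    The population het_rate of a bin is the arithmetic mean of the
    individuals' rates; counts are summed and reported alongside.
    """
    if not individual_tracks:
        raise StructuralError("need at least one individual track")
    ref = individual_tracks[0][_BIN_KEY]
    for t in individual_tracks[1:]:
        if not t[_BIN_KEY].equals(ref):
            raise StructuralError("individual tracks have mismatched binning")
    frame = individual_tracks[0][_BIN_KEY + ["partial"]].copy()
    frame["het_count"] = sum(t["het_count"].to_numpy() for t in individual_tracks)
    frame["hom_nonref_count"] = sum(
        t["hom_nonref_count"].to_numpy() for t in individual_tracks
    )
    frame["het_rate"] = (
        sum(t["het_rate"].to_numpy() for t in individual_tracks)
        / len(individual_tracks)
    )
    frame["n_individuals"] = len(individual_tracks)
    return PopulationWindowTrack(
        population=population, layout=layout, window_bp=window_bp, frame=frame
    )


def track_from_genotypes(
    records: pd.DataFrame,
    population: str,
    layout: GenomeLayout,
    individuals: list[str] | None = None,
    window_bp: int = DEFAULT_WINDOW_BP,
    min_depth: int = DEFAULT_MIN_DEPTH,
    max_depth: int = DEFAULT_MAX_DEPTH,
    min_gq: int = DEFAULT_MIN_GQ,
) -> PopulationWindowTrack:
    """Filter -> bin per individual -> average, in one call.

    ``individuals`` fixes the averaging denominator (individuals with no
    retained calls still contribute all-zero tracks); defaults to the
    individuals present in ``records``.
    """
    sub = records[records["population"] == population]
    if individuals is None:
        individuals = sorted(sub["individual"].unique())
    if not individuals:
        raise StructuralError(f"no individuals for population {population!r}")
    kept = filter_genotypes(sub, min_depth, max_depth, min_gq)
    tracks = [
        bin_individual(kept[kept["individual"] == ind], layout, window_bp)
        for ind in individuals
    ]
    return average_population(tracks, population, layout, window_bp)


def read_vcf_genotypes(
    path: str | Path, population: str
) -> tuple[pd.DataFrame, list[str]]:
    """Read non-reference genotype calls from a VCF (GT/DP/GQ per sample).

    Returns ``(records, samples)`` where records has the same columns as
    the simulator output.  Missing genotypes (./.) and homozygous-reference
    calls are skipped; a het or hom-nonref call without DP or GQ is treated
    as missing.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)  # 0=hom_ref 1=het 2=hom_alt 3=unknown
    samples = list(vcf.samples)
    sample_arr = np.array(samples)
    chroms, positions, inds, classes, dps, gqs = [], [], [], [], [], []
    for v in vcf:
        gts = v.gt_types
        mask = (gts == 1) | (gts == 2)
        if not mask.any():
            continue
        dp = v.format("DP")
        gq = v.format("GQ")
        dp = dp.reshape(-1) if dp is not None else np.full(len(samples), -1)
        gq = gq.reshape(-1) if gq is not None else np.full(len(samples), -1)
        mask &= (dp >= 0) & (gq >= 0)
        n = int(mask.sum())
        if not n:
            continue
        chroms.append(np.full(n, v.CHROM))
        positions.append(np.full(n, v.POS, dtype=np.int64))
        inds.append(sample_arr[mask])
        classes.append(np.where(gts[mask] == 1, "het", "hom_nonref"))
        dps.append(dp[mask].astype(np.int64))
        gqs.append(gq[mask].astype(np.int64))
    vcf.close()
    if not chroms:
        records = pd.DataFrame(
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
        return records, samples
    records = pd.DataFrame(
        {
            "chromosome": np.concatenate(chroms),
            "position": np.concatenate(positions),
            "individual": np.concatenate(inds),
            "population": population,
            "genotype_class": np.concatenate(classes),
            "depth": np.concatenate(dps),
            "genotype_quality": np.concatenate(gqs),
        }
    )
    return records, samples
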