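"""Genome layout: the ordered chromosomes that define binning and coordinates.

Coordinates are 0-based half-open internally; variant positions follow the
1-based VCF convention and are converted at the boundary.  Each chromosome of
length L is divided into ``ceil(L / window_bp)`` bins; the final bin may be
shorter than ``window_bp`` (a *partial* bin) and its heterozygosity is always
normalized by its actual width.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from sweepscan.errors import ConfigurationError, CoordinateError

DEFAULT_WINDOW_BP = 300_000


@dataclass(frozen=True)
class GenomeLayout:
    """Ordered list of (chromosome name, length in bp)."""

    chromosomes: tuple[tuple[str, int], ...]

    def __init__(self, chromosomes) -> None:
        object.__setattr__(
            self, "chromosomes", tuple((str(n), int(l)) for n, l in chromosomes)
        )
        names = [n for n, _ in self.chromosomes]
        if len(set(names)) != len(names):
            raise ConfigurationError("duplicate chromosome names in layout")
        if not self.chromosomes:
            raise ConfigurationError("layout must contain at least one chromosome")
        for n, l in self.chromosomes:
            if l <= 0:
                raise ConfigurationError(f"chromosome {n!r} has non-positive length {l}")

    @property
    def names(self) -> list[str]:
        return [n for n, _ in self.chromosomes]

    @property
    def lengths(self) -> dict[str, int]:
        return dict(self.chromosomes)

    @property
    def total_bp(self) -> int:
        return sum(l for _, l in self.chromosomes)

    def length_of(self, chrom: str) -> int:
        try:
            return self.lengths[chrom]
        except KeyError:
            raise CoordinateError(f"chromosome {chrom!r} not in layout") from None

    def n_bins(self, chrom: str, window_bp: int = DEFAULT_WINDOW_BP) -> int:
        return math.ceil(self.length_of(chrom) / window_bp)

    def bin_table(self, window_bp: int = DEFAULT_WINDOW_BP) -> pd.DataFrame:
        """All bins of the genome in layout order.

        Columns: chrom, bin_index, start, end, partial (end - start < window_bp).
        """
        rows = []
        for chrom, length in self.chromosomes:
            for b in range(math.ceil(length / window_bp)):
                start = b * window_bp
                end = min(start + window_bp, length)
                rows.append((chrom, b, start, end, end - start < window_bp))
        return pd.DataFrame(
            rows, columns=["chrom", "bin_index", "start", "end", "partial"]
        )

    def validate_interval(self, chrom: str, start: int, end: int) -> None:
        length = self.length_of(chrom)
        if not (0 <= start < end <= length):
            raise CoordinateError(
                f"interval {chrom}:{start}-{end} outside chromosome of length {length}"
            )

    # --- I/O -------------------------------------------------------------

    @classmethod
    def from_tsv(cls, path: str | Path) -> "GenomeLayout":
        """Read a two-column ``chrom<TAB>length`` table (with header)."""
        df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "length": int})
        return cls(zip(df["chrom"], df["length"]))

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame(self.chromosomes, columns=["chrom", "length"]).to_csv(
            path, sep="\t", index=False
        )
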