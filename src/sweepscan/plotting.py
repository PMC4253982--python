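"""Heterozygosity heat maps: populations as rows, genome bins as columns.

Cell colors follow a white-to-red ramp applied to the square root of the
bin heterozygosity (the square root stretches the low-diversity end where
sweeps live), normalized to the maximum of the plotted figure.  Rendering
is raster-exact: every bin is an integer block of pixels, so identical
inputs produce identical images.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import matplotlib
import numpy as np

matplotlib.use("Agg")

from matplotlib import image as mpl_image
from matplotlib.colors import LinearSegmentedColormap

from sweepscan.errors import ConfigurationError, StructuralError
from sweepscan.windows import PopulationWindowTrack

WHITE_RED = LinearSegmentedColormap.from_list("white_red", ["white", "red"])


@dataclass
class HeatmapSpec:
    tracks: list[PopulationWindowTrack]
    region: str | None = None  # chromosome name, or None for the whole genome
    out: str | Path = "heatmap.png"
    annotations: list[tuple[str, int, int]] = field(default_factory=list)
    cell_px: int = 6  # pixels per bin (columns) and per population row band
    row_px: int = 24


def heatmap_values(
    tracks: list[PopulationWindowTrack], region: str | None = None
) -> tuple[np.ndarray, "object"]:
    """(populations x bins) matrix of sqrt(het_rate) plus the bin table."""
    if not tracks:
        raise ConfigurationError("need at least one track")
    ref = tracks[0]
    for t in tracks[1:]:
        if t.window_bp != ref.window_bp or t.layout != ref.layout:
            raise StructuralError("tracks have mismatched binning")
    bins = ref.frame[["chrom", "bin_index", "start", "end"]]
    if region is not None:
        if region not in ref.layout.names:
            raise ConfigurationError(f"chromosome {region!r} not in layout")
        mask = (bins["chrom"] == region).to_numpy()
    else:
        mask = np.ones(len(bins), dtype=bool)
    if not mask.any():
        raise ConfigurationError("empty region")
    values = np.sqrt(np.vstack([t.het_rates[mask] for t in tracks]))
    return values, bins[mask].reset_index(drop=True)


def render_heatmap(spec: HeatmapSpec) -> Path:
    """Render the heat map to ``spec.out`` (PNG raster; .svg via matplotlib).

    Returns the output path.  Color is a monotone function of het_rate:
    white at zero, full red at the figure-wide maximum.
    """
    values, bins = heatmap_values(spec.tracks, spec.region)
    vmax = values.max()
    scaled = values / vmax if vmax > 0 else np.zeros_like(values)
    rgba = WHITE_RED(scaled)  # (rows, cols, 4)

    out = Path(spec.out)
    if out.suffix == ".svg":
        return _render_svg(spec, scaled, out)

    img = np.repeat(np.repeat(rgba, spec.row_px, axis=0), spec.cell_px, axis=1)
    for chrom, start, end in spec.annotations:
        sel = (
            (bins["chrom"] == chrom) & (bins["end"] > start) & (bins["start"] < end)
        ).to_numpy()
        idx = np.flatnonzero(sel)
        if not len(idx):
            continue
        c0, c1 = idx[0] * spec.cell_px, (idx[-1] + 1) * spec.cell_px
        img[0, c0:c1] = img[-1, c0:c1] = (0, 0, 0, 1)
        img[:, c0] = img[:, c1 - 1] = (0, 0, 0, 1)
    mpl_image.imsave(out, img)
    return out


def _render_svg(spec: HeatmapSpec, scaled: np.ndarray, out: Path) -> Path:
    from matplotlib import pyplot as plt

    fig, ax = plt.subplots(figsize=(max(6, scaled.shape[1] / 20), 1 + scaled.shape[0] / 3))
    ax.imshow(scaled, cmap=WHITE_RED, aspect="auto", interpolation="nearest", vmin=0, vmax=1)
    ax.set_yticks(range(len(spec.tracks)))
    ax.set_yticklabels([t.population for t in spec.tracks])
    ax.set_xlabel(
        f"{spec.region} bins" if spec.region else "genome bins (layout order)"
    )
    fig.savefig(out, format="svg")
    plt.close(fig)
    return out
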