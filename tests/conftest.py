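import numpy as np
import pandas as pd
import pytest

from sweepscan.genome import GenomeLayout
from sweepscan.windows import PopulationWindowTrack


def make_track(values_by_chrom, window_bp=300_000, population="pop"):
    """Build a PopulationWindowTrack directly from per-chromosome bin
    heterozygosity values (all bins full)."""
    layout = GenomeLayout(
        [(str(i + 1), len(v) * window_bp) for i, v in enumerate(values_by_chrom)]
    )
    frame = layout.bin_table(window_bp)
    frame["het_count"] = 0
    frame["hom_nonref_count"] = 0
    frame["het_rate"] = np.concatenate(
        [np.asarray(v, dtype=float) for v in values_by_chrom]
    )
    frame["n_individuals"] = 1
    return PopulationWindowTrack(
        population=population, layout=layout, window_bp=window_bp, frame=frame
    )


def make_records(rows):
    """Genotype-record frame from (chrom, pos, individual, population,
    genotype_class, depth, gq) tuples."""
    return pd.DataFrame(
        rows,
        columns=[
            "chromosome",
            "position",
            "individual",
            "population",
            "genotype_class",
            "depth",
            "genotype_quality",
        ],
    )


@pytest.fixture
def toy_layout():
    return GenomeLayout([("1", 900_000), ("2", 650_000)])


@pytest.fixture
def track_factory():
    return make_track
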