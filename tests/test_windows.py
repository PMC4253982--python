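"""Genotype filtering, binning, and population averaging."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import make_records
from sweepscan.errors import ConfigurationError, CoordinateError, StructuralError
from sweepscan.genome import GenomeLayout
from sweepscan.windows import (
    average_population,
    bin_individual,
    filter_genotypes,
    track_from_genotypes,
    PopulationWindowTrack,
)


def rec(pos, chrom="1", ind="i1", cls="het", dp=7, gq=30):
    return (chrom, pos, ind, "pop", cls, dp, gq)


class TestFilterGenotypes:
    @pytest.mark.parametrize(
        "dp,gq,kept",
        [
            (4, 30, False),  # just under the depth floor
            (5, 20, True),  # both boundaries are inclusive
            (10, 20, True),
            (11, 30, False),  # over the depth ceiling (repeat proxy)
            (7, 19, False),  # just under the quality cutoff
            (7, 20, True),
        ],
    )
    def test_inclusive_depth_band_and_gq_cutoff(self, dp, gq, kept):
        records = make_records([rec(100, dp=dp, gq=gq)])
        assert len(filter_genotypes(records)) == (1 if kept else 0)

    def test_order_preserved_and_empty_allowed(self):
        records = make_records([rec(300, dp=6), rec(100, dp=9), rec(200, dp=1)])
        out = filter_genotypes(records)
        assert list(out["position"]) == [300, 100]

    def test_inverted_bounds_rejected(self):
        with pytest.raises(ConfigurationError):
            filter_genotypes(make_records([rec(1)]), min_depth=10, max_depth=5)


class TestBinIndividual:
    def test_three_sites_in_full_bin(self, toy_layout):
        records = make_records([rec(p) for p in (10, 1000, 299_999)])
        out = bin_individual(records, toy_layout)
        assert out.loc[0, "het_count"] == 3
        assert out.loc[0, "het_rate"] == pytest.approx(1.0e-5)

    def test_bin_boundary_follows_1based_convention(self, toy_layout):
        # position 300,000 is the last bp of bin 0; 300,001 opens bin 1
        out = bin_individual(
            make_records([rec(300_000), rec(300_001)]), toy_layout
        )
        assert out.loc[0, "het_count"] == 1
        assert out.loc[1, "het_count"] == 1

    def test_empty_bins_are_zero(self, toy_layout):
        out = bin_individual(make_records([]).astype({"position": int}), toy_layout)
        assert (out["het_count"] == 0).all()
        assert (out["het_rate"] == 0).all()

    def test_partial_trailing_bin_normalized_by_width(self, toy_layout):
        # chromosome 2 is 650 Kb: its last bin spans 50 Kb and is flagged
        out = bin_individual(
            make_records([rec(620_000, chrom="2")]), toy_layout
        )
        last = out.iloc[-1]
        assert last["partial"] and last["end"] - last["start"] == 50_000
        assert last["het_rate"] == pytest.approx(1 / 50_000)

    def test_unknown_chromosome_raises(self, toy_layout):
        with pytest.raises(CoordinateError):
            bin_individual(make_records([rec(5, chrom="chrX")]), toy_layout)

    def test_agrees_with_per_record_loop(self):
        layout = GenomeLayout([("1", 1_000_000), ("2", 700_000)])
        rng = np.random.default_rng(4)
        rows = []
        for _ in range(800):
            chrom = rng.choice(["1", "2"])
            pos = int(rng.integers(1, layout.length_of(chrom) + 1))
            cls = rng.choice(["het", "hom_nonref"])
            rows.append(rec(pos, chrom=chrom, cls=cls))
        out = bin_individual(make_records(rows), layout, window_bp=100_000)
        expected = {}
        for chrom, pos, _, _, cls, _, _ in rows:
            expected.setdefault((chrom, (pos - 1) // 100_000), [0, 0])[
                0 if cls == "het" else 1
            ] += 1
        for row in out.itertuples():
            want = expected.get((row.chrom, row.bin_index), [0, 0])
            assert (row.het_count, row.hom_nonref_count) == tuple(want)

    @given(
        positions=st.lists(st.integers(1, 900_000), min_size=0, max_size=60),
        window=st.sampled_from([100_000, 300_000]),
    )
    @settings(max_examples=40, deadline=None)
    def test_count_conservation(self, positions, window):
        layout = GenomeLayout([("1", 900_000)])
        records = make_records([rec(p) for p in positions])
        out = bin_individual(records, layout, window_bp=window)
        assert out["het_count"].sum() == len(positions)

    @given(
        min_dp=st.integers(0, 6),
        max_dp=st.integers(10, 15),
        min_gq=st.integers(0, 20),
    )
    @settings(max_examples=30, deadline=None)
    def test_filter_widening_never_drops_counts(self, min_dp, max_dp, min_gq):
        rng = np.random.default_rng(8)
        records = make_records(
            [
                rec(
                    int(rng.integers(1, 900_000)),
                    dp=int(rng.integers(0, 16)),
                    gq=int(rng.integers(0, 45)),
                )
                for _ in range(120)
            ]
        )
        narrow = len(filter_genotypes(records, 5, 10, 20))
        wide = len(filter_genotypes(records, min_dp, max_dp, min_gq))
        assert wide >= narrow


class TestAveragePopulation:
    def _tracks(self, layout, rates_by_individual):
        tracks = []
        for rates in rates_by_individual:
            t = layout.bin_table()
            t["het_count"] = (np.asarray(rates) * (t["end"] - t["start"])).astype(int)
            t["hom_nonref_count"] = 0
            t["het_rate"] = rates
            tracks.append(t)
        return tracks

    def test_mean_of_rates(self):
        layout = GenomeLayout([("1", 300_000)])
        tracks = self._tracks(layout, [[1e-5], [2e-5], [3e-5]])
        track = average_population(tracks, "pop", layout)
        assert track.het_rates[0] == pytest.approx(2e-5)
        assert track.frame.loc[0, "n_individuals"] == 3

    def test_single_individual_is_identity(self):
        layout = GenomeLayout([("1", 600_000)])
        tracks = self._tracks(layout, [[1e-5, 4e-5]])
        track = average_population(tracks, "pop", layout)
        assert track.het_rates == pytest.approx([1e-5, 4e-5])

    def test_zero_individual_halves_the_mean(self):
        layout = GenomeLayout([("1", 600_000)])
        tracks = self._tracks(layout, [[2e-5, 6e-5], [0.0, 0.0]])
        track = average_population(tracks, "pop", layout)
        assert track.het_rates == pytest.approx([1e-5, 3e-5])

    def test_mismatched_binning_rejected(self):
        layout_a = GenomeLayout([("1", 600_000)])
        layout_b = GenomeLayout([("1", 900_000)])
        with pytest.raises(StructuralError):
            average_population(
                self._tracks(layout_a, [[1e-5, 1e-5]])
                + self._tracks(layout_b, [[1e-5, 1e-5, 1e-5]]),
                "pop",
                layout_a,
            )


class TestTrackIO:
    def test_tsv_round_trip(self, tmp_path):
        layout = GenomeLayout([("1", 750_000), ("2", 300_000)])
        records = make_records(
            [rec(10), rec(400_000), rec(700_001, cls="hom_nonref"), rec(5, chrom="2")]
        )
        track = track_from_genotypes(records, "pop", layout)
        path = tmp_path / "pop.windows.tsv"
        track.to_tsv(path)
        back = PopulationWindowTrack.from_tsv(path, "pop")
        assert back.layout == layout
        assert back.het_rates == pytest.approx(track.het_rates)
        pd.testing.assert_frame_equal(
            back.frame[["chrom", "start", "end", "het_count"]],
            track.frame[["chrom", "start", "end", "het_count"]],
        )
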