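"""Simulator statistics, determinism, VCF round trip, packaged reference data."""

import numpy as np
import pandas as pd
import pytest

import sweepscan as ss
from sweepscan.errors import ConfigurationError, CoordinateError, FixtureParseError
from sweepscan.synthetic import (
    DiscreteDistribution,
    default_gq_model,
    read_overlap_regions_tsv,
    write_overlap_regions_tsv,
)


def one_pop_config(layout, sweeps=(), theta=1.07e-3, n_ind=1, seed=0):
    return ss.SimulationConfig(
        layout=layout,
        populations=(("P", n_ind),),
        theta=theta,
        planted_sweeps=sweeps,
        seed=seed,
    )


class TestSimulateGenotypes:
    def test_het_site_count_matches_poisson_rate(self):
        # closed form: 30 Mb at 1.07e-3 het sites/bp -> Poisson(32,100)
        layout = ss.GenomeLayout([("1", 30_000_000)])
        rec = ss.simulate_genotypes(one_pop_config(layout, seed=7))
        n_het = (rec["genotype_class"] == "het").sum()
        mean = 1.07e-3 * 30e6
        assert abs(n_het - mean) < 4 * np.sqrt(mean)

    def test_full_reduction_leaves_interval_empty(self):
        layout = ss.GenomeLayout([("1", 6_000_000)])
        sweep = ss.PlantedSweep("P", "1", 0, 1_500_000, 0.0)
        rec = ss.simulate_genotypes(one_pop_config(layout, (sweep,), seed=3))
        het = rec[rec["genotype_class"] == "het"]
        assert not ((het["position"] <= 1_500_000) & (het["chromosome"] == "1")).any()

    @pytest.mark.parametrize("reduction", [0.02, 0.5])
    def test_planted_contrast_converges_to_reduction(self, reduction):
        # mean het rate inside a 3 Mb planted interval ~ reduction * theta
        theta = 1e-3
        layout = ss.GenomeLayout([("1", 9_000_000)])
        sweep = ss.PlantedSweep("P", "1", 3_000_000, 6_000_000, reduction)
        rec = ss.simulate_genotypes(
            one_pop_config(layout, (sweep,), theta=theta, seed=11)
        )
        het = rec[rec["genotype_class"] == "het"]
        inside = het["position"].between(3_000_001, 6_000_000).sum()
        mean = reduction * theta * 3e6
        assert abs(inside - mean) <= 4 * np.sqrt(max(mean, 1.0))

    def test_same_seed_is_reproducible_different_seed_is_not(self):
        layout = ss.GenomeLayout([("1", 2_000_000), ("2", 1_000_000)])
        a = ss.simulate_genotypes(one_pop_config(layout, n_ind=2, seed=5))
        b = ss.simulate_genotypes(one_pop_config(layout, n_ind=2, seed=5))
        c = ss.simulate_genotypes(one_pop_config(layout, n_ind=2, seed=6))
        pd.testing.assert_frame_equal(a, b)
        assert not a.equals(c)

    def test_planted_interval_outside_chromosome_rejected(self):
        layout = ss.GenomeLayout([("1", 1_000_000)])
        with pytest.raises(CoordinateError):
            one_pop_config(layout, (ss.PlantedSweep("P", "1", 0, 2_000_000, 0.5),))

    def test_unknown_population_in_planted_sweep_rejected(self):
        layout = ss.GenomeLayout([("1", 1_000_000)])
        with pytest.raises(ConfigurationError):
            one_pop_config(layout, (ss.PlantedSweep("Q", "1", 0, 300_000, 0.5),))

    def test_depth_and_gq_models_span_filter_boundaries(self):
        layout = ss.GenomeLayout([("1", 10_000_000)])
        rec = ss.simulate_genotypes(one_pop_config(layout, seed=1))
        assert rec["depth"].min() < 5 and rec["depth"].max() > 10
        gq_ge20 = (rec["genotype_quality"] >= 20).mean()
        assert 0.8 < gq_ge20 < 0.9


class TestVcfOutput:
    def test_round_trip_preserves_calls(self, tmp_path):
        layout = ss.GenomeLayout([("1", 2_000_000), ("2", 800_000)])
        cfg = ss.SimulationConfig(
            layout=layout, populations=(("A", 3), ("B", 2)), theta=1e-3, seed=9
        )
        rec = ss.simulate_genotypes(cfg)
        paths = ss.write_population_vcfs(rec, cfg, tmp_path)
        for pop in ("A", "B"):
            back, samples = ss.read_vcf_genotypes(paths[pop], pop)
            assert samples == cfg.individuals(pop)
            want = rec[rec["population"] == pop]
            key = ["chromosome", "position", "individual"]
            merged = want.merge(back, on=key, suffixes=("_sim", "_vcf"))
            assert len(merged) == len(want) == len(back)
            assert (merged["genotype_class_sim"] == merged["genotype_class_vcf"]).all()
            assert (merged["depth_sim"] == merged["depth_vcf"]).all()
            assert (
                merged["genotype_quality_sim"] == merged["genotype_quality_vcf"]
            ).all()

    def test_vcf_bytes_deterministic(self, tmp_path):
        layout = ss.GenomeLayout([("1", 1_000_000)])
        cfg = one_pop_config(layout, n_ind=2, seed=21)
        for d in ("a", "b"):
            ss.write_population_vcfs(
                ss.simulate_genotypes(cfg), cfg, tmp_path / d
            )
        assert (tmp_path / "a" / "P.vcf").read_bytes() == (
            tmp_path / "b" / "P.vcf"
        ).read_bytes()

    def test_pysam_reads_the_written_vcf(self, tmp_path):
        # independent reader: pysam must agree on sites and sample fields
        pysam = pytest.importorskip("pysam")
        layout = ss.GenomeLayout([("1", 500_000)])
        cfg = one_pop_config(layout, n_ind=2, seed=2)
        rec = ss.simulate_genotypes(cfg)
        paths = ss.write_population_vcfs(rec, cfg, tmp_path)
        n_calls = 0
        with pysam.VariantFile(str(paths["P"])) as vf:
            for site in vf:
                for sample in site.samples.values():
                    gt = sample["GT"]
                    if gt is None or gt[0] is None:
                        continue
                    n_calls += 1
                    cls = "het" if gt[0] != gt[1] else "hom_nonref"
                    row = rec[
                        (rec["position"] == site.pos)
                        & (rec["individual"] == sample.name)
                    ]
                    assert len(row) == 1
                    assert row["genotype_class"].iloc[0] == cls
                    assert row["depth"].iloc[0] == sample["DP"]
        assert n_calls == len(rec)


class TestDiscreteDistribution:
    def test_probabilities_validated(self):
        with pytest.raises(ConfigurationError):
            DiscreteDistribution([1, 2], [0.7, 0.7])

    def test_gq_default_mass_at_or_above_cutoff(self):
        model = default_gq_model()
        assert model.probs[model.values >= 20].sum() == pytest.approx(0.85)


class TestReferenceOverlapRegions:
    def test_has_23_records(self):
        assert len(ss.load_turkey_overlap_regions()) == 23

    def test_chromosome1_record(self):
        (rec,) = [
            r for r in ss.load_turkey_overlap_regions() if r.chromosome == "1"
        ]
        assert rec.populations == {"Nset", "RP"}
        assert (rec.start, rec.end) == (180_000_000, 181_800_000)
        assert (rec.span_start, rec.span_end) == (179_100_000, 181_800_000)

    def test_chromosome14_record(self):
        (rec,) = [
            r for r in ss.load_turkey_overlap_regions() if r.chromosome == "14"
        ]
        assert rec.populations == {"L1", "L3", "L6", "BvSW"}

    def test_round_trip(self, tmp_path):
        regions = ss.load_turkey_overlap_regions()
        path = tmp_path / "regions.tsv"
        write_overlap_regions_tsv(regions, path)
        assert read_overlap_regions_tsv(path) == regions

    def test_malformed_file_names_the_line(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text(
            "chrom\tsweep_start\tsweep_end\toverlap_start\toverlap_end\tpopulations\n"
            "1\t0\t100\tx\t200\tA,B\n"
        )
        with pytest.raises(FixtureParseError, match="bad.tsv:2"):
            read_overlap_regions_tsv(path)
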