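# sweepscan

Genome-wide detection of candidate selective sweeps from windowed
heterozygosity, for resequencing panels of small populations — the setting
of domesticated-bird diversity scans such as the ten-population domestic
turkey panel (commercial lines L1–L7 and the heritage varieties BvSW,
Nset, RP), where strong directional selection leaves multi-Mb stretches of
depleted polymorphism.

## Method

For each population, per-individual genotype calls are filtered (read
depth 5–10× inclusive, the upper bound acting as a crude repeat filter;
genotype quality ≥ 20) and the retained heterozygous calls are counted in
300 Kb bins. The bin heterozygosity

&nbsp;&nbsp;*H(b)* = (1/*n*) Σ<sub>i</sub> het<sub>i</sub>(*b*) / width(*b*)

is the mean over the *n* individuals of heterozygous sites per bp. A
candidate sweep is a maximal run of ≥ 5 consecutive bins with
*H(b)* ≤ *t*. The genome-wide threshold *t* is calibrated separately per
population by permutation: each replicate shuffles the genome-wide
multiset of bin values into the fixed chromosome/bin structure and records
the *minimax run threshold* — min over all 5-bin windows of the window
maximum, the smallest value admitting one significant region — and *t* is
the lower 5% quantile of 7,000 replicate thresholds, so a null genome
yields at least one sweep with 5% probability. Sweeps from different
populations are intersected at bp resolution; maximal intervals covered by
≥ 2 populations become overlapping sweep regions, the rest are
population-specific.

A synthetic-data module generates genotype calls with exactly this
statistical structure (Poisson-placed sites at a background rate of
~1.07 het SNPs per Kb, planted low-diversity intervals, depths and
qualities straddling the filters) and writes one VCF per population, so
the whole pipeline is testable end to end against planted truth. The
package also ships the 23 published multi-population turkey overlap
regions as reference data for summary operations.

## Worked example

```python
import sweepscan as ss

layout = ss.GenomeLayout([("1", 4_500_000), ("2", 4_500_000), ("3", 4_500_000)])
sim = ss.SimulationConfig(
    layout=layout,
    populations=(("P1", 3), ("P2", 3), ("P3", 3)),
    theta=1e-3,
    planted_sweeps=(ss.PlantedSweep("shared", "1", 1_500_000, 3_600_000, 0.02),),
    seed=42,
)
manifest = ss.run_pipeline(
    ss.RunConfig(outdir="scratch/demo", seed=3, simulation=sim, n_reps=200)
)
print(manifest["thresholds"])
print(manifest["n_overlap_regions"], manifest["overlap_populations"])
```

prints

```
{'P1': 0.0004455555555555556, 'P2': 0.0004477777777777778, 'P3': 0.0004477777777777778}
1 [['P1', 'P2', 'P3']]
```

Each population's permutation threshold (~4.5×10⁻⁴ het/bp) sits in the
lower tail of the ~1×10⁻³ background, and the single overlap region is the
planted 2.1 Mb shared sweep, recovered in all three populations. The same
stages are available from the shell (`sweepscan simulate | windows |
threshold | call | overlap | heatmap | run`); see `sweepscan --help`.

The reference overlap table is one call away:

```python
regions = ss.load_turkey_overlap_regions()          # 23 records
summary = ss.overlap_summary(regions, [], ss.TURKEY_POPULATION_CLASSES)
print(summary["n_overlap_chromosomes"])             # 13
```

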