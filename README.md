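# mosaicsim

Simulation toolkit for benchmarking local-ancestry inference (LAI) on
plant-like genomes.  It generates chromosome-wide genotype datasets for
admixed crop-like populations — including selfing and vegetative
(clonal) reproduction modes — tracks the true local ancestry of every
sampled chromosome exactly, and scores any inferred local-ancestry
matrix against that truth.

The simulation has three stages:

1. **Founders** (`mosaicsim.founders`) — coalescent simulation (msprime)
   of founder haplotypes from `S` source populations that split
   simultaneously from one ancestral population and diverge by pure
   drift; the expected pairwise Weir–Cockerham FST between sources is
   `1 − exp(−τ)`.  A dependency-free `"windows"` backend (independent
   single-locus windows with an explicit Wright–Fisher drift chain) is
   available for testing.
2. **Forward reproduction** (`mosaicsim.forward`) — `P` diploid
   populations founded from whole founder chromosomes and reproduced
   for `G` generations under per-population, per-generation mixes of
   within-population mating, across-population mating, selfing and
   vegetative propagation.  Sexual gametes get exactly one crossover on
   the 1-Morgan map; mutation flips existing segregating sites only;
   every chromosome carries an exact ancestry-tract list.
3. **Sampling & output** (`mosaicsim.sampling_io`) — individuals sampled
   with replacement, monomorphic SNPs filtered jointly, and datasets
   written as VCF v4.2, plink `.ped`/`.map`, truth dosage/tract tables
   and a checksum manifest.

Scoring (`mosaicsim.evaluation`) uses the accuracy metric
`alpha = 1 − Σ_s |z_s − x_s| / 2` averaged over markers and admixed
individuals, with a uniform `1/S` random baseline and optional
missing-source masking.  Summary statistics (`mosaicsim.stats`) include
multi-locus Weir–Cockerham (1984) FST, observed/expected
heterozygosities and ancestry block-size distributions.

Six scenario presets mirror the study design: `DiffGenSam`, `SamBal`,
`SrcNum`, `SrcMiss`, `SrcSelf`, `AdmxVegProp`
(`mosaicsim.scenarios.build_scenario`).

## CLI

```sh
# run a scenario preset and write per-replicate datasets
mosaicsim simulate --scenario SrcNum --reps 10 --seed 1 --out runs/srcnum
mosaicsim simulate --scenario SrcMiss --un 0.15 --reps 5 --seed 1 --out runs/srcmiss

# score an external LAI result (plain-text matrix: n*M rows in
# individual-major order, S columns of ancestry proportions)
mosaicsim score --truth runs/srcnum/rep_000/truth_dosage.tsv \
    --samples runs/srcnum/rep_000/samples.tsv \
    --inferred my_lai_output.txt --out report.tsv

# recompute summary statistics from a written dataset
mosaicsim stats --dataset runs/srcnum/rep_000
```

Scenario parameters can also be given as a flat YAML file via
`--config` (keys mirror `build_scenario` arguments).

## Python API

```python
import mosaicsim as ms

cfg = ms.build_scenario("SrcNum", S=4, replicates=10, seed=1)
results, aggregate = ms.run_replicates(cfg)
print(aggregate["alpha_random_mean"])
```

## Format notes

* VCF coordinates are 1-based (`POS = 1 + floor(map_fraction * L)`,
  collisions bumped to the next free coordinate); GT is phased (`|`)
  by default since the simulated truth is phased — `--unphased` emits
  `/` separators.
* `truth_tracts.tsv` uses BED conventions: 0-based, half-open bp
  intervals; source labels are 1-based in all files.
* plink `.ped` uses 1/2 allele coding by default (`allele_coding="AT"`
  switches to nucleotide coding); phase is lost in `.ped` by design.
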