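import numpy as np
import pytest

from mosaicsim import (FounderConfig, ReproductionSchedule, SampleSet,
                       found_populations, run_forward, sample_individuals,
                       simulate_founders)
from mosaicsim.forward import AncestryTract


def small_founder_config(**overrides) -> FounderConfig:
    """Cheap windows-backend founder config for desk-scale tests."""
    defaults = dict(
        n_sources=3,
        haplotypes_per_source=40,
        tau=0.2,
        theta=1e-4,
        rho=1e-4,
        backend="windows",
        n_windows=120,
        seed=7,
    )
    defaults.update(overrides)
    return FounderConfig(**defaults)


@pytest.fixture(scope="session")
def small_panel():
    return simulate_founders(small_founder_config())


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def run_small_admixture(panel, n_p=20, generations=10, mu=0.0, seed=5,
                        schedule=None, contributions=None, sizes=None):
    """Found a 3-pop (2 source + 1 admixed) set and reproduce it."""
    s = panel.n_sources
    if contributions is None:
        rows = [np.eye(s)[0], np.eye(s)[1], np.full(s, 1 / s)]
        contributions = np.array(rows)
    if sizes is None:
        sizes = np.full(len(contributions), n_p)
    gen = np.random.default_rng(seed)
    pops = found_populations(panel, contributions, sizes, gen)
    if schedule is None:
        schedule = ReproductionSchedule.constant(len(sizes), generations)
    return run_forward(pops, schedule, mu, gen)


def make_sample_set(genotypes, positions=None, pops=None, admixed=None,
                    n_sources=2, source_of_individual=None,
                    map_length_bp=40_000_000) -> SampleSet:
    """Hand-built SampleSet with single-tract truth for unit tests."""
    genotypes = np.asarray(genotypes, dtype=np.uint8)
    n, m = genotypes.shape[:2]
    if positions is None:
        positions = (np.arange(m) + 0.5) / m
    if pops is None:
        pops = np.zeros(n, dtype=int)
    if admixed is None:
        admixed = np.zeros(n, dtype=bool)
    if source_of_individual is None:
        source_of_individual = np.zeros(n, dtype=int)
    z = np.zeros((n, m, n_sources), dtype=np.float32)
    tracts = []
    for i in range(n):
        s = int(source_of_individual[i])
        z[i, :, s] = 1.0
        t = (AncestryTract(0.0, 1.0, s),)
        tracts.append((t, t))
    from mosaicsim.sampling_io import map_fraction_to_bp

    return SampleSet(
        genotypes=genotypes,
        positions=np.asarray(positions, dtype=float),
        bp_positions=map_fraction_to_bp(positions, map_length_bp),
        population_of_individual=np.asarray(pops, dtype=int),
        is_admixed=np.asarray(admixed, dtype=bool),
        Z=z,
        tracts=tracts,
        n_sources=n_sources,
        map_length_bp=map_length_bp,
    )
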