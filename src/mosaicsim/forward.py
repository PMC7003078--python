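"""Forward-in-time reproduction with exact ancestry-tract bookkeeping.

Populations of diploid individuals are founded from whole founder
chromosomes and reproduced generation by generation under a per-population
mix of four modes: within-population mating, across-population mating,
selfing and vegetative (clonal) propagation.  Sexual gametes are produced
by a single uniformly placed crossover (1-Morgan map), mutation flips
alleles at existing segregating sites only, and every chromosome carries
an ordered list of ancestry tracts that tiles the [0, 1) map exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError, ParameterError
from .founders import FounderPanel

# reproduction-mode column indices of a ReproductionSchedule
WITHIN = 0
ACROSS = 1
SELFING = 2
VEGETATIVE = 3
MODE_NAMES = ("within_mating", "across_mating", "selfing", "vegetative")


@dataclass(frozen=True, slots=True)
class AncestryTract:
    """Half-open map interval ``[start, end)`` inherited from one source."""

    start: float
    end: float
    source: int


@dataclass(slots=True)
class ChromosomeCopy:
    """One haploid chromosome: allele vector plus its ancestry tracts."""

    alleles: np.ndarray
    tracts: tuple[AncestryTract, ...]

    def source_at(self, positions: np.ndarray) -> np.ndarray:
        """Source label of each query map position (vectorized)."""
        starts = np.fromiter((t.start for t in self.tracts), dtype=float)
        sources = np.fromiter((t.source for t in self.tracts), dtype=np.int64)
        idx = np.searchsorted(starts, positions, side="right") - 1
        return sources[idx]

    def n_junctions(self) -> int:
        return len(self.tracts) - 1


@dataclass(slots=True)
class Individual:
    copies: tuple[ChromosomeCopy, ChromosomeCopy]
    population: int


@dataclass
class ReproductionSchedule:
    """Per-population, per-generation proportions of the four modes.

    ``proportions`` has shape ``(P, G, 4)``; each 4-vector is nonnegative
    and sums to 1 (tolerance 1e-9).
    """

    proportions: np.ndarray

    def __post_init__(self) -> None:
        self.proportions = np.asarray(self.proportions, dtype=float)
        if self.proportions.ndim != 3 or self.proportions.shape[2] != 4:
            raise ParameterError("schedule must have shape (P, G, 4)")
        if np.any(self.proportions < 0):
            raise ParameterError("mode proportions must be nonnegative")
        sums = self.proportions.sum(axis=2)
        if np.any(np.abs(sums - 1) > 1e-9):
            raise ParameterError("each mode 4-vector must sum to 1")

    @property
    def n_populations(self) -> int:
        return self.proportions.shape[0]

    @property
    def n_generations(self) -> int:
        return self.proportions.shape[1]

    @classmethod
    def constant(cls, n_populations: int, n_generations: int,
                 within: float = 1.0, across: float = 0.0,
                 selfing: float = 0.0, vegetative: float = 0.0) -> "ReproductionSchedule":
        """Same mode mix for every population and generation."""
        row = np.array([within, across, selfing, vegetative], dtype=float)
        return cls(np.tile(row, (n_populations, n_generations, 1)))

    def with_vegetative_tail(self, population: int, t_veg: int) -> "ReproductionSchedule":
        """Make the last ``t_veg`` generations of one population clonal."""
        if not 0 <= t_veg <= self.n_generations:
            raise ParameterError("t_veg out of range")
        props = self.proportions.copy()
        if t_veg > 0:
            props[population, self.n_generations - t_veg :, :] = [0, 0, 0, 1]
        return ReproductionSchedule(props)


@dataclass
class PopulationSet:
    """The P forward-simulated populations at a given generation."""

    populations: list[list[Individual]]
    positions: np.ndarray
    n_sources: int
    generation: int = 0
    map_length_bp: int = 0

    @property
    def n_populations(self) -> int:
        return len(self.populations)

    @property
    def sizes(self) -> np.ndarray:
        return np.array([len(p) for p in self.populations])


def _as_rng(rng) -> np.random.Generator:
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)


def found_populations(panel: FounderPanel, contributions, sizes, rng,
                      recorder: list | None = None) -> PopulationSet:
    """Found ``P`` populations by drawing whole founder chromosomes.

    Each individual's two chromosome copies are drawn independently:
    first a source with the population's contribution probabilities, then
    a haplotype uniformly with replacement among that source's founders.
    Every copy starts with a single tract covering [0, 1).
    """
    rng = _as_rng(rng)
    contributions = np.asarray(contributions, dtype=float)
    sizes = np.asarray(sizes, dtype=int)
    n_sources = panel.n_sources
    if contributions.ndim != 2 or contributions.shape[1] != n_sources:
        raise ParameterError("contributions must be a P x S matrix")
    if len(sizes) != contributions.shape[0]:
        raise ParameterError("sizes and contributions disagree on P")
    if np.any(sizes <= 0):
        raise ParameterError("population sizes must be positive")
    if np.any(contributions < 0) or np.any(np.abs(contributions.sum(axis=1) - 1) > 1e-9):
        raise ParameterError("each contributions row must be nonnegative and sum to 1")

    source_haps = [panel.haplotype_indices_of_source(s) for s in range(n_sources)]
    for p_row in contributions:
        for s, c in enumerate(p_row):
            if c > 0 and len(source_haps[s]) == 0:
                raise ParameterError(f"source {s} contributes but has no founders")

    populations: list[list[Individual]] = []
    founding_events: list[list[tuple]] = []
    for p, (row, n_p) in enumerate(zip(contributions, sizes)):
        pop: list[Individual] = []
        pop_events: list[tuple] = []
        src_draws = rng.choice(n_sources, size=(n_p, 2), p=row)
        for i in range(n_p):
            copies = []
            ev = []
            for c in range(2):
                s = int(src_draws[i, c])
                h = int(rng.choice(source_haps[s]))
                copies.append(
                    ChromosomeCopy(
                        alleles=panel.haplotypes[h],
                        tracts=(AncestryTract(0.0, 1.0, s),),
                    )
                )
                ev.append((s, h))
            pop.append(Individual(copies=(copies[0], copies[1]), population=p))
            pop_events.append(tuple(ev))
        populations.append(pop)
        founding_events.append(pop_events)
    if recorder is not None:
        # founding record: per population, per individual, ((s, h), (s, h))
        recorder.append(founding_events)
    return PopulationSet(
        populations=populations,
        positions=panel.positions,
        n_sources=n_sources,
        generation=0,
        map_length_bp=panel.map_length_bp,
    )


def _splice_tracts(left: tuple[AncestryTract, ...], right: tuple[AncestryTract, ...],
                   b: float) -> tuple[AncestryTract, ...]:
    """Tracts of ``left`` on [0, b) followed by ``right`` on [b, 1)."""
    out: list[AncestryTract] = []
    for t in left:
        if t.start >= b:
            break
        out.append(t if t.end <= b else AncestryTract(t.start, b, t.source))
    tail: list[AncestryTract] = []
    for t in right:
        if t.end <= b:
            continue
        tail.append(t if t.start >= b else AncestryTract(b, t.end, t.source))
    if out and tail and out[-1].source == tail[0].source:
        out[-1] = AncestryTract(out[-1].start, tail[0].end, out[-1].source)
        tail = tail[1:]
    out.extend(tail)
    return tuple(out)


def _meiosis(parent: Individual, positions: np.ndarray, rng: np.random.Generator):
    b = rng.random()
    k = int(rng.integers(2))
    c0, c1 = parent.copies[k], parent.copies[1 - k]
    idx = int(np.searchsorted(positions, b, side="left"))
    alleles = np.concatenate([c0.alleles[:idx], c1.alleles[idx:]])
    tracts = _splice_tracts(c0.tracts, c1.tracts, b)
    return ChromosomeCopy(alleles, tracts), b, k


def meiosis(parent: Individual, positions: np.ndarray, rng) -> ChromosomeCopy:
    """One gamete with exactly one crossover at Uniform(0, 1).

    The starting copy is chosen with probability 1/2; the gamete takes
    alleles and tracts from it on [0, b) and from the other copy on
    [b, 1).  Adjacent same-source tracts at the breakpoint are merged.
    """
    gamete, _, _ = _meiosis(parent, positions, _as_rng(rng))
    return gamete


def _mutate(chrom: ChromosomeCopy, mu_site: float, rng: np.random.Generator):
    m = chrom.alleles.shape[0]
    n_flip = rng.binomial(m, mu_site) if mu_site > 0 else 0
    if n_flip == 0:
        return chrom, np.empty(0, dtype=np.int64)
    flip_idx = rng.choice(m, size=n_flip, replace=False)
    alleles = chrom.alleles.copy()
    alleles[flip_idx] ^= 1
    return ChromosomeCopy(alleles, chrom.tracts), flip_idx


def mutate_chromosome(chrom: ChromosomeCopy, mu_site: float, rng) -> ChromosomeCopy:
    """Flip each allele independently with probability ``mu_site``.

    Only existing segregating positions are affected and tracts are
    unchanged; no new segregating sites can appear.  Returns the input
    object unchanged when no site flips.
    """
    if not 0 <= mu_site <= 1:
        raise ParameterError("mu_site must lie in [0, 1]")
    out, _ = _mutate(chrom, mu_site, _as_rng(rng))
    return out


def advance_generation(pops: PopulationSet, mode_props: np.ndarray, mu_site: float,
                       rng, allow_incidental_selfing: bool = False,
                       recorder: list | None = None) -> PopulationSet:
    """Produce the next generation under one schedule column.

    ``mode_props`` has shape ``(P, 4)``.  Every offspring draws its mode
    independently; mutation is applied to both offspring chromosomes
    whatever the reproduction mode.  Population sizes are constant.
    """
    rng = _as_rng(rng)
    if not 0 <= mu_site <= 1:
        raise ParameterError("mu_site must lie in [0, 1]")
    mode_props = np.asarray(mode_props, dtype=float)
    n_pops = pops.n_populations
    if mode_props.shape != (n_pops, 4):
        raise ParameterError("mode_props must have shape (P, 4)")
    if np.any(mode_props < 0) or np.any(np.abs(mode_props.sum(axis=1) - 1) > 1e-9):
        raise ParameterError("each mode 4-vector must sum to 1")
    if n_pops == 1 and mode_props[0, ACROSS] > 0:
        raise ConfigurationError("across-population mating requires P >= 2")

    positions = pops.positions
    new_populations: list[list[Individual]] = []
    gen_events: list[list[dict]] = []
    for p, pop in enumerate(pops.populations):
        n_p = len(pop)
        modes = rng.choice(4, size=n_p, p=mode_props[p])
        offspring: list[Individual] = []
        pop_events: list[dict] = []
        for i in range(n_p):
            mode = int(modes[i])
            gam_events = []
            if mode == VEGETATIVE:
                j = int(rng.integers(n_p))
                copies = pop[j].copies
                parents = ((p, j),)
            elif mode == SELFING:
                j = int(rng.integers(n_p))
                g1, b1, k1 = _meiosis(pop[j], positions, rng)
                g2, b2, k2 = _meiosis(pop[j], positions, rng)
                copies = (g1, g2)
                parents = ((p, j), (p, j))
                gam_events = [(b1, k1), (b2, k2)]
            elif mode == ACROSS:
                j = int(rng.integers(n_p))
                q = int(rng.integers(n_pops - 1))
                if q >= p:
                    q += 1
                j2 = int(rng.integers(len(pops.populations[q])))
                g1, b1, k1 = _meiosis(pop[j], positions, rng)
                g2, b2, k2 = _meiosis(pops.populations[q][j2], positions, rng)
                copies = (g1, g2)
                parents = ((p, j), (q, j2))
                gam_events = [(b1, k1), (b2, k2)]
            else:  # WITHIN
                j = int(rng.integers(n_p))
                if allow_incidental_selfing or n_p == 1:
                    j2 = int(rng.integers(n_p))
                else:
                    j2 = int(rng.integers(n_p - 1))
                    if j2 >= j:
                        j2 += 1
                g1, b1, k1 = _meiosis(pop[j], positions, rng)
                g2, b2, k2 = _meiosis(pop[j2], positions, rng)
                copies = (g1, g2)
                parents = ((p, j), (p, j2))
                gam_events = [(b1, k1), (b2, k2)]

            c1, f1 = _mutate(copies[0], mu_site, rng)
            c2, f2 = _mutate(copies[1], mu_site, rng)
            offspring.append(Individual(copies=(c1, c2), population=p))
            if recorder is not None:
                pop_events.append(
                    {
                        "mode": mode,
                        "parents": parents,
                        "gametes": gam_events,
                        "flips": (f1, f2),
                    }
                )
        new_populations.append(offspring)
        gen_events.append(pop_events)
    if recorder is not None:
        recorder.append(gen_events)
    return PopulationSet(
        populations=new_populations,
        positions=positions,
        n_sources=pops.n_sources,
        generation=pops.generation + 1,
        map_length_bp=pops.map_length_bp,
    )


def run_forward(pops: PopulationSet, schedule: ReproductionSchedule, mu_site: float,
                rng, allow_incidental_selfing: bool = False,
                recorder: list | None = None) -> PopulationSet:
    """Apply :func:`advance_generation` once per schedule column."""
    rng = _as_rng(rng)
    if schedule.n_populations != pops.n_populations:
        raise ParameterError("schedule and populations disagree on P")
    for g in range(schedule.n_generations):
        pops = advance_generation(
            pops, schedule.proportions[:, g, :], mu_site, rng,
            allow_incidental_selfing=allow_incidental_selfing,
            recorder=recorder,
        )
    return pops


def validate_tracts(tracts: tuple[AncestryTract, ...]) -> None:
    """Assert the tract tiling invariant: sorted, disjoint, covering [0, 1)."""
    if not tracts:
        raise AssertionError("empty tract list")
    if tracts[0].start != 0.0 or tracts[-1].end != 1.0:
        raise AssertionError("tracts do not cover [0, 1)")
    for a, b in zip(tracts, tracts[1:]):
        if a.end != b.start:
            raise AssertionError("tracts are not contiguous")
        if a.source == b.source:
            raise AssertionError("adjacent tracts share a source (unmerged)")
    for t in tracts:
        if not t.start < t.end:
            raise AssertionError("empty or inverted tract")
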