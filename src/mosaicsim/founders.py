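"""Founder haplotype generation under a star-shaped pure-drift divergence model.

``S`` source populations split simultaneously from a single ancestral
population and subsequently diverge by drift alone: all segregating
variation is standing variation of the ancestral population, so the
expected pairwise differentiation between sources is the classic
pure-drift value ``FST = 1 - exp(-tau)`` where ``tau`` is the divergence
time scaled by the pairwise coalescence timescale.

Two backends are provided:

* ``"msprime"`` (default) — coalescent simulation of a recombining
  1-Morgan chromosome.  Mutations are placed only on branches older than
  the split so that post-split evolution is pure drift, which is what
  makes the ``1 - exp(-tau)`` calibration hold for the realized
  Weir-Cockerham FST.
* ``"windows"`` — a slow, dependency-free fallback that simulates one
  independent locus per map window with an explicit Wright-Fisher
  frequency chain per source.  It reproduces the drift calibration but
  carries no within-source linkage disequilibrium; intended for tests
  and environments without the coalescent engine.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import EmptyPanelError, ParameterError

#: Internal diploid effective size used to de-scale theta/rho/tau for the
#: coalescent engine.  Results depend only on the scaled parameters.
DEFAULT_NE = 1000

#: Default physical length of the 1-Morgan chromosome in base pairs
#: (rho = 1e-4 per site with the default scaling gives 1 Morgan total).
DEFAULT_MAP_LENGTH_BP = 40_000_000

_BACKENDS = ("msprime", "windows")


@dataclass(frozen=True)
class FounderConfig:
    """Parameters of the founder (divergence) simulation.

    Attributes
    ----------
    n_sources
        Number of source populations ``S`` (>= 2).
    haplotypes_per_source
        Founder chromosomes sampled per source (>= 2).
    tau
        Divergence time in scaled units; expected pairwise FST between
        sources is ``1 - exp(-tau)``.
    theta
        Scaled per-site mutation rate ``4*Ne*mu`` (> 0).
    rho
        Scaled per-site recombination rate ``4*Ne*r`` (>= 0).
    map_length_bp
        Physical length of the 1-Morgan chromosome in base pairs.
    seed
        Seed controlling the whole founder simulation.
    backend
        ``"msprime"`` or ``"windows"``.
    n_windows
        Number of single-locus windows for the ``"windows"`` backend.
    """

    n_sources: int = 3
    haplotypes_per_source: int = 300
    tau: float = 0.2
    theta: float = 1e-4
    rho: float = 1e-4
    map_length_bp: int = DEFAULT_MAP_LENGTH_BP
    seed: int = 1
    backend: str = "msprime"
    n_windows: int = 200

    def __post_init__(self) -> None:
        if self.n_sources < 2:
            raise ParameterError("n_sources must be >= 2")
        if self.haplotypes_per_source < 2:
            raise ParameterError("haplotypes_per_source must be >= 2")
        if self.tau < 0:
            raise ParameterError("tau must be >= 0")
        if self.theta <= 0:
            raise ParameterError("theta must be > 0")
        if self.rho < 0:
            raise ParameterError("rho must be >= 0")
        if self.map_length_bp < 1:
            raise ParameterError("map_length_bp must be >= 1")
        if self.backend not in _BACKENDS:
            raise ParameterError(f"unknown backend {self.backend!r}")
        if self.backend == "windows" and self.n_windows < 1:
            raise ParameterError("n_windows must be >= 1")

    @property
    def mu_site(self) -> float:
        """Per-site per-generation mutation rate implied by theta."""
        return self.theta / (4 * DEFAULT_NE)


@dataclass
class FounderPanel:
    """Founder haplotypes from ``S`` diverged source populations.

    Attributes
    ----------
    positions
        Strictly increasing variant positions as map fractions in [0, 1).
    haplotypes
        ``(n_haplotypes, M0)`` matrix of 0/1 alleles (uint8).
    source_of_haplotype
        0-based source label of each haplotype row.
    map_length_bp
        Physical chromosome length carried along for coordinate export.
    """

    positions: np.ndarray
    haplotypes: np.ndarray
    source_of_haplotype: np.ndarray
    map_length_bp: int = DEFAULT_MAP_LENGTH_BP

    @property
    def n_sources(self) -> int:
        return int(self.source_of_haplotype.max()) + 1

    @property
    def n_sites(self) -> int:
        return self.haplotypes.shape[1]

    def haplotype_indices_of_source(self, source: int) -> np.ndarray:
        return np.flatnonzero(self.source_of_haplotype == source)

    def validate(self) -> None:
        if self.haplotypes.shape != (len(self.source_of_haplotype), len(self.positions)):
            raise ParameterError("panel shape mismatch")
        if np.any(np.diff(self.positions) <= 0):
            raise ParameterError("positions must be strictly increasing")
        if np.any((self.positions < 0) | (self.positions >= 1)):
            raise ParameterError("positions must lie in [0, 1)")
        freqs = self.haplotypes.sum(axis=0)
        if np.any((freqs == 0) | (freqs == self.haplotypes.shape[0])):
            raise ParameterError("panel contains monomorphic columns")


def expected_fst(tau) -> float:
    """Expected pairwise FST under pure-drift star divergence: ``1 - exp(-tau)``."""
    tau = np.asarray(tau, dtype=float)
    if np.any(tau < 0):
        raise ParameterError("tau must be >= 0")
    out = -np.expm1(-tau)
    return float(out) if out.ndim == 0 else out


def simulate_founders(cfg: FounderConfig) -> FounderPanel:
    """Simulate a :class:`FounderPanel` according to ``cfg``.

    Deterministic given ``cfg.seed``.  Raises
    :class:`~mosaicsim.errors.EmptyPanelError` if no site is polymorphic
    across the full panel.
    """
    if cfg.backend == "msprime":
        panel = _simulate_msprime(cfg)
    else:
        panel = _simulate_windows(cfg)
    if panel.n_sites == 0:
        raise EmptyPanelError(
            "founder simulation produced zero segregating sites; "
            "increase theta or map_length_bp"
        )
    panel.validate()
    return panel


def _polymorphic_columns(haplotypes: np.ndarray) -> np.ndarray:
    counts = haplotypes.sum(axis=0)
    return (counts > 0) & (counts < haplotypes.shape[0])


def _simulate_msprime(cfg: FounderConfig) -> FounderPanel:
    import msprime

    ne = DEFAULT_NE
    split_time = cfg.tau * 2 * ne  # pairwise coalescence rate is 1/(2*Ne) per gen
    mu = cfg.theta / (4 * ne)
    rec = cfg.rho / (4 * ne)
    seeds = _engine_seeds(cfg.seed)

    demography = msprime.Demography()
    demography.add_population(name="anc", initial_size=ne)
    for s in range(cfg.n_sources):
        demography.add_population(name=f"src{s}", initial_size=ne)
    sample_pops = [f"src{s}" for s in range(cfg.n_sources)]
    if split_time > 0:
        demography.add_population_split(
            time=split_time, derived=sample_pops, ancestral="anc"
        )
    else:
        # tau == 0: sources are indistinguishable; sample from the
        # ancestral population directly and relabel afterwards.
        sample_pops = ["anc"] * cfg.n_sources
        for s in range(cfg.n_sources):
            demography[f"src{s}"].initial_size = 0

    samples = [
        msprime.SampleSet(cfg.haplotypes_per_source, population=p, ploidy=1)
        for p in sample_pops
    ]
    ts = msprime.sim_ancestry(
        samples=samples,
        demography=demography,
        sequence_length=cfg.map_length_bp,
        recombination_rate=rec,
        random_seed=seeds[0],
    )
    ts = msprime.sim_mutations(
        ts,
        rate=mu,
        model=msprime.BinaryMutationModel(),
        start_time=split_time if split_time > 0 else None,
        random_seed=seeds[1],
    )
    haplotypes = ts.genotype_matrix().T.astype(np.uint8)
    positions = ts.sites_position / cfg.map_length_bp
    keep = _polymorphic_columns(haplotypes)
    source = np.repeat(np.arange(cfg.n_sources), cfg.haplotypes_per_source)
    return FounderPanel(
        positions=positions[keep],
        haplotypes=np.ascontiguousarray(haplotypes[:, keep]),
        source_of_haplotype=source,
        map_length_bp=cfg.map_length_bp,
    )


# Wright-Fisher chain resolution for the fallback backend: drift F after
# t = round(tau * n) generations of size-n binomial resampling is
# 1 - (1 - 1/n)^t ~= 1 - exp(-tau).
_WF_GENES = 1000


def _simulate_windows(cfg: FounderConfig) -> FounderPanel:
    rng = np.random.default_rng(np.random.SeedSequence((cfg.seed, 0x57494E)))
    n_win = cfg.n_windows
    positions = np.sort(rng.random(n_win))
    # enforce strict increase (ties virtually impossible with float64)
    while np.any(np.diff(positions) <= 0):
        positions = np.sort(rng.random(n_win))

    # ancestral frequencies from a truncated neutral SFS, f(p) ~ 1/p
    lo, hi = 1.0 / (2 * _WF_GENES), 1.0 - 1.0 / (2 * _WF_GENES)
    p0 = lo * (hi / lo) ** rng.random(n_win)

    t = int(round(cfg.tau * _WF_GENES))
    freqs = np.tile(p0, (cfg.n_sources, 1))
    for _ in range(t):
        freqs = rng.binomial(_WF_GENES, freqs) / _WF_GENES

    n_h = cfg.haplotypes_per_source
    haplotypes = np.empty((cfg.n_sources * n_h, n_win), dtype=np.uint8)
    for s in range(cfg.n_sources):
        haplotypes[s * n_h : (s + 1) * n_h] = (
            rng.random((n_h, n_win)) < freqs[s]
        ).astype(np.uint8)

    keep = _polymorphic_columns(haplotypes)
    source = np.repeat(np.arange(cfg.n_sources), n_h)
    return FounderPanel(
        positions=positions[keep],
        haplotypes=np.ascontiguousarray(haplotypes[:, keep]),
        source_of_haplotype=source,
        map_length_bp=cfg.map_length_bp,
    )


def _engine_seeds(seed: int, n: int = 2) -> list[int]:
    """Derive msprime-compatible seeds (1 .. 2^32-2) from a user seed."""
    state = np.random.SeedSequence(seed).generate_state(n, dtype=np.uint64)
    return [int(x % (2**32 - 2)) + 1 for x in state]
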