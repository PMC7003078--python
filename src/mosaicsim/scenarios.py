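"""Scenario presets, replicate runner and aggregation.

Six presets are provided (``DiffGenSam``, ``SamBal``, ``SrcNum``,
``SrcMiss``, ``SrcSelf``, ``AdmxVegProp``).  Unless overridden they use
300 founder haplotypes per source, 150 diploid individuals per
population, 50 forward generations, two admixed populations with equal
source contributions, 20 sampled individuals per source-representative
population and 40 per admixed population.

Replicate ``r`` of a run uses seed ``base_seed + r``; inside a replicate
the founder and forward stages draw from streams derived from that seed
with :class:`numpy.random.SeedSequence`, so replicates are independent
and every run is reproducible bit-for-bit.
"""

from __future__ import annotations

import dataclasses
import logging
import time
from dataclasses import dataclass, replace

import numpy as np

from .errors import ConfigurationError
from .evaluation import (AccuracyResult, missing_source_mask, overall_alpha,
                         random_inference)
from .forward import ReproductionSchedule, found_populations, run_forward
from .founders import FounderConfig, simulate_founders
from .sampling_io import SampleSet, filter_monomorphic, sample_individuals
from .stats import SummaryStats, mean_pairwise_fst, summarize

logger = logging.getLogger(__name__)

SCENARIO_NAMES = ("DiffGenSam", "SamBal", "SrcNum", "SrcMiss", "SrcSelf",
                  "AdmxVegProp")


@dataclass
class ScenarioConfig:
    """Fully resolved simulation scenario."""

    name: str
    founder: FounderConfig
    pop_sizes: np.ndarray               # n_p per population
    roles: tuple[str, ...]              # "source" or "admixed" per population
    contributions: np.ndarray           # P x S founding proportions
    schedule: ReproductionSchedule
    o_per_pop: np.ndarray               # sampled individuals per population
    missing_source: int | None = None   # 0-based source absent from the data
    replicates: int = 50
    base_seed: int = 1
    mu_site: float | None = None        # defaults to founder.mu_site
    allow_incidental_selfing: bool = False

    @property
    def n_populations(self) -> int:
        return len(self.pop_sizes)

    @property
    def admixed_flags(self) -> np.ndarray:
        return np.array([r == "admixed" for r in self.roles])

    @property
    def n_scored_sources(self) -> int:
        s = self.founder.n_sources
        return s - 1 if self.missing_source is not None else s

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["founder"] = dataclasses.asdict(self.founder)
        d["pop_sizes"] = self.pop_sizes.tolist()
        d["contributions"] = self.contributions.tolist()
        d["o_per_pop"] = self.o_per_pop.tolist()
        d["schedule"] = {"shape": list(self.schedule.proportions.shape)}
        return d


@dataclass
class ReplicateResult:
    seed: int
    m_before: int
    m_after: int
    summary: SummaryStats
    alpha_random: float
    alpha_n_cells: int
    runtime_s: float
    alpha_per_individual: np.ndarray | None = None
    sample: SampleSet | None = None
    accuracy: AccuracyResult | None = None


def _star_contributions(n_pops_src: int, n_sources: int,
                        n_pops_admx: int, admixed_row: np.ndarray) -> np.ndarray:
    rows = []
    for p in range(n_pops_src):
        row = np.zeros(n_sources)
        row[p] = 1.0
        rows.append(row)
    rows.extend([admixed_row] * n_pops_admx)
    return np.array(rows)


def build_scenario(name: str, *, tau: float | None = None, S: int | None = None,
                   tadm: int | None = None, op_src: int | None = None,
                   op_admx: int | None = None, op_src3: int | None = None,
                   un: float | None = None, slf: float | None = None,
                   tveg_values: list[int] | None = None,
                   n_haplotypes: int | None = None,
                   n_individuals: int | None = None,
                   replicates: int | None = None, seed: int = 1,
                   backend: str = "msprime", theta: float = 1e-4,
                   rho: float = 1e-4, map_length_bp: int | None = None,
                   n_windows: int | None = None,
                   allow_incidental_selfing: bool = False) -> ScenarioConfig:
    """Resolve a named preset (plus overrides) into a :class:`ScenarioConfig`."""
    if name not in SCENARIO_NAMES:
        raise ConfigurationError(
            f"unknown scenario {name!r}; choose from {SCENARIO_NAMES}"
        )
    if tadm is not None and name != "DiffGenSam":
        raise ConfigurationError("tadm only applies to DiffGenSam")
    if S is not None and name != "SrcNum":
        raise ConfigurationError("S only applies to SrcNum")
    if un is not None and name != "SrcMiss":
        raise ConfigurationError("un only applies to SrcMiss")
    if slf is not None and name != "SrcSelf":
        raise ConfigurationError("slf only applies to SrcSelf")
    if op_src3 is not None and name != "SamBal":
        raise ConfigurationError("op_src3 only applies to SamBal")
    if tveg_values is not None and name != "AdmxVegProp":
        raise ConfigurationError("tveg_values only applies to AdmxVegProp")

    tau = 0.2 if tau is None else tau
    n_h = 300 if n_haplotypes is None else n_haplotypes
    n_p = 150 if n_individuals is None else n_individuals
    op_src = 20 if op_src is None else op_src
    op_admx_default = 10 if name == "AdmxVegProp" else 40
    op_admx = op_admx_default if op_admx is None else op_admx
    replicates = 50 if replicates is None else replicates

    n_sources = 4 if name == "SrcMiss" else (3 if S is None else S)
    missing = None

    if name == "SrcMiss":
        un = 0.15 if un is None else un
        if not 0 <= un < 1:
            raise ConfigurationError("un must lie in [0, 1)")
        missing = n_sources - 1
        n_src_pops = n_sources - 1
        admix_row = np.full(n_sources, (1 - un) / (n_sources - 1))
        admix_row[missing] = un
        if un == 0:
            # degenerate: the "missing" source contributes nothing
            admix_row = np.append(np.full(n_sources - 1, 1 / (n_sources - 1)), 0.0)
    else:
        n_src_pops = n_sources
        admix_row = np.full(n_sources, 1.0 / n_sources)

    n_admx_pops = 10 if name == "AdmxVegProp" else 2
    n_pops = n_src_pops + n_admx_pops

    g = 50
    if name == "DiffGenSam":
        g = 50 if tadm is None else int(tadm)
        if not 0 <= g:
            raise ConfigurationError("tadm must be >= 0")

    sizes = np.full(n_pops, n_p)
    o_per_pop = np.concatenate(
        [np.full(n_src_pops, op_src), np.full(n_admx_pops, op_admx)]
    )
    if name == "AdmxVegProp":
        sizes[n_src_pops:] = 100 if n_individuals is None else n_p
    if name == "SamBal":
        op3 = 2 if op_src3 is None else op_src3
        o_per_pop[2] = op3

    schedule = ReproductionSchedule.constant(n_pops, g)
    if name == "SrcSelf":
        slf = 0.99 if slf is None else slf
        if not 0 <= slf <= 1:
            raise ConfigurationError("slf must lie in [0, 1]")
        props = schedule.proportions.copy()
        props[2, :, :] = [1 - slf, 0, slf, 0]
        schedule = ReproductionSchedule(props)
    if name == "AdmxVegProp":
        tvegs = list(range(0, 50, 5)) if tveg_values is None else list(tveg_values)
        if len(tvegs) != n_admx_pops:
            raise ConfigurationError("need one tveg per admixed population")
        for k, tveg in enumerate(tvegs):
            if not 0 <= tveg <= g:
                raise ConfigurationError("tveg out of range")
            schedule = schedule.with_vegetative_tail(n_src_pops + k, tveg)

    founder = FounderConfig(
        n_sources=n_sources,
        haplotypes_per_source=n_h,
        tau=tau,
        theta=theta,
        rho=rho,
        map_length_bp=(map_length_bp if map_length_bp is not None
                       else FounderConfig().map_length_bp),
        seed=seed,
        backend=backend,
        n_windows=(n_windows if n_windows is not None
                   else FounderConfig().n_windows),
    )
    contributions = _star_contributions(n_src_pops, n_sources, n_admx_pops,
                                        admix_row)
    roles = tuple(["source"] * n_src_pops + ["admixed"] * n_admx_pops)
    return ScenarioConfig(
        name=name,
        founder=founder,
        pop_sizes=sizes,
        roles=roles,
        contributions=contributions,
        schedule=schedule,
        o_per_pop=o_per_pop,
        missing_source=missing,
        replicates=replicates,
        base_seed=seed,
        allow_incidental_selfing=allow_incidental_selfing,
    )


def score_random_baseline(sample: SampleSet,
                          missing_source: int | None = None,
                          per_site_masking: bool = False) -> AccuracyResult:
    """Accuracy of the uniform 1/S baseline against the sample's truth."""
    z = sample.Z
    mask = None
    s = sample.n_sources
    if missing_source is not None:
        z, mask = missing_source_mask(z, missing_source,
                                      per_site=per_site_masking)
        s -= 1
    x = random_inference(s, sample.n_individuals, sample.n_sites)
    return overall_alpha(z, x.X, sample.is_admixed, mask)


def run_replicate(cfg: ScenarioConfig, seed: int,
                  keep_sample: bool = False) -> ReplicateResult:
    """Founders -> forward -> sampling -> stats -> random-baseline score."""
    t0 = time.perf_counter()
    founder_stream, forward_stream = np.random.SeedSequence(seed).spawn(2)
    founder_seed = int(founder_stream.generate_state(1)[0])
    panel = simulate_founders(replace(cfg.founder, seed=founder_seed))
    rng = np.random.default_rng(forward_stream)

    pops = found_populations(panel, cfg.contributions, cfg.pop_sizes, rng)
    pops = run_forward(pops, cfg.schedule,
                       cfg.mu_site if cfg.mu_site is not None else cfg.founder.mu_site,
                       rng, allow_incidental_selfing=cfg.allow_incidental_selfing)
    raw = sample_individuals(pops, cfg.o_per_pop, rng,
                             admixed=cfg.admixed_flags)
    sample, kept = filter_monomorphic(raw)
    summary = summarize(sample)
    accuracy = score_random_baseline(sample, cfg.missing_source)
    dt = time.perf_counter() - t0
    logger.info(
        "replicate seed=%d: M %d -> %d, alpha_random=%.4f, fst=%.4f, %.1fs",
        seed, raw.n_sites, sample.n_sites, accuracy.alpha_overall,
        mean_pairwise_fst(summary.pairwise_fst), dt,
    )
    per_ind_cells = accuracy.mask.sum(axis=1)
    keep = per_ind_cells > 0
    per_ind = ((accuracy.alpha_site * accuracy.mask).sum(axis=1)[keep]
               / per_ind_cells[keep])
    return ReplicateResult(
        seed=seed,
        m_before=raw.n_sites,
        m_after=sample.n_sites,
        summary=summary,
        alpha_random=accuracy.alpha_overall,
        alpha_n_cells=accuracy.n_included,
        runtime_s=dt,
        alpha_per_individual=per_ind,
        sample=sample if keep_sample else None,
        accuracy=accuracy if keep_sample else None,
    )


def run_replicates(cfg: ScenarioConfig, n_replicates: int | None = None,
                   keep_samples: bool = False) -> tuple[list[ReplicateResult], dict]:
    """Run ``R`` replicates with seeds ``base_seed + r`` and aggregate."""
    r_total = cfg.replicates if n_replicates is None else n_replicates
    results = [
        run_replicate(cfg, cfg.base_seed + r, keep_sample=keep_samples)
        for r in range(r_total)
    ]
    return results, aggregate_results(results)


def aggregate_results(results: list[ReplicateResult]) -> dict:
    """Aggregate the random-baseline accuracy and dataset summaries.

    ``alpha_random_sd`` / ``alpha_random_ci95`` follow the study-table
    convention: the sd is over per-individual accuracies pooled across
    replicates and the CI half-width is 1.96 * sd / sqrt(pooled n).  The
    sd over replicate means is reported separately.
    """
    alphas = np.array([r.alpha_random for r in results])
    fsts = np.array([mean_pairwise_fst(r.summary.pairwise_fst) for r in results])
    m_after = np.array([r.m_after for r in results])
    n = len(results)
    pooled = np.concatenate(
        [r.alpha_per_individual for r in results
         if r.alpha_per_individual is not None]
    ) if n else np.empty(0)
    sd_ind = float(pooled.std(ddof=1)) if pooled.size > 1 else float("nan")
    sd_rep = float(alphas.std(ddof=1)) if n > 1 else float("nan")
    return {
        "n_replicates": n,
        "alpha_random_mean": float(alphas.mean()),
        "alpha_random_sd": sd_ind,
        "alpha_random_ci95": (1.96 * sd_ind / np.sqrt(pooled.size)
                              if pooled.size > 1 else float("nan")),
        "alpha_random_sd_replicates": sd_rep,
        "fst_mean": float(fsts.mean()),
        "m_after_mean": float(m_after.mean()),
        "m_after_min": int(m_after.min()),
        "m_after_max": int(m_after.max()),
    }
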