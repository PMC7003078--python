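"""Summary statistics: pairwise FST, heterozygosities, ancestry block sizes.

FST is the Weir & Cockerham (1984) variance-components estimator with
the standard multi-locus ratio-of-averages combination,

    theta_hat = sum_l a_l / sum_l (a_l + b_l + c_l)

with per-locus components (r demes, deme sample sizes n_i, allele
frequencies p_i, observed heterozygote fractions h_i):

    nbar = mean(n_i)
    nc   = (r*nbar - sum(n_i^2)/(r*nbar)) / (r - 1)
    pbar = sum(n_i * p_i) / (r * nbar)
    s2   = sum(n_i * (p_i - pbar)^2) / ((r - 1) * nbar)
    hbar = sum(n_i * h_i) / (r * nbar)
    a = (nbar/nc) * (s2 - (pbar*(1-pbar) - s2*(r-1)/r - hbar/4) / (nbar-1))
    b = (nbar/(nbar-1)) * (pbar*(1-pbar) - s2*(r-1)/r - hbar*(2*nbar-1)/(4*nbar))
    c = hbar / 2

Loci monomorphic in the demes under comparison contribute nothing to
either sum.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ParameterError
from .founders import FounderPanel
from .sampling_io import SampleSet


@dataclass
class BlockSizeSummary:
    """Ancestry block lengths (map units) for one population's sampled copies."""

    lengths: np.ndarray
    mean: float
    median: float
    deciles: np.ndarray


@dataclass
class SummaryStats:
    pairwise_fst: np.ndarray
    het_obs: np.ndarray
    het_exp: np.ndarray
    block_sizes: dict[int, BlockSizeSummary]


def _wc_components(geno_by_pop: list[np.ndarray]):
    """WC84 a, b, c arrays from per-deme diploid allele-count matrices."""
    r = len(geno_by_pop)
    n = np.array([g.shape[0] for g in geno_by_pop], dtype=float)
    p = np.stack([g.mean(axis=0) / 2.0 for g in geno_by_pop])
    h = np.stack([(g == 1).mean(axis=0) for g in geno_by_pop])
    nbar = n.mean()
    nc = (r * nbar - (n**2).sum() / (r * nbar)) / (r - 1)
    pbar = (n[:, None] * p).sum(axis=0) / (r * nbar)
    s2 = (n[:, None] * (p - pbar) ** 2).sum(axis=0) / ((r - 1) * nbar)
    hbar = (n[:, None] * h).sum(axis=0) / (r * nbar)
    a = (nbar / nc) * (
        s2 - (pbar * (1 - pbar) - s2 * (r - 1) / r - hbar / 4) / (nbar - 1)
    )
    b = (nbar / (nbar - 1)) * (
        pbar * (1 - pbar) - s2 * (r - 1) / r - hbar * (2 * nbar - 1) / (4 * nbar)
    )
    c = hbar / 2
    return a, b, c


def weir_cockerham_fst(geno_by_pop: list[np.ndarray]) -> float:
    """Multi-locus WC84 theta-hat over demes given (n_i, M) 0/1/2 matrices.

    Returns NaN (flagged missing) when every locus has a zero
    denominator, e.g. when all demes are jointly monomorphic everywhere.
    """
    for g in geno_by_pop:
        if g.shape[0] < 2:
            raise ParameterError("each deme needs >= 2 sampled individuals")
    a, b, c = _wc_components(geno_by_pop)
    den = a + b + c
    use = den != 0
    if not np.any(use):
        return float("nan")
    return float(a[use].sum() / den[use].sum())


def _pop_genotype_matrix(sample: SampleSet, pop: int) -> np.ndarray:
    rows = sample.population_of_individual == pop
    return sample.genotypes[rows].sum(axis=2)


def pairwise_fst(sample: SampleSet, pop_a: int, pop_b: int) -> float:
    """WC84 FST between two sampled populations (NaN when undefined)."""
    return weir_cockerham_fst(
        [_pop_genotype_matrix(sample, pop_a), _pop_genotype_matrix(sample, pop_b)]
    )


def pairwise_fst_matrix(sample: SampleSet) -> np.ndarray:
    pops = np.unique(sample.population_of_individual)
    k = len(pops)
    out = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            out[i, j] = out[j, i] = pairwise_fst(sample, pops[i], pops[j])
    return out


def weir_cockerham_fst_haploid(hap_by_pop: list[np.ndarray]) -> float:
    """WC84 theta-hat for haploid data (heterozygosity terms vanish).

    ``hap_by_pop`` holds per-deme (n_i, M) 0/1 haplotype matrices; the
    components reduce to the allele-frequency variance terms with
    ``hbar = 0`` and ``c = 0``, so the estimate depends only on per-deme
    allele frequencies and counts (invariant to haplotype order).
    """
    r = len(hap_by_pop)
    n = np.array([h.shape[0] for h in hap_by_pop], dtype=float)
    if np.any(n < 2):
        raise ParameterError("each deme needs >= 2 haplotypes")
    p = np.stack([h.mean(axis=0) for h in hap_by_pop])
    nbar = n.mean()
    nc = (r * nbar - (n**2).sum() / (r * nbar)) / (r - 1)
    pbar = (n[:, None] * p).sum(axis=0) / (r * nbar)
    s2 = (n[:, None] * (p - pbar) ** 2).sum(axis=0) / ((r - 1) * nbar)
    a = (nbar / nc) * (s2 - (pbar * (1 - pbar) - s2 * (r - 1) / r) / (nbar - 1))
    b = (nbar / (nbar - 1)) * (pbar * (1 - pbar) - s2 * (r - 1) / r)
    den = a + b
    use = den != 0
    if not np.any(use):
        return float("nan")
    return float(a[use].sum() / den[use].sum())


def founder_panel_fst(panel: FounderPanel) -> np.ndarray:
    """Pairwise WC84 FST matrix among founder sources (haploid estimator)."""
    demes = [
        panel.haplotypes[panel.haplotype_indices_of_source(s)]
        for s in range(panel.n_sources)
    ]
    k = len(demes)
    out = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            out[i, j] = out[j, i] = weir_cockerham_fst_haploid(
                [demes[i], demes[j]]
            )
    return out


def mean_pairwise_fst(matrix: np.ndarray) -> float:
    iu = np.triu_indices(matrix.shape[0], k=1)
    return float(np.nanmean(matrix[iu]))


def heterozygosity(sample: SampleSet, pop: int) -> tuple[float, float]:
    """(het_obs, het_exp) for one sampled population.

    het_obs: mean over sites of the fraction of heterozygous individuals.
    het_exp: mean over sites of 2p(1-p) with the unbiased 2n/(2n-1)
    small-sample correction (n = individuals, 2n = alleles).
    """
    rows = sample.population_of_individual == pop
    if not np.any(rows):
        raise ParameterError(f"no sampled individuals in population {pop}")
    g = sample.genotypes[rows].sum(axis=2)
    n = g.shape[0]
    het_obs = float((g == 1).mean())
    p = g.mean(axis=0) / 2.0
    corr = (2 * n) / (2 * n - 1) if n > 0.5 else 1.0
    het_exp = float(np.mean(2 * p * (1 - p) * corr))
    return het_obs, het_exp


def block_lengths_of_tracts(tracts) -> np.ndarray:
    return np.array([t.end - t.start for t in tracts])


def ancestry_block_stats(sample: SampleSet,
                         admixed_only: bool = True) -> dict[int, BlockSizeSummary]:
    """Ancestry block lengths per population over sampled chromosome copies."""
    out: dict[int, BlockSizeSummary] = {}
    for pop in np.unique(sample.population_of_individual):
        rows = np.flatnonzero(sample.population_of_individual == pop)
        if admixed_only and not sample.is_admixed[rows[0]]:
            continue
        lengths = []
        for i in rows:
            for copy_tracts in sample.tracts[i]:
                lengths.append(block_lengths_of_tracts(copy_tracts))
        lengths = np.concatenate(lengths) if lengths else np.empty(0)
        out[int(pop)] = BlockSizeSummary(
            lengths=lengths,
            mean=float(lengths.mean()) if lengths.size else float("nan"),
            median=float(np.median(lengths)) if lengths.size else float("nan"),
            deciles=np.quantile(lengths, np.arange(0.1, 1.0, 0.1))
            if lengths.size
            else np.full(9, np.nan),
        )
    return out


def summarize(sample: SampleSet) -> SummaryStats:
    pops = np.unique(sample.population_of_individual)
    het = np.array([heterozygosity(sample, p) for p in pops])
    return SummaryStats(
        pairwise_fst=pairwise_fst_matrix(sample),
        het_obs=het[:, 0],
        het_exp=het[:, 1],
        block_sizes=ancestry_block_stats(sample),
    )


def write_summary_tsv(stats: SummaryStats, path: str) -> None:
    """Flat TSV export of all summary statistics for one replicate."""
    with open(path, "w") as fh:
        fh.write("statistic\tpop_a\tpop_b\tvalue\n")
        k = stats.pairwise_fst.shape[0]
        for i in range(k):
            for j in range(i + 1, k):
                fh.write(f"fst\t{i}\t{j}\t{stats.pairwise_fst[i, j]:.6g}\n")
        for i in range(len(stats.het_obs)):
            fh.write(f"het_obs\t{i}\t.\t{stats.het_obs[i]:.6g}\n")
            fh.write(f"het_exp\t{i}\t.\t{stats.het_exp[i]:.6g}\n")
        for pop, bs in stats.block_sizes.items():
            fh.write(f"block_mean\t{pop}\t.\t{bs.mean:.6g}\n")
            fh.write(f"block_median\t{pop}\t.\t{bs.median:.6g}\n")
            for q, v in zip(np.arange(0.1, 1.0, 0.1), bs.deciles):
                fh.write(f"block_q{int(round(q * 100))}\t{pop}\t.\t{v:.6g}\n")
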