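import numpy as np
import pytest
from scipy import stats as sps

from mosaicsim import (ReproductionSchedule, advance_generation,
                       found_populations, meiosis, mutate_chromosome,
                       run_forward)
from mosaicsim.errors import ConfigurationError, ParameterError
from mosaicsim.forward import (ACROSS, SELFING, VEGETATIVE, WITHIN,
                               AncestryTract, ChromosomeCopy, Individual,
                               _meiosis, _splice_tracts, validate_tracts)

from conftest import run_small_admixture, small_founder_config
from mosaicsim import simulate_founders


def chromosome(tracts, alleles):
    return ChromosomeCopy(np.asarray(alleles, dtype=np.uint8), tuple(tracts))


def single_source_chromosome(source, alleles):
    return chromosome([AncestryTract(0.0, 1.0, source)], alleles)


class TestFoundPopulations:
    def test_degenerate_mixture(self, small_panel, rng):
        pops = found_populations(small_panel, [[1.0, 0.0, 0.0]], [10], rng)
        for ind in pops.populations[0]:
            for c in ind.copies:
                assert c.tracts == (AncestryTract(0.0, 1.0, 0),)

    def test_row_not_summing_rejected(self, small_panel, rng):
        with pytest.raises(ParameterError):
            found_populations(small_panel, [[0.5, 0.4, 0.0]], [10], rng)

    def test_contribution_to_empty_source_rejected(self, small_panel, rng):
        import copy

        panel = copy.deepcopy(small_panel)
        keep = panel.source_of_haplotype != 2
        panel.haplotypes = panel.haplotypes[keep]
        panel.source_of_haplotype = panel.source_of_haplotype[keep]
        # source 2 still labeled (labels 0..2 from max) but has no rows
        panel.source_of_haplotype[-1] = 2  # keep n_sources == 3
        panel.haplotypes = panel.haplotypes[:-1]
        panel.source_of_haplotype = panel.source_of_haplotype[:-1]
        with pytest.raises(ParameterError):
            found_populations(panel, [[0.0, 0.0, 1.0]], [5], rng)

    def test_multinomial_source_counts(self, small_panel):
        # per-copy source counts over seeds ~ Multinomial(n, 1/3)
        counts = np.zeros(3)
        for seed in range(20):
            pops = found_populations(
                small_panel, [[1 / 3, 1 / 3, 1 / 3]], [150],
                np.random.default_rng(seed),
            )
            for ind in pops.populations[0]:
                for c in ind.copies:
                    counts[c.tracts[0].source] += 1
        res = sps.chisquare(counts)
        assert res.pvalue > 0.001

    def test_founder_alleles_copied_verbatim(self, small_panel, rng):
        pops = found_populations(small_panel, [[0, 1, 0]], [5], rng)
        haps = small_panel.haplotypes[small_panel.haplotype_indices_of_source(1)]
        for ind in pops.populations[0]:
            for c in ind.copies:
                assert any(np.array_equal(c.alleles, h) for h in haps)


class TestMeiosis:
    def test_splice_direct_construction(self):
        t0 = (AncestryTract(0.0, 1.0, 0),)
        t1 = (AncestryTract(0.0, 1.0, 1),)
        out = _splice_tracts(t0, t1, 0.3)
        assert out == (AncestryTract(0.0, 0.3, 0), AncestryTract(0.3, 1.0, 1))

    def test_splice_merges_same_source(self):
        t0 = (AncestryTract(0.0, 1.0, 0),)
        out = _splice_tracts(t0, t0, 0.5)
        assert out == (AncestryTract(0.0, 1.0, 0),)

    def test_gamete_matches_breakpoint(self, rng):
        positions = np.linspace(0, 1, 50, endpoint=False)
        a = single_source_chromosome(0, np.zeros(50))
        b = single_source_chromosome(1, np.ones(50))
        parent = Individual(copies=(a, b), population=0)
        for _ in range(20):
            gamete, bp, k = _meiosis(parent, positions, rng)
            validate_tracts(gamete.tracts)
            first = (a, b)[k]
            second = (a, b)[1 - k]
            idx = np.searchsorted(positions, bp)
            np.testing.assert_array_equal(gamete.alleles[:idx],
                                          first.alleles[:idx])
            np.testing.assert_array_equal(gamete.alleles[idx:],
                                          second.alleles[idx:])
            assert gamete.tracts[0].source == first.tracts[0].source

    def test_homozygous_parent_identity(self, rng):
        positions = np.linspace(0, 1, 30, endpoint=False)
        alleles = (np.arange(30) % 2).astype(np.uint8)
        a = single_source_chromosome(2, alleles)
        parent = Individual(copies=(a, chromosome(a.tracts, alleles.copy())),
                            population=0)
        for _ in range(10):
            g = meiosis(parent, positions, rng)
            np.testing.assert_array_equal(g.alleles, alleles)
            assert g.tracts == a.tracts


class TestMutation:
    def test_mu_zero_identity(self, rng):
        c = single_source_chromosome(0, np.zeros(100))
        assert mutate_chromosome(c, 0.0, rng) is c

    def test_mu_one_flips_everything(self, rng):
        alleles = np.array([0, 1, 0, 1], dtype=np.uint8)
        c = single_source_chromosome(1, alleles)
        out = mutate_chromosome(c, 1.0, rng)
        np.testing.assert_array_equal(out.alleles, 1 - alleles)
        assert out.tracts == c.tracts

    def test_invalid_rate(self, rng):
        c = single_source_chromosome(0, np.zeros(4))
        with pytest.raises(ParameterError):
            mutate_chromosome(c, 1.5, rng)
        with pytest.raises(ParameterError):
            mutate_chromosome(c, -0.1, rng)

    def test_flip_count_binomial(self, rng):
        # mu=1e-3 over M=1e4: mean flips 10, binomial oracle within 3 SE
        m, mu, trials = 10_000, 1e-3, 100
        c = single_source_chromosome(0, np.zeros(m))
        flips = []
        for _ in range(trials):
            out = mutate_chromosome(c, mu, rng)
            flips.append(int((out.alleles != c.alleles).sum()))
        mean = np.mean(flips)
        se = np.sqrt(m * mu * (1 - mu) / trials)
        assert abs(mean - m * mu) < 3 * se


class TestAdvanceGeneration:
    def test_clonal_identity(self, small_panel, rng):
        pops = found_populations(
            small_panel, [[1 / 3, 1 / 3, 1 / 3]], [15], rng
        )
        nxt = advance_generation(pops, [[0, 0, 0, 1]], 0.0, rng)
        parent_pairs = [
            tuple(c.alleles.tobytes() for c in ind.copies)
            for ind in pops.populations[0]
        ]
        for child in nxt.populations[0]:
            pair = tuple(c.alleles.tobytes() for c in child.copies)
            assert pair in parent_pairs

    def test_across_mating_requires_two_pops(self, small_panel, rng):
        pops = found_populations(small_panel, [[1, 0, 0]], [5], rng)
        with pytest.raises(ConfigurationError):
            advance_generation(pops, [[0.5, 0.5, 0, 0]], 0.0, rng)

    def test_population_sizes_constant(self, small_panel, rng):
        pops = run_small_admixture(small_panel, n_p=12, generations=4)
        assert list(pops.sizes) == [12, 12, 12]
        assert pops.generation == 4

    def test_selfing_halves_heterozygosity(self, small_panel):
        # classical recursion H_{t+1} = H_t / 2 (exact in expectation)
        gens = 5
        ratios = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            pops = found_populations(
                small_panel, [[1 / 3, 1 / 3, 1 / 3]], [400], rng
            )
            h0 = _mean_het(pops)
            for _ in range(gens):
                pops = advance_generation(pops, [[0, 0, 1, 0]], 0.0, rng)
            ratios.append(_mean_het(pops) / h0)
        ratios = np.array(ratios)
        se = ratios.std(ddof=1) / np.sqrt(len(ratios))
        assert abs(ratios.mean() - 0.5**gens) < 3 * se

    def test_vegetative_tail_freezes_block_lengths(self, small_panel):
        # switching to clonal propagation leaves mean block length at the
        # switch statistically unchanged afterwards
        at_switch, at_end = [], []
        for seed in range(10):
            rng = np.random.default_rng(100 + seed)
            pops = found_populations(
                small_panel, [[1 / 3, 1 / 3, 1 / 3]], [60], rng
            )
            sched = ReproductionSchedule.constant(1, 10)
            pops = run_forward(pops, sched, 0.0, rng)
            at_switch.append(_mean_block_length(pops))
            veg = ReproductionSchedule.constant(1, 15, within=0.0,
                                                vegetative=1.0)
            pops = run_forward(pops, veg, 0.0, rng)
            at_end.append(_mean_block_length(pops))
        diff = np.array(at_end) - np.array(at_switch)
        se = diff.std(ddof=1) / np.sqrt(len(diff))
        assert abs(diff.mean()) < 3 * se + 1e-3


class TestRunForward:
    def test_zero_generations_identity(self, small_panel, rng):
        pops = found_populations(small_panel, [[1, 0, 0]], [5], rng)
        sched = ReproductionSchedule(np.zeros((1, 0, 4)))
        assert run_forward(pops, sched, 0.0, rng) is pops

    def test_deterministic_given_seed(self, small_panel):
        def run(seed):
            return run_small_admixture(small_panel, n_p=10, generations=6,
                                       seed=seed)

        a, b = run(9), run(9)
        for pa, pb in zip(a.populations, b.populations):
            for ia, ib in zip(pa, pb):
                for ca, cb in zip(ia.copies, ib.copies):
                    np.testing.assert_array_equal(ca.alleles, cb.alleles)
                    assert ca.tracts == cb.tracts

    def test_tract_tiling_every_generation(self, small_panel):
        rng = np.random.default_rng(3)
        pops = found_populations(
            small_panel,
            [[1, 0, 0], [0, 1, 0], [1 / 3, 1 / 3, 1 / 3]],
            [8, 8, 8],
            rng,
        )
        col = np.array([[0.5, 0.2, 0.2, 0.1]] * 3)
        for g in range(8):
            pops = advance_generation(pops, col, 1e-4, rng)
            junctions = []
            for pop in pops.populations:
                for ind in pop:
                    for c in ind.copies:
                        validate_tracts(c.tracts)
                        junctions.append(c.n_junctions())
            # mean bounded by g (each meiosis adds at most one junction
            # in expectation; per-chromosome worst case is 2^g - 1)
            assert np.mean(junctions) <= pops.generation

    def test_junctions_bounded_and_blocks_shrink(self, small_panel):
        means = []
        for g in (5, 20, 50):
            pops = run_small_admixture(small_panel, n_p=10, generations=g,
                                       seed=11)
            junctions = [c.n_junctions() for ind in pops.populations[2]
                         for c in ind.copies]
            assert np.mean(junctions) <= g
            assert max(junctions) <= 2**g - 1
            means.append(_mean_block_length(pops, pop=2))
        assert means[0] > means[1] > means[2]

    def test_clonal_closure(self, small_panel, rng):
        pops = found_populations(
            small_panel, [[1 / 3, 1 / 3, 1 / 3]], [10], rng
        )
        founding = {c.alleles.tobytes() for ind in pops.populations[0]
                    for c in ind.copies}
        sched = ReproductionSchedule.constant(1, 12, within=0.0,
                                              vegetative=1.0)
        final = run_forward(pops, sched, 0.0, rng)
        for ind in final.populations[0]:
            for c in ind.copies:
                assert c.alleles.tobytes() in founding


class TestPedigreeOracle:
    """Dosage from tracts equals brute-force per-site propagation through
    the recorded pedigree (independent of the tract arithmetic)."""

    def test_dosage_matches_bruteforce(self):
        panel = simulate_founders(
            small_founder_config(n_windows=100, haplotypes_per_source=20,
                                 seed=21)
        )
        m = panel.n_sites
        positions = panel.positions
        contributions = np.array(
            [[1, 0, 0], [0, 1, 0], [1 / 3, 1 / 3, 1 / 3]]
        )
        sizes = [10, 10, 10]
        recorder: list = []
        rng = np.random.default_rng(77)
        pops = found_populations(panel, contributions, sizes, rng,
                                 recorder=recorder)
        sched = ReproductionSchedule(
            np.tile([0.6, 0.2, 0.1, 0.1], (3, 5, 1))
        )
        final = run_forward(pops, sched, 0.0, rng, recorder=recorder)

        # brute force: per-site source labels propagated by the records
        founding = recorder[0]
        labels = [
            [
                np.stack([np.full(m, ev[c][0]) for c in (0, 1)])
                for ev in pop_events
            ]
            for pop_events in founding
        ]
        for gen_events in recorder[1:]:
            new_labels = []
            for p, pop_events in enumerate(gen_events):
                pop_labels = []
                for ev in pop_events:
                    if ev["mode"] == VEGETATIVE:
                        (pp, jj), = ev["parents"]
                        pop_labels.append(labels[pp][jj].copy())
                    else:
                        rows = []
                        for (pp, jj), (b, k) in zip(ev["parents"],
                                                    ev["gametes"]):
                            par = labels[pp][jj]
                            row = np.where(positions < b, par[k], par[1 - k])
                            rows.append(row)
                        pop_labels.append(np.stack(rows))
                new_labels.append(pop_labels)
            labels = new_labels

        for p, pop in enumerate(final.populations):
            for i, ind in enumerate(pop):
                for c in (0, 1):
                    np.testing.assert_array_equal(
                        ind.copies[c].source_at(positions), labels[p][i][c]
                    )


def _mean_het(pops):
    vals = []
    for pop in pops.populations:
        for ind in pop:
            vals.append((ind.copies[0].alleles != ind.copies[1].alleles).mean())
    return float(np.mean(vals))


def _mean_block_length(pops, pop=0):
    lengths = []
    for ind in pops.populations[pop]:
        for c in ind.copies:
            lengths.extend(t.end - t.start for t in c.tracts)
    return float(np.mean(lengths))
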