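"""Simulator mechanics: architecture, seeding, fitness, recombination, drift."""

import numpy as np
import pytest

import tetrap.simulate as sim
from tetrap.simulate import (
    GenomeArchitecture,
    Haplotype,
    Individual,
    Insertion,
    Population,
    SelectionModel,
    SimulationConfig,
    build_architecture,
    classify_phase,
    count_regions,
    fitness,
    is_silenced,
    make_gamete,
    reproduce,
    run_ensemble,
    run_replicate,
    seed_population,
    standard_architecture,
)


def small_config(**kw):
    """A fast, small scenario for mechanical tests."""
    defaults = dict(
        architecture=build_architecture(2, 100_000, 0.05, 0.05, 4.0),
        N=50,
        u=0.1,
        n_seed_insertions=20,
        sample_generation=50,
        rng_seed=1,
    )
    defaults.update(kw)
    return SimulationConfig(**defaults)


class TestArchitecture:
    def test_standard_layout(self):
        arch = standard_architecture()
        assert arch.trap_intervals == tuple((c, 0, 350_000) for c in range(5))
        assert arch.reference_intervals == tuple((c, 9_650_000, 10_000_000) for c in range(5))

    def test_zero_fractions(self):
        arch = build_architecture(1, 1000, 0.0, 0.0, 4.0)
        assert arch.trap_intervals == () and arch.reference_intervals == ()

    def test_fraction_invariant(self):
        arch = build_architecture(2, 1_000_000, 0.10, 0.035, 4.0)
        total_trap = sum(e - s for _, s, e in arch.trap_intervals)
        assert total_trap == 200_000  # 10% of 2 Mb
        total_ref = sum(e - s for _, s, e in arch.reference_intervals)
        assert abs(total_ref / arch.genome_length - 0.035) <= 2 / arch.chrom_length

    def test_rejects_overlapping_fractions(self):
        with pytest.raises(ValueError):
            build_architecture(1, 1000, 0.6, 0.6, 4.0)

    def test_membership_is_half_open(self):
        arch = standard_architecture()
        assert arch.in_trap(np.array([0, 349_999, 350_000])).tolist() == [True, True, False]
        assert arch.in_reference(np.array([9_649_999, 9_650_000])).tolist() == [False, True]


class TestSeedPopulation:
    def test_exact_copy_count_at_singleton_frequency(self):
        config = SimulationConfig(rng_seed=3)
        pop = seed_population(config)
        assert pop.n_insertions == 1000
        # every seed occupies its own haplotype position: frequency 1/(2N)
        key = pop.hap.astype(np.int64) * config.architecture.genome_length + pop.pos
        assert len(np.unique(key)) == 1000

    def test_zero_seeds(self):
        pop = seed_population(small_config(n_seed_insertions=0))
        assert pop.n_insertions == 0

    def test_trap_share_matches_binomial_expectation(self):
        # over many seedings, ~3.5% of seeds land inside traps
        fractions = []
        for seed in range(200):
            pop = seed_population(small_config(n_seed_insertions=100, rng_seed=seed))
            fractions.append(small_config().architecture.in_trap(pop.pos).mean())
        p = np.mean(fractions)
        se = np.sqrt(0.05 * 0.95 / (200 * 100))
        assert abs(p - 0.05) < 3 * se


class TestFitness:
    arch = standard_architecture()

    def ind(self, *positions, cls=1):
        return Individual(Haplotype([Insertion(c, p, cls) for c, p in positions]), Haplotype([]))

    def test_two_insertions_reduce_fitness_twenty_percent(self):
        sel = SelectionModel({"neutral": 0.0, "del": 0.1}, {"neutral": 0.9, "del": 0.1})
        ind = self.ind((0, 5_000_000), (1, 5_000_000))
        assert fitness(ind, sel, self.arch) == pytest.approx(0.8)

    def test_empty_individual(self):
        assert fitness(Individual(Haplotype([]), Haplotype([])), SelectionModel.neutral(), self.arch) == 1.0

    def test_clamped_at_zero(self):
        sel = SelectionModel({"neutral": 0.0, "del": 0.1}, {"neutral": 0.9, "del": 0.1})
        ind = self.ind(*[(0, 1_000_000 + i) for i in range(15)])
        assert fitness(ind, sel, self.arch) == 0.0

    def test_trap_insertions_cost_nothing_when_traps_neutral(self):
        sel = SelectionModel({"neutral": 0.0, "del": 0.1}, {"neutral": 0.9, "del": 0.1})
        ind = self.ind((0, 100))  # inside trap [0, 350000)
        assert fitness(ind, sel, self.arch) == 1.0


class TestSilencing:
    arch = standard_architecture()

    def test_single_trap_insertion_silences(self):
        ind = Individual(Haplotype([Insertion(0, 100)]), Haplotype([]))
        assert is_silenced(ind, self.arch)

    def test_reference_insertion_does_not(self):
        ind = Individual(Haplotype([Insertion(0, 9_700_000)]), Haplotype([]))
        assert not is_silenced(ind, self.arch)

    def test_empty_individual(self):
        assert not is_silenced(Individual(Haplotype([]), Haplotype([])), self.arch)


class TestMakeGamete:
    def test_no_recombination_returns_whole_parental_haplotype(self):
        arch = build_architecture(1, 100_000, 0.0, 0.0, 0.0)
        h1 = Haplotype([Insertion(0, 10), Insertion(0, 500)])
        h2 = Haplotype([Insertion(0, 999)])
        rng = np.random.default_rng(0)
        seen = set()
        for _ in range(20):
            g = make_gamete(Individual(h1, h2), arch, rng)
            key = tuple((i.chrom, i.pos) for i in g.insertions)
            seen.add(key)
            assert key in {((0, 10), (0, 500)), ((0, 999),)}
        assert len(seen) == 2  # both haplotypes transmitted across draws

    def test_homozygous_parent_transmits_itself(self):
        arch = build_architecture(2, 100_000, 0.0, 0.0, 8.0)
        h = Haplotype([Insertion(0, 10), Insertion(1, 500)])
        rng = np.random.default_rng(1)
        for _ in range(10):
            g = make_gamete(Individual(h, Haplotype(list(h.insertions))), arch, rng)
            assert [(i.chrom, i.pos) for i in g.insertions] == [(0, 10), (1, 500)]

    def test_crossover_rate_matches_poisson_mean(self):
        # 4 cM/Mb on 10 Mb: 0.4 Morgans per chromosome per meiosis
        arch = standard_architecture()
        assert arch.crossover_mean == pytest.approx(0.4)
        rng = np.random.default_rng(2)
        draws = rng.poisson(arch.crossover_mean, size=20_000)
        se = np.sqrt(0.4 / draws.size)
        assert abs(draws.mean() - 0.4) < 3 * se


class TestReproduce:
    def test_u_zero_draws_only_from_parental_copies(self):
        config = small_config(u=0.0)
        pop = seed_population(config)
        parental = set(pop.pos.tolist())
        rng = np.random.default_rng(5)
        for _ in range(5):
            pop = reproduce(pop, config, rng)
            assert set(pop.pos.tolist()) <= parental

    def test_copy_number_expectation_conserved_under_neutral_drift(self):
        # u=0, no selection: total copies change only by segregation noise
        config = small_config(u=0.0, n_seed_insertions=200, N=100)
        totals = []
        for seed in range(60):
            cfg = small_config(u=0.0, n_seed_insertions=200, N=100, rng_seed=seed)
            pop = seed_population(cfg)
            rng = np.random.default_rng(seed + 10_000)
            for _ in range(10):
                pop = reproduce(pop, cfg, rng)
            totals.append(pop.n_insertions)
        # each copy is transmitted Bernoulli(1/2) to each of 2N gametes:
        # expectation stays 200; binomial-ish spread around it
        se = np.std(totals) / np.sqrt(len(totals))
        assert abs(np.mean(totals) - 200) < 3 * se + 1e-9

    def test_exponential_growth_without_traps(self):
        # neutral invasion without traps: copies grow ~(1+u) per generation
        arch = build_architecture(2, 1_000_000, 0.0, 0.0, 4.0)
        growth = []
        for seed in range(10):
            cfg = SimulationConfig(
                architecture=arch, N=200, u=0.1, n_seed_insertions=400,
                sample_generation=10, rng_seed=seed,
            )
            pop = seed_population(cfg)
            rng = np.random.default_rng(seed + 999)
            for _ in range(8):
                pop = reproduce(pop, cfg, rng)
            growth.append((pop.n_insertions / 400) ** (1 / 8))
        assert np.mean(growth) == pytest.approx(1.1, abs=0.02)

    def test_all_silenced_parents_add_no_copies(self):
        config = small_config(u=0.5, silencing="parent")
        arch = config.architecture
        # hand-build a population where everyone carries a trap insertion
        individuals = [
            Individual(Haplotype([Insertion(0, 10 + i), Insertion(1, 60_000 + i)]), Haplotype([]))
            for i in range(config.N)
        ]
        pop = Population.from_individuals(individuals, arch)
        rng = np.random.default_rng(0)
        child = reproduce(pop, config, rng)
        # segregation only: no new positions can appear
        assert set(child.pos.tolist()) <= set(pop.pos.tolist())

    def test_extinction_signalled_when_all_fitness_zero(self):
        sel = SelectionModel({"del": 1.0}, {"del": 1.0}, traps_neutral=False)
        config = small_config(selection=sel, u=0.0)
        individuals = [
            Individual(Haplotype([Insertion(1, 60_000), Insertion(1, 70_000)]), Haplotype([]))
            for _ in range(config.N)
        ]
        pop = Population.from_individuals(individuals, config.architecture)
        with pytest.raises(sim.ExtinctionError):
            reproduce(pop, config, np.random.default_rng(0))


class TestClassifyPhase:
    arch = build_architecture(1, 100_000, 0.1, 0.0, 4.0)  # trap [0, 10000)

    def build(self, hap_positions):
        individuals = [
            Individual(Haplotype([Insertion(0, p) for p in h1]), Haplotype([Insertion(0, p) for p in h2]))
            for h1, h2 in hap_positions
        ]
        return Population.from_individuals(individuals, self.arch)

    def test_unsilenced_individual_means_rapid(self):
        pop = self.build([([5], []), ([50_000], [])])
        assert classify_phase(pop, self.arch) == "rapid"

    def test_segregating_trap_insertions_mean_shotgun(self):
        pop = self.build([([5], []), ([7], [])])
        assert classify_phase(pop, self.arch) == "shotgun"

    def test_fixed_trap_insertion_means_inactive(self):
        pop = self.build([([5], [5]), ([5], [5])])
        assert classify_phase(pop, self.arch) == "inactive"


class TestRunReplicate:
    def test_determinism_same_seed(self):
        cfg = small_config(rng_seed=9)
        a = run_replicate(cfg)
        b = run_replicate(cfg)
        assert np.array_equal(a.trap_counts, b.trap_counts)
        assert np.array_equal(a.genome_counts, b.genome_counts)
        assert a.trajectory.equals(b.trajectory)
        assert a.phase == b.phase

    def test_numpy_and_numba_paths_agree(self):
        cfg = small_config(rng_seed=4, sample_generation=30)
        jit = run_replicate(cfg)
        old = sim._HAVE_NUMBA
        sim._HAVE_NUMBA = False
        try:
            plain = run_replicate(cfg)
        finally:
            sim._HAVE_NUMBA = old
        assert np.array_equal(jit.genome_counts, plain.genome_counts)
        assert np.array_equal(jit.trap_counts, plain.trap_counts)

    def test_counts_match_population_tally(self):
        cfg = small_config(rng_seed=2, sample_generation=20)
        rep = run_replicate(cfg)
        assert rep.genome_counts.sum() >= 0
        assert np.all(rep.trap_counts + rep.reference_counts <= rep.genome_counts)

    def test_extinction_recorded_not_raised(self):
        sel = SelectionModel({"del": 0.5}, {"del": 1.0}, traps_neutral=False)
        cfg = small_config(selection=sel, u=0.8, n_seed_insertions=500, N=30)
        rep = run_replicate(cfg)
        assert rep.extinct and rep.phase == "extinct"


class TestRunEnsemble:
    def test_singleton_matches_run_replicate_with_derived_seed(self):
        cfg = small_config()
        ens = run_ensemble(cfg, 1, base_seed=77)
        from dataclasses import replace

        direct = run_replicate(replace(cfg, rng_seed=sim.replicate_seed(77, 0)))
        assert np.array_equal(ens[0].genome_counts, direct.genome_counts)

    def test_u_sampler_uniform_mean(self):
        cfg = small_config(u=(0.005, 0.5), sample_generation=1)
        ens = run_ensemble(cfg, 300, base_seed=8)
        us = np.array([r.u for r in ens])
        assert np.all((us >= 0.005) & (us <= 0.5))
        se = (0.5 - 0.005) / np.sqrt(12 * len(us))
        assert abs(us.mean() - 0.2525) < 3 * se

    def test_sample_generation_sampler_bounds(self):
        cfg = small_config(sample_generation=(5, 15))
        ens = run_ensemble(cfg, 20, base_seed=3)
        gens = [r.sample_generation for r in ens]
        assert all(5 <= g <= 15 for g in gens) and len(set(gens)) > 1


class TestFrequencyInvariant:
    def test_per_site_counts_bounded_by_haplotype_number(self):
        # every segregating site is carried by between 1 and 2N haplotypes
        cfg = small_config(rng_seed=6, sample_generation=40, u=0.3)
        pop = seed_population(cfg)
        rng = np.random.default_rng(123)
        for _ in range(25):
            pop = reproduce(pop, cfg, rng)
        key = pop.hap.astype(np.int64) * cfg.architecture.genome_length + pop.pos
        assert len(np.unique(key)) == len(key)  # haplotypes are position sets
        _, counts = np.unique(pop.pos, return_counts=True)
        assert counts.min() >= 1 and counts.max() <= 2 * cfg.N
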