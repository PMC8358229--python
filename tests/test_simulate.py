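"""Wright-Fisher simulator: fitness, meiosis, drift and selection dynamics."""

import numpy as np
import pytest

from secoer import (
    Population,
    SelectionTarget,
    SimulationConfig,
    allele_frequencies,
    evolve,
    generate_recmap,
    individual_fitness,
    meiosis,
    next_generation,
)
from secoer.simulate import DegeneratePopulationError, _draw_crossover_cuts


def deterministic_recursion(p0, s, h, generations):
    """Infinite-population selection recursion (independent oracle)."""
    p = p0
    for _ in range(generations):
        q = 1 - p
        wbar = p * p * (1 + s) + 2 * p * q * (1 + h * s) + q * q
        p = (p * p * (1 + s) + p * q * (1 + h * s)) / wbar
    return p


class TestFitness:
    def test_no_targets_unit_fitness(self):
        assert individual_fitness(np.zeros((3, 0)), []).tolist() == [1, 1, 1]

    def test_heterozygote(self):
        t = [SelectionTarget(0, 0.1, 0.5)]
        assert individual_fitness([[1]], t)[0] == pytest.approx(1.05)

    def test_multilocus_product(self):
        t = [SelectionTarget(0, 0.1, 1.0), SelectionTarget(1, 0.07, 0.5)]
        w = individual_fitness([[1, 1]], t)[0]
        assert w == pytest.approx(1.1 * 1.035)  # 1.1385

    def test_additive_combiner(self):
        t = [SelectionTarget(0, 0.1, 1.0), SelectionTarget(1, 0.07, 0.5)]
        w = individual_fitness([[1, 1]], t, combiner="additive")[0]
        assert w == pytest.approx(1 + 0.1 + 0.035)

    def test_genotype_validation(self):
        with pytest.raises(ValueError):
            individual_fitness([[3]], [SelectionTarget(0, 0.1, 0.5)])


class TestMeiosis:
    def test_zero_rate_map_returns_parental(self, small_panel, rng):
        flat = generate_recmap(small_panel.chrom_length, 5, 0.0, seed=1)
        h1, h2 = small_panel.alleles[0], small_panel.alleles[1]
        for _ in range(5):
            g = meiosis((h1, h2), flat, small_panel.positions, True, rng)
            assert np.array_equal(g, h1) or np.array_equal(g, h2)

    def test_identical_parents_invariant(self, small_panel, small_recmap, rng):
        h = small_panel.alleles[3]
        g = meiosis((h, h), small_recmap, small_panel.positions, True, rng)
        assert np.array_equal(g, h)

    def test_nonrecombining_is_intact_haplotype(self, small_panel, small_recmap, rng):
        h1, h2 = small_panel.alleles[0], small_panel.alleles[1]
        g = meiosis((h1, h2), small_recmap, small_panel.positions, False, rng)
        assert np.array_equal(g, h1) or np.array_equal(g, h2)

    def test_crossover_count_matches_map_length(self, rng):
        """Mean crossover count over many meioses equals the map length in
        Morgans (Poisson model)."""
        rm = generate_recmap(23_500_000, 100, 0.5, seed=2)
        counts = np.diff(_draw_crossover_cuts(rm, 100_000, rng)[1])
        assert counts.mean() == pytest.approx(0.5, abs=0.01)

    def test_crossover_positions_track_local_rate(self, rng):
        """With one hot window, crossovers concentrate there."""
        from secoer import RecombinationMap
        rm = RecombinationMap("2L", np.array([1, 500_001]),
                              np.array([500_001, 1_000_001]),
                              np.array([0.0, 10.0]))
        cuts, _ = _draw_crossover_cuts(rm, 20_000, rng)
        assert np.all(cuts >= 500_001)


class TestNextGeneration:
    def test_census_preserved(self, small_panel, small_recmap, rng):
        pop = Population.outbred(small_panel, 37, rng)
        cfg = SimulationConfig(generations=1)
        for _ in range(3):
            pop = next_generation(pop, [], small_recmap, cfg, rng)
            assert pop.N == 37
            assert pop.is_female.sum() == 18

    def test_single_generation_selection_matches_recursion(self, small_panel, rng):
        """One generation at large N matches the deterministic recursion."""
        rm = generate_recmap(small_panel.chrom_length, 10, 0.042, seed=3)
        lines = [0] * 2000 + [1] * 2000
        pop = Population.from_line_indices(small_panel, lines)
        diff = np.flatnonzero(small_panel.alleles[0] != small_panel.alleles[1])
        # pick a SNP carried by line 0 only
        j = next(j for j in diff if small_panel.alleles[0, j] == 1)
        t = [SelectionTarget(int(j), 0.1, 0.5)]
        pop2 = next_generation(pop, t, rm, SimulationConfig(1), rng)
        p1 = allele_frequencies(pop2)[j]
        assert p1 == pytest.approx(deterministic_recursion(0.5, 0.1, 0.5, 1), abs=0.02)

    def test_single_sex_population_raises(self, small_panel, small_recmap, rng):
        pop = Population.from_line_indices(small_panel, [0])  # one male only
        with pytest.raises(DegeneratePopulationError):
            next_generation(pop, [], small_recmap, SimulationConfig(1), rng)


class TestEvolve:
    def test_zero_generations_identity(self, small_panel, small_recmap, rng):
        pop = Population.outbred(small_panel, 20, rng)
        f0 = allele_frequencies(pop)
        popf, traj = evolve(pop, [], small_recmap, SimulationConfig(0), rng)
        assert popf is pop
        assert traj.generations == [0]
        assert np.array_equal(traj.freqs[0], f0)

    def test_neutral_martingale(self, small_panel, small_recmap):
        """Mean frequency change over neutral replicate runs is ~0."""
        rng = np.random.default_rng(5)
        pop0 = Population.outbred(small_panel, 50, rng)
        f0 = allele_frequencies(pop0)
        drifts = []
        for _ in range(60):
            _, traj = evolve(pop0, [], small_recmap, SimulationConfig(10), rng)
            drifts.append(traj.freqs[-1] - f0)
        assert np.abs(np.mean(drifts)) < 0.01

    def test_fixation_absorption(self, small_panel, small_recmap):
        """Once lost or fixed, an allele stays there (no mutation)."""
        rng = np.random.default_rng(6)
        pop = Population.outbred(small_panel, 10, rng)
        cfg = SimulationConfig(30, record_every=1)
        _, traj = evolve(pop, [], small_recmap, cfg, rng)
        for j in range(small_panel.n_snps):
            f = traj.freqs[:, j]
            hit = np.flatnonzero((f == 0) | (f == 1))
            if len(hit):
                k = hit[0]
                assert np.all(f[k:] == f[k])

    def test_determinism(self, small_panel, small_recmap):
        t = [SelectionTarget(10, 0.08, 0.5)]
        out = []
        for _ in range(2):
            rng = np.random.default_rng(77)
            pop = Population.outbred(small_panel, 30, rng)
            _, traj = evolve(pop, t, small_recmap, SimulationConfig(15), rng)
            out.append(traj.freqs)
        assert np.array_equal(out[0], out[1])

    def test_selection_monotone_in_s(self, small_panel, small_recmap):
        """Mean final frequency of the target increases with s."""
        rng = np.random.default_rng(8)
        j = int(np.flatnonzero(small_panel.alleles[0] != small_panel.alleles[1])[0])
        if small_panel.alleles[1, j] == 1:
            lines = [1] * 50 + [0] * 50
        else:
            lines = [0] * 50 + [1] * 50
        means = []
        for s in (0.0, 0.05, 0.1):
            finals = []
            targets = [SelectionTarget(j, s, 0.5)] if s > 0 else []
            for _ in range(60):
                pop = Population.from_line_indices(small_panel, lines)
                _, traj = evolve(pop, targets, small_recmap,
                                 SimulationConfig(20), rng)
                finals.append(traj.freqs[-1, j])
            means.append(np.mean(finals))
        assert means[0] < means[1] < means[2]


class TestDriftAndSelectionOracles:
    def test_neutral_drift_variance(self, small_panel, small_recmap):
        """Var(dp) over one neutral generation at N=100 is p(1-p)/(2N)."""
        rng = np.random.default_rng(9)
        from secoer.schemes import make_line_cross_population
        pop0 = make_line_cross_population(small_panel, 0, [1], N=100)
        j = int(np.flatnonzero(small_panel.alleles[0] != small_panel.alleles[1])[0])
        cfg = SimulationConfig(1)
        deltas = np.empty(2000)
        for i in range(2000):
            pop1 = next_generation(pop0, [], small_recmap, cfg, rng)
            deltas[i] = allele_frequencies(pop1)[j] - 0.5
        expected = 0.5 * 0.5 / 200.0
        assert deltas.var() == pytest.approx(expected, rel=0.15)
        assert abs(deltas.mean()) < 3 * np.sqrt(expected / 2000) * 2

    def test_deterministic_limit_large_population(self, small_panel):
        """At N=19,200 the selected-allele trajectory follows the
        deterministic recursion within +/-0.02 after 60 generations."""
        rng = np.random.default_rng(10)
        rm = generate_recmap(small_panel.chrom_length, 10, 0.042, seed=13)
        diff = np.flatnonzero(small_panel.alleles[0] != small_panel.alleles[1])
        j = next(j for j in diff if small_panel.alleles[0, j] == 1)
        lines = [0] * 9600 + [1] * 9600
        pop = Population.from_line_indices(small_panel, lines)
        t = [SelectionTarget(int(j), 0.1, 0.5)]
        _, traj = evolve(pop, t, rm, SimulationConfig(60), rng)
        expect = deterministic_recursion(0.5, 0.1, 0.5, 60)
        assert traj.freqs[-1, j] == pytest.approx(expect, abs=0.02)


class TestTrajectoryOutput:
    def test_write_trajectory(self, small_panel, small_recmap, rng, tmp_path):
        from secoer.simulate import write_trajectory
        pop = Population.outbred(small_panel, 10, rng)
        _, traj = evolve(pop, [], small_recmap,
                         SimulationConfig(2, record_every=1), rng)
        p = tmp_path / "traj.tsv"
        write_trajectory(traj, small_panel, p)
        lines = p.read_text().strip().split("\n")
        assert lines[0] == "generation\tsnp_index\tposition\tfrequency"
        assert len(lines) == 1 + len(traj.generations) * small_panel.n_snps


class TestRepresentation:
    def test_track_decode_matches_dense_matrix(self, small_panel, small_recmap, rng):
        pop = Population.outbred(small_panel, 40, rng)
        pop, _ = evolve(pop, [], small_recmap, SimulationConfig(8), rng)
        dense = pop.haplotype_matrix()
        assert np.array_equal(dense.sum(axis=0), pop.allele_counts())

    def test_paternal_gametes_intact_without_male_recombination(
            self, small_panel, small_recmap, rng):
        """Without male recombination every paternal gamete equals one of the
        father's founder haplotypes exactly (generation 1 from inbred lines)."""
        pop = Population.from_line_indices(small_panel, list(range(10)) * 2)
        pop1 = next_generation(pop, [], small_recmap, SimulationConfig(1), rng)
        dense = pop1.haplotype_matrix()
        founders = {tuple(r) for r in small_panel.alleles}
        for i in range(pop1.N):
            paternal = tuple(dense[2 * i + 1])
            assert paternal in founders

    def test_allele_frequency_degenerate_cases(self, small_panel, rng):
        pop = Population.from_line_indices(small_panel, [0] * 6)
        f = allele_frequencies(pop)
        carried = small_panel.alleles[0] == 1
        assert np.all(f[carried] == 1.0)
        assert np.all(f[~carried] == 0.0)
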