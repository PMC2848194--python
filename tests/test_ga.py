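"""Structure-search operators: encoding, enumeration, fitness arithmetic,
crossover, mutation, selection, power-law sampling, and GA-vs-exhaustive."""

import math

import numpy as np
import pytest
from scipy import stats

from tanhgrn.dataset import ExpressionDataset
from tanhgrn.dynamics import GeneParameters
from tanhgrn.ga import (
    Chromosome,
    GAConfig,
    GeneFitCache,
    StructureSearchError,
    crossover,
    enumerate_link_sets,
    gene_score,
    mutate,
    mutation_weights,
    random_chromosome,
    repair,
    run_ga,
    search_space_size,
    select_next_generation,
    structure_from_chromosome,
)
from tanhgrn.sa import SAConfig
from tanhgrn.simulate import sample_power_law_indegrees


class TestSearchSpace:
    def test_benchmark_scale_count(self):
        assert search_space_size(11, 4) == 4**11 == 4_194_304

    def test_lmax_one_single_structure(self):
        assert search_space_size(7, 1) == 1

    def test_small_case_matches_enumeration(self):
        # n=2, l_max=3: in-degree alphabet {1,2,3} per gene -> 9
        count = sum(1 for _ in ((a, b) for a in (1, 2, 3) for b in (1, 2, 3)))
        assert search_space_size(2, 3) == count == 9

    def test_allow_zero_expands_alphabet(self):
        assert search_space_size(2, 3, allow_zero_indegree=True) == 16


class TestEnumerateLinkSets:
    def test_binomial_sum_over_degrees(self):
        cands = [f"c{i}" for i in range(13)]
        total = sum(len(enumerate_link_sets(cands, d)) for d in range(5))
        assert total == sum(math.comb(13, j) for j in range(5)) == 1093

    def test_degree_zero_single_empty_set(self):
        assert enumerate_link_sets(["a", "b"], 0) == [()]

    def test_full_degree_single_full_set(self):
        assert enumerate_link_sets(["a", "b"], 2) == [("a", "b")]

    def test_excess_degree_rejected(self):
        with pytest.raises(StructureSearchError):
            enumerate_link_sets(["a"], 2)


class TestFitnessArithmetic:
    def test_one_extra_link_costs_exactly_two_under_aic(self):
        base = gene_score(1.0, 0.5, 2, False, 58, "aic")
        extra = gene_score(1.0, 0.5, 3, False, 58, "aic")
        assert extra - base == pytest.approx(2.0, abs=1e-12)

    def test_one_extra_link_costs_ln_tprime_under_bic(self):
        base = gene_score(1.0, 0.5, 2, False, 58, "bic")
        extra = gene_score(1.0, 0.5, 3, False, 58, "bic")
        assert extra - base == pytest.approx(math.log(58), abs=1e-12)

    def test_self_link_counts_one_parameter(self):
        off = gene_score(1.0, 0.5, 2, False, 58, "aic")
        on = gene_score(1.0, 0.5, 2, True, 58, "aic")
        assert on - off == pytest.approx(2.0, abs=1e-12)

    def test_two_gene_spreadsheet_recomputation(self):
        # independent arithmetic: SSEs (0.8, 1.3), Vars (0.4, 0.9),
        # links (1, 2), no self: sum SSE/Var + 2 * (2 + L)
        expected = 0.8 / 0.4 + 2 * (2 + 1) + 1.3 / 0.9 + 2 * (2 + 2)
        got = gene_score(0.8, 0.4, 1, False, 20, "aic") + gene_score(
            1.3, 0.9, 2, False, 20, "aic"
        )
        assert got == pytest.approx(expected, rel=1e-12)

    def test_zero_sse_finite_and_positive(self):
        s = gene_score(0.0, 0.5, 1, False, 58, "aic")
        assert math.isfinite(s) and s > 0


class TestCrossover:
    def test_identical_parents_identical_children(self):
        rng = np.random.default_rng(0)
        p = random_chromosome(5, 4, rng)
        c1, c2 = crossover(p, p.copy(), rng)
        np.testing.assert_array_equal(c1.bits, p.bits)
        np.testing.assert_array_equal(c2.bits, p.bits)

    def test_positionwise_bit_sum_conserved(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            p1 = random_chromosome(6, 3, rng)
            p2 = random_chromosome(6, 3, rng)
            c1, c2 = crossover(p1, p2, rng)
            np.testing.assert_array_equal(
                c1.bits + c2.bits, p1.bits + p2.bits
            )

    def test_cut_point_uniform_over_interior(self):
        """Cut points hit every interior position uniformly (chi-square)."""
        rng = np.random.default_rng(2)
        L = 8  # 2 genes x 4 bits
        p1 = Chromosome(np.zeros((2, 4), dtype=np.uint8))
        p2 = Chromosome(np.ones((2, 4), dtype=np.uint8))
        counts = np.zeros(L)
        n = 10_000
        for _ in range(n):
            c1, _ = crossover(p1, p2, rng)
            cut = int(np.argmax(c1.flat() == 1)) if c1.flat().any() else L
            counts[cut] += 1
        # interior cuts are 1..L-1; positions 0 and L never occur
        assert counts[0] == 0
        interior = counts[1:L]
        chi2 = stats.chisquare(interior)
        assert chi2.pvalue > 0.01

    def test_too_short_rejected(self):
        rng = np.random.default_rng(0)
        p = Chromosome(np.array([[1, 0]], dtype=np.uint8))
        with pytest.raises(StructureSearchError):
            crossover(p, p.copy(), rng)


class TestMutation:
    def test_single_chromosome_always_selected(self):
        rng = np.random.default_rng(0)
        pop = [random_chromosome(3, 3, rng)]
        muts = mutate(pop, np.array([5.0]), rng, count=10)
        assert len(muts) == 10

    def test_selection_frequency_inverse_to_fitness(self):
        """Scores 1 and 3: inverse weighting picks the score-1 chromosome
        three times as often (empirical frequencies over 1e5 draws)."""
        rng = np.random.default_rng(9)
        w = mutation_weights(np.array([1.0, 3.0]))
        np.testing.assert_allclose(w, [0.75, 0.25], atol=1e-6)
        draws = rng.choice(2, size=100_000, p=w)
        assert (draws == 0).mean() / (draws == 1).mean() == pytest.approx(3.0, rel=0.03)

    def test_equal_scores_uniform_selection(self):
        rng = np.random.default_rng(1)
        w = mutation_weights(np.array([2.0, 2.0, 2.0]))
        np.testing.assert_allclose(w, 1 / 3)
        pop = [random_chromosome(2, 3, rng) for _ in range(3)]
        picks = mutate(pop, np.array([2.0, 2.0, 2.0]), rng, count=3000)
        assert len(picks) == 3000

    def test_exactly_one_bit_toggled(self):
        rng = np.random.default_rng(2)
        pop = [random_chromosome(4, 4, rng) for _ in range(5)]
        for m, orig_idx in zip(
            mutate(pop, np.ones(5), rng, count=20), range(20)
        ):
            diffs = [int(np.sum(m.bits != p.bits)) for p in pop]
            # one toggle, possibly followed by a repair that sets one bit
            assert min(diffs) in (1, 2)


class TestSelection:
    def test_children_guaranteed_half_even_when_worse(self):
        rng = np.random.default_rng(0)
        parents = [random_chromosome(3, 2, rng) for _ in range(4)]
        children = [random_chromosome(3, 2, rng) for _ in range(4)]
        pop, scores = select_next_generation(
            parents, np.array([1.0, 2, 3, 4]), children, np.array([10.0, 11, 12, 13]), 4
        )
        assert sorted(scores.tolist()) == [1.0, 2.0, 10.0, 11.0]

    def test_identical_pools_select_parents(self):
        rng = np.random.default_rng(1)
        parents = [random_chromosome(3, 2, rng) for _ in range(4)]
        s = np.array([1.0, 2, 3, 4])
        pop, scores = select_next_generation(parents, s, list(parents), s.copy(), 4)
        assert sorted(scores.tolist()) == [1.0, 1.0, 2.0, 2.0]

    def test_matches_sort_oracle(self):
        rng = np.random.default_rng(2)
        parents = [random_chromosome(2, 2, rng) for _ in range(4)]
        children = [random_chromosome(2, 2, rng) for _ in range(4)]
        ps = np.array([4.0, 1.0, 3.0, 2.0])
        cs = np.array([2.5, 0.5, 9.0, 1.5])
        _, scores = select_next_generation(parents, ps, children, cs, 4)
        assert sorted(scores.tolist()) == sorted(
            sorted(ps)[:2] + sorted(cs)[:2]
        )


class TestPowerLawSampling:
    def test_normalized_ratios(self):
        rng = np.random.default_rng(3)
        draws = sample_power_law_indegrees(100_000, 4, 2.5, rng)
        k = np.arange(1, 5, dtype=float)
        expect = k**-2.5
        expect /= expect.sum()
        freq = np.array([(draws == kk).mean() for kk in (1, 2, 3, 4)])
        np.testing.assert_allclose(freq, expect, atol=0.01)

    def test_lmax_one_degenerate(self):
        rng = np.random.default_rng(0)
        assert set(sample_power_law_indegrees(100, 1, 2.5, rng)) == {1}

    def test_gamma_out_of_range_rejected(self):
        rng = np.random.default_rng(0)
        with pytest.raises(ValueError):
            sample_power_law_indegrees(10, 4, 3.5, rng)
        with pytest.raises(StructureSearchError):
            GAConfig(power_law=1.5)

    def test_uniform_when_constraint_off(self):
        rng = np.random.default_rng(4)
        degs = [
            random_chromosome(1, 4, rng).in_degrees()[0] for _ in range(4000)
        ]
        freq = np.array([(np.array(degs) == k).mean() for k in (1, 2, 3, 4)])
        np.testing.assert_allclose(freq, 0.25, atol=0.03)


def _chain_dataset(seed=0, T=25):
    """3-gene toy generated by g1 -> g2, g2 -> g3 (known 2-link truth)."""
    rng = np.random.default_rng(seed)
    t = np.arange(T)
    g1 = 0.9 * np.sin(2 * np.pi * t / 12 + rng.uniform(0, 6))
    p2 = GeneParameters(alpha=0.6, beta=0.0, w={"g1": 1.1})
    p3 = GeneParameters(alpha=0.5, beta=0.0, w={"g2": -1.0})
    g2 = np.empty(T); g3 = np.empty(T)
    g2[0], g3[0] = 0.2, -0.1
    for k in range(T - 1):
        g2[k + 1] = g2[k] + p2.alpha * np.tanh(p2.w["g1"] * g1[k])
        g3[k + 1] = g3[k] + p3.alpha * np.tanh(p3.w["g2"] * g2[k])
    return ExpressionDataset.from_arrays(np.vstack([g1, g2, g3]), ["g1", "g2", "g3"])


class TestRunGA:
    SA = SAConfig(t_max=30, inner_iters=20, n_c=3, n_f=1, max_cycles=3)

    def test_ga_matches_exhaustive_enumeration_on_toy(self):
        """On a 3-gene problem small enough to enumerate, the GA's top-1
        equals the exhaustive argmin structure in >= 95% of seeded runs."""
        ds = _chain_dataset()
        hits = 0
        n_runs = 20
        for seed in range(n_runs):
            cfg = GAConfig(N=6, l_max=2, max_generations=15,
                           convergence_window=5, seed=seed)
            fit = run_ga(ds, factors=[], cfg=cfg, sa_cfg=self.SA)
            # exhaustive: same cache machinery over all degree vectors
            cache = GeneFitCache(ds, [], self.SA, seed=cfg.seed)
            best = None
            for d1 in (1, 2):
                for d2 in (1, 2):
                    for d3 in (1, 2):
                        bits = np.zeros((3, 2), dtype=np.uint8)
                        for i, d in enumerate((d1, d2, d3)):
                            bits[i, :d] = 1
                        st = structure_from_chromosome(
                            Chromosome(bits), cache, ds.n_times - 1, "aic"
                        )
                        if best is None or st.fitness < best.fitness:
                            best = st
            hits += abs(fit.fitness - best.fitness) < 1e-9
        assert hits >= 19

    def test_structure_respects_lmax_and_factor_exclusion(self, bench_data):
        cfg = GAConfig(N=4, l_max=2, max_generations=2,
                       convergence_window=2, seed=0)
        fit = run_ga(bench_data, cfg=cfg,
                     sa_cfg=SAConfig(t_max=10, inner_iters=5, n_c=3, n_f=1,
                                     max_cycles=1))
        for g in fit.genes:
            assert len(fit.regulators[g]) <= 2
            assert g not in fit.regulators[g]
        targets = {t for _, t, _, _ in fit.edges()}
        assert targets.isdisjoint(bench_data.factor_ids)

    def test_best_fitness_nonincreasing(self):
        ds = _chain_dataset(seed=3)
        cfg = GAConfig(N=6, l_max=2, max_generations=10,
                       convergence_window=4, seed=1)
        fit = run_ga(ds, factors=[], cfg=cfg, sa_cfg=self.SA)
        trace = np.array(fit.trace)
        assert (np.diff(trace) <= 1e-12).all()
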