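"""Evolutionary optimizers: fitness exactness, selection statistics,
crossover mechanics, and optimizer-level properties."""

import itertools

import numpy as np
import pytest
from scipy import stats

from retscreen.evolution import (EnsembleChromosome, GAConfig, HmmChromosome,
                                 PSOConfig, crossover_1pt, evolve_ensemble,
                                 evolve_hmm, evolve_synchronized, strict_majority_fitness,
                                 joint_agreement_fitness,
                                 make_redundancy_fixture, mutate_hmm,
                                 rws_select)
from retscreen.hmm import DiscreteHMM
from retscreen.synth import synthetic_context_models, synthetic_sequence_data


class TestStrictMajorityFitness:
    def test_all_vote_patterns_for_five_members(self):
        """Enumerate all 2^5 correctness patterns against the strict
        majority oracle."""
        chrom = EnsembleChromosome(list(range(5)))
        for bits in itertools.product([0, 1], repeat=5):
            C = np.asarray(bits, dtype=bool).reshape(5, 1)
            expected = 1.0 if sum(bits) > 2.5 else 0.0
            assert strict_majority_fitness(chrom, C) == expected

    def test_exact_half_counts_incorrect(self):
        chrom = EnsembleChromosome([0, 1, 2, 3])
        C = np.array([[1], [1], [0], [0]], dtype=bool)   # 2-2 split
        assert strict_majority_fitness(chrom, C) == 0.0

    def test_perfect_members_score_one(self):
        chrom = EnsembleChromosome([0, 1, 2])
        C = np.ones((3, 10), dtype=bool)
        assert strict_majority_fitness(chrom, C) == 1.0

    def test_empty_eval_set_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            strict_majority_fitness(EnsembleChromosome([0]), np.ones((1, 0), dtype=bool))


class _Ind:
    def __init__(self, fitness):
        self.fitness = fitness


class TestRouletteWheel:
    def test_equal_fitness_splits_evenly(self):
        pop = [_Ind(1.0), _Ind(1.0)]
        sel = rws_select(pop, 10_000, np.random.default_rng(0))
        freq = sum(1 for s in sel if s is pop[0]) / 10_000
        assert abs(freq - 0.5) <= 0.02

    def test_three_to_one_frequencies_chi_square(self):
        """Empirical frequencies match p_i = f_i / sum f (alpha = 0.01)."""
        pop = [_Ind(3.0), _Ind(1.0)]
        sel = rws_select(pop, 10_000, np.random.default_rng(1))
        n0 = sum(1 for s in sel if s is pop[0])
        chi2, p = stats.chisquare([n0, 10_000 - n0], [7500, 2500])
        assert p > 0.01

    def test_single_individual_always_selected(self):
        pop = [_Ind(0.7)]
        sel = rws_select(pop, 50, np.random.default_rng(2))
        assert all(s is pop[0] for s in sel)

    def test_all_zero_fitness_falls_back_to_uniform(self):
        pop = [_Ind(0.0)] * 4
        sel = rws_select(pop, 100, np.random.default_rng(3))
        assert len(sel) == 100

    def test_negative_fitness_rejected(self):
        with pytest.raises(ValueError):
            rws_select([_Ind(-1.0)], 1, np.random.default_rng(0))


class TestCrossover:
    def test_hand_traced_swap(self):
        class Cut1:
            def integers(self, lo, hi=None):
                return 1

            def random(self):
                return 0.0

        a = EnsembleChromosome([1, 2, 3])
        b = EnsembleChromosome([4, 5])
        c1, c2 = crossover_1pt(a, b, Cut1())
        assert c1.member_indices == [1, 5]
        assert c2.member_indices == [4, 2, 3]

    def test_identical_parents_children_permute_parent_set(self, rng):
        a = EnsembleChromosome([3, 1, 4, 1 + 4])
        for _ in range(20):
            c1, c2 = crossover_1pt(a, EnsembleChromosome(list(a.member_indices)), rng)
            for c in (c1, c2):
                assert set(c.member_indices) <= set(a.member_indices)
                assert len(set(c.member_indices)) == len(c.member_indices)

    def test_children_never_contain_duplicates(self, rng):
        for _ in range(50):
            la, lb = rng.integers(1, 12, size=2)
            a = EnsembleChromosome(list(rng.choice(40, la, replace=False)))
            b = EnsembleChromosome(list(rng.choice(40, lb, replace=False)))
            for c in crossover_1pt(a, b, rng):
                assert len(set(c.member_indices)) == len(c.member_indices)
                assert len(c.member_indices) >= 1


class TestEvolveEnsemble:
    def test_beats_full_pool_average_with_fewer_members(self):
        for seed in range(5):
            C, post, y = make_redundancy_fixture(seed=seed)
            best = evolve_ensemble(C, cfg=GAConfig(population_size=30,
                                                   generations=30,
                                                   rng_seed=seed))
            full_avg_acc = np.mean((post.mean(axis=0) >= 0.5) == y)
            assert best.fitness >= full_avg_acc
            assert len(best.member_indices) < C.shape[0]
            assert np.all(np.diff(best.trajectory) >= 0)

    def test_zero_generations_returns_best_of_initial_population(self):
        C, _, _ = make_redundancy_fixture(seed=1)
        best = evolve_ensemble(C, cfg=GAConfig(population_size=10,
                                               generations=0, rng_seed=1))
        assert np.isfinite(best.fitness)
        assert best.trajectory == [best.fitness]

    def test_bit_reproducible_under_fixed_seed(self):
        C, _, _ = make_redundancy_fixture(seed=2)
        cfg = GAConfig(population_size=12, generations=8, rng_seed=5)
        a = evolve_ensemble(C, cfg=cfg)
        b = evolve_ensemble(C, cfg=cfg)
        assert a.member_indices == b.member_indices
        assert a.fitness == b.fitness


class TestHmmChromosome:
    def make_chrom(self, rng, n=4, marked=()):
        return HmmChromosome(
            gene_ids=list(range(n)),
            emission_rows=rng.random((n, 6)) + 0.1,
            transmat=rng.dirichlet(np.ones(n), size=n),
            startprob=np.full(n, 1 / n),
            marked=set(marked))

    def test_mutation_without_marks_is_identity(self, rng):
        ch = self.make_chrom(rng)
        out = mutate_hmm(ch, rng)
        assert np.array_equal(out.transmat, ch.transmat)

    def test_marked_rows_redrawn_unmarked_bit_identical(self, rng):
        for _ in range(20):
            ch = self.make_chrom(rng, marked=(1, 3))
            out = mutate_hmm(ch, rng)
            assert not np.array_equal(out.transmat[1], ch.transmat[1])
            assert not np.array_equal(out.transmat[3], ch.transmat[3])
            assert np.array_equal(out.transmat[0], ch.transmat[0])
            assert np.array_equal(out.transmat[2], ch.transmat[2])
            assert np.allclose(out.transmat.sum(axis=1), 1.0)

    def test_all_marked_rows_still_stochastic(self, rng):
        ch = self.make_chrom(rng, marked=(0, 1, 2, 3))
        out = mutate_hmm(ch, rng)
        assert np.allclose(out.transmat.sum(axis=1), 1.0)
        out.decode(6).validate()


@pytest.fixture(scope="module")
def sequence_task():
    models = synthetic_context_models(separation=0.1, seed=0)
    train, Xe, ye = synthetic_sequence_data(models, 120, 180, seed=0)
    rivals = {c: DiscreteHMM(3, 16, n_init=2, random_state=0)
              .fit(train[c], max_iter=25, tol=1e-5) for c in ("BV", "BG")}
    return train, Xe, ye, rivals


class TestEvolveHmm:
    def test_returns_valid_model_and_monotone_trajectory(self, sequence_task):
        train, Xe, ye, rivals = sequence_task
        cfg = GAConfig(population_size=8, generations=4, rng_seed=0)
        model = evolve_hmm(train["MA"], Xe, ye, rivals, "MA", cfg, "GA-HMM")
        model.validate()
        assert np.all(np.diff(model.trajectory_) >= 0)
        assert 0.0 <= model.best_fitness_ <= 1.0

    def test_zero_generations_returns_best_random_init(self, sequence_task):
        train, Xe, ye, rivals = sequence_task
        cfg = GAConfig(population_size=6, generations=0, rng_seed=1)
        model = evolve_hmm(train["MA"], Xe, ye, rivals, "MA", cfg, "GA-HMM")
        model.validate()

    def test_reproducible_under_fixed_seed(self, sequence_task):
        train, Xe, ye, rivals = sequence_task
        cfg = GAConfig(population_size=6, generations=3, rng_seed=7)
        a = evolve_hmm(train["MA"], Xe, ye, rivals, "MA", cfg, "GA-HMM")
        b = evolve_hmm(train["MA"], Xe, ye, rivals, "MA", cfg, "GA-HMM")
        assert np.array_equal(a.transmat_, b.transmat_)
        assert a.best_fitness_ == b.best_fitness_

    def test_unknown_mode_rejected(self, sequence_task):
        train, Xe, ye, rivals = sequence_task
        with pytest.raises(ValueError, match="mode"):
            evolve_hmm(train["MA"], Xe, ye, rivals, "MA",
                       GAConfig(rng_seed=0), mode="simulated-annealing")


class TestJointFitness:
    def test_perfect_pair_scores_one(self):
        y = np.array([True, False, True, False])
        assert joint_agreement_fitness(np.ones(4, bool), y, y) == 1.0

    def test_perfect_ensemble_always_wrong_hmm_scores_zero(self):
        y = np.array([True, False, True, False])
        assert joint_agreement_fitness(np.ones(4, bool), y, ~y) == 0.0

    def test_agreement_on_wrong_decision_not_rewarded(self):
        y = np.array([True, True])
        ens_correct = np.array([False, False])
        hmm_pos = np.array([False, False])   # agrees with the wrong decision
        assert joint_agreement_fitness(ens_correct, y, hmm_pos) == 0.0


class TestEvolveSynchronized:
    def test_returns_valid_pair_and_respects_counts(self, sequence_task):
        train, Xe, ye, rivals = sequence_task
        yb = ye == "MA"
        C, _, _ = make_redundancy_fixture(n_members=30, seed=0, y=yb)
        cfg = GAConfig(population_size=6, generations=2, rng_seed=0)
        best, triple = evolve_synchronized(
            C, None, Xe, yb, train["MA"], rivals, cfg=cfg,
            pso=PSOConfig(swarm_size=4, iterations=3))
        best.validate(30)
        assert set(triple) == {"MA", "BV", "BG"}
        triple["MA"].validate()
        assert 0.0 <= best.fitness <= 1.0

    def test_mismatched_eval_counts_rejected(self, sequence_task):
        train, Xe, ye, rivals = sequence_task
        C, _, _ = make_redundancy_fixture(n_members=10, n_samples=5, seed=0)
        with pytest.raises(ValueError, match="differ"):
            evolve_synchronized(C, None, Xe, ye == "MA", train["MA"], rivals,
                                cfg=GAConfig(rng_seed=0))


def test_config_validation():
    with pytest.raises(ValueError):
        GAConfig(population_size=1)
    with pytest.raises(ValueError):
        GAConfig(crossover_fraction=0.0)
    with pytest.raises(ValueError):
        PSOConfig(inertia=0.0)
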