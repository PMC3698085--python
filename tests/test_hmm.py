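"""Discrete HMM machinery: Viterbi vs exhaustive enumeration, Baum-Welch
monotonicity and parameter recovery, the three-model context classifier."""

import itertools

import numpy as np
import pytest

from retscreen.hmm import DiscreteHMM, HmmContextClassifier, classify_subimage
from retscreen.synth import synthetic_context_models, synthetic_sequence_data


def path_loglik(model: DiscreteHMM, obs, path):
    """Log probability of one specific state path (oracle arithmetic)."""
    with np.errstate(divide="ignore"):
        lpi = np.log(model.startprob_)
        lA = np.log(model.transmat_)
        lB = np.log(model.emissionprob_)
    lp = lpi[path[0]] + lB[path[0], obs[0]]
    for t in range(1, len(obs)):
        lp += lA[path[t - 1], path[t]] + lB[path[t], obs[t]]
    return lp


def brute_force_viterbi(model: DiscreteHMM, obs):
    """Exhaustive enumeration over all state paths (oracle)."""
    best, best_path = -np.inf, None
    with np.errstate(divide="ignore"):
        lpi = np.log(model.startprob_)
        lA = np.log(model.transmat_)
        lB = np.log(model.emissionprob_)
    for path in itertools.product(range(model.n_states), repeat=len(obs)):
        lp = lpi[path[0]] + lB[path[0], obs[0]]
        for t in range(1, len(obs)):
            lp += lA[path[t - 1], path[t]] + lB[path[t], obs[t]]
        if lp > best:
            best, best_path = lp, path
    return best, np.asarray(best_path)


def forward_loglik_oracle(model: DiscreteHMM, obs):
    """Naive unscaled forward recursion in log space (oracle)."""
    from scipy.special import logsumexp

    with np.errstate(divide="ignore"):
        lpi = np.log(model.startprob_)
        lA = np.log(model.transmat_)
        lB = np.log(model.emissionprob_)
    a = lpi + lB[:, obs[0]]
    for t in range(1, len(obs)):
        a = logsumexp(a[:, None] + lA, axis=0) + lB[:, obs[t]]
    return logsumexp(a)


class TestViterbi:
    def test_matches_enumeration_on_random_models(self):
        rng = np.random.default_rng(1)
        for _ in range(100):
            n = int(rng.integers(1, 5))
            m = int(rng.integers(2, 6))
            T = int(rng.integers(1, 7))
            model = DiscreteHMM(n, m).init_random(rng)
            obs = rng.integers(0, m, size=T)
            res = model.viterbi(obs)
            ref_ll, ref_path = brute_force_viterbi(model, obs)
            assert res.log_likelihood == pytest.approx(ref_ll, abs=1e-9)
            # the returned path must itself be optimal (distinct paths can
            # tie to within float rounding)
            if not np.array_equal(res.path, ref_path):
                assert path_loglik(model, obs, res.path) == \
                    pytest.approx(ref_ll, abs=1e-9)
            assert model.viterbi_loglik(obs[None, :])[0] == \
                pytest.approx(ref_ll, abs=1e-9)

    def test_single_state_closed_form(self):
        model = DiscreteHMM.from_params([1.0], [[1.0]], [[0.3, 0.7]])
        obs = np.array([0, 1, 1, 0])
        res = model.viterbi(obs)
        expect = np.log(0.3) * 2 + np.log(0.7) * 2   # pi=1, a00=1
        assert res.log_likelihood == pytest.approx(expect, abs=1e-12)
        assert np.all(res.path == 0)

    def test_left_right_chain_forces_path(self):
        n = 4
        A = np.zeros((n, n))
        for i in range(n - 1):
            A[i, i + 1] = 1.0
        A[-1, -1] = 1.0
        B = np.full((n, 2), 0.5)
        model = DiscreteHMM.from_params([1, 0, 0, 0], A, B)
        res = model.viterbi(np.zeros(4, dtype=int))
        assert np.array_equal(res.path, [0, 1, 2, 3])

    def test_zero_probability_sequence_gets_sentinel(self):
        model = DiscreteHMM.from_params([1.0], [[1.0]], [[1.0, 0.0]])
        res = model.viterbi(np.array([1]))
        assert res.log_likelihood == -np.inf
        assert len(res.path) == 1

    def test_path_loglik_consistent_with_table(self):
        rng = np.random.default_rng(3)
        model = DiscreteHMM(3, 4).init_random(rng)
        obs = rng.integers(0, 4, size=6)
        res = model.viterbi(obs)
        # recompute likelihood along the returned path
        lp = np.log(model.startprob_[res.path[0]]) \
            + np.log(model.emissionprob_[res.path[0], obs[0]])
        for t in range(1, 6):
            lp += np.log(model.transmat_[res.path[t - 1], res.path[t]]) \
                + np.log(model.emissionprob_[res.path[t], obs[t]])
        assert lp == pytest.approx(res.log_likelihood, abs=1e-9)


@pytest.fixture(scope="module")
def generator():
    A = np.array([[.7, .2, .1], [.1, .8, .1], [.2, .2, .6]])
    B = np.array([[.8, .1, .05, .05, 0, 0],
                  [0, .05, .8, .1, .05, 0],
                  [0, 0, .05, .1, .8, .05]])
    B = B / B.sum(1, keepdims=True)
    return DiscreteHMM.from_params([.5, .3, .2], A, B)


class TestBaumWelch:

    def test_monotone_loglik_against_forward_oracle(self, generator):
        seqs = generator.sample(60, 9, np.random.default_rng(0))
        model = DiscreteHMM(3, 6, random_state=0)
        model.init_random(np.random.default_rng(0))
        prev = None
        for _ in range(12):
            # independent oracle recomputes the likelihood each iteration
            ll = sum(forward_loglik_oracle(model, s) for s in seqs)
            if prev is not None:
                assert ll >= prev - 1e-9
            prev = ll
            model._em(seqs, max_iter=1, tol=0.0)
            assert model.history_[0] == pytest.approx(ll, abs=1e-6)

    def test_recovers_generating_transitions_up_to_permutation(self, generator):
        seqs = generator.sample(500, 9, np.random.default_rng(42))
        model = DiscreteHMM(3, 6, n_init=4, random_state=0)
        model.fit(seqs, max_iter=300, tol=1e-8)
        errs = [np.abs(model.transmat_[np.ix_(p, p)] - generator.transmat_).max()
                for p in itertools.permutations(range(3))]
        assert min(errs) <= 0.1
        assert np.all(np.diff(model.history_) >= -1e-9)

    def test_fixed_point_is_stable(self):
        # a model already at a (local) fixed point barely moves in one sweep
        model = DiscreteHMM.from_params(
            [0.5, 0.5], [[0.9, 0.1], [0.1, 0.9]], [[1.0, 0.0], [0.0, 1.0]])
        seqs = model.sample(200, 9, np.random.default_rng(1))
        before = model.transmat_.copy()
        fitted = DiscreteHMM.from_params(model.startprob_, model.transmat_,
                                         model.emissionprob_)
        fitted.n_init = 1
        fitted.fit(seqs, max_iter=1, tol=0.0)
        # emission rows are delta functions: the E step cannot reassign
        assert np.abs(fitted.transmat_ - before).max() <= 0.05

    def test_degenerate_identical_sequences_converge(self):
        seqs = np.zeros((20, 9), dtype=int)
        model = DiscreteHMM(2, 3, random_state=0).fit(seqs, max_iter=20)
        model.validate()

    def test_stochasticity_invariants_after_fit(self, generator):
        seqs = generator.sample(50, 9, np.random.default_rng(2))
        mask = np.array([[1, 1, 0], [0, 1, 1], [1, 0, 1]], dtype=bool)
        model = DiscreteHMM(3, 6, topology_mask=mask, random_state=0)
        model.fit(seqs, max_iter=30)
        model.validate()
        assert np.all(model.transmat_[~mask] == 0.0)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            DiscreteHMM(2, 3).fit(np.empty((0, 9), dtype=int))


class TestContextClassifier:
    def test_generative_self_consistency(self):
        """Sequences drawn from each class's generator are assigned back to
        that class when the classes are well separated."""
        models = synthetic_context_models(separation=0.35, seed=3)
        train, Xe, ye = synthetic_sequence_data(models, 150, 200, seed=3)
        X = np.concatenate([train[c] for c in models])
        y = np.concatenate([[c] * 150 for c in models])
        clf = HmmContextClassifier(n_states=3, n_symbols=16,
                                   random_state=0).fit(X, y)
        pred = clf.predict(Xe)
        for cls in models:
            assert np.mean(pred[ye == cls] == cls) >= 0.9

    def test_identical_models_tie_resolves_to_ma(self):
        rng = np.random.default_rng(0)
        shared = DiscreteHMM(2, 4).init_random(rng)
        models = {c: shared for c in ("MA", "BV", "BG")}
        cls, ll = classify_subimage(models, np.array([0, 1, 2, 3, 0, 1, 2, 3, 0]))
        assert cls == "MA"
        assert len(set(np.round(list(ll.values()), 12))) == 1

    def test_per_model_loglikelihoods_match_viterbi(self):
        rng = np.random.default_rng(4)
        models = {c: DiscreteHMM(3, 5).init_random(rng) for c in ("MA", "BV", "BG")}
        obs = rng.integers(0, 5, size=9)
        _, ll = classify_subimage(models, obs)
        for c, m in models.items():
            assert ll[c] == pytest.approx(m.viterbi(obs).log_likelihood, abs=1e-9)


def test_serialization_round_trip_preserves_scores(rng):
    model = DiscreteHMM(4, 6, random_state=0).init_random(rng)
    back = DiscreteHMM.from_json(model.to_json())
    obs = rng.integers(0, 6, size=(20, 9))
    assert np.array_equal(model.viterbi_loglik(obs), back.viterbi_loglik(obs))


def test_forward_matches_hmmlearn_reference(rng):
    """Independent library cross-check of the forward likelihood."""
    hmmlearn = pytest.importorskip("hmmlearn.hmm")
    model = DiscreteHMM(3, 5).init_random(rng)
    ref = hmmlearn.CategoricalHMM(n_components=3)
    ref.startprob_ = model.startprob_
    ref.transmat_ = model.transmat_
    ref.emissionprob_ = model.emissionprob_
    seqs = model.sample(10, 9, rng)
    mine = model.forward_loglik(seqs)
    theirs = np.array([ref.score(s.reshape(-1, 1)) for s in seqs])
    assert np.allclose(mine, theirs, atol=1e-10)
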