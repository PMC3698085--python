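"""Discrete hidden Markov machinery and the three-model context classifier.

A :class:`DiscreteHMM` carries an initial vector pi, a transition matrix A
(optionally constrained by a boolean topology mask), and a discrete emission
table B over a shared codebook.  Training is Baum-Welch (EM) vectorized over
equal-length observation sequences; scoring for classification is the
*Viterbi path likelihood* — the product of the transition and emission
probabilities along the single most probable state path — computed in log
space with -inf sentinels.

The context classifier holds one model per sub-image category
(microaneurysm MA, blood vessel BV, background BG) and assigns a patch to
the model with the highest path likelihood, breaking ties in favour of the
lesion class (screening favours sensitivity).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "DiscreteHMM",
    "ViterbiResult",
    "HmmContextClassifier",
    "viterbi",
    "baum_welch",
    "classify_subimage",
]

_EPS = 1e-6  # floor for zero-count emission cells


def _log(x: np.ndarray) -> np.ndarray:
    with np.errstate(divide="ignore"):
        return np.log(x)


def _normalize_rows(m: np.ndarray, mask: np.ndarray | None = None) -> np.ndarray:
    m = np.asarray(m, dtype=np.float64).copy()
    if mask is not None:
        m[~mask] = 0.0
    s = m.sum(axis=-1, keepdims=True)
    bad = (s <= 0).ravel()
    if bad.any():
        # unvisited state: fall back to uniform over allowed entries
        fill = np.ones_like(m) if mask is None else mask.astype(np.float64)
        m[bad] = fill[bad]
        s = m.sum(axis=-1, keepdims=True)
    return m / s


@dataclass
class ViterbiResult:
    path: np.ndarray           # most probable state sequence
    V: np.ndarray              # T x N dynamic-programming table, log space
    log_likelihood: float      # max-path log probability
    backpointers: np.ndarray   # T x N


class DiscreteHMM:
    """Discrete-emission HMM (sklearn-style estimator).

    Parameters
    ----------
    n_states : int
        Number of hidden states N.
    n_symbols : int
        Codebook size (emission alphabet).
    topology_mask : (N, N) bool array, optional
        Allowed transitions; disallowed entries stay exactly zero through
        initialisation and re-estimation.  Default: fully connected.
    max_iter, tol : Baum-Welch stopping rule (improvement in mean
        per-sequence log-likelihood).
    random_state : seed for random initialisation in :meth:`fit`.

    Fitted attributes: ``startprob_`` (pi), ``transmat_`` (A),
    ``emissionprob_`` (B), ``history_`` (training log-likelihood per
    iteration, non-decreasing).
    """

    def __init__(self, n_states: int = 3, n_symbols: int = 16,
                 topology_mask: np.ndarray | None = None,
                 max_iter: int = 100, tol: float = 1e-6,
                 n_init: int = 1, random_state: int | None = 0):
        self.n_states = n_states
        self.n_symbols = n_symbols
        self.topology_mask = topology_mask
        self.max_iter = max_iter
        self.tol = tol
        self.n_init = n_init
        self.random_state = random_state

    # -- sklearn plumbing ------------------------------------------------
    def get_params(self, deep: bool = True) -> dict:
        return {"n_states": self.n_states, "n_symbols": self.n_symbols,
                "topology_mask": self.topology_mask, "max_iter": self.max_iter,
                "tol": self.tol, "n_init": self.n_init,
                "random_state": self.random_state}

    def set_params(self, **params) -> "DiscreteHMM":
        for k, v in params.items():
            setattr(self, k, v)
        return self

    # -- parameter handling ----------------------------------------------
    @property
    def mask_(self) -> np.ndarray:
        if self.topology_mask is None:
            return np.ones((self.n_states, self.n_states), dtype=bool)
        return np.asarray(self.topology_mask, dtype=bool)

    def init_random(self, rng: np.random.Generator) -> "DiscreteHMM":
        """Dirichlet-uniform initialisation respecting the topology mask."""
        n, m = self.n_states, self.n_symbols
        mask = self.mask_
        if not mask.any(axis=1).all():
            raise ValueError("topology mask has a row with no allowed transition")
        A = rng.random((n, n)) + 0.1
        self.transmat_ = _normalize_rows(A, mask)
        self.emissionprob_ = _normalize_rows(rng.random((n, m)) + 0.1)
        self.startprob_ = rng.random(n) + 0.1
        self.startprob_ /= self.startprob_.sum()
        return self

    @classmethod
    def from_params(cls, startprob, transmat, emissionprob,
                    topology_mask: np.ndarray | None = None) -> "DiscreteHMM":
        transmat = np.asarray(transmat, dtype=np.float64)
        emissionprob = np.asarray(emissionprob, dtype=np.float64)
        model = cls(n_states=transmat.shape[0], n_symbols=emissionprob.shape[1],
                    topology_mask=topology_mask)
        model.startprob_ = np.asarray(startprob, dtype=np.float64)
        model.transmat_ = transmat
        model.emissionprob_ = emissionprob
        model.validate()
        return model

    def validate(self) -> None:
        np.testing.assert_allclose(self.startprob_.sum(), 1.0, atol=1e-9)
        np.testing.assert_allclose(self.transmat_.sum(axis=1), 1.0, atol=1e-9)
        np.testing.assert_allclose(self.emissionprob_.sum(axis=1), 1.0, atol=1e-9)
        if (self.transmat_[~self.mask_] != 0).any():
            raise ValueError("transition matrix nonzero outside topology mask")

    # -- scoring ----------------------------------------------------------
    def viterbi(self, obs: np.ndarray) -> ViterbiResult:
        """Most probable state path and its log probability.

        V[0, k] = pi_k b_k(o_0); V[t, k] = max_x V[t-1, x] a_{xk} b_k(o_t).
        A sequence with probability zero under the model returns a -inf
        log-likelihood sentinel with the path still recovered from the table.
        """
        obs = np.asarray(obs, dtype=np.intp)
        T, n = len(obs), self.n_states
        logA = _log(self.transmat_)
        logB = _log(self.emissionprob_)
        V = np.full((T, n), -np.inf)
        ptr = np.zeros((T, n), dtype=np.intp)
        V[0] = _log(self.startprob_) + logB[:, obs[0]]
        for t in range(1, T):
            cand = V[t - 1][:, None] + logA          # (from, to)
            ptr[t] = np.argmax(cand, axis=0)
            V[t] = cand[ptr[t], np.arange(n)] + logB[:, obs[t]]
        path = np.zeros(T, dtype=np.intp)
        path[-1] = int(np.argmax(V[-1]))
        for t in range(T - 1, 0, -1):
            path[t - 1] = ptr[t, path[t]]
        return ViterbiResult(path=path, V=V, log_likelihood=float(V[-1].max()),
                             backpointers=ptr)

    def viterbi_loglik(self, sequences: np.ndarray) -> np.ndarray:
        """Vectorized max-path log-likelihood for an (n, T) batch."""
        seqs = np.asarray(sequences, dtype=np.intp)
        if seqs.ndim == 1:
            seqs = seqs[None, :]
        logA = _log(self.transmat_)
        logB = _log(self.emissionprob_)
        V = _log(self.startprob_)[None, :] + logB[:, seqs[:, 0]].T
        for t in range(1, seqs.shape[1]):
            V = (V[:, :, None] + logA[None, :, :]).max(axis=1) + logB[:, seqs[:, t]].T
        return V.max(axis=1)

    # -- training ----------------------------------------------------------
    def fit(self, sequences: np.ndarray, max_iter: int | None = None,
            tol: float | None = None) -> "DiscreteHMM":
        """Baum-Welch re-estimation over equal-length sequences.

        Uses the scaled forward-backward recursions; the per-iteration
        training log-likelihood is recorded in ``history_`` and is
        non-decreasing (EM).  Zero-count emission cells are floored at
        1e-6 and renormalized; masked transitions stay exactly zero.
        """
        seqs = np.asarray(sequences, dtype=np.intp)
        if seqs.ndim == 1:
            seqs = seqs[None, :]
        if seqs.size == 0:
            raise ValueError("need at least one sequence")
        max_iter = self.max_iter if max_iter is None else max_iter
        tol = self.tol if tol is None else tol
        warm = hasattr(self, "transmat_")
        n_init = max(1, self.n_init)
        best = None
        for i in range(n_init):
            if i > 0 or not warm:
                seed = None if self.random_state is None else self.random_state + 977 * i
                self.init_random(np.random.default_rng(seed))
            self._em(seqs, max_iter, tol)
            if best is None or self.history_[-1] > best[0]:
                best = (self.history_[-1], self.startprob_, self.transmat_,
                        self.emissionprob_, self.history_)
            if i == n_init - 1:
                (_, self.startprob_, self.transmat_,
                 self.emissionprob_, self.history_) = best
        return self

    def _em(self, seqs: np.ndarray, max_iter: int, tol: float) -> None:
        """One EM run from the current parameters (in place)."""
        mask = self.mask_
        n_seq, T = seqs.shape
        n = self.n_states
        self.history_ = []
        for _ in range(max_iter):
            A, B, pi = self.transmat_, self.emissionprob_, self.startprob_
            Bobs = B[:, seqs].transpose(1, 2, 0)            # (n_seq, T, N)
            alpha = np.empty((n_seq, T, n))
            c = np.empty((n_seq, T))
            a0 = pi[None, :] * Bobs[:, 0]
            c[:, 0] = a0.sum(axis=1)
            degenerate = c[:, 0] <= 0
            c[degenerate, 0] = 1.0
            alpha[:, 0] = a0 / c[:, 0, None]
            for t in range(1, T):
                at = (alpha[:, t - 1] @ A) * Bobs[:, t]
                c[:, t] = at.sum(axis=1)
                degenerate = c[:, t] <= 0
                c[degenerate, t] = 1.0
                at[degenerate] = 1.0 / n
                alpha[:, t] = at / c[:, t, None]
            loglik = float(np.log(c).sum())
            self.history_.append(loglik)

            beta = np.empty_like(alpha)
            beta[:, -1] = 1.0
            for t in range(T - 2, -1, -1):
                beta[:, t] = ((beta[:, t + 1] * Bobs[:, t + 1]) @ A.T) / c[:, t + 1, None]
            gamma = alpha * beta
            gamma /= np.maximum(gamma.sum(axis=2, keepdims=True), 1e-300)

            # expected transition counts
            xi_sum = np.zeros((n, n))
            for t in range(T - 1):
                xi_sum += np.einsum(
                    "si,ij,sj->ij", alpha[:, t], A,
                    beta[:, t + 1] * Bobs[:, t + 1] / c[:, t + 1, None])
            new_A = _normalize_rows(xi_sum, mask)

            # expected emission counts
            em = np.zeros((n, self.n_symbols))
            np.add.at(em.T, seqs.ravel(), gamma.reshape(-1, n))
            zero = em <= 0
            if zero.any():
                em[zero] = _EPS
            new_B = _normalize_rows(em)

            new_pi = gamma[:, 0].mean(axis=0)
            new_pi = new_pi / new_pi.sum()

            self.transmat_, self.emissionprob_, self.startprob_ = new_A, new_B, new_pi
            if len(self.history_) > 1 and \
                    self.history_[-1] - self.history_[-2] < tol * n_seq:
                break

    def forward_loglik(self, sequences: np.ndarray) -> np.ndarray:
        """Scaled forward log-likelihood per sequence (used by training)."""
        seqs = np.asarray(sequences, dtype=np.intp)
        if seqs.ndim == 1:
            seqs = seqs[None, :]
        Bobs = self.emissionprob_[:, seqs].transpose(1, 2, 0)
        logc = np.empty(seqs.shape)
        a = self.startprob_[None, :] * Bobs[:, 0]
        s = a.sum(axis=1)
        logc[:, 0] = _log(s)
        a = a / np.maximum(s, 1e-300)[:, None]
        for t in range(1, seqs.shape[1]):
            a = (a @ self.transmat_) * Bobs[:, t]
            s = a.sum(axis=1)
            logc[:, t] = _log(s)
            a = a / np.maximum(s, 1e-300)[:, None]
        return logc.sum(axis=1)

    # -- generation and serialization --------------------------------------
    def sample(self, n_sequences: int, length: int,
               rng: np.random.Generator) -> np.ndarray:
        """Draw (n_sequences, length) observation sequences from the model."""
        out = np.empty((n_sequences, length), dtype=np.intp)
        states = rng.choice(self.n_states, size=n_sequences, p=self.startprob_)
        cumA = np.cumsum(self.transmat_, axis=1)
        cumB = np.cumsum(self.emissionprob_, axis=1)
        for t in range(length):
            u = rng.random(n_sequences)
            out[:, t] = (u[:, None] > cumB[states]).sum(axis=1)
            if t < length - 1:
                u = rng.random(n_sequences)
                states = (u[:, None] > cumA[states]).sum(axis=1)
        return out

    def to_json(self) -> dict:
        return {
            "schema": "retscreen-hmm-1",
            "n_states": self.n_states,
            "n_symbols": self.n_symbols,
            "startprob": self.startprob_.tolist(),
            "transmat": self.transmat_.tolist(),
            "emissionprob": self.emissionprob_.tolist(),
            "topology_mask": self.mask_.astype(int).tolist(),
        }

    @classmethod
    def from_json(cls, d: dict) -> "DiscreteHMM":
        return cls.from_params(d["startprob"], d["transmat"], d["emissionprob"],
                               topology_mask=np.asarray(d["topology_mask"], dtype=bool))


# ---------------------------------------------------------------------------

class HmmContextClassifier:
    """One Baum-Welch-trained HMM per sub-image category.

    A patch sequence is assigned to the class whose model gives the highest
    Viterbi path likelihood; exact ties resolve by the ``priority`` order
    (default MA before BV before BG).
    """

    def __init__(self, n_states: int = 3, n_symbols: int = 16,
                 priority: tuple[str, ...] = ("MA", "BV", "BG"),
                 max_iter: int = 50, tol: float = 1e-4, random_state: int = 0):
        self.n_states = n_states
        self.n_symbols = n_symbols
        self.priority = priority
        self.max_iter = max_iter
        self.tol = tol
        self.random_state = random_state

    def get_params(self, deep: bool = True) -> dict:
        return {"n_states": self.n_states, "n_symbols": self.n_symbols,
                "priority": self.priority, "max_iter": self.max_iter,
                "tol": self.tol, "random_state": self.random_state}

    def set_params(self, **params) -> "HmmContextClassifier":
        for k, v in params.items():
            setattr(self, k, v)
        return self

    def fit(self, X: np.ndarray, y) -> "HmmContextClassifier":
        X = np.asarray(X, dtype=np.intp)
        y = np.asarray(y)
        self.classes_ = [c for c in self.priority if c in set(y)] + \
            sorted(set(y) - set(self.priority))
        self.models_ = {}
        for k, cls in enumerate(self.classes_):
            m = DiscreteHMM(self.n_states, self.n_symbols,
                            max_iter=self.max_iter, tol=self.tol,
                            random_state=self.random_state + 101 * k)
            m.fit(X[y == cls])
            self.models_[cls] = m
        return self

    def set_models(self, models: dict) -> "HmmContextClassifier":
        """Install externally trained/evolved models (e.g. from evolution)."""
        self.models_ = dict(models)
        self.classes_ = [c for c in self.priority if c in models] + \
            sorted(set(models) - set(self.priority))
        return self

    def log_likelihoods(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=np.intp)
        if X.ndim == 1:
            X = X[None, :]
        return np.stack([self.models_[c].viterbi_loglik(X) for c in self.classes_],
                        axis=1)

    def predict(self, X: np.ndarray) -> np.ndarray:
        ll = self.log_likelihoods(np.asarray(X))
        # argmax with ties resolved by classes_ order (= priority order)
        best = np.argmax(ll, axis=1)
        return np.asarray(self.classes_, dtype=object)[best]

    def score(self, X: np.ndarray, y) -> float:
        return float(np.mean(self.predict(X) == np.asarray(y)))


# ---------------------------------------------------------------------------
# thin functional wrappers over the estimator surface

def viterbi(model: DiscreteHMM, obs: np.ndarray) -> ViterbiResult:
    return model.viterbi(obs)


def baum_welch(model: DiscreteHMM, sequences: np.ndarray,
               max_iter: int = 100, tol: float = 1e-6) -> DiscreteHMM:
    return model.fit(sequences, max_iter=max_iter, tol=tol)


def classify_subimage(models: dict, obs: np.ndarray,
                      priority: tuple[str, ...] = ("MA", "BV", "BG")):
    """Classify one observation sequence against a model dict.

    Returns ``(class, {class: log_likelihood})``; ties break by priority.
    """
    clf = HmmContextClassifier(priority=priority).set_models(models)
    ll = clf.log_likelihoods(np.asarray(obs)[None, :])[0]
    per_model = dict(zip(clf.classes_, map(float, ll)))
    return clf.predict(np.asarray(obs)[None, :])[0], per_model
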