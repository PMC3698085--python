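"""Heterogeneous neural-network ensembles per detector.

Each detector owns a pool of feed-forward networks spanning 3 training
algorithms x 10 hidden-layer sizes x 3 weight initialisations = 90 base
classifiers per feature set; a detector with two feature sets has a pool of
180, with three 270.  At deployment the (possibly GA-pruned) pool combines
member posteriors under one of four rules: best single member, average,
sum, or majority vote.  Average and sum share their argmax by positive
scaling; ties always resolve toward the positive (lesion) class because
screening favours sensitivity.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.exceptions import ConvergenceWarning
from sklearn.neural_network import MLPClassifier
from sklearn.preprocessing import StandardScaler

__all__ = [
    "TRAIN_ALGOS",
    "DEFAULT_HIDDEN_SIZES",
    "BaseClassifier",
    "EnsemblePool",
    "build_pool",
    "combine",
]

#: The three training algorithms (any three distinct optimizers qualify).
TRAIN_ALGOS = ("sgd", "sgd-momentum", "lbfgs")
#: Ten hidden-layer widths.
DEFAULT_HIDDEN_SIZES = tuple(range(2, 21, 2))
N_INIT_SEEDS = 3

_ALGO_KWARGS = {
    "sgd": dict(solver="sgd", momentum=0.0, learning_rate_init=0.05, max_iter=120),
    "sgd-momentum": dict(solver="sgd", momentum=0.9, learning_rate_init=0.02, max_iter=120),
    "lbfgs": dict(solver="lbfgs", max_iter=120),
}


@dataclass
class BaseClassifier:
    """One trained network with its generation coordinates."""

    detector: str
    train_algo: str
    hidden_units: int
    init_seed: int
    feature_set_id: int
    model: MLPClassifier
    holdout_accuracy: float = 0.0
    converged: bool = True

    @property
    def key(self) -> tuple:
        return (self.train_algo, self.hidden_units, self.init_seed, self.feature_set_id)


class EnsemblePool:
    """Ordered pool of base classifiers for one detector (sklearn-style).

    Parameters
    ----------
    detector : schema id the pool serves.
    feature_sets : list of column-index lists into the detector's feature
        matrix; each feature set contributes 90 members.
    hidden_sizes, train_algos : the generation grid (defaults follow the
        3 x 10 x 3 construction).
    holdout_fraction : slice of the training data reserved to record each
        member's individual accuracy (used by the "best" rule and reported
        in evolution logs).
    """

    def __init__(self, detector: str, feature_sets: list | None = None,
                 hidden_sizes: tuple = DEFAULT_HIDDEN_SIZES,
                 train_algos: tuple = TRAIN_ALGOS,
                 n_init_seeds: int = N_INIT_SEEDS,
                 holdout_fraction: float = 0.2,
                 positive_threshold: float = 0.5,
                 random_state: int = 0):
        self.detector = detector
        self.feature_sets = feature_sets
        self.hidden_sizes = hidden_sizes
        self.train_algos = train_algos
        self.n_init_seeds = n_init_seeds
        self.holdout_fraction = holdout_fraction
        self.positive_threshold = positive_threshold
        self.random_state = random_state

    def get_params(self, deep: bool = True) -> dict:
        return {k: getattr(self, k) for k in (
            "detector", "feature_sets", "hidden_sizes", "train_algos",
            "n_init_seeds", "holdout_fraction", "positive_threshold", "random_state")}

    def set_params(self, **params) -> "EnsemblePool":
        for k, v in params.items():
            setattr(self, k, v)
        return self

    # ------------------------------------------------------------------
    def fit(self, X: np.ndarray, y: np.ndarray) -> "EnsemblePool":
        """Train 90 members per feature set; non-converged members are
        retained (the GA may still select them) but flagged."""
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y).astype(int)
        if len(np.unique(y)) < 2:
            raise ValueError("need at least 2 classes in training labels")
        feature_sets = self.feature_sets or [list(range(X.shape[1]))]
        rng = np.random.default_rng(self.random_state)
        n = len(y)
        idx = rng.permutation(n)
        n_hold = max(1, int(round(self.holdout_fraction * n)))
        hold, tr = idx[:n_hold], idx[n_hold:]

        self.members_: list[BaseClassifier] = []
        self.scalers_: list[StandardScaler] = []
        for fs_id, cols in enumerate(feature_sets):
            scaler = StandardScaler().fit(X[np.ix_(tr, cols)])
            self.scalers_.append(scaler)
            Xtr = scaler.transform(X[np.ix_(tr, cols)])
            Xho = scaler.transform(X[np.ix_(hold, cols)])
            for algo in self.train_algos:
                for hu in self.hidden_sizes:
                    for seed in range(self.n_init_seeds):
                        kw = dict(_ALGO_KWARGS[algo])
                        net = MLPClassifier(hidden_layer_sizes=(hu,),
                                            random_state=self.random_state
                                            + 7919 * fs_id + 104729 * seed + hash(algo) % 997,
                                            tol=1e-4, **kw)
                        converged = True
                        with warnings.catch_warnings():
                            warnings.simplefilter("error", ConvergenceWarning)
                            try:
                                net.fit(Xtr, y[tr])
                            except ConvergenceWarning:
                                converged = False
                                with warnings.catch_warnings():
                                    warnings.simplefilter("ignore", ConvergenceWarning)
                                    net.fit(Xtr, y[tr])
                        acc = float(np.mean(net.predict(Xho) == y[hold]))
                        self.members_.append(BaseClassifier(
                            detector=self.detector, train_algo=algo,
                            hidden_units=hu, init_seed=seed, feature_set_id=fs_id,
                            model=net, holdout_accuracy=acc, converged=converged))
        self.feature_sets_ = feature_sets
        self.classes_ = np.unique(y)
        keys = [m.key for m in self.members_]
        assert len(set(keys)) == len(keys), "duplicate member coordinates"
        return self

    def __len__(self) -> int:
        return len(self.members_)

    # ------------------------------------------------------------------
    def posteriors(self, X: np.ndarray, subset=None) -> np.ndarray:
        """(n_members, n_samples) positive-class posterior matrix."""
        X = np.atleast_2d(np.asarray(X, dtype=np.float64))
        subset = range(len(self.members_)) if subset is None else subset
        scaled = {fs: sc.transform(X[:, cols])
                  for fs, (sc, cols) in enumerate(zip(self.scalers_, self.feature_sets_))}
        out = np.empty((len(list(subset)), X.shape[0]))
        for row, i in enumerate(subset):
            m = self.members_[i]
            proba = m.model.predict_proba(scaled[m.feature_set_id])
            pos_col = int(np.argmax(m.model.classes_))  # positive class = 1
            out[row] = proba[:, pos_col]
        return out

    def correctness(self, X: np.ndarray, y: np.ndarray) -> np.ndarray:
        """(n_members, n_samples) boolean: member predicts the true label.

        This is the matrix the GA's strict-majority fitness consumes.
        """
        post = self.posteriors(X)
        pred = post >= self.positive_threshold
        return pred == np.asarray(y).astype(bool)[None, :]

    def predict(self, X: np.ndarray, subset=None, rule: str = "average") -> np.ndarray:
        cls, _ = self.combine(X, subset=subset, rule=rule)
        return cls

    def combine(self, X: np.ndarray, subset=None, rule: str = "average"):
        """Combined decision of a pool subset under one of four rules.

        Returns ``(decision, score)`` arrays; decision is boolean
        (positive = lesion class), score the rule's aggregate in [0, 1].
        Ties break toward the positive class.
        """
        subset = list(range(len(self.members_))) if subset is None else list(subset)
        if len(subset) == 0:
            raise ValueError("empty pool subset")
        post = self.posteriors(X, subset=subset)
        thr = self.positive_threshold
        if rule == "best":
            best = max(range(len(subset)),
                       key=lambda r: self.members_[subset[r]].holdout_accuracy)
            score = post[best]
            return score >= thr, score
        if rule == "average":
            score = post.mean(axis=0)
            return score >= thr, score
        if rule == "sum":
            total = post.sum(axis=0)
            return total >= thr * len(subset), total / len(subset)
        if rule == "majority":
            votes = (post >= thr).sum(axis=0)
            return votes >= len(subset) / 2.0, votes / len(subset)
        raise ValueError(f"unknown combination rule {rule!r}")

    # ------------------------------------------------------------------
    def to_json(self) -> dict:
        members = []
        for m in self.members_:
            net = m.model
            members.append({
                "train_algo": m.train_algo, "hidden_units": m.hidden_units,
                "init_seed": m.init_seed, "feature_set_id": m.feature_set_id,
                "holdout_accuracy": m.holdout_accuracy, "converged": m.converged,
                "coefs": [c.tolist() for c in net.coefs_],
                "intercepts": [b.tolist() for b in net.intercepts_],
                "classes": net.classes_.tolist(),
                "n_features": net.n_features_in_,
            })
        return {
            "schema": "retscreen-pool-1",
            "detector": self.detector,
            "feature_sets": [list(map(int, c)) for c in self.feature_sets_],
            "positive_threshold": self.positive_threshold,
            "scalers": [{"mean": s.mean_.tolist(), "scale": s.scale_.tolist()}
                        for s in self.scalers_],
            "members": members,
        }

    @classmethod
    def from_json(cls, d: dict) -> "EnsemblePool":
        pool = cls(detector=d["detector"], feature_sets=d["feature_sets"],
                   positive_threshold=d.get("positive_threshold", 0.5))
        pool.feature_sets_ = d["feature_sets"]
        pool.scalers_ = []
        for s in d["scalers"]:
            sc = StandardScaler()
            sc.mean_ = np.asarray(s["mean"])
            sc.scale_ = np.asarray(s["scale"])
            sc.var_ = sc.scale_ ** 2
            sc.n_features_in_ = len(s["mean"])
            pool.scalers_.append(sc)
        pool.members_ = []
        for mj in d["members"]:
            net = MLPClassifier(hidden_layer_sizes=(mj["hidden_units"],))
            net.coefs_ = [np.asarray(c) for c in mj["coefs"]]
            net.intercepts_ = [np.asarray(b) for b in mj["intercepts"]]
            net.classes_ = np.asarray(mj["classes"])
            net.n_features_in_ = mj["n_features"]
            net.n_layers_ = len(net.coefs_) + 1
            net.n_outputs_ = 1
            net.out_activation_ = "logistic"
            net._label_binarizer = _binarizer_for(net.classes_)
            pool.members_.append(BaseClassifier(
                detector=d["detector"], train_algo=mj["train_algo"],
                hidden_units=mj["hidden_units"], init_seed=mj["init_seed"],
                feature_set_id=mj["feature_set_id"], model=net,
                holdout_accuracy=mj["holdout_accuracy"], converged=mj["converged"]))
        pool.classes_ = np.asarray(d["members"][0]["classes"]) if d["members"] else None
        return pool

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_json()))

    @classmethod
    def load(cls, path: str | Path) -> "EnsemblePool":
        return cls.from_json(json.loads(Path(path).read_text()))


def _binarizer_for(classes):
    from sklearn.preprocessing import LabelBinarizer

    lb = LabelBinarizer()
    lb.fit(np.asarray(classes))
    return lb


# ---------------------------------------------------------------------------
# functional wrappers

def build_pool(X: np.ndarray, y: np.ndarray, detector: str,
               feature_sets: list | None = None, **kwargs) -> EnsemblePool:
    """Train a pool of 90 x len(feature_sets) base classifiers."""
    return EnsemblePool(detector=detector, feature_sets=feature_sets, **kwargs).fit(X, y)


def combine(pool: EnsemblePool, subset, x: np.ndarray, rule: str):
    """Combined (class, score) for one feature vector."""
    cls, score = pool.combine(np.atleast_2d(x), subset=subset, rule=rule)
    return bool(cls[0]), float(score[0])
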