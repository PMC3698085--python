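"""Evolutionary optimizers: GA ensemble pruning, GA/memetic HMM evolution,
and synchronized ensemble+HMM co-evolution.

Four searches share the same machinery:

* **GA-classifier** — prunes a base-classifier pool to a variable-length
  subset (chromosome).  Fitness is the strict-majority accuracy on a
  held-out set: a sample counts as correct iff *more than half* of the
  chromosome's members predict its true label (an exact half is wrong).
  Selection is fitness-proportionate roulette wheel (p_i = f_i / sum f),
  80% of the population is selected for 1-point crossover with
  *per-parent* cut points (chromosome lengths differ), and parents that
  still outperform both of their children re-enter the next generation.

* **GA-HMM** — evolves the structure (state count, topology) and
  parameters of one context HMM.  Baum-Welch is the local learner: every
  chromosome is trained for a few EM sweeps before evaluation and the
  trained parameters are written back (Lamarckian).  Mutation redraws the
  transition rows of states that were inherited or adopted during
  crossover.

* **M-HMM** — the memetic variant: after selection, particle swarm
  optimization refines the transition matrices of the top 20% of
  individuals on the row-stochastic simplex, and the best particle is
  written back to the chromosome.

* **C-HMM** — two populations (ensemble chromosomes, HMM chromosomes)
  evolve in lock-step; the joint fitness of a pair is the fraction of
  evaluation items on which the ensemble decision is correct AND the HMM
  decision agrees with it.

Every optimizer draws all randomness from one seeded generator, keeps an
elitist best-ever individual (so the best-fitness trajectory is
non-decreasing), resolves fitness ties by lowest index, and can append a
JSONL log line per generation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .ensembles import EnsemblePool
from .hmm import DiscreteHMM

__all__ = [
    "GAConfig",
    "PSOConfig",
    "EnsembleChromosome",
    "HmmChromosome",
    "strict_majority_fitness",
    "rws_select",
    "crossover_1pt",
    "evolve_ensemble",
    "mutate_hmm",
    "evolve_hmm",
    "evolve_synchronized",
    "joint_agreement_fitness",
    "make_redundancy_fixture",
]


@dataclass(frozen=True)
class GAConfig:
    population_size: int = 30
    generations: int = 30
    crossover_fraction: float = 0.80    # share of the population selected for crossover
    rng_seed: int = 0
    # GA-HMM structure ranges
    min_states: int = 3
    max_states: int = 8
    bw_iterations: int = 8              # Baum-Welch sweeps per fitness evaluation

    def __post_init__(self) -> None:
        if self.population_size < 2:
            raise ValueError("population_size must be >= 2")
        if not 0.0 < self.crossover_fraction <= 1.0:
            raise ValueError("crossover_fraction must lie in (0, 1]")


@dataclass(frozen=True)
class PSOConfig:
    swarm_size: int = 10
    iterations: int = 20
    inertia: float = 0.7
    cognitive: float = 1.5
    social: float = 1.5
    elite_fraction: float = 0.20

    def __post_init__(self) -> None:
        if min(self.inertia, self.cognitive, self.social) <= 0:
            raise ValueError("w, c1, c2 must be positive")


# ---------------------------------------------------------------------------
# ensemble chromosomes

@dataclass
class EnsembleChromosome:
    """Variable-length ordered subset of pool member indices."""

    member_indices: list[int]
    fitness: float = float("nan")

    def validate(self, pool_size: int) -> None:
        idx = self.member_indices
        if len(idx) < 1:
            raise ValueError("chromosome must keep at least one member")
        if len(set(idx)) != len(idx):
            raise ValueError("duplicate member indices")
        if min(idx) < 0 or max(idx) >= pool_size:
            raise ValueError("member index out of pool bounds")


def _correctness(pool, eval_set) -> np.ndarray:
    """(n_members, n_samples) boolean correctness matrix from a trained
    pool + (X, y) eval set, or pass a precomputed matrix straight through."""
    if isinstance(pool, np.ndarray):
        return pool.astype(bool)
    X, y = eval_set
    return pool.correctness(X, y)


def strict_majority_fitness(chrom: EnsembleChromosome, pool, eval_set=None) -> float:
    """Strict-majority accuracy: N_correct / N_total.

    A sample is correct iff more than half of the chromosome's members
    predict its true label; an exact half counts as incorrect.
    """
    C = _correctness(pool, eval_set)
    if C.shape[1] == 0:
        raise ValueError("empty evaluation set")
    votes = C[chrom.member_indices].sum(axis=0)
    return float(np.mean(votes * 2 > len(chrom.member_indices)))


def rws_select(population: list, n_select: int, rng: np.random.Generator,
               fitnesses: np.ndarray | None = None) -> list:
    """Roulette wheel selection: draw with replacement, p_i = f_i / sum f.

    Weak solutions keep a nonzero chance.  If every fitness is zero the
    draw falls back to uniform (flagged via the returned list only).
    """
    f = np.asarray([ind.fitness for ind in population], dtype=np.float64) \
        if fitnesses is None else np.asarray(fitnesses, dtype=np.float64)
    if (f < 0).any():
        raise ValueError("fitness must be non-negative for RWS")
    total = f.sum()
    p = np.full(len(f), 1.0 / len(f)) if total <= 0 else f / total
    idx = rng.choice(len(population), size=n_select, replace=True, p=p)
    return [population[i] for i in idx]


def crossover_1pt(parent_a: EnsembleChromosome, parent_b: EnsembleChromosome,
                  rng: np.random.Generator):
    """1-point crossover with independent per-parent cut points.

    Tails are swapped; duplicate indices in a child are removed keeping the
    first occurrence; an empty child is repaired by inheriting one random
    gene from a parent.
    """
    a, b = parent_a.member_indices, parent_b.member_indices

    def cut(genes):
        return int(rng.integers(1, len(genes))) if len(genes) > 1 else 1

    ca, cb = cut(a), cut(b)
    raw_a = list(a[:ca]) + list(b[cb:])
    raw_b = list(b[:cb]) + list(a[ca:])

    def dedup(genes):
        seen, out = set(), []
        for g in genes:
            if g not in seen:
                seen.add(g)
                out.append(g)
        return out

    out = []
    for child in (dedup(raw_a), dedup(raw_b)):
        if not child:
            donor = a if rng.random() < 0.5 else b
            child = [donor[int(rng.integers(len(donor)))]]
        out.append(EnsembleChromosome(member_indices=child))
    return out[0], out[1]


def _log_generation(log_path, record: dict) -> None:
    if log_path is None:
        return
    with Path(log_path).open("a") as fh:
        fh.write(json.dumps(record) + "\n")


def evolve_ensemble(pool, eval_set=None, cfg: GAConfig = GAConfig(),
                    log_path=None) -> EnsembleChromosome:
    """GA subset selection over a trained pool (or correctness matrix).

    Returns the best-ever chromosome; its ``fitness`` holds the strict
    majority accuracy on the evaluation set.
    """
    C = _correctness(pool, eval_set)
    n_pool = C.shape[0]
    if n_pool < 2:
        raise ValueError("pool must have at least 2 members")
    rng = np.random.default_rng(cfg.rng_seed)

    def evaluate(ch: EnsembleChromosome) -> EnsembleChromosome:
        ch.fitness = strict_majority_fitness(ch, C)
        ch.validate(n_pool)
        return ch

    def random_chrom() -> EnsembleChromosome:
        size = int(rng.integers(1, n_pool + 1))
        idx = list(map(int, rng.choice(n_pool, size=size, replace=False)))
        return evaluate(EnsembleChromosome(member_indices=idx))

    population = [random_chrom() for _ in range(cfg.population_size)]
    best = max(population, key=lambda c: c.fitness)
    best = EnsembleChromosome(list(best.member_indices), best.fitness)
    trajectory = [best.fitness]

    for gen in range(cfg.generations):
        n_sel = max(2, int(round(cfg.crossover_fraction * cfg.population_size)))
        selected = rws_select(population, n_sel, rng)
        entrants: list[EnsembleChromosome] = []
        for i in range(0, n_sel - 1, 2):
            pa, pb = selected[i], selected[i + 1]
            c1, c2 = crossover_1pt(pa, pb, rng)
            evaluate(c1)
            evaluate(c2)
            entrants.extend([c1, c2])
            worst_child = min(c1.fitness, c2.fitness)
            for p in (pa, pb):
                if p.fitness > worst_child:
                    entrants.append(p)
        entrants.append(best)
        # stable truncation: ties keep the earlier entrant
        order = sorted(range(len(entrants)),
                       key=lambda i: (-entrants[i].fitness, i))
        population = [entrants[i] for i in order[:cfg.population_size]]
        while len(population) < cfg.population_size:
            population.append(random_chrom())
        gen_best = max(population, key=lambda c: c.fitness)
        if gen_best.fitness > best.fitness:
            best = EnsembleChromosome(list(gen_best.member_indices), gen_best.fitness)
        trajectory.append(best.fitness)
        _log_generation(log_path, {
            "optimizer": "ga-ensemble", "generation": gen,
            "best_fitness": best.fitness,
            "mean_fitness": float(np.mean([c.fitness for c in population])),
            "mean_size": float(np.mean([len(c.member_indices) for c in population])),
        })
    best.trajectory = trajectory
    return best


# ---------------------------------------------------------------------------
# HMM chromosomes

@dataclass
class HmmChromosome:
    """Evolutionary encoding of one discrete HMM.

    ``genes`` are state identities (emission rows travel with their state);
    ``transmat`` rows follow gene order; ``marked`` flags states whose
    transition rows were disturbed by crossover (inherited into a new
    context or adopted from the other parent) and must be redrawn by
    mutation.
    """

    gene_ids: list[int]
    emission_rows: np.ndarray            # (n_states, n_symbols)
    transmat: np.ndarray                 # (n_states, n_states)
    startprob: np.ndarray
    topology_kind: str = "full"          # full | banded
    marked: set = field(default_factory=set)
    fitness: float = float("nan")

    @property
    def n_states(self) -> int:
        return len(self.gene_ids)

    def topology_mask(self) -> np.ndarray:
        n = self.n_states
        if self.topology_kind == "banded":
            # self-loop, forward neighbour, and wrap-around: a sparse
            # left-right-with-return structure
            m = np.zeros((n, n), dtype=bool)
            for i in range(n):
                m[i, i] = True
                m[i, (i + 1) % n] = True
            return m
        return np.ones((n, n), dtype=bool)

    def decode(self, n_symbols: int) -> DiscreteHMM:
        mask = self.topology_mask()
        A = np.where(mask, self.transmat, 0.0)
        s = A.sum(axis=1, keepdims=True)
        A = np.where(s > 0, A / np.maximum(s, 1e-300), mask / mask.sum(axis=1, keepdims=True))
        B = self.emission_rows / self.emission_rows.sum(axis=1, keepdims=True)
        pi = self.startprob / self.startprob.sum()
        return DiscreteHMM.from_params(pi, A, B, topology_mask=mask)

    def absorb(self, model: DiscreteHMM) -> None:
        """Write trained parameters back (Baum-Welch / PSO Lamarckism)."""
        self.transmat = model.transmat_.copy()
        self.emission_rows = model.emissionprob_.copy()
        self.startprob = model.startprob_.copy()


def _random_hmm_chromosome(n_symbols: int, cfg: GAConfig,
                           rng: np.random.Generator,
                           next_gene_id: list) -> HmmChromosome:
    n = int(rng.integers(cfg.min_states, cfg.max_states + 1))
    kind = "full" if rng.random() < 0.5 else "banded"
    ids = [next_gene_id[0] + i for i in range(n)]
    next_gene_id[0] += n
    chrom = HmmChromosome(
        gene_ids=ids,
        emission_rows=rng.random((n, n_symbols)) + 0.1,
        transmat=rng.random((n, n)) + 0.1,
        startprob=rng.random(n) + 0.1,
        topology_kind=kind,
    )
    return chrom


def mutate_hmm(chrom: HmmChromosome, rng: np.random.Generator) -> HmmChromosome:
    """Redraw the transition rows of marked (inherited/adopted) states from
    a uniform simplex restricted to the topology mask; unmarked rows are
    untouched.  Returns a new chromosome; the input is not modified."""
    new = HmmChromosome(
        gene_ids=list(chrom.gene_ids),
        emission_rows=chrom.emission_rows.copy(),
        transmat=chrom.transmat.copy(),
        startprob=chrom.startprob.copy(),
        topology_kind=chrom.topology_kind,
        marked=set(),
    )
    if not chrom.marked:
        return new
    mask = new.topology_mask()
    for i in sorted(chrom.marked):
        if i >= new.n_states:
            continue
        row = np.zeros(new.n_states)
        allowed = np.flatnonzero(mask[i])
        row[allowed] = rng.dirichlet(np.ones(len(allowed)))
        new.transmat[i] = row
    return new


def _crossover_hmm(pa: HmmChromosome, pb: HmmChromosome,
                   rng: np.random.Generator):
    """1-point crossover on state-gene lists with per-parent cut points.

    Children inherit head genes (with their emission rows and transition
    rows, truncated/renormalized to the new size) from one parent and tail
    genes from the other; every gene that arrived from the other parent or
    changed position is marked for transition-row mutation.
    """

    def cut(n):
        return int(rng.integers(1, n)) if n > 1 else 1

    ca, cb = cut(pa.n_states), cut(pb.n_states)

    def make_child(head: HmmChromosome, hc: int, tail: HmmChromosome, tc: int,
                   max_states: int) -> HmmChromosome:
        ids = head.gene_ids[:hc] + tail.gene_ids[tc:]
        ids = ids[:max_states]
        n = len(ids)
        em = np.vstack([head.emission_rows[:hc], tail.emission_rows[tc:]])[:n]
        A = rng.random((n, n)) + 0.1
        # head genes in unchanged positions keep their old rows (restricted
        # to surviving columns)
        marked = set(range(n))
        for i in range(min(hc, n)):
            old = head.transmat[i, :min(hc, n)]
            if old.sum() > 0:
                A[i, :min(hc, n)] = old
                A[i, min(hc, n):] = old.mean() if n > hc else 0.0
                marked.discard(i)
        start = np.vstack([head.startprob[:hc, None],
                           tail.startprob[tc:, None]])[:n, 0]
        return HmmChromosome(gene_ids=ids, emission_rows=em, transmat=A,
                             startprob=start, topology_kind=head.topology_kind,
                             marked=marked)

    limit = max(pa.n_states, pb.n_states)
    return (make_child(pa, ca, pb, cb, limit),
            make_child(pb, cb, pa, ca, limit))


# ---------------------------------------------------------------------------
# HMM evolution (GA-HMM / M-HMM)

class _TripleEvaluator:
    """Cached 3-way classification accuracy with one evolving class model.

    Rival class log-likelihoods are computed once; each candidate model for
    the target class only needs its own Viterbi pass.  Ties resolve by the
    priority order, target class first if it is the lesion class.
    """

    def __init__(self, eval_seqs: np.ndarray, eval_labels: np.ndarray,
                 target_class: str, rivals: dict,
                 priority: tuple[str, ...] = ("MA", "BV", "BG")):
        self.seqs = np.asarray(eval_seqs, dtype=np.intp)
        self.labels = np.asarray(eval_labels)
        self.order = [c for c in priority if c == target_class or c in rivals]
        self.target_pos = self.order.index(target_class)
        self.rival_ll = {c: m.viterbi_loglik(self.seqs) for c, m in rivals.items()}

    def accuracy(self, model: DiscreteHMM) -> float:
        cols = [model.viterbi_loglik(self.seqs) if c == self.order[self.target_pos]
                else self.rival_ll[c] for c in self.order]
        ll = np.stack(cols, axis=1)
        pred = np.asarray(self.order, dtype=object)[np.argmax(ll, axis=1)]
        return float(np.mean(pred == self.labels))


def _pso_refine(chrom: HmmChromosome, evaluator: _TripleEvaluator,
                n_symbols: int, pso: PSOConfig, rng: np.random.Generator) -> float:
    """PSO over the chromosome's transition matrix on the row-stochastic
    simplex; returns the best accuracy found and writes the best matrix
    back to the chromosome."""
    if chrom.n_states < 2:
        return evaluator.accuracy(chrom.decode(n_symbols))   # 1-state: no-op
    mask = chrom.topology_mask()

    def project(X: np.ndarray) -> np.ndarray:
        X = np.clip(X, 0.0, None)
        X = np.where(mask, X, 0.0)
        s = X.sum(axis=1, keepdims=True)
        uniform = mask / mask.sum(axis=1, keepdims=True)
        return np.where(s > 1e-12, X / np.maximum(s, 1e-12), uniform)

    def score(A: np.ndarray) -> float:
        trial = replace(chrom, transmat=A.copy())
        return evaluator.accuracy(trial.decode(n_symbols))

    base = project(chrom.transmat.copy())
    pos = [base.copy()]
    for _ in range(pso.swarm_size - 1):
        pos.append(project(base + rng.normal(0.0, 0.15, size=base.shape)))
    vel = [np.zeros_like(base) for _ in range(pso.swarm_size)]
    pbest = [p.copy() for p in pos]
    pbest_f = [score(p) for p in pos]
    g = int(np.argmax(pbest_f))
    gbest, gbest_f = pbest[g].copy(), pbest_f[g]
    for _ in range(pso.iterations):
        for i in range(pso.swarm_size):
            r1, r2 = rng.random(base.shape), rng.random(base.shape)
            vel[i] = (pso.inertia * vel[i]
                      + pso.cognitive * r1 * (pbest[i] - pos[i])
                      + pso.social * r2 * (gbest - pos[i]))
            pos[i] = project(pos[i] + vel[i])
            f = score(pos[i])
            if f > pbest_f[i]:
                pbest[i], pbest_f[i] = pos[i].copy(), f
                if f > gbest_f:
                    gbest, gbest_f = pos[i].copy(), f
    chrom.transmat = gbest
    return gbest_f


def evolve_hmm(train_seqs: np.ndarray, eval_seqs: np.ndarray,
               eval_labels: np.ndarray, rivals: dict,
               target_class: str = "MA",
               cfg: GAConfig = GAConfig(), mode: str = "GA-HMM",
               pso: PSOConfig = PSOConfig(), n_symbols: int = 16,
               log_path=None) -> DiscreteHMM:
    """Evolve the context HMM for one sub-image category.

    ``train_seqs`` are the target class's training sequences; fitness is
    the 3-way classification accuracy on ``eval_seqs``/``eval_labels`` with
    the fixed ``rivals`` models standing in for the other classes.  In
    ``M-HMM`` mode PSO refines the transition matrices of the top 20% of
    the selected individuals each generation.  Returns the best-ever
    decoded model (Baum-Welch-trained).
    """
    if mode not in ("GA-HMM", "M-HMM"):
        raise ValueError(f"unknown mode {mode!r}")
    train_seqs = np.asarray(train_seqs, dtype=np.intp)
    rng = np.random.default_rng(cfg.rng_seed)
    evaluator = _TripleEvaluator(eval_seqs, eval_labels, target_class, rivals)
    next_gene_id = [0]

    def evaluate(ch: HmmChromosome) -> HmmChromosome:
        model = ch.decode(n_symbols)
        model.n_init = 1
        model.fit(train_seqs, max_iter=cfg.bw_iterations, tol=1e-5)
        ch.absorb(model)                 # Lamarckian write-back
        ch.fitness = evaluator.accuracy(model)
        return ch

    population = [evaluate(_random_hmm_chromosome(n_symbols, cfg, rng, next_gene_id))
                  for _ in range(cfg.population_size)]
    best = max(population, key=lambda c: c.fitness)
    best_model = best.decode(n_symbols)
    best_fitness = best.fitness
    trajectory = [best_fitness]

    for gen in range(cfg.generations):
        n_sel = max(2, int(round(cfg.crossover_fraction * cfg.population_size)))
        selected = rws_select(population, n_sel, rng)
        if mode == "M-HMM":
            n_elite = max(1, int(round(pso.elite_fraction * len(selected))))
            elite_idx = sorted(range(len(selected)),
                               key=lambda i: (-selected[i].fitness, i))[:n_elite]
            for i in elite_idx:
                f = _pso_refine(selected[i], evaluator, n_symbols, pso, rng)
                selected[i].fitness = f
                if f > best_fitness:
                    best_fitness = f
                    best_model = selected[i].decode(n_symbols)
        entrants: list[HmmChromosome] = []
        for i in range(0, n_sel - 1, 2):
            pa, pb = selected[i], selected[i + 1]
            c1, c2 = _crossover_hmm(pa, pb, rng)
            c1, c2 = mutate_hmm(c1, rng), mutate_hmm(c2, rng)
            evaluate(c1)
            evaluate(c2)
            entrants.extend([c1, c2])
            worst_child = min(c1.fitness, c2.fitness)
            for p in (pa, pb):
                if p.fitness > worst_child:
                    entrants.append(p)
        order = sorted(range(len(entrants)), key=lambda i: (-entrants[i].fitness, i))
        population = [entrants[i] for i in order[:cfg.population_size]]
        while len(population) < cfg.population_size:
            population.append(evaluate(
                _random_hmm_chromosome(n_symbols, cfg, rng, next_gene_id)))
        gen_best = max(population, key=lambda c: c.fitness)
        if gen_best.fitness > best_fitness:
            best_fitness = gen_best.fitness
            best_model = gen_best.decode(n_symbols)
        trajectory.append(best_fitness)
        _log_generation(log_path, {
            "optimizer": mode.lower(), "generation": gen,
            "best_fitness": best_fitness,
            "mean_fitness": float(np.mean([c.fitness for c in population])),
        })
    best_model.best_fitness_ = best_fitness
    best_model.trajectory_ = trajectory
    return best_model


# ---------------------------------------------------------------------------
# synchronized co-evolution (C-HMM)

def joint_agreement_fitness(ens_correct: np.ndarray, y: np.ndarray,
                            hmm_says_positive: np.ndarray) -> float:
    """C-HMM pair fitness: ensemble correct AND HMM agrees with it.

    ``ens_correct`` marks items the ensemble decided correctly; the decision
    it actually made is therefore the truth where correct and its negation
    where not.  Agreement alone is not rewarded: a pair that is jointly
    wrong scores zero on that item.
    """
    ens_correct = np.asarray(ens_correct, dtype=bool)
    y = np.asarray(y, dtype=bool)
    dec = np.where(ens_correct, y, ~y)
    return float(np.mean(ens_correct & (np.asarray(hmm_says_positive, bool) == dec)))

def evolve_synchronized(pool, eval_features: np.ndarray | None, eval_seqs: np.ndarray,
                        eval_labels_binary: np.ndarray,
                        train_seqs: np.ndarray, rivals: dict,
                        cfg: GAConfig = GAConfig(), pso: PSOConfig | None = PSOConfig(),
                        n_symbols: int = 16, target_class: str = "MA",
                        log_path=None):
    """Lock-step co-evolution of an ensemble subset and the MA context HMM.

    ``eval_features``/``eval_seqs`` describe the same items (one shared
    binary label: target lesion vs not).  Joint fitness of the pair
    (ensemble chromosome i, HMM chromosome i) is the fraction of items on
    which the ensemble decision is correct AND the HMM decision agrees
    with it.  Returns ``(best EnsembleChromosome, {class: model} triple)``.
    """
    C = _correctness(pool, (eval_features, eval_labels_binary)) \
        if not isinstance(pool, np.ndarray) else pool.astype(bool)
    y = np.asarray(eval_labels_binary).astype(bool)
    n_eval = len(y)
    if C.shape[1] != n_eval or len(np.asarray(eval_seqs)) != n_eval:
        raise ValueError("ensemble and HMM evaluation item counts differ")
    rng = np.random.default_rng(cfg.rng_seed)
    n_pool = C.shape[0]
    evaluator = _TripleEvaluator(eval_seqs, np.where(y, target_class, "BG"),
                                 target_class, rivals)
    order = evaluator.order
    target_pos = evaluator.target_pos
    train_seqs = np.asarray(train_seqs, dtype=np.intp)
    next_gene_id = [0]

    def ens_decisions(ch: EnsembleChromosome) -> np.ndarray:
        votes = C[ch.member_indices].sum(axis=0)
        correct = votes * 2 > len(ch.member_indices)
        return np.where(correct, y, ~y)      # the decision actually made

    def hmm_positive(model: DiscreteHMM) -> np.ndarray:
        cols = [model.viterbi_loglik(evaluator.seqs) if i == target_pos
                else evaluator.rival_ll[order[i]] for i in range(len(order))]
        ll = np.stack(cols, axis=1)
        return np.argmax(ll, axis=1) == target_pos

    def joint_fitness(ech: EnsembleChromosome, hch: HmmChromosome) -> float:
        votes = C[ech.member_indices].sum(axis=0)
        correct = votes * 2 > len(ech.member_indices)
        return joint_agreement_fitness(correct, y,
                                       hmm_positive(hch.decode(n_symbols)))

    def train_hmm(ch: HmmChromosome) -> HmmChromosome:
        model = ch.decode(n_symbols)
        model.n_init = 1
        model.fit(train_seqs, max_iter=cfg.bw_iterations, tol=1e-5)
        ch.absorb(model)
        return ch

    ens_pop, hmm_pop = [], []
    for _ in range(cfg.population_size):
        size = int(rng.integers(1, n_pool + 1))
        ech = EnsembleChromosome(list(map(int, rng.choice(n_pool, size, replace=False))))
        hch = train_hmm(_random_hmm_chromosome(n_symbols, cfg, rng, next_gene_id))
        f = joint_fitness(ech, hch)
        ech.fitness = hch.fitness = f
        ens_pop.append(ech)
        hmm_pop.append(hch)

    best_i = max(range(cfg.population_size), key=lambda i: ens_pop[i].fitness)
    best_pair = (EnsembleChromosome(list(ens_pop[best_i].member_indices),
                                    ens_pop[best_i].fitness),
                 hmm_pop[best_i].decode(n_symbols))
    best_fitness = ens_pop[best_i].fitness
    trajectory = [best_fitness]

    for gen in range(cfg.generations):
        n_sel = max(2, int(round(cfg.crossover_fraction * cfg.population_size)))
        f = np.asarray([c.fitness for c in ens_pop])
        total = f.sum()
        p = np.full(len(f), 1.0 / len(f)) if total <= 0 else f / total
        sel_idx = rng.choice(cfg.population_size, size=n_sel, replace=True, p=p)
        if pso is not None:
            n_elite = max(1, int(round(pso.elite_fraction * n_sel)))
            elite = sorted(range(n_sel), key=lambda i: (-ens_pop[sel_idx[i]].fitness, i))[:n_elite]
            for i in elite:
                hch = hmm_pop[sel_idx[i]]
                ech = ens_pop[sel_idx[i]]
                sub_eval = _PairEvaluator(ens_decisions(ech), y, hmm_positive)
                _pso_refine_joint(hch, sub_eval, n_symbols, pso, rng)
        next_ens, next_hmm, fits = [], [], []
        for i in range(0, n_sel - 1, 2):
            ia, ib = sel_idx[i], sel_idx[i + 1]
            ec1, ec2 = crossover_1pt(ens_pop[ia], ens_pop[ib], rng)
            hc1, hc2 = _crossover_hmm(hmm_pop[ia], hmm_pop[ib], rng)
            hc1, hc2 = mutate_hmm(hc1, rng), mutate_hmm(hc2, rng)
            train_hmm(hc1)
            train_hmm(hc2)
            for ec, hc in ((ec1, hc1), (ec2, hc2)):
                fj = joint_fitness(ec, hc)
                ec.fitness = hc.fitness = fj
                next_ens.append(ec)
                next_hmm.append(hc)
                fits.append(fj)
            worst_child = min(fits[-2:])
            for ip in (ia, ib):
                if ens_pop[ip].fitness > worst_child:
                    next_ens.append(ens_pop[ip])
                    next_hmm.append(hmm_pop[ip])
                    fits.append(ens_pop[ip].fitness)
        order_idx = sorted(range(len(fits)), key=lambda i: (-fits[i], i))
        keep = order_idx[:cfg.population_size]
        ens_pop = [next_ens[i] for i in keep]
        hmm_pop = [next_hmm[i] for i in keep]
        while len(ens_pop) < cfg.population_size:
            size = int(rng.integers(1, n_pool + 1))
            ech = EnsembleChromosome(list(map(int, rng.choice(n_pool, size, replace=False))))
            hch = train_hmm(_random_hmm_chromosome(n_symbols, cfg, rng, next_gene_id))
            fj = joint_fitness(ech, hch)
            ech.fitness = hch.fitness = fj
            ens_pop.append(ech)
            hmm_pop.append(hch)
        gi = max(range(cfg.population_size), key=lambda i: ens_pop[i].fitness)
        if ens_pop[gi].fitness > best_fitness:
            best_fitness = ens_pop[gi].fitness
            best_pair = (EnsembleChromosome(list(ens_pop[gi].member_indices),
                                            ens_pop[gi].fitness),
                         hmm_pop[gi].decode(n_symbols))
        trajectory.append(best_fitness)
        _log_generation(log_path, {
            "optimizer": "c-hmm", "generation": gen, "best_fitness": best_fitness,
            "mean_fitness": float(np.mean([c.fitness for c in ens_pop])),
        })
    ens_best, ma_model = best_pair
    ens_best.trajectory = trajectory
    models = dict(rivals)
    models[target_class] = ma_model
    return ens_best, models


class _PairEvaluator:
    """Bundle of the fixed quantities PSO needs for the joint fitness."""

    def __init__(self, ens_dec, y, hmm_positive_fn):
        self.ens_dec = ens_dec
        self.y = y
        self.hmm_positive_fn = hmm_positive_fn


def _pso_refine_joint(chrom: HmmChromosome, pair_eval, n_symbols: int,
                      pso: PSOConfig, rng: np.random.Generator) -> float:
    """PSO on the joint agreement fitness (C-HMM variant)."""
    ens_dec, y, hmm_positive = pair_eval.ens_dec, pair_eval.y, pair_eval.hmm_positive_fn
    if chrom.n_states < 2:
        return float("nan")
    mask = chrom.topology_mask()

    def project(X):
        X = np.clip(X, 0.0, None)
        X = np.where(mask, X, 0.0)
        s = X.sum(axis=1, keepdims=True)
        uniform = mask / mask.sum(axis=1, keepdims=True)
        return np.where(s > 1e-12, X / np.maximum(s, 1e-12), uniform)

    def score(A):
        trial = replace(chrom, transmat=A.copy())
        agree = hmm_positive(trial.decode(n_symbols)) == ens_dec
        return float(np.mean((ens_dec == y) & agree))

    base = project(chrom.transmat.copy())
    pos = [base.copy()] + [project(base + rng.normal(0, 0.15, base.shape))
                           for _ in range(pso.swarm_size - 1)]
    vel = [np.zeros_like(base) for _ in pos]
    pbest = [p.copy() for p in pos]
    pbest_f = [score(p) for p in pos]
    g = int(np.argmax(pbest_f))
    gbest, gbest_f = pbest[g].copy(), pbest_f[g]
    for _ in range(pso.iterations):
        for i in range(len(pos)):
            r1, r2 = rng.random(base.shape), rng.random(base.shape)
            vel[i] = (pso.inertia * vel[i] + pso.cognitive * r1 * (pbest[i] - pos[i])
                      + pso.social * r2 * (gbest - pos[i]))
            pos[i] = project(pos[i] + vel[i])
            fsc = score(pos[i])
            if fsc > pbest_f[i]:
                pbest[i], pbest_f[i] = pos[i].copy(), fsc
                if fsc > gbest_f:
                    gbest, gbest_f = pos[i].copy(), fsc
    chrom.transmat = gbest
    return gbest_f


# ---------------------------------------------------------------------------
# synthetic benchmark for the GA-classifier

def make_redundancy_fixture(n_members: int = 90, n_strong: int = 5,
                            n_samples: int = 200, p_strong: float = 0.97,
                            p_noisy: float = 0.55, seed: int = 0,
                            y: np.ndarray | None = None):
    """Synthetic pool benchmark: a few strong members amid noisy ones.

    Returns ``(correctness, posteriors, y)``: member-level correctness and
    posterior matrices plus the binary truth, with members independent
    given the label.  The full-pool average rule is mediocre on it, while a
    pruned subset around the strong members is near-perfect — the shape of
    the published ensemble-pruning experiments.
    """
    rng = np.random.default_rng(seed)
    if y is None:
        y = rng.random(n_samples) < 0.5
    else:
        y = np.asarray(y).astype(bool)
        n_samples = len(y)
    p = np.full(n_members, p_noisy)
    p[:n_strong] = p_strong
    correct = rng.random((n_members, n_samples)) < p[:, None]
    conf = rng.uniform(0.6, 0.95, size=(n_members, n_samples))
    pred = np.where(correct, y[None, :], ~y[None, :])
    post = np.where(pred, conf, 1.0 - conf)
    return correct, post, y
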