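"""Elitist multi-objective genetic algorithm (NSGA-II), written from scratch.

The engine minimizes 1–3 objectives over a box-bounded real parameter
vector using fast non-dominated sorting, crowding-distance diversity
preservation, binary tournaments, simulated binary crossover (SBX) and
bounded polynomial mutation.  With a single objective it degenerates to an
elitist real-coded GA (rank = fitness order), which is how the
AP-only fitting scenario is solved.

Also provides the preferred-solution selector used for decision making on
the final Pareto front: each solution's per-objective min-max-normalized
errors are summed and the solution with the smallest (normalized) sum is
chosen.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .exceptions import ContractError
from .objectives import ObjectiveVector


@dataclass
class Individual:
    """One candidate solution: parameters, objectives, rank and crowding."""

    x: np.ndarray
    objectives: np.ndarray | None = None  # active objective values
    rank: int = 0
    crowding: float = 0.0
    meta: object = None  # e.g. the full ObjectiveVector


@dataclass
class Population:
    individuals: list[Individual]
    generation: int = 0

    def __len__(self):
        return len(self.individuals)

    def objective_matrix(self) -> np.ndarray:
        return np.array([ind.objectives for ind in self.individuals])


@dataclass
class NSGAConfig:
    """Hyperparameters (defaults: N=100, 10000 evaluations, η_c = η_m = 20)."""

    pop_size: int = 100
    max_evaluations: int = 10000
    eta_crossover: float = 20.0
    eta_mutation: float = 20.0
    crossover_prob: float = 0.9
    mutation_prob: float | None = None  # default 1/p
    seed: int = 0
    lb: np.ndarray = field(default_factory=lambda: np.zeros(1))
    ub: np.ndarray = field(default_factory=lambda: np.ones(1))

    def __post_init__(self):
        self.lb = np.asarray(self.lb, dtype=float)
        self.ub = np.asarray(self.ub, dtype=float)
        if self.lb.shape != self.ub.shape or np.any(self.lb >= self.ub):
            raise ValueError("bounds must satisfy lb < ub elementwise")
        if self.max_evaluations % self.pop_size != 0:
            raise ValueError("max_evaluations must be divisible by pop_size")
        for p in (self.crossover_prob,
                  self.mutation_prob if self.mutation_prob is not None else 0.5):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")

    @property
    def n_genes(self) -> int:
        return len(self.lb)

    @property
    def p_mut(self) -> float:
        return (self.mutation_prob if self.mutation_prob is not None
                else 1.0 / self.n_genes)


def _as_array(obj) -> np.ndarray:
    if isinstance(obj, ObjectiveVector):
        return obj.active_values()
    return np.asarray(obj, dtype=float)


def dominates(a, b) -> bool:
    """True iff ``a`` is no worse in every objective and better in at least one."""
    if isinstance(a, ObjectiveVector) and isinstance(b, ObjectiveVector):
        if a.active_mask != b.active_mask:
            raise ContractError("objective vectors have different active masks")
    va, vb = _as_array(a), _as_array(b)
    if va.shape != vb.shape:
        raise ContractError("objective vectors have different lengths")
    return bool(np.all(va <= vb) and np.any(va < vb))


def fast_nondominated_sort(population: Population | Sequence[Individual]
                           ) -> list[list[int]]:
    """Partition into Pareto fronts; sets each individual's rank (1-based)."""
    inds = population.individuals if isinstance(population, Population) \
        else list(population)
    F = np.array([ind.objectives for ind in inds], dtype=float)
    n = len(inds)
    dominated_by: list[list[int]] = [[] for _ in range(n)]
    domination_count = np.zeros(n, dtype=int)
    for i in range(n):
        # vectorized pairwise domination of i over all j
        le = np.all(F[i] <= F, axis=1)
        lt = np.any(F[i] < F, axis=1)
        dom = le & lt
        dom[i] = False
        dominated_by[i] = list(np.nonzero(dom)[0])
        domination_count += dom
    fronts: list[list[int]] = []
    current = list(np.nonzero(domination_count == 0)[0])
    rank = 1
    while current:
        for i in current:
            inds[i].rank = rank
        fronts.append(current)
        nxt = []
        for i in current:
            for j in dominated_by[i]:
                domination_count[j] -= 1
                if domination_count[j] == 0:
                    nxt.append(j)
        current = nxt
        rank += 1
    return fronts


def crowding_distance(front_objectives: np.ndarray) -> np.ndarray:
    """Crowding distances for one front's objective matrix (n, M).

    Boundary solutions of each objective get infinite distance; interior
    solutions accumulate the normalized gap between their neighbours.
    Objectives with zero span contribute nothing.
    """
    F = np.atleast_2d(np.asarray(front_objectives, dtype=float))
    n, M = F.shape
    d = np.zeros(n)
    if n <= 2:
        return np.full(n, np.inf)
    for m in range(M):
        order = np.argsort(F[:, m], kind="stable")
        span = F[order[-1], m] - F[order[0], m]
        d[order[0]] = d[order[-1]] = np.inf
        if span <= 0:
            continue
        d[order[1:-1]] += (F[order[2:], m] - F[order[:-2], m]) / span
    return d


def tournament_select(a: Individual, b: Individual,
                      rng: np.random.Generator) -> Individual:
    """Binary tournament: lower rank wins, then larger crowding, then random."""
    if a.rank != b.rank:
        return a if a.rank < b.rank else b
    if a.crowding != b.crowding:
        return a if a.crowding > b.crowding else b
    return a if rng.random() < 0.5 else b


def sbx_crossover(p1: np.ndarray, p2: np.ndarray, eta_c: float,
                  lb: np.ndarray, ub: np.ndarray, crossover_prob: float,
                  rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Simulated binary crossover with distribution index ``eta_c``.

    Before clipping, children are symmetric about the parents' mean
    (c1 + c2 = p1 + p2 per gene).
    """
    c1, c2 = p1.copy(), p2.copy()
    if rng.random() > crossover_prob:
        return c1, c2
    u = rng.random(len(p1))
    beta = np.where(u <= 0.5, (2 * u) ** (1 / (eta_c + 1)),
                    (1 / (2 * (1 - u))) ** (1 / (eta_c + 1)))
    c1 = 0.5 * ((1 + beta) * p1 + (1 - beta) * p2)
    c2 = 0.5 * ((1 - beta) * p1 + (1 + beta) * p2)
    return np.clip(c1, lb, ub), np.clip(c2, lb, ub)


def polynomial_mutation(x: np.ndarray, eta_m: float, lb: np.ndarray,
                        ub: np.ndarray, mutation_prob: float,
                        rng: np.random.Generator) -> np.ndarray:
    """Bounded polynomial mutation with distribution index ``eta_m``."""
    y = x.copy()
    span = ub - lb
    for i in range(len(y)):
        if rng.random() >= mutation_prob:
            continue
        u = rng.random()
        d1 = (y[i] - lb[i]) / span[i]
        d2 = (ub[i] - y[i]) / span[i]
        if u < 0.5:
            dq = (2 * u + (1 - 2 * u) * (1 - d1) ** (eta_m + 1)) \
                ** (1 / (eta_m + 1)) - 1
        else:
            dq = 1 - (2 * (1 - u) + 2 * (u - 0.5) * (1 - d2) ** (eta_m + 1)) \
                ** (1 / (eta_m + 1))
        y[i] += dq * span[i]
    return np.clip(y, lb, ub)


def _assign_crowding(inds: list[Individual], fronts: list[list[int]]) -> None:
    for front in fronts:
        F = np.array([inds[i].objectives for i in front])
        for i, d in zip(front, crowding_distance(F)):
            inds[i].crowding = float(d)


def _make_offspring(parents: list[Individual], config: NSGAConfig,
                    rng: np.random.Generator) -> list[np.ndarray]:
    N = config.pop_size
    offspring: list[np.ndarray] = []
    while len(offspring) < N:
        cands = [parents[i] for i in rng.integers(0, len(parents), 4)]
        w1 = tournament_select(cands[0], cands[1], rng)
        w2 = tournament_select(cands[2], cands[3], rng)
        c1, c2 = sbx_crossover(w1.x, w2.x, config.eta_crossover,
                               config.lb, config.ub, config.crossover_prob, rng)
        for c in (c1, c2):
            offspring.append(polynomial_mutation(
                c, config.eta_mutation, config.lb, config.ub,
                config.p_mut, rng))
    return offspring[:N]


def nsga2(evaluator: Callable[[np.ndarray], np.ndarray | ObjectiveVector],
          config: NSGAConfig,
          callback: Callable[[int, Population], None] | None = None
          ) -> tuple[list[Individual], list[np.ndarray]]:
    """Run the elitist evolutionary loop.

    ``evaluator(x)`` must be total (return penalty objectives rather than
    raise) and yields the active objective values for a parameter vector.
    Returns the first Pareto front of the final combined parent+offspring
    population, and a history of the per-generation best value of each
    objective.
    """
    rng = np.random.default_rng(config.seed)
    N = config.pop_size
    n_generations = config.max_evaluations // N

    def evaluate(x: np.ndarray) -> Individual:
        res = evaluator(x)
        return Individual(x=x, objectives=_as_array(res),
                          meta=res if isinstance(res, ObjectiveVector) else None)

    # Step 1: random initialization within bounds
    parents = [evaluate(config.lb + rng.random(config.n_genes) *
                        (config.ub - config.lb)) for _ in range(N)]
    fronts = fast_nondominated_sort(parents)
    _assign_crowding(parents, fronts)
    history: list[np.ndarray] = []
    combined = parents

    for gen in range(1, n_generations + 1):
        offspring = [evaluate(x) for x in _make_offspring(parents, config, rng)]
        combined = parents + offspring  # R_t, size 2N
        fronts = fast_nondominated_sort(combined)
        _assign_crowding(combined, fronts)
        # elitist survival: fill fronts in order, truncate the last by crowding
        survivors: list[Individual] = []
        for front in fronts:
            members = [combined[i] for i in front]
            if len(survivors) + len(members) <= N:
                survivors.extend(members)
            else:
                members.sort(key=lambda ind: -ind.crowding)  # stable: ties keep order
                survivors.extend(members[:N - len(survivors)])
                break
        parents = survivors
        history.append(np.min(np.array([ind.objectives for ind in combined]),
                              axis=0))
        if callback is not None:
            callback(gen, Population(parents, generation=gen))

    final_fronts = fast_nondominated_sort(combined)
    first_front = [combined[i] for i in final_fronts[0]]
    return first_front, history


def select_preferred(front_objectives: np.ndarray) -> int:
    """Index of the preferred (knee-like) solution of a Pareto front.

    For solution j, s_j = Σ_i (f_min^i - f_j^i)/(f_min^i - f_max^i); the
    selector returns argmin_j s_j / Σ_j s_j.  The global denominator is a
    positive constant and does not alter the argmin; objectives with zero
    span contribute nothing.
    """
    F = np.atleast_2d(np.asarray(front_objectives, dtype=float))
    if F.size == 0:
        raise ContractError("empty front")
    n, M = F.shape
    s = np.zeros(n)
    for m in range(M):
        fmin, fmax = F[:, m].min(), F[:, m].max()
        if fmax > fmin:
            s += (fmin - F[:, m]) / (fmin - fmax)
    total = s.sum()
    scores = s / total if total > 0 else s
    return int(np.argmin(scores))
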