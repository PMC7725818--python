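"""Mind Evolutionary Algorithm with populational-entropy search width (PEMEA).

The mind evolutionary algorithm keeps two kinds of sub-populations:
*superior* (winner) groups that exploit the best regions found so far, and
*temporary* groups that keep probing new regions.  Two operators drive it:

* **similartaxis** (convergence) — inside each sub-population, offspring are
  spawned around the winner and compete with it; the winner never gets worse.
* **dissimilation** (alienation) — globally, a temporary sub-population that
  out-scores the worst superior one takes its place, and displaced/released
  temporary groups are re-seeded uniformly in the search box.

The populational-entropy variant ties the offspring standard deviation to
the Shannon entropy of the score distribution: ``sigma^2 = H / ln M``.  A
concentrated population (low entropy) searches finely; a spread-out one
searches widely.  Here it initializes the weights of a small feedforward
network, with fitness the reciprocal of the network's mean squared error.

A plain real-coded genetic algorithm (:func:`run_ga`) is included as the
conventional baseline.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .bp_network import NetworkConfig, TrainingSample, decode, forward_batch

__all__ = [
    "Individual",
    "SubPopulation",
    "PopulationState",
    "PEMEAConfig",
    "GAConfig",
    "make_bp_scorer",
    "score",
    "init_population",
    "population_entropy",
    "sigma_from_entropy",
    "spawn_offspring",
    "similartaxis",
    "dissimilation",
    "run_pemea",
    "run_ga",
]

SCORE_EPS_GUARD = 1e-12

Scorer = Callable[[np.ndarray], float]


@dataclass
class Individual:
    genome: np.ndarray
    score: float


@dataclass
class SubPopulation:
    """One group: its members, its winner, and the winner's score history."""

    members: List[Individual]
    kind: str  # "superior" | "temporary"
    mature: bool = False
    stall: int = 0
    local_board: List[float] = field(default_factory=list)

    @property
    def winner(self) -> Individual:
        return max(self.members, key=lambda ind: ind.score)

    @property
    def score(self) -> float:
        return self.winner.score


@dataclass
class PopulationState:
    subpops: List[SubPopulation]
    generation: int = 0
    entropy: float = float("nan")
    sigma: float = float("nan")
    best_genome: Optional[np.ndarray] = None
    best_score: float = -math.inf

    @property
    def global_board(self) -> List[float]:
        """Sub-population scores, sorted descending."""
        return sorted((sp.score for sp in self.subpops), reverse=True)

    def all_scores(self) -> np.ndarray:
        return np.array([ind.score for sp in self.subpops for ind in sp.members])

    def winner_population_scores(self) -> np.ndarray:
        """Scores of the superior sub-populations' members.

        This is the evolving part of the population: temporary groups are
        re-seeded uniformly every generation, so their score spread is
        constant by construction and carries no information about how far
        convergence has progressed.
        """
        scores = np.array(
            [ind.score for sp in self.subpops if sp.kind == "superior" for ind in sp.members]
        )
        return scores if scores.size else self.all_scores()

    def _note_best(self) -> None:
        for sp in self.subpops:
            w = sp.winner
            if w.score > self.best_score:
                self.best_score = w.score
                self.best_genome = w.genome.copy()


@dataclass(frozen=True)
class PEMEAConfig:
    """PEMEA hyperparameters.

    Defaults are the reference configuration: population 200, five superior
    and five temporary sub-populations (20 members each), ten global
    iterations.  ``init_range`` is the half-width of the uniform sampling
    box for genomes; ``sigma_min`` floors the (dimensionless) search width
    so a fully concentrated population keeps exploring a little.
    """

    genome_length: int = 41
    M: int = 200
    n_superior: int = 5
    n_temporary: int = 5
    iterations: int = 10
    r_intervals: Optional[int] = None  # default ceil(sqrt(M))
    init_range: float = 0.5
    sigma_min: float = 0.01
    maturity_patience: int = 3
    max_rounds: int = 10  # similartaxis rounds per generation (maturity cap)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.M < self.n_superior + self.n_temporary:
            raise ValueError("population size smaller than number of sub-populations")
        if self.iterations < 0:
            raise ValueError("iterations must be >= 0")

    @property
    def n_subpops(self) -> int:
        return self.n_superior + self.n_temporary

    @property
    def subpop_size(self) -> int:
        return self.M // self.n_subpops

    @property
    def bins(self) -> int:
        return self.r_intervals if self.r_intervals is not None else math.ceil(
            math.sqrt(self.M)
        )


@dataclass(frozen=True)
class GAConfig:
    """Baseline real-coded GA: tournament selection, arithmetic crossover,
    Gaussian mutation, elitism of one."""

    genome_length: int = 41
    iterations: int = 200
    pop_size: int = 10
    p_crossover: float = 0.4
    p_mutation: float = 0.2
    init_range: float = 0.5
    mutation_sd: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        for p in (self.p_crossover, self.p_mutation):
            if not (0.0 <= p <= 1.0):
                raise ValueError("probabilities must lie in [0, 1]")


def make_bp_scorer(
    samples: Sequence[TrainingSample], net_config: NetworkConfig
) -> Scorer:
    """Fitness of a flat weight vector: 1 / (network MSE over samples + guard)."""
    X = np.stack([s.x for s in samples])
    D = np.stack([s.d for s in samples])

    def scorer(genome: np.ndarray) -> float:
        weights = decode(genome, net_config)
        out = forward_batch(weights, X, net_config)
        mse = float(np.mean((D - out) ** 2))
        return 1.0 / (mse + SCORE_EPS_GUARD)

    return scorer


def score(
    genome: Sequence[float],
    samples: Sequence[TrainingSample],
    net_config: NetworkConfig,
) -> float:
    """Convenience wrapper around :func:`make_bp_scorer` for one genome."""
    return make_bp_scorer(samples, net_config)(np.asarray(genome, dtype=float))


def _rng(seed_or_rng) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


def spawn_offspring(
    parent: Individual, sigma: float, seed
) -> Individual:
    """Child genome = parent + sigma * r, r i.i.d. standard normal (unscored)."""
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    rng = _rng(seed)
    child = parent.genome + sigma * rng.standard_normal(parent.genome.shape)
    return Individual(genome=child, score=float("nan"))


def population_entropy(state, r_intervals: int) -> float:
    """Shannon entropy of the score distribution over r equal-width bins.

    Scores are binned between the current minimum and maximum; the entropy
    is ``-sum p_i ln p_i`` over occupied bins.  All-equal scores occupy a
    single bin, giving zero entropy.  Given a :class:`PopulationState`, the
    scores are those of the winner (superior) population, whose
    concentration tracks convergence; an explicit score array is binned
    as given.
    """
    scores = (
        state.winner_population_scores()
        if isinstance(state, PopulationState)
        else np.asarray(state, dtype=float)
    )
    if scores.size == 0:
        raise ValueError("entropy of an empty population")
    lo, hi = float(scores.min()), float(scores.max())
    if hi == lo:
        return 0.0
    counts, _ = np.histogram(scores, bins=r_intervals, range=(lo, hi))
    p = counts[counts > 0] / scores.size
    return float(-np.sum(p * np.log(p)))


def sigma_from_entropy(H: float, M: int, config: PEMEAConfig) -> float:
    """Search width from entropy: ``sigma^2 = H / ln M``, floored and scaled.

    The dimensionless width (at most 1 when ``H <= ln M``) is floored at
    ``sigma_min`` and multiplied by ``init_range`` so that the search is
    proportional to the solution box.
    """
    if M < 2:
        raise ValueError("population size must be >= 2 for entropy scaling")
    if H < 0:
        raise ValueError("entropy must be >= 0")
    unscaled = math.sqrt(H / math.log(M))
    return max(unscaled, config.sigma_min) * config.init_range


def _fill_subpop(
    center: Individual,
    kind: str,
    sigma: float,
    scorer: Scorer,
    config: PEMEAConfig,
    rng: np.random.Generator,
) -> SubPopulation:
    members = [center]
    for _ in range(config.subpop_size - 1):
        child = spawn_offspring(center, sigma, rng)
        child.score = scorer(child.genome)
        members.append(child)
    sp = SubPopulation(members=members, kind=kind)
    sp.local_board.append(sp.score)
    return sp


def init_population(
    config: PEMEAConfig, scorer: Scorer, rng=None
) -> PopulationState:
    """Sample M genomes uniformly in the init box and form the sub-populations.

    The top ``n_superior`` scorers seed the superior sub-populations, the
    next ``n_temporary`` the temporary ones; each center's group is filled
    with normal perturbations of the center (width ``init_range``).
    """
    rng = _rng(config.seed if rng is None else rng)
    genomes = rng.uniform(
        -config.init_range, config.init_range, size=(config.M, config.genome_length)
    )
    scored = [Individual(g, scorer(g)) for g in genomes]
    scored.sort(key=lambda ind: ind.score, reverse=True)
    subpops = []
    for rank in range(config.n_subpops):
        kind = "superior" if rank < config.n_superior else "temporary"
        subpops.append(
            _fill_subpop(scored[rank], kind, config.init_range, scorer, config, rng)
        )
    state = PopulationState(subpops=subpops)
    state._note_best()
    return state


def similartaxis(
    subpop: SubPopulation,
    sigma: float,
    scorer: Scorer,
    config: PEMEAConfig,
    rng,
) -> SubPopulation:
    """One convergence round: offspring around the winner compete with it.

    The winner's score never decreases.  A sub-population matures after
    ``maturity_patience`` consecutive rounds without winner improvement;
    mature groups are left untouched.
    """
    if subpop.mature:
        return subpop
    rng = _rng(rng)
    old_winner = subpop.winner
    members = [old_winner]
    for _ in range(config.subpop_size - 1):
        child = spawn_offspring(old_winner, sigma, rng)
        child.score = scorer(child.genome)
        members.append(child)
    new = SubPopulation(
        members=members,
        kind=subpop.kind,
        stall=subpop.stall,
        local_board=list(subpop.local_board),
    )
    if new.score > old_winner.score:
        new.stall = 0
    else:
        new.stall += 1
        new.mature = new.stall >= config.maturity_patience
    new.local_board.append(new.score)
    return new


def dissimilation(
    state: PopulationState, scorer: Scorer, config: PEMEAConfig, rng
) -> PopulationState:
    """Global competition: promote winning temporaries, re-seed the rest.

    Every temporary sub-population scoring above the worst superior one
    swaps roles with it.  All sub-populations that end up temporary are then
    re-seeded uniformly in the init box, so the group counts are preserved
    and exploration continues.
    """
    rng = _rng(rng)
    state._note_best()
    for sp in state.subpops:
        if sp.kind == "temporary":
            superiors = [s for s in state.subpops if s.kind == "superior"]
            worst = min(superiors, key=lambda s: s.score)
            if sp.score > worst.score:
                sp.kind, worst.kind = "superior", "temporary"
                sp.mature = False
                sp.stall = 0
    new_subpops = []
    for sp in state.subpops:
        if sp.kind == "temporary":
            g = rng.uniform(
                -config.init_range, config.init_range, size=config.genome_length
            )
            center = Individual(g, scorer(g))
            new_subpops.append(
                _fill_subpop(center, "temporary", config.init_range, scorer, config, rng)
            )
        else:
            new_subpops.append(sp)
    state.subpops = new_subpops
    state._note_best()
    return state


def run_pemea(
    config: PEMEAConfig, scorer: Scorer
) -> Tuple[np.ndarray, pd.DataFrame]:
    """Full PEMEA loop; returns (best genome, per-generation trace).

    Each generation: estimate the winner-population entropy, derive the
    search width, run the convergence phase (similartaxis rounds repeated
    until every sub-population matures, capped at ``max_rounds``), then
    dissimilation.  The trace columns are generation, best_score, entropy
    and sigma; the best score is nondecreasing (elitism).
    """
    rng = _rng(config.seed)
    state = init_population(config, scorer, rng)
    rows = []
    for gen in range(1, config.iterations + 1):
        H = population_entropy(state, config.bins)
        sig = sigma_from_entropy(H, config.M, config)
        for sp in state.subpops:  # a new generation starts convergence afresh
            sp.mature, sp.stall = False, 0
        for _ in range(config.max_rounds):
            if all(sp.mature for sp in state.subpops):
                break
            state.subpops = [
                similartaxis(sp, sig, scorer, config, rng) for sp in state.subpops
            ]
        state = dissimilation(state, scorer, config, rng)
        state.generation = gen
        state.entropy, state.sigma = H, sig
        rows.append(
            {"generation": gen, "best_score": state.best_score, "entropy": H, "sigma": sig}
        )
    state._note_best()
    trace = pd.DataFrame(rows, columns=["generation", "best_score", "entropy", "sigma"])
    return state.best_genome, trace


def run_ga(config: GAConfig, scorer: Scorer) -> Tuple[np.ndarray, pd.DataFrame]:
    """Real-coded GA baseline; returns (best genome, per-generation trace).

    Tournament selection of size 2, arithmetic crossover with probability
    ``p_crossover``, per-gene Gaussian mutation with probability
    ``p_mutation`` (standard deviation ``mutation_sd``), elitism of one.
    """
    rng = np.random.default_rng(config.seed)
    pop = rng.uniform(
        -config.init_range, config.init_range, size=(config.pop_size, config.genome_length)
    )
    scores = np.array([scorer(g) for g in pop])
    best_idx = int(np.argmax(scores))
    best_genome, best_score = pop[best_idx].copy(), float(scores[best_idx])
    rows = [{"generation": 0, "best_score": best_score}]
    for gen in range(1, config.iterations + 1):
        new_pop = [best_genome.copy()]  # elitism
        while len(new_pop) < config.pop_size:
            # tournament selection, size 2
            parents = []
            for _ in range(2):
                i, j = rng.integers(0, config.pop_size, size=2)
                parents.append(pop[i] if scores[i] >= scores[j] else pop[j])
            p1, p2 = parents
            if rng.random() < config.p_crossover:
                lam = rng.random()
                child = lam * p1 + (1.0 - lam) * p2
            else:
                child = p1.copy()
            mask = rng.random(config.genome_length) < config.p_mutation
            child = np.where(
                mask, child + config.mutation_sd * rng.standard_normal(config.genome_length), child
            )
            new_pop.append(child)
        pop = np.stack(new_pop)
        scores = np.array([scorer(g) for g in pop])
        idx = int(np.argmax(scores))
        if scores[idx] > best_score:
            best_score = float(scores[idx])
            best_genome = pop[idx].copy()
        rows.append({"generation": gen, "best_score": best_score})
    trace = pd.DataFrame(rows, columns=["generation", "best_score"])
    return best_genome, trace
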