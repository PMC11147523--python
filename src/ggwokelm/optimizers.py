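"""Population metaheuristics: GA operators, Grey Wolf Optimization, G-GWO.

The Grey Wolf Optimizer mimics the hunting hierarchy of a wolf pack: the
three best solutions found so far (alpha, beta, delta) steer every other
wolf's next position.  Each wolf M is pulled toward each leader M_l via

    Y_l = | Q_l * M_l - M |,      M_l' = M_l - N_l * Y_l,

with coefficient vectors N = 2 a l1 - a (l1 ~ U[0,1], so N in [-a, a]) and
Q = 2 l2 (l2 ~ U[0,1], so Q in [0, 2]); the new position is the mean of the
three leader-relative candidates, clamped to the search box.  The control
parameter a decreases linearly from 2 to 0 over the run, shifting the pack
from exploration to exploitation.

G-GWO replaces GWO's uniform-random initial population with the decoded
final population of a short binary genetic algorithm (roulette selection on
rank weights, single-point crossover, uniform bit mutation, single-member
elitism), giving the pack a better-than-random starting spread.

Convention: all optimizers MINIMIZE; pass a negated objective to maximize.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np

__all__ = [
    "Chromosome",
    "WolfPack",
    "OptResult",
    "init_chromosomes",
    "roulette_select",
    "single_point_crossover",
    "uniform_mutation",
    "decode_chromosome",
    "ga_seed_positions",
    "control_parameter",
    "coefficient_vectors",
    "gwo_position_update",
    "gwo_optimize",
    "ggwo_optimize",
    "binarize_position",
    "ga_phase_evaluations",
]

Objective = Callable[[np.ndarray], float]
Bounds = Sequence[tuple[float, float]]


@dataclass
class Chromosome:
    """Fixed-length bit string; genes of ``bits_per_gene`` bits decode to
    one real coordinate each."""

    bits: np.ndarray  # 1-D uint8 array of 0/1
    bits_per_gene: int = 16

    def __post_init__(self) -> None:
        self.bits = np.asarray(self.bits, dtype=np.uint8)
        if self.bits.ndim != 1 or len(self.bits) % self.bits_per_gene != 0:
            raise ValueError(
                "chromosome length must be a positive multiple of bits_per_gene"
            )
        if not np.all((self.bits == 0) | (self.bits == 1)):
            raise ValueError("bits must be 0/1")


@dataclass
class LeaderRecord:
    position: np.ndarray
    fitness: float


@dataclass
class WolfPack:
    """Pack state: positions, fitnesses and the alpha/beta/delta leaders."""

    positions: np.ndarray
    fitnesses: np.ndarray
    alpha: LeaderRecord
    beta: LeaderRecord
    delta: LeaderRecord
    bounds: Bounds
    iteration: int = 0
    max_iter: int = 0


@dataclass
class OptResult:
    """Outcome of one optimizer run.

    ``history`` holds the best-so-far fitness after the initial evaluation
    and after each iteration; it is non-increasing by construction.
    """

    best_position: np.ndarray
    best_fitness: float
    history: list = field(default_factory=list)
    evaluations: int = 0
    seed: Optional[int] = None


# ---------------------------------------------------------------------------
# GA operators
# ---------------------------------------------------------------------------

def init_chromosomes(
    pop_size: int, n_bits: int, rng: np.random.Generator, bits_per_gene: int = 16
) -> list[Chromosome]:
    """Random initial population: every bit an independent fair coin."""
    if pop_size < 2:
        raise ValueError(f"pop_size must be >= 2, got {pop_size}")
    if n_bits < 1:
        raise ValueError(f"n_bits must be >= 1, got {n_bits}")
    return [
        Chromosome(rng.integers(0, 2, size=n_bits, dtype=np.uint8), bits_per_gene)
        for _ in range(pop_size)
    ]


def roulette_select(fitness_weights: Sequence[float], rng: np.random.Generator) -> int:
    """Roulette-wheel selection: P(i) proportional to weight i.

    Weights must be nonnegative with positive sum; minimization callers
    transform fitness into weights first (e.g. rank weights).
    """
    w = np.asarray(fitness_weights, dtype=float)
    if np.any(w < 0):
        raise ValueError("negative selection weight; transform fitnesses first")
    total = w.sum()
    if total <= 0:
        raise ValueError("selection weights sum to zero")
    return int(rng.choice(len(w), p=w / total))


def single_point_crossover(
    p1: Chromosome, p2: Chromosome, rate: float, rng: np.random.Generator
) -> tuple[Chromosome, Chromosome]:
    """With probability ``rate``, exchange suffixes at a random cut point."""
    if len(p1.bits) != len(p2.bits):
        raise ValueError("parent chromosomes differ in length")
    n = len(p1.bits)
    if rng.random() >= rate or n < 2:
        return (
            Chromosome(p1.bits.copy(), p1.bits_per_gene),
            Chromosome(p2.bits.copy(), p2.bits_per_gene),
        )
    cut = int(rng.integers(1, n))  # cut in {1, ..., n-1}
    c1 = np.concatenate([p1.bits[:cut], p2.bits[cut:]])
    c2 = np.concatenate([p2.bits[:cut], p1.bits[cut:]])
    return Chromosome(c1, p1.bits_per_gene), Chromosome(c2, p2.bits_per_gene)


def uniform_mutation(
    chrom: Chromosome, rate: float, rng: np.random.Generator
) -> Chromosome:
    """Flip each bit independently with probability ``rate``."""
    if not 0.0 <= rate <= 1.0:
        raise ValueError(f"mutation rate must be in [0,1], got {rate}")
    flips = rng.random(len(chrom.bits)) < rate
    return Chromosome(np.where(flips, 1 - chrom.bits, chrom.bits), chrom.bits_per_gene)


def decode_chromosome(chrom: Chromosome, bounds: Bounds, dims: int) -> np.ndarray:
    """Map each gene's unsigned-integer value affinely onto its bound box:
    coordinate = lo + (hi - lo) * v / (2^bits_per_gene - 1)."""
    bpg = chrom.bits_per_gene
    if len(chrom.bits) != dims * bpg:
        raise ValueError(
            f"chromosome length {len(chrom.bits)} != dims*bits_per_gene {dims * bpg}"
        )
    if len(bounds) != dims:
        raise ValueError("bounds length must equal dims")
    denom = float(2**bpg - 1)
    powers = 2 ** np.arange(bpg - 1, -1, -1, dtype=float)
    out = np.empty(dims)
    for d in range(dims):
        gene = chrom.bits[d * bpg : (d + 1) * bpg].astype(float)
        v = float(gene @ powers)
        lo, hi = bounds[d]
        out[d] = lo + (hi - lo) * v / denom
    return out


def ga_phase_evaluations(pop_size: int, generations: int) -> int:
    """Objective calls consumed by :func:`ga_seed_positions`: the initial
    population plus each offspring generation."""
    return pop_size * (generations + 1)


def ga_seed_positions(
    objective: Objective,
    bounds: Bounds,
    pop_size: int,
    generations: int,
    crossover_rate: float = 0.8,
    mutation_rate: float = 0.01,
    rng: Optional[np.random.Generator] = None,
    bits_per_gene: int = 16,
) -> np.ndarray:
    """Run a short binary GA and decode its final population into wolf
    starting positions.

    Selection uses rank-based roulette weights (best rank gets weight P,
    worst gets 1), which sidesteps negative or zero-sum raw fitnesses on a
    minimization objective.  The single best chromosome is carried over
    unchanged each generation (elitism).  ``generations=0`` returns the
    decoded random initial population, evaluating the objective once per
    member for accounting parity.
    """
    if pop_size < 3:
        raise ValueError(f"pop_size must be >= 3, got {pop_size}")
    rng = np.random.default_rng() if rng is None else rng
    dims = len(bounds)
    n_bits = dims * bits_per_gene

    pop = init_chromosomes(pop_size, n_bits, rng, bits_per_gene)
    fits = np.array(
        [objective(decode_chromosome(c, bounds, dims)) for c in pop]
    )
    for _ in range(generations):
        order = np.argsort(fits)  # ascending: best first
        ranks = np.empty(pop_size)
        ranks[order] = np.arange(pop_size, 0, -1)  # best -> weight P
        elite = pop[int(order[0])]
        children: list[Chromosome] = [Chromosome(elite.bits.copy(), bits_per_gene)]
        while len(children) < pop_size:
            i = roulette_select(ranks, rng)
            j = roulette_select(ranks, rng)
            c1, c2 = single_point_crossover(pop[i], pop[j], crossover_rate, rng)
            children.append(uniform_mutation(c1, mutation_rate, rng))
            if len(children) < pop_size:
                children.append(uniform_mutation(c2, mutation_rate, rng))
        pop = children
        fits = np.array(
            [objective(decode_chromosome(c, bounds, dims)) for c in pop]
        )
    return np.vstack([decode_chromosome(c, bounds, dims) for c in pop])


# ---------------------------------------------------------------------------
# GWO core
# ---------------------------------------------------------------------------

def control_parameter(t: int, max_iter: int) -> float:
    """Exploration parameter a = 2 (1 - t / max_iter), linear from 2 to 0."""
    if max_iter < 1:
        raise ValueError("max_iter must be >= 1")
    if not 0 <= t <= max_iter:
        raise ValueError(f"iteration {t} outside [0, {max_iter}]")
    return 2.0 * (1.0 - t / max_iter)


def coefficient_vectors(
    a: float, dims: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Draw the stochastic coefficient vectors N = 2 a l1 - a and Q = 2 l2."""
    if not 0.0 <= a <= 2.0:
        raise ValueError(f"control parameter a must be in [0,2], got {a}")
    l1 = rng.random(dims)
    l2 = rng.random(dims)
    return 2.0 * a * l1 - a, 2.0 * l2


def _clamp(x: np.ndarray, bounds: Bounds) -> np.ndarray:
    lo = np.array([b[0] for b in bounds])
    hi = np.array([b[1] for b in bounds])
    return np.clip(x, lo, hi)


def gwo_position_update(
    wolf: np.ndarray,
    leaders: tuple[np.ndarray, np.ndarray, np.ndarray],
    a: float,
    bounds: Bounds,
    rng: np.random.Generator,
) -> np.ndarray:
    """One wolf's position update from the three leaders.

    For each leader (alpha, beta, delta in that order), fresh coefficient
    vectors are drawn, the absolute distance Y = |Q * M_leader - M| is
    formed, and the candidate M_leader - N * Y is computed; the new
    position is the mean of the three candidates clamped to the box.
    """
    wolf = np.asarray(wolf, dtype=float)
    candidates = []
    for leader in leaders:
        leader = np.asarray(leader, dtype=float)
        if leader.shape != wolf.shape:
            raise ValueError("leader/wolf dimension mismatch")
        n_vec, q_vec = coefficient_vectors(a, len(wolf), rng)
        y = np.abs(q_vec * leader - wolf)
        candidates.append(leader - n_vec * y)
    new_pos = np.mean(candidates, axis=0)
    return _clamp(new_pos, bounds)


def _evaluate(objective: Objective, pos: np.ndarray) -> float:
    val = float(objective(pos))
    if not np.isfinite(val):
        raise ValueError(f"non-finite objective value {val} at position {pos}")
    return val


def gwo_optimize(
    objective: Objective,
    bounds: Bounds,
    pop_size: int = 8,
    max_iter: int = 200,
    rng: Optional[np.random.Generator] = None,
    init_positions: Optional[np.ndarray] = None,
    seed: Optional[int] = None,
    _extra_evaluations: int = 0,
) -> OptResult:
    """Canonical GWO minimization.

    Leaders are the three best positions ever evaluated (elitist), updated
    after every evaluation; every wolf moves each iteration via
    :func:`gwo_position_update`.  Total objective evaluations are exactly
    ``pop_size * (max_iter + 1)`` plus any seeding cost the caller reports.
    """
    if pop_size < 3:
        raise ValueError(f"pop_size must be >= 3, got {pop_size}")
    rng = np.random.default_rng(seed) if rng is None else rng
    dims = len(bounds)
    lo = np.array([b[0] for b in bounds])
    hi = np.array([b[1] for b in bounds])

    if init_positions is None:
        positions = lo + (hi - lo) * rng.random((pop_size, dims))
    else:
        positions = _clamp(np.array(init_positions, dtype=float), bounds)
        if positions.shape != (pop_size, dims):
            raise ValueError("init_positions shape must be (pop_size, dims)")

    fitnesses = np.array([_evaluate(objective, p) for p in positions])
    evaluations = pop_size + _extra_evaluations

    # best-ever leader board: (fitness, position), ascending
    order = np.argsort(fitnesses, kind="stable")[:3]
    board = [(fitnesses[i], positions[i].copy()) for i in order]

    def offer(fit: float, pos: np.ndarray) -> None:
        board.append((fit, pos.copy()))
        board.sort(key=lambda fp: fp[0])
        del board[3:]

    history = [board[0][0]]
    for t in range(1, max_iter + 1):
        a = control_parameter(t, max_iter)
        leaders = (board[0][1], board[1][1], board[2][1])
        for i in range(pop_size):
            positions[i] = gwo_position_update(positions[i], leaders, a, bounds, rng)
            fitnesses[i] = _evaluate(objective, positions[i])
            evaluations += 1
            offer(fitnesses[i], positions[i])
        history.append(board[0][0])

    return OptResult(
        best_position=board[0][1],
        best_fitness=board[0][0],
        history=history,
        evaluations=evaluations,
        seed=seed,
    )


def ggwo_optimize(
    objective: Objective,
    bounds: Bounds,
    pop_size: int = 8,
    max_iter: int = 200,
    ga_generations: int = 10,
    crossover_rate: float = 0.8,
    mutation_rate: float = 0.01,
    rng: Optional[np.random.Generator] = None,
    seed: Optional[int] = None,
) -> OptResult:
    """GA-seeded GWO: the genetic algorithm supplies the initial pack.

    Identical to :func:`gwo_optimize` except that the starting positions
    are :func:`ga_seed_positions`' decoded final population; the returned
    evaluation count includes the GA phase.
    """
    rng = np.random.default_rng(seed) if rng is None else rng
    init = ga_seed_positions(
        objective,
        bounds,
        pop_size=pop_size,
        generations=ga_generations,
        crossover_rate=crossover_rate,
        mutation_rate=mutation_rate,
        rng=rng,
    )
    ga_cost = ga_phase_evaluations(pop_size, ga_generations)
    return gwo_optimize(
        objective,
        bounds,
        pop_size=pop_size,
        max_iter=max_iter,
        rng=rng,
        init_positions=init,
        seed=seed,
        _extra_evaluations=ga_cost,
    )


def binarize_position(position: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Stochastic threshold: flag_j = 1 iff position_j > r_j, r_j ~ U[0,1).

    Coordinates at or above 1 always select; at or below 0 never do.  Used
    to turn a continuous wolf position over the feature box into a binary
    feature-inclusion mask.
    """
    position = np.asarray(position, dtype=float)
    r = rng.random(position.shape)
    return (position > r).astype(np.uint8)
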