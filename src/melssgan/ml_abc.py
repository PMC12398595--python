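"""Mutual-learning artificial bee colony (ML-ABC) over random-key genomes.

Classic ABC explores by perturbing one coordinate of a food source
toward or away from a random neighbour.  The mutual-learning variant
replaces that update with a directed full-vector move from the worse of
the (current, neighbour) pair toward the better one,

    v = x_worse + φ · (x_better − x_worse),   φ ~ U(0, F) per dimension,

which exchanges information bidirectionally and accelerates
convergence; F is the mutual-learning coefficient (kept moderate —
excessively large F disrupts the exploration/exploitation balance).
Employed, onlooker and scout phases otherwise follow standard ABC:
greedy acceptance with a per-source trial counter, fitness-proportional
onlooker selection, and uniform reinitialisation of sources whose trial
counter reaches ``limit``.

Fitness is maximised.  For onlooker probabilities the raw fitness is
passed through the classic ABC positivity transform (see
:func:`fitness_transform`) so that selection probabilities are
well-defined for loss-like objectives.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .random_key import Genome, SearchSpace, random_genome

__all__ = [
    "FoodSource",
    "ColonyConfig",
    "MLABCSearch",
    "fitness_transform",
    "initialize_colony",
    "mutual_candidate",
    "classic_candidate",
    "onlooker_probabilities",
    "optimize",
]


@dataclass
class FoodSource:
    """A colony member: position, fitness, failed-improvement counter."""

    position: Genome
    fitness: float
    trial: int = 0


@dataclass(frozen=True)
class ColonyConfig:
    num_bees: int = 20
    max_cycles: int = 200
    limit: int = 20
    F: float = 1.0
    seed: int = 0
    variant: str = "mutual"  # or "classic"

    def __post_init__(self):
        if self.num_bees < 2:
            raise ValueError("num_bees must be >= 2 (updates need a neighbour)")
        if self.max_cycles < 1:
            raise ValueError("max_cycles must be >= 1")
        if self.limit < 1:
            raise ValueError("limit must be >= 1")
        if self.F <= 0:
            raise ValueError("mutual-learning coefficient F must be > 0")
        if self.variant not in ("mutual", "classic"):
            raise ValueError("variant must be 'mutual' or 'classic'")


def fitness_transform(fitness: float) -> float:
    """Map a (maximised) fitness to a positive selection weight.

    Internally the negated fitness is treated as a loss f and the classic
    transform 1/(1+f) for f >= 0, 1+|f| for f < 0 is applied, so better
    sources always receive strictly larger positive weight.
    """
    f = -fitness
    return 1.0 / (1.0 + f) if f >= 0 else 1.0 + abs(f)


def _evaluate(fitness_fn, genome: Genome) -> float:
    try:
        value = float(fitness_fn(genome))
    except Exception as exc:
        raise RuntimeError(
            f"fitness function failed on genome {genome.values.tolist()}"
        ) from exc
    if not np.isfinite(value):
        raise RuntimeError(
            f"fitness function returned non-finite value on genome "
            f"{genome.values.tolist()}"
        )
    return value


def initialize_colony(space: SearchSpace, config: ColonyConfig, fitness_fn,
                      rng=None) -> list[FoodSource]:
    """Uniform placement x = x_min + rand(0,1)·(x_max − x_min) on [0,1]^D."""
    rng = np.random.default_rng(config.seed) if rng is None else rng
    colony = []
    for _ in range(config.num_bees):
        g = random_genome(space, rng)
        colony.append(FoodSource(position=g, fitness=_evaluate(fitness_fn, g)))
    return colony


def mutual_candidate(current: FoodSource, neighbor: FoodSource, F: float,
                     seed: int | None = None, rng=None,
                     dim: int | None = None) -> Genome:
    """Directed move from the worse source toward the better one.

    With ``dim=None`` every coordinate moves (φ drawn per dimension);
    with an integer ``dim`` only that coordinate is updated and the
    rest of the current position is kept — the per-dimension foraging
    rule the colony phases use.
    """
    if current is neighbor:
        raise ValueError("current and neighbor must be distinct sources")
    if F <= 0:
        raise ValueError("F must be > 0")
    rng = np.random.default_rng(seed) if rng is None else rng
    if current.fitness < neighbor.fitness:
        base, target = current.position.values, neighbor.position.values
    else:
        base, target = neighbor.position.values, current.position.values
    if dim is None:
        phi = rng.uniform(0.0, F, size=len(base))
        v = base + phi * (target - base)
    else:
        v = current.position.values.copy()
        phi = rng.uniform(0.0, F)
        v[dim] = base[dim] + phi * (target[dim] - base[dim])
    return Genome(np.clip(v, 0.0, 1.0))


def classic_candidate(current: FoodSource, neighbor: FoodSource,
                      seed: int | None = None, rng=None) -> Genome:
    """Standard ABC move: one random coordinate, φ ~ U(−1, 1)."""
    if current is neighbor:
        raise ValueError("current and neighbor must be distinct sources")
    rng = np.random.default_rng(seed) if rng is None else rng
    v = current.position.values.copy()
    j = rng.integers(len(v))
    phi = rng.uniform(-1.0, 1.0)
    v[j] = v[j] + phi * (v[j] - neighbor.position.values[j])
    return Genome(np.clip(v, 0.0, 1.0))


def onlooker_probabilities(colony: list[FoodSource]) -> np.ndarray:
    """Fitness-proportional selection probabilities p_i = fit_i / Σ fit_n."""
    fits = np.array([fitness_transform(s.fitness) for s in colony])
    if not np.isfinite(fits).all() or (fits <= 0).any():
        raise ValueError("transformed fitness must be positive and finite")
    return fits / fits.sum()


class MLABCSearch:
    """Colony optimizer; ``optimize`` runs employed → onlooker → scout cycles."""

    def __init__(self, space: SearchSpace, config: ColonyConfig):
        self.space = space
        self.config = config

    def _candidate(self, current, neighbor, rng) -> Genome:
        if self.config.variant == "mutual":
            dim = int(rng.integers(len(current.position.values)))
            return mutual_candidate(current, neighbor, self.config.F, rng=rng,
                                    dim=dim)
        return classic_candidate(current, neighbor, rng=rng)

    def _try_improve(self, colony, i, fitness_fn, rng) -> None:
        others = [k for k in range(len(colony)) if k != i]
        neighbor = colony[int(rng.choice(others))]
        candidate = self._candidate(colony[i], neighbor, rng)
        fit = _evaluate(fitness_fn, candidate)
        if fit > colony[i].fitness:
            colony[i] = FoodSource(position=candidate, fitness=fit, trial=0)
        else:
            colony[i].trial += 1

    def optimize(self, fitness_fn):
        """Returns (best FoodSource ever seen, per-cycle best-fitness history)."""
        cfg = self.config
        rng = np.random.default_rng(cfg.seed)
        colony = initialize_colony(self.space, cfg, fitness_fn, rng=rng)
        best = max(colony, key=lambda s: s.fitness)
        best = FoodSource(best.position, best.fitness, 0)
        history = []
        for _ in range(cfg.max_cycles):
            # employed phase: one update attempt per source
            for i in range(len(colony)):
                self._try_improve(colony, i, fitness_fn, rng)
            # onlooker phase: fitness-proportional re-exploration
            probs = onlooker_probabilities(colony)
            picks = rng.choice(len(colony), size=len(colony), p=probs)
            for i in picks:
                self._try_improve(colony, int(i), fitness_fn, rng)
            # scout phase: reinitialise stagnant sources
            for i, source in enumerate(colony):
                if source.trial >= cfg.limit:
                    g = random_genome(self.space, rng)
                    colony[i] = FoodSource(g, _evaluate(fitness_fn, g), 0)
            cycle_best = max(colony, key=lambda s: s.fitness)
            if cycle_best.fitness > best.fitness:
                best = FoodSource(cycle_best.position, cycle_best.fitness, 0)
            history.append(best.fitness)
        return best, history


def optimize(space: SearchSpace, config: ColonyConfig, fitness_fn):
    """Functional wrapper over :class:`MLABCSearch`."""
    return MLABCSearch(space, config).optimize(fitness_fn)
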