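"""Improved binary Grey Wolf Optimizer (IGWO) for feature-subset search.

Classic GWO moves a pack of candidate solutions ("wolves", points in
[0, 1]^d) toward the three current best solutions (alpha, beta, delta).
This variant adds four changes aimed at escaping local optima on feature
selection problems:

* **Random disturbance factor Q** — after two-thirds of the iterations each
  wolf's averaged leader step is scaled by ``Q = R * sigma + mean`` where
  ``R = sin(rand * pi * t/T)`` and sigma/mean are the standard deviation and
  mean of that wolf's own coordinates.
* **Randomized convergence factor** — ``a = 2 - rand * 2t/T`` instead of the
  deterministic linear decay, so the exploration radius shrinks on average
  but keeps random slack.
* **Oscillatory binarization** — positions become a feature mask by
  thresholding at ``r = sin(rand * pi) * exp(-t/T)``, an iteration-decaying
  random cutoff, rather than a fixed 0.5.
* **Scheduled dual-metric fitness** — ``w_f * ACC + (1 - w_f) * (1 - LEN/d)``
  with ``w_f = sin(pi/2 * t/T)``: early iterations favour small subsets,
  late iterations favour accuracy.

Random draw order per iteration (the reproducibility contract; a fixed seed
gives bit-identical runs):

1. one threshold ``r`` (1 uniform draw),
2. the convergence factor ``a`` (1 draw; skipped when ``random_a=False``),
3. per wolf, per leader (alpha, beta, delta): the ``A`` vector (d draws)
   then the ``C`` vector (d draws),
4. in the perturbation phase only: one ``R`` draw per wolf.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable

import numpy as np

__all__ = [
    "IGWOConfig",
    "WolfPack",
    "SubsetEvaluation",
    "OptimizerResult",
    "init_population",
    "convergence_factor",
    "coefficient_vectors",
    "gwo_position_update",
    "disturbance_factor",
    "position_update",
    "oscillatory_threshold",
    "binarize",
    "fitness_weight",
    "subset_fitness",
    "igwo_optimize",
]


@dataclass
class IGWOConfig:
    """Wrapper-search settings.

    ``perturbation=False`` together with ``random_a=False`` reduces the
    optimizer to vanilla GWO with the classic linear ``a`` schedule (the
    ablation baseline).
    """

    pop_size: int = 30
    max_iter: int = 100
    perturbation: bool = True
    random_a: bool = True

    def __post_init__(self) -> None:
        if self.pop_size < 3:
            raise ValueError("pop_size must be >= 3 (three leaders required)")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")


@dataclass
class SubsetEvaluation:
    """One evaluated feature mask with its scheduled fitness."""

    mask: np.ndarray
    acc: float
    w_f: float

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)

    @property
    def len(self) -> int:
        return int(self.mask.sum())

    @property
    def len_term(self) -> float:
        return 1.0 - self.len / self.mask.size

    @property
    def fitness(self) -> float:
        return self.w_f * self.acc + (1.0 - self.w_f) * self.len_term


@dataclass
class WolfPack:
    """Pack state: positions in [0,1]^d plus leader snapshots."""

    positions: np.ndarray  # (pop_size, d)
    fitness: np.ndarray | None = None
    leaders: list[tuple[np.ndarray, float]] = field(default_factory=list)  # alpha, beta, delta

    def set_leaders(self, fitness: np.ndarray) -> None:
        """Rank wolves by current fitness (descending, index tie-break)."""
        self.fitness = np.asarray(fitness, dtype=float)
        top = np.lexsort((np.arange(len(self.fitness)), -self.fitness))[:3]
        self.leaders = [(self.positions[i].copy(), float(self.fitness[i])) for i in top]


@dataclass
class OptimizerResult:
    """Outcome of one optimizer run."""

    mask: np.ndarray            # best-so-far feature mask
    fitness: float              # its scheduled fitness when recorded
    acc: float                  # its accuracy when recorded
    iteration: int              # iteration at which it was recorded
    history: list[dict]         # per-iteration {t, a, r, best_fitness}
    n_evaluations: int


# ---------------------------------------------------------------------------
# Primitive operations
# ---------------------------------------------------------------------------

def init_population(pop_size: int, d: int, rng: np.random.Generator) -> np.ndarray:
    """Uniform i.i.d. positions in [0, 1]^d, one row per wolf."""
    if pop_size < 3:
        raise ValueError("pop_size must be >= 3")
    if d < 1:
        raise ValueError("dimension must be >= 1")
    return rng.random((pop_size, d))


def convergence_factor(t: int, T: int, rng: np.random.Generator) -> float:
    """Randomized convergence factor a = 2 - rand * 2t/T, in [2 - 2t/T, 2]."""
    if T <= 0:
        raise ValueError("T must be positive")
    if not 0 <= t <= T:
        raise ValueError(f"iteration t={t} outside [0, {T}]")
    return 2.0 - rng.random() * t * 2.0 / T


def coefficient_vectors(a: float, d: int,
                        rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Per-coordinate coefficient vectors A = 2a*r1 - a and C = 2*r2."""
    A = 2.0 * a * rng.random(d) - a
    C = 2.0 * rng.random(d)
    return A, C


def gwo_position_update(pack: WolfPack, a: float,
                        rng: np.random.Generator) -> np.ndarray:
    """Classic three-leader position update, clamped to [0, 1].

    For each wolf and each leader L: ``D_L = |C_L * X_L - X|`` and
    ``X_L' = X_L - A_L * D_L`` with fresh per-coordinate A, C vectors; the
    new position is the mean of the three leader-guided points.
    """
    if len(pack.leaders) != 3:
        raise ValueError("leaders are unset; evaluate the pack first")
    pop, d = pack.positions.shape
    out = np.empty_like(pack.positions)
    for i in range(pop):
        x = pack.positions[i]
        acc = np.zeros(d)
        for lead_pos, _ in pack.leaders:
            A, C = coefficient_vectors(a, d, rng)
            D = np.abs(C * lead_pos - x)
            acc += lead_pos - A * D
        out[i] = acc / 3.0
    return np.clip(out, 0.0, 1.0)


def disturbance_factor(wolf_position: np.ndarray, t: int, T: int,
                       rng: np.random.Generator) -> tuple[float, float, float, float]:
    """Per-wolf disturbance scalar Q = R*sigma + mean.

    ``R = sin(rand * pi * t/T)`` (0 at t=0), sigma is the population
    standard deviation (1/s normalization) of the wolf's own coordinates
    and mean their average.  Returns ``(Q, R, sigma, mean)``.
    """
    wolf_position = np.asarray(wolf_position, dtype=float)
    if wolf_position.size == 0:
        raise ValueError("empty position vector")
    if not 0 <= t <= T:
        raise ValueError(f"iteration t={t} outside [0, {T}]")
    R = math.sin(rng.random() * math.pi * t / T)
    sigma = float(wolf_position.std())
    mean = float(wolf_position.mean())
    return R * sigma + mean, R, sigma, mean


def position_update(pack: WolfPack, t: int, T: int, rng: np.random.Generator, *,
                    a: float, perturbation: bool = True) -> np.ndarray:
    """Full IGWO position update for one iteration.

    In the late phase (``t > floor(2T/3)``, when ``perturbation`` is on) the
    averaged leader step of each wolf is scaled by its disturbance factor Q
    before clamping.
    """
    candidate = gwo_position_update(pack, a, rng)
    if perturbation and t > (2 * T) // 3:
        q = np.empty(len(candidate))
        for i in range(len(candidate)):
            q[i], *_ = disturbance_factor(pack.positions[i], t, T, rng)
        candidate = np.clip(candidate * q[:, None], 0.0, 1.0)
    return candidate


def oscillatory_threshold(t: int, T: int, rng: np.random.Generator) -> float:
    """Iteration-decaying random binarization cutoff r = sin(rand*pi) * e^(-t/T)."""
    if not 0 <= t <= T:
        raise ValueError(f"iteration t={t} outside [0, {T}]")
    return math.sin(rng.random() * math.pi) * math.exp(-t / T)


def binarize(position: np.ndarray, r: float) -> np.ndarray:
    """Mask_j = position_j > r; an empty mask falls back to the largest coordinate.

    The fallback (lowest index on ties) guarantees every evaluation sees at
    least one selected feature.
    """
    if r < 0:
        raise ValueError("threshold must be nonnegative")
    position = np.asarray(position, dtype=float)
    mask = position > r
    if not mask.any():
        mask[int(np.argmax(position))] = True
    return mask


def fitness_weight(t: int, T: int) -> float:
    """Accuracy weight w_f = sin(pi/2 * t/T): 0 at the start, 1 at the end."""
    if not 0 <= t <= T:
        raise ValueError(f"iteration t={t} outside [0, {T}]")
    return math.sin(math.pi / 2.0 * t / T)


def subset_fitness(acc: float, length: int, d: int, t: int, T: int) -> float:
    """Scheduled fitness w_f*ACC + (1-w_f)*(1 - LEN/d), in [0, 1].

    The length term is normalized and inverted so smaller subsets score
    higher; at t=T the fitness equals the accuracy alone.
    """
    if not 0.0 <= acc <= 1.0:
        raise ValueError("accuracy must be in [0, 1]")
    if not 1 <= length <= d:
        raise ValueError(f"subset length must be in [1, {d}]")
    w = fitness_weight(t, T)
    return w * acc + (1.0 - w) * (1.0 - length / d)


# ---------------------------------------------------------------------------
# Main loop
# ---------------------------------------------------------------------------

def igwo_optimize(d: int, evaluator: Callable[[np.ndarray], float],
                  config: IGWOConfig, rng: np.random.Generator) -> OptimizerResult:
    """Run the improved GWO over binary masks of ``d`` features.

    ``evaluator`` maps a boolean mask (with at least one True) to a
    classification accuracy in [0, 1].  Identical masks are evaluated once
    per run (cached); leaders are re-ranked every iteration by the current
    scheduled fitness while the best (mask, fitness) ever seen is recorded
    separately and returned.
    """
    if d < 1:
        raise ValueError("need at least one feature")
    T = config.max_iter
    positions = init_population(config.pop_size, d, rng)
    pack = WolfPack(positions)

    cache: dict[bytes, float] = {}
    n_evaluations = 0

    def accuracy(mask: np.ndarray) -> float:
        nonlocal n_evaluations
        key = np.packbits(mask).tobytes()
        if key not in cache:
            try:
                value = float(evaluator(mask))
            except Exception as exc:
                raise RuntimeError(
                    f"subset evaluator failed on a {int(mask.sum())}-feature mask") from exc
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"evaluator returned {value}, expected [0, 1]")
            cache[key] = value
            n_evaluations += 1
        return cache[key]

    best_mask: np.ndarray | None = None
    best_fitness = -np.inf
    best_acc = 0.0
    best_iter = 0
    history: list[dict] = []

    for t in range(T):
        r = oscillatory_threshold(t, T, rng)
        fitness = np.empty(config.pop_size)
        for i in range(config.pop_size):
            mask = binarize(pack.positions[i], r)
            acc = accuracy(mask)
            fitness[i] = subset_fitness(acc, int(mask.sum()), d, t, T)
            if fitness[i] > best_fitness:
                best_fitness = float(fitness[i])
                best_mask = mask.copy()
                best_acc = acc
                best_iter = t
        pack.set_leaders(fitness)

        if config.random_a:
            a = convergence_factor(t, T, rng)
        else:
            a = 2.0 * (1.0 - t / T)  # classic linear decay
        pack.positions = position_update(pack, t, T, rng, a=a,
                                         perturbation=config.perturbation)
        history.append({"t": t, "a": a, "r": r, "best_fitness": best_fitness})

    assert best_mask is not None
    return OptimizerResult(best_mask, best_fitness, best_acc, best_iter,
                           history, n_evaluations)
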