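"""Genetic-algorithm search over binary DMD masks.

Maximizes the correlation-gated photoacoustic fitness (average accepted
peak-to-peak over five acquisitions per mask). Defaults follow the
experiment: 80 generations of 50 masks, initial population of Bernoulli(½)
random masks, descending fitness ranking, rank-weighted parent selection,
uniform crossover and per-bit mutation, with a small elite copied
unchanged so the best-so-far fitness cannot regress in a noise-free world.

Identical masks are re-measured rather than cached: in the physical
experiment every evaluation is a fresh set of noisy acquisitions.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Callable, List, Optional, Sequence, Tuple

import numpy as np
from scipy.stats import rankdata

from .forward_sim import Mask, World, unit_pulse, _derive_seed
from .correlation_gate import Template, fitness_single, fitness_two_point
from .wavelet_denoise import WaveletConfig

__all__ = [
    "GAConfig",
    "GenerationRecord",
    "OptimizationHistory",
    "init_population",
    "selection_weights",
    "step",
    "run",
    "noiseless_fitness",
    "noiseless_fitness_components",
    "random_mask_baseline",
    "exhaustive_optimum",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GAConfig:
    """Genetic-algorithm settings (defaults follow the closed-loop experiment)."""

    population: int = 50
    generations: int = 80
    crossover_rate: float = 0.9
    mutation_rate: float = 0.005
    elitism: int = 2
    seed: int = 0
    selection: str = "rank"
    n_acq: int = 5

    def __post_init__(self) -> None:
        if self.population < 2:
            raise ValueError("population must be at least 2")
        if self.generations < 1:
            raise ValueError("need at least one generation")
        for name in ("crossover_rate", "mutation_rate"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if not 0 <= self.elitism < self.population:
            raise ValueError("elitism must be smaller than the population")
        if self.selection not in ("rank", "tournament"):
            raise ValueError("selection must be 'rank' or 'tournament'")
        if self.n_acq < 1:
            raise ValueError("need at least one acquisition per mask")


@dataclass(frozen=True)
class GenerationRecord:
    """Per-generation fitness statistics."""

    generation: int
    mean_fitness: float
    best_fitness: float
    best_mask: Mask


@dataclass
class OptimizationHistory:
    """The optimizer's report: per-generation statistics and the best mask."""

    records: List[GenerationRecord] = field(default_factory=list)

    @property
    def mean_fitness(self) -> np.ndarray:
        return np.array([r.mean_fitness for r in self.records])

    @property
    def best_fitness(self) -> np.ndarray:
        return np.array([r.best_fitness for r in self.records])

    @property
    def best_record(self) -> GenerationRecord:
        return max(self.records, key=lambda r: r.best_fitness)

    @property
    def best_mask(self) -> Mask:
        """Best mask observed over the whole run."""
        return self.best_record.best_mask

    @property
    def best_overall_fitness(self) -> float:
        return self.best_record.best_fitness


def init_population(cfg: GAConfig, n_segments: int) -> List[Mask]:
    """cfg.population random masks with i.i.d. Bernoulli(1/2) bits."""
    rng = np.random.default_rng(cfg.seed)
    return [Mask.random(n_segments, rng) for _ in range(cfg.population)]


def selection_weights(fitnesses: np.ndarray) -> np.ndarray:
    """Linear rank-proportional selection probabilities (descending order).

    Ties share the mean weight of their rank range, so equal fitnesses get
    exactly equal selection probability.
    """
    fitnesses = np.asarray(fitnesses, dtype=float)
    p = fitnesses.size
    # rankdata is ascending; best fitness should carry the largest weight
    ranks = rankdata(fitnesses, method="average")
    weights = ranks  # weight p for the best, 1 for the worst, ties averaged
    return weights / weights.sum()


def step(
    population: Sequence[Mask],
    fitnesses: Sequence[float],
    cfg: GAConfig,
    rng: Optional[np.random.Generator] = None,
) -> List[Mask]:
    """Produce the next generation.

    Sorts by descending fitness, copies the ``cfg.elitism`` best masks
    unchanged, then fills the population with children of rank-weighted
    parent pairs via uniform crossover (rate ``crossover_rate``) and
    per-bit mutation (rate ``mutation_rate``).
    """
    population = list(population)
    fitnesses = np.asarray(fitnesses, dtype=float)
    if len(population) != fitnesses.size:
        raise ValueError("one fitness per mask required")
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    order = np.argsort(-fitnesses, kind="stable")
    ranked = [population[i] for i in order]
    nxt: List[Mask] = [Mask(m.bits.copy()) for m in ranked[: cfg.elitism]]

    if cfg.selection == "rank":
        probs = selection_weights(fitnesses)
        pick = lambda: population[int(rng.choice(len(population), p=probs))]
    else:  # tournament of 2

        def pick() -> Mask:
            i, j = rng.integers(0, len(population), size=2)
            return population[i] if fitnesses[i] >= fitnesses[j] else population[j]

    n_bits = len(population[0])
    while len(nxt) < cfg.population:
        p1, p2 = pick(), pick()
        if rng.random() < cfg.crossover_rate:
            take = rng.integers(0, 2, size=n_bits).astype(bool)
            child = np.where(take, p1.bits, p2.bits)
        else:
            child = p1.bits.copy()
        if cfg.mutation_rate > 0:
            flips = rng.random(n_bits) < cfg.mutation_rate
            child = child ^ flips
        nxt.append(Mask(child.astype(np.uint8)))
    return nxt


def run(
    world: World,
    template,
    cfg: GAConfig,
    wavelet_cfg: WaveletConfig = WaveletConfig(),
    callback: Optional[Callable[[GenerationRecord], None]] = None,
    on_detection: Optional[Callable[[int, int, int, object], None]] = None,
):
    """The closed optimization loop.

    Executes ``generations × population`` fitness evaluations, each being
    ``cfg.n_acq`` acquisitions through the wavelet-denoising correlation
    gate; the template adapts along the way (each accepted shot replaces
    it). Fully reproducible given the world, template and config seeds.

    ``template`` is a single :class:`Template` for one absorber or a pair
    of templates with disjoint gates for the two-point experiment, where
    the fitness is √(P₁·P₂). ``on_detection(generation, individual, shot,
    result)`` logs every acquisition. Returns the history and the final
    template(s).
    """
    two_point = isinstance(template, (list, tuple))
    if two_point:
        template = tuple(template)
    rng = np.random.default_rng(_derive_seed(cfg.seed, 101))
    population = init_population(cfg, world.n_segments)
    history = OptimizationHistory()
    for g in range(cfg.generations):
        fitnesses = np.empty(cfg.population)
        for i, mask in enumerate(population):
            seed = _derive_seed(cfg.seed, g, i)
            if two_point:
                fit, template, _ = fitness_two_point(
                    mask, world, template, n_acq=cfg.n_acq, seed=seed, cfg=wavelet_cfg
                )
                fitnesses[i] = fit
            else:
                outcome = fitness_single(
                    mask, world, template, n_acq=cfg.n_acq, seed=seed, cfg=wavelet_cfg
                )
                fitnesses[i] = outcome.fitness
                template = outcome.template
                if on_detection is not None:
                    for s, res in enumerate(outcome.detections):
                        on_detection(g, i, s, res)
        best_i = int(np.argmax(fitnesses))
        record = GenerationRecord(
            generation=g,
            mean_fitness=float(fitnesses.mean()),
            best_fitness=float(fitnesses[best_i]),
            best_mask=population[best_i],
        )
        history.records.append(record)
        if callback is not None:
            callback(record)
        if g + 1 < cfg.generations:
            population = step(population, fitnesses, cfg, rng)
    return history, template


# --------------------------------------------------------------------------
# Noise-free references
# --------------------------------------------------------------------------


def noiseless_fitness_components(mask: Mask, world: World) -> Tuple[float, ...]:
    """Per-absorber noise-free gated peak-to-peak values of a mask."""
    out = []
    for i, absorber in enumerate(world.absorbers):
        rows = world.tm.entries[world.mode_rows(i)]
        intensity = float((np.abs(rows @ mask.bits.astype(float)) ** 2).sum())
        amp = (
            world.sensitivity(i) * absorber.grueneisen * absorber.mu_a * intensity
        )
        pulse = unit_pulse(
            absorber, world.transducer, world.c_s, world.dt, world.n_samples
        )
        out.append(amp * float(pulse.max() - pulse.min()))
    return tuple(out)


def noiseless_fitness(mask: Mask, world: World) -> float:
    """Noise-free peak-to-peak fitness of a mask (the physical objective).

    Summed over absorbers; each term scales with that absorber's summed
    speckle intensity.
    """
    return float(sum(noiseless_fitness_components(mask, world)))


def random_mask_baseline(world: World, n: int = 100, seed: int = 12345) -> float:
    """Mean noise-free fitness of ``n`` fresh Bernoulli(1/2) random masks."""
    rng = np.random.default_rng(seed)
    vals = [
        noiseless_fitness(Mask.random(world.n_segments, rng), world) for _ in range(n)
    ]
    return float(np.mean(vals))


def exhaustive_optimum(world: World) -> Tuple[Mask, float]:
    """Brute-force best mask by noise-free fitness; tractable for N ≲ 20."""
    n = world.n_segments
    if n > 20:
        raise ValueError("exhaustive search is limited to 20 segments")
    best_mask, best_val = None, -np.inf
    for bits in itertools.product((0, 1), repeat=n):
        mask = Mask(np.array(bits, dtype=np.uint8))
        val = noiseless_fitness(mask, world)
        if val > best_val:
            best_mask, best_val = mask, val
    return best_mask, best_val
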