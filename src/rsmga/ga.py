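"""Binary-coded genetic algorithm for box-constrained surface maximization.

Each candidate is a fixed-length bitstring: ``bits_per_variable`` bits per
decision variable, decoded to real values by linear mapping of the unsigned
integer value of each slice onto the variable's [low, high] interval.  The
GA is generational with tournament selection, uniform crossover and bitwise
mutation; maximization is posed as minimization of a duality-transformed
fitness (negation by default).

For quadratic objectives a deterministic certificate is available:
:func:`certified_box_max` enumerates the stationary points of every face of
the box (all 3^k active-constraint patterns) and returns the exact
constrained maximum, which upper-bounds any GA run on the same surface.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .doe import FactorSpace
from .rsm import QuadraticSurface

__all__ = [
    "GAConfig",
    "GAResult",
    "SweepSpec",
    "decode_chromosome",
    "objective_transform",
    "tournament_select",
    "uniform_crossover",
    "bitwise_mutate",
    "evolve",
    "surface_objective",
    "certified_box_max",
    "grid_oracle_max",
    "parametric_sweep",
]


@dataclass(frozen=True)
class GAConfig:
    """GA operator settings; defaults are the study's final tuned values."""

    bounds: tuple[tuple[float, float], ...]
    bits_per_variable: int = 10
    population_size: int = 210
    max_generations: int = 815
    crossover_prob: float = 0.5
    mutation_prob: float = 0.0015
    tournament_size: int = 2
    seed: int = 0
    elitism: bool = True
    transform: str = "negate"  # duality transform: "negate" or "inverse"
    per_bit_crossover: bool = False  # True: every pair mixed, rate = Pc per bit

    def __post_init__(self) -> None:
        if len(self.bounds) < 1:
            raise ValueError("at least one decision variable required")
        for lo, hi in self.bounds:
            if not hi > lo:
                raise ValueError(f"invalid bounds ({lo}, {hi})")
        if self.bits_per_variable < 1:
            raise ValueError("bits_per_variable must be >= 1")
        if self.population_size < 2:
            raise ValueError("population_size must be >= 2")
        if self.max_generations < 1:
            raise ValueError("max_generations must be >= 1")
        if not 0.0 <= self.crossover_prob <= 1.0:
            raise ValueError("crossover_prob must be in [0, 1]")
        if not 0.0 <= self.mutation_prob <= 1.0:
            raise ValueError("mutation_prob must be in [0, 1]")
        if self.tournament_size < 1:
            raise ValueError("tournament_size must be >= 1")
        if self.transform not in ("negate", "inverse"):
            raise ValueError("transform must be 'negate' or 'inverse'")

    @property
    def n_variables(self) -> int:
        return len(self.bounds)

    @property
    def chromosome_length(self) -> int:
        return self.bits_per_variable * self.n_variables

    @classmethod
    def for_space(cls, space: FactorSpace, **kwargs) -> "GAConfig":
        """Configuration searching a factor space's natural-unit box."""
        return cls(bounds=tuple((f.low, f.high) for f in space.factors), **kwargs)


def decode_chromosome(bits: np.ndarray, config: GAConfig) -> np.ndarray:
    """Decode bitstring(s) to natural-unit vectors by linear mapping.

    Each variable's slice (most-significant bit first) with integer value v
    maps to ``low + (high - low) * v / (2^bits - 1)``; accepts shape (L,) or
    (n, L) and returns (k,) or (n, k) accordingly.
    """
    bits = np.asarray(bits)
    scalar = bits.ndim == 1
    pop = np.atleast_2d(bits)
    if pop.shape[1] != config.chromosome_length:
        raise ValueError(
            f"chromosome length {pop.shape[1]} != "
            f"{config.n_variables} x {config.bits_per_variable}"
        )
    b = config.bits_per_variable
    weights = 2 ** np.arange(b - 1, -1, -1, dtype=np.int64)
    ints = pop.reshape(len(pop), config.n_variables, b) @ weights
    lows = np.array([lo for lo, _ in config.bounds])
    highs = np.array([hi for _, hi in config.bounds])
    out = lows + (highs - lows) * ints / (2.0**b - 1.0)
    return out[0] if scalar else out


def objective_transform(value, mode: str = "negate"):
    """Duality transform turning maximization into minimization.

    Both modes are strictly decreasing in ``value``, so the fitness argmin
    coincides with the objective argmax.
    """
    value = np.asarray(value, dtype=float)
    if mode == "negate":
        out = -value
    elif mode == "inverse":
        if np.any(1.0 + value <= 0):
            raise ValueError("inverse transform needs 1 + value > 0")
        out = 1.0 / (1.0 + value)
    else:
        raise ValueError(f"unknown transform {mode!r}")
    return float(out) if out.ndim == 0 else out


def tournament_select(
    population: np.ndarray,
    fitnesses: np.ndarray,
    size: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Return one parent: best (lowest fitness) of `size` uniform draws.

    Draws are with replacement; ties go to the first-drawn competitor.
    """
    population = np.asarray(population)
    if len(population) == 0:
        raise ValueError("population is empty")
    draws = rng.integers(0, len(population), size=size)
    winner = draws[np.argmin(np.asarray(fitnesses)[draws])]
    return population[winner]


def uniform_crossover(
    parent_a: np.ndarray,
    parent_b: np.ndarray,
    pc: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Uniform crossover: with probability ``pc`` swap each bit independently
    (probability 1/2 per position) between the two children; otherwise the
    children are copies of the parents."""
    a = np.asarray(parent_a).copy()
    b = np.asarray(parent_b).copy()
    if a.shape != b.shape:
        raise ValueError("parents must have equal length")
    if rng.random() < pc:
        swap = rng.random(a.shape) < 0.5
        a[swap], b[swap] = b[swap].copy(), a[swap].copy()
    return a, b


def bitwise_mutate(bits: np.ndarray, pm: float, rng: np.random.Generator) -> np.ndarray:
    """Flip each bit independently with probability ``pm``."""
    bits = np.asarray(bits)
    flips = rng.random(bits.shape) < pm
    return bits ^ flips.astype(bits.dtype)


@dataclass
class GAResult:
    best_bits: np.ndarray = field(repr=False)
    best_decoded: np.ndarray
    best_objective: float
    history: pd.DataFrame = field(repr=False)  # generation, best, mean
    evaluations: int
    config: GAConfig = field(repr=False)


def surface_objective(
    surface: QuadraticSurface, space: FactorSpace
) -> Callable[[np.ndarray], np.ndarray]:
    """Objective mapping natural-unit points to predicted response.

    The GA searches the natural-unit box; the surface is expressed in coded
    units, so points are coded through ``space`` before evaluation.
    """

    def objective(natural: np.ndarray) -> np.ndarray:
        return np.atleast_1d(surface.predict(space.code(natural)))

    return objective


def evolve(
    config: GAConfig,
    objective: Callable[[np.ndarray], np.ndarray] | QuadraticSurface,
    space: FactorSpace | None = None,
) -> GAResult:
    """Run the generational GA and return the best-ever individual.

    ``objective`` is a vectorized callable taking an (n, k) array of
    natural-unit points and returning n objective values (to be maximized);
    passing a :class:`QuadraticSurface` together with ``space`` wraps it via
    :func:`surface_objective`.  Runs are bit-reproducible for a fixed config.
    """
    if isinstance(objective, QuadraticSurface):
        if space is None:
            raise ValueError("a FactorSpace is required to evaluate a surface")
        objective = surface_objective(objective, space)
    rng = np.random.default_rng(config.seed)
    P, L = config.population_size, config.chromosome_length
    pop = rng.integers(0, 2, size=(P, L), dtype=np.uint8)

    def evaluate(p: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        vals = np.asarray(objective(decode_chromosome(p, config)), dtype=float)
        return vals, objective_transform(vals, config.transform)

    vals, fit = evaluate(pop)
    best_i = int(np.argmin(fit))
    best_bits, best_val = pop[best_i].copy(), float(vals[best_i])
    history = [(0, float(vals.max()), float(vals.mean()))]
    evaluations = P

    for gen in range(1, config.max_generations + 1):
        # selection: one tournament per offspring slot, ties to first-drawn
        draws = rng.integers(0, P, size=(P, config.tournament_size))
        winners = draws[np.arange(P), np.argmin(fit[draws], axis=1)]
        children = pop[winners].copy()
        # pairwise uniform crossover
        n_pairs = P // 2
        if config.per_bit_crossover:
            swap = rng.random((n_pairs, L)) < config.crossover_prob
        else:
            crossed = rng.random(n_pairs) < config.crossover_prob
            swap = (rng.random((n_pairs, L)) < 0.5) & crossed[:, None]
        a, b = children[0 : 2 * n_pairs : 2], children[1 : 2 * n_pairs : 2]
        a_sw = np.where(swap, b, a)
        b_sw = np.where(swap, a, b)
        children[0 : 2 * n_pairs : 2] = a_sw
        children[1 : 2 * n_pairs : 2] = b_sw
        # bitwise mutation
        flips = rng.random((P, L)) < config.mutation_prob
        children ^= flips.astype(np.uint8)
        if config.elitism:
            children[0] = best_bits
        pop = children
        vals, fit = evaluate(pop)
        evaluations += P
        gen_best = int(np.argmin(fit))
        if float(vals[gen_best]) > best_val:
            best_val = float(vals[gen_best])
            best_bits = pop[gen_best].copy()
        history.append((gen, float(vals.max()), float(vals.mean())))

    return GAResult(
        best_bits=best_bits,
        best_decoded=decode_chromosome(best_bits, config),
        best_objective=best_val,
        history=pd.DataFrame(history, columns=["generation", "best", "mean"]),
        evaluations=evaluations,
        config=config,
    )


def certified_box_max(
    surface: QuadraticSurface, bounds: tuple[float, float] = (-1.0, 1.0)
) -> tuple[np.ndarray, float]:
    """Exact maximum of a quadratic over the coded box, by face enumeration.

    The maximum of a quadratic over a box is attained at a stationary point
    of the restriction to some face.  Every face corresponds to a pattern in
    {low, high, free}^k; for each of the 3^k patterns the free coordinates
    solve the reduced linear stationarity system, and patterns whose solution
    leaves the box (or is singular) are discarded.  Returns the certified
    argmax (coded units) and maximum value.
    """
    k = surface.k
    A = np.diag(np.asarray(surface.square, dtype=float))
    for (i, j), c in surface.interaction.items():
        A[i, j] = A[j, i] = c / 2.0
    b = np.asarray(surface.linear, dtype=float)
    lo, hi = bounds
    best_val, best_pt = -np.inf, None
    for pattern in itertools.product((lo, hi, None), repeat=k):
        free = [i for i, p in enumerate(pattern) if p is None]
        x = np.array([0.0 if p is None else p for p in pattern])
        if free:
            fixed = [i for i in range(k) if i not in free]
            Aff = 2.0 * A[np.ix_(free, free)]
            rhs = -b[free]
            if fixed:
                rhs = rhs - 2.0 * A[np.ix_(free, fixed)] @ x[fixed]
            try:
                xf = np.linalg.solve(Aff, rhs)
            except np.linalg.LinAlgError:
                continue
            if np.any(xf < lo - 1e-12) or np.any(xf > hi + 1e-12):
                continue
            x[free] = np.clip(xf, lo, hi)
        val = float(surface.predict(x))
        if val > best_val:
            best_val, best_pt = val, x
    return best_pt, best_val


def grid_oracle_max(
    surface: QuadraticSurface, resolution: int = 11
) -> tuple[np.ndarray, float]:
    """Approximate box maximum by exhaustive grid search with one refinement.

    Evaluates a uniform ``resolution^k`` grid on the coded box, then a second
    grid of the same resolution over the cell neighbourhood of the best
    point.  Slower and coarser than :func:`certified_box_max`; useful as an
    assumption-free cross-check.
    """
    if resolution < 2:
        raise ValueError("resolution must be >= 2")
    k = surface.k

    def search(lows: np.ndarray, highs: np.ndarray) -> tuple[np.ndarray, float]:
        axes = [np.linspace(lo, hi, resolution) for lo, hi in zip(lows, highs)]
        mesh = np.meshgrid(*axes, indexing="ij")
        pts = np.column_stack([m.ravel() for m in mesh])
        vals = surface.predict(pts)
        i = int(np.argmax(vals))
        return pts[i], float(vals[i])

    lows, highs = np.full(k, -1.0), np.full(k, 1.0)
    pt, _ = search(lows, highs)
    step = 2.0 / (resolution - 1)
    lows2 = np.clip(pt - step, -1.0, 1.0)
    highs2 = np.clip(pt + step, -1.0, 1.0)
    return search(lows2, highs2)


@dataclass(frozen=True)
class SweepSpec:
    """Parametric study: vary one GA parameter, replicate runs per value."""

    parameter: str  # mutation_prob | population_size | max_generations
    values: tuple
    replicates: int
    base_config: GAConfig

    _VALID = ("mutation_prob", "population_size", "max_generations")

    def __post_init__(self) -> None:
        if self.parameter not in self._VALID:
            raise ValueError(f"parameter must be one of {self._VALID}")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        for v in self.values:
            if self.parameter == "mutation_prob" and not 0.0 <= v <= 1.0:
                raise ValueError(f"mutation_prob value {v} outside [0, 1]")
            if self.parameter in ("population_size", "max_generations") and v < 2:
                raise ValueError(f"{self.parameter} value {v} too small")


def parametric_sweep(
    spec: SweepSpec,
    objective: Callable[[np.ndarray], np.ndarray] | QuadraticSurface,
    space: FactorSpace | None = None,
) -> pd.DataFrame:
    """Run the GA across a parameter sweep; one row per parameter value.

    Replicate seeds derive deterministically from (base seed, value index,
    replicate index) via a spawned SeedSequence, so sweeps are reproducible
    and replicates are independent.
    """
    records = []
    for vi, value in enumerate(spec.values):
        bests = []
        for rep in range(spec.replicates):
            child = np.random.SeedSequence(
                entropy=spec.base_config.seed, spawn_key=(vi, rep)
            )
            seed = int(child.generate_state(1, dtype=np.uint32)[0] % (2**31))
            cfg = replace(spec.base_config, **{spec.parameter: value}, seed=seed)
            bests.append(evolve(cfg, objective, space).best_objective)
        records.append(
            {
                "parameter": spec.parameter,
                "value": value,
                "mean_best": float(np.mean(bests)),
                "sd_best": float(np.std(bests, ddof=1)) if len(bests) > 1 else 0.0,
                "replicates": spec.replicates,
            }
        )
    return pd.DataFrame.from_records(records)
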