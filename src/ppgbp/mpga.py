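"""Multiple-population genetic algorithm (MPGA) over binary-coded reals.

Several populations evolve in parallel, each with its own crossover and
mutation probability drawn once at initialization from configured ranges —
the population-level diversity that guards a plain GA against premature
convergence.  Every generation each population undergoes linear-ranking
fitness assignment, stochastic-universal-sampling selection, single-point
crossover and bit-flip mutation; an immigration operator then moves the
best individual of each population into the next population of a ring,
replacing its worst member, and an artificial-selection operator archives
the best individual of every population.  The run terminates once the
overall best individual has persisted for a minimum number of generations
(or at a safety cap).

The decision variables are binary coded: ``bits_per_variable`` bits map
linearly onto ``var_range``, so the achievable precision is
(high - low) / (2^bits - 1) per variable.  The objective is minimized; for
network optimization it is the training RMSE obtained when the decoded
vector is installed as the network's initial weights and thresholds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd

from .neuralnet import (
    NetworkParams,
    NetworkTopology,
    TrainConfig,
    init_params,
    rmse_fitness,
    train_lm,
)

__all__ = ["GAConfig", "encode", "decode", "evolve", "optimize_network"]


@dataclass(frozen=True)
class GAConfig:
    n_populations: int = 5
    pop_size: int = 20
    bits_per_variable: int = 10
    var_range: tuple[float, float] = (-0.5, 0.8)
    pc_range: tuple[float, float] = (0.7, 0.9)
    pm_range: tuple[float, float] = (0.001, 0.05)
    min_preserve_generations: int = 3
    max_generations: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        if self.var_range[0] >= self.var_range[1]:
            raise ValueError("var_range low must be below high")
        for lo, hi in (self.pc_range, self.pm_range):
            if not 0.0 < lo <= hi < 1.0:
                raise ValueError("probability ranges must lie in (0, 1)")
        if min(
            self.n_populations,
            self.pop_size,
            self.bits_per_variable,
            self.min_preserve_generations,
            self.max_generations,
        ) < 1:
            raise ValueError("all counts must be >= 1")


def encode(x: np.ndarray, cfg: GAConfig) -> np.ndarray:
    """Binary-code a real vector; error is at most half a quantization step."""
    x = np.asarray(x, float).ravel()
    lo, hi = cfg.var_range
    if np.any(x < lo) or np.any(x > hi):
        raise ValueError("values outside var_range cannot be encoded")
    levels = 2**cfg.bits_per_variable - 1
    ints = np.rint((x - lo) / (hi - lo) * levels).astype(np.int64)
    bits = (
        (ints[:, None] >> np.arange(cfg.bits_per_variable - 1, -1, -1)) & 1
    ).astype(np.uint8)
    return bits.ravel()


def decode(bits: np.ndarray, cfg: GAConfig) -> np.ndarray:
    """Inverse of :func:`encode`: low + int(bits) * step per variable."""
    bits = np.asarray(bits).reshape(-1, cfg.bits_per_variable)
    lo, hi = cfg.var_range
    weights = 2 ** np.arange(cfg.bits_per_variable - 1, -1, -1, dtype=np.int64)
    ints = bits.astype(np.int64) @ weights
    return lo + ints * (hi - lo) / (2**cfg.bits_per_variable - 1)


def _ranking_fitness(objective_values: np.ndarray, pressure: float = 2.0) -> np.ndarray:
    """Linear-ranking fitness for minimization (best gets ``pressure``)."""
    n = objective_values.size
    order = np.argsort(objective_values, kind="stable")  # best first
    ranks = np.empty(n)
    ranks[order] = np.arange(n)  # 0 = best
    if n == 1:
        return np.ones(1)
    return 2.0 - pressure + 2.0 * (pressure - 1.0) * (n - 1 - ranks) / (n - 1)


def _sus(fitness: np.ndarray, n_select: int, rng: np.random.Generator) -> np.ndarray:
    """Stochastic universal sampling; returns selected indices."""
    cum = np.cumsum(fitness)
    total = cum[-1]
    start = rng.uniform(0.0, total / n_select)
    pointers = start + total / n_select * np.arange(n_select)
    idx = np.searchsorted(cum, pointers)
    return rng.permutation(idx)


def _evaluate(
    objective: Callable[[np.ndarray], float],
    pop: np.ndarray,
    cfg: GAConfig,
) -> np.ndarray:
    vals = np.empty(len(pop))
    for i, bits in enumerate(pop):
        v = float(objective(decode(bits, cfg)))
        if np.isnan(v):
            warnings.warn("objective returned NaN; treated as +inf", stacklevel=3)
            v = np.inf
        vals[i] = v
    return vals


@dataclass
class EvolutionResult:
    best_x: np.ndarray
    best_f: float
    history: pd.DataFrame
    generations: int


def evolve(
    objective: Callable[[np.ndarray], float],
    n_variables: int,
    cfg: GAConfig,
    *,
    initial: list[np.ndarray] | None = None,
) -> EvolutionResult:
    """Run the multi-population search; returns the best decoded vector.

    ``initial`` warm-starts the search: each given real vector is encoded
    and injected into the first population, so elitism guarantees the final
    best is at least as good as the best warm start (up to coding
    quantization).  The history frame has one row per (generation,
    population) with the population's best and mean objective plus the
    archive best, suitable for plotting evolution curves.
    """
    if n_variables < 1:
        raise ValueError("n_variables must be >= 1")
    rng = np.random.default_rng(cfg.seed)
    L = n_variables * cfg.bits_per_variable

    pops = [
        rng.integers(0, 2, size=(cfg.pop_size, L), dtype=np.uint8)
        for _ in range(cfg.n_populations)
    ]
    for i, vec in enumerate(initial or []):
        if i >= cfg.pop_size:
            break
        pops[0][i] = encode(np.clip(vec, *cfg.var_range), cfg)
    pcs = rng.uniform(*cfg.pc_range, cfg.n_populations)
    pms = rng.uniform(*cfg.pm_range, cfg.n_populations)
    vals = [_evaluate(objective, p, cfg) for p in pops]

    best_bits: np.ndarray | None = None
    best_f = np.inf
    preserved = 0
    rows = []
    generation = 0

    for generation in range(1, cfg.max_generations + 1):
        for p in range(cfg.n_populations):
            pop, f = pops[p], vals[p]
            elite_i = int(np.argmin(f))
            elite_bits, elite_f = pop[elite_i].copy(), f[elite_i]

            fitness = _ranking_fitness(f)
            parents = pop[_sus(fitness, cfg.pop_size, rng)].copy()
            # single-point crossover on consecutive pairs
            for i in range(0, cfg.pop_size - 1, 2):
                if rng.random() < pcs[p] and L > 1:
                    cut = int(rng.integers(1, L))
                    tmp = parents[i, cut:].copy()
                    parents[i, cut:] = parents[i + 1, cut:]
                    parents[i + 1, cut:] = tmp
            # bit-flip mutation
            flips = rng.random(parents.shape) < pms[p]
            parents ^= flips.astype(np.uint8)

            new_vals = _evaluate(objective, parents, cfg)
            # elitist reinsertion: keep the previous best alive
            worst = int(np.argmax(new_vals))
            if new_vals[worst] > elite_f:
                parents[worst] = elite_bits
                new_vals[worst] = elite_f
            pops[p], vals[p] = parents, new_vals

        # immigration: best of population p replaces worst of the next one
        if cfg.n_populations > 1:
            migrants = [
                (pops[p][int(np.argmin(vals[p]))].copy(),
                 float(np.min(vals[p])))
                for p in range(cfg.n_populations)
            ]
            for p in range(cfg.n_populations):
                q = (p + 1) % cfg.n_populations
                worst = int(np.argmax(vals[q]))
                pops[q][worst] = migrants[p][0]
                vals[q][worst] = migrants[p][1]

        # artificial selection into the elite archive
        gen_best_p = int(np.argmin([np.min(v) for v in vals]))
        gen_best_i = int(np.argmin(vals[gen_best_p]))
        gen_best_f = float(vals[gen_best_p][gen_best_i])
        if gen_best_f < best_f:
            best_f = gen_best_f
            best_bits = pops[gen_best_p][gen_best_i].copy()
            preserved = 1
        else:
            preserved += 1

        for p in range(cfg.n_populations):
            rows.append(
                {
                    "generation": generation,
                    "population": p,
                    "best": float(np.min(vals[p])),
                    "mean": float(np.mean(vals[p])),
                    "archive_best": best_f,
                }
            )
        if preserved >= cfg.min_preserve_generations:
            break

    assert best_bits is not None
    return EvolutionResult(
        best_x=decode(best_bits, cfg),
        best_f=best_f,
        history=pd.DataFrame(rows),
        generations=generation,
    )


def optimize_network(
    X: np.ndarray,
    y: np.ndarray,
    topo: NetworkTopology,
    ga_cfg: GAConfig | None = None,
    train_cfg: TrainConfig | None = None,
    *,
    finetune: bool = True,
) -> tuple[NetworkParams, EvolutionResult]:
    """Select initial network weights by MPGA, then (optionally) train.

    The chromosome concatenates every weight and threshold of the network
    (``topo.n_params`` variables, ``bits_per_variable`` bits each) and the
    objective is the training-set RMSE of the decoded network.  With
    ``finetune`` the winning initial weights are polished by
    Levenberg-Marquardt, mirroring the usual GA-initialized training.
    """
    ga_cfg = ga_cfg or GAConfig()
    train_cfg = train_cfg or TrainConfig(seed=ga_cfg.seed)
    X = np.atleast_2d(np.asarray(X, float))
    yv = np.asarray(y, float).ravel()
    template = init_params(X, yv, topo, seed=ga_cfg.seed)

    def objective(vec: np.ndarray) -> float:
        return rmse_fitness(template.with_vector(vec), X, yv)

    result = evolve(objective, topo.n_params, ga_cfg)
    net = template.with_vector(result.best_x)
    if finetune:
        net = train_lm(X, yv, topo, train_cfg, start=net)
    return net, result
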