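"""Genetic-algorithm calibration of the most influential model parameters.

The GA minimizes a scalar fitness — for the simulator, the absolute
difference (mm⁻²) between the simulated day-3 macrophage concentration and
an experimentally quantified target.  Individuals are parameter vectors
initialized uniformly within ±50% of the literature values; evolution uses
tournament selection, arithmetic crossover, per-gene Gaussian mutation and
single-individual elitism, so the best fitness never worsens.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd


@dataclass
class GAIndividual:
    values: dict[str, float]
    fitness: float = np.inf


@dataclass
class GAPopulation:
    individuals: list[GAIndividual]
    generation: int = 0
    best_history: list[float] = field(default_factory=list)

    @property
    def best(self) -> GAIndividual:
        return min(self.individuals, key=lambda ind: ind.fitness)


@dataclass
class GAConfig:
    pop_size: int = 16
    tournament_size: int = 2
    crossover_prob: float = 0.9
    mutation_prob: float = 0.1     # per gene
    mutation_sigma_frac: float = 0.1  # of each gene's range
    elitism: int = 1
    max_generations: int = 20
    fitness_threshold: float = 0.0
    stall_generations: int = 3     # stop after this many gens with <1% improvement
    stall_rel_improvement: float = 0.01


@dataclass
class GAResult:
    best_values: dict[str, float]
    best_fitness: float
    generations: int
    history: pd.DataFrame  # per-generation rows for every individual
    best_history: list[float]


def _clip(vals: np.ndarray, lo: np.ndarray, hi: np.ndarray) -> np.ndarray:
    return np.minimum(np.maximum(vals, lo), hi)


def init_population(bounds: Mapping[str, tuple[float, float]], pop_size: int,
                    rng: np.random.Generator) -> GAPopulation:
    names = list(bounds)
    lo = np.array([bounds[n][0] for n in names])
    hi = np.array([bounds[n][1] for n in names])
    inds = [GAIndividual(dict(zip(names, lo + rng.random(len(names)) * (hi - lo))))
            for _ in range(pop_size)]
    return GAPopulation(individuals=inds)


def evolve(pop: GAPopulation, bounds: Mapping[str, tuple[float, float]],
           cfg: GAConfig, rng: np.random.Generator) -> GAPopulation:
    """One generation: tournament selection, crossover, mutation, elitism.

    Fitnesses must already be evaluated.  The best ``cfg.elitism``
    individuals carry over unchanged, so the population best is
    non-increasing across generations.
    """
    names = list(bounds)
    lo = np.array([bounds[n][0] for n in names])
    hi = np.array([bounds[n][1] for n in names])
    ranked = sorted(pop.individuals, key=lambda ind: ind.fitness)
    elites = [GAIndividual(dict(ind.values), ind.fitness) for ind in ranked[:cfg.elitism]]

    def tournament() -> GAIndividual:
        picks = rng.integers(len(pop.individuals), size=cfg.tournament_size)
        return min((pop.individuals[i] for i in picks), key=lambda ind: ind.fitness)

    children: list[GAIndividual] = []
    while len(children) < cfg.pop_size - cfg.elitism:
        p1 = np.array([tournament().values[n] for n in names])
        p2 = np.array([tournament().values[n] for n in names])
        if rng.random() < cfg.crossover_prob:
            alpha = rng.random(len(names))
            child = alpha * p1 + (1.0 - alpha) * p2
        else:
            child = p1.copy()
        mutate = rng.random(len(names)) < cfg.mutation_prob
        noise = rng.normal(0.0, cfg.mutation_sigma_frac * (hi - lo))
        child = _clip(np.where(mutate, child + noise, child), lo, hi)
        children.append(GAIndividual(dict(zip(names, child))))

    return GAPopulation(individuals=elites + children, generation=pop.generation + 1,
                        best_history=list(pop.best_history))


def minimize(fitness_fn: Callable[[dict[str, float]], float],
             bounds: Mapping[str, tuple[float, float]],
             cfg: GAConfig | None = None,
             seed: int = 0) -> GAResult:
    """Run the GA to convergence or the generation cap.

    Stops when the best fitness drops below ``fitness_threshold`` or has
    improved by less than 1% for ``stall_generations`` consecutive
    generations.  A fitness evaluation that raises yields infinite fitness
    (the individual is culled by selection).
    """
    cfg = cfg or GAConfig()
    rng = np.random.default_rng(seed)
    pop = init_population(bounds, cfg.pop_size, rng)
    hist_rows = []

    def evaluate(p: GAPopulation) -> None:
        for ind in p.individuals:
            if np.isfinite(ind.fitness):
                continue  # elites keep their fitness
            try:
                ind.fitness = float(fitness_fn(ind.values))
            except Exception:
                ind.fitness = np.inf
            if np.isnan(ind.fitness):
                ind.fitness = np.inf

    evaluate(pop)
    pop.best_history.append(pop.best.fitness)
    stall = 0
    while True:
        for ind in pop.individuals:
            hist_rows.append({"generation": pop.generation, "fitness": ind.fitness,
                              **ind.values})
        best = pop.best
        if best.fitness <= cfg.fitness_threshold or pop.generation >= cfg.max_generations:
            break
        if len(pop.best_history) >= 2:
            prev, cur = pop.best_history[-2], pop.best_history[-1]
            rel = (prev - cur) / prev if prev > 0 else 0.0
            stall = stall + 1 if rel < cfg.stall_rel_improvement else 0
            if stall >= cfg.stall_generations:
                break
        pop = evolve(pop, bounds, cfg, rng)
        evaluate(pop)
        pop.best_history.append(pop.best.fitness)

    best = pop.best
    return GAResult(best_values=dict(best.values), best_fitness=best.fitness,
                    generations=pop.generation, history=pd.DataFrame(hist_rows),
                    best_history=list(pop.best_history))


# ---------------------------------------------------------------------------
# simulator-in-the-loop calibration
# ---------------------------------------------------------------------------

DEFAULT_CALIBRATION_FACTORS = ("PMN_0", "k_R_M0", "k_p_M1", "k_e_PMN")


def literature_bounds(params, factors: Sequence[str] = DEFAULT_CALIBRATION_FACTORS,
                      rel_range: float = 0.5) -> dict[str, tuple[float, float]]:
    """±rel_range bounds around the literature values (GA initialization range)."""
    return {f: (params[f] * (1.0 - rel_range), params[f] * (1.0 + rel_range))
            for f in factors}


def simulation_fitness(values: dict[str, float], spec, base_params, target_conc: float,
                       days: float = 3.0, seeds: Sequence[int] = (0, 1, 2),
                       opts=None) -> float:
    """|mean simulated day-``days`` macrophage concentration − target| (mm⁻²).

    Averages ``len(seeds)`` replicate simulations to smooth the stochastic
    objective.  Simulation failures propagate (minimize() maps them to
    infinite fitness).
    """
    from callusim.scheduler import run_replicates

    if target_conc <= 0:
        raise ValueError("target concentration must be positive")
    params = base_params.replace(source="calibrated", **values)
    trajs = run_replicates(spec, params, seeds, days, opts)
    sim = float(np.mean([t.at_day(days)["conc_MPhi"] for t in trajs]))
    return abs(sim - target_conc)


def calibrate(spec, base_params, target_conc: float,
              factors: Sequence[str] = DEFAULT_CALIBRATION_FACTORS,
              cfg: GAConfig | None = None, days: float = 3.0,
              seeds: Sequence[int] = (0, 1, 2), seed: int = 0, opts=None) -> GAResult:
    """GA-calibrate the given parameters against a day-3 target concentration."""
    bounds = literature_bounds(base_params, factors)
    return minimize(
        lambda vals: simulation_fitness(vals, spec, base_params, target_conc,
                                        days=days, seeds=seeds, opts=opts),
        bounds, cfg=cfg, seed=seed)
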