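"""Population initialization and the full optimization loop."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd

from .config import LOAConfig
from .population import FEMALE, MALE, NOMAD, RESIDENT, Population
from . import operators as ops


def initialize_population(objective: Callable, config: LOAConfig,
                          rng: np.random.Generator | None = None) -> Population:
    """Create and evaluate the seeded initial population.

    Npop positions are drawn uniformly in the box; round(Npop *
    nomad_ratio) lions become nomads and the rest are dealt as evenly as
    possible across the prides. Each pride gets round(female_ratio *
    size) females; the nomad pool uses the complementary female share.
    Gender counts fix the quotas every later iteration returns to.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    pop = Population(objective, config.lower_bounds, config.upper_bounds)
    pop.num_prides = config.num_prides

    npop = config.population_size
    n_nomads = round(npop * config.nomad_ratio)
    n_residents = npop - n_nomads

    positions = rng.uniform(config.lower_bounds, config.upper_bounds,
                            size=(npop, config.n_dim))
    order = rng.permutation(npop)
    nomad_rows = order[:n_nomads]
    resident_rows = order[n_nomads:]

    # deal residents round-robin so pride sizes differ by at most one
    pride_rows: list[list[int]] = [[] for _ in range(config.num_prides)]
    for j, row in enumerate(resident_rows):
        pride_rows[j % config.num_prides].append(int(row))

    for pride_id, rows in enumerate(pride_rows):
        size = len(rows)
        n_females = round(config.female_ratio * size)
        female_rows = rng.choice(size, size=n_females, replace=False)
        female_set = set(int(i) for i in female_rows)
        pop.pride_female_quota.append(n_females)
        pop.pride_male_quota.append(size - n_females)
        for i, row in enumerate(rows):
            gender = FEMALE if i in female_set else MALE
            pop.spawn(positions[row], gender, RESIDENT, pride_id)

    n_nomad_females = round((1.0 - config.female_ratio) * n_nomads)
    if n_nomads:
        female_rows = rng.choice(n_nomads, size=n_nomad_females, replace=False)
        female_set = set(int(i) for i in female_rows)
    else:
        female_set = set()
    pop.nomad_female_max = n_nomad_females
    pop.nomad_male_max = n_nomads - n_nomad_females
    for i, row in enumerate(nomad_rows):
        gender = FEMALE if i in female_set else MALE
        pop.spawn(positions[row], gender, NOMAD, None)

    pop.success_counts = [0] * config.num_prides
    return pop


@dataclass
class OptimizeResult:
    """Outcome of one run: global best, its fitness, the per-iteration
    trace and the number of objective evaluations spent."""

    best_position: np.ndarray
    best_fitness: float
    trace: pd.DataFrame
    n_evaluations: int
    n_iterations: int

    def save_trace(self, path) -> None:
        self.trace.to_csv(path, sep="\t", index=False)


def optimize(objective: Callable, config: LOAConfig) -> OptimizeResult:
    """Run the full lion-optimization loop.

    Per iteration, each pride performs hunting, safe-place moves,
    roaming and mating; nomads optionally walk and then mate; defense,
    migration and equilibrium restore the census. The loop stops at
    ``max_iterations`` or after ``patience`` iterations without
    global-best improvement. Identical config + seed gives a
    bit-identical trace.
    """
    rng = np.random.default_rng(config.seed)
    pop = initialize_population(objective, config, rng)

    best = pop.global_best()
    best_position = best.best_position.copy()
    best_fitness = best.best_fitness

    rows = []
    stall = 0
    iteration = 0
    for iteration in range(1, config.max_iterations + 1):
        pop.reset_success_flags()
        for pride_id in range(pop.num_prides):
            hunter_ids, _ = ops.hunting_step(pop, pride_id, config, rng)
            ops.safe_place_step(pop, pride_id, config, rng, hunter_ids)
            ops.roaming_step(pop, pride_id, config, rng)
            ops.mating_step(pop, config, rng, pride_id)
        if config.nomad_walk:
            ops.nomad_walk_step(pop, rng)
        ops.mating_step(pop, config, rng, None)
        ops.defense_step(pop, rng)
        ops.migration_step(pop, config, rng)
        ops.equilibrium_step(pop)

        pop.success_counts = pop.collect_success_counts()
        cand = pop.global_best()
        if cand.best_fitness < best_fitness:
            best_fitness = cand.best_fitness
            best_position = cand.best_position.copy()
            stall = 0
        else:
            stall += 1
        census = pop.census()
        row = {
            "iteration": iteration,
            "best_fitness": best_fitness,
            "total": census["total"],
            "residents": census["residents"],
            "nomads": census["nomads"],
        }
        for j, k in enumerate(pop.success_counts):
            row[f"K_pride{j}"] = k
        rows.append(row)
        if config.patience and stall >= config.patience:
            break

    return OptimizeResult(
        best_position=best_position,
        best_fitness=best_fitness,
        trace=pd.DataFrame(rows),
        n_evaluations=pop.n_evaluations,
        n_iterations=iteration,
    )
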