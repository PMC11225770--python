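"""The behavioral operators of the lion optimizer.

Every operator draws from the single generator owned by the run, in a
fixed documented order, so a run is bit-reproducible from its seed.
All moves are clipped to the box bounds and a lion's personal best is
updated whenever its new fitness improves on it.
"""

from __future__ import annotations

import logging
import math

import numpy as np

from .config import LOAConfig
from .population import (
    FEMALE,
    MALE,
    NOMAD,
    RESIDENT,
    HuntState,
    Lion,
    MatingEvent,
    Population,
)

logger = logging.getLogger(__name__)

_PI_EPS = 1e-12


def tournament_size(success_count: int) -> int:
    """Tournament size from the pride's success count K: max(2, ceil(K/2)).

    Low pride success means stagnation, so selection pressure is relaxed
    by enlarging the tournament no further; high success shrinks it back
    toward greedy choice of recently improved spots.
    """
    return max(2, math.ceil(success_count / 2))


def decode_prey_flight(prey: np.ndarray, hunter: np.ndarray,
                       f_old: float, f_new: float, rng: np.random.Generator) -> np.ndarray:
    """New prey position after a successful attack.

    PREY' = PREY + rand(0,1) * PI * (PREY - Hunter), where PI is the
    hunter's fractional fitness improvement (f_old - f_new) / max(|f_old|, eps)
    clamped to [0, 1].
    """
    pi = (f_old - f_new) / max(abs(f_old), _PI_EPS)
    pi = min(max(pi, 0.0), 1.0)
    return prey + rng.uniform(0.0, 1.0) * pi * (prey - hunter)


def orthonormal_pair(start: np.ndarray, target: np.ndarray,
                     rng: np.random.Generator):
    """Direction R1 toward `target` plus a random unit vector R2 ⟂ R1.

    Returns (distance, R1, R2); R2 is the zero vector in one dimension,
    where no orthogonal direction exists.
    """
    delta = target - start
    distance = float(np.linalg.norm(delta))
    if distance == 0.0:
        return 0.0, np.zeros_like(delta), np.zeros_like(delta)
    r1 = delta / distance
    if delta.shape[0] == 1:
        return distance, r1, np.zeros_like(delta)
    r2 = rng.standard_normal(delta.shape[0])
    r2 -= r2.dot(r1) * r1
    norm = np.linalg.norm(r2)
    while norm < 1e-12:  # astronomically rare resample
        r2 = rng.standard_normal(delta.shape[0])
        r2 -= r2.dot(r1) * r1
        norm = np.linalg.norm(r2)
    return distance, r1, r2 / norm


def _rand_between(a: np.ndarray, b: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Elementwise uniform between a and b with per-dimension ordering."""
    lo = np.minimum(a, b)
    hi = np.maximum(a, b)
    return rng.uniform(lo, hi)


# ---------------------------------------------------------------------
# hunting


def hunting_step(pop: Population, pride_id: int, config: LOAConfig,
                 rng: np.random.Generator):
    """Send a fraction of the pride's females to encircle a dummy prey.

    Hunters are split into left/center/right wings. The prey starts at
    the hunters' centroid; wing hunters jump elementwise between
    (2*PREY - Hunter) and PREY, center hunters between Hunter and PREY.
    Every attack that improves the hunter's fitness makes the prey flee
    proportionally to the improvement.

    Returns the set of hunter ids and the final :class:`HuntState`
    (``None`` when the pride has no females or no hunters were drawn).
    """
    females = pop.pride_females(pride_id)
    if not females:
        logger.debug("pride %d has no females; hunting skipped", pride_id)
        return set(), None
    n_hunters = round(config.hunter_fraction * len(females))
    if n_hunters == 0:
        return set(), None
    idx = rng.choice(len(females), size=n_hunters, replace=False)
    hunters = [females[i] for i in sorted(idx)]
    wings = rng.choice(["left", "center", "right"], size=n_hunters)
    assignment = {h.id: w for h, w in zip(hunters, wings)}

    prey = np.mean([h.position for h in hunters], axis=0)
    state = HuntState(prey=prey, wing_assignment=assignment)

    for hunter in hunters:
        old_fitness = hunter.fitness
        if assignment[hunter.id] == "center":
            new_pos = _rand_between(hunter.position, state.prey, rng)
        else:
            opposite = 2.0 * state.prey - hunter.position
            new_pos = _rand_between(opposite, state.prey, rng)
        new_pos = pop.clip(new_pos)
        new_fitness = pop.evaluate(new_pos)
        hunter.move_to(new_pos, new_fitness)
        if new_fitness < old_fitness:
            pi = (old_fitness - new_fitness) / max(abs(old_fitness), _PI_EPS)
            state.improvement = min(max(pi, 0.0), 1.0)
            state.prey = decode_prey_flight(
                state.prey, new_pos, old_fitness, new_fitness, rng
            )
    return set(assignment), state


# ---------------------------------------------------------------------
# moving toward a safe place


def safe_place_step(pop: Population, pride_id: int, config: LOAConfig,
                    rng: np.random.Generator, hunter_ids: set) -> None:
    """Move each non-hunting female toward a tournament-selected
    territory point.

    The tournament samples T = max(2, ceil(K/2)) territory entries (K is
    the pride's success count of the previous iteration) and keeps the
    best. The female then takes the move
    new = old + 2 D u {R1} + U(-1,1) tan(theta) D {R2}
    with u ~ U(0,1), theta ~ U(-pi/2, pi/2), D the distance to the
    chosen point, {R1} the unit direction toward it and {R2} a random
    unit vector orthogonal to it.
    """
    territory = pop.territory(pride_id)
    if not territory:
        return
    k = pop.success_counts[pride_id] if pop.success_counts else 0
    t_size = min(tournament_size(k), len(territory))
    for female in pop.pride_females(pride_id):
        if female.id in hunter_ids:
            continue
        idx = rng.choice(len(territory), size=t_size, replace=False)
        winner = min((territory[i] for i in sorted(idx)),
                     key=lambda l: (l.best_fitness, l.id))
        d, r1, r2 = orthonormal_pair(female.position, winner.best_position, rng)
        if d == 0.0:
            continue  # already at the safe place
        u = rng.uniform(0.0, 1.0)
        v = rng.uniform(-1.0, 1.0)
        theta = rng.uniform(-np.pi / 2, np.pi / 2)
        new_pos = female.position + 2.0 * d * u * r1 + v * math.tan(theta) * d * r2
        new_pos = pop.clip(new_pos)
        female.move_to(new_pos, pop.evaluate(new_pos))


# ---------------------------------------------------------------------
# roaming


def roaming_step(pop: Population, pride_id: int, config: LOAConfig,
                 rng: np.random.Generator) -> None:
    """Resident males visit a random %R of the territory.

    Toward each chosen point the male steps x ~ U(0, 2 d) along the
    direction to it (d = distance), with the direction tilted by
    theta ~ U(-roaming_angle, roaming_angle) toward a random orthogonal
    vector so the walk is not purely collinear.
    """
    territory = pop.territory(pride_id)
    if not territory:
        logger.debug("pride %d has empty territory; roaming skipped", pride_id)
        return
    n_visits = math.ceil(config.roaming_fraction * len(territory))
    n_visits = min(n_visits, len(territory))
    for male in pop.pride_males(pride_id):
        idx = rng.choice(len(territory), size=n_visits, replace=False)
        for i in sorted(idx):
            point = territory[i].best_position
            d, r1, r2 = orthonormal_pair(male.position, point, rng)
            if d == 0.0:
                continue
            theta = rng.uniform(-config.roaming_angle, config.roaming_angle)
            direction = r1 * math.cos(theta) + r2 * math.sin(theta)
            x = rng.uniform(0.0, 2.0 * d)
            new_pos = pop.clip(male.position + x * direction)
            male.move_to(new_pos, pop.evaluate(new_pos))


# ---------------------------------------------------------------------
# mating


def _crossover(mother: Lion, fathers: list[Lion], flags: np.ndarray,
               beta: float):
    selected = [f for f, s in zip(fathers, flags) if s]
    male_mean = np.mean([f.position for f in selected], axis=0)
    off1 = beta * mother.position + (1.0 - beta) * male_mean
    off2 = (1.0 - beta) * mother.position + beta * male_mean
    return off1, off2


def mating_step(pop: Population, config: LOAConfig, rng: np.random.Generator,
                pride_id=None) -> list[MatingEvent]:
    """Mate a fraction of females and add their two cubs to the census.

    Pride mothers breed with a random nonempty subset of the pride's
    resident males; nomad mothers with exactly one random nomad male.
    Cubs are the two linear combinations
    off1 = beta*F + (1-beta)*mean(selected males),
    off2 = (1-beta)*F + beta*mean(selected males), beta ~ N(0.5, 0.1).
    One randomly chosen cub gets each gene replaced by a fresh uniform
    in-bounds value with probability %Mu; cubs are assigned one of each
    gender and join the mother's group.
    """
    if pride_id is None:
        females = pop.nomads(FEMALE)
        males = pop.nomads(MALE)
    else:
        females = pop.pride_females(pride_id)
        males = pop.pride_males(pride_id)
    events: list[MatingEvent] = []
    if not females:
        return events
    if not males:
        logger.debug("no males available for mating (pride=%s); skipped", pride_id)
        return events
    n_mate = round(config.mating_fraction * len(females))
    if n_mate == 0:
        return events
    idx = rng.choice(len(females), size=n_mate, replace=False)
    mothers = [females[i] for i in sorted(idx)]
    for mother in mothers:
        if pride_id is None:
            flags = np.zeros(len(males), dtype=int)
            flags[rng.integers(len(males))] = 1
        else:
            flags = (rng.uniform(size=len(males)) < 0.5).astype(int)
            if flags.sum() == 0:
                flags[rng.integers(len(males))] = 1
        beta = rng.normal(0.5, 0.1)
        off1, off2 = _crossover(mother, males, flags, beta)
        cubs = [off1, off2]
        mutant = int(rng.integers(2))
        if config.mutation_rate > 0.0:
            genes = rng.uniform(size=cubs[mutant].shape[0]) < config.mutation_rate
            fresh = rng.uniform(pop.lower, pop.upper)
            cubs[mutant] = np.where(genes, fresh, cubs[mutant])
        female_first = bool(rng.integers(2))
        genders = (FEMALE, MALE) if female_first else (MALE, FEMALE)
        role = NOMAD if pride_id is None else RESIDENT
        born = tuple(
            pop.spawn(cub, gender, role, pride_id)
            for cub, gender in zip(cubs, genders)
        )
        events.append(
            MatingEvent(
                mother_id=mother.id,
                selected_male_flags=flags,
                n_resident_males=len(males),
                beta=beta,
                offspring=born,
            )
        )
    return events


# ---------------------------------------------------------------------
# nomad walk (optional, default off)


def nomad_walk_step(pop: Population, rng: np.random.Generator) -> None:
    """Optional exploration move: each nomad jumps to a fresh uniform
    in-bounds point with probability 0.5 per iteration."""
    for nomad in pop.nomads():
        if rng.uniform() < 0.5:
            new_pos = rng.uniform(pop.lower, pop.upper)
            nomad.move_to(new_pos, pop.evaluate(new_pos))


# ---------------------------------------------------------------------
# defense


def defense_step(pop: Population, rng: np.random.Generator) -> None:
    """Two-phase male turnover.

    Phase 1: within each pride, males are ranked by fitness and only the
    best up to the pride's male quota stay; the rest become nomads.
    Phase 2: every nomad male challenges each pride with probability
    0.5; if his fitness beats the pride's weakest resident male, the two
    swap roles.
    """
    for pride_id in range(pop.num_prides):
        males = sorted(pop.pride_males(pride_id), key=lambda l: (l.fitness, l.id))
        for loser in males[pop.pride_male_quota[pride_id]:]:
            loser.role = NOMAD
            loser.pride_id = None
    for nomad in pop.nomads(MALE):
        for pride_id in range(pop.num_prides):
            if rng.uniform() >= 0.5:
                continue
            males = pop.pride_males(pride_id)
            if not males:
                continue
            weakest = max(males, key=lambda l: (l.fitness, l.id))
            if nomad.fitness < weakest.fitness:
                nomad.role, nomad.pride_id = RESIDENT, pride_id
                weakest.role, weakest.pride_id = NOMAD, None
                break


# ---------------------------------------------------------------------
# migration


def migration_step(pop: Population, config: LOAConfig,
                   rng: np.random.Generator) -> None:
    """Female exchange between prides and the nomad pool.

    From each pride, (surplus beyond the female quota) + round(%I *
    quota) females leave, chosen uniformly at random. Vacancies are then
    refilled pride by pride with the fittest nomad females (ties broken
    by id); counts are conserved.
    """
    for pride_id in range(pop.num_prides):
        females = pop.pride_females(pride_id)
        quota = pop.pride_female_quota[pride_id]
        surplus = max(0, len(females) - quota)
        n_migrants = min(surplus + round(config.immigration_fraction * quota),
                         len(females))
        if n_migrants == 0:
            continue
        idx = rng.choice(len(females), size=n_migrants, replace=False)
        for i in sorted(idx):
            females[i].role = NOMAD
            females[i].pride_id = None
    for pride_id in range(pop.num_prides):
        vacancies = pop.pride_female_quota[pride_id] - len(pop.pride_females(pride_id))
        if vacancies <= 0:
            continue
        candidates = sorted(pop.nomads(FEMALE), key=lambda l: (l.fitness, l.id))
        for lion in candidates[:vacancies]:
            lion.role, lion.pride_id = RESIDENT, pride_id


# ---------------------------------------------------------------------
# population equilibrium


def equilibrium_step(pop: Population) -> None:
    """Cull the worst nomads of each gender back to the fixed maxima,
    restoring the total census to Npop."""
    for gender, quota in ((FEMALE, pop.nomad_female_max), (MALE, pop.nomad_male_max)):
        nomads = sorted(pop.nomads(gender), key=lambda l: (-l.fitness, -l.id))
        excess = len(nomads) - quota
        for lion in nomads[:excess]:
            pop.remove(lion.id)
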