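"""Lions, prides and the population census."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np

from .errors import EvaluationError

FEMALE = "female"
MALE = "male"
RESIDENT = "resident"
NOMAD = "nomad"


@dataclass
class Lion:
    """One candidate solution.

    ``best_position``/``best_fitness`` record the best point this lion
    has ever visited (the elitist memory backing the pride territory).
    """

    id: int
    position: np.ndarray
    fitness: float
    best_position: np.ndarray
    best_fitness: float
    gender: str
    role: str
    pride_id: Optional[int]
    improved: bool = False  # best improved during the current iteration

    def move_to(self, position: np.ndarray, fitness: float) -> None:
        self.position = position
        self.fitness = fitness
        if fitness < self.best_fitness:
            self.best_position = position.copy()
            self.best_fitness = fitness
            self.improved = True


@dataclass
class HuntState:
    """Book-keeping of one pride's hunt."""

    prey: np.ndarray
    wing_assignment: dict  # hunter id -> "left" | "center" | "right"
    improvement: float = 0.0  # PI of the last successful attacker


@dataclass
class MatingEvent:
    """One crossover: a mother, her selected males and the two cubs."""

    mother_id: int
    selected_male_flags: np.ndarray
    n_resident_males: int
    beta: float
    offspring: tuple


class Population:
    """All lions plus pride membership and the fixed quotas.

    Quotas (per-pride female/male counts and per-gender nomad maxima)
    are frozen at initialization; the census returns to them after every
    full iteration.
    """

    def __init__(self, objective: Callable, lower: np.ndarray, upper: np.ndarray):
        self._objective = objective
        self.lower = lower
        self.upper = upper
        self.lions: dict[int, Lion] = {}
        self._next_id = 0
        self.num_prides = 0
        self.pride_female_quota: list[int] = []
        self.pride_male_quota: list[int] = []
        self.nomad_female_max = 0
        self.nomad_male_max = 0
        # per-pride success count K of the previous iteration
        self.success_counts: list[int] = []
        self.n_evaluations = 0

    # -- evaluation ---------------------------------------------------

    def evaluate(self, position: np.ndarray) -> float:
        value = float(self._objective(position))
        self.n_evaluations += 1
        if not np.isfinite(value):
            raise EvaluationError(position, value)
        return value

    def clip(self, position: np.ndarray) -> np.ndarray:
        return np.clip(position, self.lower, self.upper)

    def spawn(self, position: np.ndarray, gender: str, role: str,
              pride_id: Optional[int]) -> Lion:
        position = self.clip(np.asarray(position, dtype=float))
        fitness = self.evaluate(position)
        lion = Lion(
            id=self._next_id,
            position=position,
            fitness=fitness,
            best_position=position.copy(),
            best_fitness=fitness,
            gender=gender,
            role=role,
            pride_id=pride_id,
        )
        self._next_id += 1
        self.lions[lion.id] = lion
        return lion

    def remove(self, lion_id: int) -> None:
        del self.lions[lion_id]

    # -- views (always id-sorted for determinism) ---------------------

    def members(self, pride_id: int) -> list[Lion]:
        return sorted(
            (l for l in self.lions.values() if l.pride_id == pride_id),
            key=lambda l: l.id,
        )

    def pride_females(self, pride_id: int) -> list[Lion]:
        return [l for l in self.members(pride_id) if l.gender == FEMALE]

    def pride_males(self, pride_id: int) -> list[Lion]:
        return [l for l in self.members(pride_id) if l.gender == MALE]

    def nomads(self, gender: Optional[str] = None) -> list[Lion]:
        out = sorted(
            (l for l in self.lions.values() if l.role == NOMAD),
            key=lambda l: l.id,
        )
        if gender is not None:
            out = [l for l in out if l.gender == gender]
        return out

    def territory(self, pride_id: int) -> list[Lion]:
        """The pride's territory: one entry (personal best) per member."""
        return self.members(pride_id)

    def census(self) -> dict:
        n_res = sum(1 for l in self.lions.values() if l.role == RESIDENT)
        n_nom = len(self.lions) - n_res
        return {"total": len(self.lions), "residents": n_res, "nomads": n_nom}

    def global_best(self) -> Lion:
        return min(self.lions.values(), key=lambda l: (l.best_fitness, l.id))

    def reset_success_flags(self) -> None:
        for lion in self.lions.values():
            lion.improved = False

    def collect_success_counts(self) -> list[int]:
        """Per pride, how many members improved their personal best this
        iteration — the success count K driving tournament sizing."""
        counts = []
        for p in range(self.num_prides):
            counts.append(sum(1 for l in self.members(p) if l.improved))
        return counts


@dataclass
class Pride:
    """Lightweight per-pride summary used in traces and tests."""

    pride_id: int
    member_ids: list = field(default_factory=list)
    success_count: int = 0
    n_members: int = 0

    @property
    def tournament_size(self) -> int:
        from .operators import tournament_size

        return tournament_size(self.success_count)
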