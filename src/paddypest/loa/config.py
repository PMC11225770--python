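"""Run configuration for the lion optimizer.

Defaults follow the tuning used for the pest feature-selection study:
population 500, 20 % nomads, 5 prides, 80 % females, roaming fraction
0.2, mating fraction 0.3, mutation rate 0.2, immigration fraction 0.4.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class LOAConfig:
    """Parameters of a lion-optimization run.

    Parameters
    ----------
    population_size : int
        Total number of lions (Npop).
    nomad_ratio : float
        Share of the initial population that starts as nomads, in (0, 1).
    num_prides : int
        Number of prides the residents are split into.
    female_ratio : float
        Share of each pride that is female, in (0, 1). Nomads use the
        complementary share.
    roaming_fraction : float
        Share of the pride's territory a resident male visits per
        iteration.
    mating_fraction : float
        Share of each pride's females that mate per iteration.
    mutation_rate : float
        Per-gene mutation probability applied to one offspring of every
        mating event, in [0, 1].
    immigration_fraction : float
        Share of each pride's female quota that migrates to the nomad
        pool each iteration, on top of any surplus.
    hunter_fraction : float
        Share of each pride's females sent hunting each iteration; the
        remainder perform the safe-place move.
    lower_bounds, upper_bounds : array-like of float
        Box bounds of the search domain, elementwise lower < upper.
    max_iterations : int
        Hard iteration cap.
    patience : int
        Iterations without global-best improvement before stopping;
        0 disables early stopping.
    nomad_walk : bool
        Whether nomads take an independent uniform random-walk move each
        iteration (off by default).
    roaming_angle : float
        Half-width (radians) of the angular jitter applied to the male
        roaming direction; set 0 for purely collinear roaming.
    seed : int
        Seed of the single generator all operators draw from.
    """

    lower_bounds: np.ndarray = field(default=None)  # type: ignore[assignment]
    upper_bounds: np.ndarray = field(default=None)  # type: ignore[assignment]
    population_size: int = 500
    nomad_ratio: float = 0.2
    num_prides: int = 5
    female_ratio: float = 0.8
    roaming_fraction: float = 0.2
    mating_fraction: float = 0.3
    mutation_rate: float = 0.2
    immigration_fraction: float = 0.4
    hunter_fraction: float = 0.5
    max_iterations: int = 100
    patience: int = 20
    nomad_walk: bool = False
    roaming_angle: float = np.pi / 6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.lower_bounds is None or self.upper_bounds is None:
            raise ValueError("lower_bounds and upper_bounds are required")
        self.lower_bounds = np.asarray(self.lower_bounds, dtype=float)
        self.upper_bounds = np.asarray(self.upper_bounds, dtype=float)
        if self.lower_bounds.shape != self.upper_bounds.shape:
            raise ValueError("bounds must have identical shape")
        if self.lower_bounds.ndim != 1:
            raise ValueError("bounds must be 1-D vectors")
        if not (np.isfinite(self.lower_bounds).all() and np.isfinite(self.upper_bounds).all()):
            raise ValueError("bounds must be finite")
        if not (self.lower_bounds < self.upper_bounds).all():
            raise ValueError("lower_bounds must be < upper_bounds elementwise")
        if self.population_size < 2:
            raise ValueError("population_size must be >= 2")
        for name in ("nomad_ratio", "female_ratio", "roaming_fraction",
                     "mating_fraction", "immigration_fraction", "hunter_fraction"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must lie in (0, 1), got {v}")
        if not 0.0 <= self.mutation_rate <= 1.0:
            raise ValueError("mutation_rate must lie in [0, 1]")
        if self.num_prides < 1:
            raise ValueError("num_prides must be >= 1")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")
        if self.patience < 0:
            raise ValueError("patience must be >= 0")

    @property
    def n_dim(self) -> int:
        return self.lower_bounds.shape[0]
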