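"""Dilution of surface-bound, non-replicating phage across cell divisions.

UV-inactivated phage bind but never replicate, so the particles attached
to a founding cell are only ever redistributed: each division hands a
daughter roughly half of the mother's load, and the mean per-cell load
after n divisions is p0 / 2^n.  Starting from hundreds to a thousand
particles per cell — the range spanned by the experimental phage:bacteria
ratios — the load falls below one particle per cell within 9-10
divisions, i.e. within the first two days at the measured doubling times.

Two partitioning rules are provided: ``binomial`` (each particle
independently assigned to a daughter with probability 1/2, the default)
and ``deterministic_half`` (floor/ceil split, alternating which daughter
receives the extra particle), which has closed-form behaviour for tests.
With full survival and no lineage truncation the total bound count is
conserved exactly, per realization.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DomainError

__all__ = [
    "PhageLoadModel",
    "LineagePopulation",
    "expected_load",
    "divisions_until_below_one",
    "time_to_dilution",
    "simulate_partitioning",
    "DEFAULT_MAX_CELLS",
]

#: Lineage count beyond which the simulator subsamples (2^n cells is
#: infeasible for large n).
DEFAULT_MAX_CELLS = 4096

_RULES = ("binomial", "deterministic_half")
_FOUNDER_MODES = ("fixed", "poisson")


@dataclass
class PhageLoadModel:
    """Initial per-cell bound-phage load and how it partitions at division.

    ``p0`` is the mean initial load (particles per cell).
    ``survival_per_generation`` models passive particle degradation (each
    particle independently persists through a generation with this
    probability); the default 1 conserves particles.  ``founder_mode``
    chooses whether founders all carry exactly ``p0`` (requires an integer
    ``p0``; closed-form tests) or Poisson(``p0``) counts.
    """

    p0: float
    partition_rule: str = "binomial"
    survival_per_generation: float = 1.0
    seed: int = 0
    founder_mode: str = "fixed"

    def __post_init__(self) -> None:
        if self.p0 < 0:
            raise DomainError(f"p0 must be >= 0, got {self.p0}")
        if not 0 < self.survival_per_generation <= 1:
            raise DomainError(
                f"survival_per_generation must be in (0, 1], got {self.survival_per_generation}"
            )
        if self.partition_rule not in _RULES:
            raise DomainError(f"partition_rule must be one of {_RULES}")
        if self.founder_mode not in _FOUNDER_MODES:
            raise DomainError(f"founder_mode must be one of {_FOUNDER_MODES}")
        if self.founder_mode == "fixed" and abs(self.p0 - round(self.p0)) > 1e-9:
            raise DomainError("fixed founder loads require an integer p0; use founder_mode='poisson'")


@dataclass
class LineagePopulation:
    """Per-cell bound-phage loads at one generation of the lineage tree."""

    generation: int
    loads: np.ndarray
    subsampled: bool = False

    total_bound: int = field(init=False)

    def __post_init__(self) -> None:
        self.loads = np.asarray(self.loads, dtype=np.int64)
        self.total_bound = int(self.loads.sum())

    @property
    def mean_load(self) -> float:
        return float(self.loads.mean()) if len(self.loads) else 0.0

    @property
    def frac_zero(self) -> float:
        return float(np.mean(self.loads == 0)) if len(self.loads) else 0.0


def expected_load(p0: float, n: int) -> float:
    """Mean bound phage per cell after ``n`` divisions: ``p0 / 2**n``.

    The bound pool is fixed while the cell count doubles each division, so
    the per-cell load decreases exponentially with the division index.
    """
    if p0 < 0:
        raise DomainError(f"p0 must be >= 0, got {p0}")
    if n != int(n) or n < 0:
        raise DomainError(f"n must be a non-negative integer, got {n}")
    return p0 / 2.0 ** int(n)


def divisions_until_below_one(p0: float) -> int:
    """Smallest division count n >= 0 with ``p0 / 2**n < 1``.

    A load of 1000 needs 10 divisions (1000/2^9 ≈ 1.95 is still above
    one), a load of 500 needs 9; loads already below one need none.
    """
    if p0 < 0:
        raise DomainError(f"p0 must be >= 0, got {p0}")
    n = 0
    load = float(p0)
    while load >= 1.0:
        load /= 2.0
        n += 1
    return n


def time_to_dilution(p0: float, doubling_time: float) -> float:
    """Hours until the mean per-cell load drops below one particle.

    ``divisions_until_below_one(p0)`` divisions at the given doubling
    time; with a few hundred to a thousand particles per cell and the
    doubling times measured in the growth assays, this lands inside the
    first 48 hours.
    """
    if doubling_time <= 0:
        raise DomainError(f"doubling_time must be > 0, got {doubling_time}")
    return divisions_until_below_one(p0) * doubling_time


def _founder_loads(model: PhageLoadModel, n_founders: int, rng: np.random.Generator) -> np.ndarray:
    if model.founder_mode == "poisson":
        return rng.poisson(model.p0, size=n_founders).astype(np.int64)
    return np.full(n_founders, int(round(model.p0)), dtype=np.int64)


def simulate_partitioning(
    model: PhageLoadModel,
    generations: int,
    max_cells: int = DEFAULT_MAX_CELLS,
    n_founders: int = 1,
) -> list[LineagePopulation]:
    """Simulate per-cell bound-phage loads across ``generations`` divisions.

    Each division splits a cell's k particles between its two daughters:
    binomial(k, 1/2) under the ``binomial`` rule, floor/ceil halves
    (alternating the recipient of the odd particle) under
    ``deterministic_half``.  When the population would exceed
    ``max_cells``, a uniform random subsample of lineages is retained and
    the population is marked ``subsampled`` (conservation of the total
    then no longer holds by construction).

    Returns one :class:`LineagePopulation` per generation, generation 0
    (the founders) included.  Deterministic under a fixed model seed.
    """
    if generations < 0:
        raise DomainError(f"generations must be >= 0, got {generations}")
    if max_cells < 1:
        raise DomainError(f"max_cells must be >= 1, got {max_cells}")
    if n_founders < 1:
        raise DomainError(f"n_founders must be >= 1, got {n_founders}")
    rng = np.random.default_rng(model.seed)
    loads = _founder_loads(model, n_founders, rng)
    populations = [LineagePopulation(0, loads.copy())]
    subsampled = False
    for gen in range(1, generations + 1):
        if model.survival_per_generation < 1.0:
            loads = rng.binomial(loads, model.survival_per_generation).astype(np.int64)
        if model.partition_rule == "binomial":
            left = rng.binomial(loads, 0.5).astype(np.int64)
        else:
            # alternate which daughter of an odd load receives the extra particle
            extra = loads % 2
            take_extra = (np.arange(len(loads), dtype=np.int64) % 2).astype(np.int64)
            left = loads // 2 + extra * take_extra
        right = loads - left
        loads = np.concatenate([left, right])
        if len(loads) > max_cells:
            keep = rng.choice(len(loads), size=max_cells, replace=False)
            keep.sort()
            loads = loads[keep]
            subsampled = True
        populations.append(LineagePopulation(gen, loads.copy(), subsampled=subsampled))
    return populations
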