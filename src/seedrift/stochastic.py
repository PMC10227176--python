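"""Stochastic individual-based model of seed-size evolution on a ring.

Each habitable cell holds at most one plant.  Generations do not overlap:
every generation, parents (in uniformly random order) release their seeds
downstream; each seed travels a geometric distance drawn from the parent's
dispersal kernel and establishes iff it lands on a habitable cell not yet
claimed by a new-generation seedling, passing an independent Bernoulli(g)
germination-and-survival trial.  Established seedlings inherit the parent's
seed size, mutated by +/- 1 mm with probability ``mu`` (clamped to the
seed-size bounds).  Parents then die; their cells do not block seedlings.

The seed budget per plant follows the deterministic cost model:
``N_j = round(n_tot * (1 - c))`` with ``c = c1 * pi * S**3 / 6``.

Implementation note: a parent's seeds are i.i.d., so they are drawn in one
vectorized batch and a contested cell is occupied by that parent iff at
least one of its seeds passes the germination trial — distributionally
identical to strict seed-by-seed processing, and the dispersal loop still
short-circuits once every habitable cell is occupied.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import isnan

import numpy as np

from .deterministic import seed_cost
from .kernel import KernelParams, lambda_of_size, median_distance
from .landscape import Landscape1D, habitable_cells, habitable_mask

__all__ = [
    "StochParams",
    "Population",
    "LevelSummary",
    "founding_population",
    "seeds_per_plant",
    "mutate",
    "run_generation",
    "run_level",
    "remap_population",
]


@dataclass(frozen=True)
class StochParams:
    """Demographic and evolutionary constants of the individual-based model.

    Defaults follow the headline stochastic runs: 10,000 seeds of budget per
    plant, g = 0.3, c1 = 1e-4, mutation rate 0.001 per established seedling,
    1000 generations per fragmentation level, founders of 20 mm, 1-mm
    mutation steps.
    """

    n_tot: float = 10_000.0
    g: float = 0.3
    c1: float = 1e-4
    mu: float = 0.001
    n_gens: int = 1000
    s_init: float = 20.0
    mutation_step: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.mu <= 1.0:
            raise ValueError("mu must lie in [0, 1]")
        if self.n_gens < 0:
            raise ValueError("n_gens must be >= 0")
        if not 0.0 <= self.g <= 1.0:
            raise ValueError("g must lie in [0, 1]")


@dataclass
class Population:
    """Plants on a landscape: parallel arrays of cell index and seed size (mm)."""

    cells: np.ndarray
    sizes: np.ndarray
    generation: int = 0

    def __post_init__(self) -> None:
        self.cells = np.asarray(self.cells, dtype=np.int64)
        self.sizes = np.asarray(self.sizes, dtype=float)
        if self.cells.shape != self.sizes.shape:
            raise ValueError("cells and sizes must have equal length")

    def __len__(self) -> int:
        return self.cells.size

    @property
    def extinct(self) -> bool:
        return self.cells.size == 0

    def median_size(self) -> float:
        return float(np.median(self.sizes)) if len(self) else float("nan")


@dataclass(frozen=True)
class LevelSummary:
    """End-of-level record: median phenotype and its dispersal capacity."""

    pop_size: int
    median_size: float
    median_dispersal_distance: float
    extinct: bool
    generations_run: int = 0


def founding_population(landscape: Landscape1D, s_init: float) -> Population:
    """Every habitable cell holds a founder of size ``s_init`` mm."""
    cells = habitable_cells(landscape)
    return Population(cells=cells, sizes=np.full(cells.size, float(s_init)))


def seeds_per_plant(s: float, p: StochParams) -> int:
    """Integer seed budget N_j = round(n_tot * (1 - c)), floored at 0.

    Rounding is half-away-from-zero.  Costs >= 1 yield a budget of 0: a
    mutant whose seeds are too expensive simply leaves no offspring (mutation
    can push seed size into that region, so it must not be an error here).
    """
    c = seed_cost(s, p.c1)
    return max(int(np.floor(p.n_tot * (1.0 - c) + 0.5)), 0)


def mutate(s, mu: float, rng: np.random.Generator, *,
           step: float = 1.0, s_min: float = 0.5, s_max: float = 30.0):
    """Offspring seed size: unchanged with prob 1-mu, else +/- ``step`` mm.

    Mutations are clamped to [s_min, s_max].  Accepts scalars or arrays.
    """
    arr = np.atleast_1d(np.asarray(s, dtype=float)).copy()
    hit = rng.random(arr.size) < mu
    n_hit = int(hit.sum())
    if n_hit:
        sign = rng.integers(0, 2, size=n_hit) * 2 - 1
        arr[hit] += sign * step
        np.clip(arr, s_min, s_max, out=arr)
    return float(arr[0]) if np.isscalar(s) or np.asarray(s).ndim == 0 else arr


def run_generation(
    pop: Population,
    landscape: Landscape1D,
    kernel: KernelParams,
    p: StochParams,
    rng: np.random.Generator,
    *,
    competition: bool = True,
) -> Population:
    """One non-overlapping generation: dispersal, establishment, mutation.

    Parents disperse in random order; dispersal is strictly downstream and
    wraps around the ring.  With ``competition=False`` cells already claimed
    by seedlings do not block later seeds (single-parent diagnostic mode used
    to compare colonization probabilities against the deterministic model).
    Returns the seedling population, which may be empty (extinction).
    """
    if landscape.mode != "periodic":
        raise ValueError("the individual-based model runs on a periodic landscape")
    L = landscape.length
    hab = habitable_mask(landscape)
    n_hab = int(hab.sum())
    occupied = np.zeros(L, dtype=bool)
    n_occ = 0
    new_cells: list[np.ndarray] = []
    new_sizes: list[np.ndarray] = []

    for i in rng.permutation(len(pop)):
        if competition and n_occ == n_hab:
            break  # all habitable cells already hold a seedling
        s_parent = float(pop.sizes[i])
        n_j = seeds_per_plant(s_parent, p)
        if n_j == 0:
            continue
        lam = lambda_of_size(s_parent, kernel)
        dist = rng.geometric(1.0 - lam, size=n_j) - 1
        land = (pop.cells[i] + dist) % L
        ok = hab[land]
        if competition:
            ok &= ~occupied[land]
        land = land[ok]
        if land.size == 0:
            continue
        land = land[rng.random(land.size) < p.g]
        if land.size == 0:
            continue
        newly = np.unique(land)
        if not competition:
            newly = newly[~occupied[newly]]
        if newly.size == 0:
            continue
        occupied[newly] = True
        n_occ += newly.size
        new_cells.append(newly)
        new_sizes.append(
            mutate(np.full(newly.size, s_parent), p.mu, rng,
                   step=p.mutation_step, s_min=kernel.s_min, s_max=kernel.s_max)
        )

    if not new_cells:
        return Population(cells=np.empty(0, dtype=np.int64),
                          sizes=np.empty(0), generation=pop.generation + 1)
    return Population(
        cells=np.concatenate(new_cells),
        sizes=np.concatenate(new_sizes),
        generation=pop.generation + 1,
    )


def run_level(
    pop: Population,
    landscape: Landscape1D,
    kernel: KernelParams,
    p: StochParams,
    rng: np.random.Generator,
) -> tuple[Population, LevelSummary]:
    """Run ``n_gens`` generations at one fragmentation level.

    Stops early on extinction.  The summary reports the population median
    seed size and the median dispersal distance of that phenotype.
    """
    gens = 0
    for _ in range(p.n_gens):
        if pop.extinct:
            break
        pop = run_generation(pop, landscape, kernel, p, rng)
        gens += 1
    med = pop.median_size()
    md = float("nan") if isnan(med) else median_distance(lambda_of_size(med, kernel))
    return pop, LevelSummary(
        pop_size=len(pop),
        median_size=med,
        median_dispersal_distance=md,
        extinct=pop.extinct,
        generations_run=gens,
    )


def remap_population(pop: Population, old: Landscape1D, new: Landscape1D) -> Population:
    """Carry plants across a change in inter-patch distance.

    Plants keep their (patch index, within-patch offset); only the matrix
    between patches stretches or shrinks.  Patch count and patch size must
    match between the two landscapes.
    """
    if (old.x_h, old.n_patches) != (new.x_h, new.n_patches):
        raise ValueError("can only remap between landscapes differing in x_ipd")
    patch = pop.cells // old.period
    offset = pop.cells % old.period
    if np.any(offset >= old.x_h):
        raise ValueError("population contains plants on matrix cells")
    return Population(cells=patch * new.period + offset,
                      sizes=pop.sizes.copy(), generation=pop.generation)
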