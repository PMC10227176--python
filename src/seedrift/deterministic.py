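"""Deterministic single-plant model of seed-size evolution.

One parent plant sits at the upstream edge of a habitat patch (cell 0) and
disperses ``N_tot`` seeds downstream over a bounded window.  Producing seeds
of size ``S`` (mm) costs a fraction ``c = c1 * pi * S**3 / 6`` of the seed
budget (cost proportional to seed volume), so the expected number of seeds
deposited in the cell at distance ``d`` is::

    N_d = N_tot * (1 - c) * pmf(d)          (geometric deposition weights)

A cell is colonized if at least one seed there germinates and survives
(probability ``g`` per seed in habitat, 0 in matrix)::

    P+_d = 1 - (1 - g) ** N_d

Fitness is the expected number of colonized cells, the sum of ``P+`` over
habitable cells in the window.  Seed size evolves by an adaptive walk:
compare fitness at S, S - 0.01 and S + 0.01 mm and move to the strictly
better neighbour until a local optimum is reached.  ``N_d`` is kept
real-valued inside the occupancy formula; rounding would create plateaus
that stall the 0.01-mm walk.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .kernel import KernelParams, deposition_pmf, lambda_of_size
from .landscape import Landscape1D, habitable_mask

logger = logging.getLogger(__name__)

__all__ = [
    "DetParams",
    "seed_cost",
    "seeds_per_cell",
    "occupancy_prob",
    "det_fitness",
    "optimize_seed_size",
]


@dataclass(frozen=True)
class DetParams:
    """Demographic constants of the deterministic model.

    Defaults are the study conditions: 10,000 seeds per plant, germination-
    and-survival probability 0.3 in habitat, cost constant 1e-4 per mm^3 of
    seed volume, a 5000-cell downstream window, and a 0.01-mm mutation step.
    """

    n_tot: float = 10_000.0
    g: float = 0.3
    c1: float = 1e-4
    d_max: int = 5000
    step: float = 0.01

    def __post_init__(self) -> None:
        if self.n_tot < 1:
            raise ValueError("n_tot must be >= 1")
        if not 0.0 <= self.g <= 1.0:
            raise ValueError("g must lie in [0, 1]")
        if self.c1 < 0:
            raise ValueError("c1 must be >= 0")
        if self.d_max < 1:
            raise ValueError("d_max must be >= 1")


def seed_cost(s: float, c1: float) -> float:
    """Fraction of the seed budget spent per seed of size ``s`` (mm).

    Cost is proportional to the volume of a round seed: ``c1 * pi * s**3 / 6``.
    Values >= 1 mean the plant cannot produce any seeds of that size.
    """
    if s <= 0:
        raise ValueError("seed size must be > 0")
    if c1 < 0:
        raise ValueError("c1 must be >= 0")
    return c1 * math.pi * s**3 / 6.0


def seeds_per_cell(s: float, kernel: KernelParams, p: DetParams) -> np.ndarray:
    """Expected seed deposition N_d over cells d = 0 .. d_max-1.

    Real-valued (expected counts, not rounded); sums to ``n_tot * (1 - c)``.

    Raises
    ------
    ValueError
        If the seed cost at this size is >= 1 (no seeds can be produced).
    """
    c = seed_cost(s, p.c1)
    if c >= 1.0:
        raise ValueError(
            f"seed cost c={c:.4g} >= 1 at S={s} mm, c1={p.c1}: no seeds produced"
        )
    lam = lambda_of_size(s, kernel)
    return p.n_tot * (1.0 - c) * deposition_pmf(lam, p.d_max)


def occupancy_prob(n_d, g: float):
    """Probability a cell receiving ``n_d`` expected seeds becomes occupied.

    ``P+ = 1 - (1 - g) ** n_d`` with real-valued ``n_d``; evaluated via
    expm1/log1p for accuracy at small ``g * n_d``.  Accepts scalars or arrays.
    """
    n = np.asarray(n_d, dtype=float)
    if np.any(n < 0):
        raise ValueError("expected seed count must be >= 0")
    if not 0.0 <= g <= 1.0:
        raise ValueError("g must lie in [0, 1]")
    if g == 0.0:
        out = np.zeros_like(n)
    elif g == 1.0:
        out = (n > 0).astype(float)
    else:
        out = -np.expm1(n * math.log1p(-g))
    return float(out) if np.isscalar(n_d) or n.ndim == 0 else out


def det_fitness(
    s: float,
    landscape: Landscape1D,
    kernel: KernelParams,
    p: DetParams,
    *,
    _hab_idx: np.ndarray | None = None,
) -> float:
    """Expected number of colonized cells for a plant producing size-``s`` seeds.

    Sums ``P+`` over the habitable cells among d = 0 .. d_max-1 (matrix cells
    have zero germination and contribute nothing).  Seed sizes whose cost
    reaches 1 produce no seeds and have fitness 0.

    ``_hab_idx`` lets callers pass precomputed habitable indices for speed.
    """
    if landscape.mode != "bounded":
        raise ValueError("deterministic fitness requires a bounded landscape")
    c = seed_cost(s, p.c1)
    if c >= 1.0:
        return 0.0
    hab = _hab_idx
    if hab is None:
        hab = np.flatnonzero(habitable_mask(landscape, p.d_max))
    if hab.size == 0:
        return 0.0
    lam = lambda_of_size(s, kernel)
    log_lam = math.log(lam)
    # deposition weights restricted to habitable cells
    w = np.exp(hab * log_lam) * (1.0 - lam) / (-math.expm1(p.d_max * log_lam))
    n_d = p.n_tot * (1.0 - c) * w
    return float(np.sum(occupancy_prob(n_d, p.g)))


def optimize_seed_size(
    s_init: float,
    landscape: Landscape1D,
    kernel: KernelParams,
    p: DetParams,
    *,
    parent_offset: int = 0,
    return_history: bool = False,
):
    """Adaptive walk on the 0.01-mm seed-size grid to a local fitness optimum.

    Starting from ``s_init`` (snapped to the grid with a warning if needed),
    repeatedly compare fitness at S and its two grid neighbours; move to the
    strictly better neighbour (ties between two improving neighbours break
    toward the smaller, cheaper seed) and stop when S beats or ties both.
    Deterministic for fixed inputs.

    ``parent_offset`` places the parent that many cells downstream of its
    patch's upstream edge (the habitability pattern is shifted accordingly);
    the default 0 puts it at the upstream edge.

    Returns
    -------
    s_star : float
        The evolved seed size (mm), or ``(s_star, history)`` with the list of
        (seed size, fitness) visited when ``return_history`` is set.
    """
    s_lo, s_hi = kernel.s_min, kernel.s_max
    n_steps = int(round((s_hi - s_lo) / p.step))
    k = int(round((s_init - s_lo) / p.step))
    k = min(max(k, 0), n_steps)
    snapped = s_lo + k * p.step
    if abs(snapped - s_init) > 1e-9:
        logger.warning("s_init=%g mm not on %g-mm grid; snapped to %g", s_init, p.step, snapped)

    if not 0 <= parent_offset < landscape.x_h:
        raise ValueError("parent_offset must lie within the natal patch")
    hab = np.flatnonzero(
        ((np.arange(p.d_max) + parent_offset) % landscape.period) < landscape.x_h
    )
    cache: dict[int, float] = {}

    def f(i: int) -> float:
        if i not in cache:
            cache[i] = det_fitness(s_lo + i * p.step, landscape, kernel, p, _hab_idx=hab)
        return cache[i]

    history = [(s_lo + k * p.step, f(k))]
    for _ in range(n_steps + 1):  # a strictly improving walk cannot revisit
        fc = f(k)
        f_down = f(k - 1) if k > 0 else -math.inf
        f_up = f(k + 1) if k < n_steps else -math.inf
        if f_down <= fc and f_up <= fc:
            break
        k = k - 1 if (f_down > fc and f_down >= f_up) else k + 1
        history.append((s_lo + k * p.step, f(k)))
    s_star = s_lo + k * p.step
    if return_history:
        return s_star, history
    return s_star
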