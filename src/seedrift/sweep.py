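"""Fragmentation sweeps, hysteresis detection, and sensitivity grids.

A sweep increases the inter-patch distance level by level from its minimum to
``x_max`` (the "up" direction) and then decreases it back (the "down"
direction), carrying the evolved state across levels: the deterministic model
seeds each hill climb with the previous level's optimum; the stochastic model
carries the whole population over (no reseeding).  Evolutionary hysteresis
shows up as the two directions disagreeing over a range of inter-patch
distances.

The collapse/recovery detector operationalizes the vertical lines drawn
through the sweep figures: the up sweep "collapses" at the first level where
its evolved median dispersal distance falls to half its running maximum, and
the down sweep "recovers" at the first level (traversed from ``x_max``
downward) that regains half of the up sweep's pre-collapse maximum.  The
hysteresis zone size (cells) is the distance between those two transitions.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .config import ConfigError, RunConfig, _FIELD_NAMES
from .deterministic import DetParams, det_fitness, optimize_seed_size
from .kernel import calibrate_kernel, lambda_of_size, median_distance
from .landscape import Landscape1D
from .stochastic import (
    StochParams,
    founding_population,
    remap_population,
    run_level,
)

__all__ = [
    "SweepLevel",
    "SweepCurve",
    "HysteresisSummary",
    "ipd_grid",
    "sweep_deterministic",
    "sweep_stochastic",
    "run_sweep",
    "detect_hysteresis",
    "sensitivity_grid",
    "replicate_seeds",
]


@dataclass(frozen=True)
class SweepLevel:
    """State evolved at one inter-patch distance."""

    x_ipd: int
    seed_size: float
    median_dispersal_distance: float
    fitness: float = float("nan")   # deterministic model only
    pop_size: int = -1              # stochastic model only
    extinct: bool = False


@dataclass
class SweepCurve:
    """Ordered per-level records of one sweep direction."""

    direction: str                  # "up" | "down"
    levels: list[SweepLevel]

    @property
    def x_ipd(self) -> np.ndarray:
        return np.array([lv.x_ipd for lv in self.levels])

    @property
    def median_dispersal_distance(self) -> np.ndarray:
        return np.array([lv.median_dispersal_distance for lv in self.levels])

    @property
    def seed_size(self) -> np.ndarray:
        return np.array([lv.seed_size for lv in self.levels])

    @property
    def extinct(self) -> np.ndarray:
        return np.array([lv.extinct for lv in self.levels])

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame([vars(lv) for lv in self.levels])
        df.insert(0, "direction", self.direction)
        return df


@dataclass(frozen=True)
class HysteresisSummary:
    """Detected transitions and the size of the hysteresis zone (cells)."""

    up_transition: int | None
    down_transition: int | None
    zone_size: int


def ipd_grid(cfg: RunConfig) -> np.ndarray:
    """Inter-patch distances visited by one sweep direction (ascending)."""
    return np.arange(cfg.x_ipd_min, cfg.x_max + 1, cfg.x_ipd_step, dtype=int)


def sweep_deterministic(cfg: RunConfig) -> tuple[SweepCurve, SweepCurve]:
    """Up-then-down sweep of the deterministic model.

    Each level's hill climb starts from the previous level's optimum; the
    down sweep starts from the up sweep's final state.  Fully deterministic,
    so no replication.
    """
    kernel = calibrate_kernel(cfg.d05, cfg.d30, s_min=cfg.s_min, s_max=cfg.s_max)
    p = DetParams(n_tot=cfg.n_tot, g=cfg.g, c1=cfg.c1, d_max=cfg.d_max,
                  step=cfg.det_step)
    grid = ipd_grid(cfg)

    def run_direction(x_values: np.ndarray, s_start: float, direction: str) -> SweepCurve:
        s = s_start
        levels = []
        for x in x_values:
            ls = Landscape1D(x_h=cfg.x_h, x_ipd=int(x), mode="bounded", d_max=cfg.d_max)
            s = optimize_seed_size(s, ls, kernel, p, parent_offset=cfg.parent_offset)
            lam = lambda_of_size(s, kernel)
            levels.append(SweepLevel(
                x_ipd=int(x),
                seed_size=s,
                median_dispersal_distance=median_distance(lam),
                fitness=det_fitness(s, ls, kernel, p),
            ))
        return SweepCurve(direction=direction, levels=levels)

    up = run_direction(grid, cfg.s_init, "up")
    down = run_direction(grid[::-1], up.levels[-1].seed_size, "down")
    return up, down


def sweep_stochastic(
    cfg: RunConfig, rng: np.random.Generator
) -> tuple[SweepCurve, SweepCurve]:
    """Up-then-down sweep of the individual-based model (one replicate).

    The founding population fills every habitable cell at the starting
    inter-patch distance; the population (not a summary) carries over between
    levels and directions.  After extinction all remaining levels of the
    sweep are recorded as extinct — a once-lost population is not re-founded.
    """
    kernel = calibrate_kernel(cfg.d05, cfg.d30, s_min=cfg.s_min, s_max=cfg.s_max)
    p = StochParams(n_tot=cfg.n_tot, g=cfg.g, c1=cfg.c1, mu=cfg.mu,
                    n_gens=cfg.n_gens, s_init=cfg.s_init_stoch)
    grid = ipd_grid(cfg)

    def make_ls(x: int) -> Landscape1D:
        return Landscape1D(x_h=cfg.x_h, x_ipd=int(x), mode="periodic",
                           n_patches=cfg.n_patches)

    ls = make_ls(int(grid[0]))
    pop = founding_population(ls, cfg.s_init_stoch)

    def run_direction(x_values: np.ndarray, direction: str) -> SweepCurve:
        nonlocal ls, pop
        levels = []
        for x in x_values:
            new_ls = make_ls(int(x))
            if new_ls.x_ipd != ls.x_ipd:
                pop = remap_population(pop, ls, new_ls)
            ls = new_ls
            if pop.extinct:
                levels.append(SweepLevel(
                    x_ipd=int(x), seed_size=float("nan"),
                    median_dispersal_distance=float("nan"),
                    pop_size=0, extinct=True,
                ))
                continue
            pop, summary = run_level(pop, ls, kernel, p, rng)
            levels.append(SweepLevel(
                x_ipd=int(x),
                seed_size=summary.median_size,
                median_dispersal_distance=summary.median_dispersal_distance,
                pop_size=summary.pop_size,
                extinct=summary.extinct,
            ))
        return SweepCurve(direction=direction, levels=levels)

    up = run_direction(grid, "up")
    down = run_direction(grid[::-1], "down")
    return up, down


def run_sweep(cfg: RunConfig, seed: int | None = None):
    """Dispatch a sweep by ``cfg.model``; returns ``(up, down)``."""
    if cfg.model == "deterministic":
        return sweep_deterministic(cfg)
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    return sweep_stochastic(cfg, rng)


def detect_hysteresis(
    up: SweepCurve, down: SweepCurve, tol: float | None = None
) -> HysteresisSummary:
    """Locate the collapse and recovery transitions and size the zone between.

    ``tol`` (cells of median dispersal distance) guards against calling a
    hysteresis zone where the two curves never actually separate; it defaults
    to one sweep grid step.  Extinct levels count as zero dispersal capacity.
    """
    x_up = up.x_ipd
    x_down = down.x_ipd
    if not np.array_equal(x_up, x_down[::-1]):
        raise ValueError("up and down sweeps must share the same x_ipd grid")
    if tol is None:
        tol = float(x_up[1] - x_up[0]) if x_up.size > 1 else 1.0

    md_up = np.nan_to_num(up.median_dispersal_distance, nan=0.0)
    md_down = np.nan_to_num(down.median_dispersal_distance, nan=0.0)

    # Collapse on the up sweep: first level falling to <= 50% of the running
    # maximum of all earlier levels.
    up_transition = None
    pre_collapse_max = 0.0
    running = md_up[0]
    for i in range(1, md_up.size):
        if running > 0 and md_up[i] <= 0.5 * running:
            up_transition = int(x_up[i])
            pre_collapse_max = running
            break
        running = max(running, md_up[i])

    # Recovery on the down sweep: first level (traversing from x_max down)
    # regaining 50% of the pre-collapse maximum.
    down_transition = None
    if up_transition is not None:
        for j in range(md_down.size):
            if md_down[j] >= 0.5 * pre_collapse_max:
                down_transition = int(x_down[j])
                break

    curves_differ = bool(np.any(np.abs(md_up - md_down[::-1]) > tol))
    if up_transition is None or not curves_differ:
        zone = 0
    elif down_transition is None:
        zone = int(up_transition - x_up[0])
    else:
        zone = max(0, int(up_transition - down_transition))
    return HysteresisSummary(up_transition=up_transition,
                             down_transition=down_transition, zone_size=zone)


def has_abrupt_collapse(curve: SweepCurve, factor: float = 2.0) -> bool:
    """True if the curve's median dispersal distance ever drops by ``factor``
    (or goes extinct) between two consecutive levels."""
    md = curve.median_dispersal_distance
    for a, b in zip(md[:-1], md[1:]):
        if np.isnan(a) or a <= 0:
            continue
        if np.isnan(b) or b <= a / factor:
            return True
    return False


def replicate_seeds(base_seed: int | None, n: int, stream: int = 0) -> list[int]:
    """Derive ``n`` loggable integer seeds (< 2**31) from a base seed."""
    entropy = [0 if base_seed is None else int(base_seed), int(stream)]
    state = np.random.SeedSequence(entropy).generate_state(n, dtype=np.uint32)
    return [int(s) & 0x7FFFFFFF for s in state]


def sensitivity_grid(
    base_cfg: RunConfig, axes: dict[str, list]
) -> pd.DataFrame:
    """Sweep + hysteresis detection over the Cartesian product of ``axes``.

    ``axes`` maps config field names to lists of values.  Returns a
    long-format table with one row per parameter combination (per replicate
    for the stochastic model): axis values, detected transitions, hysteresis
    zone size, and whether the population went extinct anywhere in the sweep.
    """
    unknown = set(axes) - _FIELD_NAMES
    if unknown:
        raise ConfigError(f"unknown config keys in axes: {sorted(unknown)}")
    keys = list(axes)
    rows = []
    for combo_idx, values in enumerate(itertools.product(*(axes[k] for k in keys))):
        cfg = replace(base_cfg, **dict(zip(keys, values)))
        if cfg.model == "deterministic":
            seeds = [None]
        else:
            seeds = replicate_seeds(cfg.seed, cfg.replicates, stream=combo_idx)
        for rep, seed in enumerate(seeds):
            up, down = run_sweep(cfg, seed=seed)
            h = detect_hysteresis(up, down, tol=cfg.tol)
            row = dict(zip(keys, values))
            row.update(
                replicate=rep,
                rng_seed=-1 if seed is None else seed,
                up_transition=np.nan if h.up_transition is None else h.up_transition,
                down_transition=(np.nan if h.down_transition is None
                                 else h.down_transition),
                zone_size=h.zone_size,
                any_extinct=bool(up.extinct.any() or down.extinct.any()),
            )
            rows.append(row)
    return pd.DataFrame(rows)
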