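"""Run configuration: defaults, validation, and flat-file (de)serialization.

A :class:`RunConfig` collects every tunable of a sweep in one place.  The
defaults are the study conditions of the headline runs; a handful of ranges
reflecting the conditions actually explored are enforced on loading unless
``allow_out_of_range`` is set (programmatic construction of a ``RunConfig``
skips validation so that tiny test geometries remain easy to build).

Config files are flat YAML mappings (``key: value`` per line) and round-trip
losslessly through :func:`save_config` / :func:`load_config`.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import yaml

__all__ = [
    "RunConfig",
    "ConfigError",
    "default_config",
    "load_config",
    "save_config",
    "validate_config",
    "PRESETS",
]


class ConfigError(ValueError):
    """Raised for unknown keys, unreadable files, or out-of-range values."""


@dataclass
class RunConfig:
    """All parameters of a fragmentation sweep.

    Distances are grid cells (1 cell = 1 m), seed sizes mm.  ``model``
    selects the deterministic single-plant model or the stochastic
    individual-based model; fields not used by the selected model are
    ignored.
    """

    model: str = "deterministic"
    # landscape geometry & sweep grid
    x_h: int = 50
    x_ipd_min: int = 0
    x_ipd_step: int = 1
    x_max: int = 5000
    d_max: int = 5000
    n_patches: int = 10
    parent_offset: int = 0
    # dispersal kernel calibration
    d05: float = 60.0
    d30: float = 700.0
    s_min: float = 0.5
    s_max: float = 30.0
    # demography
    n_tot: float = 10_000.0
    g: float = 0.3
    c1: float = 1e-4
    # evolution
    s_init: float = 0.5          # deterministic starting seed size
    det_step: float = 0.01       # deterministic mutation step (mm)
    mu: float = 0.001
    n_gens: int = 1000
    s_init_stoch: float = 20.0   # stochastic founder seed size
    # hysteresis detection tolerance (cells of median distance); None = 1 grid step
    tol: float | None = None
    # run management
    replicates: int = 1
    seed: int | None = None
    outdir: str = "results"
    allow_out_of_range: bool = False


#: Model-dependent defaults applied by :func:`default_config`.
_STOCH_DEFAULTS = dict(x_ipd_min=5, x_ipd_step=5, x_max=1000)

#: Parameterizations of the headline figures (first-listed colour where a
#: figure shows several kernels).
PRESETS: dict[str, dict] = {
    "fig3a": dict(model="deterministic", d05=60.0, d30=700.0),
    "fig3b": dict(model="deterministic", d05=30.0, d30=700.0),
    "fig4a": dict(model="stochastic", d05=80.0, d30=700.0),
    "fig4b": dict(model="stochastic", d05=90.0, d30=700.0),
    "fig5": dict(model="deterministic", d05=60.0, d30=700.0),
    "fig6": dict(model="stochastic", d05=90.0, d30=700.0),
}

#: Axes of the sensitivity analysis for the grid presets.
PRESET_AXES: dict[str, dict[str, list]] = {
    "fig5": {
        "x_h": [10, 50, 100, 500],
        "n_tot": [100.0, 1000.0, 100_000.0],
        "g": [0.9, 0.6, 0.1, 0.01],
        "c1": [1e-6, 1e-5, 1e-3, 1e-2],
    },
    "fig6": {
        "n_gens": [10, 100, 1000, 10_000],
        "mu": [0.01, 0.001, 0.0001],
    },
}

_FIELD_NAMES = {f.name for f in dataclasses.fields(RunConfig)}

# (low, high) ranges enforced unless allow_out_of_range; chosen to span the
# conditions explored in the study (kernel medians, sensitivity axes).
_SOFT_RANGES: dict[str, tuple[float, float]] = {
    "d05": (20.0, 300.0),
    "d30": (50.0, 750.0),
    "x_h": (10, 500),
    "n_tot": (100.0, 100_000.0),
    "c1": (1e-6, 1e-2),
    "mu": (0.0001, 0.01),
    "n_gens": (10, 10_000),
}


def default_config(model: str = "deterministic", **overrides) -> RunConfig:
    """A RunConfig with model-appropriate defaults, then ``overrides`` applied."""
    if model not in ("deterministic", "stochastic"):
        raise ConfigError(f"unknown model {model!r}")
    base: dict = {"model": model}
    if model == "stochastic":
        base.update(_STOCH_DEFAULTS)
    unknown = set(overrides) - _FIELD_NAMES
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    base.update(overrides)
    return RunConfig(**base)


def validate_config(cfg: RunConfig) -> RunConfig:
    """Check hard invariants and (unless overridden) the studied ranges."""
    if cfg.model not in ("deterministic", "stochastic"):
        raise ConfigError(f"unknown model {cfg.model!r}")
    hard = [
        (cfg.x_h >= 1, "x_h must be >= 1"),
        (cfg.x_ipd_min >= 0, "x_ipd_min must be >= 0"),
        (cfg.x_ipd_step >= 1, "x_ipd_step must be >= 1"),
        (cfg.x_max >= cfg.x_ipd_min, "x_max must be >= x_ipd_min"),
        (cfg.d_max >= 1, "d_max must be >= 1"),
        (cfg.n_patches >= 1, "n_patches must be >= 1"),
        (0 <= cfg.parent_offset < cfg.x_h, "parent_offset must lie inside a patch"),
        (cfg.d05 > 0 and cfg.d30 > 0, "median distances must be > 0"),
        (cfg.s_min < cfg.s_max, "s_min must be < s_max"),
        (0.0 <= cfg.g <= 1.0, "g must lie in [0, 1]"),
        (cfg.c1 >= 0, "c1 must be >= 0"),
        (0.0 <= cfg.mu <= 1.0, "mu must lie in [0, 1]"),
        (cfg.n_gens >= 1, "n_gens must be >= 1"),
        (cfg.s_min <= cfg.s_init <= cfg.s_max, "s_init outside seed-size bounds"),
        (cfg.s_min <= cfg.s_init_stoch <= cfg.s_max, "s_init_stoch outside bounds"),
        (cfg.replicates >= 1, "replicates must be >= 1"),
        (cfg.det_step > 0, "det_step must be > 0"),
    ]
    for ok, msg in hard:
        if not ok:
            raise ConfigError(msg)
    if not cfg.allow_out_of_range:
        for key, (lo, hi) in _SOFT_RANGES.items():
            val = getattr(cfg, key)
            if not lo <= val <= hi:
                raise ConfigError(
                    f"{key}={val} outside studied range [{lo}, {hi}]"
                    " (set allow_out_of_range to force)"
                )
    return cfg


def load_config(path: str | Path | None = None, **overrides) -> RunConfig:
    """Build a validated RunConfig from a flat YAML file plus overrides.

    Overrides win over the file; the file wins over defaults.  Unknown keys
    raise :class:`ConfigError`.
    """
    data: dict = {}
    if path is not None:
        path = Path(path)
        if not path.exists():
            raise ConfigError(f"config file not found: {path}")
        loaded = yaml.safe_load(path.read_text()) or {}
        if not isinstance(loaded, dict):
            raise ConfigError(f"config file must be a flat key: value mapping: {path}")
        data.update(loaded)
    data.update(overrides)
    model = data.pop("model", "deterministic")
    try:
        cfg = default_config(model, **data)
    except TypeError as exc:  # wrong value type for a field
        raise ConfigError(str(exc)) from exc
    return validate_config(cfg)


def save_config(cfg: RunConfig, path: str | Path) -> Path:
    """Write the config as a flat YAML mapping (lossless round trip)."""
    path = Path(path)
    path.write_text(
        yaml.safe_dump(dataclasses.asdict(cfg), sort_keys=True, default_flow_style=False)
    )
    return path


def config_dict(cfg: RunConfig) -> dict:
    """Plain-dict view (stable key order) for result-file headers."""
    return {k: getattr(cfg, k) for k in sorted(_FIELD_NAMES)}
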