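"""Result serialization: TSV tables with embedded provenance headers.

Every table starts with ``#``-prefixed header lines recording the full run
configuration and the RNG seeds, so any result file can be regenerated from
its own header.  No timestamps are written: identical config + seeds produce
byte-identical files.
"""

from __future__ import annotations

import io as _io
from pathlib import Path

import pandas as pd

from . import __version__
from .config import RunConfig, config_dict
from .sweep import HysteresisSummary, SweepCurve

__all__ = ["write_sweep", "write_hysteresis", "write_grid", "read_table"]

_FLOAT_FMT = "%.10g"


def _header_lines(cfg: RunConfig, seeds: list[int] | None) -> list[str]:
    lines = [f"# seedrift {__version__}"]
    for key, val in config_dict(cfg).items():
        lines.append(f"# {key} = {val}")
    if seeds is not None:
        lines.append(f"# rng_seeds = {','.join(str(s) for s in seeds)}")
    return lines


def _write_table(df: pd.DataFrame, cfg: RunConfig, path: Path,
                 seeds: list[int] | None) -> Path:
    buf = _io.StringIO()
    for line in _header_lines(cfg, seeds):
        buf.write(line + "\n")
    df.to_csv(buf, sep="\t", index=False, float_format=_FLOAT_FMT)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(buf.getvalue())
    return path


def write_sweep(
    curves: list[tuple[SweepCurve, SweepCurve]] | tuple[SweepCurve, SweepCurve],
    cfg: RunConfig,
    path: str | Path,
    seeds: list[int] | None = None,
) -> Path:
    """Write sweep curves (one or more replicates) as one long TSV."""
    if isinstance(curves, tuple):
        curves = [curves]
    frames = []
    for rep, (up, down) in enumerate(curves):
        for curve in (up, down):
            df = curve.to_frame()
            df.insert(0, "replicate", rep)
            if seeds is not None:
                df.insert(1, "rng_seed", seeds[rep])
            frames.append(df)
    return _write_table(pd.concat(frames, ignore_index=True), cfg, Path(path), seeds)


def write_hysteresis(
    summaries: list[HysteresisSummary] | HysteresisSummary,
    cfg: RunConfig,
    path: str | Path,
    seeds: list[int] | None = None,
) -> Path:
    """Write one hysteresis summary row per replicate."""
    if isinstance(summaries, HysteresisSummary):
        summaries = [summaries]
    df = pd.DataFrame(
        {
            "replicate": range(len(summaries)),
            "up_transition": [s.up_transition for s in summaries],
            "down_transition": [s.down_transition for s in summaries],
            "zone_size": [s.zone_size for s in summaries],
        }
    )
    return _write_table(df, cfg, Path(path), seeds)


def write_grid(df: pd.DataFrame, cfg: RunConfig, path: str | Path) -> Path:
    """Write a sensitivity-analysis table (long format, one row per run)."""
    return _write_table(df, cfg, Path(path), None)


def read_table(path: str | Path) -> tuple[pd.DataFrame, dict[str, str]]:
    """Read a seedrift TSV back; returns (data, header key/value pairs)."""
    header: dict[str, str] = {}
    with open(path) as fh:
        lines = fh.readlines()
    body_start = 0
    for i, line in enumerate(lines):
        if not line.startswith("#"):
            body_start = i
            break
        if "=" in line:
            key, _, val = line.lstrip("# ").partition("=")
            header[key.strip()] = val.strip()
    df = pd.read_csv(_io.StringIO("".join(lines[body_start:])), sep="\t")
    return df, header


def plot_sweep(up: SweepCurve, down: SweepCurve, path: str | Path) -> Path:
    """Convenience plot of the two sweep directions (median distance vs x_ipd)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(up.x_ipd, up.median_dispersal_distance, "-", label="increasing $X_{IPD}$")
    ax.plot(down.x_ipd, down.median_dispersal_distance, "--",
            label="decreasing $X_{IPD}$")
    ax.set_xlabel("inter-patch distance (cells)")
    ax.set_ylabel("evolved median dispersal distance (cells)")
    ax.legend()
    fig.tight_layout()
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path
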