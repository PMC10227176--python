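"""1-D riverine landscape: habitat patches separated by uninhabitable matrix.

The river bank is a line of grid cells (1 cell = 1 m).  Habitat patches of
``x_h`` cells alternate with matrix stretches of ``x_ipd`` cells; the pattern
starts with a habitable run at index 0.  Two geometries are used:

* ``bounded`` — a finite downstream window of cells 0 .. d_max, used by the
  deterministic single-plant model (flow is unidirectional, so only the
  window downstream of the focal parent matters).
* ``periodic`` — a ring of ``n_patches`` pattern repeats, used by the
  stochastic individual-based model, where "continuous boundaries" are read
  as wrap-around so that seed mass is conserved.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["Landscape1D", "is_habitable", "habitable_cells", "habitable_mask"]


@dataclass(frozen=True)
class Landscape1D:
    """Geometry of a fragmented 1-D landscape.

    Parameters
    ----------
    x_h : int
        Habitat patch length in cells (>= 1).
    x_ipd : int
        Inter-patch (matrix) distance in cells (>= 0); the fragmentation axis.
    mode : {"bounded", "periodic"}
    d_max : int, optional
        Window length for bounded mode; cells are indexed 0 .. d_max.
    n_patches : int, optional
        Number of pattern repeats for periodic mode; ring length is
        ``n_patches * (x_h + x_ipd)``.
    """

    x_h: int
    x_ipd: int
    mode: str = "bounded"
    d_max: int | None = None
    n_patches: int | None = None

    def __post_init__(self) -> None:
        if self.x_h < 1:
            raise ValueError("x_h must be >= 1")
        if self.x_ipd < 0:
            raise ValueError("x_ipd must be >= 0")
        if self.mode == "bounded":
            if self.d_max is None or self.d_max < 1:
                raise ValueError("bounded mode requires d_max >= 1")
        elif self.mode == "periodic":
            if self.n_patches is None or self.n_patches < 1:
                raise ValueError("periodic mode requires n_patches >= 1")
        else:
            raise ValueError(f"unknown landscape mode {self.mode!r}")

    @property
    def period(self) -> int:
        """Length of one patch + matrix repeat."""
        return self.x_h + self.x_ipd

    @property
    def length(self) -> int:
        """Total number of cells (window size or ring circumference)."""
        if self.mode == "periodic":
            return self.n_patches * self.period
        return self.d_max + 1


def is_habitable(cell, landscape: Landscape1D):
    """True iff the cell falls inside a habitat patch.

    Periodic landscapes wrap any integer index; bounded landscapes reject
    indices outside 0 .. d_max.  Accepts scalars or integer arrays.
    """
    c = np.asarray(cell)
    if landscape.mode == "periodic":
        c = c % landscape.length
    else:
        if np.any(c < 0) or np.any(c > landscape.d_max):
            raise IndexError(f"cell index outside window 0..{landscape.d_max}")
    hab = (c % landscape.period) < landscape.x_h
    return bool(hab) if np.isscalar(cell) or np.asarray(cell).ndim == 0 else hab


def habitable_mask(landscape: Landscape1D, n_cells: int | None = None) -> np.ndarray:
    """Boolean habitability mask over the first ``n_cells`` cells.

    Defaults to the full landscape length.  The mask over 0 .. n_cells-1 is
    identical between modes; periodic wrap only matters for out-of-range
    indices.
    """
    n = landscape.length if n_cells is None else n_cells
    return (np.arange(n) % landscape.period) < landscape.x_h


def habitable_cells(landscape: Landscape1D) -> np.ndarray:
    """Ascending indices of all habitable cells in the landscape."""
    return np.flatnonzero(habitable_mask(landscape))
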