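"""Shared in-memory data structures.

Tabular data (cell tables, event streams, axial profiles) are plain pandas
DataFrames with documented column conventions; only the gridded velocity
field gets a dedicated container.

Column conventions
------------------
CellTable      : gonad_id (str), x (fraction in [0, 1]), volume_fl (> 0),
                 alive (bool)
EventStream    : x (fraction), t_h (hours), type ("apoptosis" | "mitosis")
AxialProfile   : x (fraction) plus any of Qr, Qc, J, S, Pc, Pr, Qr_smooth
                 and *_lo / *_hi confidence columns.  Fluxes are fl/min;
                 J and S are fl/min per unit fractional length.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["VelocityField", "GeometryError"]

CELL_COLUMNS = ["gonad_id", "x", "volume_fl", "alive"]
EVENT_COLUMNS = ["x", "t_h", "type"]


class GeometryError(ValueError):
    """Raised for inconsistent geometric inputs (negative radii, short centrelines)."""


@dataclass
class VelocityField:
    """Mid-plane 2D velocity field on a regular pixel grid.

    Axes follow image convention: ``u[row, col]`` is the axial (column-wise)
    velocity component and ``v[row, col]`` the transverse (row-wise) one,
    both in um/s.  ``mask`` flags pixels inside the rachis lumen.
    ``centreline`` is an ordered (n, 2) array of (axial_um, transverse_um)
    points.  ``valid`` (optional) flags grid points where the velocity
    estimate is trustworthy (PIV correlation above threshold).
    """

    u: np.ndarray
    v: np.ndarray
    mask: np.ndarray
    centreline: np.ndarray
    pixel_size: float
    valid: np.ndarray | None = None
    # (row_um, col_um) of the first grid point; defaults to half a spacing
    origin_um: tuple[float, float] | None = None
    # number of invalid PIV vectors filled from neighbours
    n_filled: int = 0

    def __post_init__(self) -> None:
        self.u = np.asarray(self.u, dtype=float)
        self.v = np.asarray(self.v, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        self.centreline = np.asarray(self.centreline, dtype=float)
        if self.u.shape != self.v.shape or self.u.shape != self.mask.shape:
            raise GeometryError("u, v and mask must share a shape")
        if self.centreline.ndim != 2 or self.centreline.shape[1] != 2:
            raise GeometryError("centreline must be an (n, 2) point list")
        if self.pixel_size <= 0:
            raise GeometryError("pixel_size must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.u.shape

    def speed(self) -> np.ndarray:
        return np.hypot(self.u, self.v)
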