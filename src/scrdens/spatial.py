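"""Trap-point geometry and habitat-mask (state space) construction.

The habitat mask discretises the region of integration for activity
centers: a regular grid of points, each owning ``cell_area`` km².  The
default mask is buffer-clipped — only points within ``buffer`` km of at
least one detector are kept — mirroring the convention of defining the
state space as a fixed radius around the traps (3-sigma by rule of thumb).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.spatial.distance import cdist

from .io import TrapArray

__all__ = ["HabitatMask", "pairwise_distances", "build_mask", "mask_area"]


@dataclass
class HabitatMask:
    points: np.ndarray          # (M, 2) km
    cell_area: float            # km^2 per point
    buffer: float               # km
    nx: int
    ny: int
    spacing: tuple[float, float]  # (dx, dy) km
    clipped: bool = False
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 2:
            raise ValueError("mask points must be (M, 2)")
        if self.cell_area <= 0:
            raise ValueError("cell_area must be positive")

    @property
    def n_points(self) -> int:
        return self.points.shape[0]

    @property
    def area(self) -> float:
        return mask_area(self)


def pairwise_distances(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Euclidean distance matrix (km) between two planar point sets."""
    a = np.atleast_2d(np.asarray(a, dtype=float))
    b = np.atleast_2d(np.asarray(b, dtype=float))
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValueError("coordinates must be finite")
    return cdist(a, b)


def build_mask(
    traps: TrapArray,
    buffer: float,
    nx: int = 64,
    clip: bool = True,
    ny: Optional[int] = None,
) -> HabitatMask:
    """Build a habitat mask over the buffered bounding box of the traps.

    An ``nx`` x ``ny`` point lattice spans the traps' bounding box expanded
    by ``buffer`` on every side, with grid points inclusive of the expanded
    edges.  ``ny`` defaults to whatever keeps cells closest to square.
    With ``clip=True`` only points within ``buffer`` of >=1 trap survive.
    """
    if buffer <= 0:
        raise ValueError("buffer must be positive")
    if nx < 2:
        raise ValueError("nx must be at least 2")
    xlo, xhi = traps.x.min() - buffer, traps.x.max() + buffer
    ylo, yhi = traps.y.min() - buffer, traps.y.max() + buffer
    dx = (xhi - xlo) / (nx - 1)
    if ny is None:
        ny = max(2, int(round((yhi - ylo) / dx)) + 1)
    dy = (yhi - ylo) / (ny - 1)
    xs = np.linspace(xlo, xhi, nx)
    ys = np.linspace(ylo, yhi, ny)
    gx, gy = np.meshgrid(xs, ys, indexing="ij")
    points = np.column_stack([gx.ravel(), gy.ravel()])
    cell_area = dx * dy
    if clip:
        dmin = cdist(points, traps.xy).min(axis=1)
        keep = dmin <= buffer
        if not keep.any():
            raise ValueError("buffer too small: clipping removed every mask point")
        points = points[keep]
    return HabitatMask(
        points=points,
        cell_area=cell_area,
        buffer=buffer,
        nx=nx,
        ny=ny,
        spacing=(dx, dy),
        clipped=clip,
    )


def mask_area(mask: HabitatMask) -> float:
    """Total state-space area in km² (point count times cell area)."""
    return mask.n_points * mask.cell_area
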