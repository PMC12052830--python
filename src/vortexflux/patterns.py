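"""Targeted coordinate patterns (TCPs): where the dark spot is placed.

One localization exposes the emitter to the doughnut beam at a small set
of K positions.  Two standard layouts are provided:

* ``four_point`` — the classic MINFLUX pattern: three exposures equally
  spaced on a circle of diameter L plus one at the pattern center.
* ``raster`` — the RASTMIN pattern: a dim x dim square grid spanning
  an L x L box.

Both are centered on the origin; L is the ring diameter for the
four-point pattern and the side length for the raster grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["ExposurePattern", "make_four_point_tcp", "make_raster_tcp"]


@dataclass(frozen=True)
class ExposurePattern:
    """An ordered set of beam-center positions (nm) with its metadata."""

    kind: str
    size: float
    positions: np.ndarray = field(repr=False)
    raster_dim: int | None = None

    def __post_init__(self) -> None:
        pos = np.atleast_2d(np.asarray(self.positions, dtype=float))
        if pos.shape[1] != 2:
            raise ValueError("positions must be an (K, 2) array")
        object.__setattr__(self, "positions", pos)
        if self.size <= 0:
            raise ValueError(f"pattern size L must be positive, got {self.size}")

    @property
    def n_exposures(self) -> int:
        return self.positions.shape[0]

    def to_csv(self, path) -> None:
        df = pd.DataFrame(
            {
                "index": np.arange(self.n_exposures),
                "x_nm": self.positions[:, 0],
                "y_nm": self.positions[:, 1],
            }
        )
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, kind: str = "custom", size: float | None = None,
                 raster_dim: int | None = None) -> "ExposurePattern":
        df = pd.read_csv(path).sort_values("index")
        pos = df[["x_nm", "y_nm"]].to_numpy(dtype=float)
        if size is None:
            # fall back to the pattern's spatial extent
            size = float(2.0 * np.max(np.hypot(pos[:, 0], pos[:, 1])))
        return cls(kind=kind, size=size, positions=pos, raster_dim=raster_dim)


def make_four_point_tcp(L: float, variant: str = "center") -> ExposurePattern:
    """Four-point MINFLUX pattern of diameter ``L`` (nm).

    ``variant="center"`` (default): three exposures on a circle of radius
    L/2 at 90, 210 and 330 degrees, plus one exposure at the origin.
    ``variant="ring"``: four exposures on the ring (90-degree spacing),
    none at the center — provided for sensitivity analysis.
    """
    if L <= 0:
        raise ValueError(f"pattern size L must be positive, got {L}")
    radius = L / 2.0
    if variant == "center":
        angles = np.deg2rad([90.0, 210.0, 330.0])
        ring = radius * np.c_[np.cos(angles), np.sin(angles)]
        pos = np.vstack([[0.0, 0.0], ring])
    elif variant == "ring":
        angles = np.deg2rad([90.0, 180.0, 270.0, 360.0])
        pos = radius * np.c_[np.cos(angles), np.sin(angles)]
    else:
        raise ValueError(f"unknown four-point variant {variant!r}")
    return ExposurePattern(kind="four_point", size=float(L), positions=pos)


def make_raster_tcp(L: float, dim: int = 5) -> ExposurePattern:
    """Square raster-scan pattern: ``dim x dim`` grid over an L x L box.

    Grid spacing is ``L / (dim - 1)``; the grid is centered on the origin.
    """
    if L <= 0:
        raise ValueError(f"pattern size L must be positive, got {L}")
    if dim < 2:
        raise ValueError(f"raster grid dimension must be >= 2, got {dim}")
    axis = np.linspace(-L / 2.0, L / 2.0, dim)
    xx, yy = np.meshgrid(axis, axis, indexing="xy")
    pos = np.c_[xx.ravel(), yy.ravel()]
    return ExposurePattern(
        kind="raster", size=float(L), positions=pos, raster_dim=int(dim)
    )
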