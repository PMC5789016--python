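"""Regular xy grids and gridded scalar maps.

A ScalarMap2D is the common product of the order / density / thickness
analyses: per-cell mean values with per-cell sample counts.  Cells that
received no samples hold NaN, never 0.0 — zero is a legal value for every
quantity mapped here.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["GridSpec", "ScalarMap2D", "GridMismatchError"]


class GridMismatchError(ValueError):
    """Two maps do not share a grid."""


@dataclass(frozen=True)
class GridSpec:
    """Uniform grid over the periodic xy plane.

    The grid must span the box exactly: ``n * cell == box length``.
    Binning is half-open, ``cell i = [origin + i*cell, origin + (i+1)*cell)``,
    with periodic wrapping.
    """

    origin: tuple[float, float]
    n_x: int
    n_y: int
    cell: float  # nm, square cells

    def __post_init__(self) -> None:
        if self.cell <= 0:
            raise ValueError("cell size must be positive")
        if self.n_x < 1 or self.n_y < 1:
            raise ValueError("grid needs at least one cell per axis")

    @classmethod
    def for_box(cls, box, cell: float = 1.0) -> "GridSpec":
        """Grid covering a periodic box, adjusting the cell to divide it exactly."""
        lx, ly = float(box[0]), float(box[1])
        n_x = max(1, int(round(lx / cell)))
        n_y = max(1, int(round(ly / cell)))
        c = lx / n_x
        if abs(ly / n_y - c) > 1e-9:
            # non-square boxes: keep x-derived cell, recompute n_y to span y
            n_y = max(1, int(round(ly / c)))
            if abs(n_y * c - ly) > 1e-6:
                raise ValueError(
                    f"cell {c:.6f} nm cannot tile a {lx} x {ly} nm box exactly"
                )
        return cls(origin=(0.0, 0.0), n_x=n_x, n_y=n_y, cell=c)

    @property
    def extent(self) -> tuple[float, float]:
        return (self.n_x * self.cell, self.n_y * self.cell)

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        x = self.origin[0] + (np.arange(self.n_x) + 0.5) * self.cell
        y = self.origin[1] + (np.arange(self.n_y) + 0.5) * self.cell
        return x, y

    def bin_index(self, xy: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Periodic half-open cell indices of xy points, shape (n, 2) or (2,)."""
        xy = np.atleast_2d(np.asarray(xy, dtype=float))
        ix = np.floor((xy[:, 0] - self.origin[0]) / self.cell).astype(int) % self.n_x
        iy = np.floor((xy[:, 1] - self.origin[1]) / self.cell).astype(int) % self.n_y
        return ix, iy

    def matches(self, other: "GridSpec", tol: float = 1e-9) -> bool:
        return (
            self.n_x == other.n_x
            and self.n_y == other.n_y
            and abs(self.cell - other.cell) < tol
            and abs(self.origin[0] - other.origin[0]) < tol
            and abs(self.origin[1] - other.origin[1]) < tol
        )


@dataclass
class ScalarMap2D:
    """Gridded leaflet observable: per-cell value + sample count + metadata."""

    grid: GridSpec
    values: np.ndarray  # (n_x, n_y) float, NaN where count == 0
    counts: np.ndarray  # (n_x, n_y) int
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.counts = np.asarray(self.counts, dtype=int)
        shape = (self.grid.n_x, self.grid.n_y)
        if self.values.shape != shape or self.counts.shape != shape:
            raise ValueError(f"values/counts must have shape {shape}")
        if np.any(self.counts < 0):
            raise ValueError("negative sample counts")
        empty = self.counts == 0
        if not np.all(np.isnan(self.values[empty])):
            raise ValueError("cells with count 0 must be NaN")
        if not np.all(np.isfinite(self.values[~empty])):
            raise ValueError("non-finite value in an occupied cell")

    @property
    def occupied(self) -> np.ndarray:
        return self.counts > 0

    def summary(self) -> dict:
        occ = self.occupied
        vals = self.values[occ]
        return {
            "occupied_cells": int(occ.sum()),
            "mean": float(np.mean(vals)) if vals.size else float("nan"),
            "std": float(np.std(vals)) if vals.size else float("nan"),
            "min": float(np.min(vals)) if vals.size else float("nan"),
            "max": float(np.max(vals)) if vals.size else float("nan"),
        }

    # ---- serialization: long-format CSV --------------------------------

    def to_dataframe(self) -> pd.DataFrame:
        xc, yc = self.grid.cell_centers()
        ix, iy = np.meshgrid(
            np.arange(self.grid.n_x), np.arange(self.grid.n_y), indexing="ij"
        )
        return pd.DataFrame(
            {
                "ix": ix.ravel(),
                "iy": iy.ravel(),
                "x_center": xc[ix.ravel()],
                "y_center": yc[iy.ravel()],
                "value": self.values.ravel(),
                "count": self.counts.ravel(),
            }
        )

    def to_csv(self, path, header_comments: dict | None = None) -> None:
        buf = _io.StringIO()
        meta = dict(self.metadata)
        if header_comments:
            meta.update(header_comments)
        for key, val in sorted(meta.items()):
            buf.write(f"# {key}={val}\n")
        buf.write(
            f"# grid: origin=({self.grid.origin[0]:.6f},{self.grid.origin[1]:.6f})"
            f" n_x={self.grid.n_x} n_y={self.grid.n_y} cell={self.grid.cell:.9f}\n"
        )
        self.to_dataframe().to_csv(buf, index=False)
        with open(path, "w") as fh:
            fh.write(buf.getvalue())

    @classmethod
    def from_csv(cls, path) -> "ScalarMap2D":
        grid = None
        metadata = {}
        with open(path) as fh:
            for line in fh:
                if not line.startswith("#"):
                    break
                body = line[1:].strip()
                if body.startswith("grid:"):
                    parts = dict(
                        p.split("=", 1) for p in body[len("grid:") :].split()
                    )
                    ox, oy = parts["origin"].strip("()").split(",")
                    grid = GridSpec(
                        origin=(float(ox), float(oy)),
                        n_x=int(parts["n_x"]),
                        n_y=int(parts["n_y"]),
                        cell=float(parts["cell"]),
                    )
                elif "=" in body:
                    k, v = body.split("=", 1)
                    metadata[k.strip()] = v.strip()
        if grid is None:
            raise ValueError(f"{path}: missing '# grid:' header line")
        df = pd.read_csv(path, comment="#")
        values = np.full((grid.n_x, grid.n_y), np.nan)
        counts = np.zeros((grid.n_x, grid.n_y), dtype=int)
        values[df["ix"], df["iy"]] = df["value"]
        counts[df["ix"], df["iy"]] = df["count"]
        values[counts == 0] = np.nan
        return cls(grid=grid, values=values, counts=counts, metadata=metadata)

    def render(self, path, cmap: str = "viridis", label: str | None = None) -> None:
        """Save a simple image of the map (matplotlib, Agg backend)."""
        import matplotlib

        matplotlib.use("Agg", force=False)
        import matplotlib.pyplot as plt

        ex, ey = self.grid.extent
        fig, ax = plt.subplots(figsize=(5, 4.2))
        im = ax.imshow(
            self.values.T,
            origin="lower",
            extent=(
                self.grid.origin[0],
                self.grid.origin[0] + ex,
                self.grid.origin[1],
                self.grid.origin[1] + ey,
            ),
            cmap=cmap,
            interpolation="nearest",
        )
        ax.set_xlabel("x (nm)")
        ax.set_ylabel("y (nm)")
        fig.colorbar(im, ax=ax, label=label or self.metadata.get("quantity", ""))
        fig.tight_layout()
        fig.savefig(path, dpi=150)
        plt.close(fig)
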