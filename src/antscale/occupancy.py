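"""Spanned area on a square occupancy grid.

The enclosure is divided into an n×n grid (default 24×24); a cell counts
as visited if any sample of any worker (active or not) falls inside it,
and the spanned area is the visited-cell count times the cell area.

The default cell length tiles the enclosure exactly
(enclosure/24 ≈ 10.33 mm for the 248 mm enclosure). A fixed cell length
(e.g. 10.6 mm, matching the interaction area πd² ≈ 10.6²) can be forced
via ``cell_length``; the grid is then anchored at the origin and may
extend past the far wall.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .records import ColonyRecord, Trajectory


@dataclass
class OccupancyGrid:
    """Visited-cell set and the implied spanned area."""

    n_cells_side: int
    cell_length: float  # mm
    visited: set  # of (row, col)

    @property
    def area(self) -> float:
        """Spanned area in mm²."""
        return len(self.visited) * self.cell_length**2


def _cell_indices(xy: np.ndarray, cell_length: float, n_cells_side: int) -> np.ndarray:
    # boundary points go to the higher-index cell; the far enclosure edge
    # belongs to the last cell
    idx = np.floor(xy / cell_length).astype(int)
    return np.clip(idx, 0, n_cells_side - 1)


def spanned_area(
    trajs: Sequence[Trajectory],
    record: ColonyRecord,
    n_cells_side: int = 24,
    cell_length: float | None = None,
) -> OccupancyGrid:
    """Occupancy grid for one colony; ``grid.area`` is the spanned area."""
    if n_cells_side < 1:
        raise ValueError(f"n_cells_side must be >= 1, got {n_cells_side}")
    trajs = [t for t in trajs if t.colony_id == record.colony_id]
    if not trajs:
        raise ValueError(f"no trajectories for colony {record.colony_id}")
    if cell_length is None:
        cell_length = record.enclosure_mm / n_cells_side
    visited: set[tuple[int, int]] = set()
    for tr in trajs:
        idx = _cell_indices(tr.xy, cell_length, n_cells_side)
        visited.update((int(r), int(c)) for c, r in idx)  # (row, col) = (y-cell, x-cell)
    return OccupancyGrid(n_cells_side=n_cells_side, cell_length=cell_length, visited=visited)


def occupancy_heatmap(
    trajs: Sequence[Trajectory],
    record: ColonyRecord,
    n_cells_side: int = 24,
    cell_length: float | None = None,
) -> np.ndarray:
    """Per-cell sample counts (rows = y cells, columns = x cells).

    The matrix total equals the total number of position samples.
    """
    if n_cells_side < 1:
        raise ValueError(f"n_cells_side must be >= 1, got {n_cells_side}")
    trajs = [t for t in trajs if t.colony_id == record.colony_id]
    if cell_length is None:
        cell_length = record.enclosure_mm / n_cells_side
    counts = np.zeros((n_cells_side, n_cells_side), dtype=int)
    for tr in trajs:
        idx = _cell_indices(tr.xy, cell_length, n_cells_side)
        np.add.at(counts, (idx[:, 1], idx[:, 0]), 1)
    return counts
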