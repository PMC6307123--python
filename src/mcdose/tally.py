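"""Dose tallies with history-by-history statistics.

Deposits are grouped per primary history before entering the accumulators:
all deposits made by one history and its progeny (split copies, delta rays,
annihilation photons) are summed into a single per-voxel contribution, and
the accumulators store sum(x) and sum(x^2) of those per-history
contributions.  This is the grouped (history-by-history) variance estimator;
a naive per-deposit estimator would underestimate the variance because
deposits within a history are correlated.

Dose is reported per source particle in MeV/g (multiply by 1.602e-10 for
Gy per history); absolute calibration is out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.interpolate import RegularGridInterpolator

from .geometry import VoxelGrid

__all__ = ["DoseGrid", "report_uncertainty", "refine_dose"]


@dataclass
class DoseGrid:
    """Per-voxel dose accumulators on a voxel grid."""

    grid: VoxelGrid
    edep: np.ndarray = None        # flat, sum of per-history deposits (MeV)
    edep_sq: np.ndarray = None     # flat, sum of squared per-history deposits
    n_hist: int = 0

    def __post_init__(self):
        n = int(np.prod(self.grid.shape))
        if self.edep is None:
            self.edep = np.zeros(n)
        if self.edep_sq is None:
            self.edep_sq = np.zeros(n)

    # -- accumulation -----------------------------------------------------
    def add_batch(self, hist: np.ndarray, voxel: np.ndarray, edep: np.ndarray) -> None:
        """Accumulate deposit records (history id, flat voxel, energy MeV).

        Records from the same (history, voxel) pair are summed before being
        squared, implementing the grouped estimator.  Does not change
        ``n_hist``; call :meth:`add_histories` with the number of primaries
        (including histories that deposited nothing).
        """
        if len(edep) == 0:
            return
        order = np.lexsort((voxel, hist))
        h, v, e = hist[order], voxel[order], edep[order]
        new = np.empty(len(e), dtype=bool)
        new[0] = True
        new[1:] = (h[1:] != h[:-1]) | (v[1:] != v[:-1])
        starts = np.flatnonzero(new)
        sums = np.add.reduceat(e, starts)
        vox_u = v[starts]
        np.add.at(self.edep, vox_u, sums)
        np.add.at(self.edep_sq, vox_u, sums * sums)

    def add_histories(self, n: int) -> None:
        self.n_hist += int(n)

    def merge(self, other: "DoseGrid") -> "DoseGrid":
        """Exact merge of tallies from disjoint history sets."""
        if self.grid.shape != other.grid.shape or not np.allclose(
                self.grid.spacing, other.grid.spacing) or not np.allclose(
                self.grid.origin, other.grid.origin):
            raise ValueError("cannot merge tallies on different grids")
        return DoseGrid(self.grid, self.edep + other.edep,
                        self.edep_sq + other.edep_sq, self.n_hist + other.n_hist)

    # -- reporting --------------------------------------------------------
    @property
    def _mass_flat(self) -> np.ndarray:
        return (self.grid.density * self.grid.voxel_volume).ravel()

    def dose(self) -> np.ndarray:
        """Mean dose per history (MeV/g), shaped like the grid."""
        m = np.maximum(self._mass_flat, 1e-300)
        return (self.edep / (max(self.n_hist, 1) * m)).reshape(self.grid.shape)

    def sigma(self) -> np.ndarray:
        """Standard uncertainty of the per-history mean dose (MeV/g)."""
        n = max(self.n_hist, 1)
        var = np.maximum(self.edep_sq / n - (self.edep / n) ** 2, 0.0) / n
        m = np.maximum(self._mass_flat, 1e-300)
        return (np.sqrt(var) / m).reshape(self.grid.shape)

    def total_energy(self) -> float:
        return float(self.edep.sum())


def report_uncertainty(dose_grid: DoseGrid, threshold: float = 0.5,
                       n_sigma: float = 1.0) -> float:
    """Average relative uncertainty (percent, ``n_sigma`` multiples) over
    voxels scoring more than ``threshold`` of the maximum dose."""
    d = dose_grid.dose()
    s = dose_grid.sigma()
    dmax = d.max()
    if dmax <= 0:
        raise ValueError("empty dose grid")
    mask = d > threshold * dmax
    return float(np.mean(n_sigma * s[mask] / d[mask]) * 100.0)


def refine_dose(coarse_grid: VoxelGrid, coarse_values: np.ndarray,
                target_grid: VoxelGrid) -> np.ndarray:
    """Trilinear interpolation of coarse voxel-center values onto the target
    grid's voxel centers; coordinates outside the coarse center lattice are
    clamped (edge voxels hold the boundary value, flagged approximate)."""
    axes = [coarse_grid.centers(k) for k in range(3)]
    interp = RegularGridInterpolator(axes, np.asarray(coarse_values, dtype=float),
                                     method="linear", bounds_error=False)
    pts = np.stack(np.meshgrid(*[target_grid.centers(k) for k in range(3)],
                               indexing="ij"), axis=-1).reshape(-1, 3)
    for k in range(3):
        pts[:, k] = np.clip(pts[:, k], axes[k][0], axes[k][-1])
    return interp(pts).reshape(target_grid.shape)
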