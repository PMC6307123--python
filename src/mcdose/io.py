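"""Gridded-volume container and profile export.

Volumes (phantoms and dose grids) are stored in a single ``.mvox`` file: a
numpy ``.npz`` archive holding the grid metadata (origin, spacing,
materials) and named data planes (``material``, ``density`` and optionally
``dose``/``sigma``).  Dose profiles along a named axis export to CSV.
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional, Tuple

import numpy as np

from .geometry import VoxelGrid
from .tally import DoseGrid

__all__ = ["save_volume", "load_volume", "save_dose", "load_dose", "export_profile"]


def save_volume(path, grid: VoxelGrid, **planes) -> None:
    np.savez_compressed(Path(path), origin=grid.origin, spacing=grid.spacing,
                        material=grid.material, density=grid.density,
                        materials=np.array(grid.materials),
                        orientation=grid.orientation, **planes)


def load_volume(path) -> Tuple[VoxelGrid, dict]:
    with np.load(Path(path), allow_pickle=False) as z:
        grid = VoxelGrid(z["origin"], z["spacing"], z["material"], z["density"],
                         materials=tuple(str(m) for m in z["materials"]),
                         orientation=z["orientation"])
        planes = {k: z[k] for k in z.files
                  if k not in ("origin", "spacing", "material", "density",
                               "materials", "orientation")}
    return grid, planes


def save_dose(path, tally: DoseGrid) -> None:
    save_volume(path, tally.grid, dose=tally.dose(), sigma=tally.sigma(),
                n_hist=np.array(tally.n_hist))


def load_dose(path) -> Tuple[VoxelGrid, np.ndarray, np.ndarray]:
    grid, planes = load_volume(path)
    if "dose" not in planes:
        raise ValueError(f"{path}: no dose plane")
    return grid, planes["dose"], planes.get("sigma")


def export_profile(path, grid: VoxelGrid, dose: np.ndarray, axis: str,
                   sigma: Optional[np.ndarray] = None, **fixed) -> None:
    """CSV dose profile along ``axis`` ('x'|'y'|'z') through the voxel
    nearest the fixed coordinates of the other axes (cm, default 0)."""
    ax = "xyz".index(axis)
    idx = [0, 0, 0]
    for k in range(3):
        if k == ax:
            continue
        want = fixed.get("xyz"[k], 0.0)
        idx[k] = int(np.argmin(np.abs(grid.centers(k) - want)))
    sl = tuple(slice(None) if k == ax else idx[k] for k in range(3))
    cols = [grid.centers(ax), dose[sl]]
    header = f"{axis}_cm,dose"
    if sigma is not None:
        cols.append(sigma[sl])
        header += ",sigma"
    np.savetxt(Path(path), np.column_stack(cols), delimiter=",", header=header, comments="")
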