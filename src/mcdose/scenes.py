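"""Benchmark scenes and the simulation driver.

Scene builders reproduce the standard verification setups: a homogeneous
water phantom (40x40x30 cm^3, 0.2x0.2x0.5 cm^3 bins), a seven-layer slab
phantom (40x40x35 cm^3, 0.5x0.5x0.25 cm^3 bins; muscle/air/lung/muscle/
bone/lung/muscle from the upstream surface) and a parametric MLC scene over
the water phantom.  Builders are pure: the same spec yields bit-identical
grids.

``run_simulation`` executes a configuration: histories are allocated to
control points by meterset weight, partitioned over independent
counter-based random streams, and merged exactly; the per-history energy
audit from the engine is asserted on every run.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .geometry import MixedGeometry, VoxelGrid
from .machine import LeafBankSpec, MachineConfig, MachineModel
from .materials import MaterialTable, default_registry
from .plans import Plan, allocate_histories
from .rng import stream_generator
from .sources import AnalyticBeam
from .tally import DoseGrid
from .transport import TransportEngine, TransportSettings

__all__ = ["build_water_phantom", "build_multilayer_phantom", "build_mlc_scene",
           "default_mlc_pattern", "RunConfig", "run_simulation"]

_MATERIALS = ("water", "air", "muscle", "lung", "bone", "tungsten")
_DENSITY = {"water": 1.0, "air": 1.20479e-3, "muscle": 1.04, "lung": 0.3,
            "bone": 1.85, "tungsten": 19.3}


def _uniform_grid(size, spacing, material_name) -> VoxelGrid:
    size = np.asarray(size, dtype=float)
    spacing = np.asarray(spacing, dtype=float)
    shape = np.round(size / spacing).astype(int)
    origin = np.array([-size[0] / 2, -size[1] / 2, -size[2]])
    mi = _MATERIALS.index(material_name)
    return VoxelGrid(origin, spacing,
                     np.full(tuple(shape), mi, dtype=np.int16),
                     np.full(tuple(shape), _DENSITY[material_name]),
                     materials=_MATERIALS)


def build_water_phantom(size=(40.0, 40.0, 30.0), spacing=(0.2, 0.2, 0.5)) -> VoxelGrid:
    """Homogeneous water phantom; default 40x40x30 cm^3 with
    0.2x0.2x0.5 cm^3 bins -> (200, 200, 60) voxels.  The surface is at
    z = 0 (SSD 100 cm for the default source at z = +100)."""
    return _uniform_grid(size, spacing, "water")


def build_multilayer_phantom(spacing=(0.5, 0.5, 0.25)) -> VoxelGrid:
    """Seven 5-cm slab layers, 40x40x35 cm^3, default bins
    0.5x0.5x0.25 cm^3 -> (80, 80, 140) voxels.  Layers from the upstream
    (z = 0) surface: muscle, air, lung, muscle, bone, lung, muscle."""
    grid = _uniform_grid((40.0, 40.0, 35.0), spacing, "water")
    layers = ["muscle", "air", "lung", "muscle", "bone", "lung", "muscle"]
    zc = grid.centers(2)
    depth = -zc                       # cm below the upstream surface at z=0
    mat = grid.material.copy()
    rho = grid.density.copy()
    for k, name in enumerate(layers):
        sel = (depth >= 5.0 * k) & (depth < 5.0 * (k + 1))
        mat[:, :, sel] = _MATERIALS.index(name)
        rho[:, :, sel] = _DENSITY[name]
    return VoxelGrid(grid.origin, grid.spacing, mat, rho, materials=_MATERIALS)


def default_mlc_pattern(n_pairs: int = 10, field_half: float = 7.0) -> MachineConfig:
    """A leaf pattern exercising the MLC's critical regions in one shot:
    a closed central pair (opposed rounded tips meeting at x=0), a
    tongue-and-groove stretch beside it, and an open segment."""
    a = np.full(n_pairs, -field_half)
    b = np.full(n_pairs, field_half)
    mid = n_pairs // 2
    a[mid], b[mid] = -0.01, 0.01          # closed central pair
    if mid + 1 < n_pairs:
        a[mid + 1], b[mid + 1] = -field_half, 0.0   # half-closed: T&G transition
    return MachineConfig(a, b, jaws_x=(-field_half - 1, field_half + 1),
                         jaws_y=(-field_half - 1, field_half + 1))


def build_mlc_scene(config: Optional[MachineConfig] = None,
                    spec: Optional[LeafBankSpec] = None,
                    phantom: Optional[VoxelGrid] = None,
                    world_material: str = "air") -> MixedGeometry:
    """Parametric two-bank MLC (plus jaws) above a water phantom."""
    spec = spec or LeafBankSpec()
    config = config if config is not None else default_mlc_pattern(spec.n_pairs)
    phantom = phantom if phantom is not None else build_water_phantom()
    model = MachineModel(spec)
    bodies = model.bodies(config)
    return MixedGeometry(bodies, phantom, z_interface=float(phantom.upper[2]),
                         world_material=world_material)


# ---------------------------------------------------------------------------
# simulation driver

@dataclass
class RunConfig:
    """Everything needed to reproduce a run."""

    geometry: object                   # VoxelGrid or MixedGeometry (static part)
    source: object = field(default_factory=AnalyticBeam)
    histories: int = 100000
    seed: int = 1
    streams: int = 1
    settings: TransportSettings = field(default_factory=TransportSettings)
    plan: Optional[Plan] = None
    machine_model: Optional[MachineModel] = None
    registry: Optional[Dict[str, MaterialTable]] = None

    def __post_init__(self):
        if self.histories < 0 or self.streams < 1:
            raise ValueError("histories must be >= 0 and streams >= 1")


def _split_counts(n: int, k: int) -> np.ndarray:
    base = np.full(k, n // k, dtype=np.int64)
    base[: n % k] += 1
    return base


def run_simulation(config: RunConfig, log=None) -> Tuple[DoseGrid, dict]:
    """Run a (possibly dynamic) simulation.

    Histories are apportioned to control points by cumulative meterset
    weight, then split across ``streams`` independent Philox streams keyed
    by (seed, stream, control point); tallies merge exactly, so the output
    is bitwise reproducible for a fixed (seed, streams) pair.
    """
    grid = config.geometry.grid if isinstance(config.geometry, MixedGeometry) \
        else config.geometry
    total = DoseGrid(grid)
    audit_all = {"source": 0.0, "deposited": 0.0, "machine": 0.0, "escaped": 0.0,
                 "max_violation": 0.0, "histories": 0}
    if config.plan is not None:
        if config.machine_model is None:
            raise ValueError("a plan requires a machine model")
        per_cp = allocate_histories(config.histories, config.plan)
        cps = config.plan.control_points
    else:
        per_cp = np.array([config.histories])
        cps = [None]
    for ci, (cp, n_cp) in enumerate(zip(cps, per_cp)):
        if n_cp == 0:
            continue
        if cp is None:
            geometry = config.geometry
        else:
            grid_cp = grid
            bodies = config.machine_model.bodies(cp.machine_config())
            geometry = MixedGeometry(bodies, grid_cp, z_interface=float(grid_cp.upper[2]),
                                     world_material=getattr(config.geometry,
                                                            "world_material", "air"))
        engine = TransportEngine(geometry, registry=config.registry,
                                 settings=config.settings)
        for si, n_s in enumerate(_split_counts(int(n_cp), config.streams)):
            if n_s == 0:
                continue
            rng = stream_generator(config.seed, si, ci)
            part, audit = engine.run(config.source, int(n_s), rng)
            total = total.merge(part)
            for k in ("source", "deposited", "machine", "escaped"):
                audit_all[k] += audit[k]
            audit_all["max_violation"] = max(audit_all["max_violation"],
                                             audit["max_violation"])
            audit_all["histories"] += int(n_s)
            if log is not None:
                log(f"control point {ci}: stream {si}: {n_s} histories, "
                    f"audit violation {audit['max_violation']:.2e}")
    if audit_all["max_violation"] > 1e-9:
        raise AssertionError(
            f"energy conservation audit failed: {audit_all['max_violation']:.3e}")
    return total, audit_all
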