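"""Parametric machine head: MLC leaf bank and jaws as quadric bodies.

The multileaf collimator is a parametric two-bank leaf set: rectangular
leaves with cylindrical (rounded) tips and an optional tongue-and-groove
step on one side, characterized by leaf count, width, thickness and tip
radius.  Leaf and jaw positions are specified at the isocenter plane and
projected to the physical leaf plane through the point source.  Gantry and
collimator rotations are rigid rotations of the machine region about the
isocenter; the couch rotation is stored inversely on the voxel grid's
orientation metadata.

Rotation sense follows the IEC convention: gantry about +y, collimator and
couch about +z (the beam axis at gantry zero points along -z).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .geometry import Body, Quadric, VoxelGrid, rotation_matrix

__all__ = ["LeafBankSpec", "MachineConfig", "MachineModel", "build_leaf_bank",
           "apply_machine_configuration"]


@dataclass(frozen=True)
class LeafBankSpec:
    """Geometry of the parametric MLC (all lengths cm)."""

    n_pairs: int = 10
    leaf_width_iso: float = 1.0        # projected width at the isocenter plane
    leaf_length: float = 14.0          # along travel (x)
    thickness: float = 6.0             # along beam (z)
    z_center: float = 46.0             # height of the leaf mid-plane above isocenter
    tip_radius: float = 8.0
    tongue_width_iso: float = 0.08     # 0 disables tongue-and-groove
    source_z: float = 100.0
    min_gap: float = 0.02              # minimum opposing tip gap at isocenter
    material: str = "tungsten"

    @property
    def scale(self) -> float:
        """Projection factor from isocenter plane to the leaf mid-plane."""
        return (self.source_z - self.z_center) / self.source_z


@dataclass
class MachineConfig:
    """One frozen machine configuration (a control point's geometry)."""

    leaves_a: np.ndarray              # tip x per leaf, bank A (from -x), isocenter scale
    leaves_b: np.ndarray              # tip x per leaf, bank B (from +x)
    jaws_x: Tuple[float, float] = (-20.0, 20.0)
    jaws_y: Tuple[float, float] = (-20.0, 20.0)
    gantry: float = 0.0               # degrees
    collimator: float = 0.0
    couch: float = 0.0

    def __post_init__(self):
        self.leaves_a = np.asarray(self.leaves_a, dtype=float)
        self.leaves_b = np.asarray(self.leaves_b, dtype=float)


def _box(x0, x1, y0, y1, z0, z1, material, name, **kw) -> Body:
    surf = ((Quadric.plane((1, 0, 0), x0), +1), (Quadric.plane((1, 0, 0), x1), -1),
            (Quadric.plane((0, 1, 0), y0), +1), (Quadric.plane((0, 1, 0), y1), -1),
            (Quadric.plane((0, 0, 1), z0), +1), (Quadric.plane((0, 0, 1), z1), -1))
    return Body(surf, material, name=name, **kw)


@dataclass
class MachineModel:
    """Leaf bank + jaws; produces transformed body lists per configuration."""

    spec: LeafBankSpec
    jaw_thickness: float = 6.0
    jaw_z_center: float = 58.0
    half_extent: float = 30.0          # lateral extent of jaw slabs (physical cm)

    def bodies(self, config: MachineConfig) -> List[Body]:
        spec = self.spec
        if len(config.leaves_a) != spec.n_pairs or len(config.leaves_b) != spec.n_pairs:
            raise ValueError(f"need {spec.n_pairs} leaf positions per bank")
        gap = config.leaves_b - config.leaves_a
        if np.any(gap < spec.min_gap - 1e-9):
            bad = np.flatnonzero(gap < spec.min_gap - 1e-9)
            raise ValueError(f"leaf collision on pairs {bad.tolist()}: opposing gap "
                             f"below the minimum {spec.min_gap} cm")
        bodies = build_leaf_bank(spec, config.leaves_a, config.leaves_b)
        bodies += self._jaw_bodies(config)
        rot = rotation_matrix("y", config.gantry) @ rotation_matrix("z", config.collimator)
        if not np.allclose(rot, np.eye(3)):
            bodies = [b.transformed(rotation=rot) for b in bodies]
        return bodies

    def _jaw_bodies(self, config: MachineConfig) -> List[Body]:
        sf = (self.spec.source_z - self.jaw_z_center) / self.spec.source_z
        z0 = self.jaw_z_center - self.jaw_thickness / 2
        z1 = self.jaw_z_center + self.jaw_thickness / 2
        he = self.half_extent
        x1, x2 = config.jaws_x[0] * sf, config.jaws_x[1] * sf
        y1, y2 = config.jaws_y[0] * sf, config.jaws_y[1] * sf
        mat = self.spec.material
        out = []
        if x1 > -he:
            out.append(_box(-he, x1, -he, he, z0, z1, mat, "jaw_x1", range_reject=True))
        if x2 < he:
            out.append(_box(x2, he, -he, he, z0, z1, mat, "jaw_x2", range_reject=True))
        zj0, zj1 = z0 - self.jaw_thickness - 0.5, z1 - self.jaw_thickness - 0.5
        if y1 > -he:
            out.append(_box(-he, he, -he, y1, zj0, zj1, mat, "jaw_y1", range_reject=True))
        if y2 < he:
            out.append(_box(-he, he, y2, he, zj0, zj1, mat, "jaw_y2", range_reject=True))
        return out


def build_leaf_bank(spec: LeafBankSpec,
                    leaves_a: Sequence[float],
                    leaves_b: Sequence[float]) -> List[Body]:
    """Bodies for both banks at the given tip positions (isocenter scale).

    Each leaf is a back box plus a rounded-tip segment (cylinder with axis
    along y), with a tongue strip on its +y side when the spec enables
    tongue-and-groove.
    """
    sf = spec.scale
    width = spec.leaf_width_iso * sf
    tw = spec.tongue_width_iso * sf
    zc = spec.z_center
    z0, z1 = zc - spec.thickness / 2, zc + spec.thickness / 2
    y_start = -spec.n_pairs * width / 2.0
    R = spec.tip_radius
    L = spec.leaf_length
    bodies: List[Body] = []
    for i in range(spec.n_pairs):
        y0 = y_start + i * width
        y1 = y0 + width
        y_main = y1 - tw
        for bank, tip_iso in (("a", leaves_a[i]), ("b", leaves_b[i])):
            tip = tip_iso * sf
            s = -1.0 if bank == "a" else 1.0    # tip normal direction (+x for A)
            # back box: from the rear to where the rounded tip begins
            back_far = tip + s * L
            back_near = tip + s * min(R, L)
            nm = f"leaf_{bank}{i}"
            bodies.append(_box(min(back_far, back_near), max(back_far, back_near),
                               y0, y_main, z0, z1, spec.material, nm + "_back",
                               tags={"bank": bank, "pair": i}, range_reject=True))
            # rounded tip segment: box clipped by the tip cylinder
            cyl = Quadric.cylinder_y(tip + s * R, zc, R)
            lo, hi = (tip - R, tip) if bank == "a" else (tip, tip + R)
            tipsurf = ((Quadric.plane((1, 0, 0), min(lo, hi) - 1e-9), +1),
                       (Quadric.plane((1, 0, 0), max(lo, hi) + 1e-9), -1),
                       (Quadric.plane((0, 1, 0), y0), +1),
                       (Quadric.plane((0, 1, 0), y_main), -1),
                       (Quadric.plane((0, 0, 1), z0), +1),
                       (Quadric.plane((0, 0, 1), z1), -1),
                       (cyl, -1))
            bodies.append(Body(tipsurf, spec.material, name=nm + "_tip",
                               tags={"bank": bank, "pair": i}, range_reject=True))
            if tw > 0:
                bodies.append(_box(min(back_far, tip), max(back_far, tip),
                                   y_main, y1, zc, z1, spec.material, nm + "_tongue",
                                   tags={"bank": bank, "pair": i}, range_reject=True))
    return bodies


def apply_machine_configuration(model: MachineModel, config: MachineConfig,
                                grid: Optional[VoxelGrid] = None) -> List[Body]:
    """Bodies for a configuration; if ``grid`` is given its orientation
    metadata receives the inverse couch rotation (pure metadata update)."""
    bodies = model.bodies(config)
    if grid is not None and config.couch != 0.0:
        grid.orientation = rotation_matrix("z", -config.couch) @ grid.orientation
    return bodies
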