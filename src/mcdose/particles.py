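"""Particle state containers.

The engine works on structure-of-arrays *banks* for throughput; the scalar
:class:`ParticleState` is the single-particle view used by the contract-level
operations and the tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict

import numpy as np

PHOTON, ELECTRON, POSITRON = 0, 1, 2
SPECIES_NAMES = {PHOTON: "photon", ELECTRON: "electron", POSITRON: "positron"}


@dataclass
class ParticleState:
    """A single particle: species, kinetic energy (MeV), position (cm),
    unit direction, statistical weight and the region tag it currently
    occupies ("machine", "voxel" or "world")."""

    species: int
    energy: float
    position: np.ndarray
    direction: np.ndarray
    weight: float = 1.0
    region: str = "voxel"
    history: int = 0

    def __post_init__(self):
        self.position = np.asarray(self.position, dtype=float)
        self.direction = np.asarray(self.direction, dtype=float)
        n = np.linalg.norm(self.direction)
        if abs(n - 1.0) > 1e-9:
            raise ValueError("direction must be a unit vector")
        if self.energy < 0:
            raise ValueError("kinetic energy must be non-negative")
        if self.weight <= 0:
            raise ValueError("statistical weight must be positive")

    def copy(self) -> "ParticleState":
        return replace(self, position=self.position.copy(), direction=self.direction.copy())


def split_particle(p: ParticleState, n_split: int):
    """Split ``p`` into ``n_split`` copies of weight w/n_split (unbiased)."""
    if n_split < 1 or int(n_split) != n_split:
        raise ValueError("n_split must be a positive integer")
    if n_split == 1:
        return [p.copy()]
    out = []
    for _ in range(n_split):
        q = p.copy()
        q.weight = p.weight / n_split
        out.append(q)
    return out


def empty_bank() -> Dict[str, np.ndarray]:
    return {"energy": np.empty(0), "pos": np.empty((0, 3)), "dir": np.empty((0, 3)),
            "weight": np.empty(0), "hist": np.empty(0, dtype=np.int64),
            "species": np.empty(0, dtype=np.int8)}


def make_bank(energy, pos, direction, weight, hist, species) -> Dict[str, np.ndarray]:
    energy = np.atleast_1d(np.asarray(energy, dtype=float))
    n = len(energy)
    return {"energy": energy,
            "pos": np.asarray(pos, dtype=float).reshape(n, 3),
            "dir": np.asarray(direction, dtype=float).reshape(n, 3),
            "weight": np.broadcast_to(np.asarray(weight, dtype=float), (n,)).copy(),
            "hist": np.broadcast_to(np.asarray(hist, dtype=np.int64), (n,)).copy(),
            "species": np.broadcast_to(np.asarray(species, dtype=np.int8), (n,)).copy()}


def concat_banks(banks):
    banks = [b for b in banks if len(b["energy"])]
    if not banks:
        return empty_bank()
    return {k: np.concatenate([b[k] for b in banks]) for k in banks[0]}


def select(bank, mask):
    return {k: v[mask] for k, v in bank.items()}
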