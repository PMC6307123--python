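"""Particle sources: analytic divergent beam and plain phase-space files.

The analytic source models the upstream (patient-independent) linac output
as a Gaussian focal spot with a Gaussian energy spectrum and a uniform
divergence cone aimed down the -z beam axis; the defaults are the nominal
6 MV beam parameters (mean energy 6.2 MeV, energy FWHM 0.186 MeV, spot FWHM
0.15 cm, half-angle 2.5 degrees).

The phase-space file format is deliberately simple: a fixed-width 128-byte
text header (magic, version, record count, plane z) followed by fixed-width
binary records.  Readers can partition a file among any number of streams
by stride without copying or pre-splitting it.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator, Optional

import numpy as np

from .particles import PHOTON, make_bank

__all__ = ["AnalyticBeam", "PhaseSpaceWriter", "read_phase_space",
           "phase_space_record_count", "PhaseSpaceSource", "PSF_DTYPE"]

_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))   # 1/2.3548
_MAGIC = "MCDOSE-PSF"
_HEADER_LEN = 128

#: species (1 byte), E, x, y, u, v (4-byte floats), sign of w (1 byte), weight
PSF_DTYPE = np.dtype([("species", "i1"), ("E", "<f4"), ("x", "<f4"), ("y", "<f4"),
                      ("u", "<f4"), ("v", "<f4"), ("wsign", "i1"), ("weight", "<f4")])


@dataclass
class AnalyticBeam:
    """Divergent Gaussian-spot photon beam pointing along -z."""

    mean_energy: float = 6.2        # MeV
    energy_fwhm: float = 0.186      # MeV
    spot_fwhm: float = 0.15         # cm, lateral, Gaussian
    divergence: float = 2.5         # degrees, cone half-angle
    source_z: float = 100.0         # cm above the isocenter
    energy_max: float = 7.0         # hard cap (tables span)

    def __post_init__(self):
        if self.energy_fwhm < 0 or self.spot_fwhm < 0:
            raise ValueError("widths must be non-negative")
        if not 0 <= self.divergence < 90:
            raise ValueError("divergence must be in [0, 90) degrees")

    def sample(self, n: int, rng: np.random.Generator) -> dict:
        sig_e = self.energy_fwhm * _FWHM_TO_SIGMA
        E = np.clip(rng.normal(self.mean_energy, sig_e, n) if sig_e > 0
                    else np.full(n, self.mean_energy), 1e-3, self.energy_max)
        sig_xy = self.spot_fwhm * _FWHM_TO_SIGMA
        xy = rng.normal(0.0, sig_xy, (n, 2)) if sig_xy > 0 else np.zeros((n, 2))
        pos = np.column_stack([xy, np.full(n, self.source_z)])
        # uniform solid angle inside the divergence cone, around -z
        cos_max = np.cos(np.deg2rad(self.divergence))
        ct = 1.0 - rng.random(n) * (1.0 - cos_max)
        phi = 2.0 * np.pi * rng.random(n)
        st = np.sqrt(1.0 - ct**2)
        d = np.column_stack([st * np.cos(phi), st * np.sin(phi), -ct])
        return make_bank(E, pos, d, 1.0, 0, PHOTON)


# ---------------------------------------------------------------------------
# phase-space files

def _write_header(fh, n_records: int, z_plane: float) -> None:
    head = json.dumps({"magic": _MAGIC, "version": 1, "n_records": int(n_records),
                       "z_plane": float(z_plane)})
    raw = head.encode()
    if len(raw) > _HEADER_LEN - 1:
        raise ValueError("header too long")
    fh.write(raw + b"\n" + b" " * (_HEADER_LEN - 1 - len(raw)))


def _read_header(path) -> dict:
    with open(path, "rb") as fh:
        raw = fh.read(_HEADER_LEN)
    if len(raw) < _HEADER_LEN:
        raise ValueError(f"{path}: truncated phase-space header")
    try:
        head = json.loads(raw.split(b"\n", 1)[0].decode())
    except Exception as exc:
        raise ValueError(f"{path}: malformed phase-space header") from exc
    if head.get("magic") != _MAGIC:
        raise ValueError(f"{path}: bad magic, not a phase-space file")
    return head


class PhaseSpaceWriter:
    """Sequential phase-space writer; finalizes the record count on close."""

    def __init__(self, path, z_plane: float = 100.0):
        self.path = Path(path)
        self.z_plane = z_plane
        self._fh = open(self.path, "wb")
        self._n = 0
        _write_header(self._fh, 0, z_plane)

    def write(self, records: np.ndarray) -> None:
        rec = np.asarray(records, dtype=PSF_DTYPE)
        rec.tofile(self._fh)
        self._n += len(rec)

    def close(self) -> None:
        self._fh.flush()
        self._fh.seek(0)
        _write_header(self._fh, self._n, self.z_plane)
        self._fh.close()

    def __enter__(self):
        return self

    def __exit__(self, *exc):
        self.close()


def phase_space_record_count(path) -> int:
    return _read_header(path)["n_records"]


def read_phase_space(path, *, stride: int = 1, offset: int = 0) -> np.ndarray:
    """Memory-mapped read of every ``stride``-th record starting at
    ``offset``; the strided views of all offsets partition the file exactly
    without copying or pre-splitting."""
    head = _read_header(path)
    n = head["n_records"]
    size = Path(path).stat().st_size
    expected = _HEADER_LEN + n * PSF_DTYPE.itemsize
    if size < expected:
        got = (size - _HEADER_LEN) // PSF_DTYPE.itemsize
        raise ValueError(f"{path}: truncated at record {got} of {n}")
    if n == 0:
        return np.empty(0, dtype=PSF_DTYPE)
    mm = np.memmap(path, dtype=PSF_DTYPE, mode="r", offset=_HEADER_LEN, shape=(n,))
    return mm[offset::stride]


class PhaseSpaceSource:
    """Replays a phase-space file as a particle source (cycling if more
    histories than records are requested)."""

    def __init__(self, path, *, stride: int = 1, offset: int = 0):
        self.records = read_phase_space(path, stride=stride, offset=offset)
        self.z_plane = _read_header(path)["z_plane"]
        self._cursor = 0
        if len(self.records) == 0:
            raise ValueError(f"{path}: empty phase space")

    def sample(self, n: int, rng: np.random.Generator) -> dict:
        idx = (self._cursor + np.arange(n)) % len(self.records)
        self._cursor = (self._cursor + n) % len(self.records)
        r = self.records[idx]
        u = r["u"].astype(float)
        v = r["v"].astype(float)
        w = np.sqrt(np.clip(1.0 - u**2 - v**2, 0.0, 1.0)) * np.where(r["wsign"] >= 0, 1.0, -1.0)
        pos = np.column_stack([r["x"], r["y"], np.full(n, self.z_plane)])
        d = np.column_stack([u, v, w])
        d /= np.linalg.norm(d, axis=1, keepdims=True)
        return make_bank(r["E"].astype(float), pos, d, r["weight"].astype(float),
                         0, r["species"].astype(np.int8))
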