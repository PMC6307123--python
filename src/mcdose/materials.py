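"""Material data: photon attenuation and electron stopping-power tables.

A :class:`MaterialTable` carries, on a shared logarithmic energy grid, the
per-channel linear attenuation coefficients (Compton, photoelectric, pair),
the restricted electron stopping power (soft collision losses below the
hard-collision threshold ``wc`` plus radiative losses), the CSDA residual
range and a small-angle scattering power.  The Compton channel is computed
analytically from the Klein-Nishina cross section per electron (free,
at-rest target; binding and Doppler broadening neglected, which is accurate
for low-Z media at megavoltage energies).  Photoelectric and pair channels
and the elemental stopping powers come from the synthetic per-element tables
shipped under ``mcdose/data`` (see ``scripts/make_element_tables.py``),
mixed by mass fraction (Bragg additivity).

Interpolation between grid nodes is log-log linear and is an explicit,
tested contract: queries outside the grid raise instead of extrapolating.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Dict, List, Sequence, Tuple

import numpy as np

from .constants import MEC2, NA, PAIR_THRESHOLD, RE, SIGMA_THOMSON
from .electrons import moller_dcs

__all__ = [
    "ElementalComposition",
    "MaterialTable",
    "kn_total_cross_section",
    "build_material_table",
    "interpolate_mu",
    "interpolate_S",
    "csda_range",
    "default_registry",
    "COMPOSITIONS",
]

DEFAULT_GRID = np.geomspace(1e-3, 7.0, 100)


# ---------------------------------------------------------------------------
# element data (synthetic shipped tables)

_ELEMENT_A = {1: 1.008, 6: 12.011, 7: 14.007, 8: 15.999, 18: 39.948, 20: 40.078, 74: 183.84}

_element_cache: dict | None = None


def _element_tables() -> dict:
    """Load the shipped per-element tables, keyed by Z."""
    global _element_cache
    if _element_cache is None:
        raw = (resources.files("mcdose") / "data" / "element_tables_synthetic.tsv").read_text()
        rows = [ln.split("\t") for ln in raw.splitlines() if ln and not ln.startswith("#")]
        data: dict = {}
        for r in rows:
            z = int(r[0])
            data.setdefault(z, []).append([float(v) for v in r[4:9]])
        _element_cache = {
            z: dict(zip(("E", "photo", "pair", "scol", "srad"),
                        np.asarray(arr, dtype=float).T))
            for z, arr in data.items()
        }
    return _element_cache


# ---------------------------------------------------------------------------
# compositions

@dataclass(frozen=True)
class ElementalComposition:
    """Mass-fraction elemental composition at a given mass density.

    ``elements`` is a sequence of ``(Z, mass_fraction)``; fractions must sum
    to one.  ``density`` is the mass density in g/cm^3.
    """

    elements: Tuple[Tuple[int, float], ...]
    density: float

    def __post_init__(self):
        fr = sum(f for _, f in self.elements)
        if abs(fr - 1.0) > 1e-6:
            raise ValueError(f"mass fractions sum to {fr}, not 1")
        if self.density <= 0:
            raise ValueError("density must be positive")
        for z, _ in self.elements:
            if not 1 <= z <= 100:
                raise ValueError(f"invalid atomic number {z}")

    def with_density(self, density: float) -> "ElementalComposition":
        return ElementalComposition(self.elements, density)

    @property
    def electron_density(self) -> float:
        """Electrons per cm^3."""
        return self.density * NA * sum(f * z / _ELEMENT_A[z] for z, f in self.elements)


#: Default compositions (simplified 4-6 element tissue formulas; bone folds
#: phosphorus into calcium because only the shipped elements are available).
COMPOSITIONS: Dict[str, ElementalComposition] = {
    "water": ElementalComposition(((1, 0.1119), (8, 0.8881)), 1.0),
    "air": ElementalComposition(((6, 0.000124), (7, 0.755268), (8, 0.231781), (18, 0.012827)),
                                1.20479e-3),
    "muscle": ElementalComposition(((1, 0.102), (6, 0.123), (7, 0.035), (8, 0.740)), 1.04),
    "lung": ElementalComposition(((1, 0.102), (6, 0.123), (7, 0.035), (8, 0.740)), 0.3),
    "bone": ElementalComposition(((1, 0.064), (6, 0.278), (7, 0.027), (8, 0.410), (20, 0.221)),
                                 1.85),
    "tungsten": ElementalComposition(((74, 1.0),), 19.3),
}


# ---------------------------------------------------------------------------
# Klein-Nishina

def kn_total_cross_section(energy):
    """Total Klein-Nishina cross section per free electron at rest (cm^2).

    Analytic closed form of the angle-integrated Klein-Nishina differential
    cross section.  Approaches the Thomson cross section as E -> 0.
    """
    E = np.asarray(energy, dtype=float)
    if np.any(E <= 0):
        raise ValueError("photon energy must be positive")
    k = E / MEC2
    t1 = (1.0 + k) / k**2 * (2.0 * (1.0 + k) / (1.0 + 2.0 * k) - np.log1p(2.0 * k) / k)
    t2 = np.log1p(2.0 * k) / (2.0 * k)
    t3 = (1.0 + 3.0 * k) / (1.0 + 2.0 * k) ** 2
    out = 2.0 * np.pi * RE**2 * (t1 + t2 - t3)
    return out if out.shape else float(out)


# ---------------------------------------------------------------------------
# interpolation

def _loglog_interp(xq, x, y):
    """Log-log linear interpolation, exact at nodes, linear fallback where
    a bracketing node is non-positive (e.g. the pair channel at threshold)."""
    xq = np.asarray(xq, dtype=float)
    idx = np.searchsorted(x, xq, side="right") - 1
    idx = np.clip(idx, 0, len(x) - 2)
    x0, x1 = x[idx], x[idx + 1]
    y0, y1 = y[idx], y[idx + 1]
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.log(xq / x0) / np.log(x1 / x0)
        res = np.where((y0 > 0) & (y1 > 0),
                       np.exp(np.log(np.where(y0 > 0, y0, 1.0)) * (1 - t)
                              + np.log(np.where(y1 > 0, y1, 1.0)) * t),
                       y0 + (y1 - y0) * (xq - x0) / (x1 - x0))
    # exact node identity (log-log round trips can lose the last ulp)
    exact = xq == x[np.clip(idx, 0, len(x) - 1)]
    res = np.where(exact, y[idx], res)
    exact_hi = xq == x[idx + 1]
    res = np.where(exact_hi, y[idx + 1], res)
    return res


def _check_span(E, grid):
    E = np.asarray(E, dtype=float)
    if np.any(E < grid[0] * (1 - 1e-12)) or np.any(E > grid[-1] * (1 + 1e-12)):
        raise ValueError(
            f"energy outside table span [{grid[0]:g}, {grid[-1]:g}] MeV; no extrapolation")
    return E


# ---------------------------------------------------------------------------
# material table

@dataclass
class MaterialTable:
    """Interaction coefficients for one material on a common energy grid.

    Attenuation coefficients are linear (1/cm) at the material's density;
    ``stopping`` is the restricted collision plus radiative stopping power
    (MeV/cm); ``csda`` the residual range (cm) measured from ``cutoff``.
    """

    name: str
    composition: ElementalComposition
    energy: np.ndarray
    mu_compton: np.ndarray
    mu_photo: np.ndarray
    mu_pair: np.ndarray
    stopping: np.ndarray
    csda: np.ndarray
    scatter_power: np.ndarray
    cutoff: float
    wc: float
    hard_imfp_energy: np.ndarray = field(default=None, repr=False)
    hard_imfp: np.ndarray = field(default=None, repr=False)

    @property
    def density(self) -> float:
        return self.composition.density

    @property
    def electron_density(self) -> float:
        return self.composition.electron_density

    @property
    def mu_total_nodes(self) -> np.ndarray:
        return self.mu_compton + self.mu_photo + self.mu_pair

    # -- photon side ------------------------------------------------------
    def mu_channels(self, E):
        """(mu_compton, mu_photo, mu_pair) at E, log-log interpolated."""
        E = _check_span(E, self.energy)
        return (_loglog_interp(E, self.energy, self.mu_compton),
                _loglog_interp(E, self.energy, self.mu_photo),
                np.where(E < PAIR_THRESHOLD, 0.0,
                         _loglog_interp(E, self.energy, self.mu_pair)))

    def mu(self, E):
        """Total linear attenuation coefficient at E (sum of the channels)."""
        c, p, pp = self.mu_channels(E)
        return c + p + pp

    # -- electron side ----------------------------------------------------
    def S(self, E):
        """Restricted total stopping power (MeV/cm)."""
        E = _check_span(E, self.energy)
        return _loglog_interp(E, self.energy, self.stopping)

    def csda_range(self, E):
        """Residual CSDA range from the transport cutoff to E (cm)."""
        E = np.asarray(E, dtype=float)
        below = E <= self.cutoff
        Ec = np.where(below, self.cutoff, E)
        _check_span(Ec, self.energy)
        r = _loglog_interp(Ec, self.energy, np.maximum(self.csda, 1e-300))
        return np.where(below, 0.0, r)

    def T_scatter(self, E):
        """Scattering power T(E) in rad^2/cm."""
        E = _check_span(E, self.energy)
        return _loglog_interp(E, self.energy, self.scatter_power)

    def hard_inverse_mfp(self, E):
        """Inverse mean free path (1/cm) for hard Moller collisions (W > wc)."""
        E = np.asarray(E, dtype=float)
        out = np.zeros_like(E, dtype=float)
        ok = E > 2.0 * self.wc
        if np.any(ok):
            out[ok] = np.interp(E[ok], self.hard_imfp_energy, self.hard_imfp)
        return out


def _moller_energy_loss_integral(T, wc):
    """integral_{wc}^{T/2} W dsigma/dW dW per electron (MeV cm^2)."""
    if T <= 2.0 * wc:
        return 0.0
    w = np.geomspace(wc, T / 2.0, 96)
    return float(np.trapezoid(w * moller_dcs(T, w), w))


def _moller_restricted_xs(T, wc):
    """integral_{wc}^{T/2} dsigma/dW dW per electron (cm^2)."""
    if T <= 2.0 * wc * (1 + 1e-12):
        return 0.0
    w = np.geomspace(wc, T / 2.0, 96)
    return float(np.trapezoid(moller_dcs(T, w), w))


def build_material_table(comp: ElementalComposition,
                         grid: Sequence[float] | None = None,
                         *,
                         name: str = "material",
                         cutoff: float = 0.2,
                         wc: float = 0.2) -> MaterialTable:
    """Assemble a MaterialTable from a composition and the shipped element data.

    ``cutoff`` is the electron transport cutoff (MeV) from which the CSDA
    residual range is integrated; ``wc`` the hard-collision threshold used to
    restrict the collision stopping power (hard Moller losses above ``wc``
    are simulated discretely and therefore removed from the soft term).
    """
    grid = np.asarray(DEFAULT_GRID if grid is None else grid, dtype=float)
    if grid.ndim != 1 or len(grid) < 2 or np.any(np.diff(grid) <= 0):
        raise ValueError("energy grid must be strictly increasing")
    tables = _element_tables()
    rho = comp.density
    n_e = comp.electron_density

    mu_c = n_e * kn_total_cross_section(grid)
    mu_ph = np.zeros_like(grid)
    mu_pp = np.zeros_like(grid)
    scol = np.zeros_like(grid)   # mass stopping powers first (MeV cm^2/g)
    srad = np.zeros_like(grid)
    inv_x0_mass = 0.0
    for z, f in comp.elements:
        if z not in tables:
            raise KeyError(f"no shipped data for element Z={z}")
        el = tables[z]
        n_atoms = rho * NA * f / _ELEMENT_A[z]
        mu_ph += n_atoms * _loglog_interp(grid, el["E"], el["photo"])
        mu_pp += n_atoms * _loglog_interp(grid, el["E"], el["pair"])
        scol += f * _loglog_interp(grid, el["E"], el["scol"])
        srad += f * _loglog_interp(grid, el["E"], el["srad"])
        # PDG radiation length, as in the shipped radiative term
        inv_x0_mass += f * z * (z + 1) * np.log(287.0 / np.sqrt(z)) / (716.4 * _ELEMENT_A[z])
    mu_pp[grid < PAIR_THRESHOLD] = 0.0

    # restricted collision stopping: subtract the hard-Moller energy-loss rate
    hard_loss = np.array([_moller_energy_loss_integral(T, wc) for T in grid])
    stopping = np.maximum((scol + srad) * rho - n_e * hard_loss, 1e-6)

    # CSDA residual range from the cutoff, refined trapezoid in log space
    csda = np.zeros_like(grid)
    s_of = lambda E: np.maximum(_loglog_interp(E, grid, stopping), 1e-12)
    prev = cutoff
    acc = 0.0
    for i, E in enumerate(grid):
        if E <= cutoff:
            continue
        seg = np.geomspace(prev, E, 33)
        acc += np.trapezoid(1.0 / s_of(seg), seg)
        csda[i] = acc
        prev = E

    # Highland-type scattering power: (13.6 MeV / (beta p c))^2 / X0[cm]
    tau = grid / MEC2
    pc = np.sqrt(grid * (grid + 2.0 * MEC2))
    beta = pc / (grid + MEC2)
    x0_cm = 1.0 / (inv_x0_mass * rho)
    t_scat = (13.6 / (beta * pc)) ** 2 / x0_cm

    # hard Moller inverse mean free path on a dedicated grid
    e_hi = np.geomspace(max(2.0 * wc * (1 + 1e-9), grid[0]), grid[-1], 80)
    imfp = n_e * np.array([_moller_restricted_xs(T, wc) for T in e_hi])

    return MaterialTable(name=name, composition=comp, energy=grid,
                         mu_compton=mu_c, mu_photo=mu_ph, mu_pair=mu_pp,
                         stopping=stopping, csda=csda, scatter_power=t_scat,
                         cutoff=cutoff, wc=wc,
                         hard_imfp_energy=e_hi, hard_imfp=imfp)


# spec-level convenience wrappers ------------------------------------------

def interpolate_mu(table: MaterialTable, E):
    """Total linear attenuation coefficient mu(E) in 1/cm."""
    return table.mu(E)


def interpolate_S(table: MaterialTable, E):
    """Restricted total stopping power S(E) in MeV/cm."""
    return table.S(E)


def csda_range(table: MaterialTable, E):
    """Residual CSDA range (cm) from the transport cutoff to E."""
    return table.csda_range(E)


def default_registry(grid: Sequence[float] | None = None, *,
                     cutoff: float = 0.2, wc: float = 0.2,
                     names: Sequence[str] | None = None) -> Dict[str, MaterialTable]:
    """Build the default material registry (water, air, muscle, lung, bone,
    tungsten) on a shared grid."""
    names = list(COMPOSITIONS if names is None else names)
    return {n: build_material_table(COMPOSITIONS[n], grid, name=n, cutoff=cutoff, wc=wc)
            for n in names}
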