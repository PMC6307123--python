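"""The coupled photon/electron transport engine.

Photons inside the voxel grid are tracked with Woodcock (delta) tracking: a
global majorant attenuation coefficient mu_max(E) lets the engine sample
path lengths without ever intersecting voxel walls; tentative interaction
sites are accepted with probability mu_local/mu_max.  In the quadric machine
region photons are ray-traced surface-to-surface with the local body's
attenuation coefficient.  Electrons (and positrons) use condensed-history
transport: continuous restricted energy loss along straight sub-steps, a
small-angle multiple-scattering deflection per step, and discrete Moller
collisions above the hard threshold.  Two variance-reduction techniques are
available: simple particle splitting applied when a particle crosses the
interface into the voxel (patient) region, and range rejection of electrons
deep inside flagged machine bodies (movable skins).

Every batch of histories is audited: source energy times weight must equal
tallied deposit + machine-body deposit + escaped energy to within 1e-9
relative, per history.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np

from .constants import MEC2
from .electrons import moller_directions, sample_moller
from .geometry import BOUNDARY_TOL, Body, MixedGeometry, VoxelGrid
from .materials import MaterialTable, default_registry
from .particles import (ELECTRON, PHOTON, POSITRON, ParticleState, concat_banks,
                        empty_bank, make_bank, select)
from .photons import (annihilation_directions, pair_production, sample_compton,
                      sample_interaction_channel)
from .tally import DoseGrid
from .vecmath import rotate_direction

__all__ = ["TransportSettings", "TransportEngine", "woodcock_flight",
           "condensed_step", "range_rejection_movable_skins"]

_MACHINE_CHUNK = 4096


@dataclass
class TransportSettings:
    """Numeric transport parameters (all configurable; defaults are typical
    for fast megavoltage engines — the physics models do not pin them)."""

    photon_cutoff: float = 0.05     # MeV; below, deposit locally
    electron_cutoff: float = 0.2    # MeV; below, deposit locally
    wc: float = 0.2                 # MeV; hard Moller threshold
    f_step: float = 0.04            # max fractional energy loss per step
    max_step: float = 0.5           # cm, geometric cap inside the voxel grid
    n_split: int = 1                # splitting factor entering the voxel region
    range_rejection: bool = False   # movable skins in flagged machine bodies
    skin_depth: float = 0.1         # cm, inner margin excluded from rejection
    multiple_scattering: bool = True
    hard_collisions: bool = True
    batch_size: int = 20000

    def __post_init__(self):
        if self.photon_cutoff <= 0 or self.electron_cutoff <= 0:
            raise ValueError("cutoffs must be positive")
        if not (0 < self.f_step <= 0.25):
            raise ValueError("f_step must be in (0, 0.25]")
        if self.n_split < 1 or int(self.n_split) != self.n_split:
            raise ValueError("splitting factor must be a positive integer")
        if self.wc < self.electron_cutoff - 1e-12:
            raise ValueError("hard threshold wc must not be below the electron cutoff")


class TransportEngine:
    """Transport in a :class:`MixedGeometry` (or a bare :class:`VoxelGrid`,
    treated as a grid in vacuum)."""

    def __init__(self, geometry, registry: Optional[Dict[str, MaterialTable]] = None,
                 settings: Optional[TransportSettings] = None):
        self.settings = settings or TransportSettings()
        if isinstance(geometry, VoxelGrid):
            self.grid = geometry
            self.bodies: List[Body] = []
            self.z_interface = float(geometry.upper[2])
            self.world_material: Optional[str] = None     # vacuum
            self.world_half_extent = 200.0
        elif isinstance(geometry, MixedGeometry):
            self.grid = geometry.grid
            self.bodies = list(geometry.bodies)
            self.z_interface = float(geometry.z_interface)
            self.world_material = geometry.world_material
            self.world_half_extent = geometry.world_half_extent
        else:
            raise TypeError("geometry must be a VoxelGrid or MixedGeometry")
        names = list(self.grid.materials)
        for b in self.bodies:
            if b.material not in names:
                names.append(b.material)
        if self.world_material and self.world_material not in names:
            names.append(self.world_material)
        if registry is None:
            registry = default_registry(cutoff=self.settings.electron_cutoff,
                                        wc=self.settings.wc, names=names)
        self.tables: List[MaterialTable] = [registry[n] for n in names]
        self._names = names
        self._body_mat = [names.index(b.material) for b in self.bodies]
        self._world_mat = names.index(self.world_material) if self.world_material else -1

        # per-voxel material / density-ratio lookups
        self._mat_flat = self.grid.material.ravel().astype(np.int64)
        rho_ref = np.array([t.density for t in self.tables])
        self._ratio_flat = self.grid.density.ravel() / rho_ref[self._mat_flat]
        self._grid_mats = np.unique(self._mat_flat)
        self._max_ratio = np.zeros(len(self.tables))
        for m in self._grid_mats:
            self._max_ratio[m] = self._ratio_flat[self._mat_flat == m].max()

        # machine surface soup (world-frame quadric matrices)
        if self.bodies:
            mats = [b.world_matrices() for b in self.bodies]
            self._surf = np.concatenate(mats, axis=0)
            self._surf_body = np.concatenate(
                [np.full(len(m), i) for i, m in enumerate(mats)]).astype(np.int64)
            self._surf_sign = np.concatenate(
                [[s for _, s in b.surfaces] for b in self.bodies]).astype(float)
            slices = []
            start = 0
            for m in mats:
                slices.append(slice(start, start + len(m)))
                start += len(m)
            self._body_slices = slices
            los, his = zip(*[b.aabb(self.world_half_extent) for b in self.bodies])
            self._machine_lo = np.min(los, axis=0) - 1e-6
            self._machine_hi = np.max(his, axis=0) + 1e-6
            # split planes (fast dot-product path) from true quadrics
            quad_part = np.abs(self._surf[:, :3, :3]).max(axis=(1, 2))
            self._is_plane = quad_part < 1e-14
            self._plane_n = 2.0 * self._surf[self._is_plane][:, :3, 3]
            self._plane_c = self._surf[self._is_plane][:, 3, 3]
            self._plane_ids = np.flatnonzero(self._is_plane)
            self._quad_ids = np.flatnonzero(~self._is_plane)
            self._quad_surf = self._surf[self._quad_ids]
        else:
            self._surf = np.zeros((0, 4, 4))
            self._surf_body = np.zeros(0, dtype=np.int64)
            self._surf_sign = np.zeros(0)
            self._body_slices = []
            self._machine_lo = np.zeros(3)
            self._machine_hi = np.zeros(3)
        self._machine_z_top = self.z_interface
        for b in self.bodies:
            # crude vertical extent for the world box: probe body corners
            self._machine_z_top = max(self._machine_z_top, b.translation[2] + 80.0)
        self._world_z_top = max(self.z_interface + 1.0, 120.0)

    # ------------------------------------------------------------------ #
    # material lookups

    def _mu_majorant(self, E: np.ndarray) -> np.ndarray:
        out = np.zeros_like(E)
        for m in self._grid_mats:
            if self._max_ratio[m] > 0:
                np.maximum(out, self.tables[m].mu(E) * self._max_ratio[m], out=out)
        return out

    def _mu_local(self, E, flat):
        mat = self._mat_flat[flat]
        ratio = self._ratio_flat[flat]
        out = np.zeros_like(E)
        for m in np.unique(mat):
            s = mat == m
            out[s] = self.tables[m].mu(E[s]) * ratio[s]
        return out

    def _mu_channels_local(self, E, flat):
        mat = self._mat_flat[flat]
        ratio = self._ratio_flat[flat]
        c = np.zeros_like(E)
        p = np.zeros_like(E)
        pp = np.zeros_like(E)
        for m in np.unique(mat):
            s = mat == m
            cc, ph, pr = self.tables[m].mu_channels(E[s])
            c[s], p[s], pp[s] = cc * ratio[s], ph * ratio[s], pr * ratio[s]
        return c, p, pp

    def _etable(self, quantity, E, mat, ratio):
        """Electron-table lookup by material id with density scaling."""
        out = np.zeros_like(E)
        for m in np.unique(mat):
            s = mat == m
            t = self.tables[m]
            if quantity == "S":
                out[s] = t.S(E[s]) * ratio[s]
            elif quantity == "T":
                out[s] = t.T_scatter(E[s]) * ratio[s]
            elif quantity == "hard":
                out[s] = t.hard_inverse_mfp(E[s]) * ratio[s]
            elif quantity == "R":
                out[s] = t.csda_range(E[s]) / np.maximum(ratio[s], 1e-300)
        return out

    # ------------------------------------------------------------------ #
    # public API

    def run(self, source, n_histories: int, rng: np.random.Generator,
            tally: Optional[DoseGrid] = None) -> Tuple[DoseGrid, dict]:
        """Simulate ``n_histories`` primaries, returning the tally and the
        per-run audit summary."""
        if tally is None:
            tally = DoseGrid(self.grid)
        audit = {"source": 0.0, "deposited": 0.0, "machine": 0.0,
                 "escaped": 0.0, "max_violation": 0.0}
        done = 0
        while done < n_histories:
            n = min(self.settings.batch_size, n_histories - done)
            bank = source.sample(n, rng)
            bank["hist"] = np.arange(n, dtype=np.int64)
            self._run_batch(bank, rng, tally, audit)
            tally.add_histories(n)
            done += n
        return tally, audit

    # ------------------------------------------------------------------ #
    # batch machinery

    def _run_batch(self, bank, rng, tally, audit):
        B = len(bank["energy"])
        self._src = np.zeros(B)
        extra = np.where(bank["species"] == POSITRON, 2.0 * MEC2, 0.0)
        np.add.at(self._src, bank["hist"], (bank["energy"] + extra) * bank["weight"])
        self._esc = np.zeros(B)
        self._mach = np.zeros(B)
        self._dep_h: List[np.ndarray] = []
        self._dep_v: List[np.ndarray] = []
        self._dep_e: List[np.ndarray] = []

        queues: Dict[str, List[dict]] = {"ph_vox": [], "e_vox": [], "ph_mach": [], "e_mach": []}
        self._route_primaries(bank, queues)
        handlers = {"ph_vox": self._photons_voxel, "e_vox": self._electrons_voxel,
                    "ph_mach": self._photons_machine, "e_mach": self._electrons_machine}
        while True:
            sizes = {k: sum(len(b["energy"]) for b in v) for k, v in queues.items()}
            key = max(sizes, key=sizes.get)
            if sizes[key] == 0:
                break
            work = concat_banks(queues[key])
            queues[key] = []
            handlers[key](work, rng, queues)

        if self._dep_e:
            h = np.concatenate(self._dep_h)
            v = np.concatenate(self._dep_v)
            e = np.concatenate(self._dep_e)
            tally.add_batch(h, v, e)
            dep = np.bincount(h, weights=e, minlength=B)
        else:
            dep = np.zeros(B)
        total = dep + self._esc + self._mach
        viol = np.abs(total - self._src) / np.maximum(self._src, 1e-300)
        audit["max_violation"] = max(audit["max_violation"], float(viol.max(initial=0.0)))
        audit["source"] += float(self._src.sum())
        audit["deposited"] += float(dep.sum())
        audit["machine"] += float(self._mach.sum())
        audit["escaped"] += float(self._esc.sum())

    def _route_primaries(self, bank, queues):
        pos = bank["pos"]
        vox = self.grid.locate(pos)
        in_grid = np.all(vox >= 0, axis=1)
        ph = bank["species"] == PHOTON
        for mask, key in ((in_grid & ph, "ph_vox"), (in_grid & ~ph, "e_vox"),
                          (~in_grid & ph, "ph_mach"), (~in_grid & ~ph, "e_mach")):
            if mask.any():
                queues[key].append(select(bank, mask))

    # -- deposit / escape helpers ---------------------------------------
    def _deposit(self, hist, flat, edep):
        keep = edep > 0
        if np.any(keep):
            self._dep_h.append(hist[keep])
            self._dep_v.append(flat[keep])
            self._dep_e.append(edep[keep])

    def _escape(self, hist, edep):
        np.add.at(self._esc, hist, edep)

    def _machine_deposit(self, hist, edep):
        np.add.at(self._mach, hist, edep)

    def _enter_voxel_region(self, bank, queues, key):
        """Hand a bank entering the voxel region over, applying splitting."""
        n = self.settings.n_split
        if n > 1:
            bank = {k: np.repeat(v, n, axis=0) for k, v in bank.items()}
            bank["weight"] = bank["weight"] / n
        queues[key].append(bank)

    # ------------------------------------------------------------------ #
    # photon transport, voxel region (Woodcock)

    def _photons_voxel(self, bank, rng, queues):
        E, pos, dirn = bank["energy"], bank["pos"].copy(), bank["dir"]
        w, hist = bank["weight"], bank["hist"]
        n = len(E)
        # below-cutoff photons deposit locally
        low = E < self.settings.photon_cutoff
        if low.any():
            vox = self.grid.locate(pos[low])
            flat = self.grid.flat_index(vox)
            self._deposit(hist[low], flat, E[low] * w[low])
        act = np.flatnonzero(~low)
        mu_max = np.zeros(n)
        if len(act):
            mu_max[act] = self._mu_majorant(E[act])
        # zero majorant (e.g. empty grid): straight-line exit
        zero = act[mu_max[act] <= 0.0]
        if len(zero):
            self._exit_grid(select(bank, zero), queues)
            act = act[mu_max[act] > 0.0]
        inter_idx: List[np.ndarray] = []
        inter_flat: List[np.ndarray] = []
        while len(act):
            s = -np.log(rng.random(len(act))) / mu_max[act]
            pos[act] += s[:, None] * dirn[act]
            vox = self.grid.locate(pos[act])
            outside = np.any(vox < 0, axis=1)
            if outside.any():
                out_ids = act[outside]
                self._exit_grid({**select(bank, out_ids), "pos": pos[out_ids]},
                                queues, from_pos=bank["pos"][out_ids])
            act = act[~outside]
            if not len(act):
                break
            flat = self.grid.flat_index(self.grid.locate(pos[act]))
            mu = self._mu_local(E[act], flat)
            real = rng.random(len(act)) < mu / mu_max[act]
            inter_idx.append(act[real])
            inter_flat.append(flat[real])
            act = act[~real]
        if inter_idx:
            ids = np.concatenate(inter_idx)
            flats = np.concatenate(inter_flat)
            if len(ids):
                self._interact_photons({**select(bank, ids), "pos": pos[ids]},
                                       flats, rng, queues)

    def _exit_grid(self, bank, queues, from_pos=None):
        """Photons leaving the voxel grid: re-enter the machine region when
        one exists and they cross the interface upward, otherwise escape
        (the grid is surrounded by vacuum below the interface)."""
        E, w, hist = bank["energy"], bank["weight"], bank["hist"]
        if from_pos is not None:
            # place the photon at its true box-exit point
            t_in, t_out = self.grid.ray_box_span(from_pos, bank["dir"])
            pos = from_pos + (t_out[:, None] + 1e-9) * bank["dir"]
        else:
            pos = bank["pos"]
        if self.bodies or self.world_material:
            up = (bank["dir"][:, 2] > 0) & (pos[:, 2] >= self.z_interface - 1e-6)
            if up.any():
                sub = {**select(bank, up), "pos": pos[up]}
                queues["ph_mach"].append(sub)
            rest = ~up
        else:
            rest = np.ones(len(E), dtype=bool)
        if rest.any():
            self._escape(hist[rest], E[rest] * w[rest])

    def _interact_photons(self, bank, flat, rng, queues):
        E, pos, dirn = bank["energy"], bank["pos"], bank["dir"]
        w, hist = bank["weight"], bank["hist"]
        mu_c, mu_p, mu_pp = self._mu_channels_local(E, flat)
        ch = sample_interaction_channel(mu_c, mu_p, mu_pp, rng)
        out_ph: List[dict] = []
        out_e: List[dict] = []
        # Compton
        m = ch == 0
        if m.any():
            Eo, ct, Ee, ce = sample_compton(E[m], rng)
            phi = 2.0 * np.pi * rng.random(m.sum())
            d_ph = rotate_direction(dirn[m], ct, phi)
            d_e = rotate_direction(dirn[m], ce, phi + np.pi)
            low = Eo < self.settings.photon_cutoff
            if low.any():
                self._deposit(hist[m][low], flat[m][low], Eo[low] * w[m][low])
            if (~low).any():
                out_ph.append({"energy": Eo[~low], "pos": pos[m][~low],
                               "dir": d_ph[~low], "weight": w[m][~low],
                               "hist": hist[m][~low],
                               "species": np.full((~low).sum(), PHOTON, np.int8)})
            out_e.append({"energy": Ee, "pos": pos[m], "dir": d_e, "weight": w[m],
                          "hist": hist[m], "species": np.full(m.sum(), ELECTRON, np.int8)})
        # photoelectric: full energy to a forward photoelectron
        m = ch == 1
        if m.any():
            out_e.append({"energy": E[m].copy(), "pos": pos[m], "dir": dirn[m].copy(),
                          "weight": w[m], "hist": hist[m],
                          "species": np.full(m.sum(), ELECTRON, np.int8)})
        # pair production
        m = ch == 2
        if m.any():
            E1, E2 = pair_production(E[m], rng)
            for Ek, sp in ((E1, ELECTRON), (E2, POSITRON)):
                out_e.append({"energy": Ek, "pos": pos[m].copy(), "dir": dirn[m].copy(),
                              "weight": w[m], "hist": hist[m],
                              "species": np.full(m.sum(), sp, np.int8)})
        if out_ph:
            queues["ph_vox"].append(concat_banks(out_ph))
        if out_e:
            queues["e_vox"].append(concat_banks(out_e))

    # ------------------------------------------------------------------ #
    # electron transport, voxel region (condensed history)

    def _electrons_voxel(self, bank, rng, queues):
        st = self.settings
        work = [bank]
        while work:
            b = concat_banks(work)
            work = []
            E = b["energy"].copy()
            pos = b["pos"].copy()
            dirn = b["dir"].copy()
            w, hist, species = b["weight"], b["hist"], b["species"]
            act = np.arange(len(E))
            while len(act):
                # locate; particles nudged out of the grid escape
                vox = self.grid.locate(pos[act])
                outside = np.any(vox < 0, axis=1)
                if outside.any():
                    ids = act[outside]
                    extra = np.where(species[ids] == POSITRON, 2.0 * MEC2, 0.0)
                    self._escape(hist[ids], (E[ids] + extra) * w[ids])
                    act = act[~outside]
                    vox = vox[~outside]
                if not len(act):
                    break
                flat = self.grid.flat_index(vox)
                # absorption below cutoff
                absorb = E[act] <= st.electron_cutoff
                if absorb.any():
                    ids = act[absorb]
                    self._deposit(hist[ids], flat[absorb], E[ids] * w[ids])
                    ann = self._annihilate(ids, pos, w, hist, species, rng)
                    if ann is not None:
                        queues["ph_vox"].append(ann)
                    act = act[~absorb]
                    flat = flat[~absorb]
                    vox = vox[~absorb]
                if not len(act):
                    break
                a = act
                mat = self._mat_flat[flat]
                ratio = self._ratio_flat[flat]
                S = np.maximum(self._etable("S", E[a], mat, ratio), 1e-12)
                s_E = st.f_step * E[a] / S
                # distance to the voxel wall along the direction
                step_dir = dirn[a]
                sign_pos = step_dir > 0
                face = self.grid.origin + (vox + sign_pos) * self.grid.spacing
                with np.errstate(divide="ignore", invalid="ignore"):
                    t_wall = np.where(step_dir != 0, (face - pos[a]) / step_dir, np.inf)
                s_geom = np.maximum(t_wall.min(axis=1), 0.0)
                if st.hard_collisions:
                    imfp = self._etable("hard", E[a], mat, ratio)
                    with np.errstate(divide="ignore"):
                        s_hard = np.where(imfp > 0,
                                          -np.log(rng.random(len(a))) / np.maximum(imfp, 1e-300),
                                          np.inf)
                else:
                    s_hard = np.full(len(a), np.inf)
                s = np.minimum.reduce([s_E, np.full(len(a), st.max_step), s_geom + 1e-9,
                                       s_hard])
                s = np.maximum(s, 1e-9)
                # midpoint-rule continuous loss over the step
                Emid = np.maximum(E[a] - 0.5 * s * S, st.electron_cutoff * 0.5)
                dE = s * np.maximum(self._etable("S", Emid, mat, ratio), 1e-12)
                terminal = E[a] - dE <= st.electron_cutoff
                dE = np.where(terminal, E[a], np.minimum(dE, E[a]))
                self._deposit(hist[a], flat, dE * w[a])
                E[a] -= dE
                pos[a] += s[:, None] * dirn[a]
                if terminal.any():
                    ids = a[terminal]
                    E[ids] = 0.0
                    ann = self._annihilate(ids, pos, w, hist, species, rng)
                    if ann is not None:
                        queues["ph_vox"].append(ann)
                cont = a[~terminal]
                if not len(cont):
                    act = cont
                    continue
                sub = ~terminal
                # hard Moller collision when it limited the step
                did_hard = sub & (s == s_hard) & (E[a] > 2.0 * st.wc)
                if did_hard.any():
                    ids = a[did_hard]
                    W = sample_moller(E[ids], st.wc, rng)
                    cos_p, cos_d = moller_directions(E[ids], W)
                    phi = 2.0 * np.pi * rng.random(len(ids))
                    d_delta = rotate_direction(dirn[ids], cos_d, phi + np.pi)
                    dirn[ids] = rotate_direction(dirn[ids], cos_p, phi)
                    E[ids] -= W
                    work.append({"energy": W, "pos": pos[ids].copy(), "dir": d_delta,
                                 "weight": w[ids].copy(), "hist": hist[ids].copy(),
                                 "species": np.full(len(ids), ELECTRON, np.int8)})
                if st.multiple_scattering:
                    T = self._etable("T", Emid[sub], mat[sub], ratio[sub])
                    theta0sq = T * s[sub]
                    theta = np.sqrt(theta0sq *
                                    -np.log(np.clip(1.0 - rng.random(len(cont)), 1e-300, None)))
                    theta = np.minimum(theta, np.pi)
                    phi = 2.0 * np.pi * rng.random(len(cont))
                    dirn[cont] = rotate_direction(dirn[cont], np.cos(theta), phi)
                act = cont

    def _annihilate(self, ids, pos, w, hist, species, rng):
        """Two back-to-back 0.511 MeV photons for absorbed positrons."""
        p_mask = species[ids] == POSITRON
        if not p_mask.any():
            return None
        pids = ids[p_mask]
        axis = annihilation_directions(len(pids), rng)
        return concat_banks([
            make_bank(np.full(len(pids), MEC2), pos[pids], axis, w[pids], hist[pids],
                      np.full(len(pids), PHOTON, np.int8)),
            make_bank(np.full(len(pids), MEC2), pos[pids], -axis, w[pids], hist[pids],
                      np.full(len(pids), PHOTON, np.int8))])

    # ------------------------------------------------------------------ #
    # machine (quadric) region

    def _ray_hits_machine(self, pos, dirn):
        """Which rays can still reach the machine bodies' bounding box."""
        with np.errstate(divide="ignore", invalid="ignore"):
            inv = np.where(dirn != 0, 1.0 / np.where(dirn != 0, dirn, 1.0), np.inf)
            t1 = (self._machine_lo - pos) * inv
            t2 = (self._machine_hi - pos) * inv
        lo = np.where(dirn != 0, np.minimum(t1, t2), -np.inf)
        hi = np.where(dirn != 0, np.maximum(t1, t2), np.inf)
        par_out = (dirn == 0) & ((pos < self._machine_lo) | (pos > self._machine_hi))
        t_in = np.where(par_out.any(axis=1), np.inf, lo.max(axis=1))
        t_out = hi.min(axis=1)
        return (t_in <= t_out) & (t_out > 0)

    def _surface_min_distance(self, pos, dirn):
        """Min positive crossing distance to any machine surface (chunk-safe,
        with a bounding-box prune)."""
        n = len(pos)
        if len(self._surf) == 0:
            return np.full(n, np.inf)
        result = np.full(n, np.inf)
        reach = np.flatnonzero(self._ray_hits_machine(pos, dirn))
        if not len(reach):
            return result
        pos, dirn = pos[reach], dirn[reach]
        n = len(pos)
        out = np.full(n, np.inf)
        for i0 in range(0, n, _MACHINE_CHUNK):
            sl = slice(i0, min(i0 + _MACHINE_CHUNK, n))
            best = np.full(sl.stop - sl.start, np.inf)
            # plane surfaces: single dot-product root
            if len(self._plane_ids):
                num = pos[sl] @ self._plane_n.T + self._plane_c
                den = dirn[sl] @ self._plane_n.T
                with np.errstate(divide="ignore", invalid="ignore"):
                    t = np.where(den != 0, -num / np.where(den != 0, den, 1.0), np.inf)
                t = np.where(t > BOUNDARY_TOL, t, np.inf)
                best = np.minimum(best, t.min(axis=1))
            # true quadric surfaces: quadratic roots
            if len(self._quad_ids):
                ph = np.concatenate([pos[sl], np.ones((sl.stop - sl.start, 1))], axis=1)
                dh = np.concatenate([dirn[sl], np.zeros((sl.stop - sl.start, 1))], axis=1)
                Md = np.einsum("sij,nj->nsi", self._quad_surf, dh)
                a = np.einsum("ni,nsi->ns", dh, Md)
                b = 2.0 * np.einsum("ni,nsi->ns", ph, Md)
                c = np.einsum("ni,sij,nj->ns", ph, self._quad_surf, ph)
                lin = np.abs(a) < 1e-300
                with np.errstate(divide="ignore", invalid="ignore"):
                    t_lin = np.where(lin & (b != 0), -c / np.where(b != 0, b, 1.0), np.inf)
                    t_lin = np.where(t_lin > BOUNDARY_TOL, t_lin, np.inf)
                    disc = b * b - 4.0 * a * c
                    sq = np.sqrt(np.where(disc >= 0, disc, 0.0))
                    t1 = (-b - sq) / (2.0 * np.where(lin, 1.0, a))
                    t2 = (-b + sq) / (2.0 * np.where(lin, 1.0, a))
                    for t in (t1, t2):
                        t = np.where(~lin & (disc >= 0) & (t > BOUNDARY_TOL), t, np.inf)
                        best = np.minimum(best, t.min(axis=1))
                    best = np.minimum(best, t_lin.min(axis=1))
            out[sl] = best
        result[reach] = out
        return result

    def _locate_bodies(self, pos):
        """Body index per point (-1 = world), via one vectorized evaluation
        of the surface soup on points inside the machine bounding box."""
        out = np.full(len(pos), -1, dtype=np.int64)
        if not self.bodies:
            return out
        near = np.flatnonzero(np.all((pos >= self._machine_lo)
                                     & (pos <= self._machine_hi), axis=1))
        if not len(near):
            return out
        p = pos[near]
        q = np.empty((len(p), len(self._surf)))
        if len(self._plane_ids):
            q[:, self._plane_ids] = p @ self._plane_n.T + self._plane_c
        if len(self._quad_ids):
            ph = np.concatenate([p, np.ones((len(p), 1))], axis=1)
            q[:, self._quad_ids] = np.einsum("ni,sij,nj->ns", ph, self._quad_surf, ph)
        ok = self._surf_sign[None, :] * q >= -1e-12
        unassigned = np.ones(len(p), dtype=bool)
        for bi, sl in enumerate(self._body_slices):
            if not unassigned.any():
                break
            inside = unassigned & ok[:, sl].all(axis=1)
            out[near[inside]] = bi
            unassigned &= ~inside
        return out

    def _world_exit(self, pos, dirn):
        """Distance to the world boundary (lateral half-extent, top plane)."""
        he = self.world_half_extent
        t = np.full(len(pos), np.inf)
        for ax, bound in ((0, he), (1, he)):
            d = dirn[:, ax]
            with np.errstate(divide="ignore", invalid="ignore"):
                t1 = np.where(d > 0, (bound - pos[:, ax]) / np.where(d != 0, d, 1.0), np.inf)
                t2 = np.where(d < 0, (-bound - pos[:, ax]) / np.where(d != 0, d, 1.0), np.inf)
            t = np.minimum.reduce([t, t1, t2])
        dz = dirn[:, 2]
        with np.errstate(divide="ignore", invalid="ignore"):
            t_top = np.where(dz > 0, (self._world_z_top - pos[:, 2]) / np.where(dz != 0, dz, 1.0),
                             np.inf)
        return np.minimum(t, t_top)

    def _interface_distance(self, pos, dirn):
        dz = dirn[:, 2]
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(dz < 0, (self.z_interface - pos[:, 2]) / np.where(dz != 0, dz, 1.0),
                         np.inf)
        return np.where(t >= 0, t, np.inf)

    def _cross_interface(self, bank, queues):
        """Particles at the interface plane: enter the voxel grid (with
        splitting) if their ray hits it, otherwise escape (vacuum below)."""
        t_in, t_out = self.grid.ray_box_span(bank["pos"], bank["dir"])
        hits = t_in < t_out
        if hits.any():
            sub = select(bank, hits)
            sub = dict(sub)
            sub["pos"] = sub["pos"] + (t_in[hits][:, None] + 1e-9) * sub["dir"]
            ph = sub["species"] == PHOTON
            if ph.any():
                self._enter_voxel_region(select(sub, ph), queues, "ph_vox")
            if (~ph).any():
                self._enter_voxel_region(select(sub, ~ph), queues, "e_vox")
        miss = ~hits
        if miss.any():
            extra = np.where(bank["species"][miss] == POSITRON, 2.0 * MEC2, 0.0)
            self._escape(bank["hist"][miss], (bank["energy"][miss] + extra)
                         * bank["weight"][miss])

    def _photons_machine(self, bank, rng, queues):
        st = self.settings
        E = bank["energy"].copy()
        pos = bank["pos"].copy()
        dirn = bank["dir"].copy()
        w, hist = bank["weight"], bank["hist"]
        act = np.arange(len(E))
        low = E[act] < st.photon_cutoff
        if low.any():
            ids = act[low]
            body = self._locate_bodies(pos[ids])
            self._machine_deposit(hist[ids], E[ids] * w[ids])
            act = act[~low]
        while len(act):
            body = self._locate_bodies(pos[act])
            mu = np.zeros(len(act))
            for bi in np.unique(body):
                sel = body == bi
                mi = self._world_mat if bi < 0 else self._body_mat[bi]
                if mi >= 0:
                    mu[sel] = self.tables[mi].mu(E[act][sel])
            t_surf = self._surface_min_distance(pos[act], dirn[act])
            t_if = self._interface_distance(pos[act], dirn[act])
            t_world = self._world_exit(pos[act], dirn[act])
            with np.errstate(divide="ignore"):
                s_int = np.where(mu > 0, -np.log(rng.random(len(act))) / np.maximum(mu, 1e-300),
                                 np.inf)
            t_geom = np.minimum.reduce([t_surf + 2.0 * BOUNDARY_TOL, t_if + 1e-9, t_world + 1e-9])
            interact = s_int < t_geom
            t = np.where(interact, s_int, t_geom)
            # nowhere to go (numerical corner): treat as escaped
            lost = ~np.isfinite(t)
            if lost.any():
                ids = act[lost]
                self._escape(hist[ids], E[ids] * w[ids])
                act = act[~lost]
                if not len(act):
                    break
                body, t, interact = body[~lost], t[~lost], interact[~lost]
            pos[act] += t[:, None] * dirn[act]
            # crossing the interface plane
            crossed = ~interact & (pos[act][:, 2] <= self.z_interface + 1e-6) \
                & (dirn[act][:, 2] < 0)
            if crossed.any():
                ids = act[crossed]
                self._cross_interface({"energy": E[ids], "pos": pos[ids], "dir": dirn[ids],
                                       "weight": w[ids], "hist": hist[ids],
                                       "species": np.full(len(ids), PHOTON, np.int8)}, queues)
            # leaving the world
            escaped = ~interact & ~crossed & (
                (np.abs(pos[act][:, 0]) >= self.world_half_extent - 1e-6)
                | (np.abs(pos[act][:, 1]) >= self.world_half_extent - 1e-6)
                | (pos[act][:, 2] >= self._world_z_top - 1e-6))
            if escaped.any():
                ids = act[escaped]
                self._escape(hist[ids], E[ids] * w[ids])
            if interact.any():
                ids = act[interact]
                keep = self._interact_photons_machine(ids, E, pos, dirn, w, hist, body[interact],
                                                      rng, queues)
            else:
                keep = np.zeros(0, dtype=np.int64)
            act = np.concatenate([act[~interact & ~crossed & ~escaped], keep])

    def _interact_photons_machine(self, ids, E, pos, dirn, w, hist, body, rng, queues):
        """Handle real interactions in the machine region; returns the ids of
        photons that continue (Compton survivors)."""
        st = self.settings
        mu_c = np.zeros(len(ids))
        mu_p = np.zeros(len(ids))
        mu_pp = np.zeros(len(ids))
        for bi in np.unique(body):
            sel = body == bi
            mi = self._world_mat if bi < 0 else self._body_mat[bi]
            c, p, pp = self.tables[mi].mu_channels(E[ids][sel])
            mu_c[sel], mu_p[sel], mu_pp[sel] = c, p, pp
        ch = sample_interaction_channel(mu_c, mu_p, mu_pp, rng)
        out_e: List[dict] = []
        keep: List[np.ndarray] = []
        m = ch == 0
        if m.any():
            sub = ids[m]
            Eo, ct, Ee, ce = sample_compton(E[sub], rng)
            phi = 2.0 * np.pi * rng.random(len(sub))
            d_e = rotate_direction(dirn[sub], ce, phi + np.pi)
            dirn[sub] = rotate_direction(dirn[sub], ct, phi)
            out_e.append({"energy": Ee, "pos": pos[sub].copy(), "dir": d_e,
                          "weight": w[sub].copy(), "hist": hist[sub].copy(),
                          "species": np.full(len(sub), ELECTRON, np.int8)})
            E[sub] = Eo
            low = Eo < st.photon_cutoff
            if low.any():
                self._machine_deposit(hist[sub][low], Eo[low] * w[sub][low])
            keep.append(sub[~low])
        m = ch == 1
        if m.any():
            sub = ids[m]
            out_e.append({"energy": E[sub].copy(), "pos": pos[sub].copy(),
                          "dir": dirn[sub].copy(), "weight": w[sub].copy(),
                          "hist": hist[sub].copy(),
                          "species": np.full(len(sub), ELECTRON, np.int8)})
        m = ch == 2
        if m.any():
            sub = ids[m]
            E1, E2 = pair_production(E[sub], rng)
            for Ek, sp in ((E1, ELECTRON), (E2, POSITRON)):
                out_e.append({"energy": Ek, "pos": pos[sub].copy(), "dir": dirn[sub].copy(),
                              "weight": w[sub].copy(), "hist": hist[sub].copy(),
                              "species": np.full(len(sub), sp, np.int8)})
        if out_e:
            queues["e_mach"].append(concat_banks(out_e))
        return np.concatenate(keep) if keep else np.zeros(0, dtype=np.int64)

    def _electrons_machine(self, bank, rng, queues):
        """Condensed-history transport among the quadric bodies and the
        world medium, with movable-skins range rejection in flagged bodies."""
        st = self.settings
        work = [bank]
        while work:
            b = concat_banks(work)
            work = []
            E = b["energy"].copy()
            pos = b["pos"].copy()
            dirn = b["dir"].copy()
            w, hist, species = b["weight"], b["hist"], b["species"]
            act = np.arange(len(E))
            while len(act):
                body = self._locate_bodies(pos[act])
                in_vacuum_world = (body < 0) & (self._world_mat < 0)
                # vacuum world: fly straight to the interface or escape
                if in_vacuum_world.any():
                    ids = act[in_vacuum_world]
                    t_if = self._interface_distance(pos[ids], dirn[ids])
                    t_surf = self._surface_min_distance(pos[ids], dirn[ids])
                    go = (t_if < np.inf) & (t_if <= t_surf)
                    if go.any():
                        gids = ids[go]
                        newpos = pos[gids] + (t_if[go][:, None] + 1e-9) * dirn[gids]
                        self._cross_interface({"energy": E[gids], "pos": newpos,
                                               "dir": dirn[gids], "weight": w[gids],
                                               "hist": hist[gids], "species": species[gids]},
                                              queues)
                    if (~go).any():
                        sids = ids[~go]
                        t_adv = t_surf[~go]
                        fin = ~np.isfinite(t_adv)
                        extra = np.where(species[sids] == POSITRON, 2.0 * MEC2, 0.0)
                        if fin.any():
                            self._escape(hist[sids[fin]],
                                         (E[sids[fin]] + extra[fin]) * w[sids[fin]])
                        mv = ~fin
                        pos[sids[mv]] += (t_adv[mv][:, None] + 2 * BOUNDARY_TOL) * dirn[sids[mv]]
                        act = np.concatenate([act[~in_vacuum_world], sids[mv]])
                        continue
                    act = act[~in_vacuum_world]
                    continue
                # material per particle
                mat = np.where(body >= 0,
                               np.array(self._body_mat + [0])[np.maximum(body, 0)],
                               self._world_mat)
                a = act
                absorb = E[a] <= st.electron_cutoff
                if absorb.any():
                    ids = a[absorb]
                    self._machine_deposit(hist[ids], E[ids] * w[ids])
                    ann = self._annihilate(ids, pos, w, hist, species, rng)
                    if ann is not None:
                        queues["ph_mach"].append(ann)
                    a = a[~absorb]
                    body = body[~absorb]
                    mat = mat[~absorb]
                if not len(a):
                    act = a
                    continue
                ratio = np.ones(len(a))
                # movable-skins range rejection
                if st.range_rejection:
                    rej_mask = np.array([bi >= 0 and self.bodies[bi].range_reject
                                         for bi in body])
                    if rej_mask.any():
                        ids = a[rej_mask]
                        R = self._etable("R", E[ids], mat[rej_mask], np.ones(rej_mask.sum()))
                        d_near = self._nearest_surface_distance(pos[ids], body[rej_mask])
                        kill = R < d_near - st.skin_depth
                        if kill.any():
                            kids = ids[kill]
                            self._machine_deposit(hist[kids], E[kids] * w[kids])
                            ann = self._annihilate(kids, pos, w, hist, species, rng)
                            if ann is not None:
                                queues["ph_mach"].append(ann)
                            keepm = np.ones(len(a), dtype=bool)
                            keepm[np.searchsorted(a, kids)] = False
                            a = a[keepm]
                            body = body[keepm]
                            mat = mat[keepm]
                            ratio = np.ones(len(a))
                if not len(a):
                    act = a
                    continue
                S = np.maximum(self._etable("S", E[a], mat, ratio), 1e-12)
                s_E = st.f_step * E[a] / S
                t_surf = self._surface_min_distance(pos[a], dirn[a])
                t_if = self._interface_distance(pos[a], dirn[a])
                if st.hard_collisions:
                    imfp = self._etable("hard", E[a], mat, ratio)
                    with np.errstate(divide="ignore"):
                        s_hard = np.where(imfp > 0,
                                          -np.log(rng.random(len(a))) / np.maximum(imfp, 1e-300),
                                          np.inf)
                else:
                    s_hard = np.full(len(a), np.inf)
                s = np.minimum.reduce([s_E, t_surf + 2 * BOUNDARY_TOL, t_if + 1e-9, s_hard])
                s = np.clip(s, 1e-9, None)
                Emid = np.maximum(E[a] - 0.5 * s * S, st.electron_cutoff * 0.5)
                dE = s * np.maximum(self._etable("S", Emid, mat, ratio), 1e-12)
                terminal = E[a] - dE <= st.electron_cutoff
                dE = np.where(terminal, E[a], np.minimum(dE, E[a]))
                self._machine_deposit(hist[a], dE * w[a])
                E[a] -= dE
                pos[a] += s[:, None] * dirn[a]
                if terminal.any():
                    ids = a[terminal]
                    E[ids] = 0.0
                    ann = self._annihilate(ids, pos, w, hist, species, rng)
                    if ann is not None:
                        queues["ph_mach"].append(ann)
                cont = a[~terminal]
                if len(cont):
                    sub = ~terminal
                    did_hard = sub & (s == s_hard) & (E[a] > 2.0 * st.wc)
                    if did_hard.any():
                        ids = a[did_hard]
                        W = sample_moller(E[ids], st.wc, rng)
                        cos_p, cos_d = moller_directions(E[ids], W)
                        phi = 2.0 * np.pi * rng.random(len(ids))
                        d_delta = rotate_direction(dirn[ids], cos_d, phi + np.pi)
                        dirn[ids] = rotate_direction(dirn[ids], cos_p, phi)
                        E[ids] -= W
                        work.append({"energy": W, "pos": pos[ids].copy(), "dir": d_delta,
                                     "weight": w[ids].copy(), "hist": hist[ids].copy(),
                                     "species": np.full(len(ids), ELECTRON, np.int8)})
                    if st.multiple_scattering:
                        T = self._etable("T", Emid[sub], mat[sub], ratio[sub])
                        theta = np.sqrt(T * s[sub] *
                                        -np.log(np.clip(1.0 - rng.random(len(cont)),
                                                        1e-300, None)))
                        theta = np.minimum(theta, np.pi)
                        phi = 2.0 * np.pi * rng.random(len(cont))
                        dirn[cont] = rotate_direction(dirn[cont], np.cos(theta), phi)
                    # electrons that reached the interface plane hand over
                    at_if = cont[pos[cont][:, 2] <= self.z_interface + 1e-6]
                    if len(at_if):
                        self._cross_interface({"energy": E[at_if], "pos": pos[at_if],
                                               "dir": dirn[at_if], "weight": w[at_if],
                                               "hist": hist[at_if],
                                               "species": species[at_if]}, queues)
                        cont = np.setdiff1d(cont, at_if, assume_unique=True)
                act = cont

    def _nearest_surface_distance(self, pos, body_idx):
        """First-order distance |Q|/|grad Q| to the nearest surface of each
        particle's own body (exact for planes)."""
        out = np.full(len(pos), np.inf)
        ph = np.concatenate([pos, np.ones((len(pos), 1))], axis=1)
        for bi in np.unique(body_idx):
            sel = np.flatnonzero(body_idx == bi)
            surf_ids = np.flatnonzero(self._surf_body == bi)
            M = self._surf[surf_ids]
            q = np.einsum("ni,sij,nj->ns", ph[sel], M, ph[sel])
            grad = 2.0 * np.einsum("sij,nj->nsi", M, ph[sel])[:, :, :3]
            gn = np.linalg.norm(grad, axis=2)
            d = np.abs(q) / np.maximum(gn, 1e-300)
            out[sel] = d.min(axis=1)
        return out


# ---------------------------------------------------------------------------
# scalar contract operations

def woodcock_flight(p: ParticleState, engine: TransportEngine,
                    rng: np.random.Generator):
    """Track a single photon through the voxel grid by delta tracking.

    Returns ``("interaction", state, flat_voxel)`` at the first real
    interaction site or ``("escape", state)`` at the grid exit; no voxel-wall
    intersections are computed.
    """
    if p.species != PHOTON:
        raise ValueError("woodcock_flight transports photons")
    grid = engine.grid
    E = np.array([p.energy])
    mu_max = float(engine._mu_majorant(E)[0])
    pos = p.position.copy()
    if mu_max <= 0.0:
        t_in, t_out = grid.ray_box_span(pos[None], p.direction[None])
        q = p.copy()
        q.position = pos + float(t_out[0] + 1e-9) * p.direction
        return ("escape", q)
    while True:
        s = -np.log(rng.random()) / mu_max
        pos = pos + s * p.direction
        vox = grid.locate(pos[None])[0]
        if np.any(vox < 0):
            q = p.copy()
            q.position = pos
            return ("escape", q)
        flat = int(grid.flat_index(vox))
        mu = float(engine._mu_local(E, np.array([flat]))[0])
        if rng.random() < mu / mu_max:
            q = p.copy()
            q.position = pos
            return ("interaction", q, flat)


def condensed_step(p: ParticleState, grid: VoxelGrid, table: MaterialTable,
                   settings: TransportSettings, rng: np.random.Generator,
                   *, s_hard: float = np.inf):
    """One condensed-history step of a charged particle in the voxel grid.

    Scalar reference implementation of the step contract: the step length is
    the minimum of the energy-loss limit f_step*E/S, the geometric cap, the
    distance to the grid boundary and the supplied hard-collision distance;
    the continuous (midpoint-rule) energy deposit is split between traversed
    voxels in proportion to the chord lengths.  Returns
    ``(state, deposits)`` with deposits as a list of (flat voxel, MeV).
    """
    from .geometry import voxel_ray_walk

    st = settings
    q = p.copy()
    vox = grid.locate(q.position[None])[0]
    if np.any(vox < 0):
        return q, []
    flat = int(grid.flat_index(vox))
    ratio = grid.density.ravel()[flat] / table.density
    if q.energy <= st.electron_cutoff:
        dep = [(flat, q.energy * q.weight)]
        q.energy = 0.0
        return q, dep
    S = float(table.S(np.array([q.energy]))[0]) * ratio
    t_in, t_out = grid.ray_box_span(q.position[None], q.direction[None])
    s = min(st.f_step * q.energy / S, st.max_step, float(t_out[0]), s_hard)
    Emid = max(q.energy - 0.5 * s * S, st.electron_cutoff * 0.5)
    dE = s * float(table.S(np.array([Emid]))[0]) * ratio
    terminal = q.energy - dE <= st.electron_cutoff
    dE = q.energy if terminal else dE
    # split the deposit over the traversed voxels by chord length
    chords = list(voxel_ray_walk(q.position, q.direction, grid))
    total = sum(c for _, c in chords)
    deposits = []
    acc = 0.0
    for idx3, c in chords:
        if acc >= s:
            break
        frac = min(c, s - acc) / s
        deposits.append((int(grid.flat_index(np.array(idx3))), dE * frac * q.weight))
        acc += c
    q.position = q.position + s * q.direction
    q.energy = 0.0 if terminal else q.energy - dE
    if not terminal and st.multiple_scattering:
        from .electrons import sample_multiple_scattering

        class _Scaled:
            def T_scatter(self_, E):
                return table.T_scatter(E) * ratio
        theta, phi = sample_multiple_scattering(np.array([Emid]), _Scaled(), s, rng)
        q.direction = rotate_direction(q.direction[None], np.cos(theta), phi)[0]
    return q, deposits


def range_rejection_movable_skins(p: ParticleState, body: Body,
                                  table: MaterialTable, skin_depth: float) -> bool:
    """Movable-skins test: absorb the electron on the spot when its residual
    CSDA range is smaller than the distance to the body's skin (the inner
    margin ``skin_depth`` from any surface)."""
    ph = np.append(p.position, 1.0)
    d_near = np.inf
    for mat in body.world_matrices():
        q = ph @ mat @ ph
        grad = 2.0 * (mat @ ph)[:3]
        d_near = min(d_near, abs(q) / max(np.linalg.norm(grad), 1e-300))
    R = float(table.csda_range(np.array([p.energy]))[0])
    return R < d_near - skin_depth
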