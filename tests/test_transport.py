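"""Transport engine: Woodcock equivalence, condensed-history limits,
conservation audits and variance-reduction unbiasedness (reduced problem
sizes; the full-size checks live in the acceptance suite)."""

import numpy as np
import pytest
from scipy.stats import kstest

from mcdose.geometry import MixedGeometry
from mcdose.machine import LeafBankSpec
from mcdose.materials import default_registry
from mcdose.particles import ELECTRON, PHOTON, ParticleState, make_bank, split_particle
from mcdose.rng import stream_generator
from mcdose.scenes import build_mlc_scene, build_water_phantom, default_mlc_pattern
from mcdose.transport import (TransportEngine, TransportSettings, condensed_step,
                              range_rejection_movable_skins, woodcock_flight)

from conftest import uniform_grid


class PencilSource:
    def __init__(self, energy=2.0, species=PHOTON, z=0.0):
        self.energy, self.species, self.z = energy, species, z

    def sample(self, n, rng):
        return make_bank(np.full(n, self.energy),
                         np.tile([0.0, 0.0, self.z], (n, 1)),
                         np.tile([0.0, 0.0, -1.0], (n, 1)), 1.0, 0, self.species)


def layered_grid():
    """Water / lung / bone slabs along z for heterogeneity tests."""
    g = uniform_grid((8, 8, 12), spacing=(1.0, 1.0, 0.5),
                     materials=("water", "lung", "bone"))
    g.material[:, :, 4:8] = 1
    g.density[:, :, 4:8] = 0.3
    g.material[:, :, 0:4] = 2
    g.density[:, :, 0:4] = 1.85
    return g


class TestWoodcock:
    def test_first_interaction_depth_matches_attenuation_law(self, registry):
        """KS test of Woodcock first-interaction depths against the
        inhomogeneous exponential law from a voxel ray walk."""
        from mcdose.geometry import voxel_ray_walk

        g = layered_grid()
        eng = TransportEngine(g, registry=registry)
        rng = stream_generator(21, 0)
        E = 2.0
        depths = []
        p0 = ParticleState(PHOTON, E, np.array([0.05, 0.05, -1e-9]),
                           np.array([0.0, 0.0, -1.0]))
        n = 4000
        for _ in range(n):
            out = woodcock_flight(p0, eng, rng)
            if out[0] == "interaction":
                depths.append(-out[1].position[2])
        # oracle CDF: 1 - exp(-integral mu dz), piecewise from the ray walk
        segs = []
        acc = 0.0
        for idx, chord in voxel_ray_walk(p0.position, p0.direction, g):
            mat = g.material[idx]
            mu = float(registry[g.materials[mat]].mu(E)) \
                * g.density[idx] / registry[g.materials[mat]].density
            segs.append((acc, acc + chord, mu))
            acc += chord

        def cdf(z):
            z = np.atleast_1d(z)
            tau = np.zeros_like(z, dtype=float)
            for z0, z1, mu in segs:
                tau += mu * np.clip(z - z0, 0.0, z1 - z0)
            total = sum(mu * (z1 - z0) for z0, z1, mu in segs)
            return (1.0 - np.exp(-tau)) / (1.0 - np.exp(-total))

        stat, p = kstest(np.array(depths), cdf)
        assert p > 0.01

    def test_near_vacuum_grid_is_transparent(self, registry):
        g = uniform_grid((4, 4, 4), spacing=1.0, density=1e-6)
        eng = TransportEngine(g, registry=registry)
        rng = stream_generator(3, 0)
        tally, audit = eng.run(PencilSource(2.0), 2000, rng)
        assert audit["escaped"] / audit["source"] > 0.999
        assert audit["max_violation"] < 1e-9

    def test_homogeneous_mean_free_path(self, registry):
        """Mean first-flight depth in a water block matches the truncated
        exponential law for 1/mu within 3 standard errors."""
        g = uniform_grid((30, 30, 120), spacing=(1.0, 1.0, 0.5), density=1.0)
        eng = TransportEngine(g, registry=registry)
        rng = stream_generator(5, 0)
        E, T = 2.0, 60.0
        p0 = ParticleState(PHOTON, E, np.array([0.0, 0.0, -1e-9]),
                           np.array([0.0, 0.0, -1.0]))
        depths = []
        for _ in range(3000):
            out = woodcock_flight(p0, eng, rng)
            if out[0] == "interaction":
                depths.append(-out[1].position[2])
        mu = float(registry["water"].mu(E))
        # mean of an exponential truncated to [0, T]
        expect = 1.0 / mu - T * np.exp(-mu * T) / (1.0 - np.exp(-mu * T))
        depths = np.array(depths)
        se = depths.std(ddof=1) / np.sqrt(len(depths))
        assert abs(depths.mean() - expect) < 3.0 * se


class TestEnergyConservation:
    def test_photon_shower_audit(self, registry):
        g = uniform_grid((10, 10, 10), spacing=1.0)
        eng = TransportEngine(g, registry=registry)
        rng = stream_generator(9, 0)
        tally, audit = eng.run(PencilSource(6.0), 3000, rng)
        assert audit["max_violation"] < 1e-9
        assert audit["source"] == pytest.approx(
            audit["deposited"] + audit["escaped"] + audit["machine"], rel=1e-12)
        assert tally.total_energy() == pytest.approx(audit["deposited"], rel=1e-12)

    def test_electron_source_audit_including_deltas(self, registry):
        g = uniform_grid((10, 10, 10), spacing=0.5)
        eng = TransportEngine(g, registry=registry)
        rng = stream_generator(10, 0)
        tally, audit = eng.run(PencilSource(6.0, species=ELECTRON), 1000, rng)
        assert audit["max_violation"] < 1e-9


class TestCondensedHistory:
    def test_csda_path_length_limit(self, registry):
        """Scattering and hard collisions off: total path length until
        absorption equals the residual CSDA range within 1% (f_step=0.02)."""
        water = registry["water"]
        g = uniform_grid((40, 40, 40), spacing=0.5)
        st = TransportSettings(f_step=0.02, multiple_scattering=False,
                               hard_collisions=False)
        rng = stream_generator(2, 0)
        E0 = 6.0
        p = ParticleState(ELECTRON, E0, np.array([0.0, 0.0, -0.01]),
                          np.array([0.0, 0.0, -1.0]))
        path = 0.0
        for _ in range(10000):
            q, deps = condensed_step(p, g, water, st, rng)
            path += np.linalg.norm(q.position - p.position)
            p = q
            if p.energy <= 0.0:
                break
        assert path == pytest.approx(float(water.csda_range(E0)), rel=0.01)

    def test_terminal_step_deposits_residual(self, registry):
        g = uniform_grid((4, 4, 4), spacing=1.0)
        st = TransportSettings()
        rng = stream_generator(2, 0)
        p = ParticleState(ELECTRON, 0.205, np.array([0.0, 0.0, -1.5]),
                          np.array([0.0, 0.0, -1.0]))
        q, deps = condensed_step(p, g, default_registry()["water"], st, rng)
        total = sum(e for _, e in deps)
        assert q.energy == pytest.approx(0.0)
        assert total == pytest.approx(0.205)

    def test_deposit_split_proportional_to_chords(self, registry):
        """A step crossing voxel walls spreads its deposit by chord length."""
        water = registry["water"]
        g = uniform_grid((60, 60, 60), spacing=0.05)
        st = TransportSettings(f_step=0.1, max_step=0.2, multiple_scattering=False,
                               hard_collisions=False)
        rng = stream_generator(4, 0)
        p = ParticleState(ELECTRON, 5.0, np.array([0.0, 0.0, -0.076]),
                          np.array([0.0, 0.0, -1.0]))
        q, deps = condensed_step(p, g, water, st, rng)
        assert len(deps) >= 3
        s = np.linalg.norm(q.position - p.position)
        chords = np.array([e for _, e in deps])
        # interior chords correspond to full voxels -> equal deposits
        assert np.allclose(chords[1:-1], chords[1], rtol=1e-9)
        assert sum(chords) == pytest.approx(chords.sum())


class TestVarianceReduction:
    def test_split_particle_weights(self):
        p = ParticleState(PHOTON, 1.0, np.zeros(3), np.array([0.0, 0.0, -1.0]))
        parts = split_particle(p, 10)
        assert len(parts) == 10
        assert sum(q.weight for q in parts) == pytest.approx(p.weight)
        assert split_particle(p, 1)[0].weight == p.weight

    def test_splitting_unbiased_and_reduces_batch_variance(self, registry):
        g = uniform_grid((16, 16, 10), spacing=1.0)
        src = PencilSource(2.0, z=20.0)
        means = {}
        batch_tot = {}
        for split in (1, 10):
            st = TransportSettings(n_split=split)
            eng = TransportEngine(g, registry=registry, settings=st)
            totals = []
            for b in range(12):
                rng = stream_generator(100 + b, split)
                tally, audit = eng.run(src, 600, rng)
                assert audit["max_violation"] < 1e-9
                totals.append(tally.total_energy() / tally.n_hist)
            totals = np.array(totals)
            means[split] = totals.mean()
            batch_tot[split] = totals.std(ddof=1)
        se = np.hypot(batch_tot[1], batch_tot[10]) / np.sqrt(12)
        assert abs(means[1] - means[10]) < 3.0 * se
        assert batch_tot[10] < batch_tot[1]

    def test_movable_skins_scalar_rule(self, registry):
        """Deep electron with short range is absorbed; one inside the skin
        is never rejected."""
        from mcdose.geometry import Body, Quadric
        slab = Body(((Quadric.plane((0, 0, 1), 40.0), +1),
                     (Quadric.plane((0, 0, 1), 46.0), -1),
                     (Quadric.plane((1, 0, 0), -5.0), +1),
                     (Quadric.plane((1, 0, 0), 5.0), -1),
                     (Quadric.plane((0, 1, 0), -5.0), +1),
                     (Quadric.plane((0, 1, 0), 5.0), -1)), "tungsten")
        w = registry["tungsten"]
        deep = ParticleState(ELECTRON, 1.0, np.array([0.0, 0.0, 43.0]),
                             np.array([0.0, 0.0, -1.0]))
        assert float(w.csda_range(1.0)) < 0.1
        assert range_rejection_movable_skins(deep, slab, w, skin_depth=0.5)
        shallow = ParticleState(ELECTRON, 1.0, np.array([0.0, 0.0, 45.9]),
                                np.array([0.0, 0.0, -1.0]))
        assert not range_rejection_movable_skins(shallow, slab, w, skin_depth=0.5)


class TestMixedGeometryTransport:
    def test_mlc_scene_runs_and_audits(self, registry):
        phantom = build_water_phantom(size=(20, 20, 10), spacing=(1.0, 1.0, 1.0))
        scene = build_mlc_scene(default_mlc_pattern(6, field_half=3.0),
                                LeafBankSpec(n_pairs=6), phantom)
        from mcdose.sources import AnalyticBeam
        eng = TransportEngine(scene, registry=registry)
        rng = stream_generator(8, 0)
        tally, audit = eng.run(AnalyticBeam(divergence=2.0), 3000, rng)
        assert audit["max_violation"] < 1e-9
        assert tally.total_energy() > 0
        assert audit["machine"] > 0        # the bank absorbs part of the beam
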