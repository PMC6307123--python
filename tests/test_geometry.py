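"""Voxel/quadric geometry: membership, ray crossings, walks, coarsening."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mcdose.geometry import (Body, Quadric, VoxelGrid, coarsen_field, coarsen_grid,
                             ray_quadric_distance, rotation_matrix, voxel_ray_walk)

from conftest import uniform_grid


def unit(v):
    v = np.asarray(v, dtype=float)
    return v / np.linalg.norm(v)


class TestLocate:
    def test_point_on_face_goes_to_higher_voxel(self):
        g = uniform_grid((4, 4, 4), spacing=1.0, origin=(0, 0, 0))
        idx = g.locate([[1.0, 0.5, 0.5]])[0]
        assert tuple(idx) == (1, 0, 0)

    def test_sphere_body_center(self):
        b = Body(((Quadric.sphere((1, 2, 3), 2.0), -1),), "water")
        assert b.contains([[1, 2, 3]])[0]
        assert not b.contains([[4.5, 2, 3]])[0]

    def test_slab_body_matches_interval_oracle(self, rng):
        """Sign-test membership of a z-slab equals a direct interval check."""
        slab = Body(((Quadric.plane((0, 0, 1), 1.0), +1),
                     (Quadric.plane((0, 0, 1), 3.0), -1)), "water")
        pts = rng.uniform(-5, 5, (1000, 3))
        expect = (pts[:, 2] >= 1.0) & (pts[:, 2] <= 3.0)
        assert np.array_equal(slab.contains(pts), expect)

    def test_outside_everything_is_world(self):
        g = uniform_grid((2, 2, 2), spacing=1.0, origin=(0, 0, 0))
        assert np.all(g.locate([[10.0, 0, 0]])[0] == -1)


class TestRayQuadric:
    def test_unit_sphere_head_on(self):
        b = Body(((Quadric.sphere((0, 0, 2), 1.0), -1),), "w")
        assert ray_quadric_distance([0, 0, 0], [0, 0, 1], b) == pytest.approx(1.0)

    def test_tangent_ray_misses(self):
        b = Body(((Quadric.sphere((0, 0, 0), 1.0), -1),), "w")
        d = ray_quadric_distance([1.0 + 1e-9, -5, 0], [0, 1, 0], b)
        assert np.isinf(d)

    def test_degenerate_surface_rejected(self):
        with pytest.raises(ValueError):
            Quadric((0,) * 10)

    def test_random_rays_against_marching_oracle(self, rng):
        """Crossing distances agree with a marching+bisection oracle to 1e-6 cm."""
        b = Body(((Quadric.sphere((0.3, -0.2, 0.1), 1.3), -1),), "w",
                 rotation=rotation_matrix("z", 30.0), translation=np.array([0.1, 0.2, 0.0]))
        for _ in range(25):
            p = rng.uniform(-3, 3, 3)
            d = unit(rng.normal(size=3))
            t_code = ray_quadric_distance(p, d, b)
            # oracle: march to bracket a membership change, then bisect
            inside0 = bool(b.contains(p[None])[0])
            ts = np.linspace(1e-9, 8.0, 10000)
            member = b.contains(p[None] + ts[:, None] * d[None])
            flips = np.flatnonzero(member != inside0)
            if len(flips) == 0:
                assert np.isinf(t_code) or t_code > 8.0
                continue
            lo, hi = ts[flips[0] - 1], ts[flips[0]]
            for _ in range(60):
                mid = 0.5 * (lo + hi)
                if bool(b.contains((p + mid * d)[None])[0]) == inside0:
                    lo = mid
                else:
                    hi = mid
            assert t_code == pytest.approx(0.5 * (lo + hi), abs=1e-6)


class TestVoxelRayWalk:
    def test_axis_aligned_chords(self):
        g = uniform_grid((5, 1, 1), spacing=1.0, origin=(0, 0, 0))
        steps = list(voxel_ray_walk([-1, 0.5, 0.5], [1, 0, 0], g))
        assert [s[0][0] for s in steps] == [0, 1, 2, 3, 4]
        assert np.allclose([s[1] for s in steps], 1.0)

    def test_diagonal_chord(self):
        g = uniform_grid((1, 1, 1), spacing=1.0, origin=(0, 0, 0))
        steps = list(voxel_ray_walk([-0.1, -0.1, -0.1], unit([1, 1, 1]), g))
        assert len(steps) == 1
        assert steps[0][1] == pytest.approx(np.sqrt(3.0), rel=1e-9)

    def test_chord_sum_equals_box_span(self, rng):
        g = uniform_grid((7, 5, 6), spacing=(0.3, 0.4, 0.25), origin=(0, 0, 0))
        for _ in range(50):
            p = rng.uniform(-1, 3, 3)
            d = unit(rng.normal(size=3))
            t_in, t_out = g.ray_box_span(p[None], d[None])
            span = max(float(t_out[0] - t_in[0]), 0.0)
            chords = sum(c for _, c in voxel_ray_walk(p, d, g))
            assert chords == pytest.approx(span, abs=1e-9 * max(span, 1.0))

    def test_face_neighbor_steps(self, rng):
        g = uniform_grid((6, 6, 6), spacing=0.5, origin=(0, 0, 0))
        for _ in range(20):
            p = rng.uniform(-0.5, 3.5, 3)
            d = unit(rng.normal(size=3))
            idxs = [np.array(i) for i, _ in voxel_ray_walk(p, d, g)]
            for a, b in zip(idxs, idxs[1:]):
                assert np.abs(a - b).sum() == 1


class TestTransforms:
    @given(st.tuples(st.floats(-180, 180), st.floats(-180, 180), st.floats(-180, 180)))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_composition_stays_orthonormal(self, angles):
        r = (rotation_matrix("y", angles[0]) @ rotation_matrix("z", angles[1])
             @ rotation_matrix("x", angles[2]))
        assert np.allclose(r @ r.T, np.eye(3), atol=1e-12)
        assert np.linalg.det(r) == pytest.approx(1.0, abs=1e-12)


class TestCoarsen:
    def test_uniform_stays_uniform(self):
        g = uniform_grid((8, 8, 8), spacing=0.125, density=1.3, origin=(0, 0, 0))
        c = coarsen_grid(g, (0.25, 0.25, 0.25))
        assert c.shape == (4, 4, 4)
        assert np.allclose(c.density, 1.3, rtol=1e-12)

    def test_2x2x2_merge_is_arithmetic_mean(self, rng):
        g = uniform_grid((4, 4, 4), spacing=0.5, origin=(0, 0, 0))
        g.density[...] = rng.random((4, 4, 4))
        c = coarsen_grid(g, (1.0, 1.0, 1.0))
        expect = g.density.reshape(2, 2, 2, 2, 2, 2).mean(axis=(1, 3, 5))
        assert np.allclose(c.density, expect, rtol=1e-12)

    def test_mass_conserved_incommensurate(self, rng):
        g = uniform_grid((21, 17, 13), spacing=0.19, origin=(0, 0, 0))
        g.density[...] = rng.random(g.shape) + 0.2
        c = coarsen_grid(g, (0.25, 0.25, 0.25))
        assert c.total_mass() == pytest.approx(g.total_mass(), rel=1e-9)

    def test_target_finer_than_source_rejected(self):
        g = uniform_grid((4, 4, 4), spacing=0.5, origin=(0, 0, 0))
        with pytest.raises(ValueError):
            coarsen_grid(g, (0.25, 0.5, 0.5))

    def test_dominant_material_assignment(self):
        g = uniform_grid((4, 1, 1), spacing=0.5, origin=(0, 0, 0),
                         materials=("water", "bone"))
        g.material[2:, 0, 0] = 1
        g.density[2:, 0, 0] = 1.85
        c = coarsen_grid(g, (1.0, 0.5, 0.5))
        assert c.material[0, 0, 0] == 0 and c.material[1, 0, 0] == 1
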