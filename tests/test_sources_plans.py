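"""Beam sampling, phase-space round trips, plan schema and history allocation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mcdose.plans import (ControlPoint, Plan, allocate_histories, export_rtplan,
                          import_rtplan, load_plan, save_plan)
from mcdose.rng import stream_generator
from mcdose.sources import (AnalyticBeam, PhaseSpaceSource, PhaseSpaceWriter,
                            PSF_DTYPE, phase_space_record_count, read_phase_space)


class TestAnalyticBeam:
    def test_pencil_beam_limit(self, rng):
        b = AnalyticBeam(energy_fwhm=0.0, spot_fwhm=0.0, divergence=0.0)
        bank = b.sample(100, rng)
        assert np.all(bank["energy"] == 6.2)
        assert np.allclose(bank["pos"][:, :2], 0.0)
        assert np.allclose(bank["dir"], [0, 0, -1])

    def test_nominal_energy_spectrum(self, rng):
        b = AnalyticBeam()    # 6.2 MeV, FWHM 0.186
        bank = b.sample(100000, rng)
        sig = 0.186 / 2.3548
        se = sig / np.sqrt(100000)
        assert abs(bank["energy"].mean() - 6.2) < 3 * se
        assert bank["energy"].std() == pytest.approx(sig, rel=0.02)

    def test_directions_inside_divergence_cone(self, rng):
        b = AnalyticBeam(divergence=2.5)
        bank = b.sample(20000, rng)
        cos_min = np.cos(np.deg2rad(2.5))
        assert np.all(-bank["dir"][:, 2] >= cos_min - 1e-12)
        assert np.allclose(np.linalg.norm(bank["dir"], axis=1), 1.0)


class TestPhaseSpace:
    def random_records(self, rng, n):
        rec = np.zeros(n, dtype=PSF_DTYPE)
        rec["species"] = rng.integers(0, 3, n)
        rec["E"] = rng.random(n).astype(np.float32) * 6 + 0.1
        rec["x"] = rng.normal(0, 1, n).astype(np.float32)
        rec["y"] = rng.normal(0, 1, n).astype(np.float32)
        u = rng.normal(0, 0.05, n).astype(np.float32)
        v = rng.normal(0, 0.05, n).astype(np.float32)
        rec["u"], rec["v"] = u, v
        rec["wsign"] = -1
        rec["weight"] = 1.0
        return rec

    def test_round_trip_bit_exact(self, tmp_path, rng):
        rec = self.random_records(rng, 1000)
        path = tmp_path / "a.psf"
        with PhaseSpaceWriter(path, z_plane=95.0) as w:
            w.write(rec[:500])
            w.write(rec[500:])
        back = read_phase_space(path)
        assert phase_space_record_count(path) == 1000
        assert np.array_equal(np.asarray(back), rec)

    def test_stride_partition_covers_every_record_once(self, tmp_path, rng):
        rec = self.random_records(rng, 997)
        path = tmp_path / "b.psf"
        with PhaseSpaceWriter(path) as w:
            w.write(rec)
        seen = np.concatenate([np.asarray(read_phase_space(path, stride=32, offset=k))
                               for k in range(32)])
        assert len(seen) == 997
        assert np.array_equal(np.sort(seen, order="E"), np.sort(rec, order="E"))

    def test_empty_file_valid_header(self, tmp_path):
        path = tmp_path / "c.psf"
        with PhaseSpaceWriter(path):
            pass
        assert phase_space_record_count(path) == 0
        assert len(read_phase_space(path)) == 0

    def test_truncated_file_reports_record_index(self, tmp_path, rng):
        rec = self.random_records(rng, 10)
        path = tmp_path / "d.psf"
        with PhaseSpaceWriter(path) as w:
            w.write(rec)
        raw = path.read_bytes()
        path.write_bytes(raw[:-7])
        with pytest.raises(ValueError, match="truncated at record 9"):
            read_phase_space(path)

    def test_malformed_header_rejected(self, tmp_path):
        path = tmp_path / "e.psf"
        path.write_bytes(b"not a phase space file" + b" " * 200)
        with pytest.raises(ValueError, match="magic|malformed"):
            read_phase_space(path)

    def test_source_replays_directions(self, tmp_path, rng):
        rec = self.random_records(rng, 64)
        path = tmp_path / "f.psf"
        with PhaseSpaceWriter(path, z_plane=90.0) as w:
            w.write(rec)
        src = PhaseSpaceSource(path)
        bank = src.sample(64, rng)
        assert np.allclose(np.linalg.norm(bank["dir"], axis=1), 1.0, atol=1e-6)
        assert np.all(bank["pos"][:, 2] == 90.0)
        assert np.all(bank["dir"][:, 2] < 0)   # wsign=-1 -> downward


def two_point_plan(w1=0.5, w2=1.0):
    leaves = np.full(4, -10.0)
    return Plan([ControlPoint(0, leaves, -leaves, cumulative_weight=w1),
                 ControlPoint(1, leaves + 1, -leaves, gantry=90.0,
                              cumulative_weight=w2)], name="t")


class TestAllocation:
    def test_equal_increments(self):
        assert allocate_histories(1000, two_point_plan()).tolist() == [500, 500]

    def test_fractional_increments(self):
        plan = two_point_plan(0.2, 1.0)
        assert allocate_histories(10, plan).tolist() == [2, 8]

    @given(st.integers(0, 10000),
           st.lists(st.floats(0.01, 10.0), min_size=1, max_size=12))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_largest_remainder_properties(self, n, incs):
        w = np.cumsum(incs)
        leaves = np.full(2, -5.0)
        plan = Plan([ControlPoint(i, leaves, -leaves, cumulative_weight=wi)
                     for i, wi in enumerate(w)])
        alloc = allocate_histories(n, plan)
        assert alloc.sum() == n
        frac = plan.increments / plan.increments.sum()
        assert np.all(np.abs(alloc - n * frac) < 1.0)

    def test_non_monotone_weights_rejected(self):
        leaves = np.full(2, -5.0)
        with pytest.raises(ValueError):
            Plan([ControlPoint(0, leaves, -leaves, cumulative_weight=0.8),
                  ControlPoint(1, leaves, -leaves, cumulative_weight=0.5)])


class TestPlanSchema:
    def test_yaml_round_trip(self, tmp_path):
        plan = two_point_plan()
        save_plan(plan, tmp_path / "p.yaml")
        back = load_plan(tmp_path / "p.yaml")
        for a, b in zip(plan.control_points, back.control_points):
            assert np.array_equal(a.leaves_a, b.leaves_a)
            assert a.cumulative_weight == b.cumulative_weight
            assert a.gantry == b.gantry

    def test_dicom_round_trip(self, tmp_path):
        plan = two_point_plan()
        export_rtplan(plan, tmp_path / "p.dcm")
        back = import_rtplan(tmp_path / "p.dcm")
        for a, b in zip(plan.control_points, back.control_points):
            assert np.allclose(a.leaves_a, b.leaves_a)
            assert np.allclose(a.leaves_b, b.leaves_b)
            assert a.cumulative_weight == pytest.approx(b.cumulative_weight)
            assert a.gantry == pytest.approx(b.gantry)
            assert a.jaws_x == pytest.approx(b.jaws_x)

    def test_single_control_point_is_static(self):
        leaves = np.full(3, -8.0)
        plan = Plan([ControlPoint(0, leaves, -leaves, cumulative_weight=1.0)])
        assert allocate_histories(100, plan).tolist() == [100]

    def test_non_rtplan_dicom_rejected(self, tmp_path):
        import pydicom
        from pydicom.dataset import Dataset, FileDataset
        meta = Dataset()
        meta.MediaStorageSOPClassUID = "1.2.840.10008.5.1.4.1.1.2"   # CT
        meta.MediaStorageSOPInstanceUID = pydicom.uid.generate_uid()
        meta.TransferSyntaxUID = pydicom.uid.ExplicitVRLittleEndian
        ds = FileDataset(str(tmp_path / "ct.dcm"), {}, file_meta=meta,
                         preamble=b"\0" * 128)
        ds.Modality = "CT"
        ds.SOPClassUID = meta.MediaStorageSOPClassUID
        ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
        ds.save_as(str(tmp_path / "ct.dcm"), enforce_file_format=True)
        with pytest.raises(ValueError, match="not a DICOM-RTPLAN"):
            import_rtplan(tmp_path / "ct.dcm")
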