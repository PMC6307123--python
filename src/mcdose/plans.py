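"""Treatment plans as control-point sequences.

A plan is an ordered list of control points, each a frozen machine
configuration (leaf/jaw positions, gantry/collimator/couch angles) with a
cumulative meterset weight; the fraction of histories simulated for a
control point equals its fraction of the final cumulative weight.  The
native schema is structured text (YAML); DICOM-RTPLAN import/export is an
optional adapter.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Sequence

import numpy as np
import yaml

from .machine import MachineConfig

__all__ = ["ControlPoint", "Plan", "allocate_histories", "load_plan", "save_plan",
           "import_rtplan", "export_rtplan"]


@dataclass
class ControlPoint:
    index: int
    leaves_a: np.ndarray
    leaves_b: np.ndarray
    jaws_x: tuple = (-20.0, 20.0)
    jaws_y: tuple = (-20.0, 20.0)
    gantry: float = 0.0
    collimator: float = 0.0
    couch: float = 0.0
    cumulative_weight: float = 1.0

    def __post_init__(self):
        self.leaves_a = np.asarray(self.leaves_a, dtype=float)
        self.leaves_b = np.asarray(self.leaves_b, dtype=float)

    def machine_config(self) -> MachineConfig:
        return MachineConfig(self.leaves_a, self.leaves_b, tuple(self.jaws_x),
                             tuple(self.jaws_y), self.gantry, self.collimator, self.couch)


@dataclass
class Plan:
    control_points: List[ControlPoint]
    name: str = "plan"

    def __post_init__(self):
        w = [cp.cumulative_weight for cp in self.control_points]
        if any(b < a - 1e-12 for a, b in zip(w, w[1:])):
            raise ValueError("cumulative meterset weights must be non-decreasing")
        if w and w[-1] <= 0:
            raise ValueError("final cumulative meterset weight must be positive")

    @property
    def increments(self) -> np.ndarray:
        w = np.array([cp.cumulative_weight for cp in self.control_points])
        return np.diff(np.concatenate([[0.0], w]))


def allocate_histories(n_total: int, plan: Plan) -> np.ndarray:
    """Histories per control point, proportional to the meterset increments.

    Exact integer allocation by the largest-remainder method: sums to
    ``n_total`` always, each |n_i - N f_i| < 1, deterministic (ties broken
    by control-point order).
    """
    if n_total < 0:
        raise ValueError("n_total must be non-negative")
    inc = plan.increments
    frac = inc / inc.sum()
    ideal = n_total * frac
    base = np.floor(ideal).astype(np.int64)
    short = n_total - base.sum()
    remainder = ideal - base
    order = np.argsort(-remainder, kind="stable")
    base[order[:short]] += 1
    return base


# ---------------------------------------------------------------------------
# native text schema

def save_plan(plan: Plan, path) -> None:
    doc = {"plan": {"name": plan.name, "control_points": [
        {"index": cp.index,
         "leaves_a": cp.leaves_a.tolist(), "leaves_b": cp.leaves_b.tolist(),
         "jaws_x": list(cp.jaws_x), "jaws_y": list(cp.jaws_y),
         "gantry": cp.gantry, "collimator": cp.collimator, "couch": cp.couch,
         "cumulative_weight": cp.cumulative_weight}
        for cp in plan.control_points]}}
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def load_plan(path) -> Plan:
    doc = yaml.safe_load(Path(path).read_text())
    body = doc["plan"]
    cps = [ControlPoint(index=c["index"], leaves_a=c["leaves_a"], leaves_b=c["leaves_b"],
                        jaws_x=tuple(c.get("jaws_x", (-20, 20))),
                        jaws_y=tuple(c.get("jaws_y", (-20, 20))),
                        gantry=c.get("gantry", 0.0), collimator=c.get("collimator", 0.0),
                        couch=c.get("couch", 0.0),
                        cumulative_weight=c["cumulative_weight"])
           for c in body["control_points"]]
    return Plan(cps, name=body.get("name", "plan"))


# ---------------------------------------------------------------------------
# DICOM-RTPLAN adapter (optional)

_RTPLAN_SOP = "1.2.840.10008.5.1.4.1.1.481.5"


def export_rtplan(plan: Plan, path) -> None:
    """Write the plan as a minimal DICOM-RTPLAN (one beam; structural, not
    clinically complete)."""
    import pydicom
    from pydicom.dataset import Dataset, FileDataset
    from pydicom.uid import ExplicitVRLittleEndian, generate_uid

    meta = Dataset()
    meta.MediaStorageSOPClassUID = _RTPLAN_SOP
    meta.MediaStorageSOPInstanceUID = generate_uid()
    meta.TransferSyntaxUID = ExplicitVRLittleEndian
    ds = FileDataset(str(path), {}, file_meta=meta, preamble=b"\0" * 128)
    ds.SOPClassUID = _RTPLAN_SOP
    ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
    ds.Modality = "RTPLAN"
    ds.RTPlanLabel = plan.name
    beam = Dataset()
    beam.BeamNumber = 1
    beam.FinalCumulativeMetersetWeight = plan.control_points[-1].cumulative_weight
    beam.ControlPointSequence = []
    for cp in plan.control_points:
        c = Dataset()
        c.ControlPointIndex = cp.index
        c.CumulativeMetersetWeight = cp.cumulative_weight
        c.GantryAngle = cp.gantry
        c.BeamLimitingDeviceAngle = cp.collimator
        c.PatientSupportAngle = cp.couch
        seq = []
        for typ, vals in (("ASYMX", list(cp.jaws_x)), ("ASYMY", list(cp.jaws_y)),
                          ("MLCX", cp.leaves_a.tolist() + cp.leaves_b.tolist())):
            d = Dataset()
            d.RTBeamLimitingDeviceType = typ
            d.LeafJawPositions = [v * 10.0 for v in vals]      # DICOM uses mm
            seq.append(d)
        c.BeamLimitingDevicePositionSequence = seq
        beam.ControlPointSequence.append(c)
    ds.BeamSequence = [beam]
    ds.save_as(str(path), enforce_file_format=True)


def import_rtplan(path) -> Plan:
    """Extract the first beam's control points from a DICOM-RTPLAN."""
    import pydicom

    ds = pydicom.dcmread(str(path))
    if getattr(ds, "Modality", "") != "RTPLAN" and getattr(ds, "SOPClassUID", "") != _RTPLAN_SOP:
        raise ValueError(f"{path}: not a DICOM-RTPLAN (Modality={getattr(ds, 'Modality', '?')})")
    missing = [t for t in ("BeamSequence",) if t not in ds]
    if missing:
        raise ValueError(f"{path}: missing required attributes: {missing}")
    beam = ds.BeamSequence[0]
    cps = []
    state = {"gantry": 0.0, "collimator": 0.0, "couch": 0.0,
             "jaws_x": (-20.0, 20.0), "jaws_y": (-20.0, 20.0),
             "leaves_a": None, "leaves_b": None}
    for c in beam.ControlPointSequence:
        if "GantryAngle" in c:
            state["gantry"] = float(c.GantryAngle)
        if "BeamLimitingDeviceAngle" in c:
            state["collimator"] = float(c.BeamLimitingDeviceAngle)
        if "PatientSupportAngle" in c:
            state["couch"] = float(c.PatientSupportAngle)
        for d in getattr(c, "BeamLimitingDevicePositionSequence", []):
            vals = [float(v) / 10.0 for v in d.LeafJawPositions]
            typ = d.RTBeamLimitingDeviceType
            if typ in ("ASYMX", "X"):
                state["jaws_x"] = tuple(vals[:2])
            elif typ in ("ASYMY", "Y"):
                state["jaws_y"] = tuple(vals[:2])
            elif typ in ("MLCX", "MLCY"):
                half = len(vals) // 2
                state["leaves_a"] = np.array(vals[:half])
                state["leaves_b"] = np.array(vals[half:])
            else:
                raise ValueError(f"unsupported beam limiting device {typ!r}")
        if state["leaves_a"] is None:
            raise ValueError(f"{path}: control point without MLC positions "
                             "(tag BeamLimitingDevicePositionSequence/MLCX)")
        cps.append(ControlPoint(index=int(c.ControlPointIndex),
                                leaves_a=state["leaves_a"].copy(),
                                leaves_b=state["leaves_b"].copy(),
                                jaws_x=state["jaws_x"], jaws_y=state["jaws_y"],
                                gantry=state["gantry"], collimator=state["collimator"],
                                couch=state["couch"],
                                cumulative_weight=float(c.CumulativeMetersetWeight)))
    return Plan(cps, name=str(getattr(ds, "RTPlanLabel", "plan")))
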