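"""Reading and writing patient records, uncertainty specs and domains.

Everything is plain, versioned, human-editable text: the patient record is
one YAML document with its three waveforms stored as sibling two-column
(time, value) CSV files; uncertainty specifications and domain definitions
are single YAML documents.
"""

from __future__ import annotations

import csv
import hashlib
from pathlib import Path
from typing import Dict

import numpy as np
import yaml

from .errors import ValidationError
from .network import VesselGeometry
from .records import PatientRecord
from .uncertainty import UncertainParameter, UncertaintySpec
from .waveforms import Waveform

__all__ = [
    "save_waveform_csv",
    "load_waveform_csv",
    "save_patient",
    "load_patient",
    "save_uncertainty_spec",
    "load_uncertainty_spec",
    "save_geometries",
    "load_geometries",
    "content_hash",
]

RECORD_SCHEMA_VERSION = 1
_WAVEFORMS = ("aortic_flow", "pressure", "distension")


def save_waveform_csv(waveform: Waveform, path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["time_s", "value"])
        for t, v in zip(waveform.time_s, waveform.values):
            w.writerow([repr(float(t)), repr(float(v))])


def load_waveform_csv(path) -> Waveform:
    with open(path, newline="") as fh:
        rows = list(csv.reader(fh))
    if not rows or rows[0] != ["time_s", "value"]:
        raise ValidationError(f"{path}: not a two-column waveform CSV")
    data = np.array([[float(a), float(b)] for a, b in rows[1:]])
    return Waveform(data[:, 0], data[:, 1])


def save_patient(record: PatientRecord, directory) -> Path:
    """Write one record as ``<id>.yaml`` plus three waveform CSVs."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    stem = record.patient_id
    doc = {
        "schema_version": RECORD_SCHEMA_VERSION,
        "patient_id": record.patient_id,
        "side": record.side,
        "map_pressure_mmhg": float(record.map_pressure_mmhg),
        "cardiac_period_s": float(record.cardiac_period_s),
        "mean_flows_ml_min": {k: float(v) for k, v in record.mean_flows_ml_min.items()},
        "dus_diameters": [
            {"vessel": vid, "position_cm": float(pos), "diameter_mm": float(d)}
            for (vid, pos), d in sorted(record.dus_diameters.items())
        ],
        "waveforms": {name: f"{stem}_{name}.csv" for name in _WAVEFORMS},
    }
    save_waveform_csv(record.aortic_flow_waveform, directory / f"{stem}_aortic_flow.csv")
    save_waveform_csv(record.pressure_waveform, directory / f"{stem}_pressure.csv")
    save_waveform_csv(record.distension_waveform, directory / f"{stem}_distension.csv")
    path = directory / f"{stem}.yaml"
    path.write_text(yaml.safe_dump(doc, sort_keys=True))
    return path


def load_patient(path) -> PatientRecord:
    """Load a record from its YAML file (waveform CSVs resolved alongside)."""
    path = Path(path)
    doc = yaml.safe_load(path.read_text())
    if doc.get("schema_version") != RECORD_SCHEMA_VERSION:
        raise ValidationError(f"{path}: unsupported record schema "
                              f"{doc.get('schema_version')!r}")
    base = path.parent
    wf = {name: load_waveform_csv(base / doc["waveforms"][name]) for name in _WAVEFORMS}
    dus = {(e["vessel"], float(e["position_cm"])): float(e["diameter_mm"])
           for e in doc["dus_diameters"]}
    return PatientRecord(
        patient_id=doc["patient_id"],
        side=doc["side"],
        dus_diameters=dus,
        distension_waveform=wf["distension"],
        pressure_waveform=wf["pressure"],
        map_pressure_mmhg=float(doc["map_pressure_mmhg"]),
        mean_flows_ml_min={k: float(v) for k, v in doc["mean_flows_ml_min"].items()},
        aortic_flow_waveform=wf["aortic_flow"],
        cardiac_period_s=float(doc["cardiac_period_s"]),
    )


def save_uncertainty_spec(spec: UncertaintySpec, path) -> None:
    doc = {
        "schema_version": 1,
        "parameters": [
            {"path": p.path, "nominal": float(p.nominal),
             "half_width": float(p.half_width), "relative": bool(p.relative)}
            for p in spec.parameters
        ],
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=True))


def load_uncertainty_spec(path) -> UncertaintySpec:
    doc = yaml.safe_load(Path(path).read_text())
    params = tuple(
        UncertainParameter(path=e["path"], nominal=float(e["nominal"]),
                           half_width=float(e["half_width"]),
                           relative=bool(e.get("relative", False)))
        for e in doc["parameters"]
    )
    return UncertaintySpec(params)


def save_geometries(geometries: Dict[str, VesselGeometry], path) -> None:
    """Write a vessel-geometry set as one versioned YAML document."""
    doc = {
        "schema_version": 1,
        "vessels": {
            vid: {
                "length_cm": float(g.length_cm),
                "diameter_profile": [[float(p), float(d)] for p, d in g.diameter_profile],
                "wall_thickness_ratio": float(g.wall_thickness_ratio),
                "youngs_modulus_kpa": float(g.youngs_modulus_kpa),
                "is_vein": bool(g.is_vein),
            }
            for vid, g in sorted(geometries.items())
        },
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=True))


def load_geometries(path) -> Dict[str, VesselGeometry]:
    doc = yaml.safe_load(Path(path).read_text())
    out = {}
    for vid, g in doc["vessels"].items():
        out[vid] = VesselGeometry(
            vessel_id=vid, length_cm=float(g["length_cm"]),
            diameter_profile=tuple((float(p), float(d))
                                   for p, d in g["diameter_profile"]),
            wall_thickness_ratio=float(g["wall_thickness_ratio"]),
            youngs_modulus_kpa=float(g["youngs_modulus_kpa"]),
            is_vein=bool(g["is_vein"]))
    return out


def content_hash(path) -> str:
    """Short sha256 of a file, for provenance blocks."""
    h = hashlib.sha256(Path(path).read_bytes()).hexdigest()
    return h[:16]
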