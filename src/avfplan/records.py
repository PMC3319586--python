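"""The per-patient measurement record feeding personalization.

Everything the pipeline needs for one patient: discrete duplex (DUS)
diameter stations for the arm vessels, the brachial wall-distension and
finger-pressure waveforms used to infer arterial stiffness, mean arterial
pressure, MR mean flows at the four measured arterial sites, the
preoperative aortic flow waveform and the cardiac period.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Dict, Tuple

from .errors import ValidationError
from .vessels import check_vessel
from .waveforms import Waveform

__all__ = ["PatientRecord", "MEASURED_FLOW_SITES"]

MEASURED_FLOW_SITES = ("aorta", "brachial", "radial", "ulnar")


@dataclass
class PatientRecord:
    """One patient's preoperative measurements (clinical units).

    ``dus_diameters`` maps ``(vessel_id, axial position cm)`` to an inner
    diameter in mm, positions counted from the proximal end of the vessel.
    ``mean_flows`` is in ml/min; the aortic flow waveform is in ml/s.
    """

    patient_id: str
    side: str
    dus_diameters: Dict[Tuple[str, float], float]
    distension_waveform: Waveform   # brachial inner diameter, mm
    pressure_waveform: Waveform     # finger pressure, mmHg
    map_pressure_mmhg: float
    mean_flows_ml_min: Dict[str, float]
    aortic_flow_waveform: Waveform  # ml/s
    cardiac_period_s: float

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        if self.side not in ("left", "right"):
            raise ValidationError("side must be 'left' or 'right'")
        if not self.dus_diameters:
            raise ValidationError("record has no duplex diameter stations")
        for (vid, pos), d in self.dus_diameters.items():
            check_vessel(vid)
            if d <= 0:
                raise ValidationError(f"{vid}@{pos}cm: diameter must be positive")
        if not 0.3 < self.cardiac_period_s < 2.0:
            raise ValidationError("cardiac period outside (0.3, 2.0) s")
        if self.map_pressure_mmhg <= 0:
            raise ValidationError("mean arterial pressure must be positive")
        missing = set(MEASURED_FLOW_SITES) - set(self.mean_flows_ml_min)
        if missing:
            raise ValidationError(f"mean flows missing sites: {sorted(missing)}")
        q = self.mean_flows_ml_min
        if any(q[s] <= 0 for s in MEASURED_FLOW_SITES):
            raise ValidationError("measured mean flows must be positive")
        if q["brachial"] > q["aorta"]:
            raise ValidationError("brachial mean flow exceeds aortic mean flow")
        if q["radial"] + q["ulnar"] > q["brachial"]:
            raise ValidationError("radial + ulnar mean flow exceeds brachial mean flow")
        wf_mean_ml_min = self.aortic_flow_waveform.mean() * 60.0
        if abs(wf_mean_ml_min - q["aorta"]) > 0.05 * q["aorta"]:
            raise ValidationError(
                "aortic waveform mean inconsistent with measured aortic mean flow "
                f"({wf_mean_ml_min:.0f} vs {q['aorta']:.0f} ml/min)"
            )

    # convenience -----------------------------------------------------------

    def stations(self, vessel_id: str):
        """Sorted (position_cm, diameter_mm) stations of one vessel."""
        return sorted(
            (pos, d) for (vid, pos), d in self.dus_diameters.items() if vid == vessel_id
        )

    def measured_vessels(self):
        return sorted({vid for vid, _ in self.dus_diameters})

    @property
    def cardiac_output_ml_min(self) -> float:
        """Mean aortic flow stands in for the cardiac output."""
        return self.mean_flows_ml_min["aorta"]

    def with_diameters(self, updates: Dict[Tuple[str, float], float]) -> "PatientRecord":
        """Copy of the record with some duplex stations replaced/added."""
        new = dict(self.dus_diameters)
        new.update(updates)
        return replace(self, dus_diameters=new)
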