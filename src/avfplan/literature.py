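"""Packaged generic (literature) vascular geometry.

Vessel lengths, aortic diameters, non-arm wall-thickness ratios and the
Young's moduli of the aorta and veins cannot be measured in the routine
preoperative work-up; they come from a generic adult arterial-tree table
shipped with the package and are scaled / overridden by the per-patient
measurements during personalization.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from importlib import resources
from typing import Dict

from .errors import UnknownVesselError, ValidationError
from .vessels import ALL_VESSELS

__all__ = ["LiteratureVessel", "LiteratureGeometry", "load_literature_geometry"]


@dataclass(frozen=True)
class LiteratureVessel:
    vessel_id: str
    length_cm: float
    diameter_mm: float
    h_over_r: float
    youngs_modulus_kpa: float
    is_vein: bool

    def __post_init__(self):
        if min(self.length_cm, self.diameter_mm, self.h_over_r,
               self.youngs_modulus_kpa) <= 0:
            raise ValidationError(f"{self.vessel_id}: literature values must be positive")


@dataclass(frozen=True)
class LiteratureGeometry:
    vessels: Dict[str, LiteratureVessel]

    def __getitem__(self, vessel_id: str) -> LiteratureVessel:
        try:
            return self.vessels[vessel_id]
        except KeyError:
            raise UnknownVesselError(vessel_id) from None

    def __contains__(self, vessel_id: str) -> bool:
        return vessel_id in self.vessels


def load_literature_geometry() -> LiteratureGeometry:
    """Load the packaged generic geometry table."""
    text = resources.files("avfplan.data").joinpath("literature_geometry.csv").read_text()
    rows = [ln for ln in text.splitlines() if ln.strip() and not ln.startswith("#")]
    table: Dict[str, LiteratureVessel] = {}
    for rec in csv.DictReader(rows):
        vid = rec["vessel_id"]
        if vid not in ALL_VESSELS:
            raise UnknownVesselError(vid)
        table[vid] = LiteratureVessel(
            vessel_id=vid,
            length_cm=float(rec["length_cm"]),
            diameter_mm=float(rec["diameter_mm"]),
            h_over_r=float(rec["h_over_r"]),
            youngs_modulus_kpa=float(rec["youngs_modulus_kpa"]),
            is_vein=bool(int(rec["is_vein"])),
        )
    missing = ALL_VESSELS - set(table)
    if missing:
        raise ValidationError(f"literature table missing vessels: {sorted(missing)}")
    return LiteratureGeometry(table)
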