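"""Synthetic patients with the statistical structure the pipeline expects.

The study's measurement records are not published, so this module emulates
them: physiologic diameter ranges at the usual duplex stations (with distal
taper), mean arterial pressure, MR-like mean-flow splits between aorta and
arm arteries, a two-phase pulsatile aortic flow waveform, and a consistent
brachial distension / finger-pressure waveform pair generated from a known
arterial stiffness.  Degraded variants reproduce the clinically observed
failure modes (thrombosed cephalic vein, small radial artery, sparse
stations) so the error paths of the pipeline are testable.

Station-position convention: positions run along the flow direction, i.e.
from the central end for arteries and from the peripheral (anastomosis) end
for veins.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Dict, List, Tuple

import numpy as np

from . import vessels as V
from .errors import ValidationError
from .literature import load_literature_geometry
from .records import PatientRecord
from .waveforms import Waveform

__all__ = [
    "SyntheticCohortSpec",
    "DEFAULT_COHORT_SPEC",
    "generate_patient",
    "generate_cohort",
    "degrade_patient",
    "DEGRADE_SCENARIOS",
]

Range = Tuple[float, float]


@dataclass(frozen=True)
class SyntheticCohortSpec:
    """Sampling ranges for the synthetic cohort (uniform per patient)."""

    n_patients: int = 25
    seed: int = 7

    # proximal diameters, mm (veins: at the peripheral/anastomosis end)
    subclavian_diameter_mm: Range = (6.5, 9.0)
    brachial_diameter_mm: Range = (3.6, 5.4)
    radial_diameter_mm: Range = (1.9, 3.3)
    ulnar_diameter_mm: Range = (1.9, 3.0)
    interosseus_diameter_mm: Range = (1.3, 2.0)
    cephalic_distal_diameter_mm: Range = (1.6, 3.4)
    cephalic_proximal_diameter_mm: Range = (2.6, 4.6)
    median_cubital_diameter_mm: Range = (2.5, 4.5)
    basilic_diameter_mm: Range = (2.8, 5.0)
    axillary_vein_diameter_mm: Range = (7.0, 11.0)
    artery_taper: Range = (0.78, 0.95)       # distal/proximal diameter ratio
    vein_central_gain: Range = (1.05, 1.30)  # central/peripheral diameter ratio

    # hemodynamics
    map_mmhg: Range = (70.0, 120.0)
    pulse_pressure_mmhg: Range = (40.0, 60.0)
    cardiac_period_s: Range = (0.7, 1.2)
    cardiac_output_l_min: Range = (3.5, 7.0)
    brachial_fraction_of_co: Range = (0.015, 0.04)
    radial_fraction_of_brachial: Range = (0.30, 0.42)
    ulnar_fraction_of_brachial: Range = (0.30, 0.42)

    # waveform shape
    systolic_fraction: Range = (0.30, 0.40)
    peak_to_mean_ratio: Range = (2.5, 3.5)

    # arterial stiffness used to synthesize the distension waveform
    brachial_youngs_modulus_kpa: Range = (400.0, 1200.0)

    samples_per_cycle: int = 200

    def __post_init__(self):
        if self.n_patients < 1:
            raise ValidationError("cohort needs at least one patient")
        for name, rng in self.__dict__.items():
            if isinstance(rng, tuple):
                lo, hi = rng
                if not (0 < lo <= hi):
                    raise ValidationError(f"{name}: range must be positive and ordered")


DEFAULT_COHORT_SPEC = SyntheticCohortSpec()


def _u(rng: np.random.Generator, band: Range) -> float:
    return float(rng.uniform(*band))


def _aortic_waveform(mean_ml_s: float, period_s: float, systolic_fraction: float,
                     peak_ratio: float, n: int) -> Waveform:
    """Two-phase pulse: systolic half-sine over a low diastolic plateau."""
    fs = systolic_fraction
    plateau_weight = 1.0 - (2.0 / np.pi) * fs
    q_d = mean_ml_s * (1.0 - peak_ratio * (2.0 / np.pi) * fs) / plateau_weight
    if q_d < 0:
        raise ValidationError("peak-to-mean ratio too large for the systolic fraction")
    t = np.linspace(0.0, period_s, n + 1)
    q = np.full_like(t, q_d)
    sys = t <= fs * period_s
    q[sys] = q_d + (peak_ratio * mean_ml_s - q_d) * np.sin(np.pi * t[sys] / (fs * period_s))
    return Waveform(t, q)


def _pressure_waveform(map_mmhg: float, pulse_pressure: float, period_s: float,
                       systolic_fraction: float, n: int) -> Waveform:
    p_dias = map_mmhg - pulse_pressure / 3.0
    t = np.linspace(0.0, period_s, n + 1)
    p = np.full_like(t, p_dias)
    sys = t <= systolic_fraction * period_s
    p[sys] = p_dias + pulse_pressure * np.sin(np.pi * t[sys] / (systolic_fraction * period_s))
    return Waveform(t, p)


def _distension_waveform(pressure: Waveform, diastolic_diameter_mm: float,
                         youngs_modulus_kpa: float, h_over_r: float = 0.15) -> Waveform:
    """Diameter waveform consistent with E via the thin-wall relation."""
    dist = 3.0 / (2.0 * youngs_modulus_kpa * 1e3 * h_over_r)  # 1/Pa
    p_d = float(np.min(pressure.values))
    dp_pa = (pressure.values - p_d) * 133.322387415
    d = diastolic_diameter_mm * np.sqrt(1.0 + dist * dp_pa)
    return Waveform(pressure.time_s, d)


def generate_patient(spec: SyntheticCohortSpec, index: int,
                     side: str = "left") -> PatientRecord:
    """Deterministically generate one synthetic patient record."""
    rng = np.random.default_rng([int(spec.seed), int(index)])
    lit = load_literature_geometry()
    n = spec.samples_per_cycle

    period = _u(rng, spec.cardiac_period_s)
    co_target_ml_s = _u(rng, spec.cardiac_output_l_min) * 1000.0 / 60.0
    fs = _u(rng, spec.systolic_fraction)
    kappa = _u(rng, spec.peak_to_mean_ratio)
    aortic = _aortic_waveform(co_target_ml_s, period, fs, kappa, n)
    q_aorta_ml_min = aortic.mean() * 60.0

    map_p = _u(rng, spec.map_mmhg)
    pp = _u(rng, spec.pulse_pressure_mmhg)
    pressure = _pressure_waveform(map_p, pp, period, fs, n)

    q_brach = q_aorta_ml_min * _u(rng, spec.brachial_fraction_of_co)
    q_radial = q_brach * _u(rng, spec.radial_fraction_of_brachial)
    q_ulnar = q_brach * _u(rng, spec.ulnar_fraction_of_brachial)

    taper = _u(rng, spec.artery_taper)
    gain = _u(rng, spec.vein_central_gain)
    sub = V.LEFT_SUBCLAVIAN if side == "left" else V.RIGHT_SUBCLAVIAN

    def artery_stations(vid: str, d0: float, t_ratio: float) -> Dict[Tuple[str, float], float]:
        length = lit[vid].length_cm
        return {(vid, 0.0): d0, (vid, length / 2.0): d0 * (1.0 + t_ratio) / 2.0,
                (vid, length): d0 * t_ratio}

    def vein_stations(vid: str, d0: float, g_ratio: float) -> Dict[Tuple[str, float], float]:
        length = lit[vid].length_cm
        return {(vid, 0.0): d0, (vid, length / 2.0): d0 * (1.0 + g_ratio) / 2.0,
                (vid, length): d0 * g_ratio}

    d_brach = _u(rng, spec.brachial_diameter_mm)
    d_radial = _u(rng, spec.radial_diameter_mm)
    d_ulnar = _u(rng, spec.ulnar_diameter_mm)

    dus: Dict[Tuple[str, float], float] = {}
    dus[(sub, 0.0)] = _u(rng, spec.subclavian_diameter_mm)
    dus.update(artery_stations(V.AXILLARY_BRACHIAL, d_brach, taper))
    dus.update(artery_stations(V.RADIAL, d_radial, taper))
    dus.update(artery_stations(V.ULNAR_PROXIMAL, d_ulnar, (1.0 + taper) / 2.0))
    dus.update(artery_stations(V.ULNAR_DISTAL, d_ulnar * (1.0 + taper) / 2.0, taper))
    dus[(V.INTEROSSEUS, 0.0)] = _u(rng, spec.interosseus_diameter_mm)
    dus.update(vein_stations(V.CEPHALIC_DISTAL,
                             _u(rng, spec.cephalic_distal_diameter_mm), gain))
    dus.update(vein_stations(V.CEPHALIC_PROXIMAL,
                             _u(rng, spec.cephalic_proximal_diameter_mm), gain))
    dus[(V.MEDIAN_CUBITAL, 0.0)] = _u(rng, spec.median_cubital_diameter_mm)
    dus.update(vein_stations(V.BASILIC, _u(rng, spec.basilic_diameter_mm), gain))
    dus[(V.AXILLARY_SUBCLAVIAN_VEIN, 0.0)] = _u(rng, spec.axillary_vein_diameter_mm)

    e_kpa = _u(rng, spec.brachial_youngs_modulus_kpa)
    distension = _distension_waveform(pressure, d_brach, e_kpa)

    return PatientRecord(
        patient_id=f"synthetic-{spec.seed}-{index:03d}",
        side=side,
        dus_diameters=dus,
        distension_waveform=distension,
        pressure_waveform=pressure,
        map_pressure_mmhg=map_p,
        mean_flows_ml_min={"aorta": q_aorta_ml_min, "brachial": q_brach,
                           "radial": q_radial, "ulnar": q_ulnar},
        aortic_flow_waveform=aortic,
        cardiac_period_s=period,
    )


def generate_cohort(spec: SyntheticCohortSpec = DEFAULT_COHORT_SPEC
                    ) -> List[PatientRecord]:
    return [generate_patient(spec, i) for i in range(spec.n_patients)]


DEGRADE_SCENARIOS = ("thrombosed_cephalic", "small_radial", "missing_station")


def degrade_patient(record: PatientRecord, scenario: str) -> PatientRecord:
    """Degrade a record to reproduce a clinical failure mode.

    ``thrombosed_cephalic``: the cephalic trajectory cannot be visualized,
    so RC/BC domains become incomplete.  ``small_radial``: all radial
    stations capped at 1.6 mm (fails the 2 mm caliber screen).
    ``missing_station``: only a single station per arm vessel survives,
    exercising the constant-extrapolation fallback.
    """
    if scenario == "thrombosed_cephalic":
        gone = {V.CEPHALIC_DISTAL, V.CEPHALIC_PROXIMAL, V.MEDIAN_CUBITAL}
        dus = {k: v for k, v in record.dus_diameters.items() if k[0] not in gone}
        return replace(record, dus_diameters=dus)
    if scenario == "small_radial":
        dus = {k: (min(v, 1.6) if k[0] == V.RADIAL else v)
               for k, v in record.dus_diameters.items()}
        return replace(record, dus_diameters=dus)
    if scenario == "missing_station":
        keep: Dict[Tuple[str, float], float] = {}
        seen = set()
        for (vid, pos), d in sorted(record.dus_diameters.items()):
            if vid in seen:
                continue
            keep[(vid, pos)] = d
            seen.add(vid)
        return replace(record, dus_diameters=keep)
    raise ValidationError(f"unknown degradation scenario: {scenario!r}")
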