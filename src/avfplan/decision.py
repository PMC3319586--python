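"""Clinical decision rule on the predicted flow distributions.

A configuration is an option for fistula creation when its predicted
postoperative flow (the Monte-Carlo median) lies in the 400-1500 ml/min
window: below 400 ml/min early thrombosis / non-maturation dominates, above
1500 ml/min steal syndrome and cardiac overload become likely.  When several
configurations qualify, the most distal wins: radiocephalic before
brachiocephalic before brachiobasilic, preserving proximal vessels for
future access.  Auxiliary outputs: a cardiac-steal flag (flow above 30 % of
cardiac output), an informational maturation projection (immediate flow is
60-70 % of the matured flow at the wrist, 90-100 % at the elbow), duplex
flow quantification with its velocity-profile correction, and a
predicted-vs-measured overlap check on closed intervals.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .errors import ValidationError
from .network import normalize_configuration
from .uncertainty import FlowDistribution
from .waveforms import Waveform

__all__ = [
    "FLOW_WINDOW_ML_MIN",
    "PREFERENCE_ORDER",
    "ConfigurationAssessment",
    "Recommendation",
    "assess_configuration",
    "recommend",
    "cardiac_steal_flag",
    "maturation_projection",
    "dus_measured_flow_interval",
    "prediction_overlap",
]

FLOW_WINDOW_ML_MIN: Tuple[float, float] = (400.0, 1500.0)
PREFERENCE_ORDER = ("RC-AVF", "BC-AVF", "BB-AVF")
STEAL_FRACTION_OF_CO = 0.30

#: immediate postoperative flow as a fraction of the matured flow
MATURATION_FRACTIONS = {"lower_arm": (0.60, 0.70), "elbow": (0.90, 1.00)}


@dataclass
class ConfigurationAssessment:
    configuration: str
    flow: Optional[FlowDistribution]
    eligible: bool
    reasons: List[str] = field(default_factory=list)
    risk_flags: Dict[str, bool] = field(default_factory=dict)

    @property
    def assessable(self) -> bool:
        return self.flow is not None and self.flow.simulable


def assess_configuration(flow: Optional[FlowDistribution],
                         thresholds: Tuple[float, float] = FLOW_WINDOW_ML_MIN,
                         configuration: Optional[str] = None,
                         cardiac_output_ml_min: Optional[float] = None
                         ) -> ConfigurationAssessment:
    """Apply the flow window to one configuration's distribution.

    The decision statistic is the Monte-Carlo median; the window bounds are
    inclusive.  A distribution with no converged run is 'not assessable'.
    """
    lo, hi = thresholds
    cfg = normalize_configuration(configuration or (flow.configuration if flow else ""))
    if flow is None or not flow.simulable:
        return ConfigurationAssessment(cfg, flow, eligible=False,
                                       reasons=["not assessable: no converged simulation"],
                                       risk_flags={"low_flow": False, "high_flow": False,
                                                   "cardiac_steal": False})
    med = flow.median
    low = med < lo
    high = med > hi
    steal = (cardiac_output_ml_min is not None
             and cardiac_steal_flag(med, cardiac_output_ml_min))
    reasons = []
    if low:
        reasons.append(f"median flow {med:.0f} ml/min below {lo:.0f} ml/min "
                       "(non-maturation risk)")
    if high:
        reasons.append(f"median flow {med:.0f} ml/min above {hi:.0f} ml/min "
                       "(high-flow risk)")
    if steal:
        reasons.append("flow exceeds 30% of cardiac output (steal/cardiac risk)")
    return ConfigurationAssessment(
        cfg, flow, eligible=not (low or high),
        reasons=reasons,
        risk_flags={"low_flow": low, "high_flow": high, "cardiac_steal": steal})


@dataclass
class Recommendation:
    candidates: List[ConfigurationAssessment]
    selected: Optional[str]
    agreement: Optional[bool] = None  # vs an (optional) surgeon's choice

    def with_surgeon_choice(self, configuration: Optional[str]) -> "Recommendation":
        if configuration is None:
            return self
        cfg = normalize_configuration(configuration)
        return Recommendation(self.candidates, self.selected,
                              agreement=(self.selected == cfg))


def recommend(assessments: Sequence[ConfigurationAssessment]) -> Recommendation:
    """Pick the most distal eligible configuration (RC > BC > BB).

    Missing or unsimulable configurations are skipped with an annotation;
    the selection is None when nothing is eligible.
    """
    if not assessments:
        raise ValidationError("no configuration assessments given")
    by_cfg = {a.configuration: a for a in assessments}
    ordered: List[ConfigurationAssessment] = []
    selected = None
    for cfg in PREFERENCE_ORDER:
        a = by_cfg.get(cfg)
        if a is None:
            ordered.append(ConfigurationAssessment(
                cfg, None, eligible=False, reasons=["not simulated"],
                risk_flags={"low_flow": False, "high_flow": False,
                            "cardiac_steal": False}))
            continue
        ordered.append(a)
        if selected is None and a.eligible:
            selected = cfg
    return Recommendation(candidates=ordered, selected=selected)


def cardiac_steal_flag(flow_ml_min: float, cardiac_output_ml_min: float) -> bool:
    """True iff the flow strictly exceeds 30 % of the cardiac output."""
    if cardiac_output_ml_min <= 0:
        raise ValidationError("cardiac output must be positive")
    return flow_ml_min > STEAL_FRACTION_OF_CO * cardiac_output_ml_min


def maturation_projection(immediate_flow_ml_min: float, configuration: str
                          ) -> Tuple[float, float]:
    """Projected matured-flow interval (ml/min) — context only.

    Immediate postoperative flow is roughly 60-70 % of the matured flow in
    lower-arm fistulas and 90-100 % in elbow fistulas; the projection is
    never used for eligibility.
    """
    if immediate_flow_ml_min < 0:
        raise ValidationError("flow must be non-negative")
    cfg = normalize_configuration(configuration)
    site = "lower_arm" if cfg == "RC-AVF" else "elbow"
    f_lo, f_hi = MATURATION_FRACTIONS[site]
    return (immediate_flow_ml_min / f_hi, immediate_flow_ml_min / f_lo)


def dus_measured_flow_interval(velocity_envelope: Waveform,
                               vessel_area_mm2: float) -> Tuple[float, float, float]:
    """Duplex flow from the Doppler velocity envelope (cm/s) and lumen area.

    Raw flow = time-averaged outer envelope x cross-sectional area.  The
    true velocity profile lies between parabolic and flat, so the measured
    flow is reported as the interval [0.5, 1.0] x raw.  Returns
    ``(low, high, raw)`` in ml/min.
    """
    if vessel_area_mm2 <= 0:
        raise ValidationError("vessel area must be positive")
    v_mean_m_s = velocity_envelope.mean() * 1e-2
    q_m3_s = v_mean_m_s * vessel_area_mm2 * 1e-6
    raw = q_m3_s * 6e7  # ml/min
    return (0.5 * raw, 1.0 * raw, raw)


def prediction_overlap(predicted: FlowDistribution,
                       measured_interval_ml_min: Tuple[float, float]) -> str:
    """'overlap' iff the predicted [p25, p75] intersects the measured interval.

    Both intervals are closed, so touching endpoints count as overlap.
    """
    if not predicted.simulable:
        raise ValidationError("predicted distribution has no converged run")
    m_lo, m_hi = sorted(measured_interval_ml_min)
    return "overlap" if predicted.p25 <= m_hi and m_lo <= predicted.p75 else "no_overlap"
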