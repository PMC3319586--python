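"""Patient-specific parameterization of the vascular network.

Turns a :class:`~avfplan.records.PatientRecord` into the vessel geometries,
stiffnesses and windkessel boundary elements that define that patient's
computational domains:

* arm vessel diameters from the duplex stations (linear inter-/extrapolation),
* lengths and non-measurable geometry from the packaged literature table,
  with the aorta and its primary branches scaled by the measured-to-generic
  subclavian diameter ratio,
* wall thickness from fixed thickness-to-radius ratios (15 % subclavian/
  axillary/brachial, 20 % radial/ulnar/interosseus, 10 % veins),
* one arm-wide arterial Young's modulus inferred from brachial distensibility
  (wall tracking + continuous finger pressure),
* windkessel terminals fitted so the preoperative mean pressure/flow
  distribution reproduces the MR-measured mean flows.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Tuple

import networkx as nx
import numpy as np

from . import units, vessels as V
from .errors import (
    InconsistentMeasurementsError,
    MissingMeasurementError,
    RigidVesselError,
    ValidationError,
)
from .literature import LiteratureGeometry, load_literature_geometry
from .network import (
    AnastomosisPlacement,
    ANASTOMOSIS_OFFSET_CM,
    DEFAULT_BLOOD,
    VascularNetwork,
    VesselGeometry,
    WindkesselTerminal,
    build_domain,
    normalize_configuration,
)
from .profiles import interpolate_diameters
from .records import PatientRecord
from .waveforms import Waveform

__all__ = [
    "Perturbation",
    "PersonalizationOptions",
    "PersonalizedModel",
    "wall_thickness",
    "distensibility",
    "youngs_modulus_from_distensibility",
    "scale_aortic_geometry",
    "assemble_geometries",
    "personalize_windkessels",
    "place_anastomosis",
    "caliber_screen",
    "build_patient_model",
    "interpolate_diameters",
    "REST_FLOW_FRACTIONS",
]

#: split of the non-arm mean flow over the remaining terminals
REST_FLOW_FRACTIONS = {
    V.THORACIC_AORTA: 0.62,
    V.LEFT_CAROTID: 0.10,
    V.RIGHT_CAROTID: 0.10,
    V.VERTEBRAL: 0.03,
    "contralateral_subclavian": 0.15,
}

DEFAULT_ANASTOMOSIS_ANGLE_DEG = 45.0
ANASTOMOSIS_ANGLE_BOUNDS_DEG = (30.0, 60.0)

#: arm-artery wall thickness-to-radius assignment; veins use 10 %
_ARM_H_OVER_R = 0.15  # subclavian, axillary, brachial

CALIBER_THRESHOLD_MM = 2.0


@dataclass(frozen=True)
class Perturbation:
    """Multiplicative/absolute input perturbations for uncertainty analysis.

    Scales default to 1 (nominal); ``anastomosis_angle_deg`` and
    ``venous_pressure_mmhg`` override their nominal values when set.
    """

    artery_diameter_scale: float = 1.0
    vein_diameter_scale: float = 1.0
    length_scale: float = 1.0
    youngs_modulus_scale: float = 1.0
    windkessel_resistance_scale: float = 1.0
    leak_resistance_scale: float = 1.0
    anastomosis_angle_deg: Optional[float] = None
    venous_pressure_mmhg: Optional[float] = None

    def __post_init__(self):
        for name in ("artery_diameter_scale", "vein_diameter_scale", "length_scale",
                     "youngs_modulus_scale", "windkessel_resistance_scale",
                     "leak_resistance_scale"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")


NOMINAL = Perturbation()


@dataclass(frozen=True)
class PersonalizationOptions:
    """Fixed conventions of the personalization procedure."""

    zwk_fraction: float = 0.10        # Z_wk as fraction of total terminal R
    wk_time_constant_s: float = 1.5   # R_wk * C_wk
    leak_multiplier: float = 100.0    # R_L = multiplier * segment R (veins)
    max_seg_len_cm: float = 5.0
    venous_pressure_mmhg: float = 10.0
    anastomosis_angle_deg: float = DEFAULT_ANASTOMOSIS_ANGLE_DEG
    loss_endpoints: Optional[Dict[str, Tuple[float, float]]] = None


DEFAULT_OPTIONS = PersonalizationOptions()


# --------------------------------------------------------------------------
# elementary personalization operations
# --------------------------------------------------------------------------

def wall_thickness(vessel_id: str, radius_mm: float,
                   literature: Optional[LiteratureGeometry] = None) -> float:
    """Wall thickness (mm) from the vessel's thickness-to-radius ratio."""
    V.check_vessel(vessel_id)
    if radius_mm <= 0:
        raise ValidationError("radius must be positive")
    return wall_ratio(vessel_id, literature) * radius_mm


def wall_ratio(vessel_id: str, literature: Optional[LiteratureGeometry] = None) -> float:
    V.check_vessel(vessel_id)
    if vessel_id in V.VEINS:
        return V.VEIN_WALL_RATIO
    if vessel_id in V.WALL_RATIO_15:
        return 0.15
    if vessel_id in V.WALL_RATIO_20:
        return 0.20
    lit = literature or load_literature_geometry()
    return lit[vessel_id].h_over_r


def distensibility(distension_waveform: Waveform,
                   pressure_waveform: Waveform) -> float:
    """Cross-sectional distensibility D = dA / (A dp), in 1/Pa.

    Computed from the systolic-diastolic excursions of the diameter and
    pressure waveforms: A scales with the diameter squared.
    """
    d = distension_waveform.values
    p = pressure_waveform.values
    d_dias, d_sys = float(np.min(d)), float(np.max(d))
    dp_pa = units.mmhg_to_pa(float(np.max(p) - np.min(p)))
    if dp_pa <= 0:
        raise ValidationError("pulse pressure must be positive")
    if d_sys <= d_dias:
        raise RigidVesselError("zero wall distension over the cardiac cycle")
    rel_area = (d_sys ** 2 - d_dias ** 2) / d_dias ** 2
    return rel_area / dp_pa


def youngs_modulus_from_distensibility(distension_waveform: Waveform,
                                       pressure_waveform: Waveform,
                                       diastolic_diameter_mm: Optional[float] = None,
                                       wall_thickness_mm: Optional[float] = None,
                                       h_over_r: float = _ARM_H_OVER_R) -> float:
    """Young's modulus (kPa) of the brachial artery from distensibility.

    Uses the thin-wall incompressible relation E = 3 / (2 D (h/r)).  The
    diastolic diameter and wall thickness default to the waveform minimum
    and the brachial 15 % thickness ratio.
    """
    dist = distensibility(distension_waveform, pressure_waveform)
    if diastolic_diameter_mm is None:
        diastolic_diameter_mm = float(np.min(distension_waveform.values))
    r_mm = diastolic_diameter_mm / 2.0
    if wall_thickness_mm is not None:
        if r_mm <= 0:
            raise ValidationError("diastolic diameter must be positive")
        h_over_r = wall_thickness_mm / r_mm
    e_pa = 3.0 / (2.0 * dist * h_over_r)
    return units.pa_to_kpa(e_pa)


def scale_aortic_geometry(literature: LiteratureGeometry,
                          measured_subclavian_diameter_mm: float,
                          youngs_modulus_scale: float = 1.0,
                          length_scale: float = 1.0) -> Dict[str, VesselGeometry]:
    """Literature aorta/primary-branch geometry scaled to the patient.

    Diameters are multiplied by the ratio of the measured to the generic
    subclavian diameter; lengths are left unchanged (apart from the explicit
    uncertainty scale).
    """
    if measured_subclavian_diameter_mm <= 0:
        raise ValidationError("measured subclavian diameter must be positive")
    central = (V.ASCENDING_AORTA, V.AORTIC_ARCH_A1, V.AORTIC_ARCH_A2,
               V.THORACIC_AORTA, V.INNOMINATE, V.LEFT_CAROTID, V.RIGHT_CAROTID,
               V.LEFT_SUBCLAVIAN, V.RIGHT_SUBCLAVIAN, V.VERTEBRAL)
    lit_sub = literature[V.LEFT_SUBCLAVIAN].diameter_mm
    factor = measured_subclavian_diameter_mm / lit_sub
    out = {}
    for vid in central:
        lv = literature[vid]
        length = lv.length_cm * length_scale
        out[vid] = VesselGeometry(
            vessel_id=vid, length_cm=length,
            diameter_profile=((0.0, lv.diameter_mm * factor),
                              (length, lv.diameter_mm * factor)),
            wall_thickness_ratio=lv.h_over_r,
            youngs_modulus_kpa=lv.youngs_modulus_kpa * youngs_modulus_scale,
            is_vein=False)
    return out


def place_anastomosis(configuration: str, geometries: Dict[str, VesselGeometry],
                      angle_deg: float = DEFAULT_ANASTOMOSIS_ANGLE_DEG,
                      loss_endpoints=None) -> AnastomosisPlacement:
    """Anastomosis position and angle for a configuration.

    5 cm proximal to the wrist on the radial artery (RC-AVF) or 5 cm
    proximal to the elbow bifurcation on the brachial artery (BC/BB-AVF);
    the angle defaults to 45 degrees (typical surgical range 30-60 degrees).
    """
    cfg = normalize_configuration(configuration)
    if cfg == "preoperative":
        raise ValidationError("preoperative configuration has no anastomosis")
    host = V.RADIAL if cfg == "RC-AVF" else V.AXILLARY_BRACHIAL
    if host not in geometries:
        raise MissingMeasurementError(V.human_name(host))
    length = geometries[host].length_cm
    if length <= ANASTOMOSIS_OFFSET_CM:
        raise ValidationError(
            f"{V.human_name(host)} ({length} cm) shorter than the "
            f"{ANASTOMOSIS_OFFSET_CM} cm anastomosis offset")
    return AnastomosisPlacement(host, length - ANASTOMOSIS_OFFSET_CM,
                                angle_deg, loss_endpoints)


def caliber_screen(record: PatientRecord,
                   threshold_mm: float = CALIBER_THRESHOLD_MM) -> Dict[str, str]:
    """Screen measured vessels for AVF-suitable caliber.

    A vessel is adequate iff its minimum measured diameter strictly exceeds
    the 2 mm threshold (conservative: the worst station governs).
    """
    out = {}
    for vid in record.measured_vessels():
        dmin = min(d for _, d in record.stations(vid))
        out[vid] = "adequate" if dmin > threshold_mm else "inadequate"
    return out


# --------------------------------------------------------------------------
# geometry assembly
# --------------------------------------------------------------------------

def _access_subclavian(side: str) -> str:
    return V.LEFT_SUBCLAVIAN if side == "left" else V.RIGHT_SUBCLAVIAN


def assemble_geometries(record: PatientRecord,
                        literature: Optional[LiteratureGeometry] = None,
                        perturbation: Perturbation = NOMINAL,
                        options: PersonalizationOptions = DEFAULT_OPTIONS
                        ) -> Dict[str, VesselGeometry]:
    """Build the full VesselGeometry set for one patient.

    Measured vessels take their diameter stations from the duplex record;
    the aorta and primary branches are generic geometry scaled by the
    measured subclavian diameter; the arm-wide arterial Young's modulus
    comes from brachial distensibility; venous lengths equal the arterial
    lengths at the same anatomical level (shipped in the literature table).
    """
    lit = literature or load_literature_geometry()
    e_arm_kpa = youngs_modulus_from_distensibility(
        record.distension_waveform, record.pressure_waveform
    ) * perturbation.youngs_modulus_scale

    access_sub = _access_subclavian(record.side)
    sub_stations = record.stations(access_sub)
    if not sub_stations:
        raise MissingMeasurementError(V.human_name(access_sub))
    sub_d = sub_stations[0][1] * perturbation.artery_diameter_scale

    geoms = scale_aortic_geometry(lit, sub_d,
                                  youngs_modulus_scale=perturbation.youngs_modulus_scale,
                                  length_scale=perturbation.length_scale)

    for vid in record.measured_vessels():
        lv = lit[vid]
        is_vein = vid in V.VEINS
        scale = (perturbation.vein_diameter_scale if is_vein
                 else perturbation.artery_diameter_scale)
        length = lv.length_cm * perturbation.length_scale
        stations = []
        for pos, d in record.stations(vid):
            pos = min(pos * perturbation.length_scale, length)
            stations.append((pos, d * scale))
        if is_vein:
            e_kpa = lv.youngs_modulus_kpa * perturbation.youngs_modulus_scale
        elif vid in V.ARM_ARTERIES or vid in (V.LEFT_SUBCLAVIAN, V.RIGHT_SUBCLAVIAN):
            e_kpa = e_arm_kpa
        else:
            e_kpa = lv.youngs_modulus_kpa * perturbation.youngs_modulus_scale
        geoms[vid] = VesselGeometry(
            vessel_id=vid, length_cm=length, diameter_profile=tuple(stations),
            wall_thickness_ratio=wall_ratio(vid, lit), youngs_modulus_kpa=e_kpa,
            is_vein=is_vein)
    return geoms


# --------------------------------------------------------------------------
# windkessel personalization
# --------------------------------------------------------------------------

def _terminal_target_flows(network: VascularNetwork,
                           mean_flows_ml_min: Dict[str, float]) -> Dict[str, float]:
    """Mean flow target (SI) per terminal vessel from the measured sites.

    The interosseus terminal absorbs the brachial flow not accounted for by
    the measured radial and ulnar flows; the non-arm remainder is split over
    the central terminals by fixed fractions.
    """
    q = {k: units.ml_per_min_to_m3_per_s(v) for k, v in mean_flows_ml_min.items()}
    q_inter = q["brachial"] - q["radial"] - q["ulnar"]
    if q_inter <= 1e-9 * q["brachial"]:
        raise InconsistentMeasurementsError(
            "radial + ulnar mean flows leave no interosseus flow")
    rest = q["aorta"] - q["brachial"]
    if rest <= 0:
        raise InconsistentMeasurementsError("arm flow exceeds aortic flow")
    contralateral = (V.RIGHT_SUBCLAVIAN if network.side == "left"
                     else V.LEFT_SUBCLAVIAN)
    targets = {
        V.RADIAL: q["radial"],
        V.ULNAR_DISTAL: q["ulnar"],
        V.INTEROSSEUS: q_inter,
        V.THORACIC_AORTA: rest * REST_FLOW_FRACTIONS[V.THORACIC_AORTA],
        V.LEFT_CAROTID: rest * REST_FLOW_FRACTIONS[V.LEFT_CAROTID],
        V.RIGHT_CAROTID: rest * REST_FLOW_FRACTIONS[V.RIGHT_CAROTID],
        V.VERTEBRAL: rest * REST_FLOW_FRACTIONS[V.VERTEBRAL],
        contralateral: rest * REST_FLOW_FRACTIONS["contralateral_subclavian"],
    }
    return targets


def personalize_windkessels(network: VascularNetwork, map_pressure_mmhg: float,
                            mean_flows_ml_min: Dict[str, float],
                            venous_pressure_mmhg: float = 10.0,
                            options: PersonalizationOptions = DEFAULT_OPTIONS
                            ) -> Dict[str, WindkesselTerminal]:
    """Fit the windkessel terminals of a preoperative network.

    Each terminal's total resistance follows from MAP, the venous reference
    pressure and its target mean flow, after subtracting the serial
    resistance of the modeled segments upstream.  The total is split into
    Z_wk (10 %) and R_wk (90 %); C_wk is set from a fixed peripheral time
    constant R_wk * C_wk = 1.5 s.
    """
    if network.configuration != "preoperative":
        raise ValidationError("windkessels are personalized on the preoperative network")
    targets = _terminal_target_flows(network, mean_flows_ml_min)

    # orient the (tree-shaped) preoperative network away from the inflow
    g = nx.DiGraph()
    for i, br in enumerate(network.branches):
        g.add_edge(br.node_a, br.node_b, branch=i)
    order = list(nx.topological_sort(g))

    node_of = network.terminal_nodes
    inflow_node_q: Dict[int, float] = {node_of[vid]: q for vid, q in targets.items()}

    # accumulate subtree flows from the leaves up
    node_flow: Dict[int, float] = {}
    edge_flow: Dict[int, float] = {}
    for node in reversed(order):
        total = inflow_node_q.get(node, 0.0)
        for _, child, data in g.out_edges(node, data=True):
            total += node_flow[child]
        node_flow[node] = total
        for parent, _, data in g.in_edges(node, data=True):
            edge_flow[data["branch"]] = total

    # node pressures by marching down from the aortic root at MAP
    p_root = units.mmhg_to_pa(map_pressure_mmhg)
    p_ven = units.mmhg_to_pa(venous_pressure_mmhg)
    node_p = {network.inflow_node: p_root}
    for node in order:
        if node == network.inflow_node:
            continue
        (parent, _, data), = g.in_edges(node, data=True)
        br = network.branches[data["branch"]]
        node_p[node] = node_p[parent] - br.elements.R * edge_flow[data["branch"]]

    out: Dict[str, WindkesselTerminal] = {}
    for vid, q_t in targets.items():
        node = node_of[vid]
        r_total = (node_p[node] - p_ven) / q_t
        if r_total <= 0:
            raise InconsistentMeasurementsError(
                f"modeled upstream resistance exceeds the total implied by MAP "
                f"and the {V.human_name(vid)} mean flow")
        z = options.zwk_fraction * r_total
        r_wk = r_total - z
        c_wk = options.wk_time_constant_s / r_wk
        out[vid] = WindkesselTerminal(Z_wk=z, R_wk=r_wk, C_wk=c_wk)
    return out


def scale_terminals(terminals: Dict[str, WindkesselTerminal], resistance_scale: float,
                    options: PersonalizationOptions = DEFAULT_OPTIONS
                    ) -> Dict[str, WindkesselTerminal]:
    """Apply an uncertainty scale to the windkessel resistances.

    The peripheral time constant is held fixed, so C_wk moves inversely
    with R_wk.
    """
    out = {}
    for vid, t in terminals.items():
        r_wk = t.R_wk * resistance_scale
        out[vid] = WindkesselTerminal(Z_wk=t.Z_wk * resistance_scale, R_wk=r_wk,
                                      C_wk=options.wk_time_constant_s / r_wk)
    return out


# --------------------------------------------------------------------------
# full pipeline
# --------------------------------------------------------------------------

@dataclass
class PersonalizedModel:
    """Everything needed to simulate one patient."""

    record: PatientRecord
    geometries: Dict[str, VesselGeometry]
    preop_network: VascularNetwork
    terminals: Dict[str, WindkesselTerminal]
    venous_pressure_mmhg: float
    options: PersonalizationOptions
    perturbation: Perturbation

    def postop_network(self, configuration: str) -> VascularNetwork:
        cfg = normalize_configuration(configuration)
        if cfg == "preoperative":
            return self.preop_network
        angle = (self.perturbation.anastomosis_angle_deg
                 if self.perturbation.anastomosis_angle_deg is not None
                 else self.options.anastomosis_angle_deg)
        placement = place_anastomosis(cfg, self.geometries, angle,
                                      self.options.loss_endpoints)
        leak_mult = self.options.leak_multiplier * self.perturbation.leak_resistance_scale
        net = build_domain(cfg, self.record.side, self.geometries,
                           anastomosis=placement,
                           max_seg_len_cm=self.options.max_seg_len_cm,
                           leak_multiplier=leak_mult)
        net.terminals = dict(self.terminals)
        return net


def build_patient_model(record: PatientRecord, *,
                        perturbation: Perturbation = NOMINAL,
                        literature: Optional[LiteratureGeometry] = None,
                        options: PersonalizationOptions = DEFAULT_OPTIONS
                        ) -> PersonalizedModel:
    """Personalize geometry and boundary conditions for one patient."""
    geoms = assemble_geometries(record, literature, perturbation, options)
    preop = build_domain("preoperative", record.side, geoms,
                         max_seg_len_cm=options.max_seg_len_cm,
                         leak_multiplier=options.leak_multiplier)
    p_ven = (perturbation.venous_pressure_mmhg
             if perturbation.venous_pressure_mmhg is not None
             else options.venous_pressure_mmhg)
    terminals = personalize_windkessels(preop, record.map_pressure_mmhg,
                                        record.mean_flows_ml_min, p_ven, options)
    terminals = scale_terminals(terminals, perturbation.windkessel_resistance_scale,
                                options)
    preop.terminals = dict(terminals)
    return PersonalizedModel(record=record, geometries=geoms, preop_network=preop,
                             terminals=terminals, venous_pressure_mmhg=p_ven,
                             options=options, perturbation=perturbation)
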