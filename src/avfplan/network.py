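"""Lumped-parameter (0D) representation of the upper-extremity circulation.

Each vessel is divided into segments of at most 5 cm and every segment is
mapped onto an electrical-analog element: a resistor ``R`` for the viscous
(Poiseuille) resistance, an inductor ``L`` for blood inertia and a capacitor
``C`` for wall storage, arranged as a transmission-line ladder.  Venous
segments additionally carry a side-branch leakage resistor ``R_L`` draining
toward the central venous pressure, standing in for the many small tributary
veins that are not modeled individually.  Peripheral beds not modeled
segment-by-segment are closed by three-element windkessels (``Z_wk``,
``R_wk``, ``C_wk``).  The surgical artery-vein junction is represented by
two nonlinear resistors, one toward the vein (``R_v``) and one toward the
distal artery (``R_d``), whose pressure loss grows with the square of the
flow and depends on the anastomosis angle.

Closed forms used for the segment elements (``l`` segment length, ``r``
inner radius, ``h`` wall thickness, ``E`` Young's modulus, ``rho``/``mu``
blood density/viscosity)::

    R = 8 mu l / (pi r^4)        L = rho l / (pi r^2)
    C = 3 pi r^3 l / (2 E h)

All stored element values are SI; geometry is carried in clinical units
(cm, mm, kPa) because that is how it is measured and recorded.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Tuple

import networkx as nx
import numpy as np

from . import units, vessels as V
from .errors import IncompleteDomainError, ValidationError
from .profiles import interpolate_diameters

__all__ = [
    "BloodProperties",
    "DEFAULT_BLOOD",
    "VesselGeometry",
    "SegmentElements",
    "WindkesselTerminal",
    "AnastomosisElement",
    "AnastomosisBranch",
    "Branch",
    "VascularNetwork",
    "CONFIGURATIONS",
    "normalize_configuration",
    "loss_coefficient",
    "make_anastomosis",
    "anastomosis_pressure_drop",
    "segment_elements",
    "discretize_vessel",
    "split_geometry",
    "required_vessels",
    "build_domain",
]


# --------------------------------------------------------------------------
# domain types
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class BloodProperties:
    """Incompressible Newtonian blood."""

    density_kg_m3: float = 1.0e3
    dynamic_viscosity_pa_s: float = 3.0e-3

    def __post_init__(self):
        if self.density_kg_m3 <= 0 or self.dynamic_viscosity_pa_s <= 0:
            raise ValidationError("blood density and viscosity must be positive")


DEFAULT_BLOOD = BloodProperties()


@dataclass(frozen=True)
class VesselGeometry:
    """A named vessel with its measured/derived geometry and stiffness.

    ``diameter_profile`` is the list of (axial position cm, inner diameter
    mm) stations, positions counted from the proximal (central) end.
    """

    vessel_id: str
    length_cm: float
    diameter_profile: Tuple[Tuple[float, float], ...]
    wall_thickness_ratio: float
    youngs_modulus_kpa: float
    is_vein: bool = False

    def __post_init__(self):
        V.check_vessel(self.vessel_id)
        if self.length_cm <= 0:
            raise ValidationError(f"{self.vessel_id}: length must be positive")
        profile = tuple((float(p), float(d)) for p, d in self.diameter_profile)
        if not profile:
            raise ValidationError(f"{self.vessel_id}: empty diameter profile")
        for p, d in profile:
            if d <= 0:
                raise ValidationError(f"{self.vessel_id}: non-positive diameter")
            if p < -1e-9 or p > self.length_cm + 1e-9:
                raise ValidationError(f"{self.vessel_id}: station outside [0, length]")
        if not 0 < self.wall_thickness_ratio < 0.5:
            raise ValidationError(f"{self.vessel_id}: wall thickness ratio outside (0, 0.5)")
        if self.youngs_modulus_kpa <= 0:
            raise ValidationError(f"{self.vessel_id}: Young's modulus must be positive")
        object.__setattr__(self, "diameter_profile", profile)

    def diameter_at(self, position_cm) -> np.ndarray:
        """Inner diameter (mm) at arbitrary axial positions."""
        f = interpolate_diameters(
            self.diameter_profile, self.length_cm, vessel_name=self.vessel_id
        )
        return f(position_cm)


@dataclass(frozen=True)
class SegmentElements:
    """One lumped Pi-element.  Values in SI; ``R_L`` is None for no leakage."""

    R: float          # Pa.s/m^3
    L: float          # Pa.s^2/m^3
    C: float          # m^3/Pa
    seg_length_cm: float
    R_L: Optional[float] = None  # Pa.s/m^3

    def __post_init__(self):
        if self.R < 0 or self.L < 0 or self.C < 0:
            raise ValidationError("segment R, L, C must be non-negative")
        if self.R_L is not None and self.R_L <= 0:
            raise ValidationError("leakage resistance must be positive (or None)")
        if self.seg_length_cm > 5.0 + 1e-9:
            raise ValidationError("segment longer than the 5 cm maximum")


@dataclass(frozen=True)
class WindkesselTerminal:
    """Three-element windkessel closing a peripheral bed (SI values)."""

    Z_wk: float  # characteristic resistance, Pa.s/m^3
    R_wk: float  # peripheral resistance, Pa.s/m^3
    C_wk: float  # peripheral compliance, m^3/Pa

    def __post_init__(self):
        if self.Z_wk < 0 or self.R_wk <= 0 or self.C_wk <= 0:
            raise ValidationError("windkessel needs Z_wk >= 0, R_wk > 0, C_wk > 0")


# default loss-coefficient endpoints at 30 and 60 degrees per limb
DEFAULT_LOSS_ENDPOINTS: Dict[str, Tuple[float, float]] = {
    "venous": (3.0, 5.0),
    "distal": (1.0, 1.5),
}

_K_FLOOR = 0.05


def loss_coefficient(angle_deg: float, limb: str,
                     endpoints: Dict[str, Tuple[float, float]] | None = None) -> float:
    """Dimensionless junction loss coefficient K(theta) for one limb.

    Linear in the angle between the K(30 deg) and K(60 deg) endpoints,
    extended linearly outside that range and floored at a small positive
    value.
    """
    endpoints = endpoints or DEFAULT_LOSS_ENDPOINTS
    if limb not in endpoints:
        raise ValidationError(f"unknown anastomosis limb: {limb!r}")
    k30, k60 = endpoints[limb]
    k = k30 + (k60 - k30) * (angle_deg - 30.0) / 30.0
    return max(k, _K_FLOOR)


@dataclass(frozen=True)
class AnastomosisElement:
    """Angle- and flow-dependent junction between artery and vein.

    ``loss_coefficients`` maps limb ("venous" / "distal") to the resolved
    dimensionless K at this element's angle.
    """

    angle_deg: float
    venous_limb_area_mm2: float
    distal_limb_area_mm2: float
    loss_coefficients: Dict[str, float]

    def __post_init__(self):
        if not 0.0 <= self.angle_deg <= 90.0:
            raise ValidationError("anastomosis angle outside [0, 90] degrees")
        if self.venous_limb_area_mm2 <= 0 or self.distal_limb_area_mm2 <= 0:
            raise ValidationError("anastomosis limb areas must be positive")
        if any(k < 0 for k in self.loss_coefficients.values()):
            raise ValidationError("loss coefficients must be non-negative")

    def limb_area_mm2(self, limb: str) -> float:
        if limb == "venous":
            return self.venous_limb_area_mm2
        if limb == "distal":
            return self.distal_limb_area_mm2
        raise ValidationError(f"unknown anastomosis limb: {limb!r}")


def make_anastomosis(angle_deg: float, venous_limb_area_mm2: float,
                     distal_limb_area_mm2: float,
                     endpoints: Dict[str, Tuple[float, float]] | None = None
                     ) -> AnastomosisElement:
    """Build an anastomosis element, resolving K(theta) per limb."""
    ks = {limb: loss_coefficient(angle_deg, limb, endpoints)
          for limb in ("venous", "distal")}
    return AnastomosisElement(angle_deg, venous_limb_area_mm2,
                              distal_limb_area_mm2, ks)


def anastomosis_pressure_drop(elem: AnastomosisElement, q_ml_s: float, limb: str,
                              blood: BloodProperties = DEFAULT_BLOOD) -> float:
    """Junction pressure loss (mmHg) across one anastomosis limb.

    Quadratic (Borda-Carnot type) law, odd in the flow::

        dp = K(theta) * rho * q * |q| / (2 A^2)

    so the loss is sign-preserving, grows with the square of |q| and is
    linear in the loss coefficient.
    """
    k = elem.loss_coefficients[limb]
    area_m2 = units.mm2_to_m2(elem.limb_area_mm2(limb))
    q = units.ml_per_s_to_m3_per_s(q_ml_s)
    dp_pa = k * blood.density_kg_m3 * q * abs(q) / (2.0 * area_m2 ** 2)
    return units.pa_to_mmhg(dp_pa)


# --------------------------------------------------------------------------
# discretization
# --------------------------------------------------------------------------

def segment_elements(seg_length_cm: float, diameter_mm: float, h_over_r: float,
                     youngs_modulus_kpa: float,
                     blood: BloodProperties = DEFAULT_BLOOD,
                     leak_resistance: Optional[float] = None) -> SegmentElements:
    """Compute the lumped element values for one segment.

    Zero length yields zero elements (the degenerate limit); all other
    inputs must be positive.
    """
    if seg_length_cm < 0:
        raise ValidationError("segment length must be non-negative")
    if seg_length_cm == 0.0:
        return SegmentElements(0.0, 0.0, 0.0, 0.0)
    if diameter_mm <= 0 or h_over_r <= 0 or youngs_modulus_kpa <= 0:
        raise ValidationError("diameter, wall ratio and Young's modulus must be positive")

    ell = units.cm_to_m(seg_length_cm)
    r = units.mm_to_m(diameter_mm) / 2.0
    h = h_over_r * r
    e_pa = units.kpa_to_pa(youngs_modulus_kpa)
    mu = blood.dynamic_viscosity_pa_s
    rho = blood.density_kg_m3

    R = 8.0 * mu * ell / (math.pi * r ** 4)
    L = rho * ell / (math.pi * r ** 2)
    C = 3.0 * math.pi * r ** 3 * ell / (2.0 * e_pa * h)
    return SegmentElements(R, L, C, seg_length_cm, R_L=leak_resistance)


def discretize_vessel(geometry: VesselGeometry, max_seg_len_cm: float = 5.0,
                      blood: BloodProperties = DEFAULT_BLOOD,
                      leak_multiplier: Optional[float] = 100.0
                      ) -> List[SegmentElements]:
    """Divide a vessel into ceil(length / max) equal segments.

    Element values use the diameter interpolated at each segment midpoint.
    Venous segments receive a leakage resistor ``R_L = leak_multiplier * R``
    (pass ``leak_multiplier=None`` to disable leakage entirely).
    """
    if max_seg_len_cm <= 0:
        raise ValidationError("maximum segment length must be positive")
    n = max(1, math.ceil(geometry.length_cm / max_seg_len_cm - 1e-12))
    seg_len = geometry.length_cm / n
    mids = (np.arange(n) + 0.5) * seg_len
    diameters = geometry.diameter_at(mids)
    out = []
    for d in diameters:
        el = segment_elements(seg_len, float(d), geometry.wall_thickness_ratio,
                              geometry.youngs_modulus_kpa, blood)
        if geometry.is_vein and leak_multiplier is not None:
            el = replace(el, R_L=leak_multiplier * el.R)
        out.append(el)
    return out


def split_geometry(geometry: VesselGeometry, position_cm: float
                   ) -> Tuple[VesselGeometry, VesselGeometry]:
    """Split a vessel at an axial position into proximal and distal parts.

    Station positions of the distal part are rebased to its own proximal
    end; the boundary diameter is added to both parts so the profile stays
    continuous.
    """
    if not 0.0 < position_cm < geometry.length_cm:
        raise ValidationError(
            f"{geometry.vessel_id}: split position {position_cm} cm outside "
            f"(0, {geometry.length_cm}) cm"
        )
    d_split = float(geometry.diameter_at(position_cm))
    prox_sta = [(p, d) for p, d in geometry.diameter_profile if p < position_cm - 1e-9]
    dist_sta = [(p - position_cm, d) for p, d in geometry.diameter_profile
                if p > position_cm + 1e-9]
    prox = replace(geometry, length_cm=position_cm,
                   diameter_profile=tuple(prox_sta + [(position_cm, d_split)]))
    dist = replace(geometry, length_cm=geometry.length_cm - position_cm,
                   diameter_profile=tuple([(0.0, d_split)] + dist_sta))
    return prox, dist


# --------------------------------------------------------------------------
# network assembly
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class Branch:
    """A lumped segment connecting two nodes (flow positive a -> b)."""

    node_a: int
    node_b: int
    elements: SegmentElements
    vessel_id: str


@dataclass(frozen=True)
class AnastomosisBranch:
    """One nonlinear anastomosis limb (venous or distal)."""

    node_a: int
    node_b: int
    limb: str
    loss_k: float
    area_m2: float
    r_linear: float  # short-segment Poiseuille term keeping q=0 well-posed


@dataclass
class VascularNetwork:
    """Assembled computational domain for one configuration.

    ``terminals`` maps terminal vessel id to its windkessel (or None until
    personalized); ``terminal_nodes`` maps the same ids to node numbers.
    ``venous_outflow_node`` is the prescribed-pressure node (None for the
    preoperative domain, whose windkessels drain to the venous reference
    directly).
    """

    configuration: str
    side: str
    n_nodes: int
    branches: List[Branch]
    anastomosis: Optional[AnastomosisElement]
    anastomosis_branches: List[AnastomosisBranch]
    terminal_nodes: Dict[str, int]
    terminals: Dict[str, Optional[WindkesselTerminal]]
    inflow_node: int
    venous_outflow_node: Optional[int]
    blood: BloodProperties
    vessel_branches: Dict[str, List[int]] = field(default_factory=dict)

    def proximal_branch(self, vessel_id: str) -> int:
        """Index of the most proximal segment of a vessel."""
        return self.vessel_branches[vessel_id][0]

    def vessel_resistance(self, vessel_id: str) -> float:
        """Total serial viscous resistance of a vessel (SI)."""
        return sum(self.branches[i].elements.R for i in self.vessel_branches[vessel_id])

    def graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(self.n_nodes))
        for br in self.branches:
            g.add_edge(br.node_a, br.node_b)
        for ab in self.anastomosis_branches:
            g.add_edge(ab.node_a, ab.node_b)
        return g

    def validate(self) -> None:
        if not nx.is_connected(self.graph()):
            raise ValidationError("network graph is not connected")
        if self.configuration == "preoperative" and (
            self.anastomosis is not None or self.anastomosis_branches
        ):
            raise ValidationError("preoperative network must not contain an anastomosis")
        for vid, node in self.terminal_nodes.items():
            if node < 0 or node >= self.n_nodes:
                raise ValidationError(f"terminal node of {vid} out of range")


CONFIGURATIONS = ("preoperative", "RC-AVF", "BC-AVF", "BB-AVF")

_CONFIG_ALIASES = {
    "preoperative": "preoperative", "preop": "preoperative",
    "rc": "RC-AVF", "rc-avf": "RC-AVF", "rcavf": "RC-AVF",
    "bc": "BC-AVF", "bc-avf": "BC-AVF", "bcavf": "BC-AVF",
    "bb": "BB-AVF", "bb-avf": "BB-AVF", "bbavf": "BB-AVF",
}


def normalize_configuration(configuration: str) -> str:
    key = configuration.strip().lower().replace("_", "-")
    if key not in _CONFIG_ALIASES:
        raise ValidationError(f"unknown configuration: {configuration!r}")
    return _CONFIG_ALIASES[key]


#: distance of the anastomosis from the distal end of the host artery (cm):
#: 5 cm proximal to the wrist (RC) or to the elbow bifurcation (BC/BB)
ANASTOMOSIS_OFFSET_CM = 5.0

_BASE_VESSELS = frozenset(
    {
        V.ASCENDING_AORTA, V.AORTIC_ARCH_A1, V.AORTIC_ARCH_A2, V.THORACIC_AORTA,
        V.INNOMINATE, V.LEFT_CAROTID, V.RIGHT_CAROTID, V.LEFT_SUBCLAVIAN,
        V.RIGHT_SUBCLAVIAN, V.VERTEBRAL,
    }
    | V.ARM_ARTERIES
)

_VENOUS_PATH = {
    "preoperative": (),
    "RC-AVF": (V.CEPHALIC_DISTAL, V.CEPHALIC_PROXIMAL, V.AXILLARY_SUBCLAVIAN_VEIN),
    "BC-AVF": (V.MEDIAN_CUBITAL, V.CEPHALIC_PROXIMAL, V.AXILLARY_SUBCLAVIAN_VEIN),
    "BB-AVF": (V.BASILIC, V.AXILLARY_SUBCLAVIAN_VEIN),
}

_HOST_ARTERY = {"RC-AVF": V.RADIAL, "BC-AVF": V.AXILLARY_BRACHIAL,
                "BB-AVF": V.AXILLARY_BRACHIAL}


def required_vessels(configuration: str, side: str) -> frozenset:
    cfg = normalize_configuration(configuration)
    return frozenset(_BASE_VESSELS | set(_VENOUS_PATH[cfg]))


@dataclass(frozen=True)
class AnastomosisPlacement:
    """Where and how the fistula is sewn onto the host artery."""

    host_vessel: str
    position_cm: float  # from the proximal end of the host artery
    angle_deg: float = 45.0
    loss_endpoints: Optional[Dict[str, Tuple[float, float]]] = None


class _Builder:
    def __init__(self, blood, max_seg_len, leak_multiplier):
        self.blood = blood
        self.max_seg_len = max_seg_len
        self.leak_multiplier = leak_multiplier
        self.n_nodes = 1  # node 0 = inflow (aortic root)
        self.branches: List[Branch] = []
        self.vessel_branches: Dict[str, List[int]] = {}

    def new_node(self) -> int:
        self.n_nodes += 1
        return self.n_nodes - 1

    def chain(self, geometry: VesselGeometry, start_node: int) -> int:
        """Discretize a vessel and append it starting at ``start_node``."""
        segs = discretize_vessel(geometry, self.max_seg_len, self.blood,
                                 self.leak_multiplier)
        idxs = self.vessel_branches.setdefault(geometry.vessel_id, [])
        node = start_node
        for el in segs:
            nxt = self.new_node()
            idxs.append(len(self.branches))
            self.branches.append(Branch(node, nxt, el, geometry.vessel_id))
            node = nxt
        return node


def build_domain(configuration: str, side: str,
                 geometries: Dict[str, VesselGeometry], *,
                 anastomosis: Optional[AnastomosisPlacement] = None,
                 blood: BloodProperties = DEFAULT_BLOOD,
                 max_seg_len_cm: float = 5.0,
                 leak_multiplier: Optional[float] = 100.0) -> VascularNetwork:
    """Assemble the computational domain for one AVF configuration.

    The arterial tree (aorta, primary branches, access-side arm arteries) is
    always included; the venous outflow trajectory depends on the
    configuration, and the preoperative domain carries no veins at all.  The
    anastomosis placement defaults to 5 cm proximal to the wrist (RC-AVF) or
    to the elbow bifurcation (BC/BB-AVF) at a 45 degree angle.

    Raises :class:`IncompleteDomainError` naming the first missing vessel.
    """
    cfg = normalize_configuration(configuration)
    if side not in ("left", "right"):
        raise ValidationError("side must be 'left' or 'right'")

    for vid in sorted(required_vessels(cfg, side)):
        if vid not in geometries:
            raise IncompleteDomainError(V.human_name(vid))

    b = _Builder(blood, max_seg_len_cm, leak_multiplier)
    g = geometries

    asc_end = b.chain(g[V.ASCENDING_AORTA], 0)
    innom_end = b.chain(g[V.INNOMINATE], asc_end)
    arch1_end = b.chain(g[V.AORTIC_ARCH_A1], asc_end)
    b.chain(g[V.LEFT_CAROTID], arch1_end)
    b.chain(g[V.RIGHT_CAROTID], innom_end)
    arch2_end = b.chain(g[V.AORTIC_ARCH_A2], arch1_end)
    b.chain(g[V.THORACIC_AORTA], arch2_end)

    if side == "left":
        sub_end = b.chain(g[V.LEFT_SUBCLAVIAN], arch2_end)
        b.chain(g[V.RIGHT_SUBCLAVIAN], innom_end)
        contralateral = V.RIGHT_SUBCLAVIAN
    else:
        sub_end = b.chain(g[V.RIGHT_SUBCLAVIAN], innom_end)
        b.chain(g[V.LEFT_SUBCLAVIAN], arch2_end)
        contralateral = V.LEFT_SUBCLAVIAN

    b.chain(g[V.VERTEBRAL], sub_end)

    anast_elem: Optional[AnastomosisElement] = None
    anast_branches: List[AnastomosisBranch] = []
    junction = None
    vein_start = None

    def _default_placement(host: str) -> AnastomosisPlacement:
        length = g[host].length_cm
        if length <= ANASTOMOSIS_OFFSET_CM:
            raise ValidationError(
                f"{V.human_name(host)} shorter than the {ANASTOMOSIS_OFFSET_CM} cm "
                "anastomosis offset"
            )
        return AnastomosisPlacement(host, length - ANASTOMOSIS_OFFSET_CM)

    if cfg in ("BC-AVF", "BB-AVF"):
        placement = anastomosis or _default_placement(V.AXILLARY_BRACHIAL)
        prox, dist = split_geometry(g[V.AXILLARY_BRACHIAL], placement.position_cm)
        junction = b.chain(prox, sub_end)
        dist_start = b.new_node()
        elbow_end = b.chain(dist, dist_start)
    else:
        placement = None
        elbow_end = b.chain(g[V.AXILLARY_BRACHIAL], sub_end)
        dist_start = None

    if cfg == "RC-AVF":
        placement = anastomosis or _default_placement(V.RADIAL)
        prox, dist = split_geometry(g[V.RADIAL], placement.position_cm)
        junction = b.chain(prox, elbow_end)
        dist_start = b.new_node()
        b.chain(dist, dist_start)
    else:
        b.chain(g[V.RADIAL], elbow_end)

    ulnar_end = b.chain(g[V.ULNAR_PROXIMAL], elbow_end)
    b.chain(g[V.INTEROSSEUS], ulnar_end)
    b.chain(g[V.ULNAR_DISTAL], ulnar_end)

    venous_outflow = None
    if cfg != "preoperative":
        vein_start = b.new_node()
        node = vein_start
        for vid in _VENOUS_PATH[cfg]:
            node = b.chain(g[vid], node)
        venous_outflow = node

        host = _HOST_ARTERY[cfg]
        d_host = float(g[host].diameter_at(placement.position_cm))
        first_vein = _VENOUS_PATH[cfg][0]
        d_vein = float(g[first_vein].diameter_at(0.0))
        area_v = math.pi * (d_vein / 2.0) ** 2
        area_d = math.pi * (d_host / 2.0) ** 2
        anast_elem = make_anastomosis(placement.angle_deg, area_v, area_d,
                                      placement.loss_endpoints)
        for limb, nb, d_mm in (("venous", vein_start, d_vein),
                               ("distal", dist_start, d_host)):
            r_lin = segment_elements(0.5, d_mm, 0.15, 500.0, blood).R
            anast_branches.append(AnastomosisBranch(
                node_a=junction, node_b=nb, limb=limb,
                loss_k=anast_elem.loss_coefficients[limb],
                area_m2=units.mm2_to_m2(anast_elem.limb_area_mm2(limb)),
                r_linear=r_lin))

    terminal_vessels = [V.THORACIC_AORTA, V.LEFT_CAROTID, V.RIGHT_CAROTID,
                        contralateral, V.VERTEBRAL, V.RADIAL, V.ULNAR_DISTAL,
                        V.INTEROSSEUS]
    terminal_nodes = {vid: b.branches[b.vessel_branches[vid][-1]].node_b
                      for vid in terminal_vessels}

    net = VascularNetwork(
        configuration=cfg, side=side, n_nodes=b.n_nodes, branches=b.branches,
        anastomosis=anast_elem, anastomosis_branches=anast_branches,
        terminal_nodes=terminal_nodes,
        terminals={vid: None for vid in terminal_vessels},
        inflow_node=0, venous_outflow_node=venous_outflow, blood=blood,
        vessel_branches=b.vessel_branches,
    )
    net.validate()
    return net
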