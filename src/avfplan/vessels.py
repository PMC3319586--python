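"""Vessel naming for the upper-extremity computational domain.

Twenty named vessels make up the domain: the aorta with its primary
branches, the arm arteries of the access side, and the superficial venous
outflow trajectories (cephalic and basilic).
"""

from __future__ import annotations

from .errors import UnknownVesselError

# arterial tree
ASCENDING_AORTA = "ascending_aorta"
AORTIC_ARCH_A1 = "aortic_arch_a1"
AORTIC_ARCH_A2 = "aortic_arch_a2"
THORACIC_AORTA = "thoracic_aorta"
INNOMINATE = "innominate"
LEFT_CAROTID = "left_carotid"
RIGHT_CAROTID = "right_carotid"
LEFT_SUBCLAVIAN = "left_subclavian"
RIGHT_SUBCLAVIAN = "right_subclavian"
VERTEBRAL = "vertebral"
AXILLARY_BRACHIAL = "axillary_brachial"
RADIAL = "radial"
ULNAR_PROXIMAL = "ulnar_proximal"
ULNAR_DISTAL = "ulnar_distal"
INTEROSSEUS = "interosseus"

# venous outflow
CEPHALIC_DISTAL = "cephalic_distal"
MEDIAN_CUBITAL = "median_cubital"
CEPHALIC_PROXIMAL = "cephalic_proximal"
BASILIC = "basilic"
AXILLARY_SUBCLAVIAN_VEIN = "axillary_subclavian_vein"

VEINS = frozenset(
    {CEPHALIC_DISTAL, MEDIAN_CUBITAL, CEPHALIC_PROXIMAL, BASILIC, AXILLARY_SUBCLAVIAN_VEIN}
)

ARM_ARTERIES = frozenset(
    {AXILLARY_BRACHIAL, RADIAL, ULNAR_PROXIMAL, ULNAR_DISTAL, INTEROSSEUS}
)

ALL_VESSELS = frozenset(
    {
        ASCENDING_AORTA,
        AORTIC_ARCH_A1,
        AORTIC_ARCH_A2,
        THORACIC_AORTA,
        INNOMINATE,
        LEFT_CAROTID,
        RIGHT_CAROTID,
        LEFT_SUBCLAVIAN,
        RIGHT_SUBCLAVIAN,
        VERTEBRAL,
    }
    | ARM_ARTERIES
    | VEINS
)

HUMAN_NAMES = {
    ASCENDING_AORTA: "ascending aorta",
    AORTIC_ARCH_A1: "aortic arch A1",
    AORTIC_ARCH_A2: "aortic arch A2",
    THORACIC_AORTA: "thoracic aorta",
    INNOMINATE: "innominate artery",
    LEFT_CAROTID: "left carotid artery",
    RIGHT_CAROTID: "right carotid artery",
    LEFT_SUBCLAVIAN: "left subclavian artery",
    RIGHT_SUBCLAVIAN: "right subclavian artery",
    VERTEBRAL: "vertebral artery",
    AXILLARY_BRACHIAL: "axillary and brachial artery",
    RADIAL: "radial artery",
    ULNAR_PROXIMAL: "proximal ulnar artery",
    ULNAR_DISTAL: "distal ulnar artery",
    INTEROSSEUS: "interosseus artery",
    CEPHALIC_DISTAL: "cephalic vein (distal)",
    MEDIAN_CUBITAL: "median cubital vein",
    CEPHALIC_PROXIMAL: "cephalic vein (proximal)",
    BASILIC: "basilic vein",
    AXILLARY_SUBCLAVIAN_VEIN: "axillary and subclavian vein",
}

# wall thickness-to-radius ratios measured for the arm arteries;
# veins uniformly use 10 %, everything else comes from the literature table
WALL_RATIO_15 = frozenset({LEFT_SUBCLAVIAN, RIGHT_SUBCLAVIAN, AXILLARY_BRACHIAL})
WALL_RATIO_20 = frozenset({RADIAL, ULNAR_PROXIMAL, ULNAR_DISTAL, INTEROSSEUS})
VEIN_WALL_RATIO = 0.10


def check_vessel(vessel_id: str) -> str:
    if vessel_id not in ALL_VESSELS:
        raise UnknownVesselError(vessel_id)
    return vessel_id


def human_name(vessel_id: str) -> str:
    return HUMAN_NAMES.get(vessel_id, vessel_id)
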