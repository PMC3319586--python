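"""Unit conversions between SI internals and clinical reporting units.

All element values and state variables inside the solver are SI
(Pa, m, m^3/s, Pa.s/m^3, ...).  Everything a clinician reads or writes —
patient records, simulation summaries, decision reports — uses mmHg, mm,
ml/min and kPa.  Every conversion in the package goes through this module.
"""

MMHG_PA = 133.322387415  # Pa per mmHg

# resistance: 1 mmHg.s/ml in Pa.s/m^3
R_CLINICAL_SI = MMHG_PA / 1e-6
# compliance: 1 ml/mmHg in m^3/Pa
C_CLINICAL_SI = 1e-6 / MMHG_PA


def mmhg_to_pa(x):
    return x * MMHG_PA


def pa_to_mmhg(x):
    return x / MMHG_PA


def kpa_to_pa(x):
    return x * 1e3


def pa_to_kpa(x):
    return x / 1e3


def mm_to_m(x):
    return x * 1e-3


def cm_to_m(x):
    return x * 1e-2


def mm2_to_m2(x):
    return x * 1e-6


def ml_per_min_to_m3_per_s(x):
    return x * 1e-6 / 60.0


def m3_per_s_to_ml_per_min(x):
    return x * 6e7


def ml_per_s_to_m3_per_s(x):
    return x * 1e-6


def m3_per_s_to_ml_per_s(x):
    return x * 1e6


def r_clinical_to_si(x):
    """mmHg.s/ml -> Pa.s/m^3."""
    return x * R_CLINICAL_SI


def r_si_to_clinical(x):
    return x / R_CLINICAL_SI


def c_clinical_to_si(x):
    """ml/mmHg -> m^3/Pa."""
    return x * C_CLINICAL_SI


def c_si_to_clinical(x):
    return x / C_CLINICAL_SI
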