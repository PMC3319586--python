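"""Discretization, element formulas and domain assembly."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from avfplan import units
from avfplan.errors import IncompleteDomainError, ValidationError
from avfplan.network import (
    DEFAULT_BLOOD,
    DEFAULT_LOSS_ENDPOINTS,
    VesselGeometry,
    anastomosis_pressure_drop,
    build_domain,
    discretize_vessel,
    loss_coefficient,
    make_anastomosis,
    required_vessels,
    segment_elements,
    split_geometry,
)
from avfplan.personalize import assemble_geometries
from avfplan import vessels as V


def _geom(length, d0, d1=None, vessel=V.RADIAL, **kw):
    d1 = d0 if d1 is None else d1
    defaults = dict(wall_thickness_ratio=0.2, youngs_modulus_kpa=900.0)
    defaults.update(kw)
    return VesselGeometry(vessel_id=vessel, length_cm=length,
                          diameter_profile=((0.0, d0), (length, d1)), **defaults)


class TestDiscretize:
    def test_length_at_the_bound_gives_one_segment(self):
        segs = discretize_vessel(_geom(5.0, 4.0))
        assert len(segs) == 1 and segs[0].seg_length_cm == 5.0

    def test_ceiling_rule_with_equal_segments(self):
        segs = discretize_vessel(_geom(12.0, 4.0))
        assert len(segs) == 3
        assert all(s.seg_length_cm == pytest.approx(4.0) for s in segs)

    def test_midpoint_diameters_on_linear_profile(self):
        # 12 cm vessel tapering 4 -> 3 mm: midpoints at 2, 6, 10 cm
        g = _geom(12.0, 4.0, 3.0)
        mids = np.array([2.0, 6.0, 10.0])
        expected = 4.0 - mids / 12.0
        assert np.allclose(g.diameter_at(mids), expected)
        segs = discretize_vessel(g)
        # R of each segment reflects the midpoint diameter (R ~ d^-4)
        r_ratio = [segs[0].R / s.R for s in segs]
        d_ratio = [(d / expected[0]) ** 4 for d in expected]
        assert np.allclose(r_ratio, d_ratio, rtol=1e-12)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.floats(min_value=0.1, max_value=100.0))
    def test_segment_count_and_total_length(self, length):
        segs = discretize_vessel(_geom(length, 3.0))
        assert len(segs) == math.ceil(round(length / 5.0, 12))
        assert sum(s.seg_length_cm for s in segs) == pytest.approx(length, rel=1e-9)


class TestSegmentElements:
    def test_zero_length_limit(self):
        el = segment_elements(0.0, 4.0, 0.15, 700.0)
        assert (el.R, el.L, el.C) == (0.0, 0.0, 0.0)

    def test_poiseuille_and_inertance_scaling_with_diameter(self):
        a = segment_elements(5.0, 2.0, 0.15, 700.0)
        b = segment_elements(5.0, 4.0, 0.15, 700.0)
        assert a.R / b.R == pytest.approx(16.0, rel=1e-12)
        assert a.L / b.L == pytest.approx(4.0, rel=1e-12)

    def test_hand_calculated_values(self):
        # 5 cm, 4 mm, h/r 0.15, E 625 kPa, mu 3e-3 Pa.s, rho 1e3 kg/m3
        el = segment_elements(5.0, 4.0, 0.15, 625.0, DEFAULT_BLOOD)
        r = 2.0e-3
        R = 8 * 3e-3 * 0.05 / (math.pi * r**4)
        L = 1e3 * 0.05 / (math.pi * r**2)
        C = 3 * math.pi * r**3 * 0.05 / (2 * 625e3 * 0.15 * r)
        assert el.R == pytest.approx(R, rel=1e-12)
        assert el.L == pytest.approx(L, rel=1e-12)
        assert el.C == pytest.approx(C, rel=1e-12)
        # and in clinical units for the record
        assert units.r_si_to_clinical(el.R) == pytest.approx(0.1790, rel=1e-3)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        st.floats(min_value=0.2, max_value=1.6),
        st.floats(min_value=1.0, max_value=25.0),
        st.floats(min_value=0.05, max_value=0.3),
        st.floats(min_value=100.0, max_value=2000.0),
        st.floats(min_value=1.2, max_value=3.0),
    )
    def test_scaling_laws(self, length, d, hr, e, factor):
        base = segment_elements(length, d, hr, e)
        # R ~ l/d^4, L ~ l/d^2, C ~ l d^3 / (E h) with h ~ d
        bigger = segment_elements(length * factor, d, hr, e)
        assert bigger.R / base.R == pytest.approx(factor, rel=1e-9)
        assert bigger.L / base.L == pytest.approx(factor, rel=1e-9)
        assert bigger.C / base.C == pytest.approx(factor, rel=1e-9)
        wider = segment_elements(length, d * factor, hr, e)
        assert base.R / wider.R == pytest.approx(factor**4, rel=1e-9)
        assert base.L / wider.L == pytest.approx(factor**2, rel=1e-9)
        assert wider.C / base.C == pytest.approx(factor**2, rel=1e-9)  # r^3 / h
        stiffer = segment_elements(length, d, hr, e * factor)
        assert base.C / stiffer.C == pytest.approx(factor, rel=1e-9)

    def test_serial_composition_recovers_unsplit_vessel(self):
        # closed forms evaluated for the whole 15 cm vessel at once
        g = _geom(15.0, 3.0)
        r = 1.5e-3
        R = 8 * 3e-3 * 0.15 / (math.pi * r**4)
        L = 1e3 * 0.15 / (math.pi * r**2)
        C = 3 * math.pi * r**3 * 0.15 / (2 * 900e3 * 0.2 * r)
        parts = discretize_vessel(g)
        assert sum(p.R for p in parts) == pytest.approx(R, rel=1e-9)
        assert sum(p.L for p in parts) == pytest.approx(L, rel=1e-9)
        assert sum(p.C for p in parts) == pytest.approx(C, rel=1e-9)

    def test_nonpositive_inputs_rejected(self):
        with pytest.raises(ValidationError):
            segment_elements(5.0, -1.0, 0.15, 700.0)
        with pytest.raises(ValidationError):
            segment_elements(5.0, 4.0, 0.15, 0.0)


class TestAnastomosisLaw:
    elem = make_anastomosis(45.0, venous_limb_area_mm2=7.0, distal_limb_area_mm2=5.0)

    def test_zero_flow_no_loss(self):
        assert anastomosis_pressure_drop(self.elem, 0.0, "venous") == 0.0

    @pytest.mark.parametrize("q", [0.5, 3.0, 12.0])
    def test_odd_and_quadratic(self, q):
        dp = anastomosis_pressure_drop(self.elem, q, "venous")
        assert anastomosis_pressure_drop(self.elem, -q, "venous") == pytest.approx(-dp)
        assert anastomosis_pressure_drop(self.elem, 2 * q, "venous") \
            == pytest.approx(4 * dp, rel=1e-12)
        assert dp > 0

    def test_linear_in_loss_coefficient(self):
        doubled = make_anastomosis(
            45.0, 7.0, 5.0,
            endpoints={k: (2 * a, 2 * b) for k, (a, b) in DEFAULT_LOSS_ENDPOINTS.items()})
        for limb in ("venous", "distal"):
            assert anastomosis_pressure_drop(doubled, 4.0, limb) == pytest.approx(
                2 * anastomosis_pressure_drop(self.elem, 4.0, limb), rel=1e-12)

    def test_angle_interpolation(self):
        k30, k60 = DEFAULT_LOSS_ENDPOINTS["venous"]
        assert loss_coefficient(30.0, "venous") == k30
        assert loss_coefficient(60.0, "venous") == k60
        assert loss_coefficient(45.0, "venous") == pytest.approx((k30 + k60) / 2)
        # steeper angle -> larger loss
        assert loss_coefficient(60.0, "venous") > loss_coefficient(30.0, "venous")

    def test_hand_calculated_magnitude(self):
        # q = 10 ml/s through 7 mm^2 with K(45) = 4: dp = K rho q^2 / (2 A^2)
        dp_pa = 4.0 * 1e3 * (1e-5) ** 2 / (2 * (7e-6) ** 2)
        assert anastomosis_pressure_drop(self.elem, 10.0, "venous") \
            == pytest.approx(units.pa_to_mmhg(dp_pa), rel=1e-12)


@pytest.fixture(scope="module")
def geoms(patient):
    return assemble_geometries(patient)


class TestBuildDomain:
    def test_preoperative_has_no_anastomosis_and_no_veins(self, geoms, patient):
        net = build_domain("preoperative", patient.side, geoms)
        assert net.anastomosis is None and not net.anastomosis_branches
        assert not (set(net.vessel_branches) & V.VEINS)
        assert net.venous_outflow_node is None

    @pytest.mark.parametrize("cfg,veins", [
        ("RC-AVF", {V.CEPHALIC_DISTAL, V.CEPHALIC_PROXIMAL, V.AXILLARY_SUBCLAVIAN_VEIN}),
        ("BC-AVF", {V.MEDIAN_CUBITAL, V.CEPHALIC_PROXIMAL, V.AXILLARY_SUBCLAVIAN_VEIN}),
        ("BB-AVF", {V.BASILIC, V.AXILLARY_SUBCLAVIAN_VEIN}),
    ])
    def test_configuration_vessel_sets(self, geoms, patient, cfg, veins):
        net = build_domain(cfg, patient.side, geoms)
        assert set(net.vessel_branches) & V.VEINS == veins
        assert net.anastomosis is not None
        assert len(net.anastomosis_branches) == 2
        assert net.venous_outflow_node is not None

    def test_rc_anastomosis_five_cm_proximal_to_wrist(self, geoms, patient):
        net = build_domain("RC-AVF", patient.side, geoms)
        junction = net.anastomosis_branches[0].node_a
        # serial length of radial segments proximal to the junction
        length = 0.0
        for i in net.vessel_branches[V.RADIAL]:
            br = net.branches[i]
            length += br.elements.seg_length_cm
            if br.node_b == junction:
                break
        assert length == pytest.approx(geoms[V.RADIAL].length_cm - 5.0, rel=1e-9)
        assert net.anastomosis.angle_deg == 45.0

    def test_missing_basilic_vein_is_an_incomplete_domain(self, geoms, patient):
        partial = {k: v for k, v in geoms.items() if k != V.BASILIC}
        with pytest.raises(IncompleteDomainError, match="basilic vein"):
            build_domain("BB-AVF", patient.side, partial)

    def test_deterministic_node_numbering(self, geoms, patient):
        a = build_domain("BC-AVF", patient.side, geoms)
        b = build_domain("BC-AVF", patient.side, geoms)
        assert [(br.node_a, br.node_b, br.vessel_id) for br in a.branches] \
            == [(br.node_a, br.node_b, br.vessel_id) for br in b.branches]
        assert a.terminal_nodes == b.terminal_nodes

    def test_required_vessels_cover_the_trajectories(self):
        assert V.CEPHALIC_DISTAL in required_vessels("rc", "left")
        assert V.BASILIC in required_vessels("bb", "left")
        assert V.BASILIC not in required_vessels("rc", "left")

    def test_split_geometry_conserves_length_and_profile(self):
        g = _geom(20.0, 4.0, 2.0)
        prox, dist = split_geometry(g, 12.5)
        assert prox.length_cm + dist.length_cm == pytest.approx(20.0)
        assert float(prox.diameter_at(12.5)) == pytest.approx(float(dist.diameter_at(0.0)))
        assert float(dist.diameter_at(0.0)) == pytest.approx(float(g.diameter_at(12.5)))
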