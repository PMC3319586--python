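"""Diameter interpolation, stiffness inference and windkessel fitting."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from avfplan import units
from avfplan import vessels as V
from avfplan.errors import (
    InconsistentMeasurementsError,
    MissingMeasurementError,
    RigidVesselError,
    UnknownVesselError,
    ValidationError,
)
from avfplan.literature import load_literature_geometry
from avfplan.network import VesselGeometry, build_domain
from avfplan.personalize import (
    ANASTOMOSIS_ANGLE_BOUNDS_DEG,
    DEFAULT_ANASTOMOSIS_ANGLE_DEG,
    assemble_geometries,
    build_patient_model,
    caliber_screen,
    interpolate_diameters,
    personalize_windkessels,
    place_anastomosis,
    scale_aortic_geometry,
    wall_thickness,
    youngs_modulus_from_distensibility,
)
from avfplan.records import PatientRecord
from avfplan.waveforms import Waveform


class TestInterpolation:
    def test_linear_midpoint(self):
        f = interpolate_diameters([(0.0, 3.0), (10.0, 4.0)], 10.0)
        assert float(f(5.0)) == pytest.approx(3.5)

    def test_single_station_is_constant(self):
        f = interpolate_diameters([(5.0, 3.0)], 20.0)
        assert np.allclose(f(np.array([0.0, 7.3, 20.0])), 3.0)

    def test_extrapolation_continues_the_slope(self):
        # slope -0.1 mm/cm from (0, 4), (10, 3); independent least-squares fit
        stations = [(0.0, 4.0), (10.0, 3.0)]
        coef = np.polyfit([p for p, _ in stations], [d for _, d in stations], 1)
        f = interpolate_diameters(stations, 20.0)
        assert float(f(20.0)) == pytest.approx(float(np.polyval(coef, 20.0)))
        assert float(f(20.0)) == pytest.approx(2.0)

    def test_floor_guards_against_aggressive_extrapolation(self):
        f = interpolate_diameters([(0.0, 4.0), (5.0, 1.0)], 20.0)
        assert float(f(20.0)) == pytest.approx(0.5)  # would be negative

    def test_zero_stations_is_a_missing_measurement(self):
        with pytest.raises(MissingMeasurementError, match="radial"):
            interpolate_diameters([], 10.0, vessel_name="radial artery")

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.lists(st.tuples(st.floats(0.0, 20.0), st.floats(1.0, 8.0)),
                    min_size=2, max_size=6, unique_by=lambda s: round(s[0], 6)))
    def test_reproduces_stations_and_is_continuous(self, stations):
        f = interpolate_diameters(stations, 20.0)
        for p, d in stations:
            assert float(f(p)) == pytest.approx(max(d, 0.5), rel=1e-12)
        xs = np.linspace(0.0, 20.0, 400)
        ys = f(xs)
        assert np.all(np.abs(np.diff(ys)) < 1.0)  # no jumps on a fine grid


class TestWallThickness:
    @pytest.mark.parametrize("vessel,r,expected", [
        (V.AXILLARY_BRACHIAL, 2.0, 0.30),   # 15 %
        (V.RADIAL, 1.5, 0.30),              # 20 %
        (V.CEPHALIC_DISTAL, 2.0, 0.20),     # veins 10 %
    ])
    def test_ratio_rules(self, vessel, r, expected):
        assert wall_thickness(vessel, r) == pytest.approx(expected)

    def test_homogeneous_of_degree_one(self):
        for vessel in (V.RADIAL, V.BASILIC, V.ASCENDING_AORTA):
            assert wall_thickness(vessel, 3.0) == pytest.approx(
                3.0 * wall_thickness(vessel, 1.0))

    def test_unknown_vessel_rejected(self):
        with pytest.raises(UnknownVesselError):
            wall_thickness("femoral", 2.0)


class TestYoungsModulus:
    @staticmethod
    def _waveforms(dist_per_pa, d_dias=4.0, pp_mmhg=50.0):
        t = np.linspace(0.0, 1.0, 101)
        p = 70.0 + pp_mmhg * np.sin(np.pi * t) ** 2
        dp_pa = (p - p.min()) * units.MMHG_PA
        d = d_dias * np.sqrt(1 + dist_per_pa * dp_pa)
        return Waveform(t, d), Waveform(t, p)

    def test_recovers_prescribed_distensibility(self):
        d_true = 2.5e-5  # 1/Pa
        dist_wf, p_wf = self._waveforms(d_true)
        e_kpa = youngs_modulus_from_distensibility(dist_wf, p_wf, h_over_r=0.15)
        assert e_kpa == pytest.approx(3.0 / (2 * d_true * 0.15) / 1e3, rel=1e-6)

    def test_monotone_decreasing_in_distension(self):
        e_small = youngs_modulus_from_distensibility(*self._waveforms(1e-5))
        e_large = youngs_modulus_from_distensibility(*self._waveforms(4e-5))
        assert e_large < e_small

    def test_rigid_vessel_raises(self):
        t = np.linspace(0.0, 1.0, 11)
        flat = Waveform(t, np.full(11, 4.0))
        p = Waveform(t, 70 + 40 * np.sin(np.pi * t) ** 2)
        with pytest.raises(RigidVesselError):
            youngs_modulus_from_distensibility(flat, p)

    def test_single_modulus_for_all_arm_arteries(self, patient):
        geoms = assemble_geometries(patient)
        e_values = {geoms[v].youngs_modulus_kpa for v in V.ARM_ARTERIES}
        assert len(e_values) == 1  # the brachial estimate is applied arm-wide


class TestWindkessels:
    def test_ohmic_total_resistance_with_negligible_upstream(self, patient):
        # huge vessels -> negligible serial resistance; radial measures
        # 60 ml/min = 1 ml/s, MAP 100, venous 10 -> Z + R = 90 mmHg.s/ml
        record = patient
        geoms = assemble_geometries(record)
        fat = {vid: VesselGeometry(vessel_id=vid, length_cm=g.length_cm,
                                   diameter_profile=((0.0, 40.0),),
                                   wall_thickness_ratio=g.wall_thickness_ratio,
                                   youngs_modulus_kpa=g.youngs_modulus_kpa,
                                   is_vein=g.is_vein)
               for vid, g in geoms.items()}
        net = build_domain("preoperative", record.side, fat)
        flows = {"aorta": 6000.0, "brachial": 150.0, "radial": 60.0, "ulnar": 60.0}
        terms = personalize_windkessels(net, 100.0, flows, 10.0)
        total = units.r_si_to_clinical(terms[V.RADIAL].Z_wk + terms[V.RADIAL].R_wk)
        assert total == pytest.approx(90.0, rel=1e-3)
        # fixed split and time constant conventions
        assert terms[V.RADIAL].Z_wk / (terms[V.RADIAL].Z_wk + terms[V.RADIAL].R_wk) \
            == pytest.approx(0.10)
        assert terms[V.RADIAL].R_wk * terms[V.RADIAL].C_wk == pytest.approx(1.5)

    def test_terminal_flows_conserve_the_measured_splits(self, patient):
        geoms = assemble_geometries(patient)
        net = build_domain("preoperative", patient.side, geoms)
        from avfplan.personalize import _terminal_target_flows
        targets = _terminal_target_flows(net, patient.mean_flows_ml_min)
        q = patient.mean_flows_ml_min
        total = units.m3_per_s_to_ml_per_min(sum(targets.values()))
        assert total == pytest.approx(q["aorta"], rel=1e-9)
        arm = units.m3_per_s_to_ml_per_min(
            targets[V.RADIAL] + targets[V.ULNAR_DISTAL] + targets[V.INTEROSSEUS])
        assert arm == pytest.approx(q["brachial"], rel=1e-9)

    def test_inconsistent_measurements_rejected(self, patient):
        geoms = assemble_geometries(patient)
        net = build_domain("preoperative", patient.side, geoms)
        q = dict(patient.mean_flows_ml_min)
        q["radial"] = q["brachial"] - q["ulnar"]  # leaves nothing for interosseus
        with pytest.raises(InconsistentMeasurementsError):
            personalize_windkessels(net, patient.map_pressure_mmhg, q, 10.0)


class TestGeometryAssembly:
    def test_aortic_scaling_identity_and_multiplicativity(self):
        lit = load_literature_geometry()
        base = scale_aortic_geometry(lit, lit[V.LEFT_SUBCLAVIAN].diameter_mm)
        assert float(base[V.ASCENDING_AORTA].diameter_at(0.0)) \
            == pytest.approx(lit[V.ASCENDING_AORTA].diameter_mm)
        scaled = scale_aortic_geometry(lit, 1.1 * lit[V.LEFT_SUBCLAVIAN].diameter_mm)
        for vid in base:
            assert float(scaled[vid].diameter_at(0.0)) == pytest.approx(
                1.1 * float(base[vid].diameter_at(0.0)), rel=1e-12)
            assert scaled[vid].length_cm == base[vid].length_cm

    def test_venous_lengths_match_arterial_level(self):
        lit = load_literature_geometry()
        # the distal cephalic vein runs along the forearm like the radial artery
        assert lit[V.CEPHALIC_DISTAL].length_cm == lit[V.RADIAL].length_cm

    def test_deterministic(self, patient):
        a = assemble_geometries(patient)
        b = assemble_geometries(patient)
        assert a == b


class TestAnastomosisPlacement:
    def test_rc_position_from_the_distal_end(self):
        g = {V.RADIAL: VesselGeometry(vessel_id=V.RADIAL, length_cm=22.0,
                                      diameter_profile=((0.0, 3.0),),
                                      wall_thickness_ratio=0.2,
                                      youngs_modulus_kpa=900.0)}
        p = place_anastomosis("rc", g)
        assert p.position_cm == pytest.approx(17.0)  # 22 - 5
        assert p.angle_deg == DEFAULT_ANASTOMOSIS_ANGLE_DEG == 45.0
        assert ANASTOMOSIS_ANGLE_BOUNDS_DEG == (30.0, 60.0)

    def test_short_vessel_rejected(self):
        g = {V.RADIAL: VesselGeometry(vessel_id=V.RADIAL, length_cm=4.0,
                                      diameter_profile=((0.0, 3.0),),
                                      wall_thickness_ratio=0.2,
                                      youngs_modulus_kpa=900.0)}
        with pytest.raises(ValidationError):
            place_anastomosis("rc", g)


class TestCaliberScreen:
    def _record(self, patient, updates):
        return patient.with_diameters(updates)

    def test_two_mm_rule(self, patient):
        rec = patient.with_diameters({
            (V.CEPHALIC_DISTAL, 0.0): 2.5, (V.CEPHALIC_DISTAL, 11.75): 2.2,
            (V.CEPHALIC_DISTAL, 23.5): 2.2,
            (V.RADIAL, 0.0): 2.4, (V.RADIAL, 11.75): 2.4, (V.RADIAL, 23.5): 1.8,
        })
        screen = caliber_screen(rec)
        assert screen[V.CEPHALIC_DISTAL] == "adequate"
        assert screen[V.RADIAL] == "inadequate"  # minimum 1.8 governs

    def test_exactly_two_mm_is_inadequate(self, patient):
        rec = patient.with_diameters({(V.RADIAL, 0.0): 2.0, (V.RADIAL, 11.75): 2.0,
                                      (V.RADIAL, 23.5): 2.0})
        assert caliber_screen(rec)[V.RADIAL] == "inadequate"
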