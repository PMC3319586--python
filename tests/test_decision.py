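"""The clinical decision rule and measurement-comparison utilities."""

import itertools

import numpy as np
import pytest

from avfplan.decision import (
    FLOW_WINDOW_ML_MIN,
    PREFERENCE_ORDER,
    assess_configuration,
    cardiac_steal_flag,
    dus_measured_flow_interval,
    maturation_projection,
    prediction_overlap,
    recommend,
)
from avfplan.uncertainty import FlowDistribution
from avfplan.waveforms import Waveform


def _dist(cfg, median):
    if median is None:  # unsimulable
        return FlowDistribution.from_flows(cfg, [np.nan, np.nan], 0)
    return FlowDistribution.from_flows(
        cfg, [median - 50.0, median, median + 50.0], 0)


STATUS_MEDIAN = {"eligible": 800.0, "low": 300.0, "high": 1600.0,
                 "unsimulable": None}


class TestAssessment:
    def test_window_membership(self):
        assert assess_configuration(_dist("RC-AVF", 800.0)).eligible
        a_low = assess_configuration(_dist("RC-AVF", 300.0))
        assert not a_low.eligible and a_low.risk_flags["low_flow"] and a_low.reasons
        a_high = assess_configuration(_dist("BB-AVF", 1600.0))
        assert not a_high.eligible and a_high.risk_flags["high_flow"]

    @pytest.mark.parametrize("median,eligible", [
        (400.0, True), (1500.0, True), (399.9, False), (1500.1, False)])
    def test_inclusive_bounds(self, median, eligible):
        assert assess_configuration(_dist("RC-AVF", median)).eligible is eligible

    def test_unsimulable_is_not_assessable(self):
        a = assess_configuration(_dist("RC-AVF", None), configuration="RC-AVF")
        assert not a.assessable and not a.eligible and a.reasons

    def test_widening_the_window_never_removes_eligibility(self):
        for med in (350.0, 500.0, 1400.0, 1550.0):
            narrow = assess_configuration(_dist("RC-AVF", med), (400.0, 1500.0))
            wide = assess_configuration(_dist("RC-AVF", med), (300.0, 1700.0))
            if narrow.eligible:
                assert wide.eligible


class TestRecommend:
    def test_most_distal_preference_examples(self):
        cases = {
            (500.0, 900.0, 1000.0): "RC-AVF",
            (300.0, 900.0, 1000.0): "BC-AVF",
            (300.0, 1600.0, 1700.0): None,
        }
        for medians, expected in cases.items():
            assessments = [assess_configuration(_dist(c, m))
                           for c, m in zip(PREFERENCE_ORDER, medians)]
            assert recommend(assessments).selected == expected

    def test_agrees_with_brute_force_enumeration(self):
        # all 4^3 = 64 status patterns vs an independent first-match oracle
        for statuses in itertools.product(STATUS_MEDIAN, repeat=3):
            assessments = [
                assess_configuration(_dist(cfg, STATUS_MEDIAN[s]), configuration=cfg)
                for cfg, s in zip(PREFERENCE_ORDER, statuses)]
            expected = next(
                (cfg for cfg, s in zip(PREFERENCE_ORDER, statuses) if s == "eligible"),
                None)
            rec = recommend(assessments)
            assert rec.selected == expected, statuses
            # ineligible candidates always carry a reason
            for a in rec.candidates:
                if not a.eligible:
                    assert a.reasons

    def test_missing_configurations_are_skipped_with_annotation(self):
        only_bb = [assess_configuration(_dist("BB-AVF", 900.0))]
        rec = recommend(only_bb)
        assert rec.selected == "BB-AVF"
        assert rec.candidates[0].reasons == ["not simulated"]

    def test_all_low_flow_selects_none(self):
        # the early-failure scenario: every configuration below the floor
        assessments = [assess_configuration(_dist(c, 250.0))
                       for c in PREFERENCE_ORDER]
        rec = recommend(assessments)
        assert rec.selected is None
        assert all(a.risk_flags["low_flow"] for a in rec.candidates)

    def test_surgeon_agreement_field(self):
        assessments = [assess_configuration(_dist("RC-AVF", 500.0))]
        rec = recommend(assessments).with_surgeon_choice("rc")
        assert rec.agreement is True
        rec = recommend(assessments).with_surgeon_choice("bb")
        assert rec.agreement is False


class TestRiskAndProjection:
    @pytest.mark.parametrize("flow,co,expected", [
        (1600.0, 5000.0, True),   # 32 %
        (1500.0, 5000.0, False),  # exactly 30 %, strict
        (0.0, 5000.0, False),
    ])
    def test_cardiac_steal_flag(self, flow, co, expected):
        assert cardiac_steal_flag(flow, co) is expected

    @pytest.mark.parametrize("cfg,flow,expected", [
        ("rc", 420.0, (600.0, 700.0)),
        ("bc", 900.0, (900.0, 1000.0)),
        ("bb", 0.0, (0.0, 0.0)),
    ])
    def test_maturation_projection(self, cfg, flow, expected):
        assert maturation_projection(flow, cfg) == pytest.approx(expected)


class TestDusQuantification:
    def test_constant_envelope_worked_example(self):
        t = np.linspace(0.0, 1.0, 11)
        env = Waveform(t, np.full(11, 50.0))  # cm/s
        low, high, raw = dus_measured_flow_interval(env, 20.0)
        assert raw == pytest.approx(600.0)
        assert (low, high) == (pytest.approx(300.0), pytest.approx(600.0))

    def test_zero_envelope(self):
        t = np.linspace(0.0, 1.0, 11)
        low, high, raw = dus_measured_flow_interval(Waveform(t, np.zeros(11)), 20.0)
        assert (low, high, raw) == (0.0, 0.0, 0.0)

    def test_linear_in_area_and_envelope(self):
        t = np.linspace(0.0, 1.0, 51)
        env = Waveform(t, 30.0 + 20.0 * np.sin(2 * np.pi * t) ** 2)
        _, _, raw = dus_measured_flow_interval(env, 15.0)
        _, _, raw2 = dus_measured_flow_interval(env, 30.0)
        _, _, raw3 = dus_measured_flow_interval(env.scaled(3.0), 15.0)
        assert raw2 == pytest.approx(2 * raw, rel=1e-12)
        assert raw3 == pytest.approx(3 * raw, rel=1e-12)


class TestOverlap:
    def test_interval_intersection(self):
        pred = FlowDistribution("RC-AVF", np.array([600.0]), 1, 1,
                                median=600.0, p25=500.0, p75=700.0, seed=0)
        assert prediction_overlap(pred, (650.0, 900.0)) == "overlap"
        assert prediction_overlap(pred, (800.0, 1000.0)) == "no_overlap"
        # closed intervals: touching endpoints overlap
        assert prediction_overlap(pred, (700.0, 900.0)) == "overlap"
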