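"""Metric extraction, stroke work, percent-change pooling, validity rule."""

import numpy as np
import pandas as pd
import pytest

from hfpefsim.analysis import (HemodynamicSummary, PVLoop, beat_metrics,
                               loop_area, percent_changes, pv_loop,
                               rv_stroke_work, validity_check)
from hfpefsim.calibration import (HemodynamicTargets, LITERATURE_TARGETS,
                                  MetricTarget)
from hfpefsim.network import PeriodicSolution, RECORD_COLUMNS, SolverSettings
from hfpefsim.baroreflex import group_baroreflex
from hfpefsim.devices import no_device
from hfpefsim.parameters import group_preset


class TestStrokeWork:
    def test_rectangle_area(self):
        v = np.array([10.0, 60.0, 60.0, 10.0, 10.0])
        p = np.array([5.0, 5.0, 30.0, 30.0, 5.0])
        loop = PVLoop(v, p, "rv")
        assert rv_stroke_work(loop) == pytest.approx(1250.0)

    def test_orientation_independent(self):
        v = np.array([10.0, 60.0, 60.0, 10.0, 10.0])
        p = np.array([5.0, 5.0, 30.0, 30.0, 5.0])
        fwd = rv_stroke_work(PVLoop(v, p, "rv"))
        rev = rv_stroke_work(PVLoop(v[::-1].copy(), p[::-1].copy(), "rv"))
        assert rev == pytest.approx(fwd)

    def test_ellipse_matches_analytic_area(self):
        # shoelace vs the closed form pi*a*b for an elliptical loop
        theta = np.linspace(0.0, 2 * np.pi, 720, endpoint=False)
        a, b = 25.0, 12.0
        loop = PVLoop(60.0 + a * np.cos(theta), 20.0 + b * np.sin(theta), "rv")
        assert loop_area(loop) == pytest.approx(np.pi * a * b, rel=0.005)

    def test_open_loop_rejected(self):
        v = np.linspace(10.0, 60.0, 50)
        p = np.linspace(5.0, 30.0, 50)
        with pytest.raises(ValueError):
            rv_stroke_work(PVLoop(v, p, "rv"))

    def test_degenerate_loop_rejected(self):
        with pytest.raises(ValueError):
            PVLoop(np.array([1.0, 2.0]), np.array([1.0, 2.0]), "rv")


def _synthetic_solution(n=800, v_lv=100.0):
    """A flat one-beat recording (constant volumes, zero flows)."""
    data = pd.DataFrame(0.0, index=range(n), columns=list(RECORD_COLUMNS))
    data["time"] = np.arange(n) * 1e-3
    data["cycle_time"] = np.arange(n) * 1e-3
    data["period"] = n * 1e-3
    data["v_lv"] = v_lv
    data["v_rv"] = 120.0
    data["p_rv"] = 10.0
    data["p_ao"] = 90.0
    return PeriodicSolution(
        data=data, beats=pd.DataFrame(), converged=True, n_beats_run=1,
        params=group_preset(1), baro=group_baroreflex(1), device=no_device(),
        settings=SolverSettings())


class TestBeatMetrics:
    def test_constant_volume_input_gives_zero_ef_and_co(self):
        m = beat_metrics(_synthetic_solution())
        assert m.ef == pytest.approx(0.0)
        assert m.co == pytest.approx(0.0)

    def test_ef_identity_and_co_crosscheck(self, sol_g1_rest):
        m = beat_metrics(sol_g1_rest)
        assert m.ef == pytest.approx(100.0 * (m.edv - m.esv) / m.edv, abs=0.1)
        # systemic output equals HR x LV stroke volume on a device-free loop
        assert m.co == pytest.approx(m.hr * (m.edv - m.esv) * 1e-3, rel=0.02)

    def test_pv_loop_extraction(self, sol_g1_rest):
        loop = pv_loop(sol_g1_rest, "rv")
        assert loop.is_closed()
        assert rv_stroke_work(loop) > 0.0


class TestPercentChanges:
    @staticmethod
    def _summary(**overrides):
        base = dict(edv=100.0, esv=40.0, ef=60.0, map=90.0, hr=75.0, rap=6.0,
                    pap=25.0, lap=15.0, co=4.5, rvsw=500.0)
        base.update(overrides)
        return HemodynamicSummary(**base)

    def test_identity_against_itself_is_zero(self):
        base = {(1, "rest"): self._summary()}
        devs = {(1, "rest", "iasd"): self._summary()}
        panel = percent_changes(devs, base)
        mean, sd, n = panel.pool("lap", "iasd")
        assert mean == 0.0 and sd == 0.0 and n == 1

    def test_matches_hand_computed_mean_and_sd(self):
        base = {(g, c): self._summary() for g in (1, 2)
                for c in ("rest", "exercise")}
        laps = [12.0, 13.5, 10.5, 9.0]  # vs baseline 15 -> -20, -10, -30, -40 %
        devs = {}
        for (g, c), lap in zip(base, laps):
            devs[(g, c, "iasd")] = self._summary(lap=lap)
        panel = percent_changes(devs, base)
        mean, sd, n = panel.pool("lap", "iasd")
        expect = [-20.0, -10.0, -30.0, -40.0]
        assert mean == pytest.approx(np.mean(expect))
        assert sd == pytest.approx(np.std(expect, ddof=1))
        assert n == 4

    def test_missing_baseline_rejected(self):
        devs = {(1, "rest", "iasd"): self._summary()}
        with pytest.raises(KeyError):
            percent_changes(devs, {})


class TestValidityRule:
    def test_literature_panel_examples(self):
        targets = LITERATURE_TARGETS[(1, "rest")]
        summary = TestPercentChanges._summary(co=4.5)
        flags = validity_check(summary, targets)
        assert flags["co"] is True  # 4.5 within 4.4 +/- 1.65

    def test_exercise_iqr_containment(self):
        targets = LITERATURE_TARGETS[(1, "exercise")]
        summary = TestPercentChanges._summary(rap=17.3)
        flags = validity_check(summary, targets)
        assert flags["rap"] is True       # 17.3 inside (10, 19)
        assert flags["edv"] is None       # not reported for this panel

    def test_boundaries_are_closed(self):
        targets = HemodynamicTargets(metrics={
            "co": MetricTarget(4.4, "sd", sd=1.1),
            "lap": MetricTarget(15.0, "iqr", iqr=(11.0, 20.0)),
        })
        on_iqr_bound = TestPercentChanges._summary(lap=20.0, co=4.4 + 1.65)
        flags = validity_check(on_iqr_bound, targets)
        assert flags["lap"] is True
        assert flags["co"] is True
        outside = TestPercentChanges._summary(lap=20.01, co=4.4 + 1.66)
        flags = validity_check(outside, targets)
        assert flags["lap"] is False
        assert flags["co"] is False
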