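"""Closed-loop heart and circulation backbone tests."""

import numpy as np
import pytest

from myoloop import HeartModel


class TestStep:
    def test_rejects_oversized_step(self, reference_clone):
        with pytest.raises(ValueError, match="2 ms"):
            reference_clone.step(dt=0.004)

    def test_two_half_steps_match_full_step(self, reference_clone):
        a = reference_clone
        b = reference_clone.clone()
        a.step(0.002)
        b.step(0.001)
        b.step(0.001)
        # volumes agree within the local-error budget
        assert np.allclose(a.y[:8], b.y[:8], atol=0.05)

    def test_blood_volume_conserved_without_regulation(self, reference_clone):
        m = reference_clone
        m.regulation_enabled = False
        v0 = m.total_blood_volume()
        m.run_beat(record=False)
        assert abs(m.total_blood_volume() - v0) / v0 < 1e-6

    def test_volume_conserved_over_ten_beats(self, reference_clone):
        m = reference_clone
        m.regulation_enabled = False
        v0 = m.total_blood_volume()
        for _ in range(10):
            m.run_beat(record=False)
        assert abs(m.total_blood_volume() - v0) / v0 < 1e-5


class TestSteadyState:
    def test_reference_hits_regulation_targets(self, steady_reference):
        model, beat = steady_reference
        assert beat.MAP == pytest.approx(model.map_target, abs=0.5)
        assert beat.stroke_volume == pytest.approx(model.sv_target, abs=0.5)

    def test_beat_to_beat_convergence(self, steady_reference):
        model, beat = steady_reference
        nxt = model.clone().run_beat(record=True)
        assert abs(nxt.EDV - beat.EDV) < 0.1

    def test_restart_from_converged_state(self, reference_clone):
        # a converged model is a fixed point: re-convergence is immediate
        beat = reference_clone.run_to_steady_state(beats_max=6)
        assert beat is not None

    def test_ef_consistent_with_stroke_volume(self, steady_reference):
        _, beat = steady_reference
        assert beat.EF == pytest.approx(
            100.0 * beat.stroke_volume / beat.EDV, abs=1.5)

    def test_pv_loop_traversed_counterclockwise(self, steady_reference):
        # signed area of the (V, p) loop is positive for a working ventricle
        _, beat = steady_reference
        v = beat.V_LV
        p = beat.p_LV
        area = np.trapezoid(p, v) - 0.5 * (p[0] + p[-1]) * (v[-1] - v[0])
        assert -area > 2000.0   # mmHg*ml of stroke work, CCW in (V, p)

    def test_physiological_pressures(self, steady_reference):
        _, beat = steady_reference
        assert 90.0 < beat.peak_p_LV < 140.0
        assert beat.p_LV.min() < 15.0


class TestRegulation:
    def test_at_target_no_drift(self, reference_clone):
        m = reference_clone
        r0 = m.r_art
        m.run_beat(record=True)
        assert m.r_art == pytest.approx(r0, rel=5e-3)

    def test_higher_map_target_raises_resistance(self, reference_clone):
        m = reference_clone
        m.map_target += 15.0
        m.run_to_steady_state(beats_max=150)
        assert m.r_art > reference_clone.gp[2] * 0.99  # grew toward target
        hi = HeartModel({"regulation": {"map": 107.0}})
        lo = HeartModel({"regulation": {"map": 82.0}})
        hi.run_to_steady_state(beats_max=150)
        lo.run_to_steady_state(beats_max=150)
        assert hi.r_art > lo.r_art

    def test_disabled_regulation_freezes_volume(self, reference_clone):
        m = reference_clone
        m.regulation_enabled = False
        m.set_afterload(1.2)
        v0 = m.total_blood_volume()
        m.run_beat(record=False)
        assert abs(m.total_blood_volume() - v0) / v0 < 1e-6


class TestAfterload:
    def test_requires_regulation_off(self, reference_clone):
        with pytest.raises(RuntimeError, match="regulation"):
            reference_clone.set_afterload(1.2)

    def test_identity_and_inverse(self, reference_clone):
        m = reference_clone
        m.regulation_enabled = False
        r0 = m.r_art
        m.set_afterload(1.0)
        assert m.r_art == r0
        m.set_afterload(1.2)
        m.set_afterload(1 / 1.2)
        assert m.r_art == pytest.approx(r0, rel=1e-12)

    def test_higher_afterload_raises_end_systolic_pressure(
            self, reference_clone):
        lo = reference_clone
        hi = reference_clone.clone()
        lo.regulation_enabled = False
        hi.regulation_enabled = False
        hi.set_afterload(1.2)
        b_lo = lo.run_to_steady_state(beats_max=80)
        b_hi = hi.run_to_steady_state(beats_max=80)
        k_lo = b_lo.aortic_valve_close_index()
        k_hi = b_hi.aortic_valve_close_index()
        assert b_hi.p_LV[k_hi] > b_lo.p_LV[k_lo]


class TestMultiPatchDegeneracy:
    def test_subdividing_walls_leaves_hemodynamics_unchanged(self):
        """N identical patches behave exactly like one patch per wall."""
        single = HeartModel()
        split = HeartModel({"walls": {
            "lv": {"patches": [{"share": 0.25}] * 4},
            "sw": {"patches": [{"share": 0.5}, {"share": 0.5}]}}})
        b1 = single.run_to_steady_state(beats_max=150)
        b2 = split.run_to_steady_state(beats_max=150)
        assert abs(b1.EDV - b2.EDV) < 0.2
        assert np.max(np.abs(b1.p_LV - b2.p_LV)) < 0.2

    def test_one_fiber_zero_stress_zero_pressure(self):
        # with no activation and volumes at the stress-free geometry the
        # transmural pressures stay near zero
        m = HeartModel({"sarcomere": {"Sf_act": 0.0},
                        "atrial_sarcomere": {"Sf_act": 0.0}})
        beat = m.clone()
        m.regulation_enabled = False
        rec = m.run_beat(record=True)
        # passive heart: no ejection, LV pressure stays low
        assert rec.p_LV.max() < 30.0


class TestValidation:
    @pytest.mark.parametrize("cfg", [
        {"heart_rate": -10.0},
        {"solver": {"dt": 0.01}},
        {"walls": {"lv": {"patches": [{"share": 1.0, "ncvf": 1.5}]}}},
    ])
    def test_invalid_configs_rejected(self, cfg):
        with pytest.raises(ValueError):
            HeartModel(cfg)
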