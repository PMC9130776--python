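"""Strain analysis and ESPVR extraction tests."""

import numpy as np
import pytest

from myoloop.strain import (ESPVRResult, StrainTrace, beat_strain,
                            detect_end_systole, engineering_strain,
                            fit_espvr, map_segment_length, strain_rate)


class TestEngineeringStrain:
    def test_zero_at_reference(self):
        assert engineering_strain(2.0, 2.0) == 0.0

    def test_arithmetic(self):
        assert engineering_strain(2.2, 2.0) == pytest.approx(10.0, rel=1e-12)
        expect = (2.2 / 2.0 - 1.0) * 100.0   # brute force
        assert engineering_strain(2.2, 2.0) == pytest.approx(expect,
                                                             rel=1e-12)

    def test_invalid_reference(self):
        with pytest.raises(ValueError):
            engineering_strain(2.0, 0.0)

    def test_roundtrip_with_length_map_is_identity(self):
        Ls = np.linspace(1.8, 2.3, 40)
        SL = map_segment_length(Ls, 2.2, 19.8)
        back = SL * (2.2 / 19.8)
        assert np.allclose(back, Ls, rtol=1e-14)


class TestStrainRate:
    def test_constant_strain_gives_zero(self):
        sr = strain_rate(np.full(50, -5.0), dt=0.002)
        assert np.allclose(sr, 0.0)
        assert sr.size == 49

    def test_linear_ramp(self):
        t = np.linspace(0.0, 0.2, 101)
        eps = -20.0 * t / 0.2
        sr = strain_rate(eps, time=t)
        assert np.allclose(sr, -100.0, rtol=1e-9)

    def test_smooth_signal_consistent_across_sampling(self):
        t1 = np.linspace(0, 1, 501)
        t2 = t1[::2]
        f = lambda t: -18.0 * np.sin(np.pi * t) ** 2
        sr1 = strain_rate(f(t1), time=t1)
        sr2 = strain_rate(f(t2), time=t2)
        # compare on the coarse midpoints
        mid1 = 0.5 * (t1[:-1] + t1[1:])
        mid2 = 0.5 * (t2[:-1] + t2[1:])
        interp = np.interp(mid2, mid1, sr1)
        assert np.max(np.abs(interp - sr2)) < 0.5

    def test_too_few_samples(self):
        with pytest.raises(ValueError):
            strain_rate([1.0], dt=0.002)

    def test_nonuniform_grid_rejected(self):
        with pytest.raises(ValueError, match="uniform"):
            strain_rate([0.0, 1.0, 2.0], time=[0.0, 0.1, 0.35])


class TestSegmentLengthMap:
    def test_calibration_point(self):
        assert map_segment_length(2.2, 2.2, 19.8) == pytest.approx(19.8)

    def test_linearity(self):
        assert map_segment_length(1.1, 2.2, 19.8) == pytest.approx(9.9)

    def test_arithmetic(self):
        assert map_segment_length(2.0, 2.2, 19.8) == pytest.approx(
            18.0, rel=1e-12)

    def test_invalid_calibration(self):
        with pytest.raises(ValueError):
            map_segment_length(2.0, 0.0, 19.8)


class TestStrainTrace:
    def test_requires_increasing_time(self):
        with pytest.raises(ValueError):
            StrainTrace(time=[0.0, 0.1, 0.1], strain=[0.0, 1.0, 2.0])


class TestFitESPVR:
    def test_two_point_line(self):
        res = fit_espvr([(50.0, 0.0), (100.0, 100.0)])
        assert res.Emax == pytest.approx(2.0, rel=1e-12)
        assert res.V0 == pytest.approx(50.0, rel=1e-12)
        assert res.residual == pytest.approx(0.0, abs=1e-9)

    def test_collinear_triple_zero_residual(self):
        pts = [(60.0, 20.0), (80.0, 60.0), (100.0, 100.0)]
        res = fit_espvr(pts)
        assert res.residual == pytest.approx(0.0, abs=1e-9)
        assert res.Emax == pytest.approx(2.0, rel=1e-12)

    def test_identical_volumes_rejected(self):
        with pytest.raises(ValueError):
            fit_espvr([(80.0, 90.0), (80.0, 110.0)])

    def test_matches_brute_force_grid_minimizer(self):
        rng = np.random.default_rng(42)
        v = np.array([60.0, 75.0, 90.0])
        p = 1.8 * (v - 15.0) + rng.normal(0, 3.0, 3)
        res = fit_espvr(np.c_[v, p])
        # dense grid search over (slope, intercept)
        slopes = np.linspace(0.5, 4.0, 701)
        inters = np.linspace(-120.0, 60.0, 721)
        S, I = np.meshgrid(slopes, inters, indexing="ij")
        sse = sum((S * (vk - 0.0) + I * 1.0 - pk) ** 2
                  for vk, pk in zip(v - 0.0, p))
        k = np.unravel_index(np.argmin(sse), sse.shape)
        emax_bf = S[k]
        v0_bf = -I[k] / emax_bf
        assert res.Emax == pytest.approx(emax_bf, abs=0.01)
        assert res.V0 == pytest.approx(v0_bf, abs=1.0)


class TestEndSystole:
    def test_valve_closure_detected(self, steady_reference):
        _, beat = steady_reference
        k = detect_end_systole(beat, method="valve")
        assert beat.q_Ao[k] <= 1e-9
        assert beat.q_Ao[k - 2] > 0.0

    def test_methods_agree_roughly(self, steady_reference):
        _, beat = steady_reference
        kv = detect_end_systole(beat, method="valve")
        ke = detect_end_systole(beat, method="elastance", v0_guess=28.0)
        dt = beat.t[1] - beat.t[0]
        assert abs(beat.t[kv] - beat.t[ke]) < 30 * dt

    def test_unknown_method(self, steady_reference):
        _, beat = steady_reference
        with pytest.raises(ValueError):
            detect_end_systole(beat, method="nope")


class TestBeatStrain:
    def test_reference_sample_is_zero(self, steady_reference):
        _, beat = steady_reference
        tr = beat_strain(beat, 0, reference="onset")
        assert tr.strain[beat.act_index] == 0.0

    def test_ed_reference_zero_at_max_volume(self, steady_reference):
        _, beat = steady_reference
        tr = beat_strain(beat, 0, reference="ed")
        k = int(np.argmax(beat.V_LV))
        assert tr.strain[k] == pytest.approx(0.0, abs=1e-12)

    def test_healthy_patch_shortens(self, steady_reference):
        _, beat = steady_reference
        tr = beat_strain(beat, 0)
        assert tr.strain.min() < -10.0
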