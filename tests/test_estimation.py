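"""Estimation pipeline tests: objective, cutoff, selection, MSPSO."""

import numpy as np
import pytest

from myoloop.estimation import (MCResults, N_DIM, N_SEG, ParameterBounds,
                                ParameterVector, SegmentDataset, Uncertainty,
                                early_diastolic_cutoff, mspso, objective,
                                segmental_error, select_candidates)
from myoloop.segments import SEGMENTS_18


def _dataset(strain_fn, n=421, hr=71.0, edv=140.0, ef=55.0):
    t = np.arange(n) * 0.002
    tc = 60.0 / hr
    eps = np.empty((n, N_SEG))
    for j in range(N_SEG):
        eps[:, j] = strain_fn(t, j)
    return SegmentDataset(time=t, strain=eps, heart_rate=hr, edv=edv, ef=ef)


def _healthy(t, j, amp=-18.0):
    tc = 60.0 / 71.0
    return amp * np.sin(np.clip(t / (0.75 * tc), 0, 1) * np.pi) ** 2


class TestCutoff:
    def test_triangular_trace_arithmetic(self):
        # peak -20% at 0.4 s, linear return to 0 at 0.8 s, cycle 1.0 s:
        # 10% re-lengthening (-18%) at 0.44 s -> cutoff at 0.54 s
        t = np.round(np.arange(0, 1.0, 0.002), 10)
        gls = np.where(t <= 0.4, -50.0 * t, np.minimum(-20.0 + 50.0 *
                                                       (t - 0.4), 0.0))
        k = early_diastolic_cutoff(gls, t, 1.0)
        assert t[k] == pytest.approx(0.54, abs=0.003)

    def test_monotone_trace_falls_back_to_end(self):
        t = np.arange(0, 1.0, 0.002)
        gls = -20.0 * t
        k = early_diastolic_cutoff(gls, t, 1.0)
        assert k == t.size - 1

    def test_invariant_to_amplitude_scaling(self):
        t = np.arange(0, 0.9, 0.002)
        gls = -15.0 * np.sin(np.pi * t / 0.9) ** 2
        k1 = early_diastolic_cutoff(gls, t, 0.9)
        k2 = early_diastolic_cutoff(3.7 * gls, t, 0.9)
        assert k1 == k2


class TestObjective:
    def test_identical_datasets_cost_zero(self):
        d = _dataset(_healthy)
        assert objective(d, d) == pytest.approx(0.0, abs=1e-12)

    def test_missing_component_is_error(self):
        d = _dataset(_healthy)
        with pytest.raises(ValueError):
            objective(None, d)

    def test_cost_invariant_to_sample_duplication(self):
        """Per-time-point correction: densifying the grid leaves cost flat."""
        d1 = _dataset(_healthy, n=301)
        d2 = _dataset(_healthy, n=601)
        # perturbed simulations on both grids (same smooth disturbance)
        def sim_fn(t, j):
            return _healthy(t, j) + 1.5 * np.sin(2 * np.pi * t)
        s1 = _dataset(sim_fn, n=301)
        s2 = _dataset(sim_fn, n=601)
        c1 = objective(s1, d1)
        c2 = objective(s2, d2)
        assert c1 == pytest.approx(c2, rel=0.05)

    def test_one_uncertainty_unit_of_noise_contributes_about_one(self):
        """White noise at the EDV uncertainty raises that term to ~1."""
        d = _dataset(_healthy)
        rng = np.random.default_rng(0)
        w = Uncertainty()
        costs = []
        for _ in range(200):
            sim = _dataset(_healthy, edv=d.edv + rng.normal(0, w.edv))
            costs.append(objective(sim, d))
        assert np.mean(costs) == pytest.approx(1.0, rel=0.25)

    def test_global_amplitude_scaling_removes_uniform_gain(self):
        d = _dataset(_healthy)
        scaled = _dataset(lambda t, j: 1.3 * _healthy(t, j))
        assert objective(scaled, d) == pytest.approx(0.0, abs=1e-12)


class TestSegmentalError:
    def test_identical_traces_zero(self):
        d = _dataset(_healthy)
        assert segmental_error(d, d, "mid_anterior") == pytest.approx(0.0)

    def test_unknown_segment(self):
        d = _dataset(_healthy)
        with pytest.raises(KeyError):
            segmental_error(d, d, "mid_of_nowhere")

    def test_localized_perturbation_lands_in_that_segment(self):
        d = _dataset(_healthy)
        jmod = SEGMENTS_18.index("apical_anterior")

        def sim_fn(t, j):
            base = _healthy(t, j)
            return base + (4.0 if j == jmod else 0.0)
        sim = _dataset(sim_fn)
        errs = {s: segmental_error(sim, d, s) for s in SEGMENTS_18}
        assert max(errs, key=errs.get) == "apical_anterior"

    def test_quadratic_scaling_with_amplitude(self):
        d = _dataset(_healthy)
        j = 3

        def pert(a):
            sim = _dataset(lambda t, jj: _healthy(t, jj)
                           + (a if jj == j else 0.0))
            # undo the global-amplitude coupling by comparing small a
            return segmental_error(sim, d, SEGMENTS_18[j])
        e1, e2 = pert(0.5), pert(1.0)
        assert e2 / e1 == pytest.approx(4.0, rel=0.2)


class TestSelectCandidates:
    def _mc(self, n=60, seed=0):
        rng = np.random.default_rng(seed)
        b = ParameterBounds()
        params = b.lower() + rng.random((n, N_DIM)) * b.width()
        costs = rng.random(n)
        seg = rng.random((n, N_SEG))
        return MCResults(params=params, costs=costs, seg_errors=seg)

    def test_output_size_is_forty(self):
        out = select_candidates(self._mc(), seed=1)
        assert out.shape == (40, N_DIM)

    def test_first_twenty_are_global_best(self):
        mc = self._mc()
        out = select_candidates(mc, seed=1)
        best = np.argsort(mc.costs)[:20]
        assert np.allclose(out[:20], mc.params[best])

    def test_recombined_segments_come_from_top20_segmental_sets(self):
        mc = self._mc()
        out = select_candidates(mc, seed=1)
        for j in range(N_SEG):
            top = set(np.round(mc.params[np.argsort(mc.seg_errors[:, j])[:20],
                                         j], 12))
            for p in out[20:]:
                assert round(p[j], 12) in top

    def test_exactly_twenty_feasible_uses_all(self):
        mc = self._mc(n=30)
        mc.costs[20:] = np.inf
        out = select_candidates(mc, seed=2)
        assert out.shape[0] == 40

    def test_too_few_feasible_is_error(self):
        mc = self._mc(n=30)
        mc.costs[10:] = np.inf
        with pytest.raises(RuntimeError, match="feasible"):
            select_candidates(mc, seed=0)

    def test_reproducible_given_seed(self):
        mc = self._mc()
        a = select_candidates(mc, seed=5)
        b = select_candidates(mc, seed=5)
        assert np.array_equal(a, b)


class TestMSPSO:
    def test_converges_on_quadratic_surrogate(self):
        """Analytic oracle: minimum of a 2-parameter quadratic bowl."""
        class Bounds2:
            def lower(self):
                return np.array([-2.0, 5.0])

            def upper(self):
                return np.array([3.0, 25.0])

            def width(self):
                return self.upper() - self.lower()

        b = Bounds2()
        lo, wd = b.lower(), b.width()
        target = lo + np.array([0.37, 0.81]) * wd

        def cost(x):
            return float(np.sum(((x - target) / wd) ** 2))
        rng = np.random.default_rng(3)
        particles = lo + rng.random((40, 2)) * wd
        best, f, state, hist, stopped = mspso(cost, particles, b, seed=4,
                                              max_iter=400)
        assert np.max(np.abs(best - target) / wd) < 1e-3
        assert f < 1e-5

    def test_stationary_swarm_stops_on_energy(self):
        b = ParameterBounds()
        x0 = np.tile(b.lower() + 0.5 * b.width(), (40, 1))

        def cost(x):
            return 1.0   # flat landscape, no movement incentive
        best, f, state, hist, stopped = mspso(cost, x0, b, seed=0,
                                              max_iter=50)
        assert stopped == "energy"
        assert state.iteration < 10

    def test_fixed_seed_reproducible(self):
        b = ParameterBounds()
        rng = np.random.default_rng(9)
        particles = b.lower() + rng.random((40, N_DIM)) * b.width()

        def cost(x):
            return float(np.sum(np.sin(x[:5]) ** 2))
        r1 = mspso(cost, particles.copy(), b, seed=7, max_iter=30)
        r2 = mspso(cost, particles.copy(), b, seed=7, max_iter=30)
        assert np.array_equal(r1[0], r2[0])
        assert r1[1] == r2[1]


class TestParameterVector:
    def test_roundtrip(self):
        pv = ParameterVector.reference()
        pv2 = ParameterVector.from_array(pv.to_array())
        assert np.array_equal(pv.ncvf, pv2.ncvf)
        assert pv2.wall_area == pv.wall_area

    def test_wrong_size_rejected(self):
        with pytest.raises(ValueError):
            ParameterVector.from_array(np.zeros(10))
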