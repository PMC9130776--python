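"""Unit tests of the Hill-type sarcomere constitutive law."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from myoloop import (SarcomereParams, SarcomereState, active_stress,
                     contractility, ecm_stress, passive_stress,
                     sarcomere_rate, titin_stress)


@pytest.fixture
def p():
    return SarcomereParams()


class TestActiveStress:
    def test_zero_contractility_gives_zero_stress(self, p):
        st_ = SarcomereState(Ls=2.2, Lsi=2.1, C=0.0)
        assert active_stress(st_, p) == 0.0

    def test_zero_active_stress_length(self, p):
        st_ = SarcomereState(Ls=p.Lsi0_act + p.Lse_iso, Lsi=p.Lsi0_act, C=1.0)
        assert active_stress(st_, p) == pytest.approx(0.0, abs=1e-15)

    def test_direct_evaluation(self):
        # Sf_act * C * (Lsi - Lsi0) * Lse/Lse_iso = 100 * 1 * 0.6 * 1
        p = SarcomereParams(Sf_act=100.0, Lsi0_act=1.51)
        st_ = SarcomereState(Ls=2.11 + p.Lse_iso, Lsi=2.11, C=1.0)
        assert active_stress(st_, p) == pytest.approx(60.0, rel=1e-12)

    def test_negative_series_element_is_an_error(self, p):
        st_ = SarcomereState(Ls=2.0, Lsi=2.1, C=0.5)
        with pytest.raises(ValueError, match="series elastic"):
            active_stress(st_, p)


class TestPassiveStress:
    def test_zero_at_slack_length(self, p):
        assert ecm_stress(p.Ls0_pas, p) == 0.0
        assert titin_stress(p.Ls0_pas, p) == 0.0
        assert passive_stress(p.Ls0_pas, p) == 0.0

    def test_ecm_direct_evaluation(self):
        p = SarcomereParams(Sf_pas=2.0, Ls0_pas=1.75, k_ECM=10.0)
        expect = 2.0 * ((2.0 / 1.75) ** 10 - 1.0)   # independent brute force
        assert ecm_stress(2.0, p) == pytest.approx(expect, rel=1e-12)
        assert ecm_stress(2.0, p) == pytest.approx(5.6021, rel=1e-4)

    def test_titin_direct_evaluation(self):
        p = SarcomereParams(Sf_act=100.0, k1_tit=0.01, k2_tit=2.0,
                            Ls0_pas=1.75)
        expect = 100.0 * 0.01 * ((2.1 / 1.75) ** 2 - 1.0)
        assert titin_stress(2.1, p) == pytest.approx(expect, rel=1e-12)
        assert titin_stress(2.1, p) == pytest.approx(0.44, abs=5e-3)

    def test_titin_vanishes_without_active_scaling(self):
        p = SarcomereParams(Sf_act=0.0)
        for Ls in (1.6, 1.9, 2.3):
            assert titin_stress(Ls, p) == 0.0
            assert passive_stress(Ls, p) == ecm_stress(Ls, p)

    def test_ecm_negative_below_slack(self, p):
        assert ecm_stress(0.9 * p.Ls0_pas, p) < 0.0

    def test_ecm_nonlinearity_monotone_in_exponent(self):
        lo = SarcomereParams(k_ECM=10.0)
        hi = SarcomereParams(k_ECM=20.0)
        assert ecm_stress(2.0, hi) > ecm_stress(2.0, lo)

    def test_sum_decomposition(self, p):
        for Ls in (1.7, 1.9, 2.1, 2.4):
            assert passive_stress(Ls, p) == pytest.approx(
                ecm_stress(Ls, p) + titin_stress(Ls, p), rel=1e-14)

    @given(Ls=st.floats(1.75, 2.6))
    @settings(max_examples=50, deadline=None)
    def test_passive_nondecreasing_above_slack(self, Ls):
        p = SarcomereParams()
        assert passive_stress(Ls + 1e-4, p) >= passive_stress(Ls, p)


class TestContractility:
    def test_zero_before_activation(self, p):
        assert contractility(-0.05, 2.0, p) == 0.0
        assert contractility(0.0, 2.0, p) == 0.0

    def test_twitch_completes_within_cycle(self, p):
        # near-zero again by end of diastole at a physiological cycle
        assert contractility(0.84, 2.0, p) < 0.02

    def test_single_smooth_twitch(self, p):
        t = np.linspace(0, 0.84, 400)
        c = np.array([contractility(tk, 2.0, p) for tk in t])
        assert np.all(c >= 0)
        assert c.max() > 0.5
        # unimodal: rises then decays
        k = int(np.argmax(c))
        assert np.all(np.diff(c[:k]) >= -1e-12)
        assert np.all(np.diff(c[k:]) <= 1e-12)

    def test_duration_increases_with_cd(self, p):
        def fwhm(cd):
            q = p.replace(CD=cd)
            t = np.linspace(0, 1.2, 2000)
            c = np.array([contractility(tk, 2.0, q) for tk in t])
            half = c.max() / 2
            above = np.nonzero(c > half)[0]
            return t[above[-1]] - t[above[0]]
        assert fwhm(1.2 * p.CD) > fwhm(p.CD)

    def test_duration_increases_with_length(self, p):
        t = 0.55
        assert contractility(t, 2.2, p) > contractility(t, 1.8, p)

    def test_nonpositive_cd_rejected(self, p):
        with pytest.raises(ValueError):
            contractility(0.1, 2.0, p.replace(CD=-1.0))


class TestSarcomereRate:
    def test_equilibrium_at_reference_series_extension(self, p):
        st_ = SarcomereState(Ls=2.0 + p.Lse_iso, Lsi=2.0)
        assert sarcomere_rate(st_, p) == pytest.approx(0.0, abs=1e-12)

    def test_sign_convention(self, p):
        stretched = SarcomereState(Ls=2.0 + 2 * p.Lse_iso, Lsi=2.0)
        slack = SarcomereState(Ls=2.0 + 0.5 * p.Lse_iso, Lsi=2.0)
        assert sarcomere_rate(stretched, p) > 0
        assert sarcomere_rate(slack, p) < 0

    def test_velocity_scales_with_v_max(self, p):
        st_ = SarcomereState(Ls=2.0 + 2 * p.Lse_iso, Lsi=2.0)
        fast = p.replace(v_max=2 * p.v_max)
        assert sarcomere_rate(st_, fast) == pytest.approx(
            2 * sarcomere_rate(st_, p), rel=1e-12)


class TestParamValidation:
    @pytest.mark.parametrize("kw", [
        {"Ls0_pas": 0.0}, {"Lse_iso": -0.01}, {"k_ECM": 0.5},
        {"k2_tit": 0.0}, {"Sf_pas": -1.0},
    ])
    def test_invalid_parameters_rejected(self, kw):
        with pytest.raises(ValueError):
            SarcomereParams(**kw)

    def test_state_series_decomposition_holds(self):
        st_ = SarcomereState(Ls=2.2, Lsi=2.15)
        assert st_.Lse == pytest.approx(0.05)
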