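"""Two-compartment subdivision of a myocardial patch.

A wall patch of volume ``V_patch`` is split into a contractile compartment
``V_C = (1 - NCVF) * V_patch`` and a noncontractile compartment
``V_NC = NCVF * V_patch`` (``Sf_act = 0``; its mechanics reduce to the ECM
power law).  The two compartments are serially coupled: at every accepted
time point they carry the same fiber stress, and the patch-level sarcomere
length is the volume-weighted average of the compartment lengths.  NCVF
(noncontractile volume fraction) in [0, 1] quantifies contractile
dysfunction severity: 0 = healthy, 1 = fully noncontractile.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from numba import njit

from .sarcomere import (
    SarcomereParams,
    SarcomereState,
    _active_stress,
    _dpassive_dLs,
    _ecm_stress,
    _passive_stress,
)

__all__ = [
    "TwoCompartmentPatch",
    "CompartmentEquilibrium",
    "ncvf",
    "composite_sarcomere_length",
    "equilibrate_compartments",
    "split_at_length",
]

# Stress-balance tolerance (relative) and stiffness floor for the series law.
_SPLIT_RTOL = 1e-10
_STIFF_FLOOR = 1e-6   # kPa/um


def ncvf(V_NC: float, V_patch: float) -> float:
    """Noncontractile volume fraction V_NC / V_patch in [0, 1]."""
    if V_patch <= 0:
        raise ValueError("V_patch must be positive")
    if V_NC < 0 or V_NC > V_patch:
        raise ValueError("V_NC must lie in [0, V_patch]")
    return V_NC / V_patch


def composite_sarcomere_length(Ls_C: float, Ls_NC: float, NCVF: float) -> float:
    """Volume-weighted average sarcomere length of the patch."""
    if Ls_C <= 0 or Ls_NC <= 0:
        raise ValueError("sarcomere lengths must be positive")
    if not 0.0 <= NCVF <= 1.0:
        raise ValueError("NCVF must lie in [0, 1]")
    return (1.0 - NCVF) * Ls_C + NCVF * Ls_NC


@dataclass
class TwoCompartmentPatch:
    """A myocardial wall patch split into contractile/noncontractile parts."""

    V_patch: float
    NCVF: float
    contractile: SarcomereParams = field(default_factory=SarcomereParams)
    noncontractile: SarcomereParams | None = None
    state: SarcomereState = field(
        default_factory=lambda: SarcomereState(Ls=2.0, Lsi=1.96))
    activation_time: float = 0.0

    def __post_init__(self) -> None:
        if self.V_patch <= 0:
            raise ValueError("V_patch must be positive")
        if not 0.0 <= self.NCVF <= 1.0:
            raise ValueError("NCVF must lie in [0, 1]")
        if self.noncontractile is None:
            self.noncontractile = self.contractile.replace(Sf_act=0.0)
        elif self.noncontractile.Sf_act != 0.0:
            raise ValueError("noncontractile compartment must have Sf_act = 0")

    @property
    def V_C(self) -> float:
        return (1.0 - self.NCVF) * self.V_patch

    @property
    def V_NC(self) -> float:
        return self.NCVF * self.V_patch


@dataclass
class CompartmentEquilibrium:
    """Equal-stress solution of the serial coupling."""

    Ls: float        # composite patch sarcomere length (um)
    Ls_C: float      # contractile compartment length (um)
    Ls_NC: float     # noncontractile compartment length (um)
    sigma: float     # common fiber stress (kPa)
    sigma_C: float
    sigma_NC: float
    dsigma_dLs: float  # series stiffness of the composite patch (kPa/um)


# ---------------------------------------------------------------------------
# Kernels
# ---------------------------------------------------------------------------

@njit(cache=True)
def _sigma_contractile(LsC, Lsi, C, Sf_act, Sf_pas, Ls0_pas, k_ECM,
                       k1_tit, k2_tit, Lsi0_act, Lse_iso):
    """Total stress of the contractile compartment at length LsC."""
    s = _passive_stress(LsC, Sf_act, Sf_pas, Ls0_pas, k_ECM, k1_tit, k2_tit)
    s += _active_stress(Lsi, LsC - Lsi, C, Sf_act, Lsi0_act, Lse_iso)
    return s


@njit(cache=True)
def _dsigma_contractile(LsC, Lsi, C, Sf_act, Sf_pas, Ls0_pas, k_ECM,
                        k1_tit, k2_tit, Lsi0_act, Lse_iso):
    d = _dpassive_dLs(LsC, Sf_act, Sf_pas, Ls0_pas, k_ECM, k1_tit, k2_tit)
    d += Sf_act * C * (Lsi - Lsi0_act) / Lse_iso
    return d


@njit(cache=True)
def _split_equal_stress(Ls, Lsi, C, NCVF,
                        Sf_act, Sf_pas, Ls0_pas, k_ECM, k1_tit, k2_tit,
                        Lsi0_act, Lse_iso,
                        Sf_pas_nc, Ls0_pas_nc, k_ECM_nc,
                        LsNC_guess):
    """Solve the serial (equal-stress) split of a two-compartment patch.

    Given the composite length Ls and the contractile-element state
    (Lsi, C), find Ls_NC such that the noncontractile ECM stress equals the
    contractile compartment's total stress at
    Ls_C = (Ls - NCVF*Ls_NC)/(1-NCVF).

    Returns (Ls_C, Ls_NC, sigma, dsigma_dLs) where dsigma_dLs is the series
    stiffness of the composite patch.
    """
    if NCVF <= 0.0:
        sig = _sigma_contractile(Ls, Lsi, C, Sf_act, Sf_pas, Ls0_pas, k_ECM,
                                 k1_tit, k2_tit, Lsi0_act, Lse_iso)
        dsig = _dsigma_contractile(Ls, Lsi, C, Sf_act, Sf_pas, Ls0_pas, k_ECM,
                                   k1_tit, k2_tit, Lsi0_act, Lse_iso)
        return Ls, Ls, sig, max(dsig, _STIFF_FLOOR)
    if NCVF >= 1.0:
        sig = _ecm_stress(Ls, Sf_pas_nc, Ls0_pas_nc, k_ECM_nc)
        dsig = Sf_pas_nc * k_ECM_nc / Ls0_pas_nc * \
            (Ls / Ls0_pas_nc) ** (k_ECM_nc - 1.0)
        return Ls, Ls, sig, max(dsig, _STIFF_FLOOR)

    w = NCVF / (1.0 - NCVF)
    lo, hi = 0.3, 4.8
    s = LsNC_guess
    if not (lo < s < hi):
        s = Ls
    # Safeguarded Newton on f(s) = sigma_NC(s) - sigma_C(Ls_C(s)); f is
    # strictly increasing, so bisection brackets are maintained.
    f_lo = -1.0
    f_hi = 1.0
    for _ in range(80):
        LsC = (Ls - NCVF * s) / (1.0 - NCVF)
        if LsC <= 0.05:
            # nonphysical trial; pull back
            s = 0.5 * (s + lo)
            continue
        sig_nc = _ecm_stress(s, Sf_pas_nc, Ls0_pas_nc, k_ECM_nc)
        sig_c = _sigma_contractile(LsC, Lsi, C, Sf_act, Sf_pas, Ls0_pas,
                                   k_ECM, k1_tit, k2_tit, Lsi0_act, Lse_iso)
        f = sig_nc - sig_c
        scale = 1.0 + abs(sig_nc) + abs(sig_c)
        if abs(f) < _SPLIT_RTOL * scale:
            break
        if f > 0.0:
            hi = s
            f_hi = f
        else:
            lo = s
            f_lo = f
        d_nc = Sf_pas_nc * k_ECM_nc / Ls0_pas_nc * \
            (s / Ls0_pas_nc) ** (k_ECM_nc - 1.0)
        d_c = _dsigma_contractile(LsC, Lsi, C, Sf_act, Sf_pas, Ls0_pas,
                                  k_ECM, k1_tit, k2_tit, Lsi0_act, Lse_iso)
        fp = d_nc + w * d_c
        if fp > _STIFF_FLOOR:
            s_new = s - f / fp
        else:
            s_new = 0.5 * (lo + hi)
        if s_new <= lo or s_new >= hi:
            s_new = 0.5 * (lo + hi)
        s = s_new
    LsC = (Ls - NCVF * s) / (1.0 - NCVF)
    sig = _ecm_stress(s, Sf_pas_nc, Ls0_pas_nc, k_ECM_nc)
    d_nc = max(Sf_pas_nc * k_ECM_nc / Ls0_pas_nc *
               (s / Ls0_pas_nc) ** (k_ECM_nc - 1.0), _STIFF_FLOOR)
    d_c = max(_dsigma_contractile(LsC, Lsi, C, Sf_act, Sf_pas, Ls0_pas,
                                  k_ECM, k1_tit, k2_tit, Lsi0_act, Lse_iso),
              _STIFF_FLOOR)
    # series springs: compliances add with volume-fraction weights
    dsig = 1.0 / ((1.0 - NCVF) / d_c + NCVF / d_nc)
    return LsC, s, sig, dsig


# ---------------------------------------------------------------------------
# Public API
# ---------------------------------------------------------------------------

def _split(patch: TwoCompartmentPatch, Ls: float,
           guess: float) -> CompartmentEquilibrium:
    cp = patch.contractile
    np_ = patch.noncontractile
    st = patch.state
    LsC, LsNC, sig, dsig = _split_equal_stress(
        Ls, st.Lsi, st.C, patch.NCVF,
        cp.Sf_act, cp.Sf_pas, cp.Ls0_pas, cp.k_ECM, cp.k1_tit, cp.k2_tit,
        cp.Lsi0_act, cp.Lse_iso,
        np_.Sf_pas, np_.Ls0_pas, np_.k_ECM, guess)
    sig_c = _sigma_contractile(LsC, st.Lsi, st.C, cp.Sf_act, cp.Sf_pas,
                               cp.Ls0_pas, cp.k_ECM, cp.k1_tit, cp.k2_tit,
                               cp.Lsi0_act, cp.Lse_iso)
    sig_nc = _ecm_stress(LsNC, np_.Sf_pas, np_.Ls0_pas, np_.k_ECM)
    if patch.NCVF <= 0.0:
        sig_nc = sig_c
    if patch.NCVF >= 1.0:
        sig_c = sig_nc
    return CompartmentEquilibrium(
        Ls=composite_sarcomere_length(LsC, LsNC, patch.NCVF),
        Ls_C=LsC, Ls_NC=LsNC, sigma=sig,
        sigma_C=sig_c, sigma_NC=sig_nc, dsigma_dLs=dsig)


def split_at_length(patch: TwoCompartmentPatch,
                    Ls: float) -> CompartmentEquilibrium:
    """Equal-stress compartment split at a given composite length (um)."""
    if Ls <= 0:
        raise ValueError("Ls must be positive")
    eq = _split(patch, Ls, Ls)
    _check(eq, patch)
    return eq


def equilibrate_compartments(patch: TwoCompartmentPatch,
                             load: float) -> CompartmentEquilibrium:
    """Equal-stress compartment state under a prescribed fiber stress (kPa).

    Both compartments carry the common stress ``load``; the composite length
    follows as the volume-weighted average of the compartment lengths.
    Solved by bisection+Newton on the composite length.
    """
    lo, hi = 0.4, 4.6
    Ls = patch.state.Ls
    if not lo < Ls < hi:
        Ls = 2.0
    for _ in range(100):
        eq = _split(patch, Ls, Ls)
        f = eq.sigma - load
        if abs(f) < 1e-9 * (1.0 + abs(load)):
            break
        if f > 0:
            hi = Ls
        else:
            lo = Ls
        step = f / max(eq.dsigma_dLs, 1e-6)
        Ls_new = Ls - step
        if not lo < Ls_new < hi:
            Ls_new = 0.5 * (lo + hi)
        Ls = Ls_new
    else:
        raise RuntimeError(
            f"compartment stress balance did not converge (load={load} kPa, "
            f"NCVF={patch.NCVF}, residual={f:.3e} kPa)")
    _check(eq, patch)
    return eq


def _check(eq: CompartmentEquilibrium, patch: TwoCompartmentPatch) -> None:
    scale = 1.0 + abs(eq.sigma_C) + abs(eq.sigma_NC)
    if abs(eq.sigma_C - eq.sigma_NC) > 1e-6 * scale:
        raise RuntimeError(
            "equal-stress balance violated: sigma_C="
            f"{eq.sigma_C:.6g} kPa, sigma_NC={eq.sigma_NC:.6g} kPa "
            f"(NCVF={patch.NCVF}, Ls={eq.Ls:.4f} um)")
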