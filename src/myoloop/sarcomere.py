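"""Hill-type sarcomere mechanics.

A myofiber is modelled as a three-element Hill arrangement: a contractile
element of length ``Lsi`` in series with an elastic element of length
``Lse``, together spanning the sarcomere length ``Ls = Lsi + Lse``, and a
parallel elastic element carrying passive stress.  Active stress scales with
a dimensionless contractility ``C`` (a smooth twitch per beat), the length
excess of the contractile element over its zero-active-stress length, and
the relative extension of the series elastic element.  Passive stress is the
sum of an extracellular-matrix (ECM) power-law term and a titin term that
scales with the active stress scaling (so a fully noncontractile fiber with
``Sf_act = 0`` carries ECM stress only).

Units: lengths in um, stresses in kPa, time in s.  ``Sf_act`` carries
kPa/um so the active-stress product has stress units.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

from numba import njit

__all__ = [
    "SarcomereParams",
    "SarcomereState",
    "active_stress",
    "ecm_stress",
    "titin_stress",
    "passive_stress",
    "contractility",
    "sarcomere_rate",
]

# Twitch shape constants (fractions of the contraction-duration scale CD and
# the length dependence of twitch duration; see docs/methods.md).
_TAU_RISE_FRAC = 0.20
_TAU_DECAY_FRAC = 0.15
_TDUR_A = 0.29   # dimensionless
_TDUR_B = 0.30   # 1/um


@dataclass
class SarcomereParams:
    """Constitutive parameters of one myofiber compartment.

    Parameters
    ----------
    Sf_act : float
        Active stress scaling (kPa/um).
    Sf_pas : float
        ECM passive stress scaling (kPa).
    Ls0_pas : float
        Zero-passive-stress sarcomere length (um).
    k_ECM : float
        ECM nonlinearity exponent (>= 1).
    k1_tit, k2_tit : float
        Titin stress scaling (relative to ``Sf_act``) and nonlinearity.
    Lsi0_act : float
        Zero-active-stress contractile element length (um).
    Lse_iso : float
        Series-elastic element length at onset of isovolumetric
        contraction (um); sets the stress-free series extension.
    CD : float
        Contraction duration scaling (s); multiplies the twitch time scales.
    v_max : float
        Contractile-element sliding velocity scale (um/s).
    C_rest : float
        Resting (diastolic) contractility floor.
    """

    Sf_act: float = 180.0
    Sf_pas: float = 0.9
    Ls0_pas: float = 1.75
    k_ECM: float = 10.0
    k1_tit: float = 0.01
    k2_tit: float = 2.0
    Lsi0_act: float = 1.51
    Lse_iso: float = 0.04
    CD: float = 0.42
    v_max: float = 7.0
    C_rest: float = 0.0

    def __post_init__(self) -> None:
        if self.Ls0_pas <= 0:
            raise ValueError("Ls0_pas must be positive")
        if self.Lse_iso <= 0:
            raise ValueError("Lse_iso must be positive")
        if self.k_ECM < 1:
            raise ValueError("k_ECM must be >= 1")
        if self.k2_tit < 1:
            raise ValueError("k2_tit must be >= 1")
        if self.Sf_pas < 0 or self.Sf_act < 0:
            raise ValueError("stress scalings must be non-negative")

    def replace(self, **kw) -> "SarcomereParams":
        return replace(self, **kw)


@dataclass
class SarcomereState:
    """Instantaneous state of one myofiber compartment.

    ``Lse`` is derived (``Ls - Lsi``) so the series decomposition holds by
    construction.
    """

    Ls: float
    Lsi: float
    C: float = 0.0
    t_act: float = 0.0

    @property
    def Lse(self) -> float:
        return self.Ls - self.Lsi

    def __post_init__(self) -> None:
        if self.C < 0:
            raise ValueError("contractility C must be non-negative")


# ---------------------------------------------------------------------------
# Scalar kernels (njit; callable from Python and from the compiled engine)
# ---------------------------------------------------------------------------

@njit(cache=True)
def _active_stress(Lsi, Lse, C, Sf_act, Lsi0_act, Lse_iso):
    return Sf_act * C * (Lsi - Lsi0_act) * (Lse / Lse_iso)


@njit(cache=True)
def _ecm_stress(Ls, Sf_pas, Ls0_pas, k_ECM):
    return Sf_pas * ((Ls / Ls0_pas) ** k_ECM - 1.0)


@njit(cache=True)
def _titin_stress(Ls, Sf_act, k1_tit, k2_tit, Ls0_pas):
    return Sf_act * k1_tit * ((Ls / Ls0_pas) ** k2_tit - 1.0)


@njit(cache=True)
def _passive_stress(Ls, Sf_act, Sf_pas, Ls0_pas, k_ECM, k1_tit, k2_tit):
    return (_ecm_stress(Ls, Sf_pas, Ls0_pas, k_ECM)
            + _titin_stress(Ls, Sf_act, k1_tit, k2_tit, Ls0_pas))


@njit(cache=True)
def _dpassive_dLs(Ls, Sf_act, Sf_pas, Ls0_pas, k_ECM, k1_tit, k2_tit):
    d = Sf_pas * k_ECM / Ls0_pas * (Ls / Ls0_pas) ** (k_ECM - 1.0)
    d += Sf_act * k1_tit * k2_tit / Ls0_pas * (Ls / Ls0_pas) ** (k2_tit - 1.0)
    return d


@njit(cache=True)
def _contractility(t_act, Lsi, CD, C_rest):
    """Smooth single-twitch contractility.

    Product of a rise factor tanh((t/tau_r)^2), exactly zero at activation,
    and a sigmoid decay centred at a length-dependent twitch duration
    T_dur = CD * (a + b * Lsi).  Longer sarcomeres and larger CD prolong
    the twitch; before activation (t_act <= 0) C equals C_rest.
    """
    if t_act <= 0.0:
        return C_rest
    tau_r = _TAU_RISE_FRAC * CD
    tau_d = _TAU_DECAY_FRAC * CD
    t_dur = CD * (_TDUR_A + _TDUR_B * Lsi)
    x = t_act / tau_r
    rise = math.tanh(x * x)
    decay = 0.5 * (1.0 - math.tanh((t_act - t_dur) / tau_d))
    c = rise * decay
    return C_rest + (1.0 - C_rest) * c if C_rest > 0.0 else c


@njit(cache=True)
def _sarcomere_rate(Ls, Lsi, Lse_iso, v_max):
    """d(Lsi)/dt: monotone in the series-element extension.

    Zero when Lse = Lse_iso; positive (contractile element lengthening,
    cross-bridge slippage under load) when Lse > Lse_iso.
    """
    return ((Ls - Lsi) / Lse_iso - 1.0) * v_max


# ---------------------------------------------------------------------------
# Public API
# ---------------------------------------------------------------------------

def active_stress(state: SarcomereState, p: SarcomereParams) -> float:
    """Active fiber stress (kPa)."""
    if state.Lse < 0:
        raise ValueError(
            f"series elastic element compressed (Lse={state.Lse:.4f} um); "
            "outside the model domain")
    if state.C == 0.0:
        return 0.0
    return _active_stress(state.Lsi, state.Lse, state.C,
                          p.Sf_act, p.Lsi0_act, p.Lse_iso)


def ecm_stress(Ls: float, p: SarcomereParams) -> float:
    """Extracellular-matrix passive stress (kPa); signed below Ls0_pas."""
    if Ls <= 0:
        raise ValueError("Ls must be positive")
    return _ecm_stress(Ls, p.Sf_pas, p.Ls0_pas, p.k_ECM)


def titin_stress(Ls: float, p: SarcomereParams) -> float:
    """Titin passive stress (kPa); proportional to Sf_act."""
    if Ls <= 0:
        raise ValueError("Ls must be positive")
    return _titin_stress(Ls, p.Sf_act, p.k1_tit, p.k2_tit, p.Ls0_pas)


def passive_stress(Ls: float, p: SarcomereParams) -> float:
    """Total passive stress: ECM + titin (kPa)."""
    return ecm_stress(Ls, p) + titin_stress(Ls, p)


def contractility(t_act: float, Lsi: float, p: SarcomereParams) -> float:
    """Contractility state C >= 0 at time t_act after activation."""
    if p.CD <= 0:
        raise ValueError("CD must be positive")
    return _contractility(t_act, Lsi, p.CD, p.C_rest)


def total_stress(state: SarcomereState, p: SarcomereParams) -> float:
    """Active plus passive fiber stress (kPa)."""
    return active_stress(state, p) + passive_stress(state.Ls, p)


def sarcomere_rate(state: SarcomereState, p: SarcomereParams,
                   total_stress_demand: float | None = None) -> float:
    """Contractile-element velocity dLsi/dt (um/s).

    The series-element kinetics depend only on the extension of the series
    elastic element relative to Lse_iso; the stress demand argument is
    accepted for interface symmetry with the wall solver but the velocity
    law itself is purely kinematic.
    """
    return _sarcomere_rate(state.Ls, state.Lsi, p.Lse_iso, p.v_max)
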