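"""Strain and pressure-volume analysis.

Engineering strain relative to a reference sarcomere length, strain rate,
affine mapping of sarcomere length to a sonomicrometry-style segment
length, end-systole detection, and extraction of the end-systolic
pressure-volume relation (ESPVR, slope Emax and zero-pressure volume V0)
from afterload manipulations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .heart import BeatRecord, HeartModel

__all__ = [
    "StrainTrace",
    "ESPVRResult",
    "engineering_strain",
    "strain_rate",
    "map_segment_length",
    "detect_end_systole",
    "fit_espvr",
    "run_espvr_protocol",
    "beat_strain",
]


@dataclass
class StrainTrace:
    """Time-sampled strain of one segment."""

    time: np.ndarray        # s, strictly increasing
    strain: np.ndarray      # %
    segment: str = ""
    Ls_ref: float = 2.0     # um
    segment_length: np.ndarray | None = None  # mm, optional mapped SL(t)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.strain = np.asarray(self.strain, dtype=float)
        if self.time.ndim != 1 or self.time.size != self.strain.size:
            raise ValueError("time and strain must be 1-D and equal length")
        if np.any(np.diff(self.time) <= 0):
            raise ValueError("time must be strictly increasing")


@dataclass
class ESPVRResult:
    """Fitted end-systolic pressure-volume relation P = Emax (V - V0)."""

    points: np.ndarray      # (n, 2) end-systolic (volume ml, pressure mmHg)
    Emax: float             # mmHg/ml
    V0: float               # ml
    residual: float = 0.0   # RMS residual of the fit (mmHg)


def engineering_strain(Ls, Ls_ref: float):
    """Engineering strain (L/L_ref - 1) * 100, in percent."""
    if Ls_ref <= 0:
        raise ValueError("Ls_ref must be positive")
    return (np.asarray(Ls, dtype=float) / Ls_ref - 1.0) * 100.0


def strain_rate(strain, time=None, dt: float | None = None):
    """First-order finite-difference strain rate (%/s), length n-1.

    The samples are interval differences; with a uniform grid the value at
    index k applies to the midpoint of [t_k, t_k+1].
    """
    eps = np.asarray(strain, dtype=float)
    if eps.size < 2:
        raise ValueError("need at least 2 samples for a strain rate")
    if dt is None:
        if time is None:
            raise ValueError("provide either time or dt")
        t = np.asarray(time, dtype=float)
        steps = np.diff(t)
        if np.any(steps <= 0):
            raise ValueError("time must be strictly increasing")
        if not np.allclose(steps, steps[0], rtol=1e-6):
            raise ValueError("strain rate requires a uniform time grid")
        dt = float(steps[0])
    return np.diff(eps) / dt


def map_segment_length(Ls, Ls_ED_baseline: float, SL_exp_ED_baseline: float):
    """Map sarcomere length (um) to measured segment length (mm).

    Affine-through-zero calibration fixed at the baseline end-diastolic
    point: SL(t) = Ls(t) * SL_exp_ED(baseline) / Ls_ED(baseline).
    """
    if Ls_ED_baseline <= 0 or SL_exp_ED_baseline <= 0:
        raise ValueError("calibration lengths must be positive")
    return np.asarray(Ls, dtype=float) * (SL_exp_ED_baseline / Ls_ED_baseline)


def detect_end_systole(beat: BeatRecord, method: str = "valve",
                       v0_guess: float = 0.0) -> int:
    """Index of end-systole in a steady-state beat.

    ``"valve"`` (default): closure of the aortic valve (ejection flow
    returning to zero).  ``"elastance"``: sample maximising the elastance
    surrogate P/(V - v0_guess).
    """
    if method == "valve":
        return beat.aortic_valve_close_index()
    if method == "elastance":
        k0 = beat.aortic_valve_open_index()  # raises if no ejection
        v = beat.V_LV
        p = beat.p_LV
        denom = np.maximum(v - v0_guess, 1e-6)
        return int(np.argmax(p / denom))
    raise ValueError(f"unknown end-systole method: {method!r}")


def fit_espvr(points) -> ESPVRResult:
    """Least-squares line P = Emax (V - V0) through end-systolic points."""
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 2:
        raise ValueError("need >= 2 (volume, pressure) points")
    v = pts[:, 0]
    p = pts[:, 1]
    if np.ptp(v) < 1e-12:
        raise ValueError("end-systolic volumes are identical; slope undefined")
    A = np.vstack([v, np.ones_like(v)]).T
    coef, *_ = np.linalg.lstsq(A, p, rcond=None)
    emax, c = coef
    resid = float(np.sqrt(np.mean((A @ coef - p) ** 2)))
    return ESPVRResult(points=pts, Emax=float(emax), V0=float(-c / emax),
                       residual=resid)


def run_espvr_protocol(model: HeartModel,
                       factors=(0.8, 1.0, 1.2),
                       es_method: str = "valve",
                       beats_max: int = 120) -> ESPVRResult:
    """ESPVR from afterload manipulations of a converged reference model.

    The model must be at its regulated reference steady state.  For each
    afterload factor, regulation is disabled, peripheral arterial
    resistance is scaled, the model is run to a new steady state, and the
    end-systolic (V, P) point is collected; a line is fitted through the
    points.
    """
    pts = []
    for f in factors:
        mm = model.clone()
        mm.regulation_enabled = False
        mm.set_afterload(f)
        beat = mm.run_to_steady_state(beats_max=beats_max)
        k = detect_end_systole(beat, method=es_method)
        pts.append((beat.V_LV[k], beat.p_LV[k]))
    return fit_espvr(np.array(pts))


def beat_strain(beat: BeatRecord, patch: int,
                reference: str = "onset") -> StrainTrace:
    """Engineering strain trace of one patch over a beat.

    ``reference="onset"`` references the sample at ventricular activation
    (beat onset, the conventional QRS-like reference); ``"ed"`` references
    the sample of maximal LV volume (end-diastole).  The two nearly
    coincide with simultaneous activation.
    """
    Ls = beat.patch_Ls(patch)
    if reference == "onset":
        ref = Ls[beat.act_index]
    elif reference == "ed":
        ref = Ls[int(np.argmax(beat.V_LV))]
    else:
        raise ValueError("reference must be 'onset' or 'ed'")
    name = beat.patch_names[patch] if beat.patch_names else str(patch)
    return StrainTrace(time=beat.t, strain=engineering_strain(Ls, ref),
                       segment=name, Ls_ref=float(ref))
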