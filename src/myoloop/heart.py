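"""Closed-loop heart and circulation model (user-facing API).

Wraps the compiled engine: builds parameter arrays from a configuration
dictionary, advances whole beats on a fixed output grid (<= 2 ms), applies
between-beat homeostatic pressure-flow regulation (peripheral resistance
and circulating volume adjusted toward MAP and SV targets), and exposes
beat records with cavity pressures, volumes, flows and per-patch sarcomere
traces.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np

from . import _engine as eng
from .defaults import reference_config

__all__ = ["HeartModel", "BeatRecord", "WALL_NAMES"]

WALL_NAMES = ("lv", "sw", "rv", "la", "ra")

_SARC_KEYS = ["Sf_act", "Sf_pas", "Ls0_pas", "k_ECM", "k1_tit", "k2_tit",
              "Lsi0_act", "Lse_iso", "v_max", "CD", "C_rest"]


def _merge(base: dict, override: dict) -> dict:
    out = copy.deepcopy(base)
    for k, v in (override or {}).items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = copy.deepcopy(v)
    return out


@dataclass
class BeatRecord:
    """One beat sampled on the fixed output grid."""

    t: np.ndarray          # (n,) s, starting at 0 (atrial activation)
    y: np.ndarray          # (n, ny) raw state
    aux: np.ndarray        # (n, naux) pressures/tensions/patch traces
    n_patch: int
    patch_walls: np.ndarray
    patch_names: list = field(default_factory=list)
    act_index: int = 0     # sample of ventricular activation (beat onset)

    # -- hemodynamic channels ------------------------------------------------
    @property
    def V_LV(self):
        return self.y[:, eng.IY_VLV]

    @property
    def V_RV(self):
        return self.y[:, eng.IY_VRV]

    @property
    def V_LA(self):
        return self.y[:, eng.IY_VLA]

    @property
    def V_RA(self):
        return self.y[:, eng.IY_VRA]

    @property
    def p_LV(self):
        return self.aux[:, eng.IA_PLV]

    @property
    def p_RV(self):
        return self.aux[:, eng.IA_PRV]

    @property
    def p_LA(self):
        return self.aux[:, eng.IA_PLA]

    @property
    def p_SyArt(self):
        return self.aux[:, eng.IA_PSA]

    @property
    def q_Ao(self):
        return np.maximum(self.y[:, eng.IY_QAO], 0.0)

    @property
    def q_Mi(self):
        return np.maximum(self.y[:, eng.IY_QMI], 0.0)

    # -- per-patch sarcomere traces -------------------------------------------
    def patch_Ls(self, i: int) -> np.ndarray:
        return self.aux[:, eng.NAUXG + 4 * i + 0]

    def patch_Ls_C(self, i: int) -> np.ndarray:
        return self.aux[:, eng.NAUXG + 4 * i + 1]

    def patch_Ls_NC(self, i: int) -> np.ndarray:
        return self.aux[:, eng.NAUXG + 4 * i + 2]

    def patch_stress(self, i: int) -> np.ndarray:
        return self.aux[:, eng.NAUXG + 4 * i + 3]

    # -- scalar summaries ------------------------------------------------------
    @property
    def EDV(self) -> float:
        """End-diastolic volume: maximum LV volume over the beat (ml)."""
        return float(self.V_LV.max())

    @property
    def ESV(self) -> float:
        return float(self.V_LV.min())

    @property
    def EF(self) -> float:
        return 100.0 * (self.EDV - self.ESV) / self.EDV

    @property
    def MAP(self) -> float:
        return float(np.mean(self.p_SyArt[:-1]))

    @property
    def peak_p_LV(self) -> float:
        return float(self.p_LV.max())

    @property
    def stroke_volume(self) -> float:
        return float(np.trapezoid(self.q_Ao, self.t))

    def aortic_valve_open_index(self) -> int:
        nz = np.nonzero(self.q_Ao > 1e-9)[0]
        if nz.size == 0:
            raise RuntimeError("aortic valve never opened during this beat")
        return int(nz[0])

    def aortic_valve_close_index(self) -> int:
        """First sample after ejection at which aortic flow returns to zero."""
        nz = np.nonzero(self.q_Ao > 1e-9)[0]
        if nz.size == 0:
            raise RuntimeError("aortic valve never opened during this beat")
        after = np.nonzero(self.q_Ao[nz[-1]:] <= 1e-9)[0]
        if after.size:
            return int(nz[-1] + after[0])
        return int(nz[-1])

    def summary(self) -> dict:
        return {"EDV": self.EDV, "ESV": self.ESV, "EF": self.EF,
                "MAP": self.MAP, "peak_p_LV": self.peak_p_LV,
                "SV": self.stroke_volume}


class HeartModel:
    """Closed-loop lumped heart + circulation with MultiPatch walls."""

    def __init__(self, config: dict | None = None):
        self.config = _merge(reference_config(), config or {})
        self._build()

    # ------------------------------------------------------------------ build
    def _build(self) -> None:
        cfg = self.config
        hr = float(cfg["heart_rate"])
        if hr <= 0:
            raise ValueError("heart_rate must be positive")
        tc = 60.0 / hr
        dt_max = float(cfg["solver"]["dt"])
        if dt_max > 0.002 + 1e-12:
            raise ValueError("solver dt must be <= 2 ms")
        n_steps = int(np.ceil(tc / dt_max - 1e-9))
        self.n_steps_beat = n_steps
        self.dt = tc / n_steps

        gp = np.zeros(eng.NGP)
        circ = cfg["circulation"]
        gp[eng.GP_TC] = tc
        gp[eng.GP_DT] = self.dt
        gp[eng.GP_RSYS] = circ["r_sys"]
        gp[eng.GP_RPULM] = circ["r_pulm"]
        gp[eng.GP_RSV] = circ["r_sys_venous"]
        gp[eng.GP_RPV] = circ["r_pulm_venous"]
        gp[eng.GP_CSA] = circ["c_syart"]
        gp[eng.GP_CSV] = circ["c_syven"]
        gp[eng.GP_CPA] = circ["c_puart"]
        gp[eng.GP_CPV] = circ["c_puven"]
        gp[eng.GP_V0SA] = circ["v0_syart"]
        gp[eng.GP_V0SV] = circ["v0_syven"]
        gp[eng.GP_V0PA] = circ["v0_puart"]
        gp[eng.GP_V0PV] = circ["v0_puven"]
        gp[eng.GP_LVALVE] = circ["valve_inertance"]
        gp[eng.GP_BMI] = circ["bernoulli"]["mi"]
        gp[eng.GP_BAO] = circ["bernoulli"]["ao"]
        gp[eng.GP_BTR] = circ["bernoulli"]["tr"]
        gp[eng.GP_BPU] = circ["bernoulli"]["pu"]
        gp[eng.GP_TACTV] = cfg["activation"]["t_ventricle"]
        gp[eng.GP_TACTA] = cfg["activation"]["t_atria"]
        gp[eng.GP_LSREF] = cfg["ls_ref"]
        gp[eng.GP_RLVALVE] = circ["valve_resistance"]
        gp[eng.GP_ERRTOL] = cfg["solver"]["err_tol"]
        self.gp = gp

        rows = []
        pwall = []
        names = []
        for w, wname in enumerate(WALL_NAMES):
            wcfg = cfg["walls"][wname]
            base = dict(cfg["sarcomere"])
            if wname in ("la", "ra"):
                base.update(cfg.get("atrial_sarcomere", {}))
            patches = wcfg["patches"]
            shares = np.array([float(p.get("share", 1.0)) for p in patches])
            if np.any(shares <= 0):
                raise ValueError(f"patch shares must be positive in {wname}")
            shares = shares / shares.sum()
            for j, (pcfg, share) in enumerate(zip(patches, shares)):
                sp = dict(base)
                for key in _SARC_KEYS:
                    if key in pcfg:
                        sp[key] = pcfg[key]
                if "sf_act_scale" in pcfg:
                    sp["Sf_act"] = sp["Sf_act"] * float(pcfg["sf_act_scale"])
                ncvf = float(pcfg.get("ncvf", 0.0))
                if not 0.0 <= ncvf <= 1.0:
                    raise ValueError("ncvf must lie in [0, 1]")
                row = np.zeros(eng.NPP)
                row[eng.PP_VW] = wcfg["wall_volume"] * share
                row[eng.PP_AMREF] = wcfg["am_ref"] * share
                row[eng.PP_NCVF] = ncvf
                row[eng.PP_SFACT] = sp["Sf_act"]
                row[eng.PP_SFPAS] = sp["Sf_pas"]
                row[eng.PP_LS0PAS] = sp["Ls0_pas"]
                row[eng.PP_KECM] = sp["k_ECM"]
                row[eng.PP_K1TIT] = sp["k1_tit"]
                row[eng.PP_K2TIT] = sp["k2_tit"]
                row[eng.PP_LSI0] = sp["Lsi0_act"]
                row[eng.PP_LSEISO] = sp["Lse_iso"]
                row[eng.PP_VMAX] = sp["v_max"]
                row[eng.PP_CD] = sp["CD"]
                row[eng.PP_ACTOFF] = float(pcfg.get("act_offset", 0.0))
                row[eng.PP_SFPASNC] = float(
                    pcfg.get("sf_pas_nc", sp["Sf_pas"]))
                row[eng.PP_LS0PASNC] = float(
                    pcfg.get("ls0_pas_nc", sp["Ls0_pas"]))
                row[eng.PP_KECMNC] = float(pcfg.get("k_ecm_nc", sp["k_ECM"]))
                row[eng.PP_CREST] = sp["C_rest"]
                rows.append(row)
                pwall.append(w)
                names.append(pcfg.get("name", f"{wname}{j}"))
        self.PP = np.array(rows)
        self.pwall = np.array(pwall, dtype=np.int64)
        self.patch_names = names
        self.n_patch = len(rows)
        self.VwWall = np.array(
            [self.PP[self.pwall == w, eng.PP_VW].sum() for w in range(5)])

        # initial state
        ny = 12 + self.n_patch
        y = np.zeros(ny)
        iv = circ["init_volumes"]
        ip = circ["init_pressures"]
        y[eng.IY_VLV] = iv["lv"]
        y[eng.IY_VRV] = iv["rv"]
        y[eng.IY_VLA] = iv["la"]
        y[eng.IY_VRA] = iv["ra"]
        y[eng.IY_VSA] = circ["v0_syart"] + circ["c_syart"] * ip["syart"]
        y[eng.IY_VSV] = circ["v0_syven"] + circ["c_syven"] * ip["syven"]
        y[eng.IY_VPA] = circ["v0_puart"] + circ["c_puart"] * ip["puart"]
        y[eng.IY_VPV] = circ["v0_puven"] + circ["c_puven"] * ip["puven"]
        y[eng.IY_LSI0:] = 1.95
        self.y = y

        cache = np.zeros(eng.IC_PATCH + 2 * self.n_patch)
        cache[eng.IC_VS] = 35.0
        cache[eng.IC_YM] = 3.2
        cache[eng.IC_XM + 0] = -3.0
        cache[eng.IC_XM + 1] = 1.2
        cache[eng.IC_XM + 2] = 3.0
        cache[eng.IC_CM + 0] = -0.30
        cache[eng.IC_CM + 1] = 0.25
        cache[eng.IC_CM + 2] = 0.30
        cache[eng.IC_CM + 3] = 0.45
        cache[eng.IC_CM + 4] = 0.45
        cache[eng.IC_PATCH::2] = 2.0
        cache[eng.IC_PATCH + 1::2] = 2.0
        self.cache = cache

        self.t = 0.0
        # derivative-evaluation budget per grid step; pathological
        # parameter sets abort instead of crawling (see _engine._run_steps)
        self.eval_budget_per_step = 200
        reg = cfg["regulation"]
        self.regulation_enabled = bool(reg["enabled"])
        self.map_target = float(reg["map"])
        self.sv_target = float(reg["sv"])
        self._gain_r = float(reg["gain_r"])
        self._gain_v = float(reg["gain_v"])
        self.last_beat: BeatRecord | None = None

    # ------------------------------------------------------------- operations
    def clone(self) -> "HeartModel":
        m = copy.copy(self)
        m.config = copy.deepcopy(self.config)
        m.gp = self.gp.copy()
        m.PP = self.PP.copy()
        m.pwall = self.pwall.copy()
        m.VwWall = self.VwWall.copy()
        m.y = self.y.copy()
        m.cache = self.cache.copy()
        m.patch_names = list(self.patch_names)
        return m

    @property
    def cycle_time(self) -> float:
        return self.gp[eng.GP_TC]

    @property
    def r_art(self) -> float:
        return self.gp[eng.GP_RSYS]

    @r_art.setter
    def r_art(self, value: float) -> None:
        if value <= 0:
            raise ValueError("arterial resistance must be positive")
        self.gp[eng.GP_RSYS] = value

    def set_afterload(self, factor: float) -> "HeartModel":
        """Scale peripheral arterial resistance (regulation must be off)."""
        if factor <= 0:
            raise ValueError("afterload factor must be positive")
        if self.regulation_enabled:
            raise RuntimeError(
                "disable homeostatic regulation before manipulating afterload")
        self.gp[eng.GP_RSYS] *= factor
        return self

    def total_blood_volume(self) -> float:
        return float(self.y[:8].sum())

    def step(self, dt: float | None = None) -> None:
        """Advance a single output-grid step (dt <= 2 ms)."""
        dt = self.dt if dt is None else float(dt)
        if dt > 0.002 + 1e-12:
            raise ValueError("dt must be <= 2 ms")
        gp = self.gp.copy()
        gp[eng.GP_DT] = dt
        naux = eng.NAUXG + 4 * self.n_patch
        ry = np.empty((2, self.y.size))
        ra = np.empty((2, naux))
        self.t, status, _, _ = eng._run_steps(
            self.t, 1, self.y, gp, self.PP, self.pwall, self.VwWall,
            self.cache, ry, ra, False, self.eval_budget_per_step)
        if status:
            raise RuntimeError("integration budget exhausted in step()")

    def run_beat(self, record: bool = True) -> BeatRecord | None:
        """Advance one full cardiac cycle; apply regulation afterwards."""
        n = self.n_steps_beat
        naux = eng.NAUXG + 4 * self.n_patch
        if record:
            rec_y = np.empty((n + 1, self.y.size))
            rec_aux = np.empty((n + 1, naux))
        else:
            rec_y = np.empty((1, self.y.size))
            rec_aux = np.empty((1, naux))
        self.t, status, map_m, sv_m = eng._run_steps(
            self.t, n, self.y, self.gp, self.PP, self.pwall, self.VwWall,
            self.cache, rec_y, rec_aux, record,
            self.eval_budget_per_step * n)
        if status:
            raise RuntimeError(
                "integration budget exhausted: the model is pathologically "
                "stiff for this parameter set")
        beat = None
        if record:
            beat = BeatRecord(
                t=np.arange(n + 1) * self.dt, y=rec_y, aux=rec_aux,
                n_patch=self.n_patch, patch_walls=self.pwall.copy(),
                patch_names=list(self.patch_names),
                act_index=int(round(self.gp[eng.GP_TACTV] / self.dt)))
            self.last_beat = beat
        if self.regulation_enabled:
            self._regulate(map_m, sv_m)
        return beat

    def _regulate(self, map_m: float, sv_m: float) -> None:
        if map_m <= 1.0 or sv_m <= 0.5:
            return
        # dead band: a model at target is a fixed point of the beat map
        if (abs(map_m - self.map_target) < 0.3
                and abs(sv_m - self.sv_target) < 0.3):
            return
        fac = (self.map_target / map_m) ** self._gain_r
        self.gp[eng.GP_RSYS] *= min(max(fac, 0.7), 1.4)
        dv = self._gain_v * (self.sv_target - sv_m)
        dv = min(max(dv, -60.0), 60.0)
        self.y[eng.IY_VSV] = max(self.y[eng.IY_VSV] + dv, 10.0)

    def run_to_steady_state(self, beats_max: int = 100, tol_edv: float = 0.1,
                            tol_map: float = 0.2) -> BeatRecord:
        """Run beats until the periodic solution is reached.

        Convergence: beat-to-beat change in EDV below ``tol_edv`` (ml) and
        in MAP below ``tol_map`` (mmHg); with regulation enabled, MAP and SV
        must additionally sit within 0.5 units of their targets.
        """
        prev = None
        for _ in range(beats_max):
            beat = self.run_beat(record=True)
            if prev is not None:
                d_edv = abs(beat.EDV - prev.EDV)
                d_map = abs(beat.MAP - prev.MAP)
                ok = d_edv < tol_edv and d_map < tol_map
                if ok and self.regulation_enabled:
                    ok = (abs(beat.MAP - self.map_target) < 0.5
                          and abs(beat.stroke_volume - self.sv_target) < 0.5)
                if ok:
                    return beat
            prev = beat
        raise RuntimeError(
            f"no steady state within {beats_max} beats "
            f"(EDV={beat.EDV:.2f} ml, MAP={beat.MAP:.2f} mmHg, "
            f"SV={beat.stroke_volume:.2f} ml; regulation="
            f"{self.regulation_enabled})")

    # ------------------------------------------------------- parameter access
    def lv_patch_indices(self) -> np.ndarray:
        """Indices of patches in the LV free wall and septum."""
        return np.nonzero(self.pwall <= 1)[0]

    def set_patch(self, i: int, *, ncvf: float | None = None,
                  ls0_pas_nc: float | None = None,
                  k_ecm_nc: float | None = None,
                  sf_act_scale: float | None = None) -> None:
        if ncvf is not None:
            if not 0.0 <= ncvf <= 1.0:
                raise ValueError("ncvf must lie in [0, 1]")
            self.PP[i, eng.PP_NCVF] = ncvf
        if ls0_pas_nc is not None:
            self.PP[i, eng.PP_LS0PASNC] = ls0_pas_nc
        if k_ecm_nc is not None:
            self.PP[i, eng.PP_KECMNC] = k_ecm_nc
        if sf_act_scale is not None:
            self.PP[i, eng.PP_SFACT] *= sf_act_scale

    def scale_lv_wall_area(self, factor: float) -> None:
        """Scale the midwall reference area of all LV + septal patches."""
        idx = self.lv_patch_indices()
        self.PP[idx, eng.PP_AMREF] *= factor

    def set_contraction_duration(self, cd: float) -> None:
        if cd <= 0:
            raise ValueError("CD must be positive")
        ventr = np.nonzero(self.pwall <= 2)[0]
        self.PP[ventr, eng.PP_CD] = cd
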